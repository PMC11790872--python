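"""Heavy-metal pollution indices: HPI, MI, and the ecological risk index RI.

HPI (heavy-metal pollution index) is the weighted arithmetic mean of
sub-indices::

    Q_i = 100 * C_i / S_i        W_i = 1 / S_i
    HPI = sum(W_i * Q_i) / sum(W_i)

so a water exactly at every standard limit scores 100.  MI (metal index)
is the plain sum of concentration-to-limit ratios ``sum(C_i / UAL_i)``;
it is additive in the concentrations.  RI is Hakanson's potential
ecological risk index ``RI = sum(E_r^i)`` with per-metal risk factors
``E_r^i = T_r^i * C_i / C_bg^i`` (toxic-response factor times the
contamination factor against a background level).

Classification scales are half-open interval lookups; a value exactly on
a printed boundary belongs to the upper (worse) class, which makes the
scales contiguous even where published wordings leave gaps (25/26, 6/...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .sample_io import ReferenceRegistry, SampleRecord, SurveyTable

__all__ = [
    "IndexResult",
    "EcologicalRisk",
    "SCALES",
    "hpi",
    "mi",
    "ri",
    "classify_index",
    "survey_index_report",
]


@dataclass(frozen=True)
class IndexResult:
    value: float
    class_label: str
    per_metal_terms: Mapping[str, float]


@dataclass(frozen=True)
class EcologicalRisk:
    """Per-sample ecological risk: contamination factors, risk factors, RI."""

    cf: Mapping[str, float]  # C_i / C_bg per metal
    er: Mapping[str, float]  # T_r * cf per metal
    ri: float
    class_label: str


#: Named classification scales as (lower bound, label) steps; intervals are
#: half-open and the last label is open-ended.
SCALES: dict[str, tuple[tuple[float, str], ...]] = {
    "hpi": (
        (0.0, "very low"),
        (25.0, "low"),
        (50.0, "medium"),
        (75.0, "high"),
        (100.0, "unsuitable"),
    ),
    "mi": (
        (0.0, "very clean"),
        (0.3, "clean"),
        (1.0, "partly affected"),
        (2.0, "moderately affected"),
        (4.0, "heavily affected"),
        (6.0, "severely affected"),
    ),
    "ri": (
        (0.0, "low"),
        (30.0, "moderate"),
        (60.0, "considerable"),
        (120.0, "very high"),
    ),
}


def classify_index(value: float, scale: str) -> str:
    """Half-open-interval class lookup on a registered scale."""
    if scale not in SCALES:
        raise KeyError(f"unknown classification scale {scale!r}")
    if value < 0:
        raise ValueError("index value must be non-negative")
    label = SCALES[scale][0][1]
    for bound, lab in SCALES[scale]:
        if value >= bound:
            label = lab
    return label


def hpi(sample: SampleRecord, registry: ReferenceRegistry) -> IndexResult:
    """Weighted-mean pollution index over the registry's metals."""
    weights = {}
    terms = {}
    for sym, ref in registry.metals.items():
        if ref.standard_limit_S <= 0:
            raise ValueError(f"{sym}: standard limit must be positive")
        w = 1.0 / ref.standard_limit_S
        q = 100.0 * sample.value(sym) / ref.standard_limit_S
        weights[sym] = w
        terms[sym] = w * q
    value = math.fsum(terms.values()) / math.fsum(weights.values())
    return IndexResult(value, classify_index(value, "hpi"), terms)


def mi(sample: SampleRecord, registry: ReferenceRegistry) -> IndexResult:
    """Metal index: sum of concentration-to-UAL ratios."""
    terms = {}
    for sym, ref in registry.metals.items():
        if ref.ual <= 0:
            raise ValueError(f"{sym}: UAL must be positive")
        terms[sym] = sample.value(sym) / ref.ual
    value = math.fsum(terms.values())
    return IndexResult(value, classify_index(value, "mi"), terms)


def ri(
    survey: SurveyTable,
    registry: ReferenceRegistry,
    included_metals: Iterable[str] | None = None,
    backgrounds: Mapping[str, float] | None = None,
) -> dict[str, EcologicalRisk]:
    """Potential ecological risk index per sample.

    Metals default to those with a toxic-response factor in the registry
    (iron carries none and is excluded).  Background levels come from
    *backgrounds* or the registry; metals missing either a T_r or a
    background are reported in one error.
    """
    if included_metals is None:
        included_metals = [
            s for s, ref in registry.metals.items() if ref.toxic_response_Tr is not None
        ]
    included_metals = list(included_metals)
    backgrounds = dict(backgrounds or {})

    missing = []
    for sym in included_metals:
        ref = registry.metals[sym]
        if ref.toxic_response_Tr is None:
            missing.append(f"{sym} (no toxic-response factor)")
        if backgrounds.get(sym, ref.background_Cbg) is None:
            missing.append(f"{sym} (no background level)")
    if missing:
        raise ValueError("RI needs: " + ", ".join(missing))

    out = {}
    for sample in survey.records:
        cf = {}
        er = {}
        for sym in included_metals:
            ref = registry.metals[sym]
            bg = backgrounds.get(sym, ref.background_Cbg)
            cf[sym] = sample.value(sym) / bg
            er[sym] = ref.toxic_response_Tr * cf[sym]
        total = math.fsum(er.values())
        out[sample.sample_id] = EcologicalRisk(
            cf=cf, er=er, ri=total, class_label=classify_index(total, "ri")
        )
    return out


def survey_index_report(
    survey: SurveyTable,
    registry: ReferenceRegistry,
    backgrounds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """HPI and MI (plus RI when backgrounds are available) per sample."""
    rows = []
    try:
        eco = ri(survey, registry, backgrounds=backgrounds)
    except ValueError:
        eco = None
    for sample in survey.records:
        h = hpi(sample, registry)
        m = mi(sample, registry)
        row = {
            "sample_id": sample.sample_id,
            "site_name": sample.site_name,
            "hpi": h.value,
            "hpi_class": h.class_label,
            "mi": m.value,
            "mi_class": m.class_label,
        }
        if eco is not None:
            row["ri"] = eco[sample.sample_id].ri
            row["ri_class"] = eco[sample.sample_id].class_label
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
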