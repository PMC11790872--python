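"""PAH aggregation, diagnostic source ratios, and risk quotients.

Sixteen parent PAHs are grouped by aromatic ring count into low molecular
weight (LPAH, 2-3 rings) and high molecular weight (HPAH, 4-6 rings)
compounds, plus a carcinogenic (CAR) subgroup.  Source apportionment uses
the classical isomer-pair diagnostic ratios: LPAH/HPAH, Phe/Ant, Flu/Pyr,
Flu/(Flu+Pyr) and BaA/(BaA+Chry).  Petrogenic signatures point to spilled
or seeping petroleum; pyrogenic signatures to combustion residues.

Ecotoxicological screening uses risk quotients against two quality values
per compound: RQ_NC = C/NC (negligible concentration) and RQ_MPC = C/MPC
(maximum permissible concentration), with the standard four-grade rule:

=========  =======================================
grade      rule
=========  =======================================
high       RQ_NC >= 800 and RQ_MPC >= 1
moderate   RQ_NC < 800 and RQ_MPC >= 1
low        RQ_MPC < 1 and RQ_NC >= 1
negligible RQ_NC < 1
=========  =======================================

Concentrations are µg/L, quality values ng/L (factor 1000 applied inside
:func:`rq`).  All thresholds are half-open: a ratio exactly on a boundary
belongs to the upper class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .sample_io import (
    ReferenceRegistry,
    SampleRecord,
    SurveyTable,
    SurveySchemaError,
)

__all__ = [
    "PAHSummary",
    "DiagnosticRatios",
    "RQResult",
    "DEFAULT_RATIO_RULES",
    "total_pahs",
    "group_totals",
    "diagnostic_ratios",
    "classify_source",
    "rq",
    "site_total_rq",
    "grade_rq",
    "toc_summary",
    "survey_pah_report",
]


@dataclass(frozen=True)
class PAHSummary:
    total: float  # µg/L, sum over the 16 compounds
    car_total: float  # µg/L, carcinogenic subgroup
    lpah_total: float  # µg/L, 2-3 ring compounds
    hpah_total: float  # µg/L, 4-6 ring compounds


@dataclass(frozen=True)
class DiagnosticRatios:
    """Source-diagnostic ratios; ``None`` marks an undefined ratio (zero
    denominator), never 0 or infinity."""

    lmw_hmw: float | None
    phe_ant: float | None
    flu_pyr: float | None
    flu_flupyr: float | None  # Flu/(Flu+Pyr), in [0, 1] when defined
    baa_baachry: float | None  # BaA/(BaA+Chry), in [0, 1] when defined


@dataclass(frozen=True)
class RQResult:
    rq_nc: float
    rq_mpc: float

    @property
    def grade(self) -> str:
        return grade_rq(self)


def _require(sample: SampleRecord, compounds) -> None:
    missing = [c for c in compounds if c not in sample.measurements]
    if missing:
        raise SurveySchemaError(
            f"sample {sample.sample_id}: missing PAH column(s) {missing}"
        )


def total_pahs(sample: SampleRecord, registry: ReferenceRegistry) -> float:
    """Arithmetic sum (µg/L) over the registered compounds.

    Non-detects must have been substituted; an all-ND sample under the
    zero policy sums to 0.
    """
    _require(sample, registry.pahs)
    return math.fsum(sample.value(c) for c in registry.pahs)


def group_totals(sample: SampleRecord, registry: ReferenceRegistry) -> PAHSummary:
    """Total, carcinogenic (CAR), LPAH, and HPAH sums for one sample."""
    _require(sample, registry.pahs)
    car = lpah = hpah = 0.0
    for ab, ref in registry.pahs.items():
        v = sample.value(ab)
        if ref.carcinogenic:
            car += v
        if ref.weight_class == "LPAH":
            lpah += v
        else:
            hpah += v
    return PAHSummary(
        total=total_pahs(sample, registry),
        car_total=car,
        lpah_total=lpah,
        hpah_total=hpah,
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def diagnostic_ratios(
    sample: SampleRecord, registry: ReferenceRegistry
) -> DiagnosticRatios:
    """All five source-diagnostic ratios; zero denominators yield ``None``."""
    s = group_totals(sample, registry)
    phe, ant = sample.value("Phe"), sample.value("Ant")
    flu, pyr = sample.value("Flu"), sample.value("Pyr")
    baa, chry = sample.value("BaA"), sample.value("Chry")
    return DiagnosticRatios(
        lmw_hmw=_ratio(s.lpah_total, s.hpah_total),
        phe_ant=_ratio(phe, ant),
        flu_pyr=_ratio(flu, pyr),
        flu_flupyr=_ratio(flu, flu + pyr),
        baa_baachry=_ratio(baa, baa + chry),
    )


#: Default per-ratio classification rules.  Each rule is a list of
#: ``(lower_bound, label)`` applied to half-open intervals from the last
#: bound upward; a value exactly on a bound takes the upper class.
DEFAULT_RATIO_RULES: dict[str, tuple[tuple[float, str], ...]] = {
    # LPAH/HPAH > 1 petrogenic, < 1 pyrogenic
    "lmw_hmw": ((0.0, "pyrogenic"), (1.0, "petrogenic")),
    # Phe/Ant < 10 pyrogenic, > 15 petrogenic, in between ambiguous
    "phe_ant": ((0.0, "pyrogenic"), (10.0, "mixed/ambiguous"), (15.0, "petrogenic")),
    # Flu/Pyr >= 1 pyrogenic, < 1 petrogenic
    "flu_pyr": ((0.0, "petrogenic"), (1.0, "pyrogenic")),
    # Flu/(Flu+Pyr) < 0.4 petroleum, 0.4-0.5 mixed, > 0.5 combustion
    "flu_flupyr": ((0.0, "petrogenic"), (0.4, "mixed/ambiguous"), (0.5, "pyrogenic")),
    # BaA/(BaA+Chry) < 0.2 petrogenic, 0.2-0.35 mixed, > 0.35 combustion
    "baa_baachry": ((0.0, "petrogenic"), (0.2, "mixed/ambiguous"), (0.35, "pyrogenic")),
}


def classify_source(
    ratios: DiagnosticRatios,
    rules: Mapping[str, tuple[tuple[float, str], ...]] = DEFAULT_RATIO_RULES,
) -> dict[str, str]:
    """Label each defined ratio and form a majority consensus.

    Returns a mapping ratio-name -> label plus a ``"consensus"`` entry:
    the majority vote over the defined ratios' petrogenic/pyrogenic labels,
    ties and ambiguous majorities resolving to ``mixed/ambiguous``.
    """
    labels: dict[str, str] = {}
    for name, rule in rules.items():
        value = getattr(ratios, name)
        if value is None:
            labels[name] = "undefined"
            continue
        label = rule[0][1]
        for bound, lab in rule:
            if value >= bound:  # boundary belongs to the upper class
                label = lab
        labels[name] = label

    votes = [v for v in labels.values() if v != "undefined"]
    if not votes:
        consensus = "mixed/ambiguous"
    else:
        counts = {lab: votes.count(lab) for lab in set(votes)}
        best = max(counts.values())
        winners = [lab for lab, n in counts.items() if n == best]
        consensus = winners[0] if len(winners) == 1 else "mixed/ambiguous"
    labels["consensus"] = consensus
    return labels


def rq(sample: SampleRecord, registry: ReferenceRegistry) -> dict[str, RQResult]:
    """Per-compound risk quotients RQ_NC and RQ_MPC for one sample.

    Concentrations in µg/L are scaled by 1000 against the ng/L quality
    values.  A measured compound with no NC or MPC raises ``KeyError``.
    """
    out: dict[str, RQResult] = {}
    for ab in registry.pahs:
        ref = registry.pahs[ab]
        if ref.nc is None or ref.mpc is None:
            raise KeyError(f"{ab}: no NC/MPC quality values in registry")
        c_ng = sample.value(ab) * 1000.0
        out[ab] = RQResult(rq_nc=c_ng / ref.nc, rq_mpc=c_ng / ref.mpc)
    return out


def site_total_rq(sample: SampleRecord, registry: ReferenceRegistry) -> RQResult:
    """Site-total risk quotient: total PAH against the TOTAL-row quality
    values (not the sum of per-compound quotients)."""
    total_ng = total_pahs(sample, registry) * 1000.0
    return RQResult(
        rq_nc=total_ng / registry.total_nc, rq_mpc=total_ng / registry.total_mpc
    )


def grade_rq(r: RQResult) -> str:
    """Four-grade ecological risk rule (boundaries belong upward)."""
    if r.rq_nc >= 800.0 and r.rq_mpc >= 1.0:
        return "high"
    if r.rq_mpc >= 1.0:
        return "moderate"
    if r.rq_nc >= 1.0:
        return "low"
    return "negligible"


def toc_summary(survey: SurveyTable) -> dict[str, float]:
    """Mean/min/max of a TOC survey (mg/L)."""
    if not survey.records:
        raise ValueError("empty TOC survey")
    values = [r.value("TOC") for r in survey.records]
    return {
        "mean": math.fsum(values) / len(values),
        "min": min(values),
        "max": max(values),
    }


def survey_pah_report(
    survey: SurveyTable, registry: ReferenceRegistry
) -> pd.DataFrame:
    """Per-site report: group totals, diagnostic ratios, source labels,
    and the site-total risk quotient with its grade.

    The survey must already have non-detects substituted.
    """
    rows = []
    for sample in survey.records:
        s = group_totals(sample, registry)
        ratios = diagnostic_ratios(sample, registry)
        labels = classify_source(ratios)
        tot = site_total_rq(sample, registry)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "site_name": sample.site_name,
                "total_pahs": s.total,
                "car_total": s.car_total,
                "lpah_total": s.lpah_total,
                "hpah_total": s.hpah_total,
                "lmw_hmw": ratios.lmw_hmw,
                "phe_ant": ratios.phe_ant,
                "flu_pyr": ratios.flu_pyr,
                "flu_flupyr": ratios.flu_flupyr,
                "baa_baachry": ratios.baa_baachry,
                "source_consensus": labels["consensus"],
                "rq_nc_total": tot.rq_nc,
                "rq_mpc_total": tot.rq_mpc,
                "rq_grade": grade_rq(tot),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
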