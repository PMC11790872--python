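"""Deterministic USEPA health-risk chain for waterborne metals.

Exposure is through drinking (oral) and skin contact (dermal) for two
receptors, adult and child.  Chronic daily intakes::

    CDI_oral   = C * IR * EF * ED / (BW * AT)
    CDI_dermal = C * ET * EF * Kp * SA * CF * ED / (BW * AT)

with C in mg/L, IR L/day, EF days/year, ED years, BW kg, AT days, ET
h/day, Kp cm/h, SA cm^2 and CF = 0.001 L/cm^3.  Non-carcinogenic risk is
the hazard quotient HQ = CDI / RfD (dermal RfD = oral RfD * ABS) and the
hazard index HI = sum of HQs over metals; HI > 1 flags concern.
Carcinogenic risk is CR = CDI * CSF, computed only for metals with a
slope factor (Cd, Cr and Pb by default); CR > 1e-4 is the high-risk flag
and CR < 1e-6 negligible.

All arithmetic accepts scalars or numpy arrays, so the Monte Carlo engine
evaluates the identical code path per draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import defaults
from .sample_io import ReferenceRegistry, SurveyTable

__all__ = [
    "ExposureScenario",
    "RouteRisk",
    "SampleRisk",
    "default_scenarios",
    "cdi_oral",
    "cdi_dermal",
    "hq",
    "hi",
    "cr",
    "classify_cr",
    "survey_risk",
]

RECEPTORS = ("adult", "child")
ROUTES = ("oral", "dermal")

CR_HIGH = 1e-4
CR_NEGLIGIBLE = 1e-6


@dataclass(frozen=True)
class ExposureScenario:
    """Receptor-specific exposure parameters (units in the module docstring).

    AT defaults to ED * 365 days, i.e. dose is averaged over the exposure
    period itself for both the non-carcinogenic and carcinogenic chains.
    """

    receptor: str
    ir: float
    ef: float
    ed: float
    bw: float
    sa: float
    et: float
    cf: float = 0.001
    at: float | None = None

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "sa", "et", "cf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.receptor}: {name} must be positive")
        if self.at is None:
            object.__setattr__(self, "at", self.ed * 365.0)
        elif self.at <= 0:
            raise ValueError(f"{self.receptor}: at must be positive")


@dataclass(frozen=True)
class RouteRisk:
    cdi: float
    hq: float | None  # None when the metal has no RfD
    cr: float | None  # None when the metal has no slope factor


@dataclass(frozen=True)
class SampleRisk:
    sample_id: str
    receptor: str
    per_metal: Mapping[str, Mapping[str, RouteRisk]]  # metal -> route -> risk
    hi_oral: float
    hi_dermal: float
    skipped: tuple[str, ...] = ()  # "metal/route/quantity" entries skipped


def default_scenarios() -> dict[str, ExposureScenario]:
    """The shipped adult and child exposure parameter sets."""
    return {
        "adult": ExposureScenario(receptor="adult", **defaults.EXPOSURE_ADULT),
        "child": ExposureScenario(receptor="child", **defaults.EXPOSURE_CHILD),
    }


def scenarios_from_config(cfg: Mapping) -> dict[str, ExposureScenario]:
    """Scenarios with ``[exposure.adult]`` / ``[exposure.child]`` overrides."""
    exposure = cfg.get("exposure", {})
    out = {}
    for receptor, base in (("adult", defaults.EXPOSURE_ADULT),
                           ("child", defaults.EXPOSURE_CHILD)):
        params = dict(base)
        params.update(exposure.get(receptor, {}))
        out[receptor] = ExposureScenario(receptor=receptor, **params)
    return out


def cdi_oral(c, s: ExposureScenario):
    """Chronic daily intake by ingestion, mg/(kg·day)."""
    return c * s.ir * s.ef * s.ed / (s.bw * s.at)


def cdi_dermal(c, kp, s: ExposureScenario):
    """Chronic daily intake by skin absorption, mg/(kg·day)."""
    return c * s.et * s.ef * kp * s.sa * s.cf * s.ed / (s.bw * s.at)


def hq(cdi, rfd_oral: float, abs_gi: float = 1.0, route: str = "oral"):
    """Hazard quotient: CDI over the route-appropriate reference dose."""
    if rfd_oral <= 0:
        raise ValueError("RfD must be positive")
    if route == "oral":
        return cdi / rfd_oral
    if route == "dermal":
        return cdi / (rfd_oral * abs_gi)
    raise ValueError(f"unknown route {route!r}")


def hi(hqs: Mapping[str, float]):
    """Hazard index: sum of hazard quotients (empty map -> 0)."""
    values = list(hqs.values())
    return sum(values) if values else 0.0


def cr(cdi, csf):
    """Carcinogenic risk: CDI times the cancer slope factor."""
    if np.any(np.asarray(csf) < 0):
        raise ValueError("CSF must be non-negative")
    return cdi * csf


def classify_cr(value: float) -> str:
    if value > CR_HIGH:
        return "high"
    if value < CR_NEGLIGIBLE:
        return "negligible"
    return "acceptable"


def _route_risk(c: float, metal: str, registry: ReferenceRegistry,
                s: ExposureScenario, route: str,
                skipped: list[str]) -> RouteRisk:
    ref = registry.metals[metal]
    if route == "oral":
        dose = cdi_oral(c, s)
        csf = ref.csf_oral
    else:
        if ref.kp is None:
            skipped.append(f"{metal}/{route}/cdi (no Kp)")
            return RouteRisk(cdi=np.nan, hq=None, cr=None)
        dose = cdi_dermal(c, ref.kp, s)
        csf = ref.csf_dermal
    if ref.rfd_oral is not None:
        quotient = hq(dose, ref.rfd_oral, ref.abs_gi, route)
    else:
        skipped.append(f"{metal}/{route}/hq (no RfD)")
        quotient = None
    risk = cr(dose, csf) if csf is not None else None
    return RouteRisk(cdi=dose, hq=quotient, cr=risk)


def survey_risk(
    survey: SurveyTable,
    registry: ReferenceRegistry,
    scenarios: Mapping[str, ExposureScenario] | None = None,
) -> tuple[list[SampleRisk], pd.DataFrame]:
    """Full deterministic chain over a metal survey.

    Returns per-sample risks for every receptor plus a summary table of
    exceedance fractions: share of samples with HQ > 1 per metal/route,
    HI > 1 per route, and CR > 1e-4 per metal/route, for each receptor.
    Metals lacking an RfD or CSF are skipped for that quantity and the
    skip recorded on the result.
    """
    scenarios = scenarios or default_scenarios()
    results: list[SampleRisk] = []
    for receptor, scen in scenarios.items():
        for sample in survey.records:
            skipped: list[str] = []
            per_metal = {}
            for metal in registry.metals:
                c = sample.value(metal)
                per_metal[metal] = {
                    route: _route_risk(c, metal, registry, scen, route, skipped)
                    for route in ROUTES
                }
            results.append(
                SampleRisk(
                    sample_id=sample.sample_id,
                    receptor=receptor,
                    per_metal=per_metal,
                    hi_oral=hi({m: rr["oral"].hq for m, rr in per_metal.items()
                                if rr["oral"].hq is not None}),
                    hi_dermal=hi({m: rr["dermal"].hq for m, rr in per_metal.items()
                                  if rr["dermal"].hq is not None}),
                    skipped=tuple(skipped),
                )
            )

    rows = []
    n = len(survey.records)
    for receptor in scenarios:
        sub = [r for r in results if r.receptor == receptor]
        for route in ROUTES:
            for metal in registry.metals:
                hqs = [r.per_metal[metal][route].hq for r in sub]
                crs = [r.per_metal[metal][route].cr for r in sub]
                rows.append(
                    {
                        "receptor": receptor,
                        "route": route,
                        "metal": metal,
                        "frac_hq_gt_1": (
                            np.nan if any(v is None for v in hqs)
                            else sum(v > 1.0 for v in hqs) / n
                        ),
                        "frac_cr_gt_1e4": (
                            np.nan if any(v is None for v in crs)
                            else sum(v > CR_HIGH for v in crs) / n
                        ),
                    }
                )
            his = [r.hi_oral if route == "oral" else r.hi_dermal for r in sub]
            rows.append(
                {
                    "receptor": receptor,
                    "route": route,
                    "metal": "HI",
                    "frac_hq_gt_1": sum(v > 1.0 for v in his) / n,
                    "frac_cr_gt_1e4": np.nan,
                }
            )
    return results, pd.DataFrame(rows)
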