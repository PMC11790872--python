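"""Survey data model, reference registry, and delimited-text I/O.

A *survey* is a small table of per-sample analyte concentrations: metals in
mg/L, PAHs in µg/L, TOC in mg/L.  Cells below the analytical detection
limit carry a non-detect flag instead of a number.  The survey file dialect
is plain CSV: ``sample_id, site_name, <analyte columns...>`` with ``ND``
(case-insensitive, ``<DL`` also accepted) marking non-detects.

The :class:`ReferenceRegistry` bundles the per-analyte constants every
downstream stage needs: standard limits and toxic-response factors for the
pollution indices, NC/MPC quality values for the PAH risk quotients, and
the dose factors (RfD, ABS, Kp, CSF) for the health-risk chain.  Defaults
live in :mod:`coastrisk.defaults`; every field is overridable from a TOML
config and every applied override is logged.
"""

from __future__ import annotations

import csv
import decimal
import logging
import tomllib
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import defaults

log = logging.getLogger(__name__)

ND_TOKENS = {"nd", "<dl"}

#: Allowed concentration units per analyte class; the first is canonical.
ALLOWED_UNITS = {
    "metals": ("mg/L", "ug/L"),
    "pahs": ("ug/L", "mg/L"),
    "toc": ("mg/L", "ug/L"),
}


class SurveySchemaError(ValueError):
    """A survey file's header does not match the expected analyte set."""


class SurveyValidationError(ValueError):
    """A survey cell violates an invariant (e.g. a negative concentration)."""


class UnitError(ValueError):
    """A unit is missing, unknown, or mixed within one survey."""


class RegistryError(ValueError):
    """A reference-registry override names an unknown analyte or is invalid."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Measurement:
    """One analyte concentration; ``nondetect`` cells carry no raw value."""

    value: float | None
    nondetect: bool = False
    detection_limit: float | None = None

    def __post_init__(self) -> None:
        if not self.nondetect:
            if self.value is None:
                raise SurveyValidationError("detected measurement without a value")
            if self.value < 0:
                raise SurveyValidationError(f"negative concentration {self.value!r}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    site_name: str
    measurements: Mapping[str, Measurement]

    def value(self, analyte: str) -> float:
        """Numeric value of *analyte*; non-detects must be substituted first."""
        m = self.measurements[analyte]
        if m.nondetect:
            raise SurveyValidationError(
                f"sample {self.sample_id}: {analyte} is a non-detect; "
                "apply substitute_nondetects() first"
            )
        assert m.value is not None
        return m.value


@dataclass(frozen=True)
class SurveyTable:
    """An ordered collection of :class:`SampleRecord` sharing one analyte set."""

    records: tuple[SampleRecord, ...]
    analyte_class: str  # metals | pahs | toc
    unit: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.analyte_class not in ALLOWED_UNITS:
            raise UnitError(f"unknown analyte class {self.analyte_class!r}")
        if self.unit not in ALLOWED_UNITS[self.analyte_class]:
            raise UnitError(
                f"unit {self.unit!r} not allowed for {self.analyte_class} "
                f"(expected one of {ALLOWED_UNITS[self.analyte_class]})"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SurveyValidationError("duplicate sample_id in survey")
        if self.records:
            first = tuple(self.records[0].measurements)
            for r in self.records:
                if tuple(r.measurements) != first:
                    raise SurveySchemaError(
                        f"sample {r.sample_id} has a different analyte set"
                    )

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.records[0].measurements) if self.records else ()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def has_nondetects(self) -> bool:
        return any(m.nondetect for r in self.records for m in r.measurements.values())

    def to_frame(self, nd_as: float | None = None) -> pd.DataFrame:
        """Survey as a DataFrame indexed by sample_id.

        Non-detects become NaN, or *nd_as* when given.
        """
        data = {}
        for r in self.records:
            row = {}
            for a, m in r.measurements.items():
                row[a] = nd_as if m.nondetect else m.value
            data[r.sample_id] = row
        frame = pd.DataFrame.from_dict(data, orient="index", dtype=float)
        frame.index.name = "sample_id"
        return frame.loc[[r.sample_id for r in self.records], list(self.analytes)]

    def site_names(self) -> dict[str, str]:
        return {r.sample_id: r.site_name for r in self.records}


@dataclass(frozen=True)
class MetalReference:
    symbol: str
    standard_limit_S: float  # mg/L, HPI sub-index denominator S_i
    ual: float  # mg/L, metal-index upper allowable limit
    toxic_response_Tr: float | None = None
    background_Cbg: float | None = None  # mg/L
    rfd_oral: float | None = None  # mg/(kg day)
    abs_gi: float = 1.0
    kp: float | None = None  # cm/h
    csf_oral: float | None = None  # (mg/(kg day))^-1
    csf_dermal: float | None = None

    def __post_init__(self) -> None:
        if self.standard_limit_S <= 0 or self.ual <= 0:
            raise RegistryError(f"{self.symbol}: non-positive standard limit")
        if not (0 < self.abs_gi <= 1):
            raise RegistryError(f"{self.symbol}: ABS must be in (0, 1]")
        for name in ("toxic_response_Tr", "rfd_oral", "kp", "csf_oral", "csf_dermal"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RegistryError(f"{self.symbol}: negative {name}")


@dataclass(frozen=True)
class PAHReference:
    abbreviation: str
    n_rings: int
    carcinogenic: bool
    nc: float | None = None  # ng/L
    mpc: float | None = None  # ng/L

    def __post_init__(self) -> None:
        if not 2 <= self.n_rings <= 6:
            raise RegistryError(f"{self.abbreviation}: ring count out of range")
        if self.nc is not None and self.nc <= 0:
            raise RegistryError(f"{self.abbreviation}: NC must be positive")
        if self.nc is not None and self.mpc is not None and self.mpc < self.nc:
            raise RegistryError(f"{self.abbreviation}: MPC below NC")

    @property
    def weight_class(self) -> str:
        """``LPAH`` for 2-3 aromatic rings, ``HPAH`` for 4-6."""
        return "LPAH" if self.n_rings <= 3 else "HPAH"


@dataclass(frozen=True)
class ReferenceRegistry:
    metals: Mapping[str, MetalReference]
    pahs: Mapping[str, PAHReference]
    total_nc: float = defaults.TOTAL_NC_NG_L  # ng/L, site-total quality values
    total_mpc: float = defaults.TOTAL_MPC_NG_L
    version_tag: str = defaults.REGISTRY_VERSION


# ---------------------------------------------------------------------------
# registry construction

_OVERRIDE_FIELDS = {
    "limits": ("standard_limit_S", "ual"),  # one table serves both by default
    "rfd": ("rfd_oral",),
    "csf": ("csf_oral",),
    "csf_dermal": ("csf_dermal",),
    "kp": ("kp",),
    "abs": ("abs_gi",),
    "tr": ("toxic_response_Tr",),
    "background": ("background_Cbg",),
}


def load_reference_registry(
    overrides: Mapping | str | Path | None = None,
) -> ReferenceRegistry:
    """Build the reference registry, optionally applying config overrides.

    *overrides* may be a nested mapping (``{"limits": {"Pb": 0.01}, ...}``)
    or a path to a TOML file with the same section layout.  Recognised
    sections: ``limits, rfd, csf, csf_dermal, kp, abs, tr, background``
    (all keyed by metal symbol), ``nc`` / ``mpc`` (keyed by PAH
    abbreviation, ng/L), and ``car`` (a list of PAH abbreviations replacing
    the carcinogenic subgroup).  Overrides for unknown analytes raise
    :class:`RegistryError`; every applied override is logged old -> new.
    """
    cfg = _load_config(overrides)

    metals = {
        sym: MetalReference(
            symbol=sym,
            standard_limit_S=defaults.STANDARD_LIMITS_MG_L[sym],
            ual=defaults.STANDARD_LIMITS_MG_L[sym],
            toxic_response_Tr=defaults.TOXIC_RESPONSE.get(sym),
            rfd_oral=defaults.RFD_ORAL[sym],
            abs_gi=defaults.ABS_GI[sym],
            kp=defaults.KP_CM_H[sym],
            csf_oral=defaults.CSF_ORAL.get(sym),
        )
        for sym in defaults.METALS
    }
    car = frozenset(defaults.CAR_PAHS)
    if "car" in cfg:
        listed = cfg["car"]
        unknown = set(listed) - set(defaults.PAHS)
        if unknown:
            raise RegistryError(f"car override names unknown PAHs: {sorted(unknown)}")
        log.info("override car: %s -> %s", sorted(car), sorted(listed))
        car = frozenset(listed)
    pahs = {
        ab: PAHReference(
            abbreviation=ab,
            n_rings=defaults.PAH_RINGS[ab],
            carcinogenic=ab in car,
            nc=defaults.NC_NG_L[ab],
            mpc=defaults.MPC_NG_L[ab],
        )
        for ab in defaults.PAHS
    }

    for section, fields in _OVERRIDE_FIELDS.items():
        for sym, value in cfg.get(section, {}).items():
            if sym not in metals:
                raise RegistryError(f"[{section}] override for unknown analyte {sym!r}")
            if value is not None and value <= 0 and section == "limits":
                raise RegistryError(f"[{section}] non-positive limit for {sym}")
            for f in fields:
                old = getattr(metals[sym], f)
                log.info("override [%s] %s.%s: %r -> %r", section, sym, f, old, value)
                metals[sym] = replace(metals[sym], **{f: value})
    for section, f in (("nc", "nc"), ("mpc", "mpc")):
        for ab, value in cfg.get(section, {}).items():
            if ab not in pahs:
                raise RegistryError(f"[{section}] override for unknown PAH {ab!r}")
            log.info("override [%s] %s: %r -> %r", section, ab, getattr(pahs[ab], f), value)
            pahs[ab] = replace(pahs[ab], **{f: value})

    # dermal CSF defaults to oral CSF scaled by the GI absorption fraction
    for sym, ref in metals.items():
        if ref.csf_dermal is None and ref.csf_oral is not None:
            metals[sym] = replace(ref, csf_dermal=ref.csf_oral / ref.abs_gi)

    tag = defaults.REGISTRY_VERSION + ("+overrides" if cfg else "")
    return ReferenceRegistry(metals=metals, pahs=pahs, version_tag=tag)


def _load_config(overrides: Mapping | str | Path | None) -> dict:
    if overrides is None:
        return {}
    if isinstance(overrides, (str, Path)):
        with open(overrides, "rb") as fh:
            return tomllib.load(fh)
    return dict(overrides)


# ---------------------------------------------------------------------------
# survey reading / writing

_DEFAULT_UNITS = {"metals": "mg/L", "pahs": "ug/L", "toc": "mg/L"}

_EXPECTED_ANALYTES = {
    "metals": set(defaults.METALS),
    "pahs": set(defaults.PAHS),
    "toc": {"TOC"},
}


def read_survey(
    path: str | Path,
    analyte_class: str,
    unit: str | None = None,
    provenance: str | None = None,
) -> SurveyTable:
    """Read a survey CSV into a validated :class:`SurveyTable`.

    The header must be ``sample_id, site_name`` followed by analyte
    abbreviations known to the active analyte class; cells are numbers or a
    non-detect token.  Unknown columns raise :class:`SurveySchemaError`,
    negative values :class:`SurveyValidationError` naming the sample.
    """
    path = Path(path)
    if analyte_class not in _EXPECTED_ANALYTES:
        raise UnitError(f"unknown analyte class {analyte_class!r}")
    unit = unit or _DEFAULT_UNITS[analyte_class]

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SurveySchemaError(f"{path}: empty file, no header") from None
        header = [h.strip() for h in header]
        if len(header) < 2 or header[0] != "sample_id" or header[1] != "site_name":
            raise SurveySchemaError(
                f"{path}: header must start with sample_id, site_name"
            )
        analytes = header[2:]
        unknown = set(analytes) - _EXPECTED_ANALYTES[analyte_class]
        if unknown:
            raise SurveySchemaError(
                f"{path}: unknown analyte column(s) {sorted(unknown)} "
                f"for class {analyte_class!r}"
            )
        records = []
        for row in reader:
            if not row or not any(cell.strip() for cell in row):
                continue
            sample_id, site_name, *cells = (c.strip() for c in row)
            if len(cells) != len(analytes):
                raise SurveySchemaError(
                    f"{path}: sample {sample_id}: expected {len(analytes)} cells"
                )
            measurements = {}
            for analyte, cell in zip(analytes, cells):
                if cell.lower() in ND_TOKENS:
                    measurements[analyte] = Measurement(None, nondetect=True)
                else:
                    try:
                        value = float(cell)
                    except ValueError:
                        raise SurveyValidationError(
                            f"{path}: sample {sample_id}, {analyte}: "
                            f"cell {cell!r} is neither a number nor an ND token"
                        ) from None
                    if value < 0:
                        raise SurveyValidationError(
                            f"{path}: sample {sample_id}, {analyte}: negative value"
                        )
                    measurements[analyte] = Measurement(value)
            records.append(SampleRecord(sample_id, site_name, measurements))

    return SurveyTable(
        records=tuple(records),
        analyte_class=analyte_class,
        unit=unit,
        provenance=provenance if provenance is not None else str(path),
    )


def write_survey(survey: SurveyTable, path: str | Path) -> None:
    """Write a survey back to the CSV dialect ``read_survey`` accepts."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "site_name", *survey.analytes])
        for r in survey.records:
            row: list[str] = [r.sample_id, r.site_name]
            for a in survey.analytes:
                m = r.measurements[a]
                row.append("ND" if m.nondetect else repr(float(m.value)))
            writer.writerow(row)


def _scale_decimal(value: float, factor: "decimal.Decimal") -> float:
    # decimal scaling: survey values are short decimal literals, so
    # multiplying/dividing by 1000 in decimal makes round trips exact
    return float(decimal.Decimal(repr(value)) * factor)


def convert_units(survey: SurveyTable, to_unit: str) -> SurveyTable:
    """Convert a survey between mg/L and µg/L (exact factor 1000).

    Scaling is done in decimal arithmetic so converting to µg/L and back
    to mg/L reproduces the original values bit-for-bit.
    """
    if to_unit == survey.unit:
        return survey
    pair = {"mg/L": decimal.Decimal(1), "ug/L": decimal.Decimal(1000)}
    if survey.unit not in pair or to_unit not in pair:
        raise UnitError(f"cannot convert {survey.unit!r} -> {to_unit!r}")
    factor = pair[to_unit] / pair[survey.unit]
    records = tuple(
        SampleRecord(
            r.sample_id,
            r.site_name,
            {
                a: (
                    m
                    if m.nondetect and m.detection_limit is None
                    else replace(
                        m,
                        value=(
                            None if m.nondetect else _scale_decimal(m.value, factor)
                        ),
                        detection_limit=(
                            None
                            if m.detection_limit is None
                            else _scale_decimal(m.detection_limit, factor)
                        ),
                    )
                )
                for a, m in r.measurements.items()
            },
        )
        for r in survey.records
    )
    return SurveyTable(records, survey.analyte_class, to_unit, survey.provenance)


def substitute_nondetects(
    survey: SurveyTable,
    policy: str = "zero",
    detection_limits: Mapping[str, float] | None = None,
) -> SurveyTable:
    """Replace non-detect flags by numbers under an explicit policy.

    ``zero``
        ND becomes 0 — the survey's own totals imply this convention
        (per-site totals equal the sums of detected values).
    ``half_dl``
        ND becomes detection_limit / 2.  The limit comes from the cell
        itself or, failing that, from *detection_limits*; cells with no
        limit anywhere are collected and reported in one error.
    """
    if policy not in ("zero", "half_dl"):
        raise ValueError(f"unknown non-detect policy {policy!r}")
    detection_limits = detection_limits or {}

    missing: list[str] = []
    records = []
    for r in survey.records:
        measurements = {}
        for a, m in r.measurements.items():
            if not m.nondetect:
                measurements[a] = m
                continue
            if policy == "zero":
                measurements[a] = Measurement(0.0, detection_limit=m.detection_limit)
            else:
                dl = m.detection_limit
                if dl is None:
                    dl = detection_limits.get(a)
                if dl is None:
                    missing.append(f"{r.sample_id}/{a}")
                    continue
                measurements[a] = Measurement(dl / 2.0, detection_limit=dl)
        records.append(SampleRecord(r.sample_id, r.site_name, measurements))
    if missing:
        raise SurveyValidationError(
            "half_dl substitution needs a detection limit for: " + ", ".join(missing)
        )
    return SurveyTable(
        tuple(records), survey.analyte_class, survey.unit, survey.provenance
    )


# ---------------------------------------------------------------------------
# packaged fixtures (the in-survey study tables)


def _fixture_path(name: str):
    return resources.files("coastrisk.data").joinpath(name)


def load_table1_metals() -> SurveyTable:
    """The 18-sample × 8-metal coastal survey (mg/L)."""
    with resources.as_file(_fixture_path("table1_metals.csv")) as p:
        return read_survey(p, "metals", provenance="packaged table1_metals.csv")


def load_table2_pahs() -> SurveyTable:
    """The 8-site × 16-PAH survey (µg/L) with non-detects."""
    with resources.as_file(_fixture_path("table2_pahs.csv")) as p:
        return read_survey(p, "pahs", provenance="packaged table2_pahs.csv")


def load_table3_toc() -> SurveyTable:
    """Total organic carbon at the eight PAH sites (mg/L)."""
    with resources.as_file(_fixture_path("table3_toc.csv")) as p:
        return read_survey(p, "toc", provenance="packaged table3_toc.csv")


def load_table5_quality_values() -> pd.DataFrame:
    """NC/MPC quality values (ng/L) per PAH, including the TOTAL row."""
    with resources.as_file(_fixture_path("table5_quality_values.csv")) as p:
        return pd.read_csv(p, index_col="abbreviation")
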