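"""Default reference constants for the coastal-seawater risk pipeline.

Everything in this module is data: per-analyte water-quality limits,
toxicity factors, and exposure parameters with their provenance.  All of it
can be overridden through the ``[limits]/[rfd]/[csf]/[kp]/[abs]/[tr]/
[background]/[exposure.*]`` sections of a TOML config (see
:func:`coastrisk.sample_io.load_reference_registry`).

Units
-----
* concentrations and limits: mg/L for metals and TOC, µg/L for PAHs,
  ng/L for the PAH quality values (NC/MPC)
* RfD and CDI: mg per kg body weight per day
* CSF: (mg/(kg·day))^-1
* Kp: cm/h
"""

from __future__ import annotations

#: The eight survey metals, in the order they appear in the survey tables.
METALS = ("Cd", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn")

#: The sixteen survey PAHs, in elution order.
PAHS = (
    "Naph", "Acthy", "Ace", "Fl", "Phe", "Ant", "Flu", "Pyr",
    "BaA", "Chry", "BbF", "BkF", "BaP", "DBA", "BghiP", "InP",
)

#: Drinking-water standard limit / upper allowable limit, mg/L (WHO-style
#: set).  Used both as S_i in the HPI sub-index and as UAL_i in the metal
#: index unless separate tables are configured.
STANDARD_LIMITS_MG_L = {
    "Cd": 0.003, "Cr": 0.05, "Cu": 2.0, "Fe": 0.3,
    "Mn": 0.1, "Ni": 0.07, "Pb": 0.01, "Zn": 3.0,
}

#: Hakanson-style toxic-response factors T_r for the ecological risk index.
#: Iron has no established factor and is excluded from RI by default.
TOXIC_RESPONSE = {
    "Cd": 30.0, "Cr": 2.0, "Cu": 5.0, "Mn": 1.0,
    "Ni": 5.0, "Pb": 5.0, "Zn": 1.0,
}

#: Oral reference doses, mg/(kg·day) (USEPA IRIS-style values).
RFD_ORAL = {
    "Cd": 0.0005, "Cr": 0.003, "Cu": 0.04, "Fe": 0.7,
    "Mn": 0.14, "Ni": 0.02, "Pb": 0.0014, "Zn": 0.3,
}

#: Gastrointestinal absorption fractions converting oral RfD to dermal RfD
#: (RAGS Part E style: Cd 5%, Cr(VI) 2.5%, full absorption otherwise).
ABS_GI = {
    "Cd": 0.05, "Cr": 0.025, "Cu": 1.0, "Fe": 1.0,
    "Mn": 1.0, "Ni": 1.0, "Pb": 1.0, "Zn": 1.0,
}

#: Dermal permeability coefficients, cm/h.
KP_CM_H = {
    "Cd": 0.001, "Cr": 0.002, "Cu": 0.001, "Fe": 0.001,
    "Mn": 0.001, "Ni": 0.0002, "Pb": 0.0001, "Zn": 0.0006,
}

#: Oral cancer slope factors, (mg/(kg·day))^-1.  Only the class-1/2A
#: carcinogens carry a slope factor; CR is computed only for these.
CSF_ORAL = {"Cd": 6.1, "Cr": 0.5, "Pb": 0.0085}

#: Analytical detection limits of the survey instrumentation (ICP-OES for
#: metals, HPLC for PAHs), used by the half-DL non-detect policy when a
#: survey does not carry its own per-cell limits.  Metals in mg/L.
DETECTION_LIMITS_METALS_MG_L = {
    "Cd": 0.0001, "Cr": 0.001, "Cu": 0.001, "Fe": 0.001,
    "Mn": 0.0005, "Ni": 0.001, "Pb": 0.001, "Zn": 0.0005,
}

#: PAH detection limits in µg/L.
DETECTION_LIMITS_PAHS_UG_L = {
    "Naph": 0.05, "Acthy": 0.10, "Ace": 0.10, "Fl": 0.05,
    "Phe": 0.05, "Ant": 0.05, "Flu": 0.05, "Pyr": 0.05,
    "BaA": 0.05, "Chry": 0.05, "BbF": 0.10, "BkF": 0.10,
    "BaP": 0.05, "DBA": 0.10, "BghiP": 0.10, "InP": 0.10,
}

#: Aromatic ring count per PAH; 2-3 rings = LPAH, 4-6 rings = HPAH.
PAH_RINGS = {
    "Naph": 2, "Acthy": 3, "Ace": 3, "Fl": 3, "Phe": 3, "Ant": 3,
    "Flu": 4, "Pyr": 4, "BaA": 4, "Chry": 4,
    "BbF": 5, "BkF": 5, "BaP": 5, "DBA": 5,
    "BghiP": 6, "InP": 6,
}

#: Default carcinogenic-PAH subgroup.  This is the set whose per-site sums
#: reproduce the survey's "Total CAR" row (e.g. Suez 2.12 + 8.04 + 19.46 =
#: 29.62 µg/L); it is the seven IARC-listed carcinogenic PAHs plus BghiP.
CAR_PAHS = frozenset({"BaA", "Chry", "BbF", "BkF", "BaP", "DBA", "BghiP", "InP"})

#: Alternative CAR grouping (the USEPA/WHO "dangerous pollutant" list as
#: quoted in narrative sources); selectable via the ``car`` override.
CAR_PAHS_PROSE = frozenset({"Naph", "Acthy", "Fl", "Phe", "Ant", "Pyr", "Flu", "BaP"})

#: Quality values (NC = negligible concentration, MPC = maximum permissible
#: concentration) per PAH in ng/L, plus the TOTAL-row pair used for
#: site-total risk quotients.  These ship as the packaged quality-value
#: fixture as well; the dict is the registry default.
NC_NG_L = {
    "Naph": 1.2, "Acthy": 0.7, "Ace": 0.7, "Fl": 0.7, "Phe": 3.0,
    "Ant": 0.7, "Flu": 3.0, "Pyr": 0.7, "BaA": 0.1, "Chry": 3.4,
    "BbF": 0.1, "BkF": 0.4, "BaP": 0.5, "DBA": 0.5, "BghiP": 0.3,
    "InP": 0.4,
}
MPC_NG_L = {
    "Naph": 1200.0, "Acthy": 700.0, "Ace": 70.0, "Fl": 70.0, "Phe": 300.0,
    "Ant": 70.0, "Flu": 300.0, "Pyr": 70.0, "BaA": 10.0, "Chry": 340.0,
    "BbF": 10.0, "BkF": 40.0, "BaP": 50.0, "DBA": 50.0, "BghiP": 30.0,
    "InP": 40.0,
}
TOTAL_NC_NG_L = 27.2
TOTAL_MPC_NG_L = 2720.0

#: Exposure scenarios for the two receptors.  IR L/day, EF days/year,
#: ED years, BW kg, SA cm^2, ET h/day, CF L/cm^3.  Averaging time AT is
#: ED·365 days for both the non-carcinogenic and the carcinogenic chain:
#: risks are averaged over the exposure period itself, which keeps the
#: receptor ordering (child > adult per unit concentration) implied by the
#: intake-to-body-weight ratios.
EXPOSURE_ADULT = {
    "ir": 2.2, "ef": 365.0, "ed": 30.0, "bw": 70.0,
    "sa": 18000.0, "et": 0.58, "cf": 0.001,
}
EXPOSURE_CHILD = {
    "ir": 1.0, "ef": 365.0, "ed": 6.0, "bw": 15.0,
    "sa": 6600.0, "et": 1.0, "cf": 0.001,
}

#: Illustrative seawater background concentrations (mg/L) for the ecological
#: risk index.  SYNTHETIC/illustrative values: RI needs per-metal background
#: levels which are site-specific and must normally come from the user's
#: config; this example set is scaled from open-ocean trace-metal levels so
#: that the packaged survey yields a low-risk RI, and ships only so the RI
#: example runs out of the box.
EXAMPLE_BACKGROUND_MG_L = {
    "Cd": 0.15, "Cr": 0.9, "Cu": 0.65, "Fe": 0.67,
    "Mn": 0.17, "Ni": 0.12, "Pb": 1.8, "Zn": 0.5,
}

REGISTRY_VERSION = "coastrisk-defaults-1"
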