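# Methods

This note documents the models behind `coastrisk`, the defaults it ships,
the numerical conventions it commits to, and what its synthetic benchmark
does and does not demonstrate.

## Scope and data

The pipeline analyses small multi-site surveys of coastal seawater: an
18-sample × 8-metal table (Cd, Cr(VI), Cu, Fe, Mn, Ni, Pb, Zn; mg/L), an
8-site × 16-compound parent-PAH table (µg/L) with non-detect cells, and a
TOC table (mg/L). These ship as packaged CSV fixtures and are the default
inputs of the `analysis/` drivers; any survey in the same dialect works.

Non-detects are substituted under an explicit policy before any
arithmetic. The default is ND → 0 because the survey's own printed
per-site totals equal the sums of the detected cells alone; ND → DL/2 is
available (`half_dl`) and uses the instruments' detection limits when a
survey carries none of its own. The substitution policy is part of the
provenance of every downstream number.

## PAH metrics

Compounds are grouped by aromatic ring count — LPAH (2–3 rings) versus
HPAH (4–6 rings) — plus a carcinogenic subgroup (CAR). The default CAR
set is {BaA, Chry, BbF, BkF, BaP, DBA, BghiP, InP}: it is the set whose
per-site sums reproduce the survey's own "Total CAR" row exactly (e.g.
2.12 + 8.04 + 19.46 = 29.62 µg/L at the harbour site). Narrative sources
sometimes quote a different eight-compound list (Naph…BaP); that set is
available through the `car` registry override but does not reproduce the
table.

Source diagnostics use the standard isomer ratios with half-open
thresholds (a ratio exactly on a boundary takes the upper class):

| ratio | petrogenic | mixed | pyrogenic/combustion |
|---|---|---|---|
| LPAH/HPAH | > 1 | — | < 1 |
| Phe/Ant | > 15 | 10–15 | < 10 |
| Flu/Pyr | < 1 | — | ≥ 1 |
| Flu/(Flu+Pyr) | < 0.4 | 0.4–0.5 | > 0.5 |
| BaA/(BaA+Chry) | < 0.2 | 0.2–0.35 | > 0.35 |

Published Phe/Ant conventions conflict (petrogenic cut-offs of 5, 10 and
15 all circulate); we use the 10/15 convention and make the table
configurable. A ratio with a zero denominator is *undefined* — it is
excluded from the consensus vote rather than coerced to 0 or infinity.
The consensus label is the majority over the defined ratios; ties go to
`mixed/ambiguous`.

Risk quotients divide each concentration by two quality values stored in
ng/L: the negligible concentration (NC) and the maximum permissible
concentration (MPC). The site-total quotient uses the dedicated
total-PAH quality pair (NC 27.2 ng/L, MPC 2720 ng/L) rather than the sum
of per-compound quotients; note this pair is *not* the sum of the
per-compound NCs — it is its own reference value. Grades: high when
RQ_NC ≥ 800 and RQ_MPC ≥ 1; moderate when RQ_NC < 800 and RQ_MPC ≥ 1;
low when RQ_MPC < 1 ≤ RQ_NC; negligible when RQ_NC < 1. Under this rule
the fifth site (RQ_NC 409, RQ_MPC 4.1) grades moderate even though some
narrative summaries of the same survey omit it from the medium list; the
rule is applied as stated.

## Metal pollution indices

* **HPI** — weighted arithmetic mean of sub-indices `Q_i = 100·C_i/S_i`
  with weights `W_i = 1/S_i`; a water exactly at every limit scores 100.
* **MI** — `Σ C_i/UAL_i`, additive in the concentrations.
* **RI** — Hakanson's potential ecological risk:
  `RI = Σ T_r^i · C_i / C_bg^i` with toxic-response factors
  Cd 30, Cr 2, Cu 5, Ni 5, Pb 5, Mn 1, Zn 1. Iron has no established
  factor and is excluded by default. Background levels `C_bg` are
  site-specific inputs; the packaged set is explicitly illustrative
  (synthetic), chosen so the example run lands in the low-risk class.

One WHO-style limit table serves as both `S_i` and `UAL_i` by default
(mg/L): Cd 0.003, Cr 0.05, Cu 2.0, Fe 0.3, Mn 0.1, Ni 0.07, Pb 0.01,
Zn 3.0. Separate tables can be configured. Classification scales are
half-open and contiguous; published wordings with gaps (e.g. "HPI < 25"
then "26 ≤ HPI ≤ 50", "MI > 6" after "4 < MI < 6") are implemented with
the boundary belonging to the upper (worse) class.

**Reproduction status on the packaged survey.** With the default limit
table the MI maximum is 101.17 (printed: 101.2; the lead-dominated
sample contributes a Pb term of 99.9 alone), and the MI class fractions
are exact: 2/18 partly affected, 10/18 severely affected. The HPI
survey mean is 489.7 against a printed 537.8 (−8.9%) and the HPI
maximum 2143 against 2097.8 (+2.2%). The MI survey mean, however,
computes to 16.99 against a printed 20.5 (−17%): the source table's own
printed "Mean" row is inconsistent with its columns (its Pb mean of
0.158 mg/L versus a column mean of 0.120), and the MI of that
inconsistent mean row (21.2) is within 3% of the printed 20.5. The
authors' exact limit table is unpublished (supplementary material), so
these summary-level discrepancies cannot be closed from the printed
data; the package carries the 18 sample rows, recomputes all summaries
from them, and reports the difference rather than absorbing it. The
regression suite asserts the printed MI mean at ±10% and that assertion
fails by design — it records the discrepancy.

## Health-risk chain

The USEPA deterministic chain for two receptors (adult, child) and two
routes:

    CDI_oral   = C · IR · EF · ED / (BW · AT)
    CDI_dermal = C · ET · EF · Kp · SA · CF · ED / (BW · AT)
    HQ = CDI / RfD_route        RfD_dermal = RfD_oral · ABS
    HI = Σ_metals HQ            CR = CDI · CSF_route

Defaults (all configurable): adult IR 2.2 L/d, BW 70 kg, ED 30 y, SA
18,000 cm², ET 0.58 h/d; child IR 1.0 L/d, BW 15 kg, ED 6 y, SA 6,600
cm², ET 1 h/d; EF 365 d/y; CF 0.001 L/cm³. **Averaging time is AT =
ED·365 days for both the non-carcinogenic and the carcinogenic chain**,
i.e. dose is averaged over the exposure period itself rather than over a
70-year lifetime. This is a deliberate design choice: it makes the
exposure duration cancel, reduces every HQ and CR to an
intake-per-body-weight form, and is the only averaging convention
consistent with the survey study's reported results (child CR above
adult CR by roughly the IR/BW ratio, and CR magnitudes in the 10⁻³–10⁻²
range). Lifetime averaging can be restored per receptor via the `at`
exposure override.

Dose factors: RfD_oral (mg/kg/d) Cd 0.0005, Cr(VI) 0.003, Cu 0.04, Fe
0.7, Mn 0.14, Ni 0.02, Pb 0.0014, Zn 0.3; GI absorption ABS Cd 0.05,
Cr 0.025, all others 1.0 (RAGS Part E convention — the low Cd/Cr values
reflect poor gastrointestinal uptake and are what make the dermal RfD
much smaller than the oral one for those metals); Kp (cm/h) Cd 0.001,
Cr 0.002, Cu 0.001, Fe 0.001, Mn 0.001, Ni 0.0002, Pb 0.0001, Zn 0.0006.
Oral slope factors exist for Cd (6.1), Cr(VI) (0.5) and Pb (0.0085)
only; carcinogenic risk is computed only for those three, with
CSF_dermal = CSF_oral/ABS unless configured. HQ/HI flag concern strictly
above 1 and CR strictly above 1×10⁻⁴ (negligible below 1×10⁻⁶).

With these defaults on the packaged survey, the chain reproduces the
survey study's qualitative structure — child ≥ adult per metal and
route, Cd/Cr/Pb as the drivers, oral HI above dermal HI in every sample,
adult dermal HQ below 1 everywhere, child dermal HQ above 1 only for Cr
(6/18 samples = 33.3%) — and several of its printed exceedance
percentages exactly (adult oral Cr and Pb 22.22%, child oral Cr 50%,
child oral Pb 22.22%). The exact exposure-parameter table behind the
study's printed HI ranges is unpublished, so those ranges are treated as
ordering/tolerance checks, not exact targets.

## Monte Carlo engine

Every uncertain input is a `DistributionSpec` (point, uniform,
triangular, normal, lognormal; optional truncation with renormalised
mass, sampled by inverse CDF). A point mass is a first-class family, so
the fully degenerate simulation equals the deterministic chain
*bit-for-bit* — the engine feeds its draw vectors through the very same
`health_risk` arithmetic.

Default template: concentrations lognormal with moments matched to each
metal's survey mean and SD; body weight normal truncated at its 5th/95th
percentiles (adult 70 ± 13 kg, child 15 ± 3 kg); ingestion rate uniform
(adult 1.5–3.0 L/d, child 0.7–1.5 L/d); exposure duration uniform (with
AT tied to ED the draw cancels from every statistic — it is retained for
configurations that fix AT independently); everything else point-mass.

Reproducibility: one global seed; each metal draws from an independent
substream derived from `(seed, crc32(metal))`; within a substream the
order is fixed (concentration, then each receptor's uncertain parameters
in sorted order). Adding a metal therefore never perturbs another
metal's draws. Default n = 10,000 iterations. Quantiles use numpy's
linear interpolation between order statistics, everywhere.

The probabilistic percentile values printed in the source study (e.g.
its 5th/95th-percentile CR bands) are **not** reproducible targets: the
input distribution families and parameters behind them are unpublished.
The engine is validated instead by its analytic and degenerate
properties — closed-form lognormal quantiles, exact point-mass
consistency, seed reproducibility, and the 1/√n shrinkage of Monte Carlo
error (quadrupling n from 2,500 to 10,000 halves the across-seed spread
of every percentile statistic) — plus the qualitative orderings above.

## Source-identification statistics

Variables are z-scored with the unbiased (n−1) standard deviation before
any multivariate step; constant variables are rejected by name.

* **Ward clustering** — scipy's Ward/Euclidean agglomeration on the
  standardised profiles (R mode clusters analytes, Q mode clusters
  samples). This is the classical minimum-variance objective: each merge
  minimises the increase ΔSS in total within-cluster sum of squares, and
  the reported height is √(2·ΔSS) ("ward.D2" convention). The test suite
  checks scipy's tree against an exhaustive brute-force implementation
  that recomputes ΔSS for every candidate merge at every step.
* **PCA** — eigendecomposition of the correlation matrix; eigenvalues
  sum to p and variance shares are eigenvalue/p. Loadings are component
  correlations (eigenvector × √eigenvalue) with the deterministic sign
  convention that each component's largest-magnitude loading is
  positive. Kaiser retention keeps eigenvalues > 1. No rotation by
  default (whether the source study rotated its loadings is not stated);
  varimax is out of scope beyond the flagged option.
* **Adequacy tests** — KMO from the anti-image partial correlations
  (−R⁻¹ᵢⱼ/√(R⁻¹ᵢᵢR⁻¹ⱼⱼ)), and Bartlett's sphericity statistic
  −(n−1−(2p+5)/6)·ln|R| with p(p−1)/2 degrees of freedom. Both are
  implemented directly (small closed forms) and cross-checked in the
  tests against brute-force evaluations and the equicorrelation closed
  form.

On the packaged survey: three components retained, 74.29% cumulative
variance (printed: 74.26%), KMO 0.53 (printed: 0.6), Bartlett p = 0.018
(printed: 0.02). The k = 3 variable cut groups {Cd, Cr}, {Cu, Pb} and
{Fe, Mn, Ni, Zn} — close to, but not identical with, the narrative
clusters {Cd, Cr, Mn}/{Ni, Zn, Fe}/{Cu, Pb}; with 18 samples the Mn
assignment is fragile, and the printed summary statistics themselves are
only tolerance-level checks here because of the source table's
inconsistent summary row.

## Synthetic-data generator

The generator emulates the structure the analysis assumes: strictly
positive, right-skewed concentrations (lognormal marginals), correlated
source groups (Gaussian copula on the log scale: within-group
correlation ρ, independent groups), optional hotspots (one analyte
multiplied by a factor in randomly chosen samples, emulating a single
dominated sample such as a lead spike), and detection-limit censoring
into non-detects. Ground truth (group labels, pre-censoring values,
hotspot rows) is returned alongside the survey.

Defaults are the benchmark conditions: 18 samples, the eight survey
metals in three groups ({Cd, Cr, Mn}, {Ni, Zn, Fe}, {Cu, Pb}), ρ = 0.9
within groups, log-mean −4.5 and log-SD 1.0 (concentrations centred near
0.01 with the spread trace-metal surveys show), no hotspot and no
censoring. The `table1_like_config()` preset adds the 50× lead hotspot
and the instruments' detection limits for emulation studies. Hotspots
are deliberately not part of the default: the planted-partition
benchmark measures correlation recovery, and a single 50× spike is a
separate robustness feature, not part of that condition.

What passing the synthetic benchmarks shows: the clustering recovers a
planted partition exactly (ARI = 1) at ρ = 0.9 with 200 samples, PCA
recovers three planted factors, the censoring machinery reproduces its
configured rates, and moments converge. What it does not show: real
surveys have spatially structured sources, correlated censoring, and
non-lognormal tails; sites here are exchangeable by construction, and no
spatial correlation field is modelled.

## Numerical conventions and degenerate inputs

* Sums use compensated summation (`math.fsum`) where a printed total is
  reproduced; quantiles use linear interpolation; standard deviations
  are ddof = 1 throughout.
* Unit conversion (mg/L ↔ µg/L) is done in decimal arithmetic so a
  round trip reproduces the original values exactly.
* Boundary values always classify into the upper (worse) class.
* A diagnostic ratio with a zero denominator is undefined, not 0/∞; an
  all-ND sample under the zero policy has total 0 and grade negligible.
* Point-mass Monte Carlo inputs yield exactly zero spread; the
  convergence report treats identical replicate values as zero spread
  rather than trusting floating-point `std` round-off (~10⁻²¹).

## Known limitations

* RI backgrounds and the exact HPI/MI limit table used by the source
  survey are unpublished; HPI/MI summary means are reproduced only to
  tolerance (and the MI mean not even to ±10%, as documented above).
* The probabilistic percentile bands of the source study are not
  reproducible (input distributions not stated); the engine is validated
  by analytic properties and orderings instead.
* No inhalation route, no age-dependent adjustment factors, no
  BaP-equivalent human cancer chain for PAHs (the metals carry the
  carcinogenic chain), no sediment-phase indices, no factor rotation
  beyond the varimax flag, and no spatial modelling.
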