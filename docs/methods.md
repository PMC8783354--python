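# Methods

## Problem

Urinary extracellular vesicles (uEVs) are shed into urine by epithelial
cells along the nephron, so the number excreted per day should scale
with functional kidney tissue ("nephron mass", proxied by total kidney
volume in humans and kidney weight in rats). Two practical consequences
drive this package: (1) inter-individual comparisons of uEV biomarkers
are confounded by nephron mass unless an excretion rate or a mass proxy
enters the analysis; (2) after surgical nephron loss, compensatory
hypertrophy of the remnant makes excretion fall *less* than nephron
number, and per-nephron biomarker changes are invisible without a
volume correction.

## Estimators

**Spot extrapolation.** `calculated_spot_excretion = uev_conc x
creat_excretion / creat_conc`. Model: during a void, uEVs and
creatinine are diluted by the same urine flow `f`; concentrations are
`E/f` and `C/f`, so the ratio times the independently measured daily
creatinine `C` returns `E`. The estimator is exactly invariant to
dilution and inherits error only from (a) measurement noise in the two
concentrations and (b) within-day variation in the excretion/creatinine
ratio. Canonical unit is uEVs/day; the per-minute form is a fixed
division by 1440 and round-trips to machine precision. Spot samples
with creatinine under 1 mmol/L are flagged (`is_dilute`) rather than
silently normalized — ratio estimates from very dilute voids are
unstable.

**TKV correction.** `corrected = abundance_per_creat x reference_tkv /
tkv` — a multiplicative rescaling to a reference volume. The reference
may be the individual's own pre-surgery TKV (pre-phase values then pass
through unchanged; post-phase values scale up by the removed fraction)
or a group-level volume. Chosen because it reproduces the expected
two-fold behaviour for a 50% volume loss and keeps the correction a
pure relabelling of units (A.U./creat per reference-volume of tissue).

**Hypertrophy projection.** Projections multiply a baseline by the
retained fraction; observed/projected ratios are the hypertrophy factor
(weights) and uEV change factor (excretion). Conventions: the
contralateral kidney's weight at uninephrectomy proxies the
polectomized kidney's pre-weight (its remnant is 1/3 of one kidney);
nephron fractions assume two equally contributing kidneys and
negligible extra-renal uEV input, giving 1/2 (uninephrectomy) and 1/6
(5/6th nephrectomy). Functions return raw ratios; the report layer
rounds folds to one decimal and projected excretions to two decimals,
and — matching the arithmetic convention of the published projection
table — divides by the *rounded* projected excretion when printing the
change factor (0.56/0.14 = 4.0 rather than 0.56/0.135 = 4.1). Tests
compare raw values with tolerances; only the report asserts printed
cells.

**CD9 gating.** Threshold = mean + 3 x SD of a marker-free liposome
control; the SD uses the n-1 (sample) estimator — the population/sample
choice is not externally fixed, and with control sizes in the tens of
thousands the difference is negligible. Ties are classified negative
(strictly-above rule), conservative for positivity claims. For a
Gaussian control this leaves ~0.13% of control particles above
threshold.

**Size histograms.** Half-open 1-nm bins with a fixed origin at the
70 nm detection limit, upper edge 1000 nm, diameters beyond pooled into
an overflow bin; the fixed origin makes per-bin comparisons across
samples well-defined. Counts are divided by creatinine concentration.
Per-bin percent change against a reference is NaN (undefined), not
infinite, where the reference bin is empty.

**Statistics.** Percent decrease is signed positive ("reduced by 24%"
=> +24), with the raw per-subject changes retained. `group_mean`
(percent change of the group means) and the mean of individual changes
are different statistics; both are computed and labelled. Bland-Altman
uses absolute differences by default with a log-scale option for
proportional error; limits are bias +/- 1.96 SD of differences.
Hypothesis tests are delegated to scipy; the package encodes only the
choice rule — Shapiro-Wilk on the paired differences at alpha = 0.05
selects paired t versus Wilcoxon (the normality test itself is a
package decision; the choice rule, not the specific screen, is the
contract). Holm-Bonferroni is delegated to statsmodels and verified
against the by-definition stepdown on hand-worked cases.

## Synthetic-data generator

The generator emulates the *structure* of a paired donor-nephrectomy
cohort plus a three-group rat nephrectomy study, so that pipeline
correctness (round-trips, invariances, estimator bias) is testable.

Human arm, per donor: sex (female fraction 12/19); TKV ~ truncated
normal (male 351 +/- 37 ml, female 300 +/- 57 ml); creatinine excretion
~ truncated normal (male 17.1 +/- 1.3, female 9.0 +/- 2.6 mmol/day);
latent excretion `E = kappa x TKV x exp(N(0, 0.30))` with kappa =
1.225e8 uEVs/day/ml for men and 0.599 x kappa for women. The female
scale captures lower nephron endowment per unit volume: the observed
sex gap in excretion (~49% lower medians in women) is far larger than
the TKV gap (~15%), so volume alone cannot carry it. Truncated normals
were chosen for positivity with modest spread; lognormals for urine
flow and the uEV noise, whose real counterparts are right-skewed.

Sampling: a 24-h collection (volume ~ truncated normal 2.0 +/- 0.75 L)
and a spot void (flow ~ lognormal, median 1.5 L/day-equivalent, sigma
0.4) per phase; concentrations are daily amounts over the collection's
flow, and measured uEV concentrations carry multiplicative lognormal
noise (sigma 0.10). Because both spot concentrations share the flow,
they are positively correlated within subject — the structure the spot
extrapolation exploits. With all sigmas zero the samples invert exactly
to the latent excretion (tested).

Nephrectomy: removed volume fraction ~ N(0.5, 0.03); post excretion =
pre x fraction kept x segment-weighted hypertrophy. The segment model
is reduced to two compartments, proximal ~ CD9- and distal ~ CD9+
(CD9 expression rises along the distal nephron and is nearly absent
proximally). Defaults h_proximal = 2.0 and h_distal = 1.4 with a CD9+
baseline share of 0.6 encode the calibration targets: CD9- output
unchanged after half-mass loss (0.5 x 2.0 = 1.0), CD9+ output down 30%
(0.5 x 1.4 = 0.7), overall down ~18%, and a downward post-surgery shift
of the CD9+ fraction. These clinical percentages (like the reported
correlations R 0.46-0.7) inform *calibration only*; the package does
not claim to recompute them from data.

Rat arm: group sizes 10/8/8 (sham / uninephrectomy / 5/6th); kidney
weight at uninephrectomy 1.2 +/- 0.1 g; baseline excretion 7.5e11 +/-
1.3e11 uEVs/day; baseline GFR 3.2 +/- 0.6 ml/min with group change
factors 1.54 / 1.16 / 0.39. Terminal weight = weight at surgery x
kidney fraction (1, 1, 1/3) x hypertrophy (1, 1.4, 4.0) x sham growth
(1.4 for sham) x exp(N(0, 0.05)); post excretion uses nephron fractions
(1, 1/2, 1/6) with sigma 0.08. Sham kidney growth and sham uEV growth
(1.33) are independent dials: whole-animal growth raised GFR more than
excretion in the motivating data, so proportionality is not assumed.
The lognormal noises have medians at 1, so estimator bias from the
noise is exp(sigma^2/2) - 1 < 0.4%, comfortably inside the 5% recovery
band the tests enforce.

One `numpy.random.Generator` seeded by `config.seed` drives everything;
the same seed reproduces byte-identical CSV tables. All defaults live
in the versioned `data/defaults.yaml` (a test pins it equal to the
in-code defaults) and any field may be overridden.

What the generator does **not** emulate: intra-day excretion rhythms,
incomplete 24-h collections, proteomes or blot images, creatinine
pharmacokinetics, measurement drift between assay platforms, or
extra-renal uEV sources. Passing tests therefore demonstrate estimator
and pipeline correctness under the stated generative assumptions, not
clinical performance on real cohorts.

## Numerical and design choices

- Degenerate SDs (zero) short-circuit to the mean/one exactly, so
  noise-free configurations give bitwise-deterministic identities.
- Truncation bounds (TKV >= 50 ml, GFR >= 0.5 ml/min, 24-h volume >=
  0.2 L, ...) only guard against physically impossible draws; at default
  parameters they are essentially never active.
- Problem sizes in tests (cohorts of 100-200 donors, 120 seeded rat
  studies, 1e4-4e5 Monte-Carlo particles) are chosen so that sampling
  error sits well below the asserted tolerances while the whole suite
  runs in well under a minute.
- Group-level table reproduction feeds printed group means through the
  same per-animal functions rather than re-deriving from per-animal
  data, matching how the projection table is constructed.
- CSV tables carry a `# units:` header line; readers validate required
  columns and units and preserve unknown columns. Reports are JSON with
  provenance strings; simulation runs write a manifest (seed, config
  hash, package version).

## Limitations

- The hypertrophy projection is bookkeeping, not biology: it assumes
  uEV output proportional to functioning tissue and cannot separate
  hypertrophy from hyperfiltration-driven per-cell changes.
- The two-compartment CD9 segment model is a deliberate simplification
  of at least five nephron segments with graded CD9 expression.
- `calculated_spot_excretion` presumes a steady excretion/creatinine
  ratio across the day; spot urines taken during rapidly changing flow
  or after exercise violate this.
- The eGFR values are consumed as inputs; no estimating equation or
  body-surface normalization is implemented.
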