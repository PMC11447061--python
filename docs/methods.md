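# Methods

This note documents the models, estimators, synthetic data and numerical
choices behind `oralmm`. All symbols follow the conventions used in the
oral-minimal-model literature.

## Setting

The package analyses extended oral glucose tolerance tests (OGTT) in
adults with pancreatic-insufficient cystic fibrosis (PI-CF): a 75 g oral
glucose load with two fasting draws (−10, −1 min) and post-dose sampling
at 10, 20, 30, 45, 60, 90, 120, 150 and 180 min, measuring glucose
(mmol/l), insulin (pmol/l) and C-peptide (pmol/l). Any grid with at
least eight points and one fasting anchor is accepted; basal values are
the arithmetic mean of the fasting draws.

Glucose tolerance is classified from the 1 h and 2 h samples:
CFRD when 2 h glucose ≥ 11.1 mmol/l; IGT when 2 h glucose is
7.8–11.0 mmol/l; otherwise EGI (early glucose intolerance) when 1 h
glucose ≥ 8.6 mmol/l and NGT when below. The 2 h criterion dominates,
so the four labels partition the (1 h, 2 h) plane, ordered
NGT < EGI < IGT < CFRD for trend tests.

## The three minimal models

**Insulin secretion (oral C-peptide minimal model).** Above-basal
C-peptide follows two-compartment kinetics with population rate
constants, fed by a secretion rate per unit accessible volume:

    dcp1/dt = −(k01 + k21) cp1 + k12 cp2 + sr(t),   cp1(0) = 0
    dcp2/dt = k21 cp1 − k12 cp2,                    cp2(0) = 0
    sr(t)   = sr_d(t) + sr_s(t)
    sr_d(t) = Φ_d · max(dG/dt, 0)
    τ dsr_s/dt = −sr_s + Φ_s · max(G(t) − h, 0),    sr_s(0) = 0

With C-peptide in pmol/l and glucose in mmol/l the numeric values of
Φ_d, Φ_s are on the conventional 10⁻⁹ (min⁻¹) scales, since
pmol/mmol = 10⁻⁹. Total responsivity is the ratio of integrals
Φ_total = ∫sr dt / ∫(G − G_b) dt over 0–180 min; the dynamic part of
the numerator is evaluated in closed form (Φ_d × summed positive
glucose increments) because sr_d is discontinuous at sampling knots.
Basal responsivity is Φ_b = k01·CP_b/G_b. Peak summaries (ISR_max,
T_max per component) are read off a 1 min evaluation grid.

The population C-peptide constants are configuration data, not
estimates: fast-phase fraction F = 0.76 (non-diabetic) / 0.78
(diabetic), fast half-life 4.95 min, slow half-life 29.2 / 33.5 min,
mapped to rates via a = ln2/t½fast, b = ln2/t½slow, k12 = F·b + (1−F)·a,
k01 = a·b/k12, k21 = a + b − k01 − k12, and accessible volume
V_c = 1.92·BSA + 0.64 litres (DuBois BSA). Diabetic status for this
table follows the CFRD classification. All of these can be overridden
per study.

**Insulin sensitivity (oral glucose minimal model).** Glucose kinetics
with remote insulin action X and an exogenous rate of appearance Ra:

    dG/dt = −(S_G + X) G + S_G G_b + Ra(t)/(V·18.016),  G(0) = G_b
    dX/dt = −p2 (X − S_I (I(t) − I_b)),                 X(0) = 0

G in mmol/l, I in pmol/l, Ra in mg kg⁻¹ min⁻¹, V in dl/kg (18.016
converts mg/dl to mmol/l). S_I is reported on the 10⁻⁴ pmol⁻¹ l min⁻¹
scale. Ra is piecewise linear on fixed breakpoints
{0, 10, 30, 60, 90, 120, 180} min, zero at both ends, with its area
constrained to 90 % absorption: AUC(Ra) = 0.9·D/weight (D in mg). The
breakpoints are a subset of the sampling times; they are configurable.

**Insulin clearance and hepatic extraction (one-compartment insulin
model).** Newly secreted insulin (equimolar with C-peptide secretion,
ISR = sr·V_c in pmol/min) reaches plasma after constant first-pass
hepatic extraction HE and is eliminated linearly:

    dI/dt = −n I + (1 − HE) ISR_ab(t)/(V_i·weight),  I(0) = 0 (above basal)

with basal closure (1 − HE)·ISR_b = n·I_b·V_i·weight. The insulin
distribution volume V_i = 0.14 l/kg is configuration, not estimated:
n, HE and V_i are not jointly identifiable from one insulin curve, and
the fractional clearance n (min⁻¹) — the headline outcome — is
invariant to V_i under the closure. HE is held constant across the
test; a sensitivity variant re-fits clearance with HE pinned at 50 %.
A profile of the weighted objective over (HE, n) is available as an
identifiability diagnostic and raises a ridge warning when the profiled
valley is flat (within 5 %) across the HE range.

## Estimation

All fits minimise weighted residual sums of squares with weights
1/(CV·y)² from assay-level coefficients of variation (glucose 2 %,
insulin 6 %, C-peptide 5 %; configurable). Forcing signals (glucose for
the secretion model, insulin for the glucose model, ISR for the insulin
model) are piecewise-linear interpolants of the sampled curves, with the
right-hand slope at knots. Residuals are taken at the post-dose samples
on (0, 180] min; fasting samples anchor the basal values only. Missing
interior samples are linearly interpolated for AUC-type indices but
excluded from fit residuals.

Positive parameters are searched on a log scale and HE through a logit
parameterisation, which enforces bounds without constrained
optimisation. The engine draws Latin-hypercube multi-starts (default 10,
fixed seed 20200801) and returns the best optimum along with
Gauss–Newton fractional SDs; identical seeds give bit-identical results.
Cohort-scale drivers use fewer starts (a data-informed initial point
plus 0–1 random starts), which the recovery studies show is sufficient
for these conditionally linear problems.

Two structural simplifications keep the fits fast and well behaved,
without changing the minimised objective:

- *Conditional linearity (variable projection).* Φ_d and Φ_s enter the
  C-peptide prediction linearly and are profiled out of the search over
  τ (and h) by nonnegative linear least squares; the interior Ra nodes
  enter the glucose prediction linearly and are profiled out of the
  search over (S_I, S_G, p2, V) subject to Ra ≥ 0 and the absorption
  equality (eliminated by pivoting, with a clip-and-rescale fallback
  that preserves the area and is flagged); (1 − HE) is profiled out of
  the one-dimensional search over n.
- *Exact linear propagation.* Between forcing knots every model is a
  linear ODE with piecewise-linear input, so states are propagated by
  exact first-order-hold maps in the eigenbasis (threshold crossings of
  max(G − h, 0) are inserted as exact segment nodes). The only
  numerically integrated state is glucose, whose coefficient S_G + X(t)
  varies in time; it uses a fixed-step fourth-order affine recurrence on
  a knot-aligned grid (0.5 min for simulation, 1 min inside the fit),
  verified against an adaptive integrator at < 10⁻⁶ mmol/l.

By default S_G and V are estimated within literature-scale bounds.
Because a single glucose curve cannot separate S_I from S_G/V/p2 at
assay noise (the objective has a long flat ridge), the glucose-model fit
runs two stages: a plain weighted least-squares stage, then a maximum a
posteriori stage with log-scale population priors on S_G (median 0.022,
sd 0.25), p2 (0.014, 0.35) and V (1.6 dl/kg, 0.15) — S_I itself carries
no prior. The prior weight is scaled by the stage-1 reduced chi-square,
so exact data switch the prior off (noise-free recovery is exact to
optimizer precision) while noisy data shrink only the ill-identified
nuisance directions. Threshold h of the secretion model is fixed at
basal glucose by default (the usual identifiability choice); freeing it
is a flag.

Subjects whose fits fail or are flagged are retained in classification
and index outputs and excluded from model-parameter statistics, with
reasons in the fit log. Two structural flags exist: a flat C-peptide
trace against rising glucose drives both Φ parameters to their lower
bounds (no secretion signal), and severely insulin-deficient curves
carry no insulin-action signal, in which case the S_I estimate crashes
to the search floor or its Gauss–Newton SD exceeds the estimate itself
(fractional SD > 100 %); such an S_I is reported but marked
non-identifiable rather than treated as a precise number. In the
synthetic recovery studies these flagged fits have ~100 % error while
the identifiable ones keep median errors near 10 %, confirming the flag
separates information from noise.

## Simple indices

HOMA-IR = G_b·I_b/22.5 (G in mmol/l, I in µU/ml; pmol/l ÷ 6.0).
Matsuda = 10000/√(G_f·I_f·Ḡ·Ī) with G in mg/dl (× 18.016), I in µU/ml,
using exactly the −1, 30, 60, 90 and 120 min samples (fasting anchor at
−1 min; missing samples interpolated with a logged warning). The
Stumvoll index uses the demographics-free OGTT variant
0.226 − 0.0032·BMI − 0.0000645·I₁₂₀ − 0.0037·G₉₀, whose scale
(~0.03–0.12) matches the values this population prints; other variants
can be substituted. The rough clearance estimate is total AUC of
C-peptide over total AUC of insulin, both by trapezoid over 0–180 min
with the t = 0 anchor interpolated between the −1 and 10 min draws.

## Group statistics

Model parameters are summarised in saturated linear models on the
(optionally log-transformed) outcome with tolerance-group indicators and
HC3 sandwich covariance; marginal means with 95 % t-based CIs are
back-transformed to geometric means for log-scale outcomes (Φ_d and S_I,
which are right-skewed). All pairwise contrasts are reported unadjusted
for multiplicity (flagged at p < 0.05), matching common practice for
these four-group descriptive comparisons; this is a documented caveat.
Trend tests regress the outcome on the ordinal group code (robust SE,
t-reference Wald test for linear outcomes; plain logit for binary
traits); for log-scale outcomes the log-scale trend is primary and the
raw-scale trend is also reported. Under a simulated null at the study's
group sizes both tests reject at 5.0 ± 1 % (verified over 2000
replicates in the acceptance suite).

The disposition index is the per-subject product Φ_total × S_I on the
printed scales (10⁻⁹ × 10⁻⁴ = 10⁻¹³). Group-level disposition is the
coefficient β of the reciprocal hyperbola Φ_total = β/S_I with both
asymptotes at zero, fitted by ordinary least squares in Φ; the closed
form β = Σ(Φ_i/S_i)/Σ(1/S_i²) is used and cross-checked against a
numeric minimiser. Note the 1/S_i² weighting makes β sensitive to
subjects with very low fitted S_I. Association models follow the
one-predictor-per-model design with HC3 SEs: the minimal set adjusts for
BMI; the multivariable set for BMI, age, sex and modelled S_I; tolerance
enters as an ordinal code when it is the predictor, and a covariate
identical to the predictor is dropped from its own adjustment set.
Normality screening is emitted as Q-Q plot artifacts, not an automated
gate.

## Synthetic cohorts

The generator emulates a 61-subject PI-CF cohort in four strata (default
sizes 13/20/10/18). Per-group parameter distributions are log-normal
(median, CV) — HE logit-normal so it stays in (0,1) — with medians
graded to encode the structure the models should resolve:

| parameter (median) | NGT | EGI | IGT | CFRD | CV |
|---|---|---|---|---|---|
| S_I (10⁻⁴ pmol⁻¹ l min⁻¹) | 1.8 | 1.1 | 0.85 | 0.30 | 0.30 |
| S_G (min⁻¹) | 0.024 | 0.023 | 0.021 | 0.020 | 0.20 |
| p2 (min⁻¹) | 0.020 | 0.016 | 0.014 | 0.012 | 0.30 |
| V (dl/kg) | 1.6 | 1.6 | 1.6 | 1.6 | 0.12 |
| Φ_d (10⁻⁹) | 2000 | 600 | 500 | 100 | 0.35/0.40 |
| Φ_s (10⁻⁹ min⁻¹) | 50 | 40 | 35 | 9 | 0.30/0.35 |
| τ (min) | 5 | 13 | 16 | 26 | 0.30 |
| fasting glucose (mmol/l) | 5.1 | 5.4 | 5.6 | 7.7 | 0.06 |
| basal C-peptide (pmol/l) | 350 | 360 | 380 | 300 | 0.25 |
| clearance n (min⁻¹) | 0.16 | 0.16 | 0.17 | 0.20 | 0.22 |
| HE | 0.50 | 0.50 | 0.50 | 0.50 | 0.30 (logit sd) |

Secretion indices are flat across NGT–EGI–IGT and collapse in CFRD; S_I
declines monotonically; the secretion delay lengthens with intolerance;
clearance is highest in CFRD while HE is flat. Fasting glucose medians
track the observed group means. Covariates (age, sex prevalence, BMI)
follow the published group summaries, heights are drawn by sex and
weight is derived from BMI; insulin-treated status is a flag on 61 % of
CFRD subjects (treatment withheld before the test, so no insulin dosing
is simulated). Basal insulin is not drawn: it is derived from the
clearance model's basal closure with ISR_b = k01·CP_b·V_c, so every
subject is internally consistent across all three models. The glucose
absorption profile is a jittered triangular template on the Ra
breakpoints, rescaled exactly to the 90 % dose constraint.

Each subject's glucose, C-peptide and insulin curves are co-simulated to
a joint fixed point of the three models (coupling order Ra template →
glucose → secretion → insulin). Up to five damped passes are followed,
if needed, by a quasi-Newton root solve on the sampled insulin vector,
leaving the final residual below 10⁻⁴ (typically 10⁻⁹). Within the
generator every downstream stage is driven by the sampled-grid
interpolant of the upstream signal — the same convention the estimators
use — so that recovery error reflects noise and identifiability rather
than forcing-interpolation bias. Measurement noise is multiplicative
Gaussian at the assay CVs, applied independently per sample. The medians
above were set once so that the noise-free curves of each stratum fall
into their intended tolerance class for most draws (overlap at the
category boundaries is deliberate and realistic).

Passing recovery tests on these cohorts shows the estimators invert the
assumed data-generating process at realistic noise; it does not show the
models are unbiased for real PI-CF physiology (no model mismatch is
simulated: no assay drift, no non-constant hepatic extraction, no
gastric-emptying structure beyond the piecewise-linear Ra class).

## Validation surface and problem sizes

The acceptance suite (and `scripts/acceptance.py`) recomputes, from
scratch: the classification boundary cases; the cohort share summary
(13/20/10/18 → 21/33/16/30 %, shares rounded to whole percent);
noise-free recovery (40 subjects, 10 per stratum — max relative error
≤ 1 % for S_I, Φ_d, Φ_s, n, HE); noisy recovery medians at assay CVs
(S_I and Φ_total < 15 %, n < 20 %, Φ_d < 25 %); the Ra area constraint
(≤ 0.5 % deviation for every converged fit); null calibration of the
trend and pairwise tests (2000 replicates, 0.05 ± 0.01); exactness of
the numerical primitives against independent oracles (trapezoid vs
fine-grid integral, hyperbola closed form vs numeric minimiser,
two-compartment impulse response vs biexponential, Spearman vs midrank
Pearson); and the three qualitative group orderings across 50 replicate
default cohorts (each in ≥ 90 % of replicates). The replicate studies
use single-start fits with data-informed initialisation, which the
recovery studies justify for these conditionally linear fits.

## Known limitations

- The flat-ridge geometry of the glucose model means noisy S_I estimates
  rely on the population priors for their nuisance parameters; grossly
  atypical S_G or V would bias S_I.
- HE and n trade off along a near-ridge for insulin curves with little
  shape information; estimates are crude there and the profile
  diagnostic should be consulted.
- The hyperbola coefficient β is dominated by low-S_I subjects under the
  plain least-squares weighting; a log-space variant is available.
- WinSAAM-style weighting and convergence rules are not documented in
  detail anywhere public; numerical equivalence with that tool is not
  claimed — the contract here is internal consistency, recovery and
  calibration as stated above.
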