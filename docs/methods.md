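# Methods

## Setting and notation

Each patient record carries predicted body weight PBW (kg), computed from
height and gender (male: 50 + 2.3·(height_in − 60); female: 45.5 +
2.3·(height_in − 60)), the lowest set tidal volume Vᴛ (mL), its
standardized form V̂ᴛ = Vᴛ / PBW (mL/kg PBW), first and lowest PaO₂/FiO₂
(P/F), optional highest plateau pressure, an ARDS-documentation flag, and
cohort membership (ARDS vs non-ARDS hypoxemic control). Inclusion requires
PBW ≥ 25 kg, intubation ≥ 5.67 h and lowest P/F ≤ 300. Berlin severity
strata on the lowest P/F: mild (200, 300], moderate (100, 200], severe
(0, 100]; boundaries belong to the worse stratum. LTVV means V̂ᴛ ≤ 6.5
mL/kg PBW (inclusive).

The analysis subgroups are pooled documented (either cohort, ARDS charted),
ARDS non-documented, and control non-documented. Both recognition models
assume: a recognised ARDS patient is ventilated like a documented patient;
an unrecognised one like a non-documented control. Documentation implies
recognition, so documented patients always count as recognised.

## Statistical procedures

**Regression screen.** Univariable OLS of V̂ᴛ on each candidate factor,
factors min-max rescaled to [0, 1] (binary 0/1 factors enter unscaled;
admitting ICU as indicator contrasts against the largest unit, flagged on
its smallest contrast p). Significance: α = 0.01 Bonferroni-corrected over
33 V̂ᴛ-outcome comparisons → p < 0.0003. Covariate fits of documentation on
rescaled lowest P/F and PBW are Newton-Raphson logistic regressions
(tolerance 1e-8, 100 iterations, perfect separation flagged rather than
silently diverging), threshold p < 0.005. Multivariable selection
enumerates every non-empty subset of the significant factors, each
augmented with every subset of pairwise interaction products, ranked by
AIC (BIC reported); ties break to fewer parameters, then lexicographic
factor order; with fewer than two significant factors selection is skipped.
Complete cases are taken per fitted model, never globally. Two sensitivity
filters rerun the screen on study duration strictly > 12 h and on PBW
strictly inside its empirical 2.5–97.5 percentile interval (linear
interpolation).

**KDE / Naïve Bayes.** Densities use a separable Gaussian product kernel
with per-axis Scott bandwidths sd · n^(−1/6), evaluated on a fixed grid
(PBW 15–115 kg step 0.5; V̂ᴛ 0–18 mL/kg step 0.05). The grid extends a few
bandwidths beyond the data range so that edge kernels keep their mass and
the trapezoidal integral stays within 1e-2 of 1 even for small bootstrap
resamples; bandwidths are floored at the grid step, below which the grid
could not resolve the kernel. Off-grid densities are bilinear
interpolations; outside the grid the density is 0. Posterior odds use flat
priors (0.5, 0.5) by default; odds > 1 classifies a patient as recognised,
while ties and 0/0 odds count as unrecognised — the conservative choice
that biases against over-claiming recognition. The decision boundary is,
per PBW column, the first documented→control sign change of
f_doc·p_doc − f_ctrl·p_ctrl scanned upward in V̂ᴛ within the region of
non-negligible total density. Its confidence band bootstraps the control
non-documented subgroup (default 100 iterations) at a resample size equal
to the pooled-documented count — the subgroup-size imbalance is the
motivation for bootstrapping, so matching sizes is the default, with the
original-size convention available by configuration. Degenerate resamples
(a single unique point) are redrawn and logged.

**L1 mixture.** Histograms share fixed bins; the objective
Δ(f) = Σ_b |h_ARDS,b − f·h_doc,b − (1−f)·h_ctrl,b| is piecewise linear and
convex on [0, 1]. Two equivalent solvers are provided: the
epsilon-formulation linear program (HiGHS via scipy) and an exact scan of
the objective's breakpoints (the residual roots c_b/d_b), which is the
default because a bootstrap of 1000 refits makes solver cost matter. A
flat argmin segment wider than 1e-9 is reported as its midpoint with a
non-uniqueness flag — silently picking an arbitrary solver vertex would
break reproducibility. The documented reference pools both cohorts'
documented patients unconditioned on severity; the control reference is
severity-matched on the controls' own lowest P/F; the target stratum uses
all ARDS patients of that severity (documented included), so the estimate
is directly comparable with the documented rate. Bootstrap: resample the
stratum's ARDS records with replacement (same n), references held fixed by
default (resampling them too is a configuration option); report the mean
and the 0.5–99.5 percentile interval. Strata under 5 records are refused.
Pairwise severity comparisons use the two-sample KS test (asymptotic p)
at p < 0.003 (0.01/3).

Every threshold above lives in `AnalysisConfig`; stage code contains no
literal cut-offs.

## Bin-width calibration

The mixture bins default to PBW 10 kg over [25, 105] and V̂ᴛ 1.0 mL/kg over
[2, 14] (~96 cells). This was calibrated by planted-fraction recovery
simulation at study scale (361/388, planted fractions 0.22/0.34/0.67,
20 replicates): with fine bins (5 kg × 0.5 mL/kg, ~360 cells) the severe
stratum's estimate is biased upward by ≈ +0.07, because a reference
histogram with only ~20–60 patients leaves sampling zeros in cells where
the target has mass, and the L1 fit shifts weight away from the sparser
reference. The 10 kg × 1.0 mL/kg grid cuts that bias to ≈ +0.03–0.06 with
per-severity recovery sd ≈ 0.06–0.10. Coarser grids trade bias in the
severe stratum for variance in the mild one. Bins are config-overridable;
users with larger reference subgroups can and should refine them.

## The synthetic cohort generator

The generator emulates the structure the analyses assume, with a latent
per-patient recognition state as ground truth. Defaults (one draw per
`CohortConfig`, fully determined by its seed):

- cohort sizes 361 ARDS / 388 control; 55% male;
- heights N(69, 3) in (male) and N(64, 2.8) in (female), redrawn to keep
  PBW ≥ 25 kg → gender-bimodal PBW;
- lowest P/F from lognormals truncated to (0, 300] by inverse-CDF:
  median 140, σ 0.55 (ARDS: ≈ 19% mild / 51% moderate / 30% severe) and
  median 180, σ 0.50 (control: ≈ 39/47/14) — an intubated hypoxemic-failure
  population carries a substantial severe fraction; first P/F is the lowest
  inflated by an exponential factor, capped at 300;
- recognition ~ Bernoulli per severity (defaults 0.22 / 0.34 / 0.67);
  documentation only for recognised patients at 0.30, which reproduces the
  ~12% ARDS documentation share; controls are documented at 0.042 so the
  pooled-documented subgroup contains control patients, as observed;
- tidal volumes: recognised (and documented-control) patients target
  N(6.0, 0.7) mL/kg × PBW rounded to the menu; everyone else draws from
  the menu {400…700 mL} with gender-specific weights putting > 70% of mass
  on {450, 500, 600} and favouring larger defaults for males;
- plateau pressure missing with probability 0.40 (not recorded at some
  hospitals), loosely anti-correlated with P/F; admission weight is PBW
  times N(1.12, 0.22); study duration 5.67 h + lognormal (≈ 6–7% of
  patients fall at ≤ 12 h, exercising the sensitivity filter).

The menu quantization is the load-bearing feature: selecting a
near-constant Vᴛ makes V̂ᴛ = Vᴛ/PBW fall mechanically with PBW, which is
exactly the emergent association the regression screen must flag in *both*
cohorts.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: longitudinal tidal-volume titration (only
a lowest Vᴛ exists), hospital- or physician-level clustering, radiographic
findings, severity-dependent ventilation *within* the recognised and
unrecognised behaviours (recognition state is the only V̂ᴛ–severity link),
and any direct continuous effect of hypoxemia on tidal-volume choice. The
synthetic admission weight is also more tightly coupled to PBW than real
body weight is, so the screen may flag it where a real cohort would not.

## Problem sizes used in validation

Recovery and separation suites run 20 replicate cohorts at study scale
with 500-resample bootstraps; the optimizer oracle checks 200 random
histogram triples against a 0.001-step grid; OLS confidence-interval
calibration uses 1000 simulations. The acceptance script averages its
recognition and regression quantities over 5 replicate cohorts with the
full 1000-resample bootstrap.

## Known limitations

- At study scale the mixture estimator's bootstrap mean retains a small
  upward bias in the severe stratum (sparse severity-matched control
  reference) and ≈ 0.1 sd in the mild one; the 99% bootstrap CIs cover the
  planted fractions almost always, but point recovery to better than ±0.1
  per replicate is not guaranteed.
- The Naïve Bayes fractions run systematically above the planted
  recognition probabilities in the mild and moderate strata: tall patients
  on default 450–600 mL menus land near or below 6.5 mL/kg and are
  classified as recognised-style behaviour. The estimate is a behavioural
  upper bound, informative chiefly through its ordering across severities.
- The KS comparisons are between bootstrap distributions, whose spread
  shrinks with resample count; their p-values order strata but should not
  be read as population-level inference.
- Histogram bins and KDE grids assume adult PBW/V̂ᴛ ranges; paediatric
  extracts would need reconfigured ranges.
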