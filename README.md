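# ardsrec

Quantifying physician recognition of acute respiratory distress syndrome
(ARDS) from ventilator settings in electronic-health-record data.

## The problem

Low tidal volume ventilation (LTVV, ≤ 6.5 mL per kg of predicted body
weight) is the evidence-based therapy for ARDS, yet it is widely underused —
largely because physicians often fail to recognise ARDS at the bedside.
Chart documentation is a poor proxy for recognition: a physician may
recognise ARDS, ventilate accordingly, and never write the word in a note.
`ardsrec` implements a behavioural alternative: infer recognition from what
physicians *do* — the standardized tidal volume V̂ᴛ = Vᴛ / PBW they select —
rather than what they document.

The package is aimed at ICU quality-improvement and clinical-informatics
researchers who have per-patient ventilator extracts (cohort label, gender,
height, PaO₂/FiO₂, tidal volumes, documentation flags) and want a
recognition estimate that is not confounded by patient characteristics.

## The models

Patients are split into three subgroups: **pooled documented** (ARDS charted
— recognised behaviour), **control non-documented** (no ARDS, no chart —
unrecognised behaviour), and **ARDS non-documented** — the group of interest,
modelled as a latent mixture of the other two behaviours.

1. **KDE / Naïve Bayes classifier.** Gaussian-kernel densities of the two
   reference subgroups are fitted in the (PBW, V̂ᴛ) plane and each
   non-documented ARDS patient is classified by the posterior odds

   P(doc | PBW, V̂ᴛ) / P(ctrl | PBW, V̂ᴛ)
   = [f̂_doc(PBW, V̂ᴛ) · P(doc)] / [f̂_ctrl(PBW, V̂ᴛ) · P(ctrl)],

   with flat priors. Odds > 1 ⇒ recognised. Bootstrap resampling of the
   control subgroup yields confidence bands on the decision boundary.

2. **L1 mixture model.** Within each Berlin severity stratum
   (mild 200 < P/F ≤ 300, moderate 100 < P/F ≤ 200, severe P/F ≤ 100), the
   ARDS histogram over (V̂ᴛ, PBW) bins is decomposed as

   h_ARDS ≈ f · h_doc + (1 − f) · h_ctrl,   minimising
   Δ(f) = Σ_b | h_ARDS,b − (f · h_doc,b + (1 − f) · h_ctrl,b) |,

   a linear program in the recognised fraction f. Bootstrapping the
   stratum gives a mean and percentile 99% CI; pairwise two-sample
   Kolmogorov–Smirnov tests compare the severity strata at the
   Bonferroni-corrected threshold p < 0.003.

A regression stage reproduces the screening that motivates the (PBW, V̂ᴛ)
feature plane: min-max rescaled univariable OLS of V̂ᴛ on candidate
determinants with α = 0.01 and Bonferroni correction (p < 0.0003 over 33
comparisons), all-subsets AIC/BIC multivariable selection, logistic
covariate checks, and two sensitivity filters (study duration > 12 h,
central 95% of PBW).

Because no patient-level data ship with the package, a synthetic cohort
generator (`ardsrec.synthetic`) emulates the statistical structure such
extracts exhibit — gender-bimodal PBW, a quantized tidal-volume menu
dominated by 450/500/600 mL, hypoxemia-dependent latent recognition, and
documentation conditional on recognition — with the latent state retained
as ground truth so every stage is testable end to end.

## Worked example

```bash
ardsrec run-all --seed 1 --out results/
```

prints (361 synthetic ARDS and 388 control patients, default conditions):

```
Physician recognition of ARDS by hypoxemia severity
severity    n  doc_n  doc%  naive_bayes%  mixture% [99% CI]
mild        69      5     7            30       12 [0, 43]
moderate   172     16     9            37       25 [8, 49]
severe     120     28    23            68       65 [35, 91]
```

Reading the table: of the 120 severe-hypoxemia ARDS patients only 23% had
ARDS documented, but both behavioural models attribute recognised-style
tidal-volume selection to roughly two-thirds of the stratum — recognition
far exceeds documentation, and it rises steeply with hypoxemia severity.
The generating cohort planted per-severity recognition probabilities of
0.22 / 0.34 / 0.67; the mixture column recovers them within its CI (a
single cohort carries several points of sampling noise). `results/` also
receives the cohort CSV, per-factor regression results, per-patient
classifications, the decision boundary with bootstrap bands, the KS table
and a YAML run manifest with all derived sub-seeds.

The library surface mirrors the pipeline: `generate_cohort`,
`split_subgroups`, `univariable_screen` / `multivariable_select`,
`fit_kde2d` / `nb_recognition_by_severity`, `build_hist2d` /
`estimate_fraction` / `bootstrap_fractions` / `ks_compare`, and
`run_pipeline`.

## Further reading

`docs/methods.md` documents the model assumptions, the synthetic-data
generator's design and its limits, numerical choices (bin-width
calibration, bandwidth rules, tie-breaking) and known limitations.
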