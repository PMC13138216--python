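# traumameta

Individual-participant-data (IPD) analysis of acute and persistent
posttraumatic stress disorder (PTSD) and major depressive disorder (MDD)
after trauma, for biostatisticians and epidemiologists pooling multi-study
emergency-room cohorts.

Pooling raw participant data across studies buys power and modelling
consistency but creates three methodological problems this package solves as
a tested, reusable pipeline:

1. **Instrument harmonization.** Depression is measured by the 21-item
   BDI-II in some studies and the 7-item HADS depression subscale in others.
   Both are calibrated with a graded response model
   (`P(X ≥ k | θ) = logistic(a(θ − b_k))`), placed on one latent metric by
   mean/sigma linking through three shared CAPS anchor symptoms, and
   connected by a true-score crosswalk: each HADS total (0–21) maps to an
   equated BDI total (0–63) via inversion of the test characteristic curves.
   Under the packaged crosswalk the probable-MDD cut BDI ≥ 20 corresponds to
   HADS ≥ 13. Unidimensionality is checked by ordinal CFA on polychoric
   correlations (CFI/TLI > 0.95, RMSEA < 0.06).
2. **Outcome classification.** CAPS interviews at an acute (0–60 days) and a
   follow-up (122–456 days) wave are scored to DSM-IV diagnoses (severity
   0–136; symptom present if frequency ≥ 1 and intensity ≥ 2; diagnosis
   requires ≥ 1 reexperiencing, ≥ 3 avoidance, ≥ 2 hyperarousal symptoms)
   and each participant is labelled Never / Acute / Persistent per disorder.
3. **Inference under missingness and heterogeneity.** Missing follow-ups are
   multiply imputed by chained equations honouring the two-level structure
   (participant random intercepts, fixed study dummies, study-specific
   residual variances, |r| ≥ 0.10 predictor screening) and pooled by Rubin's
   rules. Risk-factor effects come from multinomial logit models (Never as
   reference), with likelihood-ratio tests of equal acute/persistent
   coefficients via constrained fits, and logistic persistence models with
   odds ratios per 5 severity points (depression, PTSD clusters) or 15
   points (total PTSD). Study heterogeneity is quantified by bootstrap
   out-of-bag calibration: per-study expected/observed ratios and Brier
   scores under fixed, random-intercept and unadjusted study models, plus
   leave-one-study-out and follow-up-window sensitivity reruns.

Because consortium data of this kind are access-restricted, the package
ships a first-class synthetic cohort generator that emulates the five-study
structure (sizes, instruments, assessment timing, follow-up loss) with
exactly known generative odds ratios, so every stage is testable by
parameter recovery.

## Worked example

```python
from traumameta import (generate_cohort, default_study_configs,
                        load_reference_crosswalk, equate_score)
from traumameta.classify import classify_cohort
from traumameta.models import pool_multinomial
from traumameta.pipeline import impute_analysis_table

xw = load_reference_crosswalk()
equate_score(xw, 13), equate_score(xw, 21)   # -> (20, 63)

cohort = generate_cohort(default_study_configs(scale=0.25), seed=42)
wide = classify_cohort(cohort.data, xw)
wide["ptsd_trajectory"].value_counts()
# Never                     382
# Unclassifiable-missing    167
# Acute                      55
# Persistent                 32
# Delayed                     7

completed, meta = impute_analysis_table(wide, m=5, cycles=5,
                                        threshold=0.10, seed=7)
ors = pool_multinomial(completed, "ptsd")
ors[ors["predictor"].isin(["female", "index_assault"])]
#    outcome     predictor   or  or_low  or_high
#      Acute        female 1.03    0.61     1.73
#      Acute index_assault 1.11    0.44     2.76
# Persistent        female 2.30    1.15     4.59
# Persistent index_assault 2.39    0.88     6.53
```

The equated scores are the packaged crosswalk lookups; the trajectory counts
show the five labels a two-wave design produces (about 26% of follow-ups are
lost at this scale's study-specific rates and await imputation); the pooled
odds ratios are Rubin-combined across the five imputed datasets — the
female → persistent-PTSD OR of 2.30 (95% CI 1.15–4.59) brackets this
cohort's generative value of 2.14, and the wide assault CI reflects the small
assault stratum at quarter scale.

The same pipeline is scriptable from the shell:

```bash
traumameta run-all --seed 11 --out run_output --imputations 5
```

which writes the cohort, crosswalk, classified analysis table, imputed-data
metadata, odds-ratio and LRT tables, descriptive tables, and the per-study
calibration report into `run_output/` with a checksummed manifest.

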