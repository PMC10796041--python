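# mdci — multidimensional diagnosis-based comorbidity index

`mdci` builds mortality-prediction comorbidity indices from longitudinal
ICD-10 diagnosis histories, for epidemiologists and biostatisticians working
with administrative health registers (hospital inpatient and specialist
outpatient discharge records). Classical indices such as the Charlson
comorbidity index reduce a patient's history to the yes/no occurrence of a
few pre-specified diagnoses; much of the prognostic information in a
register — how often a code recurs, how recently it appeared, how long the
associated hospital stays were — is discarded. `mdci` keeps it.

## The method

For every ICD-10 code observed in a development cohort, the code first
contributes at four granularity levels (`I731` → `I7`, `I73`, `I731`,
`I7319`; codes recorded short are elongated with trailing `9` =
"unspecified"). Variants present in at least 0.01% of the cohort are kept.
Each retained variant *v* then generates ten binary predictors over the
10-year lookback window before each subject's index date:

| dimension | definition |
|---|---|
| `occ_primary`, `occ_any` | ≥1 occurrence as primary / any diagnosis |
| `freq_ge2`, `freq_ge3`, `freq_ge4` | primary occurrences on ≥2/3/4 distinct dates |
| `rec_90`, `rec_180`, `rec_365` | ≥1 primary occurrence within 90/180/365 days of index |
| `dur_gt7`, `dur_gt14` | total inpatient days with *v* primary > 7 / > 14 |

With x the resulting sparse binary vector, the index is the linear
predictor of an elastic-net-penalized Cox proportional-hazards model for
10-year all-cause mortality,

```
minimize_β   −(1/n)·ℓ(β)  +  λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],      MDCI(x) = xᵀβ̂,
```

where ℓ is the Breslow partial log-likelihood. λ is selected by stratified
10-fold cross-validation over a 100-value log-spaced grid descending from
λ_max (the smallest penalty giving the all-zero solution), maximizing the
event-weighted mean of fold-wise Harrell c-indices on held-out linear
predictors; ties go to the sparser model. A subject's MDCI is the sum of
the selected coefficients over their positive predictors; subjects are
categorized by the development-cohort quartiles of the score.

The package also provides a Charlson comparator (Quan 2005 ICD-10 coding,
editable table, optional cancer-cohort exclusion of the outcome code C61
and its C77–80 metastases), a validation suite (Harrell c-index with
bootstrap CIs, Breslow-baseline calibration curves, Kaplan–Meier
stratification, stratified 1-year hazard ratios, index correlations), and a
synthetic register simulator whose hazard acts through the same ten
predictor dimensions — so the whole pipeline, including parameter
recovery against known truth, is testable without access to patient data.

## Worked example

```python
from mdci import (SimulationConfig, simulate_cohort, build_vocabulary,
                  build_design_matrix, fit_penalized_cox, horizon_censor,
                  mdci_score, harrell_cindex)

cohort = simulate_cohort(SimulationConfig(n_subjects=6000, seed=1))
years = cohort.subjects["index_date"].dt.year
dev, val = (years <= 2013).to_numpy(), (years > 2013).to_numpy()   # temporal split

vocab = build_vocabulary(
    cohort.events[cohort.events["subject_id"].isin(set(cohort.subjects["subject_id"][dev]))],
    n_subjects=int(dev.sum()))
dm = build_design_matrix(cohort.events, cohort.subjects, vocab)
t, e = horizon_censor(cohort.subjects["time_days"], cohort.subjects["event"], 10)

index = fit_penalized_cox(dm.X[dev], t[dev], e[dev], alpha_mix=0.5,
                          n_lambda=50, n_folds=5, seed=1, columns=dm.columns)
scores = mdci_score(index, dm.X[val])
print(f"vocabulary: {len(vocab)} variants -> {10*len(vocab)} candidate predictors")
print(f"selected:   {len(index.selected())} predictors at lambda={index.chosen_lambda:.4f}")
print(f"10-year c-index (validation): {harrell_cindex(scores, t[val], e[val]):.3f}")
```

prints (numbers from this exact run):

```
vocabulary: 191 variants -> 1910 candidate predictors
selected:   74 predictors at lambda=0.0378
10-year c-index (validation): 0.678
Charlson c-index (validation): 0.537
top predictors:
variant dimension  coefficient
     Z3    rec_90     0.318383
    Z32    rec_90     0.292503
   Z321    rec_90     0.261949
  Z3219    rec_90     0.236145
    I63  freq_ge3     0.219581
```

The vocabulary of 191 variants expands to 1,910 candidate predictors (ten
per variant); cross-validated selection keeps 74 of them. On the held-out
2014 validation cohort the fitted index discriminates 10-year mortality
with c-index 0.678, against 0.537 for the Charlson comparator — the
synthetic truth places much of its hazard on recency/frequency/duration
features that an occurrence-only score cannot see. The strongest
predictors are recency dummies of one high-prevalence code at all four
granularity levels: nested variants are correlated, and the ridge
component of the elastic net spreads their shared effect.

A command-line interface mirrors the library
(`mdci simulate | build-features | fit | score | charlson | evaluate |
run-all`); `mdci run-all --config run.yml` drives the full pipeline and
writes vocabulary, matrices, the fitted index, scores and an evaluation
report with content hashes for reproducibility.

## Layout

- `src/mdci/simulate.py` — synthetic register generator with known truth
- `src/mdci/codes.py` — code normalization, granularity expansion, vocabulary
- `src/mdci/features.py` — ten-dimension sparse design matrix
- `src/mdci/model.py` — penalized Cox fitting, scoring, categorization
- `src/mdci/charlson.py` — Charlson comparator
- `src/mdci/evaluate.py` — c-index, bootstrap, KM, calibration, hazard ratios
- `src/mdci/pipeline.py`, `src/mdci/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, defaults and limitations
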