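# Methods

This note records the modelling assumptions, default parameters and design
choices behind `mdci`, and what the synthetic experiments do and do not
demonstrate.

## Predictor construction

**Granularity expansion.** Every cleaned code (uppercase letter + 1–4
digits; punctuation stripped; sub-classifications longer than five
characters truncated to five) is expanded to variants of length 2, 3, 4
and 5: prefixes below the recorded length, trailing-`9` padding
("unspecified") above it. Expansion is idempotent on its own outputs, and
a child variant's subject support is always a subset of its parent's, so
retained length-5 variants imply retained ancestors at any fixed
prevalence threshold.

**Vocabulary filter.** A variant is kept when the fraction of *distinct
development-cohort subjects* with at least one crediting event — any
position, any setting — is ≥ `min_prevalence` (default 0.0001, boundary
inclusive). Subject counting (rather than event counting) was chosen
because prevalence is a per-person notion; the alternative changes little
on realistic data but is not what the filter name means. An optional
`prune_redundant` switch drops a child variant whose supporting subject
set is identical to its parent's (it can carry no independent occurrence
information); it is **off** by default so that the vocabulary is exactly
the union of all four-level expansions of observed codes.

**The ten dimensions.** Frequency (≥2/3/4 distinct dates), recency
(≤90/180/365 days) and duration (>7/>14 total inpatient days) are computed
from primary-position events only; `occ_any` is the one dimension that
also credits secondary codes. Concrete conventions where a register
leaves room:

- *Stay duration* = discharge − admission in days with a 1-day minimum
  (same-day stays count one day); stays straddling either window boundary
  are clipped to the window; each distinct (admission, discharge) stay
  counts once per variant.
- *Recency* is measured from the diagnosis (event) date, not the
  discharge date, and the boundary is inclusive (exactly 90 days counts
  as within 90).
- *Unique dates* pool inpatient and outpatient primary events.
- The lookback window is `round(365.25 · years)` whole days, half-open at
  the index date: events dated on or after the index date are a schema
  error, not silently ignored. All features are functions of day
  differences only, so shifting every date and the index together changes
  nothing.

## Penalized model

The index is an elastic-net-penalized Cox model on the full binary matrix,
in the standard objective scaling `−ℓ/n + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` with
Breslow tie handling. Defaults and rationale:

- `alpha_mix = 0.5`. A strict L1/L2 mix: the L1 part performs selection,
  the ridge part spreads weight across the strongly correlated nested
  dummies (a pure lasso would pick one variant of a correlated group
  arbitrarily). Exposed as a parameter.
- 100-value log-spaced λ grid from λ_max = max|∇ℓ(0)|/(n·α) down to
  `0.01·λ_max`; the first grid point provably yields the all-zero
  solution.
- Binary predictors are scaled by their standard deviation inside the
  penalized fit (the dominant convention of penalized-regression
  software); coefficients are reported on the original 0/1 scale.
  Configurable off. Constant columns are left unscaled; they carry no
  partial-likelihood signal and stay at zero.
- Cross-validation: K = 10 folds (stratified on the event indicator,
  assignment deterministic from the seed), per-λ score = event-count-
  weighted mean of fold-wise Harrell c-indices computed on held-out linear
  predictors. Fold-wise averaging (rather than pooling held-out
  predictions) keeps each c-index within a homogeneous risk-set; the two
  options differ negligibly in practice. Tied scores choose the larger λ
  (sparser model).
- The path is solved by glmnet-style cyclical coordinate descent
  (scikit-survival's Coxnet) with tolerance 1e-7 and warm starts. The
  solver may stop a path early once the deviance saturates; remaining
  grid positions reuse the last computed solution, to which the path has
  converged. KKT subgradient conditions are verified in the test suite at
  every grid solution.
- Degenerate inputs rejected: all-censored outcome, fewer subjects than
  folds, mixing weight outside (0, 1].

Scores are categorized with the development-cohort 25/50/75% quantiles,
frozen and reused unchanged on validation cohorts; a score exactly on a
cutoff falls into the lower category.

## Charlson comparator

Quan's 2005 ICD-10 coding algorithm with the original 1/2/3/6 weights,
shipped as an editable table (register-specific adaptations can be
substituted). Primary and secondary positions count; each condition counts
once; severity hierarchies apply (moderate/severe liver disease supersedes
mild, diabetes with complications supersedes without, metastatic solid
tumour supersedes non-metastatic malignancy). Matching is by code prefix
on the recorded (cleaned) code. For cancer cohorts an exclusion rule
strips the outcome code (e.g. C61) everywhere and the metastasis block
C77–80 only for subjects who also carry the outcome code.

## Validation suite

- **Discrimination**: Harrell's c over usable pairs (a pair is usable when
  censoring leaves the ordering determinable; score ties count ½), with
  percentile bootstrap CIs from subject-level resampling (default 1000
  replicates; resamples on which a statistic is undefined are redrawn and
  counted). The index is held fixed during the bootstrap — the CI covers
  evaluation noise, not refitting noise, consistent with a temporal-split
  design where the index is frozen before validation.
- **Calibration**: a Cox model with the index score as its single
  covariate is fit on the evaluation cohort; each subject's predicted
  survival at the horizon is `exp(−H₀(h)·exp(b·score))` with Breslow
  baseline H₀. Subjects are binned on predicted survival at cutoffs
  {0, .50, .55, …, .90, 1.00}; per bin, the mean individual prediction is
  compared with the Kaplan–Meier estimate at the horizon. Empty bins are
  omitted; bins whose follow-up ends before the horizon get a flagged
  (NaN) observed value.
- **Stratified hazard ratios**: within each stratum (e.g. age band ×
  comparator level), unpenalized Cox fits of category indicators against
  Q1 over a 1-year horizon-censored outcome, Wald 95% CIs. A contrast
  needs ≥5 events in both arms, otherwise the row reports `NA` — an
  explicit smallest-cell rule standing in for the suppression conventions
  of register reports.
- **Index correlation**: Spearman by default (comorbidity scores are used
  ordinally), Pearson available.

Horizon censoring (1/5/10 years) recodes deaths after the horizon as
censored at `round(365.25·h)` days and is idempotent.

## Synthetic register generator

The generator emulates the structure of a national patient register: an
elderly male cohort (age bands 45–59/60–69/70–79/80–95 with probabilities
0.10/0.38/0.35/0.17), index dates spread uniformly over 2008–2014 (so a
temporal 2013/2014 split yields roughly 6:1 development:validation), a
10-year pre-index history of inpatient and specialist-outpatient events,
and 10-year post-index survival.

Mechanics: each of 50 synthetic conditions has a fixed ICD-10-shaped code
(lengths 3–5, spread over chapters; about a third drawn from common
chronic-disease stems so prefix-based mappings like the Charlson engage
with simulated data). Condition prevalence falls geometrically from 0.30
to 0.005. An active condition emits a Poisson stream of episodes (default
0.2/year — sparse enough that repeated coding is informative beyond mere
occurrence), each inpatient with probability 0.3. A per-subject-condition
Gamma(2) severity draw scales both the length of stay (1 + Poisson(3·s)
days) and the intensity of extra last-year "flare" episodes, so recency
and duration indicators are severity markers, correlated but not
collinear. Secondary codes co-occur with probability 0.2.

The true log-hazard is a linear combination of the subject's *realized*
predictor indicators — evaluated by the same code path the design matrix
uses — for a default truth of twelve effects spread over all four
dimensions: occurrence of chronic codes at log-HR 0.5–0.6 (one negative
−0.5 contact-with-care effect), frequency 0.6–0.8, recency 0.7–1.2 and
duration 1.0–1.3. The allocation expresses the design premise that
repeated, recent and long hospitalizations mark severe disease and carry
hazard beyond mere occurrence; hazard ratios up to ~3.7 for a recent or
long admission are within the range of severe decompensating illness.
Survival is exponential (optionally Weibull) with baseline 0.020/year,
chosen so the default cohort shows ≈30% observed ten-year mortality, with
0.01/year random dropout and administrative censoring at 10 years.

**What the simulator does not model**: competing causes of death,
emigration, primary-care contacts, calendar trends in coding practice,
chapter-level frequency structure of real registers, and within-subject
correlation of conditions beyond the shared severity mechanism. Passing
recovery experiments therefore show that the estimator finds signal of
this functional form at these effect sizes — they are evidence of
method correctness, not of real-world predictive performance, and
coefficients fitted on synthetic data transfer to nothing.

## Experiment sizes

The recovery experiment fits 20,000 development subjects (4,000 held out)
with 50 conditions, the 100-value λ grid and 5 CV folds — fold count
reduced from the 10-fold default for the experiment, which changes λ
selection negligibly at this n. Under these conditions the fitted index
recovers all twelve true effects (a true effect counts as recovered when
some granularity variant of its condition's code has a nonzero coefficient
in the exact true dimension — exact-variant attribution is ill-posed under
the nested-variant collinearity), matches the true linear predictor's
held-out c-index to well within 0.02, and beats an occurrence-only refit
by more than 0.02. The acceptance script runs the same study at 14,000
subjects end to end, including the Charlson comparator, calibration and
the Q4-vs-Q1 one-year hazard ratio.

## Known limitations

- Breslow tie handling throughout; the stratified-HR helper delegates to
  lifelines, which uses Efron — immaterial at register-scale tie rates,
  but the two likelihoods differ in edge cases.
- The calibration report's one-covariate recalibration measures
  *rank-preserving* calibration of the score, not calibration of the full
  high-dimensional model.
- `align_matrix` drops predictor columns unknown to a fitted index and
  zero-fills missing ones; scoring a cohort built against a very
  different vocabulary silently discards information (by design, but
  worth knowing).
- The prevalence filter at small cohort sizes is nearly vacuous (0.01% of
  10,000 subjects is one subject); the 45%-of-codes-surviving behaviour
  of national-register scale does not reproduce at desk scale.
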