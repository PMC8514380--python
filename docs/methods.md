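# Methods

## Signature score and call

The TP53 signature score is the ratio of the summed linear-scale expression
of the 16 mutation-up-regulated panel genes to the summed expression of the
7 mutation-down-regulated genes. Two consequences drive the implementation:

* **Scale invariance.** Multiplying a sample's profile by any c > 0 leaves
  the score unchanged, so the score is identical whether or not expression
  was first normalised to the internal controls. The three control genes
  therefore never enter the score; they serve only as an optional
  detection-QC gate (`control_qc`, configurable floor, warning not error).
* **Strict cutoff.** A sample is mutant-signature iff score > cutoff.
  The published constant 1.11 is stored as `PAPER_CUTOFF` and used for
  classification by default. A score exactly at the cutoff is wild.

Inputs must be non-negative linear values; `input_scale="log2"`
exponentiates log-stored tables before scoring. A zero down-gene sum makes
the ratio undefined and is a hard error, as is any missing scored gene
(named in the message). The gene identities live in a configuration file
(YAML or TSV); a generic 16/7/3 panel (`UP01..UP16`, `DN01..DN07`,
`CTRL1..CTRL3`) ships as the default because the score depends only on the
role partition.

## Cutoff calibration

`roc_auc` is the empirical (Mann–Whitney) concordance probability with
half-credit for ties, mutant as the positive class, computed via
scikit-learn and cross-checked in the tests against an all-pairs counting
oracle. `select_cutoff` scans midpoints between adjacent distinct scores
(±∞ sentinels), maximises Youden's J = sensitivity + specificity − 1, and
breaks ties toward the lower threshold (higher sensitivity).

On the bundled 34-sample development fixture the optimal cutoff is any
value in the open gap (1.1003, 1.2907); the scan returns the midpoint
1.1955. The published constant 1.11 lies in the same gap but is not the
midpoint, so its exact derivation is not recoverable from the printed
scores; `select_cutoff` is therefore a *recalibration tool* and never
silently replaces `PAPER_CUTOFF`.

## Survival analysis

Estimation is delegated to `lifelines` (Kaplan–Meier, the k-group log-rank
test, Cox partial likelihood with **Efron** tie handling — chosen as the
less-biased of the two standard approximations since the original analysis
software is unspecified); `scipy.stats` supplies the chi-squared (no
continuity correction, the common default for r×c tables) and
Kruskal–Wallis tests. This module owns everything around the estimators:

* **Covariate codings** (`COX_VARIABLES`): all eleven prognostic covariates
  are dichotomised with the conventional reference levels — stage II vs I,
  node-positive vs negative, >2 cm vs T1, grade 3 vs 1–2, ER/PgR negative
  vs positive, HER2 positive vs negative, Ki-67 ≥ 10% vs < 10% (the
  boundary value 10 is high), adjuvant therapy vs none, mutant vs wild
  signature.
* **Two-step model** (`run_table3`): every covariate is fitted
  univariately; those with univariate Wald p ≤ 0.05 (configurable
  `entry_p`) enter one multivariate model. The entry rule is a design
  choice — the original report shows multivariate results exactly for the
  univariately significant variables but never states the rule.
* **Missing data**: complete-case per analysis; exclusion counts are
  logged and NA counts appear as rows in the characteristics report.
* **Subgroups**: luminal A-like = ER+ and Ki-67 < 10%; luminal B-like =
  ER+ and Ki-67 ≥ 10%; TNBC = ER−, PgR−, HER2−; plus ER± and grade 1/2/3.
  Subgroups that are empty, single-class, or event-free report the
  degenerate condition instead of a p-value.

Kaplan–Meier and log-rank outputs are cross-checked in the tests against
brute-force oracles (explicit product over risk sets; per-event-time
hypergeometric observed-minus-expected sums).

## Synthetic cohorts

The simulator (`simulate`) generates the study conditions of a 189-patient
stage I–II cohort; every draw is a pure function of the configuration and
its seed.

* **Class**: each patient is mutant-signature with probability 89/189.
* **Expression**: each panel gene is an independent log-normal;
  per-class parameters (σ = 0.55; median score ≈ 0.65 wild, ≈ 2.0 mutant)
  put the score distributions astride the 1.11 cutoff with ~1–3% of either
  class crossing it — so default classification is deliberately imperfect,
  as in the development cohort — and a score-vs-class AUC ≈ 0.99. The real
  assay's per-gene distributions are unpublished; log-normal is a modelling
  choice.
* **Covariates**: drawn class-conditionally independent with the published
  per-class proportions (e.g. ER+ 55% of mutant vs 89% of wild). Real
  correlations among ER/PgR/grade/Ki-67 are *not* modelled — a documented
  simplification with one visible consequence (below).
* **Events**: recurrence is exponential with hazard
  0.010 · exp(log 3.96 · 1[mutant] + Σ β_v · v) per year — the default
  direct effect is signature status only; `table3_effects_config()` adds
  the published stage-II (HR 2.60) and node-positive (HR 2.55) univariate
  effects. The baseline 0.010/yr yields ≈ 15–25 recurrences per default
  cohort over the ≤ 10.18-year uniform censoring window, matching the wide
  published confidence intervals. Breast-cancer death follows recurrence at
  0.25/yr; other-cause death is an independent 0.005/yr exponential. By
  construction RFS ≤ OS and a breast-cancer death is a death, so the three
  endpoints are mutually consistent.

**What passing simulator-based tests shows** — that the estimators recover
known truth under proportional hazards with independent censoring (mean
Cox HR within 5% of 3.96 at n = 2000 over 200 seeds; uniform log-rank
p-values under the null). It does **not** show robustness to correlated
covariates, non-proportional hazards, informative censoring, or assay batch
effects, none of which are generated.

**Model-selection structure.** Because covariates are class-conditional and
the signature carries a large hazard ratio, any covariate strongly
associated with class (grade, Ki-67) inherits a marginal prognostic effect
in large simulated cohorts — more strongly than in the real data, where
grade was univariately null. The selection check is therefore stated
per-variable: stage, nodal status and signature status each enter the
multivariate model in a majority of seeds (and jointly in a majority),
rather than demanding that the selected set contain nothing else.

## Numerical and interface choices

* Candidate ROC thresholds are midpoints, not observed scores, so a
  selected cutoff never sits exactly on a sample.
* TSV is canonical; CSV is sniffed from the header line; decimal points
  only. Expression/clinical writers emit full-precision floats (`repr`) so
  write-then-read round-trips are bit-exact.
* Pipeline JSON summaries are sorted and timestamp-free: identical inputs,
  configuration and seed give byte-identical files; each summary carries a
  hash of its configuration.
* Validation failures raise typed exceptions with row/column coordinates
  (parsing), offending identifiers (alignment, duplicates), or allowed
  vocabularies (categorical levels).

## Problem sizes

Default analyses use the study-size cohort (n = 189). Calibration checks
use n = 2000 patients × 200 seeds (Cox recovery), 500 default cohorts
(null calibration), 10,000 patients (expression separation), and 30 seeds
(model-selection structure) — sizes at which the Monte-Carlo error is well
inside the tolerances asserted.

## Known limitations

* The real 26 gene names are not bundled; analyses of real data need a
  panel file.
* Competing risks for BCSS, proportional-hazards diagnostics and
  time-varying covariates are out of scope.
* The simulator cannot reproduce cohort-specific results (exact published
  hazard ratios, characteristics-table p-values, survival curves) — those
  depend on unreleased patient data; it reproduces the *structure* the
  analysis assumes and the published effect sizes as generating truth.
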