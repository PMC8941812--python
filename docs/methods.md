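# Methods

## Problem and model

A participant undergoing carotid endarterectomy (CEA) is *symptomatic* if a
qualifying ischemic event (stroke, TIA, or retinal ischemia) occurred within
six months before surgery, and *asymptomatic* otherwise. The package
classifies this status from two administrative sources: the hospital
discharge abstract of the surgical stay (ICD-10-CA diagnoses with diagnosis
types, CCI intervention codes, admission category) and fee-for-service
physician claims (3–5 character ICD-9 diagnoses, 5-character fee items,
provider specialty, service dates) in the window from 183 days before to
7 days after the index procedure.

Five classifiers of increasing complexity are compared:

| model | inputs | family |
|---|---|---|
| Rule_DX | discharge diagnoses only | deterministic rule |
| Logistic_HOSP | demographics, admission category, discharge cluster flags | elastic-net logistic |
| Logistic_DX | HOSP + claims diagnosis features | elastic-net logistic |
| Logistic_ALL | DX + claimed-service features | elastic-net logistic |
| Forest_ALL | same as ALL | random forest |

Rule_DX calls a participant symptomatic iff any index-abstract diagnosis
maps to a symptomatic cluster (ischemic stroke, TIA, retinal, cerebral) and
is coded as a most-responsible or preadmit diagnosis type (policy
configurable). Continuous models are compared with the rule by *sensitivity
at matched specificity*: with the rule's specificity s* measured on the
cohort, each model is thresholded at the smallest score cut whose
specificity reaches s* and its sensitivity there is reported. No
interpolation between attainable operating points is used — the model is
only credited with thresholds it can realize, which is the conservative
reading of a like-to-like comparison. Models are compared with each other
by rank-based AUC (ties counted one half).

## Synthetic-data generator

The restricted source data cannot be shipped, so the generator emulates its
structure. Each participant gets demographics (age ~ N(72, 9.3) rounded and
clipped to [45, 95]; 33% female; 78% metro residence), one index discharge
abstract carrying a CEA intervention code, and a claims history. A latent
status (70% symptomatic; symptom types retinal/TIA/stroke at 26/46.5/27.5%
of symptomatic cases, matching the observed cohort mix) with an event day
uniform on [0, 183] days before surgery drives two observable channels:

* **Discharge coding.** With probability `p_emergent_given_sympt` (default
  0.33) a symptomatic participant is admitted emergently for the event and,
  with `p_mrdx_event_given_emergent` (default 0.95), the event diagnosis is
  coded as most-responsible (70%) or preadmit (30%) type — the pattern the
  rule can see. Otherwise the admission is an elective, stenosis-only-coded
  re-admission for scheduled surgery and the rule is blind. Asymptomatic
  participants are coded for stenosis only (leak probabilities default 0 on
  both sides and are configurable). Rule-based sensitivity therefore
  converges to `p_emergent × p_mrdx_event` ≈ 0.31 and specificity to ~1.0,
  the high-specificity/low-sensitivity regime the method is known for; the
  default 0.33 is a tuning default placing the rule near the reported
  ~33%-sensitivity regime, not an empirical claim.
* **Claims.** Symptomatic participants emit, near the event day, a
  neurologist event diagnosis (probability 0.60), a non-specialist event
  diagnosis (0.50), a head-CT fee item (0.70), and a nonspecific
  neurological-symptom claim (0.40). All participants emit carotid-imaging
  /stenosis workup claims, Poisson(6) background claims drawn from a decoy
  dictionary (including ICD-9 784, which looks neurological but is
  deliberately unclustered), and rare background head CTs (0.04) and
  neurology visits (0.05) that keep the service signal imperfect. The
  claims probabilities have no published values; they were fixed once at
  clinically plausible rates that put the claims-bearing models in a
  high-AUC regime, and are all exposed in `GeneratorParams`.

Duplicate claim lines (default rate 0.10) are exact copies differing only
in adjudication sequence number, mimicking billing adjudication by-products.
Symptom type is blanked at rate 0.01 to exercise the descriptive
median-imputation path (the observed cohort had ~0.8% missing). Identical
parameters and seed reproduce byte-identical tables.

What the generator does *not* emulate: real fee-schedule economics,
hospital transfer chains, out-of-province events, coding drift over years,
and correlated comorbidity structure. Passing tests therefore demonstrate
that the pipeline recovers a signal of this mechanism's form — not that the
shipped defaults match any particular jurisdiction's data.

## Data preparation

Six months is encoded as 183 days; the event window [index − 183,
index + 7] is closed on both ends (both boundaries configurable, since the
original convention is unstated). Claims identical on (participant, service
date, diagnosis, fee item, specialty) collapse to one row, ignoring the
adjudication sequence. ICD-9 codes are dot-stripped and truncated to three
characters (V/E prefixes retained within them). Cohort index date is the
earliest CEA admission; ties break by discharge date then record order. The
test split is the final calendar year, with no shuffling.

The cluster maps ship as editable plain-text files
(`src/ceaphen/data/*.tsv`). ICD-10-CA matching is by longest dot-stripped
prefix, so G45.3 (amaurosis fugax) overrides the G45 TIA prefix and I63.6
(venous thrombosis) is carved out of ischemic stroke; "R47.8" is included
in the cerebral cluster reading a source typo ("R7.8") as the third member
of the aphasia/dysarthria run. The fee-item → service-category table
(head CT, carotid imaging, neurology consult, ECG/cardiac, generic visit)
is a synthetic reconstruction with invented 5-character codes: the real
payment-schedule table is not publicly distributable.

## Feature engineering

The 4-step claims workflow: (1) *clustering* maps each claim to a diagnosis
event (ICD-9 cluster × provider-specialty flag, default neurologist/other)
and/or a service event (fee-item category); (2) *reduction* collapses
events sharing (participant, category, flag) to the occurrence nearest
surgery — services only when configured `reduce=True`, otherwise all
occurrences are kept; (3) *weighting* values an event at
2^(−max(d, 0)/half-life) with a 90-day half-life (post-operative days weigh
1); (4) *summarizing* takes the maximum weight for diagnosis features
(presence strength) and the summed weight for service features (weighted
volume). The weight function is not specified by any source beyond
monotone recency; exponential decay is the default, with linear and step
alternatives in `FeatureConfig`. The same reasoning fixes max-for-diagnosis
/ sum-for-service, with per-category overrides.

Absence of a code is a structural zero, never a missing value; the only
imputation in the package is the descriptive median imputation of symptom
type on the ordinal coding asymptomatic < retinal < TIA < stroke (lower
median on ties), which is never used as a predictor. Age is standardized
using training-split moments only, so the held-out year cannot leak into
the scaling and logistic coefficients are reported on a standardized scale.

## Model workflow and numerics

Learned models follow tune → assess → fit → bootstrap. Tuning selects the
hyperparameter combination maximizing mean held-out AUC over a repeated
stratified 10-fold grid (3 repeats by default); the search strategy is
pluggable and defaults to seeded random search — tuner identity is outside
the contract. Assessment uses 10-fold 10-repeat CV, reporting mean ± 1.96
standard errors over the fold estimates. Final models are fit on the full
training split and evaluated on the held-out year with 2000 bootstrap
resamples (percentile 95% CIs; single-class resamples are redrawn and
counted). CV folds are stratified by outcome to avoid single-class folds
at small n. Smaller search budgets (4 candidates, 1 tuning repeat,
2 assessment repeats) are used in the shipped study-scale runs and
acceptance script; the contract — resampling scheme plus AUC selection —
is unchanged.

The elastic net uses the glmnet parameterization: `mixture` is the L1
proportion, `penalty` (λ) the strength on the mean-log-likelihood scale,
mapped internally to scikit-learn's saga solver with C = 1/(nλ), predictors
standardized internally, and a 1-D Newton polish of the unpenalized
intercept after the solver returns (a no-op at a joint optimum; saga can
stall on the intercept at extreme penalties). Under exact collinearity the
lasso solution is non-unique — any same-sign split across duplicated
columns has identical loss and L1 norm, and saga returns the symmetric
split — so the package guarantees the *sum* of duplicated-column
coefficients, not a one-nonzero selection. Forest probabilities are plain
ensemble leaf-frequency averages; out-of-bag scores are not used because
evaluation happens on a held-out year. `candidates_per_split` warns outside
the working range [2, 20] and errors outside [1, p].

## Evaluation statistics

Exact binomial intervals are Clopper–Pearson from beta quantiles, with
boundary cases pinned to 0 and 1; reporting rounds point estimates to one
decimal percent and CI bounds to whole percent. Calibration is assessed by
logistic recalibration of outcomes on logit(p̂) (probabilities clipped at
1e−6): intercept a and slope b_L from the joint fit, and the unreliability
index as the likelihood-ratio chi-square against the fixed (0, 1) model on
2 df. A LOESS-smoothed observed-vs-predicted curve is returned for
plotting only — a chi-square test on smoothed-curve parameters is not
well-defined, so the testable statistic uses the standard recalibration
construction and the smoother is cosmetic. Degenerate (constant)
probability vectors are a flagged error.

Variable importance is standardized logistic coefficients (zero-variance
columns exactly 0) or seeded permutation importance (mean AUC drop;
negative values possible for noise features). Cohen's kappa uses
marginal-product expected agreement. Descriptive tables report mean (SD)
with a two-sample t-test for age and counts (%) with Fisher exact tests
for categorical rows; tables larger than 2×2 use a seeded Monte-Carlo
estimate of the Fisher p (fixed-margin table sampling with the table
probability as statistic), since no installed routine provides the exact
network algorithm. A power helper computes the probability that the exact
CI for an observed sensitivity excludes a comparison value; the historical
sample-size claim it relates to is not asserted anywhere because it is not
reproducible from the stated construction.

## Problem sizes

Study-scale analyses in the tests and acceptance script use n = 2000
synthetic participants (final-year test split ≈ 10–12%), 200 replicates at
n = 2000 for calibration recovery, 10,000 replicates per setting for
interval coverage, and 1000 random score sets for threshold-selection
oracle checks. These sizes were chosen as the package's own desk-scale
defaults; all are parameters.

## Known limitations

* The generator's claims-signal probabilities and the fee-item table are
  plausible reconstructions, not estimates from data.
* Single-center-style structure: no between-site heterogeneity, no coding
  drift across years, so temporal-validation behaviour is optimistic.
* The discharge-rule specificity on default synthetic data is ≈ 1.0 (the
  asymptomatic leak defaults to 0), slightly cleaner than the ~98.6%
  observed in real data; the leak parameters exist to degrade it.
* Calibration metrics on small held-out sets (tens of participants) are
  unstable, as the 2-df test has little power there; study-scale runs use
  the 200-participant-plus test year.
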