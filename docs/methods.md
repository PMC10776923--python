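# Methods

`stabsel` implements a biomarker-discovery pipeline for granulocytic
asthma phenotypes: given a clinical table and a serum or sputum protein
abundance matrix, it identifies a sparse set of proteins jointly
associated with a binary eosinophilic or neutrophilic status, and
quantifies their predictive value over established clinical covariates.
This note records the models, conventions and numerical choices; every
number mentioned here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Phenotype definitions

A phenotype is a cut-off on a granulocyte measure, with the comparator
fixed at `>=`:

| phenotype | primary | alternative | units |
|---|---|---|---|
| blood eosinophilic | >= 300 | >= 150 | cells/uL |
| blood neutrophilic | >= 7500 | >= 5000 | cells/uL |
| sputum eosinophilic | >= 1.5% | >= 3% | % of granulocytes |
| sputum neutrophilic | >= 73.6% | >= 60% | % of granulocytes |

Participants with a missing count get a missing status and are dropped
(and counted in provenance) when the design is assembled; outcome-
defining counts are never imputed, because imputing them would
manufacture labels.

## Preprocessing

1. **Median normalisation.** Every sample is rescaled so its median
   abundance equals the median of per-sample medians of the training
   data (a symmetric choice — no designated reference sample). The
   operation is idempotent and removes any per-sample multiplicative
   assay factor exactly.
2. **Log + standardise.** Natural log, then per-protein centring and
   scaling to unit SD. The reverse order (standardise, then log) is not
   executable — centred data contain non-positive values — so log comes
   first and the convention is recorded in provenance. Standardisation
   uses the sample (n-1) SD by default (`ddof` is a parameter; the
   population convention is also supported and tested). Zero-variance
   proteins are dropped with a warning and listed in provenance.
3. **Clinical k-NN imputation** (k = 5 by default). Distances are
   Euclidean over standardised numeric covariates with pairwise-available
   handling; numeric cells take the mean of the k nearest donors,
   categorical cells a majority vote (ties by lexicographic order);
   neighbour-rank ties are broken by donor order after a seeded shuffle.
   Observed cells are never altered. The imputer is a fitted transformer,
   so follow-up data is imputed with baseline donors.

Because normalisation precedes the log-standardisation, the assembled
design is invariant to any positive per-sample scaling of the raw
abundances (tested property).

## Design matrix and adjustment

The design contains the forced clinical covariates followed by all
proteins. Penalty factors implement adjustment: forced covariates carry
factor 0 (present in every model, never penalised), proteins carry 1.
Two modes mirror the study design: `age_sex` (2 forced covariates) and
`full_clinical` (11: age, sex, BMI, age of asthma onset, ACQ-5 score,
predicted FEV1, FEV1/FVC, nasal polyps, OCS dose, pack-years,
exacerbations/year).

## Penalised solver

The solver minimises the mean logistic deviance plus
`lambda * sum_j pf_j |beta_j|` by coordinate descent with
soft-thresholding inside an IRLS loop, warm-started along a decreasing
penalty grid with active-set updates and full KKT sweeps. `lambda_max`
(all penalised coefficients zero) is obtained from the KKT condition at
the null-restricted fit and anchors a geometric grid of 50 values down
to `0.01 * lambda_max` (both configurable); the head of the grid is
inflated by a relative 1e-7 so full shrinkage holds at loose tolerances.
IRLS weights are floored at 1e-5 and linear predictors clipped at +-30
for numerical safety. Two tolerance regimes exist: precise (single fits;
KKT residual ~1e-9, checked post-hoc against a 1e-5 bound) and path
(subsample fits, tolerance 1e-4 on coefficient updates — supports are
unchanged vs. the precise regime on our benchmarks while being ~10x
faster). Complete separation of an unpenalised block is reported as a
warning and the capped fit returned.

## Stability selection and calibration

K subsamples (default 1000) of floor(n/2) participants are drawn without
replacement, stratified by outcome (largest-remainder allocation, so the
subsample size is exact); stratification is this package's choice — it
prevents class-empty subsamples for imbalanced phenotypes. The full
penalty path is fitted per subsample and the per-(lambda, protein)
selection counts accumulated; q(lambda) is the mean selected-support
size. Forced covariates are excluded from counts, q, and the score, and
reported with selection proportion exactly 1.

The penalty and the stability threshold pi are calibrated jointly by
maximising the stability score: with H ~ Binomial(K, round(q)/p),
features are categorised at threshold pi into low
(count <= floor(K(1-pi))), high (count >= ceil(K pi)) and mid, and the
score is `-sum_j log P(H in category_j)` — the negative log-likelihood
of the observed pattern under equiprobable (unstable) selection. The
three category masses are direct pmf sums (computing the mid mass as
1 - low - high cancels catastrophically), probabilities are floored at
1e-300 before logs, pi is searched on 0.51..0.99 by 0.01, grid points
with degenerate q (0 or p) are excluded, and ties break toward the
larger penalty then the larger pi. The stable set is the proteins with
selection proportion >= pi* at lambda*, in decreasing order of
proportion.

Two caveats, both visible in the test suite:

* **Shared credit under collinearity.** Two identical (or highly
  correlated) proteins split their selections across subsamples, so
  neither may individually pass the threshold even when the pair is
  jointly informative. Selection proportions of duplicated columns need
  not be equal.
* **Global-null behaviour.** With overlapping 50% subsamples the
  selection counts of pure-noise features are overdispersed relative to
  the binomial equiprobability null (features differ in their fixed
  full-sample alignment with the outcome, so their selection events are
  strongly dependent across subsamples). The score maximisation then
  flags the most-aligned noise features: on zero-effect simulated
  cohorts (n=300, p=200, K=100) the calibrated stable set is typically
  *not* empty (~10 spurious proteins). This is a property of the
  calibration itself, not of the solver — an independent L1 fitter
  produces the same counts. With genuine signal the calibration is
  conservative: on cohorts with ten causal proteins at log-OR 1.0
  (n=600, p=1124-scale), pi* calibrates near 0.99 and the stable set
  recovers 8-10/10 causal proteins with zero false positives across
  replicates. A stable set should therefore be interpreted jointly with
  the score surface and the reproducibility frequencies, not as a
  familywise-error guarantee.

**Reproducibility runs** re-run the whole calibrated procedure on B
(default 100) outer subsamples of 80% of the participants and report how
often each protein is stably selected. The inner K defaults to 250
inside these runs to keep 100 outer repetitions tractable; the full K is
a flag away.

## Predictive evaluation

Unpenalised logistic models are refit on each of `n_splits` (default
1000) stratified 80/20 train/test splits; the test AUC uses the
Mann-Whitney formulation with ties counted 1/2, and the summary is the
mean with a percentile 2.5/97.5 interval across splits (the CI method is
this package's choice and is recorded in output). The sequential-
addition curve starts from the clinical-only model and adds stable
proteins one at a time in decreasing selection proportion, reusing the
same split seed at every step so the curve is comparable split-by-split.
Selection and evaluation reuse the full data (the apparent procedure of
the study design this pipeline follows); this is optimistic relative to
nested selection-within-split, and the curve should be read as
descriptive rather than as an unbiased generalisation estimate.

Follow-up validation freezes the baseline model and the baseline
preprocessing constants (normalisation reference, per-protein centring
and scaling, imputation donors) and scores the follow-up samples once;
the CI is a bootstrap (2000 resamples) over follow-up participants.

The matched-subsample re-analysis draws outcome-stratified subsamples of
a target size until every matching variable's mean is within 0.1
full-data SDs of the full-data mean (acceptance sampling, 1000 attempts
before reporting the best achieved balance), then re-runs selection and
evaluation on the subsample — the design used to ask whether a smaller
cohort's weaker results are a power artefact.

## Synthetic cohorts

No public data accompanies the method, so the generator emulates the
study's data structure with known ground truth:

* **Proteins:** log-normal abundances; log-scale multivariate normal
  with equicorrelated blocks (default: blocks of ~20 proteins,
  within-block rho 0.3 — placeholders for an unknown real correlation
  structure, fully configurable), protein-specific location
  (log-RFU ~ N(7,1)) and scale (U(0.2, 0.6)), plus a per-sample
  log-normal assay scale factor (SD 0.2) that median normalisation must
  remove.
* **Outcome:** a sparse causal support (default 10 proteins, unit
  log-odds effects) acts on the standardised latent log-signal. In
  `latent_logistic` mode, status ~ Bernoulli(sigmoid(alpha + X beta))
  with alpha = logit(0.33), matching a one-third high-phenotype share.
  In `granulocyte_counts` mode the targeted count is negative binomial
  with log-mean linear in the causal proteins (blood eosinophils: mean
  360/uL, dispersion 0.52; blood neutrophils: 4780/uL, 3.1), and sputum
  percentages are computed from three positive cell tallies
  (eosinophils, neutrophils, other granulocytes) so the "% of
  granulocytes" denominator is well defined.
* **Clinical covariates:** marginals matched to a pooled mild-moderate +
  severe asthma population (age ~ N(48.7, 14.6), BMI ~ N(28.0, 5.8),
  58.7% female, ...); right-skewed non-negative variables (OCS dose,
  pack-years, exacerbations, ACQ-5, age of onset) use moment-matched
  gammas so the stated means/SDs hold without truncation. Covariates are
  drawn independently of the proteins.
* **Missingness:** missing-completely-at-random in clinical covariates
  only (default rate 5%).
* **Follow-up visits:** the latent standardised signal is redrawn with
  autocorrelation 0.7 around the participant's baseline value, with
  fresh assay scale factors, for 62 mild-cohort participants —
  emulating a day-14 repeat sample.

What the generator does **not** emulate: aptamer cross-reactivity, plate
or batch structure beyond the scalar per-sample factor, correlation
between clinical covariates and protein levels, mixed
eosinophilic-and-neutrophilic status, or the real cohorts' joint
covariate distribution. Passing tests therefore demonstrate that the
machinery is correct and well calibrated under this stylised data
model, not that the real-data findings are reproduced.

## Reproducibility and problem sizes

Every random stage takes an explicit seed; the pipeline derives
per-stage seeds by hashing the master seed with the stage name, so any
stage can be re-run in isolation. Two runs of the same configuration
produce byte-identical manifests (no timestamps; SHA-256 hashes of all
outputs). Tables are written with 10 significant digits.

The test suite and the acceptance script run the method at reduced but
structurally faithful sizes chosen for a desk-scale single-CPU budget:
support recovery at n=600, p=1000, K=200 over 25 replicates; null
calibration at n=300, p=200, K=100 over 20 replicates; the acceptance
script's main analysis at the study scale n=574, p=1124 with K=1000
subsamples and 1000 evaluation splits.
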