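# Methods

This note documents the models, conventions and design choices behind
`nmrconfound`, and what the simulation-based tests do and do not show.

## Data model

A peak table is a samples × peaks matrix of nonnegative NMR peak
intensities; a cell may be a *non-detect* (below the detection limit),
carried as NaN and distinct from a measured zero. Metadata records the
design: role (STUDY patient, pooled-plasma QC replicate, healthy
volunteer HV), disease group (PHT control; PA, PPGL, CS pooled as EHT),
center of origin, center cluster (1 or 2), sample age in days (storage
time before acquisition), analytical batch, run order within batch,
patient sex and age.

## Synthetic multicenter cohort

The generator emulates the structure of a retrospective multicenter
study; all effects are additive on the log scale (multiplicative on
intensities), reflecting the positivity of NMR intensities and the
log-type variance stabilization applied downstream:

log x_ij = baseline_j + disease effect + cluster effect + flagged-subgroup
effect + age_slope·sign_j·age_i/1000 + batch offset + run-order drift +
N(0, σ_j)

* **Peak namespace** (~40 peaks): the signature-table peaks plus the
  remaining confounder-panel peaks and eight uninformative unknowns.
  Per-peak baselines are fixed scenario constants (drawn once from a
  fixed generator, U(3, 6) in log units); biological SD defaults to 0.4.
* **Confounder panel**: a fixed 14-metabolite direction template
  (acetylcarnitine −, creatine +, dimethyl sulfone +, glucose −,
  glutamate +, glutamine −, glycerol +, glycine −, lactate +, methanol −,
  methionine −, ornithine +, pyruvate −, unknown 3.284 +). Cluster-2
  samples are shifted by `cluster_effect_scale`·sign; samples with high
  storage age are shifted in the same directions via `age_slope`
  (log-intensity per 1000 days). The flagged subgroup (the cluster-2
  center whose control samples sat at room temperature before storage)
  gets its own amino-acid-only sub-panel (glutamate +, glutamine −,
  methionine −) and is assigned to cluster 1, mirroring how it groups in
  a principal-component view.
* **Default scenario**: the published center × disease cell counts
  (106 PHT, 104 PA, 94 PPGL, 33 CS over 13 centers), the seven-center
  cluster-1 membership, 133 QC replicates and 98 HV samples from one
  center. Storage-age ranges are per (cluster, disease): the retained
  cluster-1 cohort is young and age-homogeneous (PHT 127–1307 d,
  PA 83–1598 d, PPGL 121–2841 d) while cluster-2 controls dominate the
  old end (1307–6418 d); a Beta-skew knob (`age_cluster_corr`, default
  1.5) correlates age with cluster membership. Effect magnitudes for the
  confounders are not published; the defaults (cluster scale 0.5
  log-units, age slope 0.08 per 1000 days) were chosen so that the two
  clusters separate along the first principal component while technical
  variation (QC noise 5 %, batch SD 0.05, run-order drift 0.002) stays an
  order of magnitude smaller. Disease effects default to zero — scenarios
  inject them explicitly, so every recovery test states its own truth.
* QC samples are replicate draws around the pooled baseline with
  technical noise only; HV samples are baseline draws from the designated
  reference center. Intensities below `lod` become non-detects, making
  missingness intensity-dependent as in real peak tables.

What the generator does **not** emulate: spectral overlap and peak-shape
artifacts, correlated metabolite panels beyond the shared direction
template, hemolysis, medication and diet effects, and run-order effects
that differ per peak. Passing tests therefore demonstrate correctness of
the pipeline's behaviour under the modelled confounding geometry, not
performance on real spectra.

## Preprocessing chain

Order: presence filter → PQN → CV filter → kNN imputation → GLOG; then an
optional robust-PCA outlier pass over the QC and HV groups, after which
the PQN reference and GLOG λ are recomputed without the outliers and the
chain is reapplied (the minimal re-run; peak filters are recomputed in
the same pass). STUDY samples are never dropped. The alternative order
(CV filter before PQN) is available behind an explicit flag.

* **Presence filter**: keep a peak iff detected in ≥80 % of QC *or* of HV
  samples (the groups measured under controlled conditions).
* **PQN**: reference spectrum = per-peak median over HV samples from one
  configured center, ignoring non-detects; each sample is divided by the
  median of its detected-peak quotients. After normalization the median
  quotient is exactly 1 — a test invariant. QC samples are normalized
  against the same HV reference, never by study-sample factors. The CV
  filter runs on post-PQN intensities (it follows PQN in the chain); the
  pre-PQN variant sits behind the order flag.
* **kNN imputation** (k = 10): classic expression-data variant — distance
  is the root-mean-square difference over mutually detected peaks,
  neighbors are the k nearest samples that detect the peak, weighted
  1/distance (ties at zero distance: equal weights). An exhaustive-search
  oracle checks it on all matrices up to 10×8.
* **GLOG**: g(x) = ln(x + √(x² + λ)), strictly increasing, → ln 2x for
  x ≫ √λ. λ is selected on a 25-point log grid (10⁻² … 10⁸) minimizing
  the squared coefficient of variation of per-peak QC replicate variances
  after transform. The normalization by the mean variance matters: the
  raw variance of variances is trivially minimized by λ → ∞, which
  shrinks every variance toward zero. This grid criterion is a deliberate
  simplification of the maximum-likelihood variance-stabilization fit; on
  mixed additive/multiplicative QC noise it lands within one grid step of
  σ²_add/σ²_mult and rescales by c² when intensities are scaled by c.
* **Outlier pass**: PCA on median-centered, MAD-scaled data; a sample is
  flagged when its score distance exceeds the χ²(0.975) quantile or its
  orthogonal distance exceeds the Box-type cutoff on OD^(2/3). The
  component count covers 90 % of variance, capped at 5. This is a plain
  robust-standardization PCA, not the sparse-robust variant.

## PLS-DA, sparsity, VIP, prediction

NIPALS PLS2 on mean-centered X (no scaling) against a centered
one-column-per-class dummy Y; X is deflated per component, Y is not.
Component signs are fixed by forcing the largest-|weight| entry positive.
The sparse variant truncates the weight vector to its keepX
largest-magnitude entries inside each NIPALS iteration and renormalizes;
keepX = p reproduces the dense fit exactly. Explained Y-variance per
component is ssy_a = ‖t_a‖²‖c_a‖², the weight in
VIP_j = √(p·Σ_a ssy_a (w_ja/‖w_a‖)² / Σ_a ssy_a); mean VIP² over features
is exactly 1. New samples are projected with R = W(PᵀW)⁻¹ and classified
by Mahalanobis distance to the class score-means under the pooled
within-class covariance (n − g denominator; ridge ε = 10⁻⁸·trace/A on
singularity; ties break to the first class in sorted order, i.e.
CS < PA < PHT < PPGL). Regression coefficients are B = R Cᵀ; binary
signatures report the disease-minus-control contrast column.

The L1 logistic alternative wraps scikit-learn's saga solver on a
decreasing λ grid (glmnet-style, from the smallest all-zero λ downward),
picks the λ minimizing cross-validated misclassification, and polishes
the unpenalized intercept by a one-dimensional Newton step (the
stochastic solver leaves it imprecise at strong penalties; the polish
makes the λ→∞ intercept equal the base-rate log-odds exactly).

## Double cross-validation

Class-stratified folds (sizes within one per class; fold counts above the
smallest class count are reduced with a warning). Defaults: 8 outer / 7
inner folds, one inner repeat, 50 outer repeats with re-randomized folds,
max 10 latent variables; high-imbalance scenarios override to 7/6
(CS-PHT) or 6/5. The inner loop scores overall accuracy for every
(ncomp, keepX) cell — one nested fit per keepX evaluates all component
counts — and picks the maximum accuracy, ties resolved to the minimum
ncomp then the smallest keepX. The outer model is refit on the outer
training set and predicts the held-out fold by Mahalanobis distance; VIP
vectors of every refit outer model are stored. Metrics (balanced
accuracy = mean per-class true-positive rate; sensitivity/specificity for
binary scenarios) are summarized as mean ± t₀.₉₇₅,ᵣ₋₁·sd/√r across
repeats, rendered "79 (78–79)"-style on the percent scale.

Preprocessing is fitted once on the full table (its statistics come from
QC/HV samples); only model hyperparameters are re-selected inside folds.
This mirrors common practice and is documented as an accepted leakage.

Signatures: (a) features with median VIP > 1 across all outer-fold
models; (b) sparse-PLS-DA coefficients of a model fit on all samples with
the modal (ncomp, keepX) across repeated single CV (ties to the smaller
value — the aggregation rule is a convention, the protocol only fixes the
repeat count).

**Null behaviour of the VIP rule.** Because mean VIP² ≡ 1, roughly a
third of features exceed VIP 1 even for a label vector unrelated to the
data (the χ²₁-like mass above 1). `confounder_signature` therefore only
interprets VIPs when the grouping is predictable — mean CV2 balanced
accuracy ≥ 60 % — and returns an empty list (with a warning) otherwise.
Every genuinely confounded scenario in the test suite classifies at
90–100 %, far above the gate.

**Null calibration.** CV2 is unbiased at 50 % under the null, but a
single permuted dataset of n ≈ 80 carries ±6 points of irreducible
finite-sample noise; calibration checks therefore average over several
label permutations.

## Confounder approaches

* **A (ASCA)**: effect matrices are level means of the centered data
  (interaction: cell means minus main effects; requires a full crossing —
  an empty cluster×disease cell raises an error naming the cell, the
  situation that blocks this correction for group CS). Reconstruction is
  exact by construction; in balanced designs the effect matrices are
  mutually orthogonal. The default correction removes the cluster main
  effect *and* the cluster×disease interaction while retaining the
  disease effect; per-effect flags make other readings runnable.
  Correction of *new* samples uses the stored level means
  (`asca_correct(..., levels=...)`). Judging removal by cross-validating
  the removed factor on the same samples the effect was estimated from is
  biased far below chance (the corrected class means are constrained to
  zero, so held-out samples sit on the wrong side of training means); the
  deconfounding tests therefore estimate the correction on a disjoint
  set. Even out of sample, a correction estimated from n samples leaves a
  residual class signal of order σ√(2p/n) — the calibration tests use a
  large estimation set so this residual is negligible.
* **B (peak exclusion)**: the exclusion list is the union of the cluster
  signature (cluster 1 without the flagged subgroup vs cluster 2), the
  sample-age signature (dichotomized at the global median over all STUDY
  samples), and the flagged-subgroup PCA contrast (the component whose
  scores best separate the flag; features with |loading correlation| >
  0.5, only consulted when some component reaches |r| > 0.3). The list is
  excluded at the start of preprocessing and the scenario re-analyzed.
* **C (center exclusion)**: STUDY samples are restricted to the retained
  centers; CS is dropped from the pooled EHT count because the retained
  centers contribute almost no CS samples. The excluded patients are
  predicted externally by a model refit on all retained samples with the
  CV2-modal hyperparameters. Center exclusion removes the *cluster*
  channel only: a storage-age confounder that persists within the
  retained centers remains in the signature — the simulations reproduce
  this, matching the published cross-approach comparison in which several
  confounder-related metabolites are selected by the center-excluded
  model.

## Problem sizes and numerical conventions

Simulation-based tests and the acceptance script run at reduced problem
sizes chosen for statistical adequacy (e.g. 5 outer repeats where the
protocol's 50 would only tighten already-decisive intervals; 10–100 seeds
per recovery sweep; cohorts of 80–570 samples × 20–40 peaks); the
protocol defaults remain the package defaults. Degenerate inputs are
handled explicitly: constant peaks get zero PLS weight; rank-deficient
PCA reduces the component count with a warning; contingency tables with a
single row or column return p = 1; r×c Fisher tests use 10⁵ fixed-margin
Monte-Carlo draws with a fixed seed.

## Known limitations

The exact ROSPCA algorithm, vendor spectral processing, peak
picking/alignment, permutation testing of model significance and
multinomial L1 logistic regression are out of scope. The GLOG λ criterion
is a grid heuristic, not the cited likelihood fit. Synthetic cohorts
cannot certify real-data performance; they certify that each stage does
what it claims under a known ground truth.
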