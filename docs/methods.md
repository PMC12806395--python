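# Methods

## Problem and model

The package classifies gastric tumours into the four TCGA molecular
subtypes — CIN, GS, MSI, EBV — from three DNA alteration matrices (boolean
somatic mutation, gene-level copy number, methylation beta values) and
evaluates candidate classification strategies both as classifiers and as
clinical stratifiers.

A *strategy* is a tree over the subtype set.  Each internal node partitions
its subtype set into ordered groups and carries one L1-penalised softmax
regression over those groups,

    Pr(G = k | x) ∝ exp(β₀ₖ + βₖᵀ x),

fitted by minimising `-(1/N) Σ log-likelihood + λ Σ|β|` with unpenalised
intercepts.  Three named strategies are built in: the flat 4-way I-MC; the
two-step II-HC that first separates the hypermutated/hypermethylated pair
{EBV, MSI} from {CIN, GS}; and the three-step III-HC chain that peels off
EBV, then MSI, then splits GS from CIN.  II-HC's topology is one of several
two-step trees consistent with a "two-step" description; it is the package
default because it groups the two epigenetically/mutationally extreme
subtypes first, and any custom topology can be supplied as YAML.

Four-class probabilities are composed multiplicatively along each
root-to-leaf path.  This is the unique composition under which the four
probabilities are a proper distribution for every tree shape and summing
composed probabilities within a node's group reproduces that node model's
group probability exactly; hard stepwise routing is the discarded
alternative (it yields no usable 4-class scores for ROC analysis).
Prediction is the probability argmax with ties broken by the fixed order
CIN < GS < MSI < EBV.

## Preprocessing

* Mutation inputs may be per-variant records; they collapse to a boolean
  gene × sample matrix (1 = at least one variant).
* Probe-level methylation collapses to genes by the arithmetic mean over
  non-missing probes.
* Missing methylation values: genes missing in more than half the samples
  are removed (imputing a mostly-missing feature would manufacture data);
  the rest are KNN-imputed with k = 10 — each missing cell takes the mean of
  the k nearest samples, nearness by Euclidean distance over mutually
  observed genes normalised by the number of shared genes so distances are
  comparable across missingness patterns.
* Min–max scaling to [0, 1] per feature.  Scalers are fitted on the
  training samples only and applied to test samples with clipping to
  [0, 1]; constant features map to 0.  Fitting on train only is a
  leakage-safety decision — refitting on test data would let the test
  distribution influence the representation.

## Class balancing

EBV (~7%) and GS (~11%) are heavily outnumbered by CIN (~67%).  SMOTE
oversampling equalises class counts by interpolating synthetic minority
samples, `x + u·(x_nn − x)` with `u ~ U[0,1]` and `x_nn` one of the k = 5
nearest same-class neighbours.  Balancing targets the majority-class count
(an absolute target is available).  Two placements are used deliberately:

* for the final node fits, SMOTE runs once on the full 4-class training set
  and each node trains on its balanced subset, so all strategies see
  identical data;
* during cross-validated λ selection, SMOTE runs *inside each training
  fold* only.  Balancing before CV leaks the interpolation structure of
  synthetic points into held-out folds; empirically that bias inflates the
  CV score of heavily overfitted models precisely at nodes with little real
  signal, which then corrupts composed cascade probabilities.  Fold-internal
  balancing removes the bias.

## Penalty selection

The λ grid is log-spaced from λ_max (the smallest penalty that zeroes every
coefficient, computed from the KKT bound at the intercept-only solution)
downward; `cv_select_lambda` defaults to 50 points over 4 decades, while
the pipeline harness uses 5–6 points over 2 decades — at the cohort sizes
it runs, CV cannot resolve finer grids and the coarse path keeps the full
12-classifier grid tractable on one CPU.  Each grid point is scored by mean
held-out macro one-vs-rest auROC over stratified 5-fold CV (stratification
is required: with ~7% EBV, unstratified folds can lose a class), and the
smallest λ among the top scorers is chosen.

The solver is FISTA (accelerated proximal gradient) on the penalised
average negative log-likelihood: full-batch gradients through BLAS matrix
products, soft-thresholding of the penalised block, Nesterov momentum with
restart on objective increase, and a step size from the softmax-Hessian
bound L = σ_max([1 X])² / (2N) (1/(4N) in the binary specialisation, which
solves the equivalent single-weight logistic problem).  The spectral norm
comes from 15 power iterations inflated by 5% so the step stays
Lipschitz-valid.  CV ranking fits run in float32 with a 20-iteration cap
(ranking stabilises long before convergence); final node fits run to a
1e-5 relative-objective tolerance.  Agreement of the optimum with an
independent solver (scikit-learn's saga path on the same objective) is
asserted in the test suite to ~1e-6 in objective value.

## Evaluation

Per subtype, one-vs-rest: ROC and PR curves from the subtype's composed
probability column; auROC by trapezoid (equal to the Mann–Whitney statistic
with ties counted ½), auPRC by the step-wise non-interpolated sum
Σ (rᵢ − rᵢ₋₁)·precisionᵢ; accuracy and F1 from binarised argmax
predictions, with precision/recall/F1 defined as 0 on empty denominators.
Overall scores are unweighted means over the four subtypes; a subtype
absent from the truth is excluded from the mean with a warning.  Both areas
are verified against brute-force oracles (exhaustive pair counting and
threshold sweeps) to 1e-12.

Clinical stratification: Kaplan–Meier curves and the multi-group log-rank
test for univariate comparison; a multivariate Cox model on subtype
indicators (reference CIN), age ≥ 65 (the age cut matches the reference
stratum "age < 65"; a continuous-age variant is a one-line change) and sex
(reference female, configurable).  Hazard ratios are exp(coefficients) with
Wald 95% CIs and p-values; the overall stratification p-value is the
likelihood-ratio test of the full model against the null.  Levels with no
events or no variation are reported as inestimable rather than aborting the
fit.  Strategy ranking: among classifiers within 0.02 macro auROC of the
best, the one with the smallest overall stratification p wins.

## Rates and markers

Per-subtype alteration rates are cell means over the subtype's samples ×
genes: the mutation rate of the boolean matrix, the fraction of CNA cells
with a nonzero call (|value| > 1e-9 on discrete calls; continuous log-ratios
are first thresholded at |value| ≥ 0.3, the conventional gain/loss call),
and the mean methylation beta.

Markers are tested one-vs-rest per feature: Fisher's exact test on the 2×2
altered × in-subtype table for mutations; Welch's two-sample t-test for CNA
and methylation (the unequal-variance form is the safe default when group
variances differ by construction; the pooled form is available).  P-values
are BH-adjusted within each modality — modalities are separate test
families with very different test statistics — and rows with adjusted
p < 1e-5 are kept, directed by the sign of the in-subtype minus rest mean,
and deduplicated to the most significant row per (gene, modality).  By
default the tests run on the features the fitted cascade selected (nonzero
coefficients in any node), mirroring marker discovery on
classifier-selected alterations; an all-features option exists.  The
MANOVA integration check (Wilks' lambda) compares two sample sets on
per-sample summary variables — mutation burden, CNA fraction, mean beta —
chosen because they are the package's own cohort-level summaries and are
defined for every modality combination.

## Synthetic cohorts

The simulator generates labelled cohorts with the subtype structure of real
gastric-cancer series, at a desk scale of 1,000 genes per modality
(real genome-wide feature spaces run to tens of thousands of genes across
the three modalities; desk scale keeps the full test suite minutes-long).  Defaults:

* subtype proportions (CIN, GS, MSI, EBV) = (0.67, 0.11, 0.15, 0.07);
* per-subtype mean alteration intensities anchored to observed rates —
  mutation (0.0123, 0.0044, 0.0998, 0.0140), CNA event fraction (0.544,
  0.0245, 0.097, 0.0433), methylation beta means (0.254, 0.271, 0.281,
  0.326);
* mutation cells are Bernoulli with rate = subtype rate × per-sample burden
  factor (log-normal, σ = 0.3, mean-normalised) × per-gene mutability
  (log-normal, σ = 1.0, drawn from a fixed stream so all cohorts share the
  gene profile — the analogue of gene length and hotspot structure);
* CNA cells are sparse events with per-sample log-normal burden (σ = 0.6),
  discrete ±{1, 2} levels plus Gaussian jitter (σ = 0.1), and a
  locus-consistent direction per gene (alternating amplification/deletion
  across the gene index) — without per-gene direction consistency a linear
  model cannot exploit copy-number burden at all, which real gene-level
  CNA data clearly allows;
* methylation cells are Beta draws (concentration 30) around the subtype
  mean plus a global per-sample shift (σ = 0.05);
* marker genes: 5 per supported (subtype, modality) pair, planted only in
  the modalities where subtype-specific markers are actually observed
  (mutation: GS, MSI; CNA: CIN; methylation: CIN, GS, EBV), at moderate
  effects (mutation rate 0.08, CNA event rate 0.15, beta shift ±0.08) with
  a 5× boost in each subtype's defining modality (MSI–mutation, CIN–CNA,
  EBV–methylation, hypermethylation always "+" for EBV);
* survival: exponential event times with hazard = 0.02/month × subtype
  multiplier (1, 1.23, 0.64, 0.69) × 1.3 if age ≥ 65 × 1.1 if male;
  independent exponential censoring calibrated to censor a baseline
  subject with probability 0.4;
* 5% of methylation cells are masked at random to exercise imputation.

Marker layout is a deterministic function of the configuration, not the
seed, so a train and a test cohort drawn with different seeds share the
same informative genes, as two cohorts assayed on one platform would.

What the simulator does **not** model: gene–gene correlation (linkage,
co-amplified regions), tumour purity, platform batch effects, probe-level
methylation structure, or label noise in the subtype assignments.  Passing
tests therefore demonstrate that the pipeline recovers planted structure of
realistic shape and scale — not that it would reach the same operating
points on real TCGA data, where correlated features and label uncertainty
make classification harder in some ways (effective sample size) and easier
in others (vastly more features carrying the burden signatures).

## Numerical choices and degenerate inputs

* Constant features scale to 0; scaled test values clip to [0, 1].
* Softmax shift invariance is fixed by centring intercepts at mean 0.
* Coefficients with |β| > 1e-8 count as selected features.
* Probability-composition identities hold to 1e-9; report serialisation
  rounds nothing.
* A subtype absent from a prediction vector is skipped (with a warning) in
  rate/marker computations; a CV fold missing a class is an error rather
  than a silent re-stratification.
* Zero-variance features in both groups are skipped in t-tests and logged.
* Exact equality of group means short-circuits the MANOVA to Wilks = 1,
  p = 1 (the general-purpose solver is singular there).

## Known limitations

* The lasso path uses a coarse grid in the pipeline harness; λ resolution
  below ~20% relative is not meaningful at these cohort sizes.
* The tie rule "smallest λ among the best CV scorers" deliberately favours
  weaker regularisation on ties; at nodes with no real signal the chosen
  model can be an overfitted noise model (fold-internal balancing mitigates
  but does not eliminate this).
* Per-subtype accuracy/F1 are one-vs-rest quantities from hard argmax
  labels; a within-class recall variant is a documented alternative.
* The Cox model assumes proportional hazards and independent censoring; no
  diagnostics are run.
* Group-lasso coupling of a feature's coefficients across classes is not
  implemented (the penalty is elementwise L1); elastic-net mixing is
  likewise fixed at pure L1.
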