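# Methods

## Classifier

The core model is a binary soft-margin SVM over a composite kernel
K = Σₗ dₗ K⁽ˡ⁾ with simplex-constrained kernel coefficients (dₗ ≥ 0,
Σ dₗ = 1). Writing J(d) for the optimal value of the SVM dual

W(α) = Σᵢ αᵢ − ½ Σᵢⱼ αᵢαⱼyᵢyⱼKᵢⱼ,  0 ≤ αᵢ ≤ C,  Σᵢ αᵢyᵢ = 0,

the weights minimize J(d) over the simplex. J is convex in d (pointwise
maximum of affine functions) and its exact gradient at the inner optimum is
∂J/∂dₗ = −½ (αy)ᵀK⁽ˡ⁾(αy) by the envelope theorem, so no re-differentiation
through the solver is needed. The optimizer is a reduced-gradient descent in
the SimpleMKL family: the gradient is reduced against the largest-weight
coordinate (so steps preserve Σ dₗ = 1), coordinates pinned at zero whose
reduced gradient points outward are frozen, and a backtracking line search
accepts the first step that decreases J. Steps beyond the first
coordinate-zeroing bound remain feasible via clipping to the nonnegative
orthant followed by renormalization; allowing them matters in practice,
because near a sparse solution the feasible step to the next zero crossing
can be orders of magnitude smaller than the useful step length, and a search
capped there stalls far from optimality.

Termination uses the relative duality gap (maxₗ Sₗ − Σₗ dₗSₗ)/J with
Sₗ = ½ (αy)ᵀK⁽ˡ⁾(αy), default tolerance 1e-4, capped at 200 outer
iterations. Weights below 1e-8 are then set to exactly zero and the
remainder renormalized, making "this kernel does not participate" literal in
reports, and the SVM is re-solved at the final weights.

The inner QP is solved by libsvm through scikit-learn's `SVC` with a
precomputed kernel (solver tolerance 1e-9). Two quantities are recomputed
independently of the solver: the dual objective from α, and the bias from
the KKT conditions, averaged over unbounded support vectors
(b = mean of yᵢ − Σⱼ yⱼαⱼKᵢⱼ over 0 < αᵢ < C), falling back to the solver's
intercept only when every support vector is at the box bound.

The margin tie rule is fixed for determinism: sign(0) = +1.

### Soft-margin constant

The hinge-loss box constraint C defaults to 100 with a config override; an
inner grid search was deliberately left out of the default path to keep
cross-validation runs inexpensive and reproducible. All base kernels have
unit trace (see below), which puts C on a comparable scale across data type
mixtures.

## Base kernels

Kernel functions: linear, inhomogeneous polynomial (x·z + 1)^d with
d ∈ {2, 3}, and Gaussian exp(−‖x−z‖²/2σ²). The Gaussian bandwidth σ is the
median pairwise Euclidean distance of the training subset (median
heuristic). Gaussian kernels are off by default — in high-dimensional omics
blocks the classes are typically linearly separable and Gaussian kernels end
up with zero weight — but are available by config.

Feature subsets come from three sources, all computed on training samples
only:

* **statistical** — features ranked by the two-sample pooled-variance t
  statistic against the training labels (|t| descending, ties kept in
  original column order; zero-variance features with equal class means score
  0, with differing means they rank first). Nested kernels are built on the
  top 2, 3, …, N features, N = 15 by default: larger banks cost roughly
  linearly more per MKL iteration while the added kernels are near-duplicates
  of their predecessors.
* **pathway** — columns restricted to the genes of one pathway (GMT file);
  pathways matching fewer than two features of a block are skipped with a
  warning. Optional within-pathway top-k selection (off by default) adds
  t-test-selected sub-kernels per pathway.
* **clinical** — one kernel per original covariate over its Boolean
  indicator columns (or its standardized numeric column). Binary covariates
  become a single 0/1 indicator, categorical ones a full one-hot group, and
  missing values an explicit `col=missing` indicator rather than an imputed
  value. Numeric covariates are standardized with training-fold mean/sd.

Every Gram matrix is normalized to unit trace, which removes the arbitrary
scale differences between data types; test-vs-train projections divide by
the *training* trace so the test kernel is consistent with the training one
(projecting the training set reproduces the training Gram exactly).

## Posterior calibration and abstention

Decision values are mapped to posteriors p(+1|f) = 1/(1 + exp(Af + B)).
(A, B) minimize the cross-entropy against targets tᵢ = (yᵢ+1)/2, by Newton
steps with Levenberg–Marquardt damping (initial damping 1e-3, ×10 on a
rejected step, ÷10 on an accepted one; stop at gradient norm < 1e-8, at a
step below float resolution, or after 500 iterations). Platt-style target
smoothing t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) is on by default: with hard 0/1
targets and separable decision values the likelihood has no finite maximizer
(A → −∞), a condition the fitter detects via a vanishing cross-entropy and
reports as an error when smoothing is disabled. Calibration is fitted on the
training decision values themselves; an option for cross-validated decision
values exists as the standard remedy for in-sample optimism, but the default
mirrors the plain protocol.

Pruning removes training samples whose own-label posterior is strictly below
θ_train (default 0.8; the boundary is kept), followed by exactly one refit —
no iteration. Cautious prediction emits a label only when
max(p, 1−p) ≥ θ_predict (default 0.95; the exact boundary predicts, with a
1e-12 float tolerance on both thresholds). Coverage (predicted fraction) and
accuracy on the predicted subset are always co-reported so neither can be
quoted without the other.

## Evaluation protocol

k-fold cross-validation (default 5) with one prior reshuffle of the sample
order by the config seed, contiguous unstratified folds by default and a
stratified option for small or imbalanced sets. Everything data-dependent —
clinical encoding schema, t-test ranking, pathway matching, bandwidths,
trace constants, standardization, calibration — is derived from the training
fold alone; tests assert that corrupting held-out rows leaves the trained
fold model hash-identical. Per-fold kernel rankings are aggregated into a
report of mean weight across folds (absent = 0) and selection frequency.

All outputs embed the config hash and seed, and identical config+seed gives
byte-identical tables and manifests; run manifests therefore carry no
wall-clock timestamps.

## Synthetic data

The generator emulates a two-block breast-cancer-style prognosis cohort: an
expression-like block of standard-normal values, a copy-number-like block
discretized to {−2…2} with jitter 0.1, overlapping pathways drawn from the
pooled gene namespace with members from both blocks (so integrating blocks
genuinely beats either alone), one outcome-associated binary clinical
covariate (an ER-status analogue, prevalence 0.55, effect 0.8) plus an
uninformative categorical one, and labels from a logistic model: each gene
of a designated informative pathway contributes β·x_g (β = 0.8 by default)
to a latent score, and P(y=+1) = σ(score/scale). The intercept is corrected
for the latent-score variance (logistic-normal mean approximation
E σ(z) ≈ σ(m/√(1+πv/8))) so the realized class fraction matches the
requested one — by default 387:252 ≈ 0.606, the balance of the cohort the
generator mimics. The label score uses the continuous gene values; the CNV
discretization happens afterwards and acts as measurement coarsening.

What the generator does *not* emulate: real gene–gene covariance, probe-level
noise, batch effects, censoring, or nonlinear effect structure. Passing
tests therefore demonstrate correctness of the machinery and recoverability
of planted linear pathway signal — not expected accuracy on real cohorts.

The default recovery experiment uses n = 300 samples, 150+150 features,
20 pathways of size 8–16 with 3 informative, and 5-fold CV over 5 seeds;
these sizes were chosen so a full run of the experiment completes in minutes
on a single core while leaving the planted signal comfortably detectable.

## Numerical choices and degenerate inputs

* Gram symmetry tolerance 1e-10, PSD tolerance: smallest eigenvalue
  ≥ −1e-8 × largest; trace-1 tolerance 1e-10.
* Degenerate kernels (trace ≤ 0, e.g. a constant covariate on a training
  fold) are an error at the primitive level and are dropped with a warning
  at the bank level.
* A bank in which no descent step exists from uniform weights returns the
  uniform-weight model with a warning.
* Empty sample intersections, single-class folds, single-level covariates,
  and pruning that would empty a class all raise informative errors.

## Known limitations

Binary classification only (no multiclass or time-to-event modes); sparse
ℓ1-style MKL only (no ℓ2-MKL variant); no asymmetric class costs; pathway
lookup assumes feature ids share the gene namespace of the GMT file, with a
user-supplied mapping expected for probe-level data.
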