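# Methods

This note records the model, the numerical choices, and the reasoning behind
design decisions that were genuinely open.

## Model and procedure

**Similarity graphs.** Each modality gets its own graph over all `n` samples
(training and test alike — the setting is transductive, a test sample must
exist as a node to be classified).  Edge weights are raw cosine
similarities; no absolute value or rescaling is applied, so negative
similarities are legal edge candidates but are excluded in practice whenever
the derived threshold `ε` is positive.  `ε` is not user-set: the user picks
`K`, the desired average number of retained connections per node including
the self-connection, and `ε` is chosen *from the multiset of observed
similarity values* (sort-and-scan, largest first) as the largest value whose
average retained count is ≥ K.  This makes the inversion deterministic and
gives exact counting semantics: ties at `ε` are all retained, `K = 1`
retains self-connections only (so the normalized adjacency is the identity
and the GCN degenerates to a dense network), `K = n` yields the complete
graph.  One caveat: exact duplicate samples have similarity 1 and are always
retained together once `ε = 1`, so `K = 1` on data with duplicated rows does
enroll those edges.

**Normalization.** `Ã = D^{-1/2}(A + I)D^{-1/2}` with `D` the row sums of
`A + I` (the self-loop is added before computing degrees; this keeps `Ã = I`
exact at `K = 1`).  If negative edge weights ever drive a degree to zero or
below, the build aborts rather than producing complex entries.

**Per-omics classifier.** `L` graph-convolution layers (default 3, widths
200/200/100, ReLU, no biases in the propagation step, matching
`H⁽ˡ⁺¹⁾ = σ(ÃH⁽ˡ⁾W⁽ˡ⁾)` literally) followed by a two-layer perceptron head
(one hidden layer, default width 100, then `c` logits and a softmax).  The
head widths are a package default, not an externally fixed quantity.
Dropout (default rate 0.5) is applied to every graph-layer input during
training; together with seed-varied Glorot initialization it supplies the
stochasticity the trial ensembles measure.  Loss is mean cross-entropy over
training nodes only; the gradient is structurally zero on all other rows
(tested by flipping test labels and asserting bit-identical training).

**Optimization.** Full-batch Adam (lr 1e-3, standard betas), a fixed epoch
budget rather than a convergence test (defaults: 500 epochs for standalone /
pretraining fits, 300 alternating epochs for fusion).  The sample sizes this
method targets (hundreds of subjects) make full-batch training cheap, so all
neural components are implemented directly in numpy/scipy with hand-written
reverse-mode gradients; a single BLAS thread evaluates identical operations
in identical order, which is what makes the determinism tests exact.

**Fusion.** The cross-omics tensor is the outer product of per-view class
distributions; its entries sum to 1 for normalized inputs.  Flattening is
row-major (last view's class index fastest) and fixed permanently for
checkpoint compatibility.  The fusion network is one hidden layer of width
`c^order · h` (h = 8 by default) with ReLU, then `c` logits.  Training
alternates per epoch: step A updates each view classifier with the VCDN
frozen, step B updates the VCDN on eval-mode view outputs with the views
frozen.  By default step A minimizes only the per-view cross-entropies (the
literal reading of the alternating scheme); setting `joint_gcn_update=True`
additionally routes the fusion loss gradient through the cross tensor into
the view classifiers.  Step B consumes dropout-free view outputs so the
fusion network sees the same inputs it will see at prediction time.

**Per-view seeding.** Inside a fusion fit, each view's RNG seed is derived
from the run seed and a CRC of the modality name, so a view's training
trajectory does not depend on the order in which views are listed.

**Uncertainty.** `T` independent retrainings (fresh initialization and
dropout masks; the data split is held fixed so the spread reflects model
variance, not split variance).  The per-trial quantity ensembled is the
predicted probability of the positive class — not the argmax label, whose
spread would be a binomial artifact; averaging probabilities is what makes
the mean a usable score and the standard deviation a graded uncertainty.
σ uses the `T−1` denominator, so `T ≥ 2` is required; `T = 10` is the
default, desk-scale studies in the tests use `T = 5`.  Majority vote:
per-trial label 1 iff `p ≥ 0.5`; a strict majority wins; an even split falls
back to the mean probability.  Each trial is a full retraining (not merely a
stochastic re-inference), which also captures optimization variance.

**Staged routing and threshold selection.** Routing is a strict partition:
stage 1 iff `σ₁ ≤ t1`, stage 2 iff `σ₁ > t1` and `σ₂ ≤ t2`, stage 3
otherwise.  The grid for each threshold spans the observed uncertainty range
of its stage in 100 evenly spaced values, endpoints included; the scan is
ascending (t1 outer, t2 inner) and requires strict improvement, so with the
`"smallest"` tie rule the smallest optimal pair is returned.  The package
adds a `"cheapest"` tie rule — at equal accuracy prefer the combination
finalizing more samples at stage 1, then stage 2 — and the pipeline uses it
by default.  Rationale: on well-separated data many threshold pairs attain
identical (often perfect) accuracy, and the smallest-threshold rule then
escalates nearly every sample to the most expensive stage, defeating the
purpose of staging; the cheapest rule implements the method's actual
objective (minimal acquisition cost at maximal accuracy) and changes nothing
whenever the accuracy optimum is unique.

**Threshold optimization set.** Optimizing `(t1, t2)` on test labels leaks;
the pipeline default carves a stratified 20% validation subset out of the
training samples (excluded from every model fit) and optimizes thresholds
there.  `optimize_on="train"` or `"all"` are available, the latter matching
the literal protocol of scanning all labeled patients.

**Stage order.** By default the pipeline picks the best single view by
validation accuracy, then the best bi-view combination containing it, then
all three views.  The order can be pinned in the config
(`[["mRNA"], ["mRNA","meth"], ["mRNA","meth","miRNA"]]` is the canonical
choice when the first modality is the designated cheap assay).

**Metrics.** Accuracy, positive-class F1, and AUC computed from the assigned
stage's mean case probability (scikit-learn implementations; the tests check
them against an independent confusion-matrix / rank-statistic reference).
With a single-class truth set AUC is undefined and reported as `None`.

## Synthetic data generator

The generator emulates the statistical structure the method assumes rather
than any particular assay's marginal distributions.  Features are
class-conditional Gaussians: in modality `k`, `n_informative` features shift
their mean by `±δ_k/2` with the class; a shared standard-normal latent
factor, scaled by `cross_modal_correlation`, is added to the informative
features of *all* modalities so views carry correlated, complementary
evidence — the structure label-space fusion exploits.  A `hard_fraction` of
samples (drawn uniformly, both classes) has its modality-1 shift multiplied
by 0.1: the minimal construction that makes staged escalation necessary,
since those samples look ambiguous to the first view but remain fully
resolvable once later views join.  Defaults mirror a 351-subject cohort
(169 controls / 182 cases, three 200-feature layers) with effect sizes
ordered so the first view is strongest.  All randomness comes from numpy's
PCG64 generator seeded from the spec; regeneration is byte-identical.

What the generator does *not* model: realistic methylation beta-value or
count distributions, feature-feature covariance beyond the single latent
factor, batch effects, or missing modalities.  Tests passing on this data
therefore demonstrate the machinery (graphs, fusion, uncertainty, routing)
under the method's own assumptions, not performance on real cohorts.

## Problem sizes used in the test and acceptance studies

Desk-scale end-to-end studies run at n = 300 (or the canonical 240-sample
routing fixture), 50 features per modality, 10 informative, T = 5 trials,
300-epoch budgets, and a reduced architecture (GCN widths 64/64/32, head
width 32).  These sizes were chosen once as the package's standard study
conditions: they preserve every structural property the full-size defaults
have (three-layer propagation, staged escalation, ensemble spread) while
keeping a complete multi-trial pipeline run in the tens of seconds.

## Degenerate inputs and numerical details

* Zero-norm feature rows make cosine similarity undefined → explicit error
  naming the sample.
* A single-class training set is rejected before any fit.
* Non-finite losses abort training with the epoch index; inside an ensemble
  the failing trial index is reported.
* Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e-300 before the log.
* Probability rows sum to 1 within 1e-6 by construction (exact softmax);
  tensor sums inherit that bound.
* CSV floats are written with 12 significant digits; round-trips reproduce
  values to well below 1e-9.

## Known limitations

* Transductive only: classifying a new sample requires rebuilding graphs and
  retraining with that sample as a node.
* At most three views and three stages; no cost-weighted threshold
  objective (accuracy is the only optimization target, cost enters only
  through the tie rule).
* The ensemble quantifies model/initialization variance, not data noise; it
  is not a calibrated posterior.
* Feature preprocessing/selection is out of scope — matrices are consumed
  as given, and missing values are an error rather than imputed.
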