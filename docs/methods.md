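# Methods

## Problem setting and data model

The package targets per-recording tabular speech-biomarker data: each subject
contributes `recordings_per_subject` rows (default 3), each row holds a few
hundred numeric features grouped into families (baseline, time-frequency,
MFCC, wavelet, TQWT, vocal-fold), and the binary label (1 = disease) is
constant within subject.  Because rows of one subject are correlated, every
accuracy estimate in the package — the wrapper fitness and the outer
evaluation — groups folds by subject; recordings of one subject never appear
on both sides of a split.

## Synthetic generator

`generate_synthetic(SyntheticSpec)` plants ground truth for selector
benchmarking:

- **informative** columns: unit total variance, class means at
  `±effect_size/2`;
- **redundant** columns: `ρ·parent + √(1−ρ²)·ε` with parents assigned
  round-robin among informative columns.  Parents include the class shift, so
  copies are themselves class-correlated, and the *marginal* copy–parent
  correlation slightly exceeds the nominal `redundant_rho` (≈ 0.92 at
  ρ = 0.9, effect 1.2);
- **noise** columns: standard normal;
- a per-subject random effect with variance `within_subject_rho` (default
  0.3 — a moderate within-speaker correlation; informative and noise columns
  share the mechanism) correlates a subject's recordings.

Defaults are the package's desk-scale benchmark: 20 subjects per class × 3
recordings (120 rows), 10 informative at effect 1.2, 20 redundant at ρ = 0.9,
170 noise.  What the generator does **not** emulate: family-specific
marginal distributions, heteroscedastic measurement noise, label noise, class
imbalance at the subject level, and nonlinear class boundaries.  Passing
recovery tests therefore demonstrate the machinery under a linear,
homoscedastic signal model, not performance on real voice data.

## Wrapper fitness

A mask's fitness is the subject-grouped stratified k-fold CV accuracy
(3 folds) of a k-NN classifier (k = 5) on the masked columns, memoized by
mask, optionally blended with a parsimony term:
`fitness = (1−w)·accuracy + w·(1 − |S|/D)` with `w = size_penalty`
(0 by default; 0.1 in the packaged ensemble configuration).  Two refinements
matter in practice:

- **Repeated CV** (`n_repeats`, default 1; 2 in the ensemble configuration):
  a deterministic search evaluating thousands of masks against one fixed
  split eventually exploits fold-specific chance structure (internal accuracy
  reaches 1.0 through cherry-picked noise features).  Averaging over
  independent split replicates makes luck much harder to exploit.
- **Per-selector CV seeds**: inside `run_obefs` each selector receives its
  own fold split, so chance features rewarded by one selector's folds are not
  rewarded by another's — the majority vote then cancels them.

## Selector parameterization

All three selectors share the encoding: positions in the unit cube, mask =
`position > 0.5`, all-zero masks resolved by activating the largest entry.
Iteration budgets are reported per selector; an LFCSA iteration costs ~1
evaluation (one Lévy proposal plus `prb_a·N` abandonment redraws) while AFA
and FMBOA sweep the whole population per generation, so the packaged ensemble
gives LFCSA 20× the iteration count to roughly equalize evaluation budgets.

Defaults and rationale:

- `LfcsaParams`: `β = 3/2` (the customary Lévy index), `prb_a = 0.25`
  (literature-standard abandonment; 0.1 in the ensemble configuration to
  spend fewer evaluations on random redraws), `alpha0 = 1` at the operator
  level.  The ensemble configuration uses `alpha0 = 200`: the Lévy move
  scales as `0.01·(f − f_best)`, i.e. ~10⁻³ per coordinate for unit-cube
  positions, far too small to cross the 0.5 binarization threshold; the
  larger step size makes proposals flip a handful of mask bits.
- `AfaParams`: `β₀ = 1`; `γ` defaults to `1/D` because squared distances
  between random points in the unit D-cube grow linearly with D — a fixed
  `γ = 1` extinguishes all attraction already at D ≈ 50.  The undefined
  two-generation history at t < 2 is bootstrapped with the initial fitness
  and a fixed step `α_init = 0.5`.  The attraction term uses the canonical
  sign (toward the brighter firefly); a `printed_sign` flag restores the
  repulsive variant for fidelity experiments.  Each firefly accumulates all
  attraction moves of one generation and is re-evaluated once, keeping the
  evaluation bound at one population sweep per generation.
- `FmboaParams`: canonical constants p = 5/12, peri = 1.2, bar = p,
  s_max = 1.  The adjusting perturbation is applied when `rand > bar` and
  dampened by `s_max/t²`, so FMBOA converges (and stalls) quickly; elitism
  re-injects the best candidate over the worst each generation.

Determinism: every selector draws all randomness from one
`numpy.random.Generator` seeded by its config; `run_obefs` derives selector
and fitness seeds from the global seed through fixed `SeedSequence` spawn
keys (see `obefs/_rng.py`), so a global seed reproduces the whole ensemble
bit-for-bit.

## Ensemble fusion

Vote-then-filter (the default order; filter-then-vote is available): a
feature needs ≥ 2 of 3 votes; consensus pairs with `|r| > r_threshold`
(default 0.9) are scanned in descending |r|, and the member with the lower
absolute label correlation is dropped (ties drop the higher column index;
constant columns always lose).  An empty consensus falls back to the union
of masks (configurable to a hard error).  Pearson correlation follows the
summation form and returns NaN for constant vectors.

## Classifiers

The default backend is k-NN (k = 5, capped by the row count) — deterministic,
fast, and adequate as both wrapper fitness and final classifier at desk
scale.  The fuzzy-weighted convolutional Bi-LSTM backend standardizes the
masked columns, scales them by fuzzy Gaussian relevance weights (one minus
the Bhattacharyya overlap of the two class-conditional Gaussians; affine
invariant, floored at 10⁻³), and feeds the row as a length-D sequence of
scalar tokens to two parallel branches — stacked tanh 1-D convolutions with
global average pooling, and a bidirectional LSTM — fused by factorized
bilinear pooling (project both summaries to a factor×output space, multiply
elementwise, sum-pool over factors) into a logistic output.  The two branches
are parallel because a serial ordering is ambiguous in the source
description; the bilinear fusion presupposes two branch outputs.  Training is
full-batch-or-minibatch Adam on analytic gradients (verified against central
differences to ~10⁻⁸ relative error); desk-scale defaults are 16 conv
filters, kernel 3, 16 LSTM units, factor dimension 8, 30 epochs, learning
rate 0.01.  The backend is optional: the pipeline runs end-to-end on the
default backend alone.

## Evaluation harness

Leave-one-person-out: one fold per subject, feature selection (and KPCA, if
enabled) fitted **inside** each fold on the training subjects only; the
held-out subject's label is the majority of its recording predictions, with
even splits resolved to the positive class (screening-conservative).  A
`select_once` flag provides the faster, deliberately leaky variant for
comparison.  Fold-level selection seeds derive from the global seed and the
fold index only, so an auditor can recompute any fold's mask from its
training rows and compare hashes — the leakage audit in the test suite does
exactly that.  Metrics: precision, recall, F on [0,1]; accuracy and error in
percent with `accuracy + error = 100` exact; MCC on [−1,1]; zero
denominators yield 0 with a named flag.

## Kernel PCA

Eigendecomposition (`scipy.linalg.eigh`) of the double-centered Gram matrix;
eigenvalues below a relative tolerance of 10⁻¹⁰ are clamped to zero and
their components dropped, setting a `rank_deficient` flag when fewer
components than requested survive.  Component count defaults to the smallest
M retaining 95% of the positive spectrum mass; RBF bandwidth defaults to
`1/(D·var(X))`.  Out-of-sample rows are projected through the cross-kernel
centered with stored training statistics.  Whether selection runs in
component space or on original columns is a pipeline switch: component space
matches the preprocessing chain, original space keeps masks interpretable as
named features; both are supported and neither is forced.

## Problem sizes and numerical choices

The packaged benchmark and tests run at deliberately small scale: 120-row
tables, populations of 4–25, up to a few thousand selector iterations,
10⁶-draw Monte Carlo for the Lévy tail (estimated by regressing the log
survival function on log |step| across the 99–99.99% quantile range).
Ranking ties break by stable sort order; fitness comparisons use strict
improvement; stall-based early stopping (20 non-improving iterations) exists
but is off by default.

## Known limitations

- **Recovery at strong redundancy is structurally hard for the specified
  operators.** On the benchmark table the wrapper accuracy is nearly flat:
  with 30 class-correlated columns, any dozen of them yields ≈ 0.99 CV
  accuracy, so one noise column's marginal contribution (~5·10⁻⁴) is far
  below the CV resolution (1/240).  Noise removal is then a near-neutral
  random walk for all three search dynamics, and a parsimony weight strong
  enough to drain noise also culls true parents, because accuracy cannot
  distinguish a parent from its ρ = 0.9 copy.  The measured benchmark
  consequence: informative recall reaches the 0.6–0.8 range while precision
  stays low (dozens of noise survivors).  The vote-rule and
  correlation-threshold audits hold regardless; `scripts/acceptance.py`
  reports the measured recall/precision for inspection.
- The "fuzzy" qualifier of the monarch-butterfly variant has no defined
  operator in the source description; the canonical operators are used and
  the name retained.
- MCC is reported on [−1,1]; some published tables print it ×100 — compare
  scales before comparing numbers.
- No bootstrap confidence intervals, no significance tests on metric
  differences, no GPU, no audio feature extraction (the data model starts at
  precomputed feature tables).
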