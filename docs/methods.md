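# Methods

## The problem

A typical predictive-modelling analysis cross-validates many
*configurations* — combinations of preprocessing, feature selection and
learning algorithms together with their hyper-parameter values — and
deploys the one whose pooled out-of-sample loss is smallest (trained on
all data).  The pooled loss of that winner is an optimistically biased
estimate of the deployed model's performance: selecting the minimum of
C noisy loss estimates yields, in expectation, a value below the true
loss of the selected configuration (Jensen's inequality applied to the
minimum).  The optimism grows with the number of configurations and
shrinks with sample size, and is most severe in the small-sample
regimes common in the life sciences.

All estimators in this package operate on the same object: the pooled
out-of-sample prediction tensor `Π` of shape `N × C × R` (samples ×
configurations × repeated fold partitions), where entry `(i, j, k)` is
configuration `j`'s prediction on sample `i` made while `i`'s fold was
held out in repeat `k`.  Internally every metric is handled in loss
orientation (0–1 loss for accuracy, `1 − AUC` for AUC) and converted
back for reporting; the configuration selection strategy `css(Π, y)` is
the arg-min of the pooled column losses with ties broken to the
smallest index, so every run is deterministic given a seed.

## Estimation protocols

**CVT** (cross-validation with tuning) cross-validates every
configuration on one shared stratified K-fold partition, selects the
css winner and retrains it on all rows: `K·C + 1` model fits.  Its
estimate — the winner's pooled loss — is the biased baseline.

**Nested CV** treats tuning as part of learning: each outer fold is
held out while CVT runs on the rest, and the single returned model is
scored on the held-out fold; the fold losses are averaged.  The inner
loop reuses the remaining `K − 1` outer folds regrouped as inner folds
rather than re-drawing a partition; this matches the closure view of
nested CV, keeps the replay-on-recorded-predictions variant
well-defined on a fixed `Π`, and gives exactly `K²·C + K + 1` fits
(verified by an instrumented learner in the test-suite).  Outer
aggregation is per-fold-averaged; a single-class outer fold under a
setwise metric is dropped from the average with a warning.

**TT correction** adds to the CVT loss a per-fold estimate of the
selection optimism: the selected configuration's fold loss minus the
best fold loss, averaged over folds.  By construction
`0 ≤ TTBias ≤ L_CVT`, so `L_CVT ≤ L_TT ≤ 2·L_CVT`.  With single-sample
folds and many configurations the per-fold minimum is usually zero and
the correction degenerates to doubling the loss (a selected
configuration at 70 % 0–1 loss is "corrected" to 140 %) — the package
reproduces this pathology as a worked example.  TT requires the metric
inside every fold, so setwise metrics on small or single-class folds
raise rather than silently degrade.

**BBC** (bootstrap bias correction) resamples the *rows* of `Π` B
times; on each draw the selection runs on the in-bag rows and the
in-bag winner's loss is computed on the out-of-bag rows.  The mean of
the B out-of-bag losses is the point estimate; the same population
yields percentile confidence intervals
`[L_(⌈α/2·B⌉), L_(⌊(1−α/2)·B⌋)]` (order statistics 25 and 975 at
B=1000, 95 %).  No model is retrained.  A single shared bootstrap plan
(the full `B × N` index matrix, drawn up front, rows with an empty
out-of-bag set redrawn) backs both the point estimate and the interval.
For samplewise metrics the implementation is exact linear algebra:
in-bag column losses are multiplicity-weighted means (`W @ L / N`),
bit-identical to explicit resampling for integer-valued losses, which
the test-suite checks against an independently coded double-loop
oracle.  With repeated partitions (R > 1) the resampled unit is the
*instance*: a drawn sample carries all R of its predictions, and
selection and scoring pool the repeats (equivalently, per-sample losses
are averaged over repeats for samplewise metrics); at R=1 this reduces
exactly to plain BBC.

**BBCD** adds early dropping: after each completed fold, the pooled
predictions so far are bootstrapped and, for each active configuration
`θ`, `p̂_θ` is the fraction of draws in which `θ`'s in-bag loss
*strictly* exceeds the current best configuration's.  Ties never count
against a configuration — an exact duplicate of the best is retained —
and a dropped configuration never reactivates.  Configurations with
`p̂_θ > α` (default 0.99) are never trained again, so the number of
fits is at most `K·C + 1`, with equality iff nothing is dropped; at
`α = 1` the run is bit-identical to CVT followed by BBC with the same
plan.  The library default delays testing until 50 pooled out-of-sample
predictions exist, because with only a handful of predictions the test
drops good configurations too eagerly; the simulation harness sets this
gate to 0 to mirror the study conditions.  The final estimate is the
BBC estimate computed over the surviving configurations' complete
columns.  A ragged alternative — letting each bootstrap draw also
consider dropped configurations on the rows they did see — was
evaluated and rejected: per-draw selection then favours columns
supported by a handful of rows, whose out-of-bag losses are extreme,
and the estimate becomes wildly pessimistic (mean bias versus nested CV
near −0.2 accuracy points in the synthetic study instead of a few
thousandths).

## The synthetic study

The generator emulates the out-of-sample prediction matrix of a binary
classification task directly, with no training: true accuracies
`P_j ~ Beta(a, b)` per configuration and correctness indicators
`Π_ij = 1(r_ij < P_j)` with uniform draws.  The grid crosses
`N ∈ {20, 40, 60, 80, 100, 500, 1000}`,
`C ∈ {50, 100, 200, 300, 500, 1000, 2000}` and
`(a, b) ∈ {(9,6), (14,6), (24,6), (54,6)}` — mean accuracies 0.6–0.9
with variances 0.015 down to 0.0015 — 196 cells, 500 repetitions each
at full scale (98,000 matrices), K=10 folds, B=1000, dropping threshold
0.99.  Within a repetition every protocol is applied to the same matrix
and the same fold split, so protocol contrasts are paired; the recorded
quantity is the bias `P̂ − P` with `P` the true accuracy of the
configuration the protocol selected.

The uniform draws are independent per configuration.  This is a
deliberate reading of the generator: with a single shared difficulty
draw per sample, the empirical ranking of configurations is monotone in
the true ranking (a higher-accuracy configuration is correct on a
superset of samples), selection optimism nearly vanishes (mean CVT bias
≈ 0.03 at N=20, C=2000 instead of ≈ 0.17), and none of the study's
bias phenomena appear.  The shared-difficulty variant is kept as an
explicit ablation switch.  What the generator does *not* emulate:
correlation between configurations induced by shared algorithms or
hyper-parameter neighbourhoods, class imbalance, setwise metrics
(accuracy only), and any dependence of a configuration's accuracy on
training-set size — so passing tests bound the estimators' behaviour
under exchangeable, independently-erring configurations, not under
every real learning pipeline.

Because the simulated matrix is a correctness indicator, the harness
scores it against an all-ones label vector with 0–1 loss, and fold
assignment is a plain (unstratified) equal-size random partition —
correctness indicators carry no class structure to stratify on.

## Numerical and design choices

* Tie-breaks everywhere (css, per-bootstrap selections, drop tests) go
  to the smallest configuration index; first-index `argmin` makes runs
  reproducible and permutation-equivariant up to relabeling.
* Stratified folds: each class is shuffled with the seeded generator
  and dealt round-robin with a running pointer, so total fold sizes and
  per-class fold counts both differ by at most one; a class smaller
  than K triggers a best-effort warning.
* Degenerate bootstrap draws (empty out-of-bag set; single-class in- or
  out-of-bag set under AUC) are redrawn up to 100 times, then skipped
  with a logged count, keeping the effective B close to nominal.
* AUC is computed pooled for CVT/BBC/BBCD and per-fold for TT and
  nested CV; pooling scores across folds assumes the models' scores are
  on a comparable scale, which the library documents but cannot verify.
* Estimates are reported in the metric's native direction; confidence
  bounds are complemented and re-sorted for higher-is-better metrics.

## Problem sizes used in the shipped replications

The shipped tests and the reproduction script run the Beta(9, 6) grid
at 100 repetitions per cell with B=500, the package's desk-scale
choice; the reproduction script additionally runs the cheap N=20 row
and the (N=20, C=2000) cell at the full 500 repetitions, since the
worst-case statistics are read there.  Monte-Carlo standard errors at
these sizes are reported alongside every bias estimate, and stochastic
checks use twice that standard error as tolerance.

## Known limitations

* The drop test follows the strict-inequality definition of `p̂_θ`
  against the fixed current best.  Under this rule, configurations that
  frequently tie the best (common with 0–1 loss on few samples) are
  retained, so early dropping is gentle at small N; the bias of the
  resulting estimate relative to nested CV is a few thousandths of an
  accuracy point conservative in the synthetic study.
* Survival and regression metrics satisfy the `Metric` contract and can
  be registered by users, but are not built in or tested.
* `BBCD` with setwise metrics loops over bootstrap draws and is
  markedly slower than the samplewise linear-algebra path.
* Confidence intervals are percentile-only; BCa or studentized variants
  are out of scope.
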