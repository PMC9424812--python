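# Methods

## Model and procedure

The package selects features for classification from an N×M numeric table
with a categorical class c. The pipeline has a filter stage (relevance
ranking, grouping, subset ordering) that never touches a classifier, and a
wrapper stage that does.

**Per-feature relevance.** `Ic(f; c) = α·I(f; c) + (1 − α)·|corr(f; c)|`.
Mutual information I is the plug-in estimate on the empirical joint
distribution after discretization, in bits; corr is Pearson correlation
between the raw feature and the integer-coded class. The blend assumes
both terms are informative on their own scales — no cross-scale
normalization is applied by default (a min–max flag exists), so with MI in
bits and |corr| ≤ 1 the α weight also absorbs the scale difference.

**Grouping.** Features ranked by Ic are dealt into r = round(M/Fc) groups
of Fc = round(log2 M) by a serpentine walk (group indices 1..r, r..1,
1..r, …). Fc mirrors the number of features a random-forest base tree
draws; the serpentine deal ensures each candidate subset spans the
relevance range instead of stacking the top features into one group.
Rounding is half-away-from-zero, reproducing Fc = 4, r = 5 at M = 20.
When r·Fc ≠ M the walk simply stops when features run out, leaving group
sizes within one of each other — the minimal consistent extension of the
evenly divisible case.

**Subset ordering.** Subset relevance
`D(Fx; c) = β·Σ I(f_i; c) + (1 − β)·Σ |corr(f_i; c)|` and redundancy
`R(Fx; S) = (1/|S|)·Σ_{Fy∈S} [β·Σ_{i,j} I(f_i; f_j) + (1 − β)·Σ_{i,j} |corr(f_i; f_j)|]`
are raw sums over members and member pairs, not means — the subset-level
criterion is defined with sums even though the classic single-feature
criterion uses means; a `normalize_subset_sums` flag provides mean scaling
for sensitivity analysis. Because all subsets share (near-)equal size the
sums are comparable across subsets. The greedy order starts from the
largest accumulated Ic and then maximizes D − R; with EGM partitions the
subsets are disjoint so i = j pairs cannot occur, but they are excluded
defensively if overlapping subsets are supplied. |S| counts the
already-selected subsets, matching the denominator's role in the classic
incremental search.

**Wrapper.** SFS is prefix evaluation along the flattened subset sequence:
the filter stage fixes the order, the wrapper evaluates the M nested
prefixes and keeps the accuracy-maximizing one (ties → shortest). This
costs O(M) classifier fits rather than O(M²) for re-searching each step,
and matches the convention of ranking first and searching forward along
the ranking. SFSFs adds whole subsets until accuracy reaches the
all-features baseline under the same protocol, returning the best
cumulative set (flagged non-converged) if it never does. The (α, β) grid
defaults to {0.1, …, 1.0}²; the best β per α gives b_max(α), the best
over α gives CS*. Grid ties break to the shortest subset, then the
lexicographically smallest (α, β).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α, β | grid 0.1–1.0 step 0.1 | weight of MI vs \|corr\| in per-feature / subset scores; 1.0 = MI only |
| n_bins | 10 | equal-frequency bins for MI estimation; features with ≤ 10 distinct values pass through unchanged |
| θ | 0.5 | accuracy vs dimensionality-reduction tradeoff in Z |
| train_fraction | 0.7 | stratified hold-out split; train size = round(0.7·N) |
| repeats | 30 | hold-out repetitions; repeat i uses seed + i |
| n_estimators | 100 | trees in the default random-forest wrapper classifier |
| protocol | cv | `cv` = 5-fold CV on train; `paper_faithful` = score on held-out 30% |

## Numerical choices

- **MI estimator.** Plug-in histogram estimate, log base 2. The base
  rescales MI uniformly, so MI-only rankings (α = β = 1) are
  base-invariant. The plug-in estimate is biased upward for independent
  variables (order 1/n per degree of freedom); tests account for this
  when asserting near-zero MI.
- **Absolute Pearson.** |corr| enters all combined scores: a strongly
  negative correlate is relevant, and a signed term could cancel MI
  relevance. A flag restores signed correlation.
- **Constant columns.** Pearson returns 0 by convention (logged) instead
  of NaN; a constant feature discretizes to a single bin with MI 0.
- **Tie-breaks.** Lowest original index wins everywhere, and "tie" means
  scores within 1e-9 of the maximum: mathematically equal scores computed
  through different summation orders differ at the 1e-16 level, and
  without the tolerance the documented tie-break would depend on float
  round-off. Grid ties: shortest subset, then smallest (α, β).
- **Split sizes.** The stratified split apportions round(0.7·N) training
  samples across classes by largest remainder, each class keeping at
  least one sample on each side; an unstratified flag restores a plain
  random split. Stratification stabilizes the repeated protocol on small
  classes (a 214-sample, 6-class table keeps every class represented).
- **Caching.** Pairwise MI and |corr| are computed once into M×M matrices
  per table; identical results, lower complexity.

## Synthetic data: what it does and does not emulate

The generator plants class-conditional Gaussian "relevant" columns (unit
within-class sd, class k shifted by k·separation), "redundant" columns
that are a relevant column plus N(0, sd²) noise, and independent Gaussian
"noise" columns, with near-balanced classes. Defaults — 300 samples, 2
classes, 5 relevant + 5 redundant (copy sd 0.1) + 40 noise, separation 2 —
give tables where relevance ranking, redundancy scoring and wrapper
selection all have known right answers. `make_table1_like` reproduces only
the N×M×K shapes of seven published benchmarks (e.g. Glass 214×9×6,
Movement 360×90×15) with synthetic content, for problem-size testing.

What passing tests on this generator show: the estimators rank planted
signal above noise, the redundancy term demotes duplicate-rich subsets,
and the wrapper recovers the planted signal directions. What they do not
show: behavior under heavy-tailed or multimodal feature distributions,
correlated noise, class imbalance, or feature semantics of real spectral
or audio data — real tables can order differently under Ic than under MI
alone.

One measurement detail: at copy-noise sd 0.1 a duplicate correlates with
its original at ≈ 0.995, so a selector cannot systematically prefer the
original; planted-signal recovery is therefore measured as signal
coverage, counting a selected duplicate toward its source signal.

## Problem sizes used by the shipped checks

The oracle-equivalence suite runs 200 random tables with 30–50 samples
and 4–24 features against step-wise exhaustive brute-force oracles;
partition properties are enumerated for every M in 2..1000; recovery runs
the 50-feature generator default over 20 seeds at the single grid cell
(α, β) = (0.5, 0.5) with a 50-tree forest under the `paper_faithful`
protocol — a single cell, because the recovery claim concerns the fixed
study condition α = 0.5, not the grid argmax. Reproducibility is checked
byte-for-byte on reruns of the full pipeline.

## Known limitations

- The plug-in MI estimate is biased at small n and insensitive to
  structure finer than the bin resolution; no kernel/k-NN estimators are
  provided.
- Greedy subset ordering and prefix-SFS are heuristics; neither is
  guaranteed to find the accuracy-optimal subset, and no floating or
  global search is included.
- The `paper_faithful` protocol reuses the held-out split for model
  selection; its accuracies are optimistically biased and should not be
  reported as generalization estimates.
- ARFF support covers numeric attributes plus one nominal class (read
  only); sparse formats and missing-value imputation are out of scope.
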