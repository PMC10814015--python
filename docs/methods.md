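# Methods

## Model and assumptions

`pnnclass` classifies by aggregating a family of exactly-normalized
neighbor-interaction label models. For rank `r`, the nonlocal model places
probability proportional to `exp(β_r T_r(y))` on a label vector `y`, where
`T_r(y)` counts the units whose label agrees with their r-th nearest
neighbor's. The model conditions on the predictors only through the
neighbor ranking; it assumes a meaningful global distance (Euclidean here),
so predictors on wildly different scales should be standardized by the user
first. Labels are exchangeable given the neighborhood structure — there is
no per-class interaction strength.

The tractability argument is structural: the rank-r interaction digraph
`i → [i]_r` is a functional graph (outdegree one everywhere). Every weakly
connected component contains exactly one simple directed cycle — a
component with none would need a vertex of outdegree zero, one with two
would need a vertex of outdegree two. Summing the unnormalized mass
vertex-by-vertex from the leaves inward contributes `e^{β_r} + L − 1` per
tree vertex regardless of its neighbor's label, and the residual sum around
a cycle of size `m` is the trace of the m-th power of the `L × L` transfer
matrix `S_{ab} = exp(β_r I(a=b))`, whose eigenvalues are `e^{β_r} − 1`
(multiplicity `L − 1`) and `e^{β_r} + L − 1`. The partition function is the
product of these factors; the cycle census `c_m(r)` is the only structural
input.

By contrast, the joint model that couples each unit with all k nearest
neighbors has a normalizing constant whose exact summation would determine,
via polynomial interpolation in `z = e^{β/k}`, the number of binary
labelings at every value of the interaction statistic — equivalently the
number of cuts of every size of the weighted k-neighborhood graph
(`cut_size(y) = ½ Σ b_ij − T(y)` with `B = A + Aᵀ`). The `oracle` module
verifies this identity exhaustively on tiny instances; the package never
attempts the joint constant at realistic size.

## Estimation

`T_r` is a sufficient statistic, so the log-likelihood
`β T_r − log Z_r(β)` is concave and the constrained MLE on `[0, β_max]` is
found by bounded scalar minimization (Brent-type, `xatol = 1e−8`). Two
boundary cases are handled analytically rather than numerically:

* the score at zero is `T_r − n/L`, so `β̂_r = 0` exactly whenever
  `T_r ≤ n/L`;
* when `T_r = n` (every unit agrees with its r-th neighbor) the likelihood
  is strictly increasing for all finite β — the MLE does not exist. The fit
  is then reported at `β_max` with the `clipped` flag set. Downstream
  summaries that average estimates should drop clipped fits: the recorded
  value there measures the bound, not the data. `β_max` defaults to 30
  (`e^{30} ≈ 10^{13}` dominates any finite-n likelihood ratio), a
  convention with no visible effect on predictions beyond saturating the
  already-degenerate case.

All partition-function arithmetic is in log space; the two-term cycle
factor uses log-sum-exp, and `log(e^β − 1)` is computed as
`β + log1p(−e^{−β})` (exactly `−inf` at β = 0, which the log-sum-exp
absorbs). `log Z_r` is finite and overflow-free over the whole admissible
β range.

## Prediction and the insertion view

A query point enters the predictive exponent twice: through the label of
its own r-th nearest training unit, and through every training unit that
the query *captures* — units whose r-th nearest neighbor becomes the query
once it is inserted. The estimated `β̂_r` multiplies the whole bracket
(both terms), the reading consistent with the model's full conditional.
Capture is computed in `O(n)` per query by counting, for each unit `i`, the
training units at distance `≤ d(i, query)`: the query occupies rank
`count + 1` in i's augmented list. This is verified exactly against full
bracket recomputation on the augmented sample (property-tested to n = 50,
all ranks).

Tie conventions, fixed for determinism: equidistant training units rank by
smaller index (stable sort); a query at exactly a training unit's distance
ranks after it; probability ties in argmax resolve to the smallest class
label; LOOCV error ties resolve to the smallest k. The entire fit/predict
path is deterministic — identical inputs give bit-identical model files and
probabilities.

Indices are 0-based throughout the public surface, and class labels
(arbitrary strings or numbers) are encoded to `0..L−1` in sorted order
following the scikit-learn `classes_` convention.

## Choice of k

`k` is selected by leave-one-out cross-validation: each training unit is
predicted from the other `n − 1` (its rank-r neighbor read from the full
brackets, its captured set `{j : [j]_r = i}`), per-rank distributions are
averaged over `r ≤ k`, and the misclassification curve is minimized. The
default k grid is all of `1..n−1`.

By default the per-rank `β̂_r` are fitted **once** on the full training
sample and reused across folds (`loocv_refit=False`). This keeps the whole
fit at `O(n²)` and matches the millisecond-scale runtimes the method is
known for, but it is mildly optimistic: on label-free (null) data, ranks
whose full-sample `T_r` was high by chance get positive `β̂_r`, and the
held-out unit's own agreement contributed to that selection, so the
shared-fit LOOCV curve can dip well below the chance error level at large
k. The exact mode (`loocv_refit=True`) rebuilds brackets, census and fits
within each fold, restores chance-level behavior on null data (verified in
the test suite), and costs a factor ~n more. On data with real signal the
two modes agree closely; the default trades a small optimism in the
*selection criterion* (not in any reported test-set metric) for speed.

## Synthetic data

The generators emulate the structure of the method's standard benchmarks so
that everything runs without downloads:

* `ripley_like`: two classes in 2-D, each an equal-weight mixture of two
  isotropic Gaussians (class 0 means `(−0.7, 0.3)`, `(0.3, 0.3)`; class 1
  means `(−0.3, 0.7)`, `(0.4, 0.7)`; variance 0.03), 250 training / 1000
  test points, balanced priors. These defaults are this package's choices,
  set so that a tuned majority-vote k-NN lands near an 8–12% test error —
  the difficulty regime of the classic two-class mixture benchmark.
* `multiclass_blobs`: L isotropic Gaussian blobs on a circle of radius
  `separation`, from chance-level (`separation = 0`) to perfectly separable.
* `random_functional_graph`: uniform successor maps without self-loops, the
  harness for the cycle and partition-function cross-checks.

What passing tests on these generators does *not* show: behavior under
heavy-tailed or discrete predictors, unequal feature scales (no internal
standardization), strong class imbalance, or `p ≫ n` geometry — real
datasets need the usual preprocessing judgment.

## Verification strategy and problem sizes

Every fast path is certified against an independent slow path: the
closed-form `log Z_r` against exhaustive `L^n` summation (n ≤ 10,
L ≤ 4, ~200+ configurations, worst relative error ~1e−15); the walk-stack
cycle counter against successor iteration (hundreds of graphs to n = 200,
exact); the insertion view against full rebuild (exact); the cut-size
identity over all `2^n` labelings of random instances (n ≤ 10); coefficient
recovery by interpolation against direct enumeration (n ≤ 8). The
small-sample MLE check draws 500 exact samples at known β₀ on an n = 12
structure and compares the mean of the finite (non-clipped) estimates with
β₀ at Monte-Carlo precision. Sizes were chosen to keep the full suite and
the acceptance script in the seconds-to-minutes range on one CPU.

Coefficient interpolation deserves a numerical note: the Vandermonde system
is catastrophically ill-conditioned in double precision beyond degree ~20,
so the default path evaluates `Z(z)` at integer nodes `z = 1..nk+1` in
exact integer arithmetic and solves the system over the rationals — exact
at any degree. A double-precision path (with integer rounding and a
residual check) remains available for user-supplied float nodes at small
degree.

## Known limitations

* `O(n²)` memory and time in the training size; intended for the
  moderate-n regime of its benchmarks (hundreds to a few thousand units).
* No per-class or distance-weighted interactions; the model sees ranks, not
  distances, beyond the neighbor ordering.
* The shared-fit LOOCV optimism described above.
* Ties in high-dimensional discrete predictors can make the neighbor
  ranking convention-dependent; the lower-index rule is deterministic but
  arbitrary.
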