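# Methods

## Model and estimators

All dependency measures assume the expression vector is jointly Gaussian,
under which mutual information and conditional mutual information reduce to
covariance determinants:

```
MI(X,Y)    = ½ ln( σ²_X σ²_Y / |C(X,Y)| )  =  −½ ln(1 − ρ²_XY)
CMI(X,Y|Z) = ½ ln( |C(X,Z)| |C(Y,Z)| / (|C(Z)| |C(X,Y,Z)|) )
```

Natural logarithms are used throughout, so thresholds are in nats; the
practical θ range for expression data is roughly 0.01–0.1. Covariances use
the unbiased divisor n−1. The determinant ratios of the CMI formula are
invariant to that choice; raw MI magnitudes are not, which only matters
against θ1 at very small sample sizes. With an empty conditioning set the
CMI formula reduces exactly to MI, and first-order CMI equals the
partial-correlation closed form −½ ln(1 − ρ²_{XY·Z}) (both equalities are
exercised by the test suite against independently coded oracles).

A widely used variant of the marginal formula divides by the covariance
σ_XY instead of the determinant |C(X,Y)|; that form is dimensionally
inconsistent and can go negative, so this package implements the
determinant form, which is also the |Z| = 0 special case of the CMI
formula.

**CMI2** (conditional mutual *inclusive* information) scores an edge by the
symmetrized Kullback–Leibler divergence between the observed joint law P
over (X, Y, **Z**) and the two interventional laws that sever one direction
of influence:

```
CMI2(X,Y|Z) = ( DKL(P ‖ P_{X→Y}) + DKL(P ‖ P_{Y→X}) ) / 2,
P_{X→Y}(x,y,z) = p(x,z) · ∫ p(y|z,x') p(x') dx'
```

Under Gaussianity the interventional law is again Gaussian with the same
mean: writing the regression of Y on (X, **Z**) as Y = aX + b·**Z** + ε, the
interventional covariance keeps the (X, **Z**) block and replaces
Var(Y) = a²σ²_X + bᵀC_ZZ b + Var(ε), Cov(Y,**Z**) = bᵀC_ZZ,
Cov(Y,X) = bᵀC_ZX — i.e. Y is re-generated from an independent copy of X.
Each KL term then has the standard Gaussian closed form
½[tr(Σq⁻¹Σ) − d + ln|Σq| − ln|Σ|]. Two consequences follow directly and are
tested: CMI2 with an empty conditioning set equals MI, and CMI2 is exactly 0
whenever the empirical partial correlation of (X,Y) given **Z** is 0.

### Degenerate configurations

A determinant below `1e−12 ×` (product of the diagonal) marks the value
*saturated*: the estimator returns the finite cap ½ ln(1/1e−12) ≈ 13.8 nats
instead of an infinity. A perfectly collinear pair is maximally dependent,
so saturated values participate in percentile statistics at the cap and can
never cause an edge removal. Tiny negative round-off values are clamped
to 0.

## The inference loop

Orders 0–2 are applied in sequence, each producing the next skeleton from
the previous one:

* **Order 0** — remove every pair with `MI < θ1` (strict) from the complete
  graph.
* **Order 1** — for each surviving edge X–Y, the pool is
  `V_XY = ADJ(X) ∩ ADJ(Y)` on the order-0 skeleton; the statistic is the
  k-th percentile of `{CMI(X,Y|Z) : Z ∈ V_XY}`; remove when it is `< θ2`.
* **Order 2** — pool `U_XY = (ADJ(X) ∪ ADJ(Y)) \ {X,Y}` on the order-1
  skeleton; statistic over all unordered pairs {Z,W} ⊆ U_XY (CMI is
  symmetric in its conditioners, so ordered pairs would double-count and
  repetitions {Z,Z} would be singular); same removal rule.

Pools are computed once per order and frozen, and removals are applied in a
single batch at the end of the order. These two choices are the entire
mechanism of order independence; they are also why the loop costs more CMI
evaluations than the mutating classical loop, which shrinks its pools as it
deletes. Edges whose pool is empty (order 1) or has fewer than two members
(order 2) are kept untested — the PC-family convention of removing only on
positive evidence. The loop stops at order 2: higher orders add little on
expression-sized samples and the pool `U_XY` already covers length-3 paths.

The percentile uses linear interpolation between order statistics (position
(n−1)·k/100) — continuous in k, and k = 100 recovers the classical
`CMI_max` rule exactly. The per-edge reading of the percentile (each edge's
statistic is the quantile of *its own* conditioner values, not a global
quantile across edges) matches the per-edge notation CMI_70(X,Y|Z,W) of the
method's step description. Equality with a threshold keeps the edge (both
comparisons are strict `<`). Both variants use MI at order 0; the estimator
choice (CMI vs CMI2) affects orders 1–2 only.

Numerical order independence additionally requires that no floating-point
result depend on column order. Two implementation details guarantee this:
the full-gene covariance is computed once (its entries are bitwise
independent of column permutation), and every submatrix passed to a
determinant is assembled in a canonical gene-id-sorted order.

## The baseline

`pca_cmi` preserves the classical behavior faithfully: pairs are visited in
lexicographic order of their positions in an explicit `gene_order`
permutation, `V_XY` is recomputed on the current (mutating) skeleton at
every test, and the edge is deleted immediately when
`CMI_max(X,Y|M) < θ` over i-subsets M (order 0 uses MI). A single pass is
made per order; a `until_stable` switch repeats each order to a fixed point
for experiments that want the recursive variant. The scan-order convention
is immaterial to the experiments, which randomize `gene_order` itself.

## Evaluation conventions

Confusion counts run over all n(n−1)/2 unordered pairs; directed gold
standards are collapsed to undirected edges first, because the inferred
object carries no orientations. MCC uses the square-rooted denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) — the form that reproduces the standard
benchmark values. Every 0/0 ratio (PPV of an empty prediction, F when
PPV+TPR = 0, MCC with a zero factor) is defined as 0, the empty-prediction
limit. ROC curves append the anchors (0,0) and (1,1) before trapezoid
integration since finite θ grids never reach the extremes; for the quantile
method the sweep sets θ1 = θ2 = θ with k fixed at 70. Threshold and
quantile sweeps report the population (divisor N) standard deviation of TP
and FP over the grid — the grid is exhaustive, not a sample — while the
subsample study reports the sample (divisor N−1) standard deviation over
replicates; both expose the divisor as an option. The default sweep grids
are θ ∈ {0.001, …, 0.999} in steps of 0.001 and k ∈ [50, 90] percent in
steps of 0.1; the sweep varies θ1 and θ2 jointly, matching the ROC
protocol.

## Synthetic data

The simulator draws an Erdős–Rényi-style DAG on a random topological order
(edge probability `expected_degree/(n−1)`), weights uniform on ±[0.6, 1.0],
and samples the linear SEM `X_j = Σ w·X_parent + ε`, ε ~ N(0, 0.5²),
ancestrally. The linear-Gaussian family is chosen deliberately: the
Gaussian estimators are exact in it, so recovery results measure the
algorithm, not estimator bias. Columns are emitted in gene-id order, never
topological order, so no consumer can accidentally exploit a causal
ordering. What the simulator does *not* emulate: nonlinear regulation and
saturation kinetics, non-Gaussian noise, time courses and knockout designs,
and the scale-free degree structure of real transcriptional networks —
passing recovery tests therefore demonstrate correctness of the machinery
under the model's own assumptions, not performance on real compendia.

Study conditions used by the tests and the acceptance script: 20-gene
models with expected degree 2, 500 samples, θ1 = θ2 = 0.05, k = 70, 20
seeds; order-independence checks use 20 permutations on each of 3 datasets.
These sizes keep the full suite in the tens of seconds while giving every
statistic a stable value. A pilot run under exactly these conditions gave a
median F-measure of 0.885 across the 20 seeds; the regression floor
asserted by the tests is 0.75, i.e. well below the pilot point, so it
detects gross breakage rather than run-to-run noise. The 4-gene
order-sensitivity fixture (simulator seed 0, 40 samples, θ = 0.08) was
selected by an exhaustive pilot search as a small dataset on which the
mutating baseline provably returns different skeletons for different
visitation orders; the test verifies that property by enumerating all 24
orders, so the fixture carries no frozen expectation beyond "≥ 2 distinct".

## Known limitations

* The Gaussian closed forms are exact only for linear dependencies;
  strongly nonlinear regulation calls for non-Gaussian MI estimators, which
  are out of scope.
* Order-2 tests require ≥ 5 samples for a full-rank 4×4 covariance;
  meaningful thresholds require far more.
* The quantile k is a fixed global parameter (default 70); no per-dataset
  tuner is shipped.
* Skeletons are undirected; edge orientation (v-structures, Meek rules) is
  out of scope.
* The exhaustive order-2 enumeration over `U_XY` pairs is quadratic in the
  pool size per edge; dense skeletons after order 1 are the dominant cost.
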