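# Methods

## Model and estimation

The package estimates diagonal-penalized sparse canonical correlation:
for column-standardized views `X1` (n × p1), `X2` (n × p2),

maximize `uᵀ X1ᵀ X2 v` subject to `‖u‖₂² ≤ 1`, `‖v‖₂² ≤ 1`,
`‖u‖₁ ≤ s1`, `‖v‖₁ ≤ s2`, and (by default) `u, v ≥ 0`.

Replacing each view's covariance by its diagonal — the identity after
standardization — sidesteps the singular covariance inversions that make
classical CCA undefined at p ≫ n and makes the penalized solution unique.
The estimator is the alternating penalized matrix decomposition (PMD): with
one weight vector fixed, the other's update is closed-form — soft-threshold
the cross-product image (`Z v` or `Zᵀ u`) and rescale to the unit L2 sphere,
with the threshold chosen so the L1 budget holds.  Each half-step maximizes
the bilinear objective exactly over its block, so the objective is
monotonically non-decreasing (asserted in tests to 1e-10 slack).

Interpretation note: the model yields a *single* similarity measure per
component (the canonical correlation q) and a pair of multivariate weight
vectors; individual weights are not voxel-wise effect estimates and should
not be thresholded for local inference.

### Parameterization of sparsity

`c1, c2 ∈ (0, 1]` are fractional budgets; the effective bound for view k is
`s_k = c_k·√p_k`, making c comparable across views of different dimension.
`c = 1` gives the densest solution the L2 ball admits (not necessarily fully
dense).  Bounds below 1 are infeasible against the unit-L2 constraint and
are clamped to 1 with a warning.  Because an active L1 constraint pins
`‖w‖₁/‖w‖₂` exactly at `s_k`, solutions are only as sparse as the budget —
at `c = 0.3`, `p = 500` the budget (6.71) exceeds the L1/L2 ratio of any
10-feature support (≤ √10 ≈ 3.16), so several budget units necessarily land
on noise features.  Exact-support recovery therefore requires budgets near
`√(true support size)`; with the conventional 0.3–0.9 grid, expect perfect
sensitivity with moderate specificity rather than exact support
identification.  This is a property of the estimator, not of the
implementation.

### The L1-sphere projection

The projection `w = S(a, Δ*)/‖S(a, Δ*)‖₂` needs the smallest threshold `Δ*`
with `‖w‖₁ ≤ s`.  The ratio `‖S(a, Δ)‖₁/‖S(a, Δ)‖₂` is continuous and
decreasing in Δ, piecewise-smooth between sorted magnitudes; the solver
locates the crossing interval from cumulative sums of the sorted magnitudes
and solves the resulting quadratic for Δ exactly (O(p log p)).  A scalar
bisection fallback covers degenerate intervals (exact ties, s² equal to the
support size), and exact top-magnitude ties that make the constraint
unreachable collapse to the unit basis vector of the lowest-index maximal
entry (a reproducibility tie-break).  Tests verify the solver against an
independent 1e-10 scalar-bisection oracle.  The closed-form route was chosen
over per-call bisection because the projection sits in the innermost loop of
the permutation grid search.

### Initialization and convergence

v starts at the leading right-singular direction of the (deflated)
cross-product operator, estimated by power iteration (30 sweeps, 1e-7 stop)
from a seed-0 random start, oriented so the largest-magnitude entry is
positive; in nonnegative mode the flipped start is tried once if the first
half-step has no admissible direction.  Users may supply a vector or an
integer seed instead.  Alternation stops when
`max(‖u_t − u_{t−1}‖∞, ‖v_t − v_{t−1}‖∞) < tol` (default 1e-6) or at
`max_iter` (default 100, `converged=False` flag).  Degenerate instances —
no positive entry under nonnegativity, a numerically zero operator, or a
zero-variance canonical variable — return a flagged zero component with
q = 0 rather than raising, so parameter grids can score over-sparse cells.

### Deflation and matrix-free products

Component i+1 is fit against `Z − Σ_{j≤i} (uⱼᵀZvⱼ)·uⱼvⱼᵀ`.  The explicit
matrix is materialized only when `p1·p2 ≤ 10⁶`; beyond that all products are
computed as `X1ᵀ(X2 w)` at O(n(p1+p2)) plus rank-one corrections, so
voxel-scale problems (p ≈ 37,000 per view) never form the cross-product.
Both routes agree to 1e-8 (tested).  Extracted components are not
orthogonal; the deflation merely removes the captured rank-one cross term.
The deflated bilinear score `q_raw` is kept separately from the reported
canonical correlation q, which is always the Pearson correlation of `X1u`
and `X2v` on the *original* data.

## Permutation selection of (c1, c2)

For every grid pair, the observed first-component correlation is compared to
k refits on row-permuted views (independent uniform permutations per view;
column moments are untouched, only the inter-view correspondence breaks)
via `z = (atanh(q) − mean(atanh(q̇)))/sd(atanh(q̇))` with the n−1 sd and
|q| clamped at 1−1e-12 before atanh.  The default grid is 0.3–0.9 in steps
of 0.1 per view and k defaults to 1000.  Design choices:

- The same k permutation streams (spawned deterministically from the seed)
  are shared by all grid cells — a paired design that removes independent
  Monte Carlo noise from cell-to-cell z comparisons.  A standalone
  `null_distribution` call with the same seed reproduces any cell's null.
- The cross-product and power-iteration start depend only on the data, so
  they are computed once per (permuted) dataset and shared across cells.
- Scoring fits (observed cells and nulls alike) use a reduced sweep budget
  (`scoring_max_iter = 15`): permuted-fit correlations stabilize to well
  within Monte Carlo noise long before the weight vectors settle, and the
  budget is symmetric between observed and null fits so z is unbiased.  The
  final refit at the chosen pair runs to full convergence.  (The reference
  PMD implementation scores permutations with 3 sweeps.)
- Exact z ties prefer larger c1 + c2, then larger c1 — conservative about
  discarding features.
- A zero-spread null yields the largest finite z of the appropriate sign,
  with a warning, so degenerate grids remain comparable.

## Permutation p-values

At fixed (typically the selected) parameters, the observed m-component fit
is compared against k replicates that re-run the *entire* deflation pipeline
on independently permuted views; component i's null is the set of i-th
extracted correlations, and `p_i = (#{q̇_i ≥ q_i} + 1)/(k + 1)`.  The
add-one form keeps p strictly positive and the test exactly valid at finite
k (a raw count divided by k can return 0).  Observed and permuted fits use
identical solver settings, preserving exchangeability.  A degenerate
observed component reports p = 1, as do all components above it.

Known limitation: like-indexed nulls are exactly calibrated under the
global null (verified: per-component type-I error ≈ 0.05 for m = 3), but
when earlier components carry real signal the nulls for *later* components
are anti-conservative — the observed component 2 is the best residual noise
direction while permuted component-2 values are second-best order
statistics.  Treat higher-component p-values as a screening device, reading
the sequence until the first clearly nonsignificant component, rather than
as exact per-component error rates.  (Exact inference for later components
requires conditioning schemes that are themselves miscalibrated under the
global null; no fixed scheme achieves both.)

## Synthetic paired views

The generator emulates the structure the model assumes: per factor, a
standard-normal latent score per sample enters both views through sparse,
nonnegative (uniform (0.5, 1], then unit-normalized) loading vectors, plus
independent Gaussian noise; supports of distinct factors are disjoint within
a view, and a spatial variant lays supports as contiguous blocks for
masked-volume fixtures.  Defaults — n = 50, p = 500 per view, support 10,
signal 3.0, noise sd 1.0 — put the population correlation of the best
projections at `signal²/(signal² + noise²) = 0.9`, the magnitude regime of
the drug-response perfusion data this generator stands in for; the empirical
first canonical correlation at large n matches this closed form (tested at
n = 2000).  Support sizes may differ between views (`s1 ≠ s2`), emulating
drugs with unequal spatial extent of effect.

What the generator does *not* emulate: spatial autocorrelation and
smoothness of real images, physiological noise structure, scanner/session
effects beyond a per-scan mean, and registration error.  Passing recovery
and calibration tests on these views validates the estimator and its
permutation machinery, not robustness to those real-data features.

## Imaging I/O and preprocessing

Masked ingestion binarizes the mask at > 0 and takes in-mask voxels as
matrix columns in C-order linear-index order of the grid — fixed and
documented because the weight-vector/image correspondence depends on it.
Per-scan mean scaling subtracts each scan's in-mask mean (out-of-mask voxels
are background; a whole-volume-mean option exists), removing session
effects; condition contrasts subtract the control scan per subject (matched
by id) after mean scaling.  Column standardization happens afterwards, at
view construction; zero-variance columns are dropped there, recorded, and
re-inflated as explicit zeros in weight maps.  Weight maps copy the mask's
affine, with exact zeros outside the mask.  Upstream spatial preprocessing
(registration, normalization, smoothing, CBF quantification) is out of
scope.

## Problem sizes in tests and the acceptance script

Test and script simulations use the default generator conditions with
permutation counts k = 50–100 for grid selection and k = 99–199 for
inference, 200 calibration replicates in the test suite (100 in the
script), and 10–20 seeds per property — sizes at which the Monte Carlo
error of each reported rate is small relative to the contract being
checked, while a full run stays in the minutes range on one CPU.
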