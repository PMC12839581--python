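# Methods

## Model and estimand

`dcrank` estimates the coefficient vector β\* of a sparse linear model
Y = X′β\* + ε from data sharded across m machines (n observations each,
N = nm in total), without moment assumptions on ε. The loss is the
convolution-smoothed Wilcoxon rank loss: with residuals r_i = Y_i − X_i′β,

    L̂_h(β) = 1/(N(N−1)) Σ_{i≠j} L_h(r_i − r_j),
    L_h(u) = ∫ |u − v| K_h(v) dv,     K_h(v) = K(v/h)/h.

Because the loss depends only on pairwise residual differences it is
intercept-free and translation invariant, and its population minimiser
equals β\* for every bandwidth h > 0 — h only controls smoothness. The
default kernel is the Epanechnikov density K(u) = (3/4)(1 − u²) on [−1, 1],
for which L_h has the closed form 3u²/(4h) − u⁴/(8h³) + 3h/8 inside
[−h, h] and |u| outside. Default h = 1; the theory only needs h = O(1).

## Distributed estimation

Machine 1 never sees the other machines' raw data. Each communication
round broadcasts the current anchor β̂^(t−1), collects gradients, and solves
the surrogate problem on machine 1:

    β̂^(t) ∈ argmin_β  L̂_{1,h}(β) − ⟨υ₃, β⟩ + Σ_j p_λ(|β_j|),
    υ₃ = ∇L̂_{1,h}(β̂^(t−1)) − ∇L̂_h(β̂^(t−1)),

so the local loss is tilted toward the global one at the cost of one
p-vector per machine per round. β̂^(0) is the penalized local fit on
machine 1. T = ⌈log m⌉ rounds (natural log; 3 for m = 10) suffice for the
local-sample error term to contract to the pooled rate. T is configurable,
as is an optional early stop on the sup-norm of the surrogate gradient
(off by default).

**Global gradient semantics.** The printed global loss is a full
N(N−1)-pair U-statistic, but cross-machine pairs require co-resident data.
Both readings are implemented: `"pooled"` (exact full-pair gradient,
default — matches the defining equations and is feasible in the simulation
harness where shards are in-process) and `"machine-average"` (mean of
per-shard local gradients, an incomplete U-statistic moving only p numbers
per machine, for genuinely federated use). The fit logs which mode ran and
a per-round communication ledger.

**Baselines.** Local CR (machine 1 only), DC-CR (entrywise average of m
independently tuned local fits; averaging unions the spurious supports,
which is why its F1 degrades under heavy tails), and Global CR (pooled fit
on all N rows; O(N²) pair work, intended for moderate N).

## Solver

The SCAD penalty (default, a = 3.7; MCP and L1 also provided) is handled by
local linear approximation: each sweep replaces p_λ(|β_j|) with tangent
weights p_λ′(|β_j^prev|)|β_j|, refreshed at sweep granularity. Each
coordinate minimises a quadratic majorizer of the smooth part with
curvature 2k₆υ₂/h (valid since |L_h″| ≤ 2k₆/h, k₆ = sup K = 3/4),
giving a closed-form soft-threshold update. Both majorizations are exact
tangencies, so the penalized surrogate objective is monotone nonincreasing
across updates; the per-sweep trace is recorded and asserted in tests.

Numerical choices:

* υ₂ (mean squared pairwise covariate difference) is precomputed once per
  solve via 2nΣx² − 2(Σx)²; a zero value (constant column) makes the
  coefficient unidentifiable in a rank loss and pins it to 0 with a warning.
* Residual-derivative row sums are refreshed exactly after every accepted
  coordinate move; because L_h′ saturates at ±1 outside [−h, h], the
  refresh sorts the residuals once and reduces the saturated pairs to rank
  counts (prefix sums for the loss), evaluating the polynomial only on the
  ±h window — O(n log n + window) instead of O(n²), a large saving
  precisely on heavy-tailed data. Residuals are recomputed from scratch
  every 10 sweeps to guard float drift. The inner loop is numba-compiled;
  full sweeps alternate with active-set sweeps, and convergence is
  certified by a full sweep with max_l d_l² < tol (default 1e−7, max 500
  sweeps; non-convergence returns a flagged report, never raises).
* Monotonicity forces any LLA tangent-weight limit cycle to have a constant
  objective, so an objective flat to 1e−12 (relative) over 30 consecutive
  sweeps while moves stay above tol is reported as a stall — the iterate is
  a valid approximate minimiser cycling between equivalent points — rather
  than burning the full sweep budget.
* Thresholded coordinates are exactly 0 (bit-exact sparsity); sign(0) = 0.
* Because the SCAD penalty is bounded while the surrogate's shift term is
  linear, the surrogate objective can be unbounded below at small λ — the
  regime the theoretical side constraint |β|₁ ≤ R exists to exclude. The
  constraint is not enforced (R's constant is unknowable in practice);
  instead |β|₁ is tracked, a runaway norm (> 10³ × (1 + the warm start's
  norm)) flags the solve as diverged, and such solutions are excluded from
  tuning (below).

## Tuning

λ is chosen by the high-dimensional BIC

    HBIC(λ) = log L̂_h^{(1)}(β̂^(1)) + |M_λ| (log log n)(log p)/n,

evaluated over a decreasing geometric grid of L = 50 values spanning one
decade down from λ₁,₁ = |∇L̂_{1,h}(0)|_∞ (computed from machine 1's raw
response differences; at the head the all-zero vector is a solution). Path
solves are warm-started downward and run under a 100-sweep budget (the
usual pathwise-optimisation economy); the HBIC winner is then refit to the
full tolerance from its path solution, so the returned estimate always
honours tol = 1e−7. Natural logarithms throughout; ties break toward the
larger λ (sparser model). λ is selected once — on the local
objective for β̂^(0), and on the round-1 surrogate objective for λ₁, which
is reused in every later round (λ_t = λ₁).

The surrogate loss can be nonpositive because of its linear shift term;
`hbic` floors it at 1e−12 with a warning so the criterion stays total. A
floored value (log ≈ −27.6) would spuriously dominate the selection, so the
path selection treats fits with nonpositive surrogate loss — like diverged
fits — as outside the feasible regime: they are recorded on the path but
skipped by the argmin, falling back to the raw argmin only if no valid fit
exists, and later warm starts resume from the last valid solution. A
merely non-converged fit keeps its HBIC: it is an imprecise but meaningful
minimiser, and excluding it would bias selection toward the sparse end of
the path.

## Synthetic data

The generator draws the heteroscedastic design used throughout testing:
X ~ N(0, Σ) with Σ_ij = 0.5^{|i−j|} (via Cholesky), β\* = (3,3,3,3,3,0,…,0),
and

    Y = X′β* + (3|β*|₂²)^{-1} (X′β*)² ε,      3|β*|₂² = 135,

with ε standard normal, t(2), standard Cauchy, or 0.75N(0,1) + 0.25N(0,100)
(plus a degenerate noiseless family for tests). The noise variance grows
with the squared signal, so no error moments exist under Cauchy noise and
the design punishes least-squares-style estimators. Defaults are the study
conditions p = 400, n = 200, m ∈ {10,…,50}. Covariates, noise deviates and
mixture indicators come from separate child streams, so machine 1's shard
is invariant to m at a fixed replicate seed (the local baseline is constant
across m by construction).

What the generator does *not* emulate: dependent or non-identically
distributed rows, covariate contamination, model misspecification, or
machines with heterogeneous data distributions. Passing tests therefore
demonstrate correctness of the procedure and its robustness to heavy-tailed
*response* noise under a correctly specified sparse linear model, not
robustness to arbitrary real-data pathologies.

## Metrics and experiment harness

Estimation error is the per-coordinate RMSE sqrt((1/p) Σ_j (β̂_j − β\*_j)²)
— the convention that reproduces the reference magnitudes (the raw ℓ₂ error,
= RMSE·√p, is available in the detailed per-replicate table). Support
recovery is the F1 score of the exact-zero pattern (1 when both supports are
empty, 0 when the denominator vanishes against a nonempty truth). The
harness runs a (method × family × m) grid with common random numbers across
methods within a replicate; replicate seeds derive from
(seed, family index, replicate), so results are reproducible and comparisons
are paired. Failed fits become NaN cells rather than aborting the grid.

The comparison study and the acceptance script use 20 replicates per cell
(the replication count of the reference study is not stated; 20 keeps
Monte-Carlo error on F1 means near 0.01 at desk scale). Statistical property
tests run scaled designs (p = 100, n ∈ {100, 200}, m ∈ {5, 10}) chosen so
the qualitative orderings (local > distributed error; multi-round ≥ one-shot
F1 under Cauchy noise; round-over-round error contraction) are in their
asymptotic regime.

## Known limitations

* The surrogate problem's possible unboundedness at small λ is handled by
  exclusion-from-tuning rather than the theoretical |β|₁ ≤ R projection.
* The compiled solver supports the Epanechnikov kernel only; other symmetric
  kernels on [−1, 1] are available for loss evaluation via quadrature but
  are untested extras.
* Global CR materialises O(N²) pairwise work per coordinate move and is not
  intended for large N.
* "Machines" are in-process shards; there is no network layer, fault
  tolerance, or privacy mechanism. The communication ledger counts what a
  real deployment would transmit.
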