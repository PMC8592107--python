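# Methods

## Model

The design treats a two-arm trial as a sequential sampling problem on
the incremental net monetary benefit scale. Pairwise allocations are
the sampling unit; pair j yields X_j = λ(E_N,j − E_S,j) − (C_N,j −
C_S,j), assumed i.i.d. Normal(W, σ_X²) with σ_X known and fixed (read
from configuration, never re-estimated from the stream). Beliefs about
W are conjugate normal, tracked as (posterior mean μ, effective pair
count m); the prior contributes n0 = σ_X²/σ_0² pairs of weight. The
posterior mean therefore depends on the data only through its weighted
sum, which is why block means with multiplicities update it exactly —
the published data are blocks of 10 pairs, and the engine treats a
block mean with multiplicity n_pairs as equivalent to its pairs.

Outcomes lag allocations by τ pairs. A trial run has three stages:
Stage I (τ pairs allocated, nothing observed), Stage II (outcomes
arrive; after each block an interim analysis may halt recruitment),
Stage III (the τ pipeline pairs report; the technology is adopted by
the sign of the terminal posterior mean, since the switching cost I is
zero in all shipped analyses). The reward P·max(terminal decision
value) accrues to the P post-trial patients only — there is no
"online" benefit to in-trial patients and no discounting.

## Backward induction

`solve_boundary` discretises μ on a uniform grid and recurses from the
last observable count N = Qmax − τ (where stopping is forced) down to
0. Continuation from n pays c and moves the posterior mean by a
Normal(0, v_n²) increment with v_n = σ_X·sqrt(1/(n0+n) − 1/(n0+n+1));
the expectation E[V(n+1, ·)] uses Gauss–Hermite quadrature (21 nodes by
default) with linear interpolation of V on the grid. Off-grid
quadrature nodes clamp to the edge value, which is benign while the
continuation region stays well inside the grid; the solver raises
`GridTooNarrowError` whenever the computed boundary comes within 5% of
the grid span of an edge. Ties stop: continuation must strictly beat
the stopping value. Boundary edges are refined between grid points by
the linear zero-crossing of (continuation − stop).

Grid default: 1001 points spanning μ0 ± 6σ_X/√n0. With the shipped
parameters that is ±£60k for a boundary that never exceeds ±£25k, so
clamping never binds. With I = 0 the problem is symmetric: V(n, μ) −
P·μ = V(n, −μ), hence upper(n) = −lower(n); the test suite asserts this
to within one grid spacing, and checks the full recursion against an
exhaustive enumeration of all interval stopping policies on a tiny
instance (Qmax = 4, τ = 1, 5-point grid, two-point outcome
discretisation), evaluated by exact expectation under the same
discretisation.

Design classification compares, at the prior mean: the no-trial value
P·max(μ0, 0); the best one-stage design (fixed n ∈ {1..τ−1}, value
P·E[max(μ_n, 0)] − c·n — with n < τ no interim information exists, so
EVSI-maximisation is the optimal fixed design); and the sequential
value −c·τ + V(0, μ0). Stage I's variable cost c·τ is charged to the
sequential design at classification time but is sunk once Stage II
begins, so it never affects the boundary itself. The four prior-mean
thresholds (B ≤ C ≤ D ≤ A) come from bisection on the pairwise value
differences; a dense-sweep cross-check is in the tests.

## Monitoring and replay

Interim analyses occur every block_size observed pairs (default 10, as
published; block_size = 1 recovers per-pair monitoring), with a final
forced look at Qmax − τ when that is not a block multiple (recruitment
cannot exceed Qmax). "Outside the boundary" means strictly below
lower(n) or strictly above upper(n), mirroring the solver's tie-break;
an empty continuation interval at a scheduled look always stops, and
the crossing side is then labelled by the sign of the posterior mean.
A terminal posterior mean of exactly zero adopts the standard
technology. Budget accounting prices the sample-size change against a
reference design (default 125 pairs) at c per pair and expresses it
against the total research budget (default £1,470,000); both
percentage conventions (sample-size change and budget share) are
reported.

## Resampling analyses

The bootstrap resamples whole blocks i.i.d. with replacement until Qmax
pairs are available, then replays — the block is the resampling unit
because the available data are block summaries. The Monte Carlo
analysis draws per-pair outcomes Normal(true_mean, σ_X²) and aggregates
them into blocks of block_size so look times match the bootstrap
exactly; the per-pair granularity of the redraw is a convention choice
documented here. The fixed-design comparator observes all Qmax pairs
with no interim stopping. Summary SDs use the n−1 denominator
(conventional sample SD). All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
path lists. Shipped analyses use 5,000 paths.

## Synthetic data

The generator draws per-pair (incremental effectiveness, incremental
cost) from a bivariate normal and aggregates to blocks. Defaults
target the application's published moments: mean incremental cost
£1,808 with zero mean effect (so mean INB = −£1,808 at λ = £20,000),
and per-pair SDs back-derived from the printed 95% CIs (cost £1,126–
£2,389, QALYs −0.13–0.11, over 125 pairs), giving a per-pair INB SD of
about £14,156 at zero effect–cost correlation. The correlation is the
emulator's key free parameter: none is published, and 0 is the
default. The generator reproduces the distributional structure the
model assumes (i.i.d. normal pairs, exact block aggregation); it does
not emulate missing data, loss to follow-up, treatment crossovers,
calendar-time accrual or the drift visible in real cumulative paths —
passing tests show the pipeline is correct under the model's own
assumptions, not that the model describes any particular real trial.

## Parameter defaults and provenance

| parameter | default | units | why |
|---|---|---|---|
| λ | 20,000 | GBP/QALY | NHS convention used by the application |
| c | 4,080 | GBP/pair | 50:50 fixed/variable split of the £1.02M recruitment+follow-up spend over 125 pairs |
| c_fixed | 161,000 | GBP | pre-recruitment spend; sunk, reporting only |
| I | 0 | GBP | adoption by sign of the posterior mean |
| Qmax | 250 | pairs | double the realised sample size; 125 also shipped |
| τ | 47 | pairs | one year of follow-up at ~47 pairs/year |
| μ0, n0 | 0, 2 | GBP, pairs | near non-informative prior |
| block size | 10 | pairs | published interim cadence |
| σ_X | 14,156 | GBP | CI-derived estimate (see above), flagged as such |
| P | 5,000 | patients | order-of-magnitude estimate of the population covered by the adoption decision (a few thousand displaced proximal humeral fractures facing the surgery-vs-sling choice per year in the UK, over a short adoption horizon) |

σ_X and P deserve emphasis: the application's own values are not in
the public text, so both are configuration inputs with estimated
defaults. The printed CIs are 2-year quantities while the −£1,808 mean
is a 1-year figure; which horizon sets σ_X is not stated, so the
generator and config expose both knobs. The shipped (σ_X, P) pair
yields a qualitatively faithful design — the sequential design is
optimal at the prior mean, stopping is driven by lower-boundary
crossings and recommends the standard technology — but a wider
boundary and later stopping than the published analysis, whose
narrower boundary implies a smaller σ_X and/or smaller P. We chose not
to reverse-engineer the pair from the published stopping time: the
region reproducing it exactly is narrow, and fitting two unknowns to
one printed point would manufacture agreement the data do not support.
Supplying the original values through `RunConfig` reproduces the
published geometry directly.

## Numerical and scope notes

- Currency is floating GBP throughout; no integer-pence arithmetic.
- Nonzero switching cost I is carried in the types as an extension
  point but not exercised; it would break the sign-rule symmetry.
- Unknown sampling variance (normal-gamma updating), continuous-time
  free-boundary solutions, discounting and multi-arm extensions are out
  of scope.
- Problem sizes: boundary recursion 204 × 1001 grid (≈0.2 s); 5,000
  bootstrap/Monte Carlo paths (≈1–2 s each); the whole test suite runs
  in well under a minute.
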