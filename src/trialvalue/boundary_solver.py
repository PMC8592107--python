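"""Optimal-stopping boundary for the value-based sequential trial.

The design problem: pairs of patients are allocated sequentially; each
observed pair yields an incremental net monetary benefit draw
X ~ Normal(W, sigma_x**2) with conjugate-normal beliefs about W.
Outcomes lag allocations by ``tau`` pairs, so when recruitment stops
after observing ``n`` pairs a further ``p = min(tau, q_max - n)`` pipeline
pairs are still to be followed up.  After follow-up, the better
technology is adopted by the sign of the terminal posterior mean
(switching cost 0) and the reward P * max(W-decision value) accrues to
the P post-trial patients.

Continuing recruitment costs ``c`` per pair and buys one more
observation.  Backward induction over the observed count n gives the
value function V(n, mu) on a grid of posterior means and, from the
region where continuation strictly beats stopping, the stopping
boundary of the sequential design (Stage II).  A one-stage alternative
(pick a fixed sample size below the delay, maximising expected value of
sample information net of sampling cost) and the no-trial options are
compared with the sequential value to classify the optimal design as a
function of the prior mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trial_model import Beliefs, EconomicParams

__all__ = [
    "MuGrid",
    "StoppingBoundary",
    "DesignChoice",
    "GridTooNarrowError",
    "expected_positive_part",
    "preposterior_sd",
    "stop_value",
    "solve_boundary",
    "one_stage_design",
    "classify_prior",
]


class GridTooNarrowError(ValueError):
    """The stopping boundary approaches the edge of the mu grid."""


@dataclass(frozen=True)
class MuGrid:
    """Uniform grid of posterior-mean values (GBP) for the recursion."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 5:
            raise ValueError("grid must be a 1-D array of at least 5 values")
        d = np.diff(v)
        if not np.all(d > 0):
            raise ValueError("grid values must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError("grid must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    @classmethod
    def default(
        cls,
        prior: Beliefs,
        n_points: int = 1001,
        halfwidth_sds: float = 6.0,
    ) -> "MuGrid":
        """Grid centred on the prior mean spanning +-halfwidth_sds prior SDs.

        The prior SD sigma_x/sqrt(n0) bounds the spread of any reachable
        posterior mean (the prior-predictive SD of the terminal posterior
        mean is below it), so six of them comfortably cover the state
        space.
        """
        half = halfwidth_sds * prior.sigma_x / math.sqrt(prior.m)
        return cls(np.linspace(prior.mu - half, prior.mu + half, n_points))


@dataclass
class StoppingBoundary:
    """Per-observed-count continuation limits of the sequential design.

    Entry ``n`` covers observed counts 0..q_max-tau.  ``lower``/``upper``
    are NaN where the continuation region is empty (recruitment cannot
    usefully continue).  ``allocations`` counts pairs allocated when
    stopping at that point (observed plus pipeline) and
    ``plot_coordinate`` additionally offsets by the prior effective
    sample size n0, the convention used when drawing the boundary
    against an effective-sample-size axis.
    """

    n_observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    allocations: np.ndarray
    plot_coordinate: np.ndarray
    params: EconomicParams
    prior: Beliefs
    grid: MuGrid | None = None
    value: np.ndarray | None = None  # V(n, mu) on the grid, shape (N+1, G)
    field_order = ("n_observed", "allocations", "plot_coordinate", "lower_gbp", "upper_gbp")

    def continuation_interval(self, n: int) -> tuple[float, float] | None:
        """(lower, upper) continuation interval at observed count n, or None."""
        lo, hi = self.lower[n], self.upper[n]
        if math.isnan(lo) or math.isnan(hi):
            return None
        return float(lo), float(hi)

    def is_inside(self, n: int, mu: float) -> bool:
        """True if mu lies in the (closed) continuation region at n."""
        iv = self.continuation_interval(n)
        return iv is not None and iv[0] <= mu <= iv[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_observed": self.n_observed,
                "allocations": self.allocations,
                "plot_coordinate": self.plot_coordinate,
                "lower_gbp": self.lower,
                "upper_gbp": self.upper,
            }
        )

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path, params: EconomicParams, prior: Beliefs) -> "StoppingBoundary":
        df = pd.read_csv(path, comment="#", na_values=["NA"])
        return cls(
            n_observed=df["n_observed"].to_numpy(int),
            lower=df["lower_gbp"].to_numpy(float),
            upper=df["upper_gbp"].to_numpy(float),
            allocations=df["allocations"].to_numpy(int),
            plot_coordinate=df["plot_coordinate"].to_numpy(float),
            params=params,
            prior=prior,
        )


@dataclass(frozen=True)
class DesignChoice:
    """Optimal design as a function of the prior mean.

    ``thresholds_abcd`` are the four prior-mean cutpoints, ordered
    B <= C <= D <= A on the prior-mean axis: above A adopt the new
    technology with no trial; below B adopt the standard with no trial;
    in (C, D) run the sequential trial; in the flanking bands run the
    one-stage design.
    """

    label: str  # adopt_new_no_trial | adopt_std_no_trial | one_stage | sequential
    value: float
    one_stage_n: int | None
    thresholds_abcd: tuple[float, float, float, float]  # (A, B, C, D)

    def __post_init__(self) -> None:
        a, b, c, d = self.thresholds_abcd
        if not (b <= c <= d <= a):
            raise ValueError("thresholds must satisfy B <= C <= D <= A")


def expected_positive_part(mu: float, s: float):
    """E[max(Z, 0)] for Z ~ Normal(mu, s^2); max(mu, 0) when s = 0.

    The standard normal partial expectation mu*Phi(mu/s) + s*phi(mu/s),
    used to value the terminal adopt-by-sign decision before the
    remaining uncertainty resolves.  Vectorised in ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    if s < 0:
        raise ValueError("s must be >= 0")
    if s == 0:
        out = np.maximum(mu, 0.0)
    else:
        z = mu / s
        out = mu * norm.cdf(z) + s * norm.pdf(z)
    return float(out) if out.ndim == 0 else out


def preposterior_sd(m: float, k: float, sigma_x: float) -> float:
    """SD of the posterior-mean movement after k further observations.

    Starting from effective pair count m, the future posterior mean is
    distributed Normal(mu, s^2) with s = sigma_x*sqrt(1/m - 1/(m+k)):
    the uncertainty that the next k pairs will resolve.
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 0.0
    return sigma_x * math.sqrt(1.0 / m - 1.0 / (m + k))


def stop_value(n_observed: int, mu, params: EconomicParams, prior: Beliefs):
    """Expected terminal reward of stopping recruitment at observed count n.

    The p = min(tau, q_max - n) pipeline pairs still deliver outcomes, so
    the terminal posterior mean is Normal(mu, s^2) with
    s = preposterior_sd(n0 + n, p, sigma_x); adopting by its sign is worth
    P * E[max(terminal mean, 0)].  Vectorised in ``mu``.
    """
    if not 0 <= n_observed <= params.q_max:
        raise ValueError("n_observed out of range")
    p = min(params.delay_tau, params.q_max - n_observed)
    s = preposterior_sd(prior.m + n_observed, p, prior.sigma_x)
    return params.pop_to_benefit * expected_positive_part(mu, s)


def _gauss_hermite(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(Z)], Z ~ N(0,1), by Gauss-Hermite quadrature."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def solve_boundary(
    params: EconomicParams,
    prior: Beliefs,
    grid: MuGrid | None = None,
    quadrature_nodes: int = 21,
    quadrature: tuple[np.ndarray, np.ndarray] | None = None,
    edge_margin: float = 0.05,
) -> StoppingBoundary:
    """Backward induction for the Stage II stopping boundary.

    At the last possible observation count N = q_max - tau the trial must
    stop: V(N, mu) = stop_value.  For n < N,

        C(n, mu) = -c + E[ V(n+1, mu + v*Z) ],  v = preposterior_sd(n0+n, 1, sigma_x)
        V(n, mu) = max(stop_value(n, mu), C(n, mu))

    with Z standard normal (Gauss-Hermite quadrature, linear
    interpolation of V on the grid; values beyond the grid clamp to the
    edge, which is benign while the boundary stays well inside it).  The
    continuation region at n is the mu interval where C strictly exceeds
    the stopping value; ties stop.  Boundary edges are refined by linear
    interpolation of C - stop between grid points.

    Parameters
    ----------
    quadrature : optional (nodes, weights) for a custom standard-normal
        discretisation (e.g. a two-point rule for cross-checks against
        exhaustive policy search).
    edge_margin : raise :class:`GridTooNarrowError` if the boundary comes
        within this fraction of the grid span of either edge.
    """
    if grid is None:
        grid = MuGrid.default(prior)
    mu = grid.values
    n_max = params.n_looks_max
    if quadrature is None:
        z_nodes, z_weights = _gauss_hermite(quadrature_nodes)
    else:
        z_nodes = np.asarray(quadrature[0], dtype=float)
        z_weights = np.asarray(quadrature[1], dtype=float)
        if abs(z_weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")

    value = np.empty((n_max + 1, mu.size))
    lower = np.full(n_max + 1, np.nan)
    upper = np.full(n_max + 1, np.nan)

    value[n_max] = stop_value(n_max, mu, params, prior)
    for n in range(n_max - 1, -1, -1):
        m = prior.m + n
        v = preposterior_sd(m, 1, prior.sigma_x)
        shifted = mu[:, None] + v * z_nodes[None, :]
        cont = -params.var_cost_c + np.interp(shifted, mu, value[n + 1]) @ z_weights
        stop = stop_value(n, mu, params, prior)
        value[n] = np.maximum(stop, cont)
        gain = cont - stop
        inside = gain > 0.0
        if inside.any():
            if inside[0] or inside[-1]:
                raise GridTooNarrowError(
                    "continuation region touches the grid edge; widen the mu grid"
                )
            idx = np.nonzero(inside)[0]
            i0, i1 = idx[0], idx[-1]
            if idx.size != i1 - i0 + 1:
                # numerical ties can fragment the set; take the hull
                i0, i1 = idx[0], idx[-1]
            # refine the zero of gain between the bracketing grid points
            lower[n] = mu[i0 - 1] + grid.spacing * (
                -gain[i0 - 1] / (gain[i0] - gain[i0 - 1])
            )
            upper[n] = mu[i1] + grid.spacing * (
                gain[i1] / (gain[i1] - gain[i1 + 1])
            )

    finite = np.concatenate([lower[np.isfinite(lower)], upper[np.isfinite(upper)]])
    if finite.size:
        span = mu[-1] - mu[0]
        if finite.min() < mu[0] + edge_margin * span or finite.max() > mu[-1] - edge_margin * span:
            raise GridTooNarrowError(
                "stopping boundary within the edge margin of the mu grid; widen the grid"
            )

    n_observed = np.arange(n_max + 1)
    pipeline = np.minimum(params.delay_tau, params.q_max - n_observed)
    allocations = n_observed + pipeline
    return StoppingBoundary(
        n_observed=n_observed,
        lower=lower,
        upper=upper,
        allocations=allocations,
        plot_coordinate=prior.m + allocations,
        params=params,
        prior=prior,
        grid=grid,
        value=value,
    )


def one_stage_design(params: EconomicParams, prior: Beliefs) -> tuple[int, float]:
    """Best fixed sample size below the delay: maximise EVSI minus cost.

    With a fixed design of n < tau pairs there is no interim information
    (all outcomes arrive after the last allocation), so the design simply
    maximises P * E[max(posterior mean after n, 0)] - c*n over
    n in {1, .., tau-1}; n = 0 is the no-trial value P*max(mu0, 0).
    Returns (n_star, value at n_star) over n >= 1; compare with the
    no-trial value separately.
    """
    no_trial = params.pop_to_benefit * max(prior.mu, 0.0)
    n_best, v_best = _best_fixed_design(params, prior)
    if n_best > 0 and v_best > no_trial:
        return n_best, v_best
    return 0, no_trial


def _best_fixed_design(params: EconomicParams, prior: Beliefs) -> tuple[int, float]:
    """Best strictly-positive fixed sample size n in {1..tau-1} and its value."""
    if params.delay_tau < 1:
        raise ValueError("one-stage design requires delay_tau >= 1")
    if params.delay_tau == 1:
        return 0, -math.inf
    n = np.arange(1, params.delay_tau)
    s = prior.sigma_x * np.sqrt(1.0 / prior.m - 1.0 / (prior.m + n))
    z = prior.mu / s
    vals = (
        params.pop_to_benefit * (prior.mu * norm.cdf(z) + s * norm.pdf(z))
        - params.var_cost_c * n
    )
    k = int(np.argmax(vals))
    return int(n[k]), float(vals[k])


def _design_values(
    mu0: float,
    params: EconomicParams,
    prior: Beliefs,
    boundary: StoppingBoundary,
) -> tuple[float, float, float, int]:
    """(no-trial, strict one-stage, sequential) values at prior mean mu0.

    The one-stage value here is the best over n >= 1 (it may fall below
    the no-trial value); the comparison with n = 0 happens in the
    classification itself, so the thresholds where running any trial
    stops paying are well defined.
    """
    pr = Beliefs(mu=mu0, m=prior.m, sigma_x=prior.sigma_x)
    no_trial = params.pop_to_benefit * max(mu0, 0.0)
    n1, v1 = _best_fixed_design(params, pr)
    # Stage I allocates tau pairs before any outcome arrives; their
    # variable cost is committed up front.  V(0, .) nets all later costs.
    seq = -params.var_cost_c * params.delay_tau + float(
        np.interp(mu0, boundary.grid.values, boundary.value[0])
    )
    return no_trial, v1, seq, n1


def classify_prior(
    params: EconomicParams,
    prior: Beliefs,
    boundary: StoppingBoundary,
) -> DesignChoice:
    """Pick the optimal design at the prior mean and locate thresholds A-D.

    Compares the no-trial value, the best one-stage value and the
    sequential value at ``prior.mu``, then finds the four prior-mean
    cutpoints by bisection on the pairwise value differences: A/B where
    running any trial stops paying (positive/negative side), D/C where
    the sequential and one-stage values cross.
    """
    if boundary.value is None or boundary.grid is None:
        raise ValueError("classify_prior needs a boundary with its value table (solve_boundary output)")

    def values(mu0: float) -> tuple[float, float, float, int]:
        return _design_values(mu0, params, prior, boundary)

    no_trial, v1, seq, n1 = values(prior.mu)
    options = {
        "sequential": seq,
        "one_stage": v1,
        ("adopt_new_no_trial" if prior.mu > 0 else "adopt_std_no_trial"): no_trial,
    }
    label = max(options, key=lambda k: options[k])

    grid = boundary.grid.values
    lo, hi = grid[0], grid[-1]

    def bisect(f: Callable[[float], float], a: float, b: float, iters: int = 80) -> float:
        fa, fb = f(a), f(b)
        if fa == 0.0:
            return a
        if fb == 0.0:
            return b
        if fa * fb > 0:
            # no crossing in [a, b]; report the endpoint nearer the sign change
            return b if abs(fb) < abs(fa) else a
        for _ in range(iters):
            mid = 0.5 * (a + b)
            fm = f(mid)
            if fm == 0.0:
                return mid
            if fa * fm < 0:
                b, fb = mid, fm
            else:
                a, fa = mid, fm
        return 0.5 * (a + b)

    def trial_minus_none(mu0: float) -> float:
        nt, v_one, v_seq, _ = values(mu0)
        return max(v_one, v_seq) - nt

    def seq_minus_one(mu0: float) -> float:
        _, v_one, v_seq, _ = values(mu0)
        return v_seq - v_one

    centre = 0.5 * (lo + hi)
    a_thr = bisect(trial_minus_none, centre, hi)
    b_thr = bisect(trial_minus_none, lo, centre)
    d_thr = bisect(seq_minus_one, centre, a_thr)
    c_thr = bisect(seq_minus_one, b_thr, centre)
    b_thr = min(b_thr, c_thr)
    d_thr = min(d_thr, a_thr)
    c_thr = min(c_thr, d_thr)

    return DesignChoice(
        label=label,
        value=options[label],
        one_stage_n=n1 if label == "one_stage" else None,
        thresholds_abcd=(a_thr, b_thr, c_thr, d_thr),
    )
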