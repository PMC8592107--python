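"""Replay of an outcome stream against a stopping boundary.

Stage II: after each block of observed outcomes the posterior mean is
compared with the continuation interval at the current observed count;
the trial stops at the first interim at which the posterior mean lies
outside it (or when the maximum observable count q_max - tau is
reached).  Stage III: the pipeline pairs already allocated but not yet
followed up are observed, the posterior is updated once more, and the
technology is adopted by the sign of the final posterior mean.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

from .boundary_solver import StoppingBoundary
from .trial_model import Beliefs, BlockSummary, EconomicParams, blocks_to_observations, update_posterior

__all__ = ["PathResult", "BudgetImpact", "run_path", "budget_change"]

PROFHER_REFERENCE_PAIRS = 125
PROFHER_TOTAL_BUDGET = 1_470_000.0


@dataclass(frozen=True)
class BudgetImpact:
    """Budget consequences of a realised sample size versus a reference."""

    gbp: float
    pct_of_budget: float
    pct_sample_size: float


@dataclass(frozen=True)
class PathResult:
    """One replayed or simulated trial path."""

    stop_look: int | str           # 1-based interim index, or "reached_max"
    n_observed_at_stop: int        # observed pairs when recruitment stopped
    allocations_t: int             # observed + pipeline pairs (T)
    mu_at_stop: float              # posterior mean at the stopping interim
    mu_final: float                # posterior mean after pipeline follow-up
    decision: str                  # "new" (surgery) or "std" (sling)
    crossing: str                  # "lower", "upper" or "reached_max"
    variable_cost: float           # c * allocations_t
    budget_change: float
    budget_change_pct: float

    def to_dict(self) -> dict:
        return asdict(self)


def budget_change(
    allocations_t: int,
    params: EconomicParams,
    reference_pairs: int = PROFHER_REFERENCE_PAIRS,
    total_budget: float = PROFHER_TOTAL_BUDGET,
) -> BudgetImpact:
    """Change in spend and sample size versus a reference fixed design.

    GBP change is (allocations - reference) times the variable cost per
    pair; the budget percentage expresses it against the total research
    budget, and the sample-size percentage against the reference pairs.
    """
    if reference_pairs <= 0:
        raise ValueError("reference_pairs must be > 0")
    if total_budget <= 0:
        raise ValueError("total_budget must be > 0")
    diff = allocations_t - reference_pairs
    gbp = diff * params.var_cost_c
    return BudgetImpact(
        gbp=gbp,
        pct_of_budget=gbp / total_budget * 100.0,
        pct_sample_size=diff / reference_pairs * 100.0,
    )


class _PairStream:
    """Consume (value, multiplicity) observations pair by pair."""

    def __init__(self, observations: Sequence[tuple[float, int]]):
        self._obs = list(observations)
        self._i = 0
        self._left = self._obs[0][1] if self._obs else 0

    def take(self, n_pairs: int) -> list[tuple[float, int]]:
        """Next n_pairs pairs as (value, multiplicity) chunks."""
        out: list[tuple[float, int]] = []
        need = n_pairs
        while need > 0:
            if self._i >= len(self._obs):
                raise ValueError(
                    f"outcome stream exhausted: {need} more pairs required"
                )
            take = min(need, self._left)
            out.append((self._obs[self._i][0], take))
            self._left -= take
            need -= take
            if self._left == 0:
                self._i += 1
                if self._i < len(self._obs):
                    self._left = self._obs[self._i][1]
        return out


def _interim_schedule(params: EconomicParams) -> list[int]:
    """Observed counts at which interim analyses occur.

    Every block_size observed pairs, plus a final forced look at
    q_max - tau when that is not a multiple of the block size
    (recruitment cannot exceed q_max).
    """
    n_max = params.n_looks_max
    looks = list(range(params.block_size, n_max + 1, params.block_size))
    if not looks or looks[-1] != n_max:
        looks.append(n_max)
    return looks


def run_path(
    blocks: Sequence[BlockSummary] | Sequence[tuple[float, int]],
    boundary: StoppingBoundary,
    params: EconomicParams,
    prior: Beliefs,
    reference_pairs: int = PROFHER_REFERENCE_PAIRS,
    total_budget: float = PROFHER_TOTAL_BUDGET,
) -> PathResult:
    """Replay one outcome stream against a solved stopping boundary.

    ``blocks`` is an ordered stream of :class:`BlockSummary` (or already
    flattened (per-pair INB value, multiplicity) tuples) supplying at
    least q_max pairs.  Stopping is strict: the interim stops the trial
    only if the posterior mean lies strictly outside [lower, upper]; an
    empty continuation interval always stops.
    """
    if boundary.params.q_max != params.q_max or boundary.params.delay_tau != params.delay_tau:
        raise ValueError("boundary was solved for different q_max/delay_tau than params")
    if boundary.prior.m != prior.m or boundary.prior.sigma_x != prior.sigma_x:
        raise ValueError("boundary was solved for a different prior")

    if blocks and isinstance(blocks[0], BlockSummary):
        observations = blocks_to_observations(blocks, params.wtp_lambda)  # type: ignore[arg-type]
    else:
        observations = [(float(v), int(w)) for v, w in blocks]  # type: ignore[misc]
    total_pairs = sum(w for _, w in observations)
    if total_pairs < params.q_max:
        raise ValueError(
            f"stream supplies {total_pairs} pairs but q_max={params.q_max} are required"
        )

    stream = _PairStream(observations)
    beliefs = prior
    n_observed = 0
    stop_look: int | str = "reached_max"
    crossing = "reached_max"

    for look_idx, look_n in enumerate(_interim_schedule(params), start=1):
        beliefs = update_posterior(beliefs, stream.take(look_n - n_observed))
        n_observed = look_n
        interval = boundary.continuation_interval(look_n)
        if interval is None:
            if look_n == params.n_looks_max:
                stop_look, crossing = "reached_max", "reached_max"
            else:
                # continuation empty before the horizon: forced stop; label
                # the side by the sign of the posterior mean
                stop_look = look_idx
                crossing = "lower" if beliefs.mu <= 0 else "upper"
            break
        lo, hi = interval
        if beliefs.mu < lo:
            stop_look, crossing = look_idx, "lower"
            break
        if beliefs.mu > hi:
            stop_look, crossing = look_idx, "upper"
            break
    else:  # pragma: no cover - schedule always ends at n_looks_max
        stop_look, crossing = "reached_max", "reached_max"

    mu_at_stop = beliefs.mu
    pipeline = min(params.delay_tau, params.q_max - n_observed)
    beliefs = update_posterior(beliefs, stream.take(pipeline))
    mu_final = beliefs.mu
    allocations_t = n_observed + pipeline
    decision = "new" if mu_final > 0 else "std"
    impact = budget_change(allocations_t, params, reference_pairs, total_budget)

    return PathResult(
        stop_look=stop_look,
        n_observed_at_stop=n_observed,
        allocations_t=allocations_t,
        mu_at_stop=mu_at_stop,
        mu_final=mu_final,
        decision=decision,
        crossing=crossing,
        variable_cost=params.var_cost_c * allocations_t,
        budget_change=impact.gbp,
        budget_change_pct=impact.pct_of_budget,
    )
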