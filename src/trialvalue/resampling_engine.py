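"""Bootstrap and Monte Carlo operating characteristics.

Many trial paths are generated — by resampling observed blocks with
replacement, or by drawing fresh per-pair outcomes from a normal
distribution — and each is replayed against the stopping boundary.  The
aggregates mirror the operating characteristics a trials unit would
report for a design: distribution of the realised sample size, budget
impact, terminal posterior mean, and the probabilities of each
decision-by-crossing outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .boundary_solver import StoppingBoundary
from .monitoring_engine import (
    PROFHER_REFERENCE_PAIRS,
    PROFHER_TOTAL_BUDGET,
    PathResult,
    budget_change,
    run_path,
)
from .trial_model import Beliefs, BlockSummary, EconomicParams, block_inb, update_posterior

__all__ = [
    "OperatingCharacteristics",
    "bootstrap_paths",
    "monte_carlo_paths",
    "fixed_design_paths",
    "summarize",
]

DECISIONS = ("std", "new")
CROSSINGS = ("lower", "upper", "reached_max")


@dataclass
class OperatingCharacteristics:
    """Aggregates over many replayed/simulated paths.

    ``decision_crossing`` is a decision x crossing probability table
    (rows std/new, columns lower/upper/reached_max) summing to 1;
    ``look_fractions`` maps the 1-based interim index (or
    "reached_max") to the fraction of paths stopping there.  SDs use the
    n-1 (sample) denominator.
    """

    paths: list[PathResult]
    allocations: dict
    budget: dict
    mu_final: dict
    decision_crossing: pd.DataFrame
    look_fractions: dict
    reference_pairs: int = PROFHER_REFERENCE_PAIRS
    total_budget: float = PROFHER_TOTAL_BUDGET

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    def prob_decision(self, decision: str) -> float:
        return float(self.decision_crossing.loc[decision].sum())

    def prob_crossing(self, crossing: str) -> float:
        return float(self.decision_crossing[crossing].sum())

    def allocations_ecdf(self) -> pd.DataFrame:
        """Empirical CDF of the realised sample size (pairwise allocations)."""
        a = np.sort([p.allocations_t for p in self.paths])
        return pd.DataFrame(
            {"allocations": a, "ecdf": np.arange(1, a.size + 1) / a.size}
        )

    def to_table_frame(self) -> pd.DataFrame:
        """Summary table: one row per statistic, mirroring a design report."""
        rows = []
        for name, agg in (
            ("sample_size_pairs", self.allocations),
            ("budget_change_gbp", self.budget),
            ("posterior_mean_final_gbp", self.mu_final),
        ):
            rows.append(
                {
                    "statistic": name,
                    "mean": agg["mean"],
                    "pct_change": agg.get("pct_change"),
                    "sd": agg["sd"],
                    "min": agg["min"],
                    "max": agg["max"],
                }
            )
        for d in DECISIONS:
            for c in CROSSINGS:
                rows.append(
                    {
                        "statistic": f"prob_{d}_{c}",
                        "mean": float(self.decision_crossing.loc[d, c]),
                        "pct_change": None,
                        "sd": None,
                        "min": None,
                        "max": None,
                    }
                )
        return pd.DataFrame(rows)

    def paths_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_dict() for p in self.paths])


def _agg(values: np.ndarray, pct_change_ref: float | None = None) -> dict:
    out = {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }
    if pct_change_ref:
        out["pct_change"] = (out["mean"] - pct_change_ref) / pct_change_ref * 100.0
    return out


def summarize(
    paths: Sequence[PathResult],
    params: EconomicParams,
    reference_pairs: int = PROFHER_REFERENCE_PAIRS,
    total_budget: float = PROFHER_TOTAL_BUDGET,
) -> OperatingCharacteristics:
    """Aggregate per-path results into operating characteristics."""
    if not paths:
        raise ValueError("no paths to summarise")
    alloc = np.array([p.allocations_t for p in paths], dtype=float)
    mu_fin = np.array([p.mu_final for p in paths], dtype=float)
    budg = np.array([p.budget_change for p in paths], dtype=float)

    alloc_agg = _agg(alloc, pct_change_ref=reference_pairs)
    budget_agg = _agg(budg)
    # budget percentage follows the sample-size change priced at c per pair,
    # against the total research budget
    budget_agg["pct_change"] = budget_change(
        alloc_agg["mean"], params, reference_pairs, total_budget
    ).pct_of_budget
    mu_agg = _agg(mu_fin)

    table = pd.DataFrame(0.0, index=list(DECISIONS), columns=list(CROSSINGS))
    looks: dict = {}
    for p in paths:
        table.loc[p.decision, p.crossing] += 1.0
        looks[p.stop_look] = looks.get(p.stop_look, 0) + 1
    table /= len(paths)
    look_fractions = {
        k: v / len(paths)
        for k, v in sorted(looks.items(), key=lambda kv: (isinstance(kv[0], str), kv[0]))
    }

    return OperatingCharacteristics(
        paths=list(paths),
        allocations=alloc_agg,
        budget=budget_agg,
        mu_final=mu_agg,
        decision_crossing=table,
        look_fractions=look_fractions,
        reference_pairs=reference_pairs,
        total_budget=total_budget,
    )


def _resample_stream(
    rng: np.random.Generator,
    block_values: np.ndarray,
    block_sizes: np.ndarray,
    needed_pairs: int,
) -> list[tuple[float, int]]:
    """Draw blocks i.i.d. with replacement until needed_pairs are available."""
    out: list[tuple[float, int]] = []
    total = 0
    while total < needed_pairs:
        i = int(rng.integers(0, block_values.size))
        out.append((float(block_values[i]), int(block_sizes[i])))
        total += int(block_sizes[i])
    return out


def bootstrap_paths(
    block_table: Sequence[BlockSummary],
    n_paths: int,
    boundary: StoppingBoundary,
    params: EconomicParams,
    prior: Beliefs,
    seed: int,
    reference_pairs: int = PROFHER_REFERENCE_PAIRS,
    total_budget: float = PROFHER_TOTAL_BUDGET,
) -> OperatingCharacteristics:
    """Nonparametric bootstrap of the sequential design.

    Each path draws whole blocks i.i.d. with replacement from the block
    table until q_max pairs are available, then replays them against the
    boundary.  The resampling unit is the block, matching the available
    block-level summaries.
    """
    if not block_table:
        raise ValueError("block table is empty")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.array([block_inb(b, params.wtp_lambda) for b in block_table])
    sizes = np.array([b.n_pairs for b in block_table], dtype=int)
    paths = []
    for _ in range(n_paths):
        stream = _resample_stream(rng, values, sizes, params.q_max)
        paths.append(run_path(stream, boundary, params, prior, reference_pairs, total_budget))
    return summarize(paths, params, reference_pairs, total_budget)


def monte_carlo_paths(
    true_mean: float,
    sigma_x: float,
    n_paths: int,
    boundary: StoppingBoundary,
    params: EconomicParams,
    prior: Beliefs,
    seed: int,
    reference_pairs: int = PROFHER_REFERENCE_PAIRS,
    total_budget: float = PROFHER_TOTAL_BUDGET,
) -> OperatingCharacteristics:
    """Parametric simulation of the sequential design.

    Per-pair incremental net monetary benefits are drawn
    Normal(true_mean, sigma_x**2) and aggregated into blocks of
    ``params.block_size`` so the interim schedule matches the bootstrap
    exactly.
    """
    if sigma_x <= 0:
        raise ValueError("sigma_x must be > 0")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    bs = params.block_size
    n_blocks = math.ceil(params.q_max / bs)
    paths = []
    for _ in range(n_paths):
        draws = rng.normal(true_mean, sigma_x, size=n_blocks * bs)
        stream = [
            (float(draws[i * bs : (i + 1) * bs].mean()), bs) for i in range(n_blocks)
        ]
        paths.append(run_path(stream, boundary, params, prior, reference_pairs, total_budget))
    return summarize(paths, params, reference_pairs, total_budget)


def fixed_design_paths(
    source: Sequence[BlockSummary] | tuple[float, float],
    n_paths: int,
    params: EconomicParams,
    prior: Beliefs,
    seed: int,
    reference_pairs: int = PROFHER_REFERENCE_PAIRS,
    total_budget: float = PROFHER_TOTAL_BUDGET,
) -> OperatingCharacteristics:
    """Fixed-sample-size comparator: every path runs to q_max pairs.

    ``source`` is either a block table (bootstrap resampling) or a
    (true_mean, sigma_x) tuple (Monte Carlo).  There is no interim
    stopping; the decision is taken by the sign of the posterior mean
    after all q_max pairs are observed.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(seed)
    parametric = isinstance(source, tuple)
    if not parametric:
        if not source:
            raise ValueError("block table is empty")
        values = np.array([block_inb(b, params.wtp_lambda) for b in source])
        sizes = np.array([b.n_pairs for b in source], dtype=int)
    paths = []
    for _ in range(n_paths):
        if parametric:
            true_mean, sigma_x = source  # type: ignore[misc]
            draws = rng.normal(true_mean, sigma_x, size=params.q_max)
            stream = [(float(v), 1) for v in draws]
        else:
            stream = _resample_stream(rng, values, sizes, params.q_max)
        # consume exactly q_max pairs
        beliefs = prior
        taken = 0
        obs = []
        for v, w in stream:
            take = min(w, params.q_max - taken)
            obs.append((v, take))
            taken += take
            if taken == params.q_max:
                break
        beliefs = update_posterior(beliefs, obs)
        impact = budget_change(params.q_max, params, reference_pairs, total_budget)
        paths.append(
            PathResult(
                stop_look="reached_max",
                n_observed_at_stop=params.q_max,
                allocations_t=params.q_max,
                mu_at_stop=beliefs.mu,
                mu_final=beliefs.mu,
                decision="new" if beliefs.mu > 0 else "std",
                crossing="reached_max",
                variable_cost=params.var_cost_c * params.q_max,
                budget_change=impact.gbp,
                budget_change_pct=impact.pct_of_budget,
            )
        )
    return summarize(paths, params, reference_pairs, total_budget)
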