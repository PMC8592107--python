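"""Core domain types and conjugate-normal Bayesian updating.

The sampling unit throughout is the *pairwise allocation*: one patient
randomised to the new technology (N) and one to the standard (S).  The
outcome of interest for pair ``j`` is the incremental net monetary benefit

    X_j = lambda * (E_N,j - E_S,j) - (C_N,j - C_S,j)

where ``E`` is effectiveness (QALYs), ``C`` is treatment cost (GBP) and
``lambda`` is the willingness to pay per QALY.  X is modelled as normal
with unknown mean W and *known* sampling SD ``sigma_x``; beliefs about W
are conjugate normal, parameterised here by the posterior mean ``mu`` and
the effective pair count ``m`` (prior effective sample size n0 plus pairs
observed), so that Var(W) = sigma_x**2 / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "EconomicParams",
    "Beliefs",
    "PairOutcome",
    "BlockSummary",
    "incremental_net_benefit",
    "block_inb",
    "update_posterior",
    "effective_sample_size",
    "variable_cost_per_pair",
    "read_block_table",
    "write_block_table",
    "blocks_to_observations",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class EconomicParams:
    """Design constants of the value-based sequential trial.

    Attributes
    ----------
    wtp_lambda : float
        Willingness to pay for one unit of effectiveness (GBP/QALY).
    pop_to_benefit : float
        Number of post-trial patients P to whom the adoption decision
        applies.
    var_cost_c : float
        Variable research cost per pairwise allocation (GBP).
    fixed_cost : float
        Fixed research cost (GBP); sunk at the design stage and carried
        for reporting only.
    switch_cost_i : float
        Cost of switching technologies at adoption (GBP).  All shipped
        analyses use 0, under which the terminal rule is simply the sign
        of the posterior mean.
    q_max : int
        Maximum number of pairwise allocations.
    delay_tau : int
        Outcome delay expressed in pairwise allocations: the number of
        pairs in the pipeline when recruitment stops.
    delay_delta_years : float
        The same delay in years (informational only).
    block_size : int
        Pairwise allocations between interim analyses.
    """

    wtp_lambda: float
    pop_to_benefit: float
    var_cost_c: float
    fixed_cost: float = 0.0
    switch_cost_i: float = 0.0
    q_max: int = 250
    delay_tau: int = 47
    delay_delta_years: float = 1.0
    block_size: int = 10

    def __post_init__(self) -> None:
        if self.wtp_lambda < 0:
            raise ValueError("wtp_lambda must be >= 0")
        if self.pop_to_benefit <= 0:
            raise ValueError("pop_to_benefit must be > 0")
        if self.var_cost_c < 0:
            raise ValueError("var_cost_c must be >= 0")
        if not (self.q_max > self.delay_tau >= 0):
            raise ValueError("require q_max > delay_tau >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    @property
    def n_looks_max(self) -> int:
        """Number of possible observed pairs in Stage II: q_max - delay_tau."""
        return self.q_max - self.delay_tau


@dataclass(frozen=True)
class Beliefs:
    """Conjugate-normal state of knowledge about the expected INB W.

    ``mu`` is the prior/posterior mean (GBP); ``m`` the effective pair
    count (n0 + pairs observed); ``sigma_x`` the known per-pair sampling
    SD (GBP).  The posterior variance of W is ``sigma_x**2 / m``.
    """

    mu: float
    m: float
    sigma_x: float

    def __post_init__(self) -> None:
        _require_finite("mu", self.mu)
        if self.m <= 0:
            raise ValueError("effective pair count m must be > 0")
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be > 0")

    @property
    def sd(self) -> float:
        """Posterior SD of W: sigma_x / sqrt(m)."""
        return self.sigma_x / math.sqrt(self.m)


@dataclass(frozen=True)
class PairOutcome:
    """Arm-level outcomes for one pairwise allocation."""

    eff_new: float
    eff_std: float
    cost_new: float
    cost_std: float

    def __post_init__(self) -> None:
        for name in ("eff_new", "eff_std", "cost_new", "cost_std"):
            _require_finite(name, getattr(self, name))


@dataclass(frozen=True)
class BlockSummary:
    """Per-block (typically 10 pairs) summary of incremental outcomes.

    ``mean_inc_eff`` and ``mean_inc_cost`` are the block means of
    (E_N - E_S) and (C_N - C_S) per pair.  A block that only records a
    mean incremental net monetary benefit ``b`` is represented exactly as
    mean_inc_eff = 0, mean_inc_cost = -b, which maps back to ``b`` under
    any willingness to pay.
    """

    block_index: int
    n_pairs: int
    mean_inc_eff: float
    mean_inc_cost: float

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        _require_finite("mean_inc_eff", self.mean_inc_eff)
        _require_finite("mean_inc_cost", self.mean_inc_cost)

    @classmethod
    def from_mean_inb(cls, block_index: int, n_pairs: int, mean_inb: float) -> "BlockSummary":
        return cls(block_index, n_pairs, 0.0, -float(mean_inb))


def incremental_net_benefit(pair: PairOutcome, wtp_lambda: float) -> float:
    """Incremental net monetary benefit of one pair:
    lambda*(E_N - E_S) - (C_N - C_S).  Positive favours the new technology."""
    lam = _require_finite("wtp_lambda", wtp_lambda)
    return lam * (pair.eff_new - pair.eff_std) - (pair.cost_new - pair.cost_std)


def block_inb(block: BlockSummary, wtp_lambda: float) -> float:
    """Mean incremental net monetary benefit of a block of pairs."""
    lam = _require_finite("wtp_lambda", wtp_lambda)
    return lam * block.mean_inc_eff - block.mean_inc_cost


def update_posterior(
    beliefs: Beliefs,
    observations: Iterable[float] | Iterable[tuple[float, float]],
) -> Beliefs:
    """Update conjugate-normal beliefs with per-pair INB observations.

    ``observations`` is either a sequence of per-pair values, or of
    ``(value, multiplicity)`` pairs where a block mean counts with
    multiplicity n_pairs.  With known sigma_x the posterior mean depends
    on the data only through the weighted sum, so a block mean with its
    multiplicity is exactly equivalent to the individual pairs:

        mu' = (mu*m + sum_j w_j x_j) / (m + sum_j w_j),   m' = m + sum_j w_j
    """
    total_w = 0.0
    total_wx = 0.0
    for obs in observations:
        if isinstance(obs, tuple):
            x, w = obs
        else:
            x, w = obs, 1.0
        x = _require_finite("observation", x)
        if w < 0:
            raise ValueError("observation multiplicity must be >= 0")
        total_w += w
        total_wx += w * x
    if total_w == 0.0:
        return beliefs
    new_m = beliefs.m + total_w
    new_mu = (beliefs.mu * beliefs.m + total_wx) / new_m
    return replace(beliefs, mu=new_mu, m=new_m)


def effective_sample_size(sigma_x: float, sigma_0: float) -> float:
    """Prior effective sample size n0 = sigma_x**2 / sigma_0**2 (pairs).

    A wider prior SD sigma_0 means a less informative prior: n0 -> 0 as
    sigma_0 -> infinity.
    """
    if sigma_0 <= 0:
        raise ValueError("sigma_0 must be > 0 (an infinitely informative prior is unsupported)")
    if sigma_x <= 0:
        raise ValueError("sigma_x must be > 0")
    return (sigma_x / sigma_0) ** 2


def variable_cost_per_pair(
    recruitment_followup_spend: float,
    n_pairs: int,
    variable_share: float = 0.5,
) -> float:
    """Average variable research cost c per pairwise allocation.

    The recruitment-and-follow-up spend is split between fixed and
    variable costs (default 50:50) and the variable part divided by the
    number of pairwise allocations made.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    if not 0.0 <= variable_share <= 1.0:
        raise ValueError("variable_share must lie in [0, 1]")
    return recruitment_followup_spend * variable_share / n_pairs


# ---------------------------------------------------------------------------
# Block-table I/O
# ---------------------------------------------------------------------------

_FULL_COLS = ["block_index", "n_pairs", "mean_inc_eff", "mean_inc_cost"]
_INB_COLS = ["block_index", "n_pairs", "mean_inb"]


def read_block_table(path) -> list[BlockSummary]:
    """Read a block-summary CSV.

    Accepts either columns block_index, n_pairs, mean_inc_eff,
    mean_inc_cost, or the single-outcome alternative block_index,
    n_pairs, mean_inb.  Lines starting with '#' are ignored.
    """
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if set(_FULL_COLS) <= cols:
        rows = [
            BlockSummary(int(r.block_index), int(r.n_pairs),
                         float(r.mean_inc_eff), float(r.mean_inc_cost))
            for r in df.itertuples()
        ]
    elif set(_INB_COLS) <= cols:
        rows = [
            BlockSummary.from_mean_inb(int(r.block_index), int(r.n_pairs), float(r.mean_inb))
            for r in df.itertuples()
        ]
    else:
        raise ValueError(
            f"block table must have columns {_FULL_COLS} or {_INB_COLS}; got {sorted(cols)}"
        )
    rows.sort(key=lambda b: b.block_index)
    return rows


def write_block_table(blocks: Sequence[BlockSummary], path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "block_index": [b.block_index for b in blocks],
            "n_pairs": [b.n_pairs for b in blocks],
            "mean_inc_eff": [b.mean_inc_eff for b in blocks],
            "mean_inc_cost": [b.mean_inc_cost for b in blocks],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def blocks_to_observations(
    blocks: Sequence[BlockSummary], wtp_lambda: float
) -> list[tuple[float, int]]:
    """Flatten a block stream to (per-pair INB value, multiplicity) tuples."""
    return [(block_inb(b, wtp_lambda), int(b.n_pairs)) for b in blocks]
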