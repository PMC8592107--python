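"""ProFHER-like synthetic trial data.

The real application compared surgical fixation with sling
immobilisation for displaced proximal humeral fracture: surgery cost
about £1,758 more per patient (95% CI £1,126 to £2,389) and yielded
about 0.0101 fewer QALYs (95% CI -0.13 to 0.11), so at £20,000/QALY the
mean incremental net monetary benefit per pair is roughly -£1,808 (the
1-year figure used by the resampling analyses).  This module draws
per-pair (incremental effectiveness, incremental cost) outcomes from a
bivariate normal with those moments and aggregates them into blocks, so
every downstream stage is testable without the original trial data.

Per-pair variability is back-derived from the printed confidence
intervals of the trial-level estimates: a 95% CI of width w on a mean
over n pairs implies SE = w/3.92 and per-pair SD = SE * sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trial_model import BlockSummary, PairOutcome

__all__ = [
    "GeneratorSpec",
    "derive_pair_sd",
    "generate_pairs",
    "generate_blocks",
    "PROFHER_CI_COST",
    "PROFHER_CI_EFF",
    "profher_like_spec",
]

# Printed 2-year trial-level estimates (per patient, surgery minus sling)
PROFHER_CI_COST = (1126.0, 2389.0)
PROFHER_CI_EFF = (-0.13, 0.11)
PROFHER_N_PAIRS = 125
PROFHER_MEAN_INB = -1808.0  # 1-year mean incremental net monetary benefit

_CI95_WIDTH_SDS = 3.92  # 2 * 1.96


@dataclass(frozen=True)
class GeneratorSpec:
    """Moments and shape of the synthetic outcome stream.

    Defaults emulate the application's resampling input: mean per-pair
    incremental net monetary benefit of -£1,808 (realised as a pure cost
    difference), with per-pair SDs back-derived from the printed CIs and
    zero effect-cost correlation (the key free parameter of the
    emulator; no correlation is reported).
    """

    mean_inc_eff: float = 0.0
    mean_inc_cost: float = -PROFHER_MEAN_INB
    sd_inc_eff: float = (PROFHER_CI_EFF[1] - PROFHER_CI_EFF[0]) / _CI95_WIDTH_SDS * math.sqrt(PROFHER_N_PAIRS)
    sd_inc_cost: float = (PROFHER_CI_COST[1] - PROFHER_CI_COST[0]) / _CI95_WIDTH_SDS * math.sqrt(PROFHER_N_PAIRS)
    eff_cost_correlation: float = 0.0
    n_pairs: int = 250
    block_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_inc_eff < 0 or self.sd_inc_cost < 0:
            raise ValueError("SDs must be >= 0")
        if not -1.0 <= self.eff_cost_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.n_pairs < 1 or self.block_size < 1:
            raise ValueError("n_pairs and block_size must be >= 1")

    def mean_inb(self, wtp_lambda: float) -> float:
        return wtp_lambda * self.mean_inc_eff - self.mean_inc_cost

    def pair_inb_sd(self, wtp_lambda: float) -> float:
        """Per-pair SD of incremental net monetary benefit implied by the spec."""
        le = wtp_lambda * self.sd_inc_eff
        return math.sqrt(
            le**2 + self.sd_inc_cost**2 - 2.0 * self.eff_cost_correlation * le * self.sd_inc_cost
        )


def derive_pair_sd(
    ci_cost: tuple[float, float],
    ci_eff: tuple[float, float],
    n_pairs: int,
    wtp_lambda: float,
    correlation: float = 0.0,
) -> float:
    """Per-pair SD of incremental net monetary benefit from printed 95% CIs.

    The CI widths give the standard errors of the trial-level mean
    incremental cost and effectiveness (width / 3.92); combining them on
    the net-benefit scale and scaling by sqrt(n_pairs) recovers the
    per-pair SD:

        sqrt((lambda*SE_eff)**2 + SE_cost**2
             - 2*rho*lambda*SE_eff*SE_cost) * sqrt(n_pairs)

    This is an estimate, used as the default sampling SD when the
    application's own value is not supplied.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    if ci_cost[1] < ci_cost[0] or ci_eff[1] < ci_eff[0]:
        raise ValueError("confidence intervals must be ordered (low, high)")
    se_cost = (ci_cost[1] - ci_cost[0]) / _CI95_WIDTH_SDS
    se_eff = (ci_eff[1] - ci_eff[0]) / _CI95_WIDTH_SDS
    le = wtp_lambda * se_eff
    var = le**2 + se_cost**2 - 2.0 * correlation * le * se_cost
    return math.sqrt(max(var, 0.0)) * math.sqrt(n_pairs)


# Arbitrary standard-arm baselines; only increments matter downstream.
_BASELINE_EFF = 1.0
_BASELINE_COST = 5000.0


def generate_pairs(spec: GeneratorSpec) -> list[PairOutcome]:
    """Draw per-pair outcomes from the bivariate-normal increment model.

    The standard arm is held at a fixed baseline and the new arm at
    baseline plus the drawn increment, so the pair's incremental values
    equal the draws exactly.
    """
    rng = np.random.default_rng(spec.seed)
    cov = spec.eff_cost_correlation * spec.sd_inc_eff * spec.sd_inc_cost
    sigma = np.array(
        [[spec.sd_inc_eff**2, cov], [cov, spec.sd_inc_cost**2]]
    )
    draws = rng.multivariate_normal(
        [spec.mean_inc_eff, spec.mean_inc_cost], sigma, size=spec.n_pairs,
        method="cholesky" if np.linalg.matrix_rank(sigma) == 2 else "svd",
    )
    return [
        PairOutcome(
            eff_new=_BASELINE_EFF + float(de),
            eff_std=_BASELINE_EFF,
            cost_new=_BASELINE_COST + float(dc),
            cost_std=_BASELINE_COST,
        )
        for de, dc in draws
    ]


def generate_blocks(
    spec: GeneratorSpec, return_pairs: bool = False
) -> list[BlockSummary] | tuple[list[BlockSummary], list[PairOutcome]]:
    """Aggregate generated pairs into ordered block summaries.

    The final block may be shorter when n_pairs is not a multiple of
    block_size.
    """
    pairs = generate_pairs(spec)
    blocks: list[BlockSummary] = []
    for i in range(0, spec.n_pairs, spec.block_size):
        chunk = pairs[i : i + spec.block_size]
        blocks.append(
            BlockSummary(
                block_index=len(blocks) + 1,
                n_pairs=len(chunk),
                mean_inc_eff=float(np.mean([p.eff_new - p.eff_std for p in chunk])),
                mean_inc_cost=float(np.mean([p.cost_new - p.cost_std for p in chunk])),
            )
        )
    if return_pairs:
        return blocks, pairs
    return blocks


def profher_like_spec(seed: int = 0, n_pairs: int = 250, block_size: int = 10) -> GeneratorSpec:
    """Default emulation of the application's resampling input."""
    return GeneratorSpec(seed=seed, n_pairs=n_pairs, block_size=block_size)
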