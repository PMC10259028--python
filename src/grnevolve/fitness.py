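"""Fitness of a developmental trajectory.

Four criteria are scored on the expression matrix and combined into one
value in [0, 1]:

* **boundedness** — gene quantities must not grow exponentially.  Measured
  as a penalty on the terminal growth ratio g = (total quantity at the
  final step) / (total quantity one stability window earlier): 1 for
  g <= 1, decreasing linearly to 0 at g = 1 + growth_cap.  A trajectory
  that overflowed double precision scores 0.
* **participation** — the more genes expressed, the fitter: the fraction
  of genes expressed at any point of development.
* **stability** — late expression should settle: 1 / (1 + mean coefficient
  of variation of each expressed gene's quantities over the final window).
* **maturity** — a hard gate: a designated marker gene (by default the
  last gene) must exceed a quantity threshold at some step and still be
  expressed at the final step; otherwise total fitness is 0.

The total is the product of the four components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .development import ExpressionMatrix

__all__ = [
    "FitnessConfig",
    "FitnessBreakdown",
    "score_boundedness",
    "score_participation",
    "score_stability",
    "score_maturity",
    "total_fitness",
    "evaluate_fitness",
]

_EPS = 1e-12


@dataclass(frozen=True)
class FitnessConfig:
    """Knobs of the four fitness criteria.

    ``marker_gene``: index of the maturity marker (None = last gene).
    ``maturity_threshold``: quantity the marker must exceed (arbitrary
    units, same scale as the seed quantity).
    ``stability_window``: number of final developmental steps over which
    stability and terminal growth are measured (None = m // 5, at least 1).
    ``growth_cap``: how much terminal growth beyond ratio 1 drives the
    boundedness score to 0.
    """

    marker_gene: int | None = None
    maturity_threshold: float = 1.0
    stability_window: int | None = None
    growth_cap: float = 1.0

    def __post_init__(self):
        if self.maturity_threshold <= 0:
            raise ValueError("maturity_threshold must be positive")
        if self.growth_cap <= 0:
            raise ValueError("growth_cap must be positive")

    def resolve_window(self, m: int) -> int:
        w = self.stability_window if self.stability_window is not None else m // 5
        return max(1, min(w, m - 1)) if m > 1 else 1

    def resolve_marker(self, n: int) -> int:
        g = self.marker_gene if self.marker_gene is not None else n - 1
        if not 0 <= g < n:
            raise ValueError(f"marker gene {g} out of range for {n} genes")
        return g


@dataclass(frozen=True)
class FitnessBreakdown:
    boundedness: float
    participation: float
    stability: float
    maturity: int
    total: float


def score_boundedness(E: ExpressionMatrix, cfg: FitnessConfig | None = None) -> float:
    cfg = cfg or FitnessConfig()
    if not E.is_finite():
        return 0.0
    m = E.n_steps
    if m == 1:
        return 1.0
    w = cfg.resolve_window(m)
    tot_end = float(E.values[:, -1].sum())
    tot_prev = float(E.values[:, m - 1 - w].sum())
    g = tot_end / (tot_prev + _EPS)
    if g <= 1.0:
        return 1.0
    return max(0.0, 1.0 - (g - 1.0) / cfg.growth_cap)


def score_participation(E: ExpressionMatrix) -> float:
    return float(E.expressed_mask().mean())


def score_stability(E: ExpressionMatrix, cfg: FitnessConfig | None = None) -> float:
    cfg = cfg or FitnessConfig()
    if not E.is_finite():
        return 0.0
    w = cfg.resolve_window(E.n_steps)
    expressed = E.expressed_mask()
    if not expressed.any():
        return 1.0
    window = E.values[expressed, E.n_steps - w :]
    cv = window.std(axis=1) / (window.mean(axis=1) + _EPS)
    return float(1.0 / (1.0 + cv.mean()))


def score_maturity(E: ExpressionMatrix, cfg: FitnessConfig | None = None) -> int:
    cfg = cfg or FitnessConfig()
    g = cfg.resolve_marker(E.n_genes)
    row = E.values[g]
    with np.errstate(invalid="ignore"):
        passed = bool((row > cfg.maturity_threshold).any())
        final_on = bool(row[-1] > 0)
    return 1 if passed and final_on else 0


def total_fitness(breakdown: FitnessBreakdown) -> float:
    """Product of the four components; maturity acts as a hard gate."""
    return (
        breakdown.maturity
        * breakdown.boundedness
        * breakdown.participation
        * breakdown.stability
    )


def evaluate_fitness(E: ExpressionMatrix, cfg: FitnessConfig | None = None) -> FitnessBreakdown:
    """Score all four criteria and their product on one expression matrix."""
    cfg = cfg or FitnessConfig()
    b = score_boundedness(E, cfg)
    p = score_participation(E)
    s = score_stability(E, cfg)
    mt = score_maturity(E, cfg)
    bd = FitnessBreakdown(b, p, s, mt, 0.0)
    return FitnessBreakdown(b, p, s, mt, total_fitness(bd))
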