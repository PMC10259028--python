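"""Regulatory genotype and the sequence-to-regulation mutation coupling.

The regulatory genotype of an n-gene system is an n x n interaction matrix
R (R[i, j] = effect of gene j's product on gene i), a per-gene activation
threshold vector theta, and a per-gene exponential decay rate vector lam.
R is initialised uniformly on a user range spanning repression (negative)
and activation (positive), with a Bernoulli sparseness mask zeroing a
user-defined expected proportion of cells; theta and lam are uniform on
nonnegative ranges.

Every synonymous or nonsynonymous sequence mutation in gene g triggers
exactly one regulatory mutation among gene g's 2+n candidate values: its
n incoming links (row g of R), theta_g, and lam_g.  With probability
2/(2+n) the mutation hits theta_g or lam_g (equiprobably); otherwise it
hits one incoming link, chosen uniformly among links whose source gene is
expressed in the parental expression matrix for a nonsynonymous mutation,
or among links with an unexpressed source for a synonymous one (silent
"under the hood" rewiring).  Nonsense mutations change no regulatory
parameter: their phenotypic effect flows entirely through the coding mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .development import ExpressionMatrix

__all__ = [
    "RegulatoryParams",
    "RegInitConfig",
    "RegulatoryTarget",
    "init_regulatory",
    "active_link_set",
    "apply_regulatory_mutation",
    "nonsense_effect",
]


@dataclass(frozen=True)
class RegInitConfig:
    """Initialisation ranges and mutation kernel for regulatory parameters.

    ``value_range`` should span negative (repression) and positive
    (activation) values; ``sparseness`` is the expected proportion of R
    cells masked to zero at initialisation.  ``mutation_kernel`` is either
    ``"resample"`` (redraw the hit parameter from its init range; default)
    or ``"gaussian"`` (additive perturbation of scale ``gaussian_sigma``,
    with theta/lam clipped at 0).  ``exact_sparseness`` masks an exact
    count of cells instead of i.i.d. Bernoulli draws.
    """

    value_range: tuple[float, float] = (-2.0, 2.0)
    sparseness: float = 0.25
    theta_range: tuple[float, float] = (0.0, 1.0)
    lam_range: tuple[float, float] = (0.0, 2.0)
    mutation_kernel: str = "resample"
    gaussian_sigma: float = 0.1
    exact_sparseness: bool = False

    def __post_init__(self):
        if not 0.0 <= self.sparseness <= 1.0:
            raise ValueError(f"sparseness must be in [0, 1], got {self.sparseness}")
        for name in ("value_range", "theta_range", "lam_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is not well-ordered: ({lo}, {hi})")
        for name in ("theta_range", "lam_range"):
            if getattr(self, name)[0] < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mutation_kernel not in ("resample", "gaussian"):
            raise ValueError(f"unknown mutation kernel {self.mutation_kernel!r}")


@dataclass
class RegulatoryParams:
    """Interaction matrix R (n x n), thresholds theta (n,), decay rates lam (n,)."""

    R: np.ndarray
    theta: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        n = self.R.shape[0]
        if self.R.shape != (n, n):
            raise ValueError("R must be square")
        if self.theta.shape != (n,) or self.lam.shape != (n,):
            raise ValueError("theta and lam must be length-n vectors")
        if (self.theta < 0).any() or (self.lam < 0).any():
            raise ValueError("theta and lam must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.R.shape[0]

    def copy(self) -> "RegulatoryParams":
        return RegulatoryParams(self.R.copy(), self.theta.copy(), self.lam.copy())


class RegulatoryTarget(NamedTuple):
    """Identifies the single scalar changed by one regulatory mutation."""

    kind: str  # "R" | "theta" | "lam"
    gene: int
    source: int  # source-gene column for kind == "R", else -1


def init_regulatory(
    n: int, cfg: RegInitConfig, rng: np.random.Generator
) -> RegulatoryParams:
    """Sample a fresh regulatory genotype for an n-gene system."""
    R = rng.uniform(*cfg.value_range, size=(n, n))
    if cfg.exact_sparseness:
        k = int(round(cfg.sparseness * n * n))
        flat = rng.choice(n * n, size=k, replace=False)
        mask = np.zeros(n * n, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(n, n)
    else:
        mask = rng.random((n, n)) < cfg.sparseness
    R[mask] = 0.0
    theta = rng.uniform(*cfg.theta_range, size=n)
    lam = rng.uniform(*cfg.lam_range, size=n)
    return RegulatoryParams(R, theta, lam)


def active_link_set(E: "ExpressionMatrix") -> set[tuple[int, int]]:
    """All (target, source) links whose source gene is expressed in E."""
    expressed = E.expressed_mask()
    n = E.n_genes
    return {(i, j) for j in np.flatnonzero(expressed) for i in range(n)}


def _resample(old: float, lo: float, hi: float, cfg: RegInitConfig, rng) -> float:
    if cfg.mutation_kernel == "resample":
        return float(rng.uniform(lo, hi))
    return float(max(lo if lo >= 0 else -np.inf, old + rng.normal(0.0, cfg.gaussian_sigma)))


def _hit_theta_or_lam(
    params: RegulatoryParams, g: int, cfg: RegInitConfig, rng
) -> RegulatoryTarget:
    if rng.random() < 0.5:
        params.theta[g] = _resample(params.theta[g], *cfg.theta_range, cfg, rng)
        return RegulatoryTarget("theta", g, -1)
    params.lam[g] = _resample(params.lam[g], *cfg.lam_range, cfg, rng)
    return RegulatoryTarget("lam", g, -1)


def apply_regulatory_mutation(
    params: RegulatoryParams,
    gene_index: int,
    classification: str,
    E_parent: "ExpressionMatrix",
    cfg: RegInitConfig,
    rng: np.random.Generator,
) -> tuple[RegulatoryParams, RegulatoryTarget]:
    """Apply one regulatory mutation for a sequence event in ``gene_index``.

    Pure: returns a new parameter set (the input is unmodified) together
    with a record of the single scalar that changed.  With probability
    2/(2+n) the hit lands on theta_g or lam_g; otherwise on one incoming
    link of gene g, uniformly among active-source links (nonsynonymous) or
    inactive-source links (synonymous).  If the eligible link class is
    empty, the mutation is redirected to theta_g or lam_g so that the 1-1
    sequence/regulation coupling is preserved.
    """
    from .genome import NONSYNONYMOUS, SYNONYMOUS

    if classification not in (SYNONYMOUS, NONSYNONYMOUS):
        raise ValueError(
            f"regulatory mutations apply only to synonymous/nonsynonymous events, "
            f"got {classification!r}"
        )
    g = gene_index
    n = params.n_genes
    if not 0 <= g < n:
        raise ValueError(f"gene index {g} out of range for {n} genes")
    new = params.copy()
    if rng.random() < 2.0 / (2.0 + n):
        return new, _hit_theta_or_lam(new, g, cfg, rng)
    expressed = E_parent.expressed_mask()
    eligible = np.flatnonzero(expressed if classification == NONSYNONYMOUS else ~expressed)
    if eligible.size == 0:
        return new, _hit_theta_or_lam(new, g, cfg, rng)
    j = int(eligible[rng.integers(eligible.size)])
    new.R[g, j] = _resample(new.R[g, j], *cfg.value_range, cfg, rng)
    return new, RegulatoryTarget("R", g, j)


def nonsense_effect(params: RegulatoryParams) -> RegulatoryParams:
    """A nonsense event leaves every regulatory parameter untouched.

    The gene's silencing is carried by the coding mask during development;
    its regulatory parameters stay in place and become functional again if
    a later mutation reverts the stop codon.
    """
    return params
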