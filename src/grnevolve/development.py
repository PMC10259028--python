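"""Discrete-time development: from regulatory genotype to expression phenotype.

Development iterates, for a user-defined number of steps m,

    q_t = (ReLU_theta(R . q_{t-1}) + q_{t-1} * exp(-lambda)) * c

where q_t holds the per-gene product quantities (arbitrary units),
ReLU_theta zeroes any input signal strictly below a gene's activation
threshold, exp(-lambda) is per-step exponential decay, and c is the coding
mask that zeroes genes whose sequence carries an in-frame stop codon.
The chain is seeded with quantity 1 for the first gene and 0 elsewhere;
the seed is injected before the first application of c, which is why the
seed gene counts as expressed even when its own reading frame is broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidOrganismError
from .regulatory import RegulatoryParams

__all__ = ["ExpressionMatrix", "relu_theta", "develop", "is_expressed"]


@dataclass
class ExpressionMatrix:
    """Gene-quantity trajectory: ``values[i, t-1]`` = quantity of gene i at step t.

    ``q0`` is the seed vector injected at step 0 (kept alongside because
    expression of the seed gene is judged from it, not from the masked
    trajectory).
    """

    values: np.ndarray  # (n, m), nonnegative (or non-finite on runaway growth)
    q0: np.ndarray  # (n,)
    _finite: bool | None = field(default=None, repr=False, compare=False)
    _expressed: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def is_finite(self) -> bool:
        if self._finite is None:
            self._finite = bool(np.isfinite(self.values).all())
        return self._finite

    def expressed_mask(self) -> np.ndarray:
        """Boolean per-gene vector of :func:`is_expressed` (values are
        immutable by convention, so the mask is computed once)."""
        if self._expressed is None:
            with np.errstate(invalid="ignore"):
                self._expressed = (self.q0 > 0) | (self.values > 0).any(axis=1)
        return self._expressed

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.q0.copy(), self._finite, self._expressed
        )


def relu_theta(v: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Thresholded rectifier: values strictly below theta are zeroed.

    A value exactly at its threshold passes.
    """
    v = np.asarray(v, dtype=float)
    return np.where(v >= theta, v, 0.0)


def develop(
    c: np.ndarray,
    params: RegulatoryParams,
    m: int,
    seed_quantity: float = 1.0,
) -> ExpressionMatrix:
    """Run the development recursion for ``m`` steps and return E (n x m).

    ``c`` is the coding mask from the current genome.  Deterministic; a
    trajectory that leaves double precision (runaway growth) is carried as
    non-finite values and scored as unbounded by the fitness module rather
    than raising.
    """
    if m < 1:
        raise ValueError("need at least one developmental step")
    n = params.n_genes
    c = np.asarray(c, dtype=float)
    if c.shape != (n,):
        raise InvalidOrganismError(f"coding mask has shape {c.shape}, expected ({n},)")
    if not (
        np.isfinite(params.R).all()
        and np.isfinite(params.theta).all()
        and np.isfinite(params.lam).all()
    ):
        raise InvalidOrganismError("regulatory parameters must be finite")
    q0 = np.zeros(n)
    q0[0] = seed_quantity
    decay = np.exp(-params.lam)
    R, theta = params.R, params.theta
    E = np.empty((n, m))
    q = q0
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(m):
            s = R @ q
            s[s < theta] = 0.0
            q = (s + q * decay) * c
            E[:, t] = q
    return ExpressionMatrix(E, q0)


def is_expressed(E: ExpressionMatrix, i: int) -> bool:
    """True iff gene ``i`` has positive quantity at any step, or was seeded.

    The seed gene is always expressed: its quantity enters at step 0,
    before the coding mask applies, so it kick-starts development even with
    a stop codon in its own sequence.
    """
    with np.errstate(invalid="ignore"):
        return bool(E.q0[i] > 0 or (E.values[i] > 0).any())
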