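"""Block-structured feasibility problems.

A :class:`BlockConstraint` bundles one anatomical structure's slice of the
dose-influence matrix with its dose bound, the direction of the bound, and
the optional percentage-violation parameters ``alpha`` (fraction of rows
allowed to violate) and ``beta`` (relative amount by which they may
violate).  A :class:`FeasibilityProblem` is an ordered collection of such
blocks plus the nonnegativity set for the beamlet intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .operators import LOWER, UPPER, spectral_norm_sq

__all__ = ["BlockConstraint", "FeasibilityProblem"]


def _as_matrix(A):
    if sp.issparse(A):
        return sp.csr_matrix(A)
    return np.atleast_2d(np.asarray(A, dtype=float))


@dataclass
class BlockConstraint:
    """One structure's block: matrix, bound, sense and PVC parameters.

    Parameters
    ----------
    A:
        The ``m x n`` block of the dose-influence matrix (dense or sparse).
    bound:
        Per-row base bound ``b`` (upper) or ``c`` (lower); a scalar is
        broadcast to all rows.
    sense:
        ``"upper"`` for avoidance-type bounds ``Ax <= b``; ``"lower"`` for
        target-type bounds ``Ax >= c``.
    alpha:
        Fraction of rows permitted to violate the base bound, or ``None``
        when the block carries no percentage-violation constraint.
    beta:
        Relative relaxation of the base bound for the violating rows; the
        hard (per-row) bound is ``(1 + beta) b`` resp. ``(1 - beta) c``.
    lam:
        Relaxation of the row projections, in ``(0, 2)``.
    gamma:
        Step size of the Landweber operator; ``None`` selects the default
        ``1 / ||A||^2`` at solve time.
    """

    A: object
    bound: np.ndarray
    sense: str = UPPER
    alpha: Optional[float] = None
    beta: float = 0.0
    lam: float = 1.0
    gamma: Optional[float] = None
    name: str = ""

    # lazily computed caches
    _norm_sq: Optional[float] = field(default=None, repr=False, compare=False)
    _row_norm_sq: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.A = _as_matrix(self.A)
        m = self.A.shape[0]
        bound = np.asarray(self.bound, dtype=float)
        if bound.ndim == 0:
            bound = np.full(m, float(bound))
        if bound.shape != (m,):
            raise ValueError(f"bound has shape {bound.shape}, expected ({m},)")
        self.bound = bound
        if m == 0:
            raise ValueError("empty block (m = 0) is invalid")
        if self.sense not in (UPPER, LOWER):
            raise ValueError(f"sense must be 'upper' or 'lower', got {self.sense!r}")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must lie in [0, 1), got {self.beta}")
        if not 0.0 < self.lam < 2.0:
            raise ValueError(f"lam must lie in (0, 2), got {self.lam}")

    # ------------------------------------------------------------------
    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def has_pvc(self) -> bool:
        return self.alpha is not None

    @property
    def effective_bound(self) -> np.ndarray:
        """Relaxed per-row bound ``(1 + beta) b`` resp. ``(1 - beta) c``."""
        if self.sense == UPPER:
            return (1.0 + self.beta) * self.bound
        return (1.0 - self.beta) * self.bound

    @property
    def budget(self) -> int:
        """Number of rows allowed beyond the base bound: ``floor(alpha m)``."""
        if self.alpha is None:
            return 0
        return int(np.floor(self.alpha * self.m))

    # ------------------------------------------------------------------
    def norm_sq(self) -> float:
        """``||A||^2``, computed once and cached."""
        if self._norm_sq is None:
            self._norm_sq = spectral_norm_sq(self.A)
        return self._norm_sq

    def row_norms_sq(self) -> np.ndarray:
        """Per-row squared Euclidean norms, cached."""
        if self._row_norm_sq is None:
            if sp.issparse(self.A):
                rn = np.asarray(self.A.multiply(self.A).sum(axis=1)).ravel()
            else:
                rn = np.einsum("ij,ij->i", self.A, self.A)
            self._row_norm_sq = rn
        return self._row_norm_sq

    def dose(self, x: np.ndarray) -> np.ndarray:
        d = self.A @ x
        return np.asarray(d).ravel()


@dataclass
class FeasibilityProblem:
    """Ordered blocks plus the nonnegative orthant for the intensities."""

    blocks: Sequence[BlockConstraint]
    nonneg: bool = True

    def __post_init__(self) -> None:
        self.blocks = list(self.blocks)
        if not self.blocks:
            raise ValueError("a feasibility problem needs at least one block")
        n = self.blocks[0].n
        for blk in self.blocks:
            if blk.n != n:
                raise ValueError(
                    f"inconsistent column counts across blocks: {blk.n} vs {n}"
                )

    @property
    def n(self) -> int:
        return self.blocks[0].n

    @property
    def p(self) -> int:
        """Number of blocks."""
        return len(self.blocks)

    def max_residual(self, x: np.ndarray, doses: Optional[Sequence] = None) -> float:
        """Largest violation of any relaxed row bound (0 when feasible).

        ``doses`` may carry precomputed per-block dose vectors.
        """
        worst = 0.0
        for k, blk in enumerate(self.blocks):
            d = doses[k] if doses is not None else blk.dose(x)
            eff = blk.effective_bound
            if blk.sense == UPPER:
                r = np.max(d - eff, initial=0.0)
            else:
                r = np.max(eff - d, initial=0.0)
            worst = max(worst, float(r))
        if self.nonneg:
            worst = max(worst, float(np.max(-x, initial=0.0)))
        return worst
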