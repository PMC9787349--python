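"""Elementary operators for CQ-type projection methods.

This module provides the three numerical kernels everything else is built
from: relaxed projections onto half-spaces, operator-norm estimation, and
the Landweber-type block operator

    V = Id - gamma * A^T (Id - T) A,

whose fixed points are exactly the preimages under ``A`` of the fixed
points of ``T``.  All spaces are finite-dimensional real coordinate spaces
with the standard dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp

__all__ = [
    "UPPER",
    "LOWER",
    "HalfspaceConstraint",
    "LandweberSpec",
    "project_halfspace",
    "spectral_norm_sq",
    "landweber_step",
]

UPPER = "upper"
LOWER = "lower"

#: Absolute tolerance used when *testing* feasibility of a constraint.
#: Projections land on hyperplanes only to rounding error, so membership
#: checks need a little slack; the projection formulae themselves use
#: strict comparisons and no epsilon.
FEASIBILITY_ATOL = 1e-9


class InvalidConstraintError(ValueError):
    """A constraint is degenerate (e.g. an all-zero coefficient vector)."""


class DegenerateOperatorError(ValueError):
    """An operator norm was requested for an all-zero matrix."""


@dataclass(frozen=True)
class HalfspaceConstraint:
    """A single relaxed half-space ``<a, x> <= (1+beta) b`` (or the lower
    mirror ``<a, x> >= (1-beta) c``).

    Parameters
    ----------
    coefficients:
        The row vector ``a`` (not all zero).
    bound:
        The base bound ``b`` (upper sense) or ``c`` (lower sense).
    sense:
        ``"upper"`` or ``"lower"``.
    beta:
        Percentage-violation relaxation in ``[0, 1)``; ``0`` means the
        bound is hard.
    """

    coefficients: np.ndarray
    bound: float
    sense: str = UPPER
    beta: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", a)
        if a.ndim != 1 or not np.any(a):
            raise InvalidConstraintError("coefficient vector must be nonzero 1-d")
        if self.sense not in (UPPER, LOWER):
            raise ValueError(f"sense must be 'upper' or 'lower', got {self.sense!r}")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must lie in [0, 1), got {self.beta}")

    @property
    def effective_bound(self) -> float:
        """The relaxed bound ``(1+beta) b`` resp. ``(1-beta) c``."""
        if self.sense == UPPER:
            return (1.0 + self.beta) * self.bound
        return (1.0 - self.beta) * self.bound

    def satisfied(self, x: np.ndarray, atol: float = FEASIBILITY_ATOL) -> bool:
        dot = float(self.coefficients @ x)
        if self.sense == UPPER:
            return dot <= self.effective_bound + atol
        return dot >= self.effective_bound - atol


def project_halfspace(
    x: np.ndarray, h: HalfspaceConstraint, lam: float = 1.0
) -> np.ndarray:
    """Relaxed projection of ``x`` onto the half-space ``h``.

    Points already inside the half-space are returned unchanged.  For a
    violating point the relaxed projection is

        x + lam * (effective_bound - <a, x>) / <a, a> * a,

    which for ``lam = 1`` is the metric projection onto the bounding
    hyperplane and for ``lam`` in ``(0, 2)`` a relaxed cutter.
    """
    if not 0.0 < lam < 2.0:
        raise ValueError(f"relaxation parameter must lie in (0, 2), got {lam}")
    x = np.asarray(x, dtype=float)
    a = h.coefficients
    if x.shape != a.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs coefficients {a.shape}")
    dot = float(a @ x)
    eff = h.effective_bound
    if h.sense == UPPER and dot <= eff:
        return x
    if h.sense == LOWER and dot >= eff:
        return x
    return x + (lam * (eff - dot) / float(a @ a)) * a


def spectral_norm_sq(A, *, tol: float = 1e-8, max_iter: int = 10_000) -> float:
    """Squared spectral norm ``||A||^2`` (largest eigenvalue of ``A^T A``).

    Uses power iteration on ``A^T A`` with a deterministic all-ones start
    vector, so repeated calls give identical results without any seed.
    Works for dense arrays and scipy sparse matrices alike.
    """
    if sp.issparse(A):
        nnz = A.count_nonzero()
    else:
        A = np.asarray(A, dtype=float)
        nnz = np.count_nonzero(A)
    if nnz == 0:
        raise DegenerateOperatorError("spectral norm of an all-zero matrix")

    n = A.shape[1]
    v = np.ones(n) / np.sqrt(n)
    est = 0.0
    for _ in range(max_iter):
        u = A.T @ (A @ v)
        if sp.issparse(u):  # pragma: no cover - sparse @ dense gives dense
            u = np.asarray(u).ravel()
        norm_u = float(np.linalg.norm(u))
        if norm_u == 0.0:
            # all-ones start happens to lie in the null space; restart from
            # a deterministic non-uniform direction
            v = np.arange(1.0, n + 1.0)
            v /= np.linalg.norm(v)
            continue
        new_est = float(v @ u)  # Rayleigh quotient of A^T A
        v = u / norm_u
        if abs(new_est - est) <= tol * max(new_est, 1e-300):
            return new_est
        est = new_est
    return est


@dataclass(frozen=True)
class LandweberSpec:
    """Step parameters for the Landweber-type operator.

    ``gamma`` must satisfy ``0 < gamma <= 1 / norm_sq``; the endpoint
    ``gamma = 1 / norm_sq`` is the classical Landweber step and the
    package default, while ``gamma = 1 / (2 norm_sq)`` keeps strictly to
    the open interval required by the convergence theory.
    """

    gamma: float
    norm_sq: float

    def __post_init__(self) -> None:
        if self.norm_sq <= 0.0:
            raise ValueError("norm_sq must be positive")
        if not 0.0 < self.gamma <= 1.0 / self.norm_sq:
            raise ValueError(
                f"gamma must lie in (0, 1/norm_sq] = (0, {1.0 / self.norm_sq:g}], "
                f"got {self.gamma}"
            )

    @classmethod
    def endpoint(cls, norm_sq: float) -> "LandweberSpec":
        """gamma at the interval endpoint ``1 / ||A||^2``."""
        return cls(gamma=1.0 / norm_sq, norm_sq=norm_sq)

    @classmethod
    def strict(cls, norm_sq: float) -> "LandweberSpec":
        """gamma at the interval midpoint ``1 / (2 ||A||^2)``, strictly
        inside the open interval the theory requires."""
        return cls(gamma=0.5 / norm_sq, norm_sq=norm_sq)


def landweber_step(
    x: np.ndarray,
    A_block,
    q_projector: Callable[[np.ndarray], np.ndarray],
    spec: LandweberSpec,
) -> np.ndarray:
    """One application of ``V = Id - gamma * A^T (Id - P_Q) A``.

    ``q_projector`` maps dose-space vectors (length = row count of
    ``A_block``) to dose-space vectors; typically it is a metric
    projection onto a closed set ``Q``.  If ``A x`` is already a fixed
    point of ``q_projector`` the input is returned exactly.
    """
    x = np.asarray(x, dtype=float)
    if A_block.shape[1] != x.shape[0]:
        raise ValueError(
            f"shape mismatch: A has {A_block.shape[1]} columns, x has length {x.shape[0]}"
        )
    Ax = A_block @ x
    if sp.issparse(Ax):  # pragma: no cover
        Ax = np.asarray(Ax).ravel()
    residual = Ax - q_projector(Ax)
    if not np.any(residual):
        return x
    return x - spec.gamma * (A_block.T @ residual)
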