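"""Percentage-violation constraints (PVCs) and their nonconvex projections.

A dose-volume constraint such as "at most 10% of the structure may receive
more than 20 units" is encoded as a sparsity bound on the vector of
exceedances: writing ``v = A x`` for the structure's dose vector, the
constraint is ``||(v - b)+||_0 <= alpha m``, i.e. the number of rows whose
dose exceeds the base bound ``b`` is capped by a budget ``floor(alpha m)``.
The feasible set is nonconvex, but a nearest point can be computed
explicitly: keep the largest exceedances (up to the budget) and clip the
remaining ones back to the bound.

This module implements the rectifier, the positive-entry count, the
projections onto the sparsity sets, and the translation of a prescription
(Dmax / Dmin / DV% rules per structure) into block constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .operators import LOWER, UPPER
from .problem import BlockConstraint, FeasibilityProblem

__all__ = [
    "PvcSpec",
    "Dvc",
    "StructureRule",
    "Prescription",
    "PrescriptionError",
    "positive_part",
    "count_positive",
    "project_sparsity_set",
    "project_dvc",
    "translate_lfp_pvc",
    "prescription_to_blocks",
]


class PrescriptionError(ValueError):
    """A prescription is internally inconsistent."""


# ----------------------------------------------------------------------
# elementary pieces

def positive_part(y: np.ndarray) -> np.ndarray:
    """Componentwise rectifier ``max(0, y_i)``."""
    return np.maximum(np.asarray(y, dtype=float), 0.0)


def count_positive(y: np.ndarray) -> int:
    """Number of strictly positive entries, ``||y+||_0``.

    The sign test is exact: no epsilon, boundary zeros never count.
    """
    return int(np.count_nonzero(np.asarray(y) > 0))


def project_sparsity_set(y: np.ndarray, budget: int) -> np.ndarray:
    """Nearest point to ``y`` with at most ``budget`` positive entries.

    If ``y`` already has at most ``budget`` positive entries it is
    returned unchanged (as a copy).  Otherwise the smallest positive
    components are replaced by zero until exactly ``budget`` remain;
    negative and zero components are never touched.  Among equal smallest
    positive values the lowest indices are zeroed first, which makes the
    (in general non-unique) projection deterministic.
    """
    if budget < 0:
        raise ValueError(f"budget must be nonnegative, got {budget}")
    y = np.asarray(y, dtype=float)
    k = count_positive(y)
    out = y.copy()
    if k <= budget:
        return out
    pos_idx = np.flatnonzero(y > 0)
    # ascending by value, ties broken by lowest index first
    order = np.lexsort((pos_idx, y[pos_idx]))
    out[pos_idx[order[: k - budget]]] = 0.0
    return out


@dataclass(frozen=True)
class PvcSpec:
    """Parameters of one block's percentage-violation constraint.

    ``alpha`` is the fraction of the block's ``m`` rows allowed beyond the
    base bound; the integer budget is ``floor(alpha m)``.  With
    ``literal_floor=True`` the removal count is ``floor(k - alpha m)``
    (``k`` = current number of exceedances) instead, which for fractional
    ``alpha m`` can leave ``ceil(alpha m)`` exceedances behind; the
    default guarantees the result actually lies in the constraint set.
    """

    alpha: float
    base_bound: np.ndarray
    sense: str = UPPER
    m: int = 0
    literal_floor: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.sense not in (UPPER, LOWER):
            raise ValueError(f"sense must be 'upper' or 'lower', got {self.sense!r}")
        b = np.asarray(self.base_bound, dtype=float)
        m = self.m if self.m else b.shape[0] if b.ndim else 0
        if m <= 0:
            raise ValueError("m must be a positive integer")
        if b.ndim == 0:
            b = np.full(m, float(b))
        if b.shape != (m,):
            raise ValueError(f"base_bound has shape {b.shape}, expected ({m},)")
        object.__setattr__(self, "base_bound", b)
        object.__setattr__(self, "m", m)

    @property
    def budget(self) -> int:
        return int(math.floor(self.alpha * self.m))


def project_dvc(v: np.ndarray, spec: PvcSpec) -> np.ndarray:
    """Projection of a dose vector onto the dose-volume constraint set.

    Upper sense: ``P_Qbar(v - b) + b``; lower sense: ``-P_Qbar(c - v) + c``,
    where ``P_Qbar`` is :func:`project_sparsity_set` with the block's
    budget.  The result violates the base bound in at most ``budget``
    components (default mode).
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (spec.m,):
        raise ValueError(f"dose vector has shape {v.shape}, expected ({spec.m},)")
    if spec.sense == UPPER:
        y = v - spec.base_bound
    else:
        y = spec.base_bound - v
    if spec.literal_floor:
        k = count_positive(y)
        if k <= spec.alpha * spec.m:
            z = y.copy()
        else:
            z = project_sparsity_set(y, k - math.floor(k - spec.alpha * spec.m))
    else:
        z = project_sparsity_set(y, spec.budget)
    if spec.sense == UPPER:
        return z + spec.base_bound
    return spec.base_bound - z


def pvc_spec_for(block: BlockConstraint, literal_floor: bool = False) -> Optional[PvcSpec]:
    """The block's :class:`PvcSpec`, or ``None`` if it carries no PVC."""
    if not block.has_pvc:
        return None
    return PvcSpec(
        alpha=block.alpha,
        base_bound=block.bound,
        sense=block.sense,
        m=block.m,
        literal_floor=literal_floor,
    )


# ----------------------------------------------------------------------
# problem translation

def translate_lfp_pvc(blocks: Sequence[BlockConstraint], nonneg: bool = True) -> FeasibilityProblem:
    """Assemble the translated block feasibility problem.

    Per block the relaxed half-space family ``<a_i, x> <= (1+beta) b_i``
    (resp. the lower mirror) is implied by the block's ``beta``; blocks
    with ``alpha`` set additionally carry the sparsity constraint on the
    exceedances of the base bound.  Blocks without a PVC revert to a plain
    system of bound constraints.  Parameter validation happens in the
    :class:`BlockConstraint` constructor; here we only collect and check
    cross-block consistency.
    """
    return FeasibilityProblem(blocks=list(blocks), nonneg=nonneg)


# ----------------------------------------------------------------------
# prescriptions

@dataclass(frozen=True)
class Dvc:
    """A DV% rule: for sense 'upper', ``D_V% <= dose`` (at most V% of the
    structure may exceed ``dose``); for 'lower', ``D_V% >= dose`` (at
    least V% must reach ``dose``)."""

    volume_percent: float
    dose: float
    sense: str = UPPER

    def __post_init__(self) -> None:
        if not 0.0 < self.volume_percent <= 100.0:
            raise ValueError("volume_percent must lie in (0, 100]")
        if self.sense not in (UPPER, LOWER):
            raise ValueError(f"sense must be 'upper' or 'lower', got {self.sense!r}")


@dataclass(frozen=True)
class StructureRule:
    """Dose rules for one structure: optional hard Dmax/Dmin bounds and
    dose-volume rules."""

    d_max: Optional[float] = None
    d_min: Optional[float] = None
    dvcs: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "dvcs", tuple(self.dvcs))
        for sense in (UPPER, LOWER):
            if sum(1 for d in self.dvcs if d.sense == sense) > 1:
                raise PrescriptionError(
                    f"at most one {sense} DV% rule per structure is supported"
                )


@dataclass(frozen=True)
class Prescription:
    """Ordered mapping from structure name to its dose rules."""

    structures: Mapping[str, StructureRule]

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", dict(self.structures))

    def n_hard_bounds(self) -> int:
        return sum(
            (r.d_max is not None) + (r.d_min is not None)
            for r in self.structures.values()
        )

    def n_dvcs(self) -> int:
        return sum(len(r.dvcs) for r in self.structures.values())


def _block_params(rule: StructureRule, sense: str, name: str):
    """Resolve (base bound, beta, alpha) for one (structure, sense) pair,
    or None when the structure has no rule of that sense."""
    hard = rule.d_max if sense == UPPER else rule.d_min
    dvc = next((d for d in rule.dvcs if d.sense == sense), None)
    if dvc is None:
        if hard is None:
            return None
        return float(hard), 0.0, None
    base = float(dvc.dose)
    if hard is None:
        beta = 0.0
    elif sense == UPPER:
        if base > hard:
            raise PrescriptionError(
                f"{name}: upper DV% dose {base} exceeds Dmax {hard}"
            )
        beta = hard / base - 1.0
    else:
        if base < hard:
            raise PrescriptionError(
                f"{name}: lower DV% dose {base} is below Dmin {hard}"
            )
        beta = 1.0 - hard / base
    alpha = dvc.volume_percent / 100.0 if sense == UPPER else 1.0 - dvc.volume_percent / 100.0
    return base, beta, alpha


def prescription_to_blocks(
    prescription: Prescription,
    matrices: Mapping[str, object],
    lam: float = 1.0,
    gamma: Optional[Mapping[str, float]] = None,
) -> list:
    """Translate a prescription into block constraints.

    Each (structure, sense) pair with a DV% rule becomes a block with base
    bound equal to the DV% dose, ``beta`` solved from
    ``(1 +/- beta) * dose = hard bound`` and ``alpha = V/100`` (upper) or
    ``1 - V/100`` (lower).  A structure with both a Dmin and a Dmax rule
    yields two blocks over the same rows (same matrix).  Hard-bound-only
    rules yield ``beta = 0`` and no PVC.  Lower (minimum-dose) blocks are
    emitted before upper ones within a structure.

    ``matrices`` maps structure name to its dose-influence block.
    """
    blocks = []
    for name, rule in prescription.structures.items():
        if name not in matrices:
            raise KeyError(f"no dose-influence block for structure {name!r}")
        A = matrices[name]
        for sense in (LOWER, UPPER):
            params = _block_params(rule, sense, name)
            if params is None:
                continue
            base, beta, alpha = params
            blocks.append(
                BlockConstraint(
                    A=A,
                    bound=base,
                    sense=sense,
                    alpha=alpha,
                    beta=beta,
                    lam=lam,
                    gamma=None if gamma is None else gamma.get(name),
                    name=f"{name}:{sense}",
                )
            )
    if not blocks:
        raise PrescriptionError("prescription contains no dose rules")
    return blocks
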