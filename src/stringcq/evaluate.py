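"""Plan evaluation: dose reconstruction, DVH curves and violation counts.

The cumulative dose-volume histogram (DVH) of a structure reports, for
each dose level ``d``, the percentage of the structure's voxels receiving
at least ``d``.  The quantity ``D_V%`` is the dose received by V% of the
structure; here it is computed as an exact order statistic (the
``ceil(V m / 100)``-th largest dose), which agrees with the counting form
of the percentage-violation constraints.  Interpolated DVH curves are a
display matter only and are never used for satisfaction tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .operators import LOWER, UPPER
from .problem import BlockConstraint, FeasibilityProblem

__all__ = [
    "DvhCurve",
    "ViolationReport",
    "structure_dose",
    "compute_dvh",
    "dose_at_volume",
    "count_violations",
    "default_thresholds",
]

#: Absolute slack on dose comparisons when counting violations: row
#: projections satisfy their bounds only to rounding error.
VIOLATION_ATOL = 1e-9

CATEGORIES = ("hdc_min", "hdc_max", "dvc_lower", "dvc_upper")


def structure_dose(x: np.ndarray, block: BlockConstraint) -> np.ndarray:
    """Dose vector ``A_l x`` for one structure block."""
    x = np.asarray(x, dtype=float)
    if block.n != x.shape[0]:
        raise ValueError(
            f"intensity vector has length {x.shape[0]}, block expects {block.n}"
        )
    return block.dose(x)


@dataclass(frozen=True)
class DvhCurve:
    """Cumulative DVH: percentage of voxels receiving at least each dose."""

    thresholds: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        v = np.asarray(self.volume_fraction, dtype=float)
        if t.shape != v.shape:
            raise ValueError("thresholds and volume_fraction must align")
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be non-decreasing")
        if np.any(np.diff(v) > 0):
            raise ValueError("a cumulative DVH must be non-increasing")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "volume_fraction", v)


def default_thresholds(dose: np.ndarray, n: int = 512) -> np.ndarray:
    """Evenly spaced dose levels from 0 to 1.05 x max dose (for plotting)."""
    top = 1.05 * float(np.max(dose, initial=0.0))
    return np.linspace(0.0, top if top > 0 else 1.0, n)


def compute_dvh(dose: np.ndarray, thresholds: Optional[np.ndarray] = None) -> DvhCurve:
    """Cumulative DVH of a dose vector at the given dose levels."""
    dose = np.asarray(dose, dtype=float).ravel()
    if dose.size == 0:
        raise ValueError("cannot evaluate a DVH on an empty structure")
    if thresholds is None:
        thresholds = default_thresholds(dose)
    thresholds = np.asarray(thresholds, dtype=float)
    srt = np.sort(dose)
    m = dose.size
    # voxels with dose >= t:  m - (number strictly below t)
    frac = 100.0 * (m - np.searchsorted(srt, thresholds, side="left")) / m
    return DvhCurve(thresholds=thresholds, volume_fraction=frac)


def dose_at_volume(dose: np.ndarray, v_percent: float) -> float:
    """``D_V%``: the largest dose received by at least V% of the voxels.

    Computed as the ``ceil(V m / 100)``-th largest dose (order statistic,
    no interpolation); ``D_100%`` is the minimum dose.
    """
    if not 0.0 < v_percent <= 100.0:
        raise ValueError(f"V must lie in (0, 100], got {v_percent}")
    dose = np.asarray(dose, dtype=float).ravel()
    if dose.size == 0:
        raise ValueError("cannot evaluate D_V% on an empty structure")
    m = dose.size
    k = int(math.ceil(v_percent * m / 100.0))  # 1 <= k <= m
    return float(np.sort(dose)[m - k])


@dataclass
class ViolationReport:
    """Violation counts by category for one iterate.

    ``hdc_min`` / ``hdc_max`` count voxels whose dose falls below /
    exceeds the hard (relaxed) bound of their block.  ``dvc_lower`` /
    ``dvc_upper`` count the *excess* over the violation budget: per PVC
    block, ``max(0, #{voxels beyond the base bound} - floor(alpha m))``,
    summed by sense.  Percentages are relative to each category's voxel
    population (for DVC categories, the voxels of the PVC blocks of that
    sense).
    """

    counts: Dict[str, int]
    populations: Dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> Dict[str, float]:
        return {
            c: (100.0 * self.counts[c] / self.populations[c]) if self.populations[c] else 0.0
            for c in CATEGORIES
        }

    def as_row(self) -> Dict[str, float]:
        """Flat dict for CSV logging."""
        row: Dict[str, float] = {}
        for c in CATEGORIES:
            row[c] = self.counts[c]
        for c, v in self.percentages.items():
            row[f"{c}_pct"] = v
        row["total"] = self.total
        return row


def count_violations(
    x: np.ndarray,
    problem: FeasibilityProblem,
    atol: float = VIOLATION_ATOL,
    doses=None,
) -> ViolationReport:
    """Count constraint violations of an iterate, by category.

    ``doses`` may carry precomputed per-block dose vectors (one per
    block, in block order) to avoid recomputing ``A_l x``.
    """
    counts = {c: 0 for c in CATEGORIES}
    pops = {c: 0 for c in CATEGORIES}
    for k, blk in enumerate(problem.blocks):
        d = doses[k] if doses is not None else blk.dose(x)
        eff = blk.effective_bound
        if blk.sense == UPPER:
            counts["hdc_max"] += int(np.count_nonzero(d > eff + atol))
            pops["hdc_max"] += blk.m
        else:
            counts["hdc_min"] += int(np.count_nonzero(d < eff - atol))
            pops["hdc_min"] += blk.m
        if blk.has_pvc:
            if blk.sense == UPPER:
                beyond = int(np.count_nonzero(d > blk.bound + atol))
                counts["dvc_upper"] += max(0, beyond - blk.budget)
                pops["dvc_upper"] += blk.m
            else:
                beyond = int(np.count_nonzero(d < blk.bound - atol))
                counts["dvc_lower"] += max(0, beyond - blk.budget)
                pops["dvc_lower"] += blk.m
    return ViolationReport(counts=counts, populations=pops)
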