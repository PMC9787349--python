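"""Synthetic two-dimensional pseudo-dose phantom.

A bank of isotropic Gaussian kernels on a uniform lattice emulates the
dose deposited by elementary beamlets on a square pixel grid.  A single
common amplitude is calibrated so that the superposition of all kernels
at unit beamlet weight is a homogeneous map with a prescribed mean
intensity.  Collapsing each kernel's pixel map to a column (row-major)
yields the dose-influence matrix ``A``; the rows falling inside each
structure rectangle form the per-structure blocks.

The packaged full-size default: a 512x512 grid, 1156 kernels on a 34x34
lattice with standard deviation 20 px, calibrated to a mean of 50
intensity units, with two avoidance structures and one target structure
carrying the standard prescription (Dmax/Dmin bounds plus DV% rules).
The exact rectangles of the three structures are this repository's
choice — three disjoint squares on the horizontal midline — and are
configurable like every other geometry parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .operators import LOWER, UPPER
from .problem import BlockConstraint, FeasibilityProblem
from .pvc import Dvc, Prescription, StructureRule, prescription_to_blocks, translate_lfp_pvc

__all__ = [
    "Rect",
    "PhantomSpec",
    "KernelBank",
    "DoseInfluenceMatrix",
    "generate_kernels",
    "calibrate_amplitude",
    "summed_map",
    "assemble_matrix",
    "full_default",
    "scaled_default",
    "build_problem",
]


class CalibrationError(ValueError):
    """The kernel bank cannot be calibrated (degenerate, all-zero)."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle of pixels, half-open 0-based ranges."""

    name: str
    rows: Tuple[int, int]
    cols: Tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.rows[0] < self.rows[1] and self.cols[0] < self.cols[1]):
            raise ValueError(f"empty rectangle {self.name!r}")

    def mask(self, grid: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(grid, dtype=bool)
        m[self.rows[0]: self.rows[1], self.cols[0]: self.cols[1]] = True
        return m

    def row_indices(self, grid: Tuple[int, int]) -> np.ndarray:
        """Row-major flat pixel indices covered by the rectangle."""
        rr = np.arange(self.rows[0], self.rows[1])
        cc = np.arange(self.cols[0], self.cols[1])
        return (rr[:, None] * grid[1] + cc[None, :]).ravel()

    def scaled(self, factor: float) -> "Rect":
        return Rect(
            name=self.name,
            rows=(int(round(self.rows[0] * factor)), int(round(self.rows[1] * factor))),
            cols=(int(round(self.cols[0] * factor)), int(round(self.cols[1] * factor))),
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic phantom.

    ``n_kernels`` must be a perfect square: the kernel centers form a
    uniform ``sqrt(n) x sqrt(n)`` lattice over the grid.  ``sigma`` is the
    kernel standard deviation in pixels and ``truncation_radius`` the
    radial cutoff beyond which a kernel contributes exactly zero (keeps
    the dose-influence matrix sparse; ``4 sigma`` by default, where the
    relative amplitude has fallen to ``exp(-8) ~ 3e-4``).
    """

    grid: Tuple[int, int] = (512, 512)
    n_kernels: int = 1156
    sigma: float = 20.0
    target_mean: float = 50.0
    truncation_radius: Optional[float] = None
    structures: Tuple[Rect, ...] = ()

    def __post_init__(self) -> None:
        k = int(round(math.sqrt(self.n_kernels)))
        if k * k != self.n_kernels:
            raise ValueError(f"n_kernels must be a perfect square, got {self.n_kernels}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.truncation_radius is None:
            object.__setattr__(self, "truncation_radius", 4.0 * self.sigma)
        object.__setattr__(self, "structures", tuple(self.structures))
        # structures must be pairwise disjoint
        for i, a in enumerate(self.structures):
            for b in self.structures[i + 1:]:
                if (
                    a.rows[0] < b.rows[1]
                    and b.rows[0] < a.rows[1]
                    and a.cols[0] < b.cols[1]
                    and b.cols[0] < a.cols[1]
                ):
                    raise ValueError(f"structures {a.name!r} and {b.name!r} overlap")

    @property
    def lattice_side(self) -> int:
        return int(round(math.sqrt(self.n_kernels)))

    @property
    def n_pixels(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class KernelBank:
    """Kernel centers plus each kernel's (clipped) local pixel map.

    ``patches[j]`` is ``(r0, r1, c0, c1, values)`` with half-open pixel
    ranges and a dense 2-d array of unit-amplitude kernel values.
    """

    spec: PhantomSpec
    centers: np.ndarray  # (K, 2) kernel centers in (row, col) pixel coords
    patches: List[Tuple[int, int, int, int, np.ndarray]]


def _lattice_centers(extent: int, k: int) -> np.ndarray:
    """k uniformly spaced centers along one axis of `extent` pixels."""
    return (np.arange(k) + 0.5) * (extent / k) - 0.5


def generate_kernels(spec: PhantomSpec) -> KernelBank:
    """Build the bank of truncated isotropic Gaussian kernels.

    Kernel value at pixel (r, c) for a center (r0, c0):
    ``exp(-((r - r0)^2 + (c - c0)^2) / (2 sigma^2))``, set to exactly zero
    beyond the truncation radius.  Patches are clipped at the grid edges.
    """
    rows, cols = spec.grid
    k = spec.lattice_side
    cr = _lattice_centers(rows, k)
    cc = _lattice_centers(cols, k)
    rad = spec.truncation_radius
    inv = 1.0 / (2.0 * spec.sigma ** 2)
    centers = np.empty((spec.n_kernels, 2))
    patches: List[Tuple[int, int, int, int, np.ndarray]] = []
    j = 0
    for r0 in cr:
        r_lo = max(0, int(math.ceil(r0 - rad)))
        r_hi = min(rows, int(math.floor(r0 + rad)) + 1)
        rr = np.arange(r_lo, r_hi, dtype=float)
        dr2 = (rr - r0) ** 2
        for c0 in cc:
            c_lo = max(0, int(math.ceil(c0 - rad)))
            c_hi = min(cols, int(math.floor(c0 + rad)) + 1)
            ccc = np.arange(c_lo, c_hi, dtype=float)
            dc2 = (ccc - c0) ** 2
            d2 = dr2[:, None] + dc2[None, :]
            vals = np.exp(-d2 * inv)
            vals[d2 > rad * rad] = 0.0
            centers[j] = (r0, c0)
            patches.append((r_lo, r_hi, c_lo, c_hi, vals))
            j += 1
    return KernelBank(spec=spec, centers=centers, patches=patches)


def summed_map(bank: KernelBank, amplitude: float = 1.0) -> np.ndarray:
    """Superposition of all kernels at a common amplitude (the map
    produced by the all-ones beamlet vector)."""
    grid = np.zeros(bank.spec.grid)
    for r0, r1, c0, c1, vals in bank.patches:
        grid[r0:r1, c0:c1] += vals
    return amplitude * grid


def calibrate_amplitude(bank: KernelBank, target_mean: float) -> float:
    """Common amplitude making the grid-wide mean of the summed map equal
    to ``target_mean``."""
    total = sum(float(vals.sum()) for *_, vals in bank.patches)
    if total <= 0.0:
        raise CalibrationError("kernel bank sums to zero; cannot calibrate")
    unit_mean = total / bank.spec.n_pixels
    return target_mean / unit_mean


@dataclass
class DoseInfluenceMatrix:
    """The sparse dose-influence matrix with named structure blocks."""

    A: sp.csr_matrix
    grid: Tuple[int, int]
    structure_rows: Dict[str, np.ndarray]

    def block(self, name: str) -> sp.csr_matrix:
        """Rows of ``A`` belonging to one structure."""
        return self.A[self.structure_rows[name], :]

    def blocks(self) -> Dict[str, sp.csr_matrix]:
        return {name: self.block(name) for name in self.structure_rows}

    def structure_mask(self, name: str) -> np.ndarray:
        m = np.zeros(self.grid[0] * self.grid[1], dtype=bool)
        m[self.structure_rows[name]] = True
        return m.reshape(self.grid)

    def label_map(self) -> np.ndarray:
        """Integer-labeled grid: 0 outside, i+1 inside structure i."""
        lab = np.zeros(self.grid[0] * self.grid[1], dtype=np.int32)
        for i, rows in enumerate(self.structure_rows.values()):
            lab[rows] = i + 1
        return lab.reshape(self.grid)


def assemble_matrix(
    bank: KernelBank,
    amplitude: float,
    structures: Optional[Sequence[Rect]] = None,
) -> DoseInfluenceMatrix:
    """Collapse every kernel map to a column (row-major flattening) and
    stack them into the sparse dose-influence matrix."""
    spec = bank.spec
    if structures is None:
        structures = spec.structures
    rows, cols = spec.grid
    nnz = sum(np.count_nonzero(vals) for *_, vals in bank.patches)
    row_idx = np.empty(nnz, dtype=np.int64)
    col_idx = np.empty(nnz, dtype=np.int64)
    data = np.empty(nnz, dtype=float)
    pos = 0
    for j, (r0, r1, c0, c1, vals) in enumerate(bank.patches):
        rr, cc = np.nonzero(vals)
        k = rr.size
        row_idx[pos: pos + k] = (rr + r0) * cols + (cc + c0)
        col_idx[pos: pos + k] = j
        data[pos: pos + k] = amplitude * vals[rr, cc]
        pos += k
    A = sp.csr_matrix(
        (data, (row_idx, col_idx)), shape=(rows * cols, spec.n_kernels)
    )
    structure_rows = {s.name: s.row_indices(spec.grid) for s in structures}
    return DoseInfluenceMatrix(A=A, grid=spec.grid, structure_rows=structure_rows)


# ----------------------------------------------------------------------
# packaged configurations

AVOIDANCE_A = "Avoidance A"
AVOIDANCE_B = "Avoidance B"
TARGET = "Target"

#: Canonical structure rectangles on the 512x512 grid (three disjoint
#: 96 px squares on the horizontal midline; repository-chosen geometry).
_CANONICAL_STRUCTURES = (
    Rect(AVOIDANCE_A, rows=(208, 304), cols=(48, 144)),
    Rect(TARGET, rows=(208, 304), cols=(208, 304)),
    Rect(AVOIDANCE_B, rows=(208, 304), cols=(368, 464)),
)


def table_prescription() -> Prescription:
    """The packaged prescription: two avoidance structures with a Dmax and
    an upper DV% rule each, one target with Dmin, Dmax and a lower DV%."""
    return Prescription(
        structures={
            AVOIDANCE_A: StructureRule(d_max=25.0, dvcs=(Dvc(10.0, 20.0, UPPER),)),
            AVOIDANCE_B: StructureRule(d_max=40.0, dvcs=(Dvc(25.0, 30.0, UPPER),)),
            TARGET: StructureRule(
                d_min=60.0, d_max=70.0, dvcs=(Dvc(90.0, 65.0, LOWER),)
            ),
        }
    )


def full_default() -> Tuple[PhantomSpec, Prescription]:
    """The full-size worked-example configuration: 512x512 grid, 1156
    kernels (34x34 lattice), sigma 20 px, mean 50 units, standard
    prescription, unit row-projection relaxation, 40 cycles."""
    spec = PhantomSpec(
        grid=(512, 512),
        n_kernels=1156,
        sigma=20.0,
        target_mean=50.0,
        structures=_CANONICAL_STRUCTURES,
    )
    return spec, table_prescription()


def scaled_default(
    grid_size: int = 128, n_kernels: int = 289
) -> Tuple[PhantomSpec, Prescription]:
    """A proportionally scaled-down phantom (default 128x128 grid, 289
    kernels) with the same prescription.

    All lengths scale with the grid: ``sigma`` and the structure
    rectangles shrink by ``grid_size / 512``, so the geometry is similar
    to the full-size phantom and the interior of the summed map stays
    homogeneous.
    """
    factor = grid_size / 512.0
    spec = PhantomSpec(
        grid=(grid_size, grid_size),
        n_kernels=n_kernels,
        sigma=20.0 * factor,
        target_mean=50.0,
        structures=tuple(r.scaled(factor) for r in _CANONICAL_STRUCTURES),
    )
    return spec, table_prescription()


def build_problem(
    spec: PhantomSpec,
    prescription: Prescription,
    lam: float = 1.0,
) -> Tuple[FeasibilityProblem, DoseInfluenceMatrix]:
    """Generate kernels, calibrate, assemble the matrix and translate the
    prescription into the block feasibility problem."""
    bank = generate_kernels(spec)
    amplitude = calibrate_amplitude(bank, spec.target_mean)
    dim = assemble_matrix(bank, amplitude)
    blocks = prescription_to_blocks(prescription, dim.blocks(), lam=lam)
    return translate_lfp_pvc(blocks), dim
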