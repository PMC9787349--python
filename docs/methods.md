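# Methods

## Problem

The solver addresses block-structured feasibility problems of the kind
that arise in fluence-map (inverse) radiotherapy planning.  The unknown
is a nonnegative beamlet-intensity vector `x ∈ R^n_+`.  A dose-influence
matrix `A` maps intensities to dose per voxel; each anatomical structure
`ℓ` owns a block `A_ℓ` of its rows.  A prescription imposes, per block,

* **hard dose constraints (HDCs)** — per-voxel bounds `A_ℓ x ≤ b_hard`
  (avoidance structures) or `A_ℓ x ≥ c_hard` (targets), and
* **dose-volume constraints (DVCs)** — "at most a fraction α of the
  structure may exceed the base bound `b`, and those voxels by at most a
  fraction β".  Writing `v = A_ℓ x`, the DVC is the sparsity bound
  `‖(v − b)⁺‖₀ ≤ α m_ℓ` together with the relaxed per-voxel bound
  `v ≤ (1+β) b` (mirrored for lower bounds).

The DVC set in dose space is closed but nonconvex.  The solver treats
the problem as a split feasibility problem: convex half-space constraints
act in intensity space, the nonconvex dose-volume sets act in dose space
behind the linear maps `A_ℓ`.

## Operators

* **Relaxed half-space projection** (per voxel `i` of block `ℓ`): leave
  `x` unchanged if `⟨a_ℓi, x⟩` satisfies the relaxed bound, otherwise

  `x ← x + λ_ℓ · (bound − ⟨a_ℓi, x⟩) / ⟨a_ℓi, a_ℓi⟩ · a_ℓi`,

  with `λ_ℓ ∈ (0, 2)`; the comparison is strict with no epsilon.
* **Sparsity-set projection** `P_Q̄` with budget `s = ⌊α m⌋`: if the
  vector has at most `s` positive entries it is unchanged; otherwise its
  smallest positive entries are zeroed until exactly `s` remain.  This is
  a global Euclidean nearest point (verified exhaustively in tests).  The
  projection is not unique when the smallest kept and largest removed
  values tie; ties are broken by zeroing the lowest indices first, making
  the operator deterministic.  A `literal_floor` variant instead removes
  `⌊k − α m⌋` entries (`k` = current positive count), which for
  fractional `α m` leaves `⌈α m⌉` positives and hence can land *outside*
  the constraint set; the default removal count is used everywhere
  because the fixed-point framework needs the projection to actually
  reach the set.
* **Dose-volume projection** `P_Q`: shift by the base bound, apply
  `P_Q̄`, shift back (`P_Q(v) = P_Q̄(v − b) + b` for upper bounds,
  `−P_Q̄(c − v) + c` for lower).
* **Landweber-type block operator**
  `V_ℓ = Id − γ_ℓ A_ℓᵀ (Id − P_Q) A_ℓ`, with
  `γ_ℓ ∈ (0, 1/‖A_ℓ‖²]`.  Its fixed points are exactly the preimages
  `A_ℓ⁻¹(Fix P_Q)`; when `P_Q` is a projection onto a convex set and
  `γ_ℓ < 1/‖A_ℓ‖²`, `V_ℓ` is a cutter (both properties are property-
  tested).

## Iteration

Each block induces `R_ℓ = U_ℓ V_ℓ`: the Landweber step `V_ℓ` first
(rightmost factor acts first; skipped for blocks without a DVC), then
`U_ℓ`, a sequential sweep of the block's relaxed half-space projections
in ascending voxel order (a seeded random order is available; any order
without replacement is admissible).  The order can be swapped via
`SolverOptions(u_before_v=True)` since it is a genuinely open choice.

A *string* is a finite sequence of block indices; its operator is the
composition of the `R_ℓ` along it.  One averaging step evaluates every
string of the current plan from the same iterate and convexly combines
the endpoints.  Plans are *admissible* when the strings jointly cover
every block (fitness), string lengths are capped by `q̄ ≥ p`, and each
weight is at least a floor `Δ ∈ (0, 1/p)`; admissibility is re-validated
every cycle, and plans may change between cycles (dynamic averaging).

The sequential planning specialization runs the single full-length
string with unit weight, then clamps negative intensities to zero at the
end of each cycle (nonnegativity is enforced only there, not per
projection).  The default run performs a fixed number of cycles; optional
stopping rules (residual tolerance, violation-free, no-improvement
window) can end the run earlier.

On purely convex instances the averaging operator is strongly
quasi-nonexpansive, so iterates are Fejér monotone with respect to the
feasible set; with the nonconvex dose-volume sets no such guarantee
exists and the solver is a heuristic feasibility seeker that tracks
violation counts.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `λ_ℓ` | row-projection relaxation, (0, 2) | 1 | metric projection; midrange |
| `γ_ℓ` | Landweber step, (0, 1/L_ℓ], L_ℓ=‖A_ℓ‖² | 1/L_ℓ | classical Landweber step (`gamma_mode="endpoint"`); `"strict"` gives 1/(2L_ℓ), strictly inside the open interval the convergence theory uses — the theory's "midrange" language is ambiguous, so both are exposed |
| `α_ℓ` | DVC violation fraction | from prescription | upper DVC `D_V% ≤ b` → `α = V/100`; lower DVC `D_V% ≥ c` → `α = 1 − V/100` (the self-consistent reading of the budget; the alternative literal reading is documented, not adopted) |
| `β_ℓ` | DVC dose relaxation | solved from `(1±β)·(DVC dose) = hard bound` | makes the relaxed per-voxel bound coincide with Dmax/Dmin |
| `Δ`, `q̄` | weight floor, length cap | 1e-6, `p` | loose bounds; only admissibility matters |
| cycles | sequential cycles | 40 | the packaged experiment's setting |

Spectral norms are computed by power iteration on `AᵀA` with a
deterministic all-ones start (restarted from a fixed non-uniform vector
if that start lies in the null space), relative tolerance 1e-8, 10,000
iteration cap — reproducible without a seed.

## Numerical choices

* Feasibility *tests* use absolute tolerance 1e-9 on constraint
  residuals (projections land on hyperplanes only to rounding error);
  the projection formulae themselves use strict comparisons with no
  epsilon, and the positive-entry count is a strict sign test.
* Violation counting uses the same 1e-9 absolute dose slack.
* String endpoints are combined with compensated (Kahan) summation in
  plan order, so results are independent of evaluation order to ~1e-12.
* `D_V%` is the `⌈V·m/100⌉`-th largest dose (order statistic, no
  interpolation), which makes `D_V% ≤ b` equivalent to "fewer than
  `⌈V·m/100⌉` voxels exceed `b`".  Note the violation *budget* is
  `⌊α m⌋`; when `V·m/100` is an integer the metric is one voxel stricter
  than the budget.  Discretized DVH curves are for display only and are
  never used in satisfaction tests.
* Degenerate inputs: all-zero constraint rows, all-zero matrices, empty
  blocks and empty structures are rejected with specific errors rather
  than silently skipped.

## Synthetic phantom

The generator emulates a two-dimensional "pseudo-dose" planning
geometry: `n` isotropic Gaussian kernels (standard deviation σ, radial
truncation at 4σ where the relative amplitude is `e⁻⁸ ≈ 3·10⁻⁴`) on a
uniform `√n × √n` lattice over a square pixel grid.  A single common
amplitude is calibrated so the superposition of all kernels at unit
weight has a prescribed grid-wide mean (50 units by default); matching
an interior-plateau value instead is available as an option.  Each
kernel map, flattened row-major, is one column of the sparse
dose-influence matrix; structure blocks are the rows inside axis-aligned
rectangles, which must be pairwise disjoint.  A structure with both a
minimum and a maximum dose rule contributes two blocks over the same
rows.

The full-size configuration uses a 512×512 grid, 1156 kernels (34×34
lattice, spacing ≈ 15.06 px), σ = 20 px and mean 50; the matrix has
262,144 rows and 1156 columns.  Because the lattice spacing is well
below σ, the interior of the summed map is flat (coefficient of
variation below 1% over the central window — asserted as a generator
sanity check).  The three structure rectangles are this repository's
choice (96 px squares on the horizontal midline at columns 48–144,
208–304 and 368–464); they are fully configurable, and consequently the
per-block `γ_ℓ = 1/‖A_ℓ‖²` values depend on this geometry.

A proportionally scaled-down configuration (`scaled_default()`,
128×128 grid, 289 kernels) shrinks *all* lengths by the grid ratio
(σ = 5 px, 24 px structures).  An alternative scaling that keeps σ tied
to the kernel-lattice spacing (σ = 10 px) was considered and rejected:
it couples the structures more strongly than the full-size problem and
is not geometrically similar.  The test suite runs the scaled
configuration (seconds) and assembles the full-size matrix once; these
problem sizes are the package's own choice of test scale.

What the phantom does *not* emulate: three-dimensional voxel geometries,
physically realistic beamlet kernels (pencil-beam or Monte-Carlo dose
engines), heterogeneous patient anatomy, and DICOM-RT plumbing.  Passing
tests therefore demonstrate the algorithmic machinery on an idealized
smooth, noiseless dose model, not clinical plan quality.

## Known limitations

* With dose-volume constraints the feasible sets are nonconvex; the
  iteration is only guaranteed to converge (weakly) in the convex case.
  In practice violation counts decay roughly geometrically at first and
  then plateau: on both the scaled and full-size phantom runs a small
  residual set of voxels (order 0.1–3% of a structure) keeps hovering
  just beyond the dose-volume budgets as consecutive blocks push dose in
  opposite directions, and a handful of voxels sit fractions of a dose
  unit above hard bounds at any finite cycle count.  The per-cycle,
  per-category violation log exists precisely to surveil this behavior.
* Strings are evaluated serially; the order-independence contract is
  about arithmetic, not threading.
* The adaptive re-weighting of `λ`, `γ` across cycles is exposed only as
  a configuration hook (per-block values), not as an automatic policy.
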