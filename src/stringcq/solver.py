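"""The dynamic string-averaging CQ iteration.

Each block ``l`` of the feasibility problem induces an operator
``R_l = U_l V_l``: first the Landweber-type step ``V_l`` pulls the dose
vector ``A_l x`` toward the (possibly nonconvex) dose-volume set ``Q_l``,
then ``U_l`` sweeps the block's relaxed half-space projections row by
row.  A *string* is a finite sequence of block indices; its operator is
the composition of the ``R_l`` along the string.  One iteration applies
every string of the current plan to the iterate and takes the convex
combination of the endpoints.  Strings and weights may change from cycle
to cycle, subject to admissibility: every block index appears in some
string, string lengths are capped, and weights stay above a floor.

The fully sequential treatment-planning specialization runs a single
full-length string per cycle with unit weight and clamps negative beamlet
intensities to zero at the end of each cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .operators import LOWER, UPPER, InvalidConstraintError, LandweberSpec, landweber_step
from .problem import BlockConstraint, FeasibilityProblem
from .pvc import project_dvc, pvc_spec_for
from . import evaluate

__all__ = [
    "IndexVector",
    "StringPlan",
    "SolverOptions",
    "StoppingRule",
    "SolverState",
    "PlanError",
    "validate_string_plan",
    "block_operator",
    "apply_string",
    "sa_iterate",
    "run_dynamic_sa",
    "run_sequential_rttp",
    "sequential_plan",
    "simultaneous_plan",
]


class PlanError(ValueError):
    """A string plan violates admissibility (fitness, weights or length)."""


@dataclass(frozen=True)
class IndexVector:
    """An ordered tuple of block indices defining one string."""

    entries: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(int(i) for i in self.entries))
        if len(self.entries) == 0:
            raise PlanError("an index vector must contain at least one block index")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class StringPlan:
    """A fit set of strings with weights, a weight floor and a length cap.

    ``delta`` is the weight floor (must lie in ``(0, 1/p)``) and
    ``max_len`` the string-length cap (at least ``p``); together they
    define the admissible family from which a dynamic schedule may pick a
    plan at every cycle.
    """

    strings: tuple
    weights: tuple
    delta: float = 1e-6
    max_len: Optional[int] = None

    def __post_init__(self) -> None:
        strings = tuple(
            s if isinstance(s, IndexVector) else IndexVector(tuple(s))
            for s in self.strings
        )
        object.__setattr__(self, "strings", strings)
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(self.strings) != len(self.weights):
            raise PlanError("need exactly one weight per string")


def sequential_plan(p: int, order: Optional[Sequence[int]] = None) -> StringPlan:
    """The single full-length string ``(0, 1, ..., p-1)`` with unit weight."""
    entries = tuple(order) if order is not None else tuple(range(p))
    return StringPlan(strings=(IndexVector(entries),), weights=(1.0,), max_len=max(p, len(entries)))


def simultaneous_plan(p: int) -> StringPlan:
    """``p`` singleton strings with equal weights ``1/p``."""
    return StringPlan(
        strings=tuple(IndexVector((i,)) for i in range(p)),
        weights=(1.0 / p,) * p,
        delta=0.5 / p,
        max_len=p,
    )


def validate_string_plan(plan: StringPlan, p: int) -> StringPlan:
    """Check plan admissibility against a problem with ``p`` blocks.

    Raises :class:`PlanError` when the strings do not cover every block
    index (fitness), a weight drops below the floor or the weights do not
    sum to one, or a string exceeds the length cap.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    max_len = plan.max_len if plan.max_len is not None else p
    if max_len < p:
        raise PlanError(f"length cap {max_len} is below the block count {p}")
    if not 0.0 < plan.delta < 1.0 / p:
        raise PlanError(f"weight floor delta={plan.delta} must lie in (0, 1/p)")
    covered = set()
    for s in plan.strings:
        if len(s) > max_len:
            raise PlanError(f"string {s.entries} exceeds the length cap {max_len}")
        for i in s:
            if not 0 <= i < p:
                raise PlanError(f"block index {i} out of range for p={p}")
            covered.add(i)
    if covered != set(range(p)):
        missing = sorted(set(range(p)) - covered)
        raise PlanError(f"plan is not fit: block indices {missing} appear in no string")
    total = float(np.sum(plan.weights))
    if abs(total - 1.0) > 1e-12:
        raise PlanError(f"weights must sum to 1 (got {total!r})")
    for w in plan.weights:
        if w < plan.delta:
            raise PlanError(f"weight {w} is below the floor delta={plan.delta}")
    return plan


# ----------------------------------------------------------------------
# options

@dataclass(frozen=True)
class SolverOptions:
    """Knobs of the iteration that the theory leaves open.

    gamma_mode:
        ``"endpoint"`` uses the step ``gamma = 1/||A||^2`` (the classical
        Landweber choice); ``"strict"`` uses ``1/(2 ||A||^2)``, strictly
        inside the open interval required by the convergence analysis.
        A block's explicit ``gamma`` overrides either.
    u_before_v:
        Apply the half-space sweep before the dose-volume step inside
        each block operator (default is V first, then U, i.e. the
        rightmost factor of ``U V`` acts first).
    voxel_order:
        ``"ascending"`` (default, deterministic) or ``"random"`` row
        order inside the half-space sweep; random order draws from the
        generator passed to the run functions.
    literal_floor:
        Use the literal floor placement in the sparsity-projection
        removal count (see :class:`stringcq.pvc.PvcSpec`).
    """

    gamma_mode: str = "endpoint"
    u_before_v: bool = False
    voxel_order: str = "ascending"
    literal_floor: bool = False

    def __post_init__(self) -> None:
        if self.gamma_mode not in ("endpoint", "strict"):
            raise ValueError("gamma_mode must be 'endpoint' or 'strict'")
        if self.voxel_order not in ("ascending", "random"):
            raise ValueError("voxel_order must be 'ascending' or 'random'")

    def resolve_gamma(self, block: BlockConstraint) -> float:
        if block.gamma is not None:
            return block.gamma
        if self.gamma_mode == "endpoint":
            return 1.0 / block.norm_sq()
        return 0.5 / block.norm_sq()


# ----------------------------------------------------------------------
# elementary building blocks

def _sweep_halfspaces(
    x: np.ndarray,
    block: BlockConstraint,
    options: SolverOptions,
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    """Sequential relaxed projections onto the block's rows (the U_l part).

    Rows are visited in ascending order (or a seeded permutation), each
    exactly once per sweep.  A row already satisfying its relaxed bound
    is skipped; the comparison is strict with no epsilon, matching the
    closed-form projection formula.
    """
    lam = block.lam
    eff = block.effective_bound
    rn = block.row_norms_sq()
    m = block.m
    if options.voxel_order == "random":
        if rng is None:
            raise ValueError("random voxel order needs a random generator")
        order = rng.permutation(m)
    else:
        order = range(m)
    upper = block.sense == UPPER
    x = x.copy()
    if sp.issparse(block.A):
        indptr = block.A.indptr
        indices = block.A.indices
        data = block.A.data
        for i in order:
            s, e = indptr[i], indptr[i + 1]
            idx = indices[s:e]
            a = data[s:e]
            dot = float(a @ x[idx])
            if (dot > eff[i]) if upper else (dot < eff[i]):
                if rn[i] == 0.0:
                    raise InvalidConstraintError(
                        f"zero row {i} of block {block.name!r} violates its bound"
                    )
                x[idx] += (lam * (eff[i] - dot) / rn[i]) * a
    else:
        A = block.A
        for i in order:
            a = A[i]
            dot = float(a @ x)
            if (dot > eff[i]) if upper else (dot < eff[i]):
                if rn[i] == 0.0:
                    raise InvalidConstraintError(
                        f"zero row {i} of block {block.name!r} violates its bound"
                    )
                x += (lam * (eff[i] - dot) / rn[i]) * a
    return x


def block_operator(
    x: np.ndarray,
    block_index: int,
    problem: FeasibilityProblem,
    options: Optional[SolverOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply one block's operator ``R_l = U_l V_l`` to ``x``.

    ``V_l`` is the Landweber-type step toward the block's dose-volume set
    (skipped for blocks without a PVC); ``U_l`` the sequential sweep of
    relaxed half-space projections over the block's rows.
    """
    if options is None:
        options = SolverOptions()
    if not 0 <= block_index < problem.p:
        raise IndexError(f"block index {block_index} out of range (p={problem.p})")
    block = problem.blocks[block_index]
    x = np.asarray(x, dtype=float)

    def v_step(y: np.ndarray) -> np.ndarray:
        if not block.has_pvc:
            return y
        qspec = pvc_spec_for(block, literal_floor=options.literal_floor)
        lspec = LandweberSpec(gamma=options.resolve_gamma(block), norm_sq=block.norm_sq())
        return landweber_step(y, block.A, lambda v: project_dvc(v, qspec), lspec)

    def u_step(y: np.ndarray) -> np.ndarray:
        return _sweep_halfspaces(y, block, options, rng)

    if options.u_before_v:
        return v_step(u_step(x))
    return u_step(v_step(x))


def apply_string(
    x: np.ndarray,
    t: IndexVector,
    problem: FeasibilityProblem,
    options: Optional[SolverOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Composition of block operators along the string ``t`` (first entry
    of ``t`` applied first)."""
    if not isinstance(t, IndexVector):
        t = IndexVector(tuple(t))
    y = np.asarray(x, dtype=float)
    for i in t:
        y = block_operator(y, i, problem, options=options, rng=rng)
    return y


def sa_iterate(
    x: np.ndarray,
    plan: StringPlan,
    problem: FeasibilityProblem,
    options: Optional[SolverOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One string-averaging step: evaluate every string from the same
    iterate and convexly combine the endpoints.

    String evaluations are independent of one another; the combination
    uses compensated (Kahan) summation in the plan's string order, so the
    result does not depend on the order in which endpoints are computed.
    """
    validate_string_plan(plan, problem.p)
    x = np.asarray(x, dtype=float)
    acc = np.zeros_like(x)
    comp = np.zeros_like(x)
    for t, w in zip(plan.strings, plan.weights):
        term = w * apply_string(x, t, problem, options=options, rng=rng)
        y = term - comp
        tmp = acc + y
        comp = (tmp - acc) - y
        acc = tmp
    return acc


# ----------------------------------------------------------------------
# full runs

@dataclass(frozen=True)
class StoppingRule:
    """When to stop iterating.

    ``max_cycles`` always applies; optionally stop early when the largest
    relaxed-bound residual drops below ``residual_tol``, when the total
    violation count reaches zero (``stop_when_violation_free``), or when
    it has not improved over the last ``no_improve_window`` cycles.
    """

    max_cycles: int = 40
    residual_tol: Optional[float] = None
    stop_when_violation_free: bool = False
    no_improve_window: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError(f"max_cycles must be at least 1, got {self.max_cycles}")


@dataclass
class CycleRecord:
    """Per-cycle evaluation snapshot."""

    cycle: int
    residual: float
    violations: "evaluate.ViolationReport"


@dataclass
class SolverState:
    """Final iterate plus the per-cycle history (entry 0 describes the
    starting point, entry k the iterate after cycle k)."""

    x: np.ndarray
    cycle: int
    history: list = field(default_factory=list)

    @property
    def initial_report(self) -> CycleRecord:
        return self.history[0]

    @property
    def final_report(self) -> CycleRecord:
        return self.history[-1]


def _record(x: np.ndarray, cycle: int, problem: FeasibilityProblem) -> CycleRecord:
    doses = [blk.dose(x) for blk in problem.blocks]
    return CycleRecord(
        cycle=cycle,
        residual=problem.max_residual(x, doses=doses),
        violations=evaluate.count_violations(x, problem, doses=doses),
    )


def _should_stop(stop: StoppingRule, history: Sequence[CycleRecord]) -> bool:
    rec = history[-1]
    if stop.residual_tol is not None and rec.residual < stop.residual_tol:
        return True
    if stop.stop_when_violation_free and rec.violations.total == 0:
        return True
    if stop.no_improve_window is not None and len(history) > stop.no_improve_window:
        window = [r.violations.total for r in history[-(stop.no_improve_window + 1):]]
        if min(window[1:]) >= window[0]:
            return True
    return False


def run_dynamic_sa(
    x0: np.ndarray,
    plan_schedule: Sequence[StringPlan],
    problem: FeasibilityProblem,
    stop: Optional[StoppingRule] = None,
    options: Optional[SolverOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> SolverState:
    """Run the dynamic string-averaging iteration.

    ``plan_schedule`` is cycled through if shorter than the number of
    cycles: plan ``k mod len(schedule)`` is used at cycle ``k``, so both
    static (single-plan) and dynamic (alternating-plan) runs are covered.
    Every plan is validated against the problem before the run starts.
    If the problem includes the nonnegativity set, negative intensities
    are clamped to zero at the end of every cycle.
    """
    if len(plan_schedule) == 0:
        raise ValueError("plan schedule must contain at least one plan")
    for plan in plan_schedule:
        validate_string_plan(plan, problem.p)
    if stop is None:
        stop = StoppingRule()
    x = np.asarray(x0, dtype=float).copy()
    history = [_record(x, 0, problem)]
    cycle = 0
    for cycle in range(1, stop.max_cycles + 1):
        plan = plan_schedule[(cycle - 1) % len(plan_schedule)]
        x = sa_iterate(x, plan, problem, options=options, rng=rng)
        if problem.nonneg:
            np.maximum(x, 0.0, out=x)
        history.append(_record(x, cycle, problem))
        if _should_stop(stop, history):
            break
    return SolverState(x=x, cycle=cycle, history=history)


def run_sequential_rttp(
    problem: FeasibilityProblem,
    x0: Optional[np.ndarray] = None,
    n_cycles: int = 40,
    block_order: Optional[Sequence[int]] = None,
    options: Optional[SolverOptions] = None,
    seed: Optional[int] = None,
    stop: Optional[StoppingRule] = None,
) -> SolverState:
    """Fully sequential treatment-planning run.

    Per cycle the blocks are traversed once each in ``block_order``
    (default ascending), the rows within each block likewise; after all
    projections of the cycle the nonnegativity constraint is enforced by
    clamping negative intensities to zero.  The default start is the
    all-ones intensity vector and the run performs exactly ``n_cycles``
    cycles unless a stopping rule is supplied.
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be at least 1, got {n_cycles}")
    if x0 is None:
        x0 = np.ones(problem.n)
    rng = np.random.default_rng(seed) if seed is not None else None
    plan = sequential_plan(problem.p, order=block_order)
    if stop is None:
        stop = StoppingRule(max_cycles=n_cycles)
    else:
        stop = replace(stop, max_cycles=n_cycles)
    return run_dynamic_sa(
        x0, [plan], problem, stop=stop, options=options, rng=rng
    )
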