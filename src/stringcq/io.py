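"""Configuration files, problem I/O and run reports.

Run configurations are YAML.  An empty configuration reproduces the
packaged full-size phantom run; any field can be overridden, and unknown
keys are rejected with the offending field path.  Dose-influence matrices
travel as MatrixMarket coordinate files (1-based per that standard;
internal indices are 0-based, converted at the boundary only), structure
row sets and prescriptions as JSON/YAML, logs and DVH curves as CSV.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml

from .evaluate import CATEGORIES, DvhCurve
from .operators import LOWER, UPPER
from .phantom import (
    DoseInfluenceMatrix,
    PhantomSpec,
    Rect,
    build_problem,
    full_default,
)
from .problem import FeasibilityProblem
from .pvc import Dvc, Prescription, StructureRule, prescription_to_blocks, translate_lfp_pvc
from .solver import SolverOptions, StoppingRule

__all__ = [
    "ConfigError",
    "RunConfig",
    "SolverSettings",
    "load_config",
    "write_problem",
    "read_problem",
    "write_violation_log",
    "write_dvh_csv",
    "prescription_to_dict",
    "prescription_from_dict",
]


class ConfigError(ValueError):
    """A configuration file violates the schema."""


def _check_keys(mapping: dict, allowed: Sequence[str], path: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")


# ----------------------------------------------------------------------
# prescriptions

def prescription_to_dict(p: Prescription) -> dict:
    out = {}
    for name, rule in p.structures.items():
        entry: dict = {}
        if rule.d_max is not None:
            entry["d_max"] = rule.d_max
        if rule.d_min is not None:
            entry["d_min"] = rule.d_min
        if rule.dvcs:
            entry["dvc"] = [
                {"volume": d.volume_percent, "dose": d.dose, "sense": d.sense}
                for d in rule.dvcs
            ]
        out[name] = entry
    return out


def prescription_from_dict(data: dict, path: str = "prescription") -> Prescription:
    structures = {}
    for name, entry in data.items():
        if not isinstance(entry, dict):
            raise ConfigError(f"'{path}.{name}' must be a mapping")
        _check_keys(entry, ("d_max", "d_min", "dvc"), f"{path}.{name}")
        dvcs = []
        for i, d in enumerate(entry.get("dvc", []) or []):
            _check_keys(d, ("volume", "dose", "sense"), f"{path}.{name}.dvc[{i}]")
            try:
                dvcs.append(
                    Dvc(
                        volume_percent=float(d["volume"]),
                        dose=float(d["dose"]),
                        sense=d.get("sense", UPPER),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"invalid DV% rule at '{path}.{name}.dvc[{i}]': {exc}")
        structures[name] = StructureRule(
            d_max=None if entry.get("d_max") is None else float(entry["d_max"]),
            d_min=None if entry.get("d_min") is None else float(entry["d_min"]),
            dvcs=tuple(dvcs),
        )
    return Prescription(structures=structures)


# ----------------------------------------------------------------------
# solver settings

@dataclass(frozen=True)
class SolverSettings:
    cycles: int = 40
    lam: float = 1.0
    gamma_mode: str = "endpoint"
    voxel_order: str = "ascending"
    block_order: object = "ascending"  # "ascending" | "random" | explicit list
    u_before_v: bool = False
    literal_floor: bool = False
    seed: int = 0
    residual_tol: Optional[float] = None
    stop_when_violation_free: bool = False
    no_improve_window: Optional[int] = None

    def options(self) -> SolverOptions:
        return SolverOptions(
            gamma_mode=self.gamma_mode,
            u_before_v=self.u_before_v,
            voxel_order=self.voxel_order,
            literal_floor=self.literal_floor,
        )

    def stopping_rule(self) -> StoppingRule:
        return StoppingRule(
            max_cycles=self.cycles,
            residual_tol=self.residual_tol,
            stop_when_violation_free=self.stop_when_violation_free,
            no_improve_window=self.no_improve_window,
        )


def _solver_settings(data: dict, path: str = "solver") -> SolverSettings:
    _check_keys(
        data,
        (
            "cycles",
            "lam",
            "gamma_mode",
            "voxel_order",
            "block_order",
            "u_before_v",
            "literal_floor",
            "seed",
            "residual_tol",
            "stop_when_violation_free",
            "no_improve_window",
        ),
        path,
    )
    try:
        settings = SolverSettings(
            cycles=int(data.get("cycles", 40)),
            lam=float(data.get("lam", 1.0)),
            gamma_mode=data.get("gamma_mode", "endpoint"),
            voxel_order=data.get("voxel_order", "ascending"),
            block_order=data.get("block_order", "ascending"),
            u_before_v=bool(data.get("u_before_v", False)),
            literal_floor=bool(data.get("literal_floor", False)),
            seed=int(data.get("seed", 0)),
            residual_tol=(
                None
                if data.get("residual_tol") is None
                else float(data["residual_tol"])
            ),
            stop_when_violation_free=bool(data.get("stop_when_violation_free", False)),
            no_improve_window=(
                None
                if data.get("no_improve_window") is None
                else int(data["no_improve_window"])
            ),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}")
    if not 0.0 < settings.lam < 2.0:
        raise ConfigError(f"'{path}.lam' must lie in (0, 2), got {settings.lam}")
    if settings.cycles < 1:
        raise ConfigError(f"'{path}.cycles' must be at least 1")
    try:
        settings.options()
    except ValueError as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}")
    return settings


# ----------------------------------------------------------------------
# run configuration

def _phantom_spec(data: dict, path: str = "phantom") -> PhantomSpec:
    _check_keys(
        data,
        ("grid", "n_kernels", "sigma", "target_mean", "truncation_radius", "structures"),
        path,
    )
    base, _ = full_default()
    structures = base.structures
    if "structures" in data:
        structures = []
        for i, s in enumerate(data["structures"]):
            _check_keys(s, ("name", "rows", "cols"), f"{path}.structures[{i}]")
            try:
                structures.append(
                    Rect(
                        name=s["name"],
                        rows=tuple(int(v) for v in s["rows"]),
                        cols=tuple(int(v) for v in s["cols"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"invalid rectangle at '{path}.structures[{i}]': {exc}")
    try:
        return PhantomSpec(
            grid=tuple(int(v) for v in data.get("grid", base.grid)),
            n_kernels=int(data.get("n_kernels", base.n_kernels)),
            sigma=float(data.get("sigma", base.sigma)),
            target_mean=float(data.get("target_mean", base.target_mean)),
            truncation_radius=(
                None
                if data.get("truncation_radius") is None
                else float(data["truncation_radius"])
            ),
            structures=tuple(structures),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}")


@dataclass
class RunConfig:
    """Fully validated run configuration.

    Exactly one input source is active: a phantom specification (from
    which everything is generated) or paths to an external matrix plus
    block row lists.
    """

    phantom: Optional[PhantomSpec]
    matrix_dir: Optional[Path]
    prescription: Prescription
    solver: SolverSettings
    outdir: Path

    def build(self) -> Tuple[FeasibilityProblem, Optional[DoseInfluenceMatrix]]:
        if self.phantom is not None:
            return build_problem(self.phantom, self.prescription, lam=self.solver.lam)
        _, _, problem = read_problem(self.matrix_dir, self.prescription, lam=self.solver.lam)
        return problem, None


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Defaults are filled from the packaged full-size phantom run; an empty
    file therefore describes that run verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(data, ("phantom", "matrix", "prescription", "solver", "output"), "<root>")

    if "phantom" in data and "matrix" in data:
        raise ConfigError("exactly one of 'phantom' and 'matrix' may be given")

    base_spec, base_rx = full_default()
    matrix_dir: Optional[Path] = None
    spec: Optional[PhantomSpec]
    if "matrix" in data:
        mdata = data["matrix"]
        _check_keys(mdata, ("dir",), "matrix")
        matrix_dir = Path(mdata["dir"])
        if not matrix_dir.exists():
            raise FileNotFoundError(f"matrix directory {matrix_dir} does not exist")
        spec = None
    else:
        spec = _phantom_spec(data.get("phantom", {}) or {})

    if "prescription" in data:
        rx = prescription_from_dict(data["prescription"])
    else:
        rx = base_rx

    solver = _solver_settings(data.get("solver", {}) or {})
    outdir = Path(data.get("output", "stringcq-out"))
    return RunConfig(
        phantom=spec,
        matrix_dir=matrix_dir,
        prescription=rx,
        solver=solver,
        outdir=outdir,
    )


# ----------------------------------------------------------------------
# problem files

def write_problem(dirpath, dim: DoseInfluenceMatrix, prescription: Prescription) -> None:
    """Write matrix (MatrixMarket), structure row sets (JSON) and the
    prescription (YAML) to a directory."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(dim.A))
    blocks = {
        "grid": list(dim.grid),
        "structure_rows": {k: np.asarray(v).tolist() for k, v in dim.structure_rows.items()},
    }
    (d / "blocks.json").write_text(json.dumps(blocks))
    (d / "prescription.yaml").write_text(
        yaml.safe_dump(prescription_to_dict(prescription))
    )


def read_problem(
    dirpath,
    prescription: Optional[Prescription] = None,
    lam: float = 1.0,
) -> Tuple[DoseInfluenceMatrix, Prescription, FeasibilityProblem]:
    """Load a problem directory written by :func:`write_problem` and
    reassemble the block feasibility problem."""
    d = Path(dirpath)
    A = sp.csr_matrix(scipy.io.mmread(str(d / "matrix.mtx")))
    blocks_meta = json.loads((d / "blocks.json").read_text())
    grid = tuple(blocks_meta["grid"])
    structure_rows = {}
    for name, rows in blocks_meta["structure_rows"].items():
        idx = np.asarray(rows, dtype=np.int64)
        if len(idx) == 0:
            raise ConfigError(f"structure {name!r} has an empty row set")
        if idx.min() < 0 or idx.max() >= A.shape[0]:
            raise ConfigError(
                f"structure {name!r} references rows outside the matrix "
                f"(valid range 0..{A.shape[0] - 1})"
            )
        structure_rows[name] = idx
    dim = DoseInfluenceMatrix(A=A, grid=grid, structure_rows=structure_rows)
    if prescription is None:
        rx_path = d / "prescription.yaml"
        if not rx_path.exists():
            raise FileNotFoundError(f"no prescription found in {d}")
        prescription = prescription_from_dict(yaml.safe_load(rx_path.read_text()) or {})
    blocks = prescription_to_blocks(prescription, dim.blocks(), lam=lam)
    return dim, prescription, translate_lfp_pvc(blocks)


# ----------------------------------------------------------------------
# reports

def write_violation_log(path, history) -> None:
    """Append-only CSV log with one row per cycle."""
    path = Path(path)
    fieldnames = ["cycle", "residual"]
    fieldnames += list(CATEGORIES)
    fieldnames += [f"{c}_pct" for c in CATEGORIES]
    fieldnames += ["total"]
    new = not path.exists()
    with path.open("a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        if new:
            writer.writeheader()
        for rec in history:
            row = {"cycle": rec.cycle, "residual": f"{rec.residual:.6e}"}
            row.update(rec.violations.as_row())
            writer.writerow(row)


def write_dvh_csv(path, curves: Dict[str, DvhCurve]) -> None:
    """DVH curves of several structures on a shared threshold grid."""
    path = Path(path)
    names = list(curves)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["dose"] + names)
        first = curves[names[0]]
        for i, t in enumerate(first.thresholds):
            writer.writerow(
                [f"{t:.6g}"] + [f"{curves[n].volume_fraction[i]:.6g}" for n in names]
            )
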