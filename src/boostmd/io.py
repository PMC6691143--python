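"""File formats, fixtures and run configuration.

Trajectories persist as a multi-model PDB (beads as C-alpha atoms, one MODEL
per frame; coordinates at the format's 3-decimal precision) plus a
full-precision CSV of the per-frame scalars (time, V, V_D, deltaV,
instantaneous T).  Real or synthetic C-alpha traces are read with Bio.PDB
(first model only).  Run configuration is a YAML file validated against a
typed schema; unknown keys are rejected with their location.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .engine import BoostParams, SimulationConfig, TrajectoryRecord
from .models import (
    ModelSystem,
    extended_coords,
    ideal_helix_coords,
    make_cg_helix,
    make_double_well,
)

__all__ = [
    "TraceStructure",
    "read_pdb_trace",
    "write_ca_pdb",
    "read_multimodel_frames",
    "write_trajectory",
    "read_trajectory_scalars",
    "make_fixtures",
    "RunConfig",
    "load_config",
    "build_system",
    "build_sim_config",
    "provenance_block",
]


# --------------------------------------------------------------------------
# PDB ingestion / emission (fixed-column ATOM/MODEL/ENDMDL subset)
# --------------------------------------------------------------------------


@dataclass
class TraceStructure:
    """A C-alpha trace read from a PDB file (first model)."""

    coords: np.ndarray  # (n_res, 3)
    residue_names: list[str]
    residue_ids: list[int]
    chain_breaks: list[int]  # trace indices where the chain id changed
    n_skipped: int  # residues lacking the requested atom


def read_pdb_trace(path, atom_name: str = "CA") -> TraceStructure:
    """Extract one atom per residue (default C-alpha) from the first model."""
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("trace", str(path))
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"{path}: no ATOM records / models found")
    model = models[0]

    coords, names, ids, breaks = [], [], [], []
    n_skipped = 0
    prev_chain = None
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # skip waters / heteroatoms
                continue
            if atom_name not in residue:
                n_skipped += 1
                warnings.warn(
                    f"{path.name}: residue {residue.get_resname()}{residue.id[1]} "
                    f"missing atom {atom_name}; skipped",
                    stacklevel=2,
                )
                continue
            if prev_chain is not None and chain.id != prev_chain:
                breaks.append(len(coords))
            prev_chain = chain.id
            coords.append(residue[atom_name].coord.astype(float))
            names.append(residue.get_resname())
            ids.append(int(residue.id[1]))
    if not coords:
        raise ValueError(f"{path}: no usable ATOM records")
    return TraceStructure(
        coords=np.array(coords),
        residue_names=names,
        residue_ids=ids,
        chain_breaks=breaks,
        n_skipped=n_skipped,
    )


def _format_atom(serial: int, resseq: int, xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:>5d}  CA  ALA A{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
    )


def write_ca_pdb(path, frames: np.ndarray) -> Path:
    """Write frames ``(n_frames, n_res, 3)`` as a multi-model CA-trace PDB."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, n_res, 3)")
    path = Path(path)
    lines = []
    for m, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:>4d}")
        for i, xyz in enumerate(frame):
            lines.append(_format_atom(i + 1, i + 1, xyz))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_multimodel_frames(path, atom_name: str = "CA") -> np.ndarray:
    """Read every model of a multi-model PDB into ``(n_frames, n_res, 3)``."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("frames", str(path))
    frames = []
    for model in structure:
        coords = [
            residue[atom_name].coord.astype(float)
            for chain in model
            for residue in chain
            if residue.id[0] == " " and atom_name in residue
        ]
        frames.append(coords)
    if not frames:
        raise ValueError(f"{path}: no models found")
    return np.array(frames)


# --------------------------------------------------------------------------
# Trajectory persistence
# --------------------------------------------------------------------------

SCALAR_COLUMNS = ["time_ps", "V", "V_D", "deltaV", "T_inst"]


def write_trajectory(traj: TrajectoryRecord, path_prefix) -> dict[str, Path]:
    """Persist a trajectory: scalars CSV always, multi-model PDB for 3-D systems.

    Lower-dimensional systems get their coordinates as a long-format CSV
    instead of a PDB.  Scalars are written at full precision and round-trip
    bit-exactly; PDB coordinates round-trip to the format's 3-decimal
    precision.
    """
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    df = pd.DataFrame(
        {
            "time_ps": traj.times,
            "V": traj.V,
            "V_D": traj.V_D,
            "deltaV": traj.deltaV,
            "T_inst": traj.T_inst,
        }
    )
    csv_path = prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False, float_format="%.17g")
    out["scalars"] = csv_path

    if traj.coords.shape[2] == 3:
        out["frames"] = write_ca_pdb(prefix.with_suffix(".pdb"), traj.coords)
    else:
        nf, npart, dim = traj.coords.shape
        cols = {"frame": np.repeat(np.arange(nf), npart)}
        cols["particle"] = np.tile(np.arange(npart), nf)
        for d in range(dim):
            cols[f"x{d}"] = traj.coords[:, :, d].ravel()
        coords_path = prefix.parent / (prefix.name + "_coords.csv")
        pd.DataFrame(cols).to_csv(coords_path, index=False)
        out["frames"] = coords_path
    return out


def read_trajectory_scalars(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = set(SCALAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing scalar columns {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# Fixture generation (synthetic stand-ins for reference/native structures)
# --------------------------------------------------------------------------

FIXTURE_KINDS = ("ideal_helix", "extended", "decoy_set", "two_conformer_mix")


def make_fixtures(
    kind: str,
    n_res: int,
    seed: int,
    out_dir,
    sigmas: tuple[float, ...] = (0.5, 1.0, 2.0),
    n_frames: int = 50,
) -> list[Path]:
    """Deterministic synthetic PDB fixtures.

    * ``ideal_helix`` / ``extended`` — single-model reference traces.
    * ``decoy_set`` — the helix with isotropic per-bead Gaussian displacement
      of RMS magnitude sigma (sigma/sqrt(3) per coordinate), one file per
      sigma level.
    * ``two_conformer_mix`` — a multi-model file mixing jittered helix and
      extended conformers half/half (for clustering demos).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    helix = ideal_helix_coords(n_res)
    paths: list[Path] = []
    if kind == "ideal_helix":
        paths.append(write_ca_pdb(out_dir / f"ideal_helix_{n_res}.pdb", helix))
    elif kind == "extended":
        paths.append(
            write_ca_pdb(out_dir / f"extended_{n_res}.pdb", extended_coords(n_res))
        )
    elif kind == "decoy_set":
        for sigma in sigmas:
            decoy = helix + (sigma / np.sqrt(3.0)) * rng.standard_normal(helix.shape)
            paths.append(
                write_ca_pdb(out_dir / f"decoy_{n_res}_sigma{sigma:g}.pdb", decoy)
            )
    else:  # two_conformer_mix
        ext = extended_coords(n_res)
        frames = []
        for i in range(n_frames):
            base = helix if i % 2 == 0 else ext
            frames.append(base + 0.3 * rng.standard_normal(base.shape))
        paths.append(
            write_ca_pdb(out_dir / f"two_conformer_mix_{n_res}.pdb", np.array(frames))
        )
    return paths


# --------------------------------------------------------------------------
# Run configuration schema
# --------------------------------------------------------------------------


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DoubleWellBlock(_Block):
    barrier_height: float = 6.0  # kcal/mol
    half_separation: float = 2.0  # Angstrom
    mass: float = 10.0  # amu


class CGHelixBlock(_Block):
    n_res: int = 15
    bond_k: float = 40.0
    angle_k: float = 15.0
    torsion_k: float = 1.5
    torsion_barrier: float = 3.0
    contact_eps: float = 1.5
    repulsion_sigma: float = 4.0
    mass: float = 110.0


class SystemBlock(_Block):
    kind: Literal["double_well", "cg_helix"] = "cg_helix"
    double_well: DoubleWellBlock = DoubleWellBlock()
    cg_helix: CGHelixBlock = CGHelixBlock()


class SimulationBlock(_Block):
    timestep: float = 0.01  # ps
    temperature: float = 300.0  # K
    collision_frequency: float = 1.0  # 1/ps
    n_steps: int = 10_000
    save_interval: int = 10
    heat_ramp_steps: int = 0
    minimize_first: bool = False
    energy_ceiling: float = 1e8


class ExplicitBoostBlock(_Block):
    E_P: float = 0.0
    alpha_P: float = 0.0
    E_D: float = 0.0
    alpha_D: float = 0.0


class BoostBlock(_Block):
    mode: Literal["none", "dihedral", "total", "dual"] = "none"
    a1: float = 3.5  # kcal/mol
    a2: float = 0.2  # kcal/mol per atom
    n_res_effective: Optional[int] = None  # override for analytic systems
    n_atom_effective: Optional[int] = None
    prerun_steps: int = 20_000
    burn_in: float = 0.5
    nested_total: bool = False
    explicit: Optional[ExplicitBoostBlock] = None  # bypass the pre-run


class AnalysisBlock(_Block):
    reference: str = "ideal_helix"  # or a PDB path
    contact_cutoff: float = 7.0  # Angstrom
    min_seq_sep: int = 2
    selection: Optional[list[int]] = None  # helix-region residue indices
    bins: int = 50
    helix_window_deg: float = 30.0
    n_clusters: int = 3


class OutputBlock(_Block):
    directory: str = "boostmd_out"
    prefix: str = "run"
    write_pdb: bool = True


class RunConfig(_Block):
    seed: int = 0
    system: SystemBlock = SystemBlock()
    simulation: SimulationBlock = SimulationBlock()
    boost: BoostBlock = BoostBlock()
    analysis: AnalysisBlock = AnalysisBlock()
    output: OutputBlock = OutputBlock()


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: {locs}") from err


def build_system(cfg: RunConfig) -> ModelSystem:
    if cfg.system.kind == "double_well":
        p = cfg.system.double_well
        return make_double_well(p.barrier_height, p.half_separation, p.mass)
    p = cfg.system.cg_helix
    return make_cg_helix(
        n_res=p.n_res,
        bond_k=p.bond_k,
        angle_k=p.angle_k,
        torsion_k=p.torsion_k,
        torsion_barrier=p.torsion_barrier,
        contact_eps=p.contact_eps,
        repulsion_sigma=p.repulsion_sigma,
        mass=p.mass,
        contact_cutoff=cfg.analysis.contact_cutoff,
        min_seq_sep=cfg.analysis.min_seq_sep,
    )


def build_sim_config(
    cfg: RunConfig,
    boost_mode: str | None = None,
    seed: int | None = None,
    n_steps: int | None = None,
) -> SimulationConfig:
    sim = cfg.simulation
    return SimulationConfig(
        timestep=sim.timestep,
        temperature=sim.temperature,
        n_steps=sim.n_steps if n_steps is None else n_steps,
        collision_frequency=sim.collision_frequency,
        save_interval=sim.save_interval,
        seed=cfg.seed if seed is None else seed,
        boost_mode=cfg.boost.mode if boost_mode is None else boost_mode,
        heat_ramp_steps=sim.heat_ramp_steps,
        minimize_first=sim.minimize_first,
        energy_ceiling=sim.energy_ceiling,
        nested_total_boost=cfg.boost.nested_total,
    )


def provenance_block(cfg: RunConfig, boost: BoostParams | None = None) -> dict:
    """Provenance sufficient to reproduce a run bit-for-bit."""
    cfg_json = json.dumps(cfg.model_dump(), sort_keys=True)
    block = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "boostmd_version": __version__,
        "numpy_version": np.__version__,
    }
    if boost is not None:
        block["boost_params"] = boost.as_dict()
    return block
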