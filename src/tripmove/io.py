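"""PDB input/output, trajectory files and run configuration.

The PDB layer is a thin adapter over biotite's structure I/O: a single
protein chain of standard residues, heavy atoms only (hydrogens and
OXT are ignored on read).  Bond lengths and angles are taken as read
and held rigid thereafter.  Serial numbers, occupancy and B-factor are
carried through to output.

Run configurations are schema-validated (unknown keys rejected) and a
manifest with the configuration hash, seed and package versions is
written next to every run's outputs, enough to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .chain import BackboneChain
from .decomposition import decompose
from .engine import DEFAULT_CLASS_STEPS, MCConfig, MCTrajectory, run
from .energy import ClashParams, DefaultEnergy
from .fixtures import build_polypeptide_fixture
from .moves import StepSizes
from .residues import GeometryTable

__all__ = [
    "read_pdb",
    "write_pdb",
    "write_trajectory",
    "write_internal_table",
    "RunConfig",
    "load_config",
    "execute_run",
]


def read_pdb(path, table: GeometryTable | None = None) -> BackboneChain:
    """Read a single-chain protein PDB file into a BackboneChain.

    Takes the first model (with a warning if there are several), the
    first altloc, and errors on missing backbone atoms or chain breaks
    (C-N distance > 1.8 A), naming the residue.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models > 1:
        warnings.warn(f"{path}: {n_models} models present, using the first")
    atoms = pdb_file.get_structure(model=1, altloc="first", extra_fields=["atom_id", "occupancy", "b_factor"])
    atoms = atoms[struc.filter_amino_acids(atoms)]
    atoms = atoms[atoms.element != "H"]
    atoms = atoms[atoms.atom_name != "OXT"]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no amino-acid atoms found")
    chain_ids = np.unique(atoms.chain_id)
    if len(chain_ids) > 1:
        raise ValueError(f"{path}: multiple chains {list(chain_ids)}; single-chain input required")

    res_ids = []
    res_names = []
    atom_names = []
    coords = []
    serials = []
    occupancy = []
    b_factor = []
    for rid in np.unique(atoms.res_id):
        sel = atoms[atoms.res_id == rid]
        res_ids.append(int(rid))
        res_names.append(str(sel.res_name[0]))
        atom_names.append([str(nm) for nm in sel.atom_name])
        coords.append(np.asarray(sel.coord, float))
        serials.append(sel.atom_id.tolist())
        occupancy.append(sel.occupancy.tolist())
        b_factor.append(sel.b_factor.tolist())

    # chain-break check before measuring internal coordinates
    for i in range(len(res_ids) - 1):
        d = dict(zip(atom_names[i], coords[i]))
        d2 = dict(zip(atom_names[i + 1], coords[i + 1]))
        if "C" in d and "N" in d2:
            gap = float(np.linalg.norm(d2["N"] - d["C"]))
            if gap > 1.8:
                raise ValueError(
                    f"{path}: chain break between residues {res_ids[i]} and "
                    f"{res_ids[i + 1]} (C-N distance {gap:.2f} A)"
                )

    chain = BackboneChain.from_cartesian(res_names, atom_names, coords, table=table)
    chain.metadata = {
        "res_ids": res_ids,
        "chain_id": str(chain_ids[0]),
        "serials": serials,
        "occupancy": occupancy,
        "b_factor": b_factor,
        "source": str(path),
    }
    return chain


def _chain_to_atom_array(chain: BackboneChain) -> struc.AtomArray:
    chain.refresh()
    n = chain.n_atoms
    arr = struc.AtomArray(n)
    meta = chain.metadata
    res_ids = meta.get("res_ids", list(range(1, chain.n_residues + 1)))
    arr.coord = chain.coords.copy()
    arr.chain_id = np.full(n, meta.get("chain_id", "A"))
    arr.res_id = np.array([res_ids[r] for r in chain.atom_res])
    arr.res_name = np.array([chain.residues[r].name for r in chain.atom_res])
    arr.atom_name = np.array(chain.atom_names)
    arr.element = chain.atom_elements.copy()
    arr.hetero = np.zeros(n, bool)
    arr.set_annotation("atom_id", _per_atom(chain, meta.get("serials"), np.arange(1, n + 1), int))
    arr.set_annotation("occupancy", _per_atom(chain, meta.get("occupancy"), np.ones(n), float))
    arr.set_annotation("b_factor", _per_atom(chain, meta.get("b_factor"), np.zeros(n), float))
    return arr


def _per_atom(chain, nested, default, dtype):
    if nested is None:
        return np.asarray(default, dtype=dtype)
    flat = [v for sub in nested for v in sub]
    if len(flat) != chain.n_atoms:  # atom set changed; fall back
        return np.asarray(default, dtype=dtype)
    return np.asarray(flat, dtype=dtype)


def write_pdb(chain: BackboneChain, path) -> None:
    """Write standard ATOM records (serial/occupancy/B-factor carried
    through from the source file when available)."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_chain_to_atom_array(chain))
    pdb_file.write(str(path))


def write_trajectory(traj: MCTrajectory, chain: BackboneChain, out_dir, models: bool = True) -> dict:
    """Write a trajectory as an internal-coordinate table plus an
    optional multi-model PDB; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table_path = out_dir / "trajectory_torsions.tsv"
    n_res = chain.n_residues
    with open(table_path, "w") as fh:
        cols = ["record", "step", "energy", "move"]
        for i in range(n_res):
            cols += [f"phi_{i + 1}", f"psi_{i + 1}"]
        fh.write("\t".join(cols) + "\n")
        for rec, (step, tors, e, tag) in enumerate(
            zip(traj.step_indices, traj.torsions, traj.energies, traj.move_tags)
        ):
            row = [str(rec), str(step), f"{e:.6f}", tag]
            row += [f"{np.degrees(v):.4f}" for v in tors]
            fh.write("\t".join(row) + "\n")
    paths["torsions"] = table_path

    if models:
        pdb_path = out_dir / "trajectory.pdb"
        work = chain.copy()
        pdb_file = pdb.PDBFile()
        arrays = []
        for tors, chis in zip(traj.torsions, traj.chi):
            for i in range(n_res):
                work.set_phi(i, tors[2 * i])
                work.set_psi(i, tors[2 * i + 1])
                for k, v in enumerate(chis[i]):
                    work.set_chi(i, k, v)
            work.refresh()
            arrays.append(_chain_to_atom_array(work))
        stack = struc.stack(arrays)
        pdb_file.set_structure(stack)
        pdb_file.write(str(pdb_path))
        paths["models"] = pdb_path
    return paths


def write_internal_table(chain: BackboneChain, path) -> None:
    """Plain-text internal coordinates: one row per residue with index,
    name, phi, psi, omega and chi angles (degrees in the file)."""
    chain.refresh()
    with open(path, "w") as fh:
        fh.write("# residue\tname\tphi\tpsi\tomega\tchi...\n")
        for i in range(chain.n_residues):
            row = [
                str(i + 1),
                chain.residues[i].name,
                f"{np.degrees(chain.phi[i]):.4f}",
                f"{np.degrees(chain.psi[i]):.4f}",
                f"{np.degrees(chain.omega[i]):.4f}",
            ]
            row += [f"{np.degrees(v):.4f}" for v in chain.chi(i)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


class FixtureSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sequence: str
    preset: str = "helix"


class InputSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pdb: str | None = None
    fixture: FixtureSpec | None = None


class StepSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delta_b: float = 0.025
    delta_pt: float = 0.05
    delta_pr: float = 0.003


class MovesSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    weights: dict[str, float] = Field(
        default_factory=lambda: {c: 0.25 for c in ("OneTorsion", "ConRot", "OneParticle", "Hinge")}
    )
    step_sizes: dict[str, StepSpec] = Field(default_factory=dict)
    hinge_range: tuple[int, int] = (3, 10)
    closest_threshold: float = 1.0
    solver_mode: str = "continuation"


class MCSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    temperature: float = 300.0
    backbone_prob: float = 0.5
    delta_chi: float = 0.1
    target_accepted: int = 10_000
    max_steps: int | None = None
    record_stride: int = 100
    start_offset: int = 0
    frozen_residues: list[int] = Field(default_factory=list)


class EnergySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: str = "default"  # "default" | "none"
    clash_filter: bool = True
    clash_scale: float = 0.7


class RunConfig(BaseModel):
    """Schema-validated configuration of one sampling run."""

    model_config = ConfigDict(extra="forbid")
    input: InputSpec
    mc: MCSpec = Field(default_factory=MCSpec)
    moves: MovesSpec = Field(default_factory=MovesSpec)
    energy: EnergySpec = Field(default_factory=EnergySpec)
    output_dir: str = "tripmove_out"
    seed: int = 0
    write_models: bool = False


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def execute_run(config: RunConfig, log=None) -> MCTrajectory:
    """Load the input, run the Metropolis loop, write outputs + manifest."""
    from . import __version__

    if (config.input.pdb is None) == (config.input.fixture is None):
        raise ValueError("exactly one of input.pdb / input.fixture must be given")
    if config.input.pdb is not None:
        chain = read_pdb(config.input.pdb)
    else:
        chain = build_polypeptide_fixture(config.input.fixture.sequence, config.input.fixture.preset)

    class_steps = dict(DEFAULT_CLASS_STEPS)
    for name, spec in config.moves.step_sizes.items():
        class_steps[name] = StepSizes(spec.delta_b, spec.delta_pt, spec.delta_pr)

    mc_config = MCConfig(
        temperature=config.mc.temperature,
        backbone_prob=config.mc.backbone_prob,
        move_weights=dict(config.moves.weights),
        class_steps=class_steps,
        delta_chi=config.mc.delta_chi,
        target_accepted=config.mc.target_accepted,
        max_steps=config.mc.max_steps,
        record_stride=config.mc.record_stride,
        seed=config.seed,
        frozen_residues=tuple(config.mc.frozen_residues),
        start_offset=config.mc.start_offset,
        closest_threshold=config.moves.closest_threshold,
        hinge_range=tuple(config.moves.hinge_range),
        solver_mode=config.moves.solver_mode,
    )
    decomp = decompose(chain, config.mc.start_offset)
    energy_model = DefaultEnergy(chain) if config.energy.model == "default" else None
    clash = ClashParams(scale_factor=config.energy.clash_scale) if config.energy.clash_filter else None

    traj = run(chain, decomp, mc_config, energy_model=energy_model, clash_params=clash, log=log)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_trajectory(traj, chain, out_dir, models=config.write_models)
    write_pdb(chain, out_dir / "final.pdb")
    config_json = config.model_dump_json()
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "tripmove_version": __version__,
        "numpy_version": np.__version__,
        "n_steps": traj.n_steps,
        "n_accepted": traj.n_accepted,
        "acceptance_rates": traj.acceptance_rates,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return traj
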