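"""End-to-end docking protocol orchestration and table/file artifacts.

A single run is: FFT sampling → energy scoring (optional restraints) →
ranking; artifacts are a transform table (one row per pose: Euler angles,
translation, grid score), an energy table (per-pose term breakdown and rank)
and PDB files for the best-scoring models.  Benchmark-style execution
repeats the run from several random initial rotations of the inputs, merges
every run's best models into one pool in a common receptor frame, and
removes redundancy by GROMOS clustering; representatives are ranked by
total score.

All tables are whitespace-separated with one ``#`` header line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as clustering
from . import energy as energy_mod
from . import sampling
from .forcefield import assign_forcefield
from .geometry import random_rotation_matrix, transform_about
from .restraints import parse_restraints
from .sampling import DockPose, pose_coords
from .structure import Structure, concat_structures, write_pdb

logger = logging.getLogger("dnadock")


@dataclass
class RunConfig:
    """All protocol parameters, with the published defaults."""

    cell: float = sampling.DEFAULT_CELL                       # 0.7 Å
    surface_thickness: float = sampling.DEFAULT_SURFACE_THICKNESS  # 1.3 Å
    rotation_step: float = sampling.DEFAULT_ROTATION_STEP     # 12°
    keep_per_rotation: int = sampling.DEFAULT_KEEP_PER_ROTATION  # 3
    total_keep: int = sampling.DEFAULT_TOTAL_KEEP             # 10,000
    scheme: str = "default"                                   # vdW weight 0.1
    restraints_path: str | None = None
    n_runs: int = 1                                           # benchmark mode: 10
    seed: int = 1
    cluster_cutoff: float = clustering.DEFAULT_CLUSTER_CUTOFF  # 4.0 Å
    top_per_run: int = clustering.DEFAULT_TOP_PER_RUN          # 100
    n_top_models: int = 100
    bins: int = 50
    initial_rotation: bool = False   # rotate inputs randomly before run 1

    def __post_init__(self):
        for name in ("cell", "surface_thickness", "rotation_step",
                     "keep_per_rotation", "total_keep", "cluster_cutoff",
                     "top_per_run", "n_top_models", "bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def run_seeds(self) -> list[int]:
        """Per-run seeds expanded deterministically from the master seed."""
        rng = np.random.default_rng(self.seed)
        return [int(x) for x in rng.integers(0, 2**31 - 1, self.n_runs)]


# ---------------------------------------------------------------- tables

def write_transform_table(poses: list[DockPose], path) -> None:
    lines = ["# run_id pose_id phi theta psi tx ty tz grid_score"]
    for p in poses:
        phi, theta, psi = p.euler
        tx, ty, tz = p.translation
        lines.append(f"{p.run_id} {p.pose_id} {phi:.6f} {theta:.6f} "
                     f"{psi:.6f} {tx:.6f} {ty:.6f} {tz:.6f} {p.grid_score}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_transform_table(path) -> list[DockPose]:
    poses = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        poses.append(DockPose(run_id=int(f[0]), pose_id=int(f[1]),
                              euler=(float(f[2]), float(f[3]), float(f[4])),
                              translation=np.array([float(f[5]), float(f[6]),
                                                    float(f[7])]),
                              grid_score=int(f[8])))
    return poses


def write_energy_table(poses: list[DockPose], path) -> None:
    """Energy table for scored poses; rank is ascending total under the
    active scheme."""
    ranked = energy_mod.rank_poses(list(poses))
    rank_of = {(p.run_id, p.pose_id): i + 1 for i, p in enumerate(ranked)}
    lines = ["# run_id pose_id ele desolv vdw restraint total rank"]
    for p in poses:
        e = p.energies
        lines.append(f"{p.run_id} {p.pose_id} {e.ele:.6f} {e.desolv:.6f} "
                     f"{e.vdw:.6f} {e.restraint:.6f} {e.total:.6f} "
                     f"{rank_of[(p.run_id, p.pose_id)]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_energy_table(path) -> dict[tuple[int, int], energy_mod.EnergyBreakdown]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        out[(int(f[0]), int(f[1]))] = energy_mod.EnergyBreakdown(
            ele=float(f[2]), desolv=float(f[3]), vdw=float(f[4]),
            restraint=float(f[5]), total=float(f[6]))
    return out


def write_cluster_table(pool: clustering.PosePool,
                        cset: clustering.ClusterSet, path) -> None:
    lines = ["# cluster_id size rep_run_id rep_pose_id rep_total"]
    for ci, cl in enumerate(cset.clusters, start=1):
        rep = pool.entries[cl.representative]
        lines.append(f"{ci} {len(cl.members)} {rep.run_id} {rep.pose_id} "
                     f"{rep.total:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def summary_plot_data(poses: list[DockPose], bins: int = 50) -> dict:
    """Histogram tables (bin edges + counts) of each energy term."""
    if not poses:
        raise ValueError("no scored poses to summarise")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    out = {}
    for term in ("ele", "desolv", "vdw", "total"):
        values = np.array([getattr(p.energies, term) for p in poses])
        counts, edges = np.histogram(values, bins=bins)
        out[term] = (edges, counts)
    return out


# ---------------------------------------------------------------- running

def _prepare(structure: Structure) -> Structure:
    return structure if structure.annotated else assign_forcefield(structure)


def run_single(protein: Structure, dna: Structure, config: RunConfig,
               outdir, run_id: int = 1,
               rotation_seed: int | None = None) -> clustering.RunRecord:
    """One docking execution; writes poses.tsv, scored.tsv and top models.

    If ``rotation_seed`` is given, both inputs are first rotated about their
    centroids by a seeded uniform random rotation (recorded in
    rotation.json so multi-run pools can be merged in a common frame).
    """
    outdir = Path(outdir)
    run_dir = outdir / f"run_{run_id}"
    run_dir.mkdir(parents=True, exist_ok=True)
    try:
        stage = "input preparation"
        protein = _prepare(protein)
        dna = _prepare(dna)
        rot = None
        if rotation_seed is not None:
            rot = random_rotation_matrix(rotation_seed)
            protein = protein.with_coords(
                transform_about(protein.coords, rot, protein.centroid()))
            dna = dna.with_coords(
                transform_about(dna.coords, rot, dna.centroid()))
        receptor, ligand = sampling.choose_receptor(protein, dna)

        stage = "sampling"
        spec = sampling.make_gridspec(receptor, ligand, cell=config.cell,
                                      surface_thickness=config.surface_thickness)
        rotations = sampling.generate_rotations(config.rotation_step)
        poses = sampling.sample(receptor, ligand, spec, rotations,
                                keep_per_rotation=config.keep_per_rotation,
                                total_keep=config.total_keep, run_id=run_id)
        write_transform_table(poses, run_dir / "poses.tsv")

        stage = "scoring"
        restraints = (parse_restraints(config.restraints_path)
                      if config.restraints_path else None)
        energy_mod.score_poses(receptor, ligand, poses, scheme=config.scheme,
                               restraints=restraints)
        write_energy_table(poses, run_dir / "scored.tsv")

        stage = "model output"
        ranked = energy_mod.rank_poses(poses)
        top_dir = run_dir / "top100"
        top_dir.mkdir(exist_ok=True)
        for rank, p in enumerate(ranked[:config.n_top_models], start=1):
            posed = ligand.with_coords(pose_coords(ligand, p))
            write_pdb(concat_structures(receptor, posed),
                      top_dir / f"model_{rank}.pdb")

        record = {
            "run_id": run_id,
            "rotation_seed": rotation_seed,
            "rotation": None if rot is None else rot.tolist(),
            "receptor_center": receptor.centroid().tolist(),
            "receptor_moltype": receptor.moltype,
        }
        (run_dir / "rotation.json").write_text(json.dumps(record, indent=1))
    except Exception as exc:
        shutil.rmtree(run_dir, ignore_errors=True)
        raise RuntimeError(f"docking run {run_id} failed at stage "
                           f"'{stage}': {exc}") from exc

    return clustering.RunRecord(run_id=run_id, poses=poses, ligand=ligand,
                                receptor_rotation=rot,
                                receptor_center=receptor.centroid())


def run_merged(protein: Structure, dna: Structure, config: RunConfig,
               outdir):
    """n_runs independent executions → merge top models → GROMOS clustering.

    Returns ``(pool, cluster_set, representatives)`` where representatives
    are pool entries sorted ascending by total score.  Writes
    merged/clusters.tsv and merged/top100 representative models.
    """
    outdir = Path(outdir)
    seeds = config.run_seeds()
    records = []
    for k in range(config.n_runs):
        rotation_seed = seeds[k] if (config.n_runs > 1 or
                                     config.initial_rotation) else None
        records.append(run_single(protein, dna, config, outdir,
                                  run_id=k + 1, rotation_seed=rotation_seed))

    pool = clustering.merge_runs(records, top_per_run=config.top_per_run)
    matrix = clustering.pairwise_lrmsd(pool)
    cset = clustering.gromos_cluster(matrix, cutoff=config.cluster_cutoff,
                                     scores=pool.scores())
    merged_dir = outdir / "merged"
    merged_dir.mkdir(parents=True, exist_ok=True)
    write_cluster_table(pool, cset, merged_dir / "clusters.tsv")

    reps = sorted((pool.entries[c.representative] for c in cset.clusters),
                  key=lambda e: (e.total, e.run_id, e.pose_id))
    # representative models in the canonical receptor frame of the inputs
    protein_a = _prepare(protein)
    dna_a = _prepare(dna)
    receptor, ligand = sampling.choose_receptor(protein_a, dna_a)
    top_dir = merged_dir / "top100"
    top_dir.mkdir(exist_ok=True)
    for rank, entry in enumerate(reps[:config.n_top_models], start=1):
        posed = ligand.with_coords(entry.coords)
        write_pdb(concat_structures(receptor, posed),
                  top_dir / f"model_{rank}.pdb")
    return pool, cset, reps
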