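"""Multi-run pose merging and GROMOS clustering on ligand RMSD.

After several docking runs started from different random initial rotations,
the best-scoring models of every run are merged into one pool expressed in a
common receptor frame, the pairwise ligand-RMSD (L-RMSD) matrix is computed,
and redundancy is removed with the GROMOS algorithm: repeatedly take the pose
with the most neighbours within the cutoff (default 4.0 Å) together with
those neighbours as a cluster.  The lowest-scoring (best) member represents
each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import DockPose, pose_coords
from .structure import Structure

DEFAULT_CLUSTER_CUTOFF = 4.0  # Å L-RMSD
DEFAULT_TOP_PER_RUN = 100


@dataclass
class PoolEntry:
    """One pooled pose: ligand coordinates in the common receptor frame."""

    run_id: int
    pose_id: int
    total: float
    coords: np.ndarray  # (n_ligand_atoms, 3)


@dataclass
class PosePool:
    entries: list[PoolEntry]
    source_runs: int

    def __len__(self) -> int:
        return len(self.entries)

    def scores(self) -> np.ndarray:
        return np.array([e.total for e in self.entries])


@dataclass
class Cluster:
    members: list[int]         # pool indices
    representative: int        # pool index, min total score among members


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    cutoff: float


@dataclass
class RunRecord:
    """One docking run plus the record needed to merge it with others.

    ``rotation`` is the initial random rotation applied to both input
    structures (about their own centroids) before this run; ``None`` means
    the run used the canonical (unrotated) inputs.
    """

    run_id: int
    poses: list[DockPose]          # scored
    ligand: Structure              # the (possibly rotated) ligand this run docked
    receptor_rotation: np.ndarray | None  # 3x3, or None for identity
    receptor_center: np.ndarray | None = None


def pairwise_lrmsd(pool: PosePool) -> np.ndarray:
    """Symmetric L-RMSD matrix over all pooled ligand coordinate sets.

    Receptors are already superposed (common frame), so this is the plain
    per-atom RMSD, computed for all pairs at once via the Gram-matrix
    identity Σ|xᵢ−xⱼ|² = |xᵢ|² + |xⱼ|² − 2 xᵢ·xⱼ.
    """
    n = len(pool)
    if n == 0:
        return np.zeros((0, 0))
    m = pool.entries[0].coords.shape[0]
    for e in pool.entries:
        if e.coords.shape[0] != m:
            raise ValueError("ligand atom count mismatch across pool entries")
    X = np.stack([e.coords.ravel() for e in pool.entries])  # (n, 3m)
    sq = np.sum(X * X, axis=1)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)) / m
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def gromos_cluster(matrix: np.ndarray, cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                   scores: np.ndarray | None = None) -> ClusterSet:
    """Greedy GROMOS clustering of a symmetric distance matrix.

    Neighbour = distance ≤ cutoff (inclusive).  The pose with the most
    remaining neighbours seeds each cluster (ties → lower score, then lower
    index); representatives are the minimum-score members.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n and (np.abs(matrix - matrix.T).max() > 1e-9
              or np.abs(np.diag(matrix)).max() > 1e-9):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    scores = np.zeros(n) if scores is None else np.asarray(scores, float)

    neighbors = matrix <= cutoff
    alive = np.ones(n, dtype=bool)
    clusters = []
    while alive.any():
        counts = (neighbors & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        best = counts.max()
        cand = np.flatnonzero((counts == best) & alive)
        # ties: lower total score, then lower pose index
        seed = cand[np.lexsort((cand, scores[cand]))[0]]
        members = np.flatnonzero(neighbors[seed] & alive)
        rep_pos = np.lexsort((members, scores[members]))[0]
        clusters.append(Cluster(members=[int(i) for i in members],
                                representative=int(members[rep_pos])))
        alive[members] = False
    return ClusterSet(clusters=clusters, cutoff=cutoff)


def merge_runs(run_records: list[RunRecord],
               top_per_run: int = DEFAULT_TOP_PER_RUN) -> PosePool:
    """Union of each run's best-scoring poses, mapped to one receptor frame.

    Each run's posed ligand coordinates are expressed in the canonical
    receptor frame by inverting that run's initial random rotation (applied
    about the receptor centroid), so pose pools from independent executions
    are directly comparable.
    """
    entries = []
    for rec in run_records:
        if rec.receptor_rotation is not None and rec.receptor_center is None:
            raise ValueError(f"run {rec.run_id}: initial-rotation record "
                             "missing the receptor center")
        scored = [p for p in rec.poses if p.energies is not None]
        if len(scored) != len(rec.poses):
            raise ValueError(f"run {rec.run_id} contains unscored poses")
        best = sorted(scored, key=lambda p: (p.energies.total, p.pose_id))
        for p in best[:top_per_run]:
            coords = pose_coords(rec.ligand, p)
            if rec.receptor_rotation is not None:
                c = rec.receptor_center
                coords = (coords - c) @ rec.receptor_rotation + c
            entries.append(PoolEntry(run_id=rec.run_id, pose_id=p.pose_id,
                                     total=float(p.energies.total),
                                     coords=coords))
    return PosePool(entries=entries, source_runs=len(run_records))
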