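"""Rigid-body pose generation by FFT shape-complementarity search.

The classic grid-correlation scheme: both molecules are discretised on a
cubic grid (default 0.7 Å cells).  Receptor cells are marked surface (+1) or
core (−15, a steric penalty); ligand cells are all +1.  For every ligand
orientation on a systematic Euler-angle sweep (default 12° spacing, duplicate
orientations removed) the shape-correlation score of every grid translation
is evaluated at once by forward/inverse FFT; the best few translations per
rotation are kept and the pooled candidates are ranked by grid score.

The fixed molecule (receptor) is the one with the longer maximal atom-pair
distance; the other is rotated/translated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .geometry import euler_to_matrix, random_rotation_matrix, transform_about
from .structure import Structure, max_span

logger = logging.getLogger("dnadock")

DEFAULT_CELL = 0.7             # Å
DEFAULT_SURFACE_THICKNESS = 1.3  # Å
DEFAULT_ROTATION_STEP = 12.0   # degrees
DEFAULT_KEEP_PER_ROTATION = 3
DEFAULT_TOTAL_KEEP = 10000
CORE_PENALTY = -15
DEFAULT_MARGIN = 1.0           # Å


@dataclass
class GridSpec:
    """Cubic grid geometry for the correlation search."""

    cell: float = DEFAULT_CELL
    surface_thickness: float = DEFAULT_SURFACE_THICKNESS
    dims: tuple[int, int, int] = (0, 0, 0)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    core_penalty: int = CORE_PENALTY

    def cell_center(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.cell


@dataclass
class DiscreteGrid:
    spec: GridSpec
    values: np.ndarray  # 3-D int array


@dataclass
class RotationSet:
    step: float
    eulers: list[tuple[float, float, float]]
    matrices: np.ndarray  # (n, 3, 3)

    def __len__(self) -> int:
        return len(self.eulers)


@dataclass
class DockPose:
    """One rigid-body placement of the ligand in the receptor frame.

    Model coordinates are reproduced exactly by
    ``R(euler)·(x − centroid) + centroid + translation`` applied to the
    canonical ligand.
    """

    run_id: int
    pose_id: int
    euler: tuple[float, float, float]   # degrees, intrinsic z-y-z
    translation: np.ndarray             # Å, ligand-centroid displacement
    grid_score: int
    energies: object | None = None      # EnergyBreakdown, filled by scoring


def pose_coords(ligand: Structure, pose: DockPose) -> np.ndarray:
    """Ligand coordinates under a pose transform (canonical ligand input)."""
    R = euler_to_matrix(*pose.euler)
    return transform_about(ligand.coords, R, ligand.centroid(),
                           np.asarray(pose.translation, float))


def choose_receptor(a: Structure, b: Structure) -> tuple[Structure, Structure]:
    """The molecule with the longer maximal atom-pair span is held fixed."""
    if max_span(a) >= max_span(b):  # tie → first argument
        return a, b
    return b, a


def random_initial_rotation(s: Structure, seed: int) -> Structure:
    """Rotate a structure about its centroid by a seeded uniform rotation."""
    R = random_rotation_matrix(seed)
    return s.with_coords(transform_about(s.coords, R, s.centroid()))


def smooth_dim(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}."""
    if n < 1:
        return 1
    m = n
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


def make_gridspec(receptor: Structure, ligand: Structure,
                  cell: float = DEFAULT_CELL,
                  surface_thickness: float = DEFAULT_SURFACE_THICKNESS,
                  margin: float = DEFAULT_MARGIN,
                  core_penalty: int = CORE_PENALTY) -> GridSpec:
    """Grid sized so circular correlation has no wrap-around contamination.

    The occupied extent of a molecule exceeds its atom span by twice the
    largest vdW radius (plus the surface layer), so that inflation is added
    on top of the user margin before rounding dims up to the next
    2/3/5-smooth integer for FFT efficiency.
    """
    if not (receptor.annotated and ligand.annotated):
        raise ValueError("structures must be force-field annotated before "
                         "grid discretisation")
    rmax = float(max(receptor.vdw_rstar.max(), ligand.vdw_rstar.max()))
    extent = (max_span(receptor) + max_span(ligand)
              + 2.0 * (margin + rmax + surface_thickness))
    n = smooth_dim(math.ceil(extent / cell))
    origin = receptor.centroid() - (n - 1) * cell / 2.0
    return GridSpec(cell=cell, surface_thickness=surface_thickness,
                    dims=(n, n, n), origin=origin, core_penalty=core_penalty)


def _stamp_occupancy(coords: np.ndarray, radii: np.ndarray,
                     spec: GridSpec) -> np.ndarray:
    """Boolean grid: cells whose center lies within an atom's vdW radius."""
    dims = spec.dims
    occ = np.zeros(dims, dtype=bool)
    if len(coords) == 0:
        return occ
    cell = spec.cell
    rmax = float(radii.max())
    k = int(math.floor(rmax / cell)) + 1
    rng = np.arange(-k, k + 1)
    offsets = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"),
                       axis=-1).reshape(-1, 3)
    i0 = np.rint((coords - spec.origin) / cell).astype(int)
    cand = i0[:, None, :] + offsets[None, :, :]            # (n_atoms, m, 3)
    centers = spec.origin + cand * cell
    d2 = np.sum((centers - coords[:, None, :]) ** 2, axis=-1)
    mask = d2 <= (radii[:, None] ** 2)
    sel = cand[mask]
    if sel.size and (sel.min() < 0 or (sel >= np.asarray(dims)).any()):
        raise ValueError("structure exceeds grid extent; increase dims/margin")
    occ[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return occ


def _erosion_ball(spec: GridSpec) -> np.ndarray:
    """Structuring element: cell offsets within surface_thickness (Å)."""
    k = int(math.floor(spec.surface_thickness / spec.cell))
    rng = np.arange(-k, k + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    d = np.sqrt(dx**2 + dy**2 + dz**2) * spec.cell
    return d <= spec.surface_thickness


def discretize(s: Structure, spec: GridSpec, role: str) -> DiscreteGrid:
    """Discretise a structure: ligand all-occupied=1; receptor surface=1,
    core=core_penalty (occupied cells not within surface_thickness of an
    empty cell)."""
    if role not in ("receptor", "ligand"):
        raise ValueError("role must be 'receptor' or 'ligand'")
    if not s.annotated:
        raise ValueError("structure must be annotated (vdW radii needed)")
    occ = _stamp_occupancy(s.coords, s.vdw_rstar, spec)
    values = occ.astype(np.int32)
    if role == "receptor":
        from scipy.ndimage import binary_erosion
        core = binary_erosion(occ, structure=_erosion_ball(spec))
        values[core] = spec.core_penalty
    return DiscreteGrid(spec=spec, values=values)


def generate_rotations(step: float = DEFAULT_ROTATION_STEP) -> RotationSet:
    """Systematic z-y-z Euler lattice with duplicate orientations removed.

    φ and ψ sweep [0, 360) and θ [0, 180] at the given spacing; orientations
    that produce the same rotation matrix (poles of θ) are deduplicated,
    keeping the first occurrence in lattice order.
    """
    if step <= 0:
        raise ValueError("rotation step must be positive")
    if abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ValueError("rotation step must divide 360 evenly")
    n = int(round(360.0 / step))
    phis = [i * step for i in range(n)]
    thetas = [i * step for i in range(n // 2 + 1)]  # [0, 180]
    seen: dict[tuple, int] = {}
    eulers: list[tuple[float, float, float]] = []
    mats: list[np.ndarray] = []
    for phi in phis:
        for theta in thetas:
            for psi in phis:
                R = euler_to_matrix(phi, theta, psi)
                key = tuple(np.rint(R.ravel() * 1e7).astype(np.int64))
                if key in seen:
                    continue
                seen[key] = len(eulers)
                eulers.append((phi, theta, psi))
                mats.append(R)
    return RotationSet(step=step, eulers=eulers, matrices=np.array(mats))


def fft_correlate(receptor: DiscreteGrid, ligand: DiscreteGrid) -> np.ndarray:
    """Integer circular cross-correlation over all grid translations.

    ``score[t] = Σ_y L[y]·R[y + t]`` — the overlap score with the ligand
    occupancy shifted by +t cells, computed via forward/inverse FFT and
    rounded to the nearest integer.
    """
    if receptor.values.shape != ligand.values.shape:
        raise ValueError("receptor and ligand grids must share dims")
    FR = scipy.fft.rfftn(receptor.values.astype(np.float64))
    FL = scipy.fft.rfftn(ligand.values.astype(np.float64))
    corr = scipy.fft.irfftn(np.conj(FL) * FR, s=receptor.values.shape)
    return np.rint(corr).astype(np.int64)


def _signed_shifts(flat_idx: np.ndarray, dims) -> np.ndarray:
    idx = np.stack(np.unravel_index(flat_idx, dims), axis=-1).astype(int)
    dims = np.asarray(dims)
    return np.where(idx > dims // 2, idx - dims, idx)


def sample(receptor: Structure, ligand: Structure,
           spec: GridSpec | None = None,
           rotations: RotationSet | None = None,
           keep_per_rotation: int = DEFAULT_KEEP_PER_ROTATION,
           total_keep: int = DEFAULT_TOTAL_KEEP,
           run_id: int = 1) -> list[DockPose]:
    """Full rigid-body search: rotate, re-discretise, correlate, pool, rank.

    Returns up to ``total_keep`` poses sorted by grid score (descending),
    ties broken by rotation index then translation (lexicographic).
    """
    if spec is None:
        spec = make_gridspec(receptor, ligand)
    if rotations is None:
        rotations = generate_rotations()
    rec_grid = discretize(receptor, spec, "receptor")
    FR = scipy.fft.rfftn(rec_grid.values.astype(np.float64))
    shape = rec_grid.values.shape

    lig_coords0 = ligand.coords
    c0 = ligand.centroid()
    center_idx = np.asarray(spec.dims) // 2
    center_pos = spec.cell_center(center_idx)
    radii = ligand.vdw_rstar

    candidates = []  # (-score, rot_idx, shift tuple, translation)
    for ri, R in enumerate(rotations.matrices):
        rot = (lig_coords0 - c0) @ R.T + center_pos
        occ = _stamp_occupancy(rot, radii, spec)
        FL = scipy.fft.rfftn(occ.astype(np.float64))
        corr = scipy.fft.irfftn(np.conj(FL) * FR, s=shape)
        flat = corr.ravel()
        k = min(keep_per_rotation, flat.size)
        top = np.argpartition(flat, -k)[-k:]
        scores = np.rint(flat[top]).astype(np.int64)
        shifts = _signed_shifts(top, shape)
        for s_int, sh in zip(scores, shifts):
            t = center_pos + sh * spec.cell - c0
            candidates.append((-int(s_int), ri, tuple(int(x) for x in sh), t))

    if not candidates:
        logger.warning("grid too small for any placement; no poses generated")
        return []
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    poses = []
    for i, (neg_score, ri, _sh, t) in enumerate(candidates[:total_keep]):
        poses.append(DockPose(run_id=run_id, pose_id=i + 1,
                              euler=rotations.eulers[ri],
                              translation=np.asarray(t, float),
                              grid_score=-neg_score))
    return poses
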