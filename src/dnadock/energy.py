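"""Pose rescoring: electrostatics + desolvation + van der Waals.

The composite score of a pose is

    total = w_ele·E_ele + w_desolv·E_desolv + w_vdw·E_vdw + E_restraint

with the default weighting (1, 1, 0.1).  Published variants are exposed as
named schemes: ``no_desolv`` (1, 0, 0.1), ``vdw1`` (vdW weight raised to
1.0) and ``ele_only`` (1, 0, 0).

Term definitions (all pairwise sums run over *inter*-molecular atom pairs):

* electrostatics — Coulomb with distance-dependent dielectric ε(r) = 4r:
  E = Σ 332.0·qᵢqⱼ/(4r²), each pair clamped to ±1.0 kcal/mol.
* van der Waals — AMBER 6-12 form εᵢⱼ[(Rᵢⱼ/r)¹² − 2(Rᵢⱼ/r)⁶] with
  Lorentz–Berthelot combination (Rᵢⱼ = rᵢ* + rⱼ*, εᵢⱼ = √(εᵢεⱼ)); each pair
  clamped at +1.0 kcal/mol (no lower clamp).
* desolvation — Σ aspᵢ·ΔSASAᵢ over atoms of both molecules, where ΔSASA is
  the accessible area buried on complexation (Shrake–Rupley, probe 1.4 Å).

Pair distances are floored at 1.0 Å to avoid singularities on degenerate
input; pairs beyond the cutoff (default 12 Å) contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .sampling import DockPose, pose_coords
from .structure import Structure

COULOMB_K = 332.0          # kcal·Å/(mol·e²)
ELE_CLAMP = 1.0            # kcal/mol, symmetric per-pair clamp
VDW_CLAMP = 1.0            # kcal/mol, upper per-pair clamp
DEFAULT_CUTOFF = 12.0      # Å
MIN_PAIR_DISTANCE = 1.0    # Å
PROBE_RADIUS = 1.4         # Å
SASA_POINTS = 960


@dataclass(frozen=True)
class WeightScheme:
    name: str
    w_ele: float
    w_desolv: float
    w_vdw: float


SCHEMES = {
    "default": WeightScheme("default", 1.0, 1.0, 0.1),
    "no_desolv": WeightScheme("no_desolv", 1.0, 0.0, 0.1),
    "vdw1": WeightScheme("vdw1", 1.0, 1.0, 1.0),
    "ele_only": WeightScheme("ele_only", 1.0, 0.0, 0.0),
}


def get_scheme(name: str) -> WeightScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown weighting scheme {name!r}; "
                         f"choose from {sorted(SCHEMES)}") from None


@dataclass
class EnergyBreakdown:
    ele: float
    desolv: float
    vdw: float
    restraint: float
    total: float
    scheme: str = "default"


def _check_annotated(*structures: Structure) -> None:
    for s in structures:
        if not s.annotated:
            raise ValueError("structure must be force-field annotated")


def _pairs(a_coords, b_coords, cutoff):
    """Inter-molecular pairs within cutoff: (i, j, distance) arrays."""
    if cutoff is None:
        i, j = np.meshgrid(np.arange(len(a_coords)), np.arange(len(b_coords)),
                           indexing="ij")
        i, j = i.ravel(), j.ravel()
    else:
        pairs = cKDTree(a_coords).query_ball_tree(cKDTree(b_coords), cutoff)
        i = np.concatenate([[ia] * len(js) for ia, js in enumerate(pairs)]
                           or [[]]).astype(int)
        j = np.concatenate([js for js in pairs if js] or [[]]).astype(int)
    if len(i) == 0:
        return i, np.asarray(j, int), np.zeros(0)
    d = np.linalg.norm(a_coords[i] - b_coords[j], axis=1)
    return i, j, d


def electrostatics(receptor: Structure, posed_ligand: Structure,
                   cutoff: float | None = DEFAULT_CUTOFF) -> float:
    _check_annotated(receptor, posed_ligand)
    i, j, d = _pairs(receptor.coords, posed_ligand.coords, cutoff)
    if len(i) == 0:
        return 0.0
    d = np.maximum(d, MIN_PAIR_DISTANCE)
    e = COULOMB_K * receptor.charges[i] * posed_ligand.charges[j] / (4.0 * d * d)
    return float(np.clip(e, -ELE_CLAMP, ELE_CLAMP).sum())


def vdw(receptor: Structure, posed_ligand: Structure,
        cutoff: float | None = DEFAULT_CUTOFF) -> float:
    _check_annotated(receptor, posed_ligand)
    i, j, d = _pairs(receptor.coords, posed_ligand.coords, cutoff)
    if len(i) == 0:
        return 0.0
    d = np.maximum(d, MIN_PAIR_DISTANCE)
    rij = receptor.vdw_rstar[i] + posed_ligand.vdw_rstar[j]
    eij = np.sqrt(receptor.vdw_eps[i] * posed_ligand.vdw_eps[j])
    x6 = (rij / d) ** 6
    e = eij * (x6 * x6 - 2.0 * x6)
    return float(np.minimum(e, VDW_CLAMP).sum())


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=True)
def _count_accessible(coords, exp, pts, subset, indptr, indices):
    """Accessible test-point counts per subset atom (early-exit burial)."""
    m = subset.size
    k = pts.shape[0]
    out = np.zeros(m, dtype=np.int64)
    for a in range(m):
        i = subset[a]
        cnt = 0
        for p in range(k):
            px = coords[i, 0] + exp[i] * pts[p, 0]
            py = coords[i, 1] + exp[i] * pts[p, 1]
            pz = coords[i, 2] + exp[i] * pts[p, 2]
            buried = False
            for q in range(indptr[a], indptr[a + 1]):
                j = indices[q]
                dx = px - coords[j, 0]
                dy = py - coords[j, 1]
                dz = pz - coords[j, 2]
                if dx * dx + dy * dy + dz * dz < exp[j] * exp[j]:
                    buried = True
                    break
            if not buried:
                cnt += 1
        out[a] = cnt
    return out


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral point set on the unit sphere."""
    k = np.arange(n)
    z = (2.0 * k + 1.0) / n - 1.0
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = k * golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_from_arrays(coords: np.ndarray, radii: np.ndarray,
                     probe: float = PROBE_RADIUS, n_points: int = SASA_POINTS,
                     subset: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Shrake–Rupley), Å².

    Areas are measured on the expanded sphere of radius rᵢ + probe.  If
    ``subset`` (atom indices) is given, only those atoms' areas are computed
    (their neighbours are still drawn from the full atom set) and an array of
    that length is returned.
    """
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    radii = np.asarray(radii, float)
    pts = _spiral_points(n_points)
    exp = radii + probe
    tree = cKDTree(coords)
    idx = np.arange(len(coords)) if subset is None else np.asarray(subset, int)
    # neighbour lists (CSR): atoms j that can bury points of atom i, i.e.
    # |xi - xj| < exp_i + exp_j
    raw = tree.query_ball_point(coords[idx], exp[idx] + exp.max())
    lens = np.fromiter((len(r) for r in raw), dtype=np.int64, count=len(raw))
    if lens.sum() == 0:
        indices = np.zeros(0, dtype=np.int64)
        indptr = np.zeros(len(idx) + 1, dtype=np.int64)
    else:
        flat = np.concatenate([np.asarray(r, dtype=np.int64) for r in raw])
        src = np.repeat(idx, lens)
        group = np.repeat(np.arange(len(idx)), lens)
        d2 = np.sum((coords[src] - coords[flat]) ** 2, axis=1)
        keep = (flat != src) & (d2 < (exp[src] + exp[flat]) ** 2)
        indices = flat[keep]
        counts = np.bincount(group[keep], minlength=len(idx))
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    counts = _count_accessible(coords, exp, pts, idx.astype(np.int64),
                               indptr, indices)
    return 4.0 * np.pi * exp[idx] ** 2 * counts / n_points


def sasa(s: Structure, probe: float = PROBE_RADIUS,
         n_points: int = SASA_POINTS) -> np.ndarray:
    """Per-atom SASA of one molecule (radii = vdW r*)."""
    _check_annotated(s)
    return sasa_from_arrays(s.coords, s.vdw_rstar, probe, n_points)


def desolvation(receptor: Structure, posed_ligand: Structure,
                probe: float = PROBE_RADIUS, n_points: int = SASA_POINTS,
                receptor_sasa: np.ndarray | None = None,
                ligand_sasa: np.ndarray | None = None) -> float:
    """Σ aspᵢ·ΔSASAᵢ over all atoms of both molecules.

    Only atoms close enough to the partner molecule for their neighbour set
    to change are recomputed in the complex — ΔSASA of every other atom is
    exactly zero, so the result is identical to a full recomputation.
    Free-molecule areas can be passed in (they are pose-invariant).
    """
    _check_annotated(receptor, posed_ligand)
    if receptor_sasa is None:
        receptor_sasa = sasa(receptor, probe, n_points)
    if ligand_sasa is None:
        ligand_sasa = sasa(posed_ligand, probe, n_points)

    nr = len(receptor)
    coords = np.vstack([receptor.coords, posed_ligand.coords])
    radii = np.concatenate([receptor.vdw_rstar, posed_ligand.vdw_rstar])
    asp = np.concatenate([receptor.asp, posed_ligand.asp])
    alone = np.concatenate([receptor_sasa, ligand_sasa])

    reach = 2.0 * (radii.max() + probe)
    tr = cKDTree(receptor.coords)
    tl = cKDTree(posed_ligand.coords)
    near_r = sorted({i for i, js in
                     enumerate(tr.query_ball_tree(tl, reach)) if js})
    near_l = sorted({j for j, isx in
                     enumerate(tl.query_ball_tree(tr, reach)) if isx})
    subset = np.asarray(near_r + [nr + j for j in near_l], dtype=int)
    if len(subset) == 0:
        return 0.0
    complex_area = sasa_from_arrays(coords, radii, probe, n_points,
                                    subset=subset)
    delta = alone[subset] - complex_area
    return float(np.sum(asp[subset] * delta))


def score_pose(receptor: Structure, ligand: Structure, pose: DockPose,
               scheme: WeightScheme | str = "default",
               restraints=None, cutoff: float | None = DEFAULT_CUTOFF,
               receptor_sasa: np.ndarray | None = None,
               ligand_sasa: np.ndarray | None = None) -> EnergyBreakdown:
    """Apply the pose to the canonical ligand and evaluate all terms."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    posed = ligand.with_coords(pose_coords(ligand, pose))
    e = electrostatics(receptor, posed, cutoff)
    v = vdw(receptor, posed, cutoff)
    # the desolvation term is the expensive one; skip it when its weight is 0
    ds = 0.0
    if scheme.w_desolv != 0.0:
        ds = desolvation(receptor, posed, receptor_sasa=receptor_sasa,
                         ligand_sasa=ligand_sasa)
    rst = 0.0
    if restraints:
        from .restraints import restraint_energy
        rst = restraint_energy(restraints, receptor, posed)
    total = (scheme.w_ele * e + scheme.w_desolv * ds + scheme.w_vdw * v + rst)
    return EnergyBreakdown(ele=e, desolv=ds, vdw=v, restraint=rst,
                           total=total, scheme=scheme.name)


def score_poses(receptor: Structure, ligand: Structure,
                poses: list[DockPose], scheme: WeightScheme | str = "default",
                restraints=None,
                cutoff: float | None = DEFAULT_CUTOFF) -> list[DockPose]:
    """Score a pose list in place (free-molecule SASA computed once)."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    rec_sasa = sasa(receptor) if scheme.w_desolv != 0.0 else np.zeros(len(receptor))
    lig_sasa = sasa(ligand) if scheme.w_desolv != 0.0 else np.zeros(len(ligand))
    for pose in poses:
        pose.energies = score_pose(receptor, ligand, pose, scheme,
                                   restraints=restraints, cutoff=cutoff,
                                   receptor_sasa=rec_sasa,
                                   ligand_sasa=lig_sasa)
    return poses


def rank_poses(poses: list[DockPose],
               scheme: WeightScheme | str | None = None) -> list[DockPose]:
    """Ascending by total score (lower is better); stable pose_id tie-break."""
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    for p in poses:
        if p.energies is None:
            raise ValueError(f"pose {p.pose_id} has not been scored")
        if scheme is not None and p.energies.scheme != scheme.name:
            raise ValueError(f"pose {p.pose_id} scored under "
                             f"{p.energies.scheme!r}, expected {scheme.name!r}")
    return sorted(poses, key=lambda p: (p.energies.total, p.pose_id))
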