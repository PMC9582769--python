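"""Synthetic structures and pose sets for testing every docking stage.

These generators use only residues covered by the shipped parameter
templates (poly-alanine helices; canonical B-DNA duplexes), so fixtures
annotate with zero unmatched atoms and round-trip through PDB I/O cleanly.
"""

from __future__ import annotations

import numpy as np

from .bdna import build_bdna
from .geometry import euler_to_matrix, matrix_to_euler
from .sampling import DockPose, choose_receptor, pose_coords
from .structure import Structure, concat_structures

HELIX_RISE = 1.5       # Å per residue, ideal α-helix
HELIX_TWIST = 100.0    # degrees per residue
HELIX_RADIUS = 2.3     # Å, CA radius


def toy_protein(n_res: int, chain: str = "P") -> Structure:
    """Ideal poly-alanine α-helix (backbone N/CA/C/O plus CB, 5 heavy
    atoms per residue)."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    names, resnames, chains, resseqs, coords, elements = [], [], [], [], [], []
    for i in range(n_res):
        th = np.deg2rad(HELIX_TWIST * i)
        u = np.array([np.cos(th), np.sin(th), 0.0])      # radial, outward
        v = np.array([-np.sin(th), np.cos(th), 0.0])     # azimuthal
        ca = HELIX_RADIUS * u + np.array([0.0, 0.0, HELIX_RISE * i])
        t = (0.3 * v + np.array([0.0, 0.0, 1.0]))
        t /= np.linalg.norm(t)
        d_n = (-t + 0.4 * u) / np.linalg.norm(-t + 0.4 * u)
        d_c = (t + 0.4 * u) / np.linalg.norm(t + 0.4 * u)
        d_o = np.cross(d_c, u)
        d_o /= np.linalg.norm(d_o)
        atoms = {
            "N": ca + 1.46 * d_n,
            "CA": ca,
            "C": ca + 1.52 * d_c,
            "O": ca + 1.52 * d_c + 1.23 * d_o,
            "CB": ca + 1.53 * u,
        }
        for name, xyz in atoms.items():
            names.append(name)
            resnames.append("ALA")
            chains.append(chain)
            resseqs.append(i + 1)
            coords.append(xyz)
            elements.append(name[0])
    return Structure(names, resnames, chains, resseqs, np.array(coords),
                     elements, "protein")


def toy_dna(seq: str) -> Structure:
    """Canonical B-DNA duplex for a sequence (chains D/E)."""
    return build_bdna(seq, chain_ids=("D", "E"))


def _min_interdistance(a: np.ndarray, b: np.ndarray) -> float:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def planted_complex(protein: Structure, dna: Structure,
                    transform: tuple | None = None,
                    clash_free: bool = True,
                    contact: float = 3.0):
    """Place the ligand at a known rigid transform; record the ground truth.

    ``transform`` is ``(euler_degrees, translation)`` applied to the ligand
    (the smaller-span molecule) about its centroid.  If omitted, a snug
    side-by-side placement along x is constructed with the minimum
    inter-molecular heavy-atom distance at ``contact`` Å (vdW touching, so
    shape-complementarity search can recover the pose).  Returns
    ``(complex_structure, receptor, ligand, truth_pose)``.
    """
    from .structure import max_span

    receptor, ligand = choose_receptor(protein, dna)
    if transform is None:
        far = (max_span(receptor) + max_span(ligand)) / 2.0 + 10.0
        base = (receptor.centroid() - ligand.centroid())

        def mind(shift: float) -> float:
            t = base + np.array([shift, 0.0, 0.0])
            return _min_interdistance(receptor.coords, ligand.coords + t)

        lo, hi = 0.0, far  # mind(hi) > contact; mind(lo) ~ overlapping
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if mind(mid) < contact:
                lo = mid
            else:
                hi = mid
        transform = ((0.0, 0.0, 0.0), base + np.array([hi, 0.0, 0.0]))
    euler, translation = transform
    truth = DockPose(run_id=0, pose_id=0, euler=tuple(float(a) for a in euler),
                     translation=np.asarray(translation, float),
                     grid_score=0)
    posed = ligand.with_coords(pose_coords(ligand, truth))
    if clash_free:
        d2 = np.sum((receptor.coords[:, None, :]
                     - posed.coords[None, :, :]) ** 2, axis=-1)
        dmin = float(np.sqrt(d2.min()))
        if dmin < 2.5:
            raise ValueError(f"clash_free placement violated: min "
                             f"inter-molecular distance {dmin:.2f} Å < 2.5 Å")
    return concat_structures(receptor, posed), receptor, ligand, truth


def planted_optimal_complex(protein: Structure, dna: Structure,
                            cell: float = 0.7,
                            surface_thickness: float = 1.3):
    """Plant the ligand at the identity-rotation grid-correlation optimum.

    The ground-truth pose is the best-scoring translation of the unrotated
    ligand on the shape-complementarity grid, so a correct sampler must
    reproduce it exactly (it is, by construction, the best identity-rotation
    candidate).  Used for transform-bookkeeping recovery tests.  Inputs must
    be force-field annotated.  Returns ``(complex, receptor, ligand, truth)``.
    """
    import numpy as np

    from .sampling import (_signed_shifts, _stamp_occupancy, discretize,
                           fft_correlate, make_gridspec)

    receptor, ligand = choose_receptor(protein, dna)
    spec = make_gridspec(receptor, ligand, cell=cell,
                         surface_thickness=surface_thickness)
    rec_grid = discretize(receptor, spec, "receptor")
    c0 = ligand.centroid()
    center_pos = spec.cell_center(np.asarray(spec.dims) // 2)
    occ = _stamp_occupancy(ligand.coords - c0 + center_pos,
                           ligand.vdw_rstar, spec)
    corr = fft_correlate(rec_grid,
                         type(rec_grid)(spec=spec, values=occ.astype(np.int32)))
    shift = _signed_shifts(np.array([int(corr.argmax())]), spec.dims)[0]
    translation = center_pos + shift * spec.cell - c0
    truth = DockPose(run_id=0, pose_id=0, euler=(0.0, 0.0, 0.0),
                     translation=translation,
                     grid_score=int(corr.max()))
    posed = ligand.with_coords(pose_coords(ligand, truth))
    return concat_structures(receptor, posed), receptor, ligand, truth


def pose_cloud(center_pose: DockPose, n: int, spread: float,
               seed: int) -> list[DockPose]:
    """n perturbed copies of a pose: Gaussian translations (σ = spread Å)
    and small random rotations (σ = spread degrees); spread 0 gives n
    identical poses."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    R0 = euler_to_matrix(*center_pose.euler)
    t0 = np.asarray(center_pose.translation, float)
    out = []
    for i in range(n):
        dt = rng.normal(0.0, spread, 3) if spread > 0 else np.zeros(3)
        if spread > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.normal(0.0, spread))
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            Rp = (np.eye(3) + np.sin(angle) * K
                  + (1 - np.cos(angle)) * K @ K)
        else:
            Rp = np.eye(3)
        out.append(DockPose(run_id=center_pose.run_id, pose_id=i + 1,
                            euler=matrix_to_euler(Rp @ R0),
                            translation=t0 + dt,
                            grid_score=center_pose.grid_score))
    return out
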