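"""Rigid-body geometry helpers: Euler rotations, pose transforms, Kabsch fit.

Convention used throughout the package: intrinsic z-y-z Euler angles in
degrees; rotations act about the ligand centroid, translation applied after
rotation (coords' = R·(x − c) + c + t).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "ZYZ"  # intrinsic z-y-z


def euler_to_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Rotation matrix for intrinsic z-y-z Euler angles in degrees."""
    return Rotation.from_euler(EULER_CONVENTION, [phi, theta, psi],
                               degrees=True).as_matrix()


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    phi, theta, psi = Rotation.from_matrix(R).as_euler(EULER_CONVENTION,
                                                       degrees=True)
    return float(phi), float(theta), float(psi)


def random_rotation_matrix(seed: int) -> np.ndarray:
    """Uniform random rotation (Haar measure), reproducible from the seed."""
    return Rotation.random(random_state=np.random.default_rng(int(seed))).as_matrix()


def transform_about(coords: np.ndarray, R: np.ndarray, center: np.ndarray,
                    translation=None) -> np.ndarray:
    """Rotate about ``center`` then translate: R·(x − c) + c + t."""
    out = (coords - center) @ R.T + center
    if translation is not None:
        out = out + translation
    return out


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal least-squares superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with coords' = mobile @ R.T + t.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("kabsch needs two equal coordinate sets of >= 3 atoms")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - cm @ R.T
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no superposition) RMSD between two coordinate sets."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
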