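import numpy as np
import pytest

from dnadock import (DockPose, GridSpec, choose_receptor, discretize,
                     fft_correlate, generate_rotations, make_gridspec,
                     max_span, pose_coords, random_initial_rotation, sample)
from dnadock.fixtures import planted_optimal_complex
from dnadock.geometry import euler_to_matrix, kabsch
from dnadock.sampling import DiscreteGrid, smooth_dim
from tests.conftest import random_annotated


# ------------------------------------------------------------ receptor choice

def test_choose_receptor_longest_span(helix6, duplex8):
    receptor, ligand = choose_receptor(helix6, duplex8)
    assert receptor.moltype == "dna"  # duplex span ≫ short helix span
    assert max_span(receptor) >= max_span(ligand)


def test_choose_receptor_tie_breaks_to_first(helix6):
    receptor, ligand = choose_receptor(helix6, helix6.copy())
    assert receptor is helix6


# ------------------------------------------------------ initial random rotation

def test_random_initial_rotation_reproducible_and_rigid(helix6):
    a = random_initial_rotation(helix6, seed=5)
    b = random_initial_rotation(helix6, seed=5)
    np.testing.assert_array_equal(a.coords, b.coords)
    # rigid: pairwise distances preserved
    d0 = np.linalg.norm(helix6.coords[:, None] - helix6.coords[None], axis=-1)
    d1 = np.linalg.norm(a.coords[:, None] - a.coords[None], axis=-1)
    np.testing.assert_allclose(d1, d0, atol=1e-9)
    np.testing.assert_allclose(a.centroid(), helix6.centroid(), atol=1e-9)
    c = random_initial_rotation(helix6, seed=6)
    assert np.abs(a.coords - c.coords).max() > 1e-3


# ------------------------------------------------------------- discretisation

def _brute_occupancy(coords, radii, spec):
    nx, ny, nz = spec.dims
    occ = np.zeros(spec.dims, dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                center = spec.origin + np.array([ix, iy, iz]) * spec.cell
                d = np.linalg.norm(coords - center, axis=1)
                occ[ix, iy, iz] = bool(np.any(d <= radii))
    return occ


def test_single_atom_occupancy_matches_brute_force():
    spec = GridSpec(cell=0.7, dims=(12, 12, 12),
                    origin=np.array([-4.0, -4.0, -4.0]))
    coords = np.array([[0.13, -0.2, 0.4]])
    radii = np.array([1.5])
    s = random_annotated(1, 0)
    s.coords = coords
    s.vdw_rstar = radii
    grid = discretize(s, spec, "ligand")
    brute = _brute_occupancy(coords, radii, spec)
    np.testing.assert_array_equal(grid.values.astype(bool), brute)
    assert grid.values.sum() == brute.sum()


def test_thin_rod_has_no_core_cells():
    spec = GridSpec(cell=0.7, surface_thickness=1.3, dims=(24, 24, 24),
                    origin=np.array([-8.0, -8.0, -8.0]))
    s = random_annotated(2, 1)
    s.coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 3.0]])
    s.vdw_rstar = np.array([1.6, 1.6])
    grid = discretize(s, spec, "receptor")
    assert (grid.values == spec.core_penalty).sum() == 0
    assert (grid.values == 1).sum() > 0


def test_receptor_core_inside_large_blob():
    spec = GridSpec(cell=0.7, surface_thickness=1.3, dims=(30, 30, 30),
                    origin=np.array([-10.0, -10.0, -10.0]))
    s = random_annotated(1, 2)
    s.coords = np.zeros((1, 3))
    s.vdw_rstar = np.array([5.0])
    grid = discretize(s, spec, "receptor")
    assert grid.values[15, 15, 15] == spec.core_penalty
    assert (grid.values == 1).sum() > 0


def test_structure_exceeding_grid_raises():
    spec = GridSpec(cell=0.7, dims=(8, 8, 8), origin=np.zeros(3))
    s = random_annotated(1, 3)
    s.coords = np.array([[30.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="grid extent"):
        discretize(s, spec, "ligand")


# ------------------------------------------------------------------ rotations

def _brute_rotation_dedup(step):
    n = int(round(360 / step))
    mats = []
    for phi in [i * step for i in range(n)]:
        for theta in [i * step for i in range(n // 2 + 1)]:
            for psi in [i * step for i in range(n)]:
                R = euler_to_matrix(phi, theta, psi)
                if not any(np.linalg.norm(R - M) < 1e-6 for M in mats):
                    mats.append(R)
    return mats


@pytest.mark.parametrize("step", [180.0, 120.0, 90.0])
def test_rotation_count_matches_exhaustive_dedup(step):
    rset = generate_rotations(step)
    oracle = _brute_rotation_dedup(step)
    assert len(rset) == len(oracle)
    # no two retained rotations coincide
    for i in range(len(rset)):
        for j in range(i + 1, len(rset)):
            assert np.linalg.norm(rset.matrices[i] - rset.matrices[j]) > 1e-6


def test_identity_rotation_always_present():
    for step in (180.0, 90.0, 45.0):
        rset = generate_rotations(step)
        assert any(np.allclose(M, np.eye(3)) for M in rset.matrices)


def test_invalid_rotation_step_rejected():
    with pytest.raises(ValueError):
        generate_rotations(-12.0)
    with pytest.raises(ValueError):
        generate_rotations(7.0)  # does not divide 360


# ---------------------------------------------------------------- correlation

def _brute_correlate(R, L):
    out = np.zeros(R.shape, dtype=np.int64)
    for t in np.ndindex(R.shape):
        out[t] = int(np.sum(R * np.roll(L, t, axis=(0, 1, 2))))
    return out


def _wrap(values, spec=None):
    spec = spec or GridSpec(dims=values.shape, origin=np.zeros(3))
    return DiscreteGrid(spec=spec, values=values)


def test_fft_matches_brute_force_on_random_grids():
    rng = np.random.default_rng(11)
    for trial in range(30):
        n = int(rng.integers(4, 13))
        R = rng.choice([0, 0, 1, -15], size=(n, n, n)).astype(np.int32)
        L = (rng.random((n, n, n)) < 0.3).astype(np.int32)
        fft = fft_correlate(_wrap(R), _wrap(L))
        np.testing.assert_array_equal(fft, _brute_correlate(R, L))


def test_single_cell_correlation():
    R = np.zeros((6, 6, 6), dtype=np.int32)
    L = np.zeros((6, 6, 6), dtype=np.int32)
    R[2, 3, 1] = 1
    L[0, 1, 4] = 1
    corr = fft_correlate(_wrap(R), _wrap(L))
    assert corr.sum() == 1
    assert corr[2, 2, 3] == 1  # shift t = R_pos - L_pos (mod n)
    R[2, 3, 1] = -15
    corr = fft_correlate(_wrap(R), _wrap(L))
    assert corr[2, 2, 3] == -15


def test_zero_ligand_grid_scores_zero():
    R = np.ones((5, 5, 5), dtype=np.int32)
    L = np.zeros((5, 5, 5), dtype=np.int32)
    assert np.all(fft_correlate(_wrap(R), _wrap(L)) == 0)


def test_dims_mismatch_raises():
    with pytest.raises(ValueError):
        fft_correlate(_wrap(np.zeros((4, 4, 4), dtype=int)),
                      _wrap(np.zeros((5, 5, 5), dtype=int)))


def test_smooth_dims():
    assert smooth_dim(17) == 18
    assert smooth_dim(65) == 72
    for n in (18, 72, 80, 96):
        assert smooth_dim(n) == n


# ------------------------------------------------------------------- sampling

def test_planted_solution_recovered_within_cell_diagonal(helix6, duplex8):
    cplx, receptor, ligand, truth = planted_optimal_complex(helix6, duplex8)
    spec = make_gridspec(receptor, ligand)
    poses = sample(receptor, ligand, spec, generate_rotations(90.0),
                   total_keep=len(generate_rotations(90.0)) * 3)
    errors = [np.linalg.norm(p.translation - truth.translation)
              for p in poses if p.euler == (0.0, 0.0, 0.0)]
    assert errors, "identity-rotation poses missing from the pool"
    assert min(errors) <= 0.7 * np.sqrt(3)


def test_degenerate_settings_return_global_maximum(helix6, duplex8):
    from dnadock import RotationSet
    receptor, ligand = choose_receptor(helix6, duplex8)
    spec = make_gridspec(receptor, ligand)
    identity = RotationSet(step=360.0, eulers=[(0.0, 0.0, 0.0)],
                           matrices=np.eye(3)[None])
    poses = sample(receptor, ligand, spec, identity, keep_per_rotation=1,
                   total_keep=10)
    assert len(poses) == 1
    _cplx, _r, _l, truth = planted_optimal_complex(helix6, duplex8)
    assert poses[0].grid_score == truth.grid_score


def test_poses_sorted_with_unique_ids(helix6, duplex8):
    receptor, ligand = choose_receptor(helix6, duplex8)
    poses = sample(receptor, ligand, rotations=generate_rotations(120.0),
                   total_keep=100)
    scores = [p.grid_score for p in poses]
    assert scores == sorted(scores, reverse=True)
    ids = [p.pose_id for p in poses]
    assert ids == list(range(1, len(poses) + 1))


def test_pose_transform_round_trip(helix6, duplex8):
    receptor, ligand = choose_receptor(helix6, duplex8)
    pose = DockPose(run_id=1, pose_id=1, euler=(24.0, 48.0, 132.0),
                    translation=np.array([8.0, -3.0, 2.5]), grid_score=0)
    coords = pose_coords(ligand, pose)
    # recompute the transform from coordinates: rotation and translation
    R, t, fit = kabsch(ligand.coords, coords)
    assert fit < 1e-9
    np.testing.assert_allclose(R, euler_to_matrix(*pose.euler), atol=1e-6)
    centroid_shift = coords.mean(axis=0) - ligand.centroid()
    np.testing.assert_allclose(centroid_shift, pose.translation, atol=1e-6)


def test_grid_score_invariant_under_joint_translation(helix6, duplex8):
    receptor, ligand = choose_receptor(helix6, duplex8)
    rots = generate_rotations(180.0)
    poses0 = sample(receptor, ligand, rotations=rots, total_keep=5)
    shift = np.array([3.31, -2.17, 5.03])
    rec2 = receptor.with_coords(receptor.coords + shift)
    lig2 = ligand.with_coords(ligand.coords + shift)
    poses1 = sample(rec2, lig2, rotations=rots, total_keep=5)
    assert [p.grid_score for p in poses0] == [p.grid_score for p in poses1]
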