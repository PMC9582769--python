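import numpy as np
import pytest

from dnadock import (DockPose, desolvation, electrostatics, get_scheme,
                     rank_poses, sasa, score_pose, vdw)
from dnadock.energy import (COULOMB_K, EnergyBreakdown, sasa_from_arrays,
                            score_poses)
from dnadock.geometry import random_rotation_matrix, transform_about
from tests.conftest import random_annotated


def _two_atoms(q1, q2, r, rstar=1.9, eps=0.1):
    a = random_annotated(1, 0)
    b = random_annotated(1, 1)
    a.coords = np.zeros((1, 3))
    b.coords = np.array([[r, 0.0, 0.0]])
    a.charges, b.charges = np.array([q1]), np.array([q2])
    a.vdw_rstar = b.vdw_rstar = np.array([rstar])
    a.vdw_eps = b.vdw_eps = np.array([eps])
    return a, b


# --------------------------------------------------------------- closed forms

def test_electrostatics_closed_form_spot_value():
    a, b = _two_atoms(0.3, -0.2, 5.0)
    # 332.0 * (0.3 * -0.2) / (4 * 25) = -0.1992 kcal/mol
    assert electrostatics(a, b) == pytest.approx(-0.1992, abs=1e-12)


def test_electrostatics_clamped_at_plus_one():
    a, b = _two_atoms(0.5, 0.5, 4.0)
    raw = COULOMB_K * 0.25 / (4 * 16)
    assert raw > 1.0
    assert electrostatics(a, b) == pytest.approx(1.0)


def test_electrostatics_zero_charges(helix6, duplex8):
    a = helix6.copy()
    b = duplex8.copy()
    a.charges = np.zeros(len(a))
    b.charges = np.zeros(len(b))
    assert electrostatics(a, b) == 0.0


def test_electrostatics_symmetric_in_molecule_order(helix6, duplex8):
    assert electrostatics(helix6, duplex8) == pytest.approx(
        electrostatics(duplex8, helix6), abs=1e-9)


def test_vdw_minimum_identity():
    a, b = _two_atoms(0.0, 0.0, r=3.8, rstar=1.9, eps=0.16)
    # at r = ri* + rj* the 6-12 well depth is exactly -eps_ij
    assert vdw(a, b) == pytest.approx(-0.16, abs=1e-12)


def test_vdw_clamped_on_close_contact():
    a, b = _two_atoms(0.0, 0.0, r=0.1)
    assert vdw(a, b) == pytest.approx(1.0)


def test_terms_zero_beyond_cutoff():
    a, b = _two_atoms(0.5, 0.5, r=100.0)
    assert electrostatics(a, b, cutoff=12.0) == 0.0
    assert vdw(a, b, cutoff=12.0) == 0.0
    assert desolvation(a, b) == 0.0  # no shared buried surface


# -------------------------------------------------------- double-loop oracles

def _oracle_terms(rec, lig, cutoff=None):
    ele = 0.0
    vw = 0.0
    for i in range(len(rec)):
        for j in range(len(lig)):
            r = float(np.linalg.norm(rec.coords[i] - lig.coords[j]))
            if cutoff is not None and r > cutoff:
                continue
            r = max(r, 1.0)
            e = COULOMB_K * rec.charges[i] * lig.charges[j] / (4 * r * r)
            ele += min(max(e, -1.0), 1.0)
            rij = rec.vdw_rstar[i] + lig.vdw_rstar[j]
            eij = np.sqrt(rec.vdw_eps[i] * lig.vdw_eps[j])
            x6 = (rij / r) ** 6
            vw += min(eij * (x6 * x6 - 2 * x6), 1.0)
    return ele, vw


@pytest.mark.parametrize("seed,n", [(1, 60), (2, 120), (3, 250)])
def test_pairwise_terms_match_naive_double_loop(seed, n):
    rec = random_annotated(n, seed, box=18.0)
    lig = random_annotated(n, seed + 100, box=18.0, center=(10.0, 2.0, -3.0))
    ele_o, vdw_o = _oracle_terms(rec, lig)
    assert electrostatics(rec, lig, cutoff=None) == pytest.approx(
        ele_o, rel=1e-9, abs=1e-12)
    assert vdw(rec, lig, cutoff=None) == pytest.approx(
        vdw_o, rel=1e-9, abs=1e-12)
    # and with the default cutoff
    ele_c, vdw_c = _oracle_terms(rec, lig, cutoff=12.0)
    assert electrostatics(rec, lig) == pytest.approx(ele_c, rel=1e-9, abs=1e-12)
    assert vdw(rec, lig) == pytest.approx(vdw_c, rel=1e-9, abs=1e-12)


# ----------------------------------------------------------------------- SASA

def test_isolated_atom_sasa_closed_form():
    area = sasa_from_arrays(np.zeros((1, 3)), np.array([1.9]))
    exact = 4 * np.pi * (1.9 + 1.4) ** 2
    assert area[0] == pytest.approx(exact, rel=1e-12)


def test_two_sphere_sasa_matches_cap_formula():
    # two overlapping atoms: exposed area has an exact spherical-cap solution
    r1, r2, d = 1.9, 1.66, 2.8
    probe = 1.4
    e1, e2 = r1 + probe, r2 + probe
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    areas = sasa_from_arrays(coords, np.array([r1, r2]), probe=probe,
                             n_points=960)
    h1 = e1 - (d * d + e1 * e1 - e2 * e2) / (2 * d)
    h2 = e2 - (d * d + e2 * e2 - e1 * e1) / (2 * d)
    exact1 = 4 * np.pi * e1 ** 2 - 2 * np.pi * e1 * h1
    exact2 = 4 * np.pi * e2 ** 2 - 2 * np.pi * e2 * h2
    assert areas[0] == pytest.approx(exact1, rel=0.01)
    assert areas[1] == pytest.approx(exact2, rel=0.01)


def test_buried_central_atom_has_no_area():
    # central atom fully caged by a shell of large neighbours
    shell = []
    for th in np.linspace(0, np.pi, 8):
        for ph in np.linspace(0, 2 * np.pi, 16, endpoint=False):
            shell.append([2.2 * np.sin(th) * np.cos(ph),
                          2.2 * np.sin(th) * np.sin(ph), 2.2 * np.cos(th)])
    coords = np.vstack([[0.0, 0.0, 0.0], shell])
    radii = np.full(len(coords), 1.9)
    areas = sasa_from_arrays(coords, radii)
    assert areas[0] == pytest.approx(0.0, abs=1e-9)


def test_subset_sasa_agrees_with_full_computation(duplex8):
    full = sasa(duplex8)
    sub = sasa_from_arrays(duplex8.coords, duplex8.vdw_rstar,
                           subset=np.arange(10, 30))
    np.testing.assert_allclose(sub, full[10:30], atol=1e-9)


# --------------------------------------------------------------- desolvation

def test_desolvation_single_contact_matches_direct_delta():
    rec = random_annotated(1, 5)
    lig = random_annotated(1, 6)
    rec.coords = np.zeros((1, 3))
    lig.coords = np.array([[3.1, 0.0, 0.0]])
    rec.asp, lig.asp = np.array([0.02]), np.array([-0.03])
    alone_r = sasa(rec)
    alone_l = sasa(lig)
    both = sasa_from_arrays(np.vstack([rec.coords, lig.coords]),
                            np.concatenate([rec.vdw_rstar, lig.vdw_rstar]))
    expected = (0.02 * (alone_r[0] - both[0]) + -0.03 * (alone_l[0] - both[1]))
    assert desolvation(rec, lig) == pytest.approx(expected, abs=1e-9)


def test_desolvation_zero_when_asp_zero(helix6, duplex8):
    rec = duplex8.copy()
    lig = helix6.copy()
    # bring them into contact
    lig = lig.with_coords(lig.coords - lig.centroid() + rec.centroid()
                          + np.array([11.0, 0.0, 0.0]))
    rec.asp = np.zeros(len(rec))
    lig.asp = np.zeros(len(lig))
    assert desolvation(rec, lig) == 0.0


def test_desolvation_matches_full_recomputation(helix6, duplex8):
    rec = duplex8
    lig = helix6.with_coords(helix6.coords - helix6.centroid()
                             + duplex8.centroid() + np.array([10.0, 1.0, 2.0]))
    fast = desolvation(rec, lig)
    # oracle: recompute every atom's area in the complex
    coords = np.vstack([rec.coords, lig.coords])
    radii = np.concatenate([rec.vdw_rstar, lig.vdw_rstar])
    asp = np.concatenate([rec.asp, lig.asp])
    alone = np.concatenate([sasa(rec), sasa(lig)])
    both = sasa_from_arrays(coords, radii)
    assert fast == pytest.approx(float(np.sum(asp * (alone - both))),
                                 abs=1e-9)


# ---------------------------------------------------------- schemes & ranking

def _plain_pose(translation):
    return DockPose(run_id=1, pose_id=1, euler=(0.0, 0.0, 0.0),
                    translation=np.asarray(translation, float), grid_score=0)


def test_scheme_weight_identities(helix6, duplex8):
    pose = _plain_pose(duplex8.centroid() - helix6.centroid()
                       + np.array([11.0, 0.0, 0.0]))
    default = score_pose(duplex8, helix6, pose, "default")
    vdw1 = score_pose(duplex8, helix6, pose, "vdw1")
    no_desolv = score_pose(duplex8, helix6, pose, "no_desolv")
    # vdw1 vs default differ by exactly 0.9·vdw
    assert vdw1.total - default.total == pytest.approx(0.9 * default.vdw,
                                                       abs=1e-9)
    # no_desolv total is the weight identity with the desolvation term off
    assert no_desolv.total == pytest.approx(
        no_desolv.ele + 0.1 * no_desolv.vdw, abs=1e-12)
    # weight identity holds exactly for every breakdown
    for bd, s in ((default, get_scheme("default")), (vdw1, get_scheme("vdw1"))):
        assert bd.total == pytest.approx(
            s.w_ele * bd.ele + s.w_desolv * bd.desolv + s.w_vdw * bd.vdw
            + bd.restraint, abs=1e-12)


def test_identical_pose_scores_identically(helix6, duplex8):
    pose = _plain_pose([25.0, 0.0, 0.0])
    a = score_pose(duplex8, helix6, pose, "default")
    b = score_pose(duplex8, helix6, pose, "default")
    assert (a.ele, a.desolv, a.vdw, a.total) == (b.ele, b.desolv, b.vdw,
                                                 b.total)


def test_energy_invariant_under_joint_rigid_transform(helix6, duplex8):
    pose = _plain_pose(duplex8.centroid() - helix6.centroid()
                       + np.array([11.0, 0.0, 0.0]))
    from dnadock.sampling import pose_coords
    lig = helix6.with_coords(pose_coords(helix6, pose))
    e0, v0 = electrostatics(duplex8, lig), vdw(duplex8, lig)
    d0 = desolvation(duplex8, lig)
    R = random_rotation_matrix(17)
    shift = np.array([5.0, -8.0, 3.0])
    center = duplex8.centroid()
    rec2 = duplex8.with_coords(
        transform_about(duplex8.coords, R, center, shift))
    lig2 = lig.with_coords(transform_about(lig.coords, R, center, shift))
    assert electrostatics(rec2, lig2) == pytest.approx(e0, abs=1e-6)
    assert vdw(rec2, lig2) == pytest.approx(v0, abs=1e-6)
    # the SASA quadrature points are fixed in the lab frame, so the
    # desolvation term is invariant only up to the point-set resolution
    assert desolvation(rec2, lig2) == pytest.approx(d0, abs=0.05)


def test_rank_poses_orders_and_tie_breaks():
    def bd(total):
        return EnergyBreakdown(0, 0, 0, 0, total, "default")

    poses = [DockPose(1, 1, (0, 0, 0), np.zeros(3), 0, bd(3.0)),
             DockPose(1, 2, (0, 0, 0), np.zeros(3), 0, bd(-5.0)),
             DockPose(1, 3, (0, 0, 0), np.zeros(3), 0, bd(1.2)),
             DockPose(1, 4, (0, 0, 0), np.zeros(3), 0, bd(1.2))]
    ranked = rank_poses(poses)
    assert [p.pose_id for p in ranked] == [2, 3, 4, 1]
    poses[0].energies = None
    with pytest.raises(ValueError):
        rank_poses(poses)


def test_ranking_differs_between_schemes_when_desolv_varies(helix6, duplex8):
    # two poses whose order flips when the desolvation term is dropped
    rec, lig = duplex8, helix6
    base = rec.centroid() - lig.centroid()
    poses = [_plain_pose(base + np.array([10.5, 0.0, 0.0])),
             _plain_pose(base + np.array([12.5, 0.0, 3.0]))]
    poses[1].pose_id = 2
    sd = [score_pose(rec, lig, p, "default") for p in poses]
    sn = [score_pose(rec, lig, p, "no_desolv") for p in poses]
    # desolvation genuinely varies between the two poses
    assert abs(sd[0].desolv - sd[1].desolv) > 1e-6
    # and the no_desolv totals equal the default totals minus desolvation
    for a, b in zip(sd, sn):
        assert b.total == pytest.approx(a.total - a.desolv, abs=1e-9)
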