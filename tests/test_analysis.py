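"""Folding metrics: superposition RMSD, Rg, contacts, helix content, clustering."""

import numpy as np
import pytest
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from boostmd import models
from boostmd.analysis import (
    cluster_trajectory,
    fraction_native,
    helix_content,
    native_contacts,
    radius_of_gyration,
    superpose_rmsd,
)
from boostmd.protocols import planted_mixture_frames


def brute_force_rmsd(mobile, reference, n_grid=300, seed=0):
    """Independent minimum-RMSD oracle: quaternion grid plus local refinement.

    Searches rotations directly (rotation-vector parameterisation) instead of
    the closed-form superposition under test.
    """
    rng = np.random.default_rng(seed)
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    n = len(mc)

    def rmsd_of_rotvec(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(np.mean(np.sum((mc @ r.T - rc) ** 2, axis=1)))

    best, best_rv = np.inf, None
    for q in Rotation.random(n_grid, random_state=rng):
        rv = q.as_rotvec()
        val = rmsd_of_rotvec(rv)
        if val < best:
            best, best_rv = val, rv
    res = scipy_minimize(rmsd_of_rotvec, best_rv, method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return min(best, float(res.fun))


class TestSuperposeRMSD:
    def test_identical_structures_are_zero(self, rng):
        x = rng.normal(0, 3, (8, 3))
        rmsd, rot, _ = superpose_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_invariance_under_rigid_motion(self, rng):
        x = rng.normal(0, 3, (10, 3))
        for _ in range(5):
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(0, 10, 3)
            rmsd, _, _ = superpose_rmsd(x @ rot.T + shift, x)
            assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(0, 3, (9, 3))
        b = a + 0.5 * rng.standard_normal((9, 3))
        assert superpose_rmsd(a, b)[0] == pytest.approx(superpose_rmsd(b, a)[0],
                                                        abs=1e-9)

    def test_matches_brute_force_rotation_search(self, rng):
        for trial in range(3):
            a = rng.normal(0, 2, (8, 3))
            b = rng.normal(0, 2, (8, 3))
            fast, _, _ = superpose_rmsd(a, b)
            slow = brute_force_rmsd(a, b, seed=trial)
            assert fast == pytest.approx(slow, abs=1e-6)

    def test_alignment_transform_reproduces_reference(self, rng):
        a = rng.normal(0, 3, (7, 3))
        rot_true = Rotation.random(random_state=rng).as_matrix()
        b = a @ rot_true.T + np.array([1.0, -2.0, 3.0])
        rmsd, rot, trans = superpose_rmsd(b, a)
        np.testing.assert_allclose(b @ rot.T + trans, a, atol=1e-9)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_selection_warns(self):
        a = models.extended_coords(5)
        with pytest.warns(UserWarning):
            superpose_rmsd(a, a + 0.1)


class TestRadiusOfGyration:
    def test_point_pair_chain_closed_forms(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0
        pair = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert radius_of_gyration(pair) == pytest.approx(2.0)
        n, d = 11, 3.8
        assert radius_of_gyration(models.extended_coords(n, d)) == pytest.approx(
            np.sqrt(d * d * (n * n - 1) / 12.0)
        )

    def test_mass_weighting_moves_com(self):
        pair = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        rg = radius_of_gyration(pair, masses=np.array([3.0, 1.0]))
        # com at x=1: rg^2 = (3*1 + 1*9)/4 = 3
        assert rg == pytest.approx(np.sqrt(3.0))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((3, 3)), selection=[])


class TestNativeContacts:
    def test_strict_cutoff_excludes_7p6(self):
        chain = models.extended_coords(3, 3.8)  # (0,2) distance 7.6 > 7.0
        assert len(native_contacts(chain, cutoff=7.0, min_seq_sep=2)) == 0

    def test_closer_chain_has_single_contact(self):
        chain = models.extended_coords(3, 3.0)  # (0,2) at 6.0 < 7.0
        cs = native_contacts(chain, cutoff=7.0, min_seq_sep=2)
        assert [tuple(p) for p in cs.pairs] == [(0, 2)]

    def test_boundary_distance_not_a_contact(self):
        chain = models.extended_coords(3, 3.5)  # (0,2) exactly 7.0
        assert len(native_contacts(chain, cutoff=7.0, min_seq_sep=2)) == 0

    def test_helix_has_all_i_ip3_contacts(self):
        ref = models.ideal_helix_coords(10)
        keys = {tuple(p) for p in native_contacts(ref).pairs}
        assert all((i, i + 3) in keys for i in range(7))

    def test_pairs_respect_min_seq_sep(self):
        ref = models.ideal_helix_coords(12)
        cs = native_contacts(ref, min_seq_sep=3)
        assert np.all(cs.pairs[:, 1] - cs.pairs[:, 0] >= 3)


class TestFractionNative:
    def test_native_frame_scores_one(self):
        ref = models.ideal_helix_coords(12)
        assert fraction_native(ref, native_contacts(ref)) == 1.0

    def test_extended_frame_scores_zero(self):
        ref = models.ideal_helix_coords(12)
        assert fraction_native(models.extended_coords(12), native_contacts(ref)) == 0.0

    def test_partially_formed_fixture(self):
        # first six residues keep native geometry, the rest are pulled away:
        # exactly the contacts fully inside the intact half remain formed
        contacts = native_contacts(models.ideal_helix_coords(12))
        frame = models.ideal_helix_coords(12)
        # scatter the tail so that every pair touching it is broken
        frame[6:] += 100.0 * np.arange(1, 7)[:, None]
        kept = sum(1 for i, j in contacts.pairs if j < 6)
        assert fraction_native(frame, contacts) == pytest.approx(
            kept / len(contacts)
        )

    def test_empty_contact_set_rejected(self):
        empty = native_contacts(models.extended_coords(3, 3.8))
        with pytest.raises(ValueError):
            fraction_native(models.extended_coords(3, 3.8), empty)


class TestHelixContent:
    def test_ideal_helix_is_fully_helical(self):
        assert helix_content(models.ideal_helix_coords(12)) == 1.0

    def test_extended_chain_is_not_helical(self):
        x = models.perturbed_extended_coords(12)
        assert helix_content(x) == 0.0

    def test_half_helix_fixture_is_intermediate(self):
        frames, _ = planted_mixture_frames(3, n_frames=1, fractions=(0.0, 0.0, 1.0),
                                           jitter=0.0)
        val = helix_content(frames[0])
        assert 0.3 < val < 0.7

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            helix_content(np.zeros((3, 3)))


class TestClustering:
    def test_two_well_separated_conformers(self, rng):
        helix = models.ideal_helix_coords(10)
        ext = models.extended_coords(10)
        frames = np.array(
            [h + 0.2 * rng.standard_normal(h.shape)
             for h in [helix] * 50 + [ext] * 50]
        )
        res = cluster_trajectory(frames, n_clusters=2, native=helix)
        np.testing.assert_allclose(res.populations, [0.5, 0.5])
        # one representative near the helix, one far from it
        rmsds = np.sort(res.rmsd_of_representative_to_native)
        assert rmsds[0] < 0.5 and rmsds[1] > 2.0

    def test_identical_frames_single_cluster(self):
        frames = np.repeat(models.ideal_helix_coords(8)[None], 5, axis=0)
        res = cluster_trajectory(frames, n_clusters=1)
        assert res.populations.tolist() == [1.0]
        assert res.representatives[0] == 0

    def test_planted_80_15_5_mixture_recovered(self):
        frames, labels = planted_mixture_frames(7, n_frames=200)
        res = cluster_trajectory(frames, n_clusters=3)
        planted = np.sort(np.bincount(labels) / 200.0)[::-1]
        assert np.max(np.abs(res.populations - planted)) <= 0.03

    def test_populations_sum_to_one_and_reps_belong(self, rng):
        frames, _ = planted_mixture_frames(9, n_frames=60)
        res = cluster_trajectory(frames, n_clusters=3)
        assert res.populations.sum() == pytest.approx(1.0)
        for cid, rep in enumerate(res.representatives):
            assert res.labels[rep] == cid

    def test_exactly_one_selection_rule_required(self):
        frames, _ = planted_mixture_frames(1, n_frames=10)
        with pytest.raises(ValueError):
            cluster_trajectory(frames)
        with pytest.raises(ValueError):
            cluster_trajectory(frames, n_clusters=2, rmsd_cutoff=1.0)
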