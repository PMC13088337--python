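"""Trajectory observables: distances, angles, NAC, H-bonds, RMSD, energies."""

import numpy as np
import pytest

from etkit.constants import COULOMB_KCAL
from etkit.ensembles import (
    GeometrySeries,
    HBondCriterion,
    NonbondedParams,
    attack_angle_series,
    distance_series,
    hbond_occupancy,
    interaction_energy_series,
    nac_summary,
    rmsd_series,
)
from etkit.synthetic import PlantedTrajectorySpec, make_planted_trajectory


class TestDistanceSeries:
    def test_static_two_frames(self, point_trajectory_factory):
        frame = [[0, 0, 0], [5, 0, 0]]
        traj = point_trajectory_factory([frame, frame])
        s = distance_series(traj, {0}, {1})
        np.testing.assert_allclose(s.frame_values, [5.0, 5.0])
        assert s.sd == 0.0

    def test_planted_gaussian_mean(self):
        traj, truth = make_planted_trajectory(
            PlantedTrajectorySpec(
                n_frames=2000, distance_law=("gaussian", 4.19, 0.75), seed=5
            )
        )
        i = truth.indices
        s = distance_series(traj, {i["oxo"]}, {i["h25"]})
        np.testing.assert_allclose(s.frame_values, truth.distances, atol=1e-9)
        assert abs(s.mean - 4.19) < 3 * 0.75 / np.sqrt(2000)

    def test_min_mode_equals_brute_force(self, point_trajectory_factory):
        rng = np.random.default_rng(2)
        frames = [rng.uniform(0, 10, size=(6, 3)) for _ in range(4)]
        traj = point_trajectory_factory(frames)
        A, B = {0, 1, 2}, {3, 4, 5}
        s = distance_series(traj, A, B, mode="min")
        for k, frame in enumerate(frames):
            expected = min(
                np.linalg.norm(frame[i] - frame[j]) for i in A for j in B
            )
            assert s.frame_values[k] == pytest.approx(expected)


class TestAttackAngle:
    def test_collinear_and_right_angle(self, point_trajectory_factory):
        collinear = [[0, 0, -1], [0, 0, 0], [0, 0, 1]]
        right = [[1, 0, 0], [0, 0, 0], [0, 1, 0]]
        traj = point_trajectory_factory([collinear, right])
        s = attack_angle_series(traj, 0, 1, 2)
        np.testing.assert_allclose(s.frame_values, [180.0, 90.0], atol=1e-9)

    def test_planted_angle_distribution(self):
        traj, truth = make_planted_trajectory(
            PlantedTrajectorySpec(
                n_frames=2000, angle_law=("gaussian", 142.0, 7.7), seed=6
            )
        )
        i = truth.indices
        s = attack_angle_series(traj, i["fe"], i["oxo"], i["c25"])
        np.testing.assert_allclose(s.frame_values, truth.angles, atol=1e-8)
        assert abs(s.mean - 142.0) < 3 * 7.7 / np.sqrt(2000)

    def test_coincident_atoms_name_frame(self, point_trajectory_factory):
        good = [[1, 0, 0], [0, 0, 0], [0, 1, 0]]
        bad = [[0, 0, 0], [0, 0, 0], [0, 1, 0]]
        traj = point_trajectory_factory([good, bad])
        with pytest.raises(ValueError, match="frame 1"):
            attack_angle_series(traj, 0, 1, 2)


class TestNACSummary:
    def test_half_within(self):
        d = GeometrySeries("d", [3.0, 5.0, 3.0, 5.0])
        a = GeometrySeries("a", [140.0] * 4)
        out = nac_summary(d, a, threshold=4.0)
        assert out.fraction_within == pytest.approx(0.5)

    def test_all_within(self):
        d = GeometrySeries("d", [1.0, 2.0, 3.0])
        a = GeometrySeries("a", [140.0] * 3)
        assert nac_summary(d, a).fraction_within == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        d = GeometrySeries("d", rng.uniform(2, 6, 500))
        a = GeometrySeries("a", rng.uniform(100, 180, 500))
        fracs = [nac_summary(d, a, threshold=t).fraction_within for t in (3, 4, 5)]
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nac_summary(GeometrySeries("d", [1.0]), GeometrySeries("a", [1.0, 2.0]))


class TestHBondOccupancy:
    def test_always_satisfied(self):
        traj, truth = make_planted_trajectory(
            PlantedTrajectorySpec(n_frames=40, hbond_frame_fraction=1.0, seed=1)
        )
        i = truth.indices
        occ = hbond_occupancy(traj, i["donor"], i["hydrogen"], i["acceptor"])
        assert occ == pytest.approx(100.0)

    def test_exactly_planted_fraction(self, planted_small):
        traj, truth = planted_small
        i = truth.indices
        occ = hbond_occupancy(traj, i["donor"], i["hydrogen"], i["acceptor"])
        assert occ == pytest.approx(100.0 * truth.hbond_labels.mean())

    def test_angle_failure_gives_zero(self, point_trajectory_factory):
        # d(D,A) passes the 3.5 Å criterion but the D-H-A angle is 90° < 135°
        frame = [[0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]]
        traj = point_trajectory_factory([frame] * 3, elements=["N", "H", "O"])
        occ = hbond_occupancy(traj, 0, 1, 2, HBondCriterion())
        assert occ == 0.0

    def test_hydrogen_must_bond_donor(self, point_trajectory_factory):
        frame = [[0, 0, 0], [5.0, 0, 0], [6.0, 0, 0]]
        traj = point_trajectory_factory([frame], elements=["N", "H", "O"])
        with pytest.raises(ValueError, match="not covalently bonded"):
            hbond_occupancy(traj, 0, 1, 2)


class TestRMSD:
    @staticmethod
    def _symmetric_fixture():
        # square in the xy-plane plus a center atom on the symmetry axis
        return np.array(
            [
                [1.0, 0.0, 0.0],
                [-1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, -1.0, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )

    def test_identical_frame_zero(self, point_trajectory_factory):
        ref = self._symmetric_fixture()
        traj = point_trajectory_factory([ref, ref.copy()])
        np.testing.assert_allclose(rmsd_series(traj).frame_values, 0.0, atol=1e-9)

    def test_rigid_motion_invariance(self, point_trajectory_factory):
        ref = self._symmetric_fixture()
        theta = np.pi / 2
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = ref @ R.T + np.array([3.0, -2.0, 7.0])
        traj = point_trajectory_factory([ref, moved])
        np.testing.assert_allclose(rmsd_series(traj).frame_values, 0.0, atol=1e-9)

    def test_displaced_center_closed_form(self, point_trajectory_factory):
        # displacing the on-axis atom along z leaves the optimal rotation at
        # identity; after the centroid shift the exact RMSD is δ·√(N−1)/N
        ref = self._symmetric_fixture()
        delta = 0.5
        moved = ref.copy()
        moved[4, 2] += delta
        traj = point_trajectory_factory([ref, moved])
        n = ref.shape[0]
        expected = delta * np.sqrt(n - 1) / n
        assert rmsd_series(traj).frame_values[1] == pytest.approx(expected, rel=1e-9)

    def test_collinear_selection_rejected(self, point_trajectory_factory):
        line = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        traj = point_trajectory_factory([line])
        with pytest.raises(ValueError, match="collinear"):
            rmsd_series(traj)


def _params(n, q=None, sigma=1.0, eps=1.0, **kw):
    return NonbondedParams(
        charges=np.full(n, 1.0) if q is None else np.asarray(q, float),
        sigma=np.full(n, sigma),
        epsilon=np.full(n, eps),
        **kw,
    )


class TestInteractionEnergies:
    def test_unit_charges_at_unit_distance(self, point_trajectory_factory):
        traj = point_trajectory_factory([[[0, 0, 0], [1.0, 0, 0]]])
        params = _params(2, eps=0.0)
        out = interaction_energy_series(traj, {0}, {1}, params)
        assert out.electrostatic[0] == pytest.approx(COULOMB_KCAL)

    def test_pair_beyond_cutoff_contributes_zero(self, point_trajectory_factory):
        traj = point_trajectory_factory([[[0, 0, 0], [150.0, 0, 0]]])
        params = _params(2, eps=0.0, cutoff=99.0)
        out = interaction_energy_series(traj, {0}, {1}, params)
        assert out.electrostatic[0] == 0.0

    def test_lj_zero_at_sigma_and_minimum(self, point_trajectory_factory):
        sigma = 3.4
        eps = 0.25
        traj = point_trajectory_factory(
            [[[0, 0, 0], [sigma, 0, 0]], [[0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]]]
        )
        params = _params(2, q=[0, 0], sigma=sigma, eps=eps)
        out = interaction_energy_series(traj, {0}, {1}, params)
        assert out.vdw[0] == pytest.approx(0.0, abs=1e-10)
        assert out.vdw[1] == pytest.approx(-eps, rel=1e-12)

    def test_brute_force_double_loop_oracle(self, point_trajectory_factory):
        rng = np.random.default_rng(23)
        coords = rng.uniform(0, 8, size=(10, 3))
        traj = point_trajectory_factory([coords])
        q = rng.uniform(-1, 1, 10)
        sig = rng.uniform(2.5, 4.0, 10)
        eps = rng.uniform(0.05, 0.3, 10)
        params = NonbondedParams(charges=q, sigma=sig, epsilon=eps, cutoff=np.inf)
        A, B = range(5), range(5, 10)
        out = interaction_energy_series(traj, A, B, params)
        elec = vdw = 0.0
        for i in A:
            for j in B:
                r = np.linalg.norm(coords[i] - coords[j])
                elec += COULOMB_KCAL * q[i] * q[j] / r
                sij = 0.5 * (sig[i] + sig[j])
                eij = np.sqrt(eps[i] * eps[j])
                vdw += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
        assert out.electrostatic[0] == pytest.approx(elec, rel=1e-12)
        assert out.vdw[0] == pytest.approx(vdw, rel=1e-12)

    def test_symmetric_under_group_swap(self, point_trajectory_factory):
        rng = np.random.default_rng(31)
        coords = rng.uniform(0, 8, size=(8, 3))
        traj = point_trajectory_factory([coords])
        params = _params(8, q=rng.uniform(-1, 1, 8))
        a = interaction_energy_series(traj, range(4), range(4, 8), params)
        b = interaction_energy_series(traj, range(4, 8), range(4), params)
        np.testing.assert_allclose(a.electrostatic, b.electrostatic, rtol=1e-12)
        np.testing.assert_allclose(a.vdw, b.vdw, rtol=1e-12)

    def test_missing_parameters_listed(self, point_trajectory_factory):
        traj = point_trajectory_factory([[[0, 0, 0], [2.0, 0, 0]]])
        params = NonbondedParams(
            charges=[1.0, np.nan], sigma=[1.0, 1.0], epsilon=[0.1, 0.1]
        )
        with pytest.raises(ValueError, match="serial"):
            interaction_energy_series(traj, {0}, {1}, params)
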