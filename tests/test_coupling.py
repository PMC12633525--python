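"""Aromatic-pair distances, PC correlations, free-energy surfaces, basins."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confcouple import synthetic, trajio
from confcouple.coupling import (
    KB_KCAL,
    ClusterMember,
    DistanceSeries,
    compensation_score,
    distance_pc_correlation,
    find_basins,
    free_energy_surface,
    pair_distance_series,
    ring_centroid,
)
from confcouple.essential_dynamics import compute_pca
from confcouple.synthetic import POINT_RING_RULE, RingSpec, generate_toy_structure
from confcouple.trajio import AtomSelection, Trajectory

from conftest import make_point_structure


class TestRingCentroid:
    def test_hexagon_at_origin(self):
        s = generate_toy_structure([RingSpec("PHE", (0, 0, 0), "A", 1)])
        c = ring_centroid(s.coords, s, ClusterMember("A", 1, "PHE"))
        np.testing.assert_allclose(c, [0, 0, 0], atol=1e-9)

    def test_translated_hexagon(self):
        s = generate_toy_structure([RingSpec("PHE", (3, 4, 0), "A", 1)])
        c = ring_centroid(s.coords, s, ClusterMember("A", 1, "PHE"))
        np.testing.assert_allclose(c, [3, 4, 0], atol=1e-9)

    def test_trp_hand_placed_mean_oracle(self):
        """Six hand-placed ring atoms: centroid equals their arithmetic mean."""
        names = ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.4, 0.1, 0.0],
                [-0.7, 1.2, 0.3],
                [2.1, 1.3, -0.2],
                [0.0, 2.4, 0.4],
                [1.4, 2.5, 0.1],
            ]
        )
        s = make_point_structure(
            [(n, "C", 7, "TRP", "B", tuple(c)) for n, c in zip(names, coords)]
        )
        c = ring_centroid(s.coords, s, ClusterMember("B", 7, "TRP"))
        np.testing.assert_allclose(c, coords.mean(axis=0), atol=1e-12)

    def test_missing_ring_atom_named_in_error(self):
        s = make_point_structure([("CG", "C", 1, "PHE", "A", (0, 0, 0))])
        with pytest.raises(KeyError, match="CD1"):
            ring_centroid(s.coords, s, ClusterMember("A", 1, "PHE"))


def _two_point_traj(xyz_a, xyz_b, n_frames=3):
    top = make_point_structure(
        [
            ("CA", "C", 1, "GLY", "A", tuple(xyz_a)),
            ("CA", "C", 2, "GLY", "A", tuple(xyz_b)),
        ]
    )
    frames = np.tile(top.coords, (n_frames, 1, 1))
    return Trajectory(top, frames)


class TestPairDistanceSeries:
    def test_three_four_five(self):
        traj = _two_point_traj((0, 0, 0), (3, 4, 0))
        s = pair_distance_series(
            traj,
            ClusterMember("A", 1, "GLY"),
            ClusterMember("A", 2, "GLY"),
            POINT_RING_RULE,
        )
        np.testing.assert_allclose(s.values, 5.0)

    def test_self_pair_warns_and_is_zero(self):
        traj = _two_point_traj((0, 0, 0), (3, 4, 0))
        m = ClusterMember("A", 1, "GLY")
        with pytest.warns(UserWarning):
            s = pair_distance_series(traj, m, m, POINT_RING_RULE)
        np.testing.assert_allclose(s.values, 0.0)

    def test_planted_sinusoid_separation(self):
        top = make_point_structure(
            [
                ("CA", "C", 1, "GLY", "A", (0, 0, 0)),
                ("CA", "C", 2, "GLY", "A", (5, 0, 0)),
            ]
        )
        t = np.linspace(0, 4 * np.pi, 200)
        d = 5.0 + np.sin(t)
        frames = np.zeros((200, 2, 3))
        frames[:, 1, 0] = d
        traj = Trajectory(top, frames)
        s = pair_distance_series(
            traj,
            ClusterMember("A", 1, "GLY"),
            ClusterMember("A", 2, "GLY"),
            POINT_RING_RULE,
        )
        np.testing.assert_allclose(s.values, d, atol=1e-9)

    def test_rigid_motion_invariance(self):
        """Per-frame global rotation+translation leaves distances unchanged."""
        params = synthetic.CoupledTrajectoryParams(
            n_background=2, n_frames=50, pairs=[synthetic.PairSpec(rho=0.5)], seed=4
        )
        traj, truth = synthetic.generate_coupled_trajectory(params)
        a, b = truth.pair_members[0]
        ref = pair_distance_series(traj, a, b, POINT_RING_RULE)
        rng = np.random.default_rng(0)
        frames = np.empty_like(traj.frames)
        for i in range(traj.n_frames):
            R = Rotation.random(rng=rng).as_matrix()
            frames[i] = traj.frames[i] @ R.T + rng.normal(size=3) * 10
        moved = Trajectory(traj.topology, frames)
        s = pair_distance_series(moved, a, b, POINT_RING_RULE)
        np.testing.assert_allclose(s.values, ref.values, atol=1e-9)


class TestDistancePcCorrelation:
    def _pca_and_proj(self):
        rng = np.random.default_rng(9)
        top = make_point_structure(
            [("CA", "C", i + 1, "GLY", "A", (0, 0, 0)) for i in range(3)]
        )
        traj = Trajectory(top, rng.normal(size=(100, 3, 3)))
        pca = compute_pca(traj, AtomSelection((0, 1, 2)), align=False)
        return pca, pca.projections[:, 0]

    def test_perfect_linear_gives_unity(self):
        pca, p1 = self._pca_and_proj()
        s = DistanceSeries("x", 2.0 * p1 + 7.0)
        m = distance_pc_correlation([s], pca, n_pcs=2)
        assert m.r.loc["x", "PC1"] == pytest.approx(1.0)

    def test_anti_linear_gives_minus_one(self):
        pca, p1 = self._pca_and_proj()
        s = DistanceSeries("x", -p1 + 100.0)
        m = distance_pc_correlation([s], pca, n_pcs=1)
        assert m.r.loc["x", "PC1"] == pytest.approx(-1.0)

    def test_textbook_pearson_oracle(self):
        """r for x={1..5}, y={2,1,4,3,5} via the direct-sum formula."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        n = len(x)
        r_oracle = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        from confcouple.coupling import _pearson

        assert _pearson(x, y) == pytest.approx(r_oracle, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        pca, _ = self._pca_and_proj()
        s = DistanceSeries("flat", np.full(100, 3.0))
        with pytest.warns(UserWarning, match="zero variance"):
            m = distance_pc_correlation([s], pca, n_pcs=1)
        assert np.isnan(m.r.loc["flat", "PC1"])

    def test_planted_correlation_recovery(self, coupled_traj_rho08):
        """Recovered |r| with PC1 is within ±0.05 of the planted ρ = 0.8."""
        traj, truth = coupled_traj_rho08
        sel = trajio.select(traj.topology, "name CA")
        pca = compute_pca(traj, sel, align=False)
        a, b = truth.pair_members[0]
        s = pair_distance_series(traj, a, b, POINT_RING_RULE)
        m = distance_pc_correlation([s], pca, n_pcs=1)
        sign = np.sign(pca.modes[:, 0] @ truth.mode)
        assert sign * m.r.iloc[0, 0] == pytest.approx(0.8, abs=0.05)


class TestFreeEnergySurface:
    def test_single_occupied_bin(self):
        x = np.zeros(10)
        y = np.zeros(10)
        with pytest.warns(UserWarning, match="single bin"):
            fes = free_energy_surface(x, y, n_bins=(2, 2), ranges=((-1, 1), (-1, 1)))
        finite = np.isfinite(fes.free_energy)
        assert finite.sum() == 1
        assert fes.free_energy[finite][0] == 0.0
        assert fes.counts.sum() == 10

    def test_two_bin_closed_form(self):
        """Counts 3:1 at 310 K give ΔF = k_B·310·ln 3 exactly."""
        x = np.array([0.0, 0.0, 0.0, 1.0])
        y = np.zeros(4)
        fes = free_energy_surface(
            x, y, n_bins=(2, 2), temperature=310.0, ranges=((-0.5, 1.5), (-1, 1))
        )
        F = np.sort(fes.free_energy[np.isfinite(fes.free_energy)])
        assert F[0] == 0.0
        assert F[1] == pytest.approx(KB_KCAL * 310.0 * np.log(3.0), rel=1e-12)

    def test_doubling_counts_leaves_f_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        ranges = ((-4, 4), (-4, 4))
        f1 = free_energy_surface(x, y, n_bins=(10, 10), ranges=ranges)
        f2 = free_energy_surface(
            np.concatenate([x, x]), np.concatenate([y, y]),
            n_bins=(10, 10), ranges=ranges,
        )
        np.testing.assert_allclose(f2.free_energy, f1.free_energy, atol=1e-12)
        assert f2.counts.sum() == 2 * f1.counts.sum()

    def test_rebinning_idempotent_and_counts_conserved(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 300))
        ranges = ((-4, 4), (-4, 4))
        f1 = free_energy_surface(x, y, n_bins=(8, 8), ranges=ranges)
        f2 = free_energy_surface(x, y, n_bins=(8, 8), ranges=ranges)
        np.testing.assert_array_equal(f1.counts, f2.counts)
        assert f1.counts.sum() == 300

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            free_energy_surface(np.arange(4.0), np.arange(4.0), temperature=0.0)


class TestFindBasins:
    def test_single_paraboloid_one_basin(self):
        g = np.linspace(-2, 2, 21)
        X, Y = np.meshgrid(g, g, indexing="ij")
        counts = np.exp(-(X**2 + Y**2)) * 1000
        x = np.repeat(X.ravel(), counts.ravel().astype(int))
        y = np.repeat(Y.ravel(), counts.ravel().astype(int))
        fes = free_energy_surface(x, y, n_bins=(21, 21))
        basins = find_basins(fes, depth_threshold=0.5)
        assert len(basins) == 1
        assert abs(basins[0].x_center) < 0.3 and abs(basins[0].y_center) < 0.3
        assert basins[0].free_energy == 0.0

    def test_flat_grid_no_basins(self):
        x = np.repeat(np.arange(5.0), 10)
        fes = free_energy_surface(x, np.zeros_like(x), n_bins=(5, 2))
        assert find_basins(fes, depth_threshold=0.1) == []

    def test_planted_double_well_recovered(self):
        """Two-state pair (4 Å / 14 Å) yields exactly 2 basins within one
        bin width of the planted centers."""
        params = synthetic.CoupledTrajectoryParams(
            n_frames=20_000,
            pairs=[synthetic.PairSpec(jump=10.0, d0=4.0)],
            noise_sigma=0.3,
            seed=3,
        )
        traj, truth = synthetic.generate_coupled_trajectory(params)
        a, b = truth.pair_members[0]
        s = pair_distance_series(traj, a, b, POINT_RING_RULE)
        fes = free_energy_surface(s, s, n_bins=(60, 60))
        basins = find_basins(fes, depth_threshold=0.5)
        assert len(basins) == 2
        bin_width = fes.x_edges[1] - fes.x_edges[0]
        centers = sorted(b.x_center for b in basins)
        assert abs(centers[0] - 4.0) <= bin_width
        assert abs(centers[1] - 14.0) <= bin_width


class TestCompensationScore:
    def test_anti_coupled_is_minus_one(self):
        a = DistanceSeries("a", np.array([1.0, 2, 3, 4]))
        b = DistanceSeries("b", -a.values + 10.0)
        assert compensation_score(a, b) == pytest.approx(-1.0)

    def test_identical_is_plus_one(self):
        a = DistanceSeries("a", np.array([1.0, 2, 3, 4]))
        assert compensation_score(a, a) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(12)
        a = DistanceSeries("a", 5 + rng.normal(size=10_000))
        b = DistanceSeries("b", 5 + rng.normal(size=10_000))
        assert abs(compensation_score(a, b)) < 0.05  # 3/sqrt(n) bound

    def test_zero_variance_undefined(self):
        a = DistanceSeries("a", np.full(10, 2.0))
        b = DistanceSeries("b", np.arange(10.0))
        with pytest.warns(UserWarning):
            assert np.isnan(compensation_score(a, b))
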