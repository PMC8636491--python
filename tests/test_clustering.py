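import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from abdyn.clustering import (
    cluster_summary, essential_dynamics, kabsch_superpose, medoid_frame,
    pairwise_rmsd, radius_of_gyration, relabel_by_rg, upgma_cut,
)
from abdyn.synthetic import make_ca_topology
from abdyn.trajectory_io import Trajectory
from conftest import label_agreement


def _random_points(n, seed=0):
    return np.random.default_rng(seed).uniform(-1, 1, size=(n, 3))


class TestKabsch:
    def test_rigid_copy_rmsd_zero(self):
        P = _random_points(10, seed=1)
        R = Rotation.from_euler("xyz", [20, -40, 75], degrees=True).as_matrix()
        Q = P @ R.T + np.array([1.0, -2.0, 0.5])
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_analytic_two_point_case(self):
        P = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        Q = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.5, abs=1e-12)

    def test_mirror_not_matched(self):
        P = _random_points(8, seed=2)
        Q = P.copy()
        Q[:, 0] *= -1  # improper transform of a chiral point set
        _, _, rmsd = kabsch_superpose(P, Q)
        # brute-force grid over proper rotations cannot reach zero either
        assert rmsd > 0.05

    def test_rotation_is_proper(self):
        P = _random_points(6, seed=3)
        Q = _random_points(6, seed=4)
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_transform_achieves_reported_rmsd(self):
        P = _random_points(7, seed=5)
        Q = _random_points(7, seed=6)
        R, t, rmsd = kabsch_superpose(P, Q)
        moved = Q @ R.T + t
        assert np.sqrt(((moved - P) ** 2).sum() / 7) == pytest.approx(rmsd)


class TestPairwiseRMSD:
    def test_identical_frames_zero(self):
        top = make_ca_topology(5)
        frame = _random_points(5, seed=0)
        traj = Trajectory(top, np.stack([frame, frame]))
        M = pairwise_rmsd(traj, np.arange(5))
        np.testing.assert_allclose(M.values, 0.0, atol=1e-12)

    def test_matches_per_pair_kabsch(self):
        top = make_ca_topology(6)
        rng = np.random.default_rng(8)
        traj = Trajectory(top, rng.uniform(0, 2, size=(5, 6, 3)))
        M = pairwise_rmsd(traj, np.arange(6)).values
        for i in range(5):
            for j in range(i + 1, 5):
                _, _, r = kabsch_superpose(traj.coords[i], traj.coords[j])
                assert M[i, j] == pytest.approx(r, abs=1e-10)

    def test_symmetry_and_separation(self, three_state_trajectory):
        traj, truth = three_state_trajectory
        M = pairwise_rmsd(traj, traj.topology.ca_indices()).values
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        lab = truth.frame_state_labels
        within = max(
            M[np.ix_(lab == k, lab == k)].max() for k in range(3)
        )
        between = min(
            M[np.ix_(lab == a, lab == b)].min()
            for a in range(3) for b in range(3) if a != b
        )
        assert between > 3 * within


class TestUPGMA:
    def test_threshold_above_max_single_cluster(self):
        D = np.array(
            [[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]], dtype=float
        )
        from abdyn.clustering import RMSDMatrix

        a = upgma_cut(RMSDMatrix(D, np.arange(3)), threshold=10.0)
        assert a.n_clusters == 1

    def test_two_tight_pairs(self):
        from abdyn.clustering import RMSDMatrix

        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.2
        D[2, 3] = D[3, 2] = 0.2
        a = upgma_cut(RMSDMatrix(D, np.arange(4)), threshold=1.0)
        assert a.n_clusters == 2
        assert a.labels[0] == a.labels[1]
        assert a.labels[2] == a.labels[3]

    def test_merge_heights_match_hand_recursion(self):
        # classic 5-leaf example, agglomerated by hand with size-weighted
        # average linkage
        from abdyn.clustering import RMSDMatrix

        D = np.array(
            [
                [0, 17, 21, 31, 23],
                [17, 0, 30, 34, 21],
                [21, 30, 0, 28, 39],
                [31, 34, 28, 0, 43],
                [23, 21, 39, 43, 0],
            ],
            dtype=float,
        )
        a = upgma_cut(RMSDMatrix(D, np.arange(5)), threshold=100.0)
        heights = sorted(a.dendrogram[:, 2])
        expected = sorted(_upgma_heights_oracle(D))
        np.testing.assert_allclose(heights, expected, atol=1e-10)

    def test_monotone_coarsening(self, three_state_trajectory):
        traj, _ = three_state_trajectory
        M = pairwise_rmsd(traj, traj.topology.ca_indices())
        ks = [upgma_cut(M, t).n_clusters for t in (0.0, 0.3, 0.5, 2.0, 100.0)]
        assert ks == sorted(ks, reverse=True)
        assert ks[-1] == 1

    def test_negative_threshold_rejected(self, three_state_trajectory):
        traj, _ = three_state_trajectory
        M = pairwise_rmsd(traj, traj.topology.ca_indices())
        with pytest.raises(ValueError):
            upgma_cut(M, -0.1)

    def test_planted_state_recovery(self, three_state_trajectory):
        traj, truth = three_state_trajectory
        M = pairwise_rmsd(traj, traj.topology.ca_indices())
        a = upgma_cut(M, 0.5)
        assert a.n_clusters == 3
        assert label_agreement(truth.frame_state_labels, a.labels) == 1.0


def _upgma_heights_oracle(D):
    """Direct average-linkage agglomeration from the definition.

    Cluster distance = arithmetic mean of the original distances over all
    cross pairs of leaves; merge the closest pair until one cluster is left.
    """
    clusters = [[i] for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [D[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [
            c for k, c in enumerate(clusters) if k not in (a, b)
        ] + [merged]
    return heights


class TestSummaries:
    def test_radius_of_gyration_analytic(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(two) == pytest.approx(1.0)
        cube = np.array(
            [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)],
            dtype=float,
        )
        assert radius_of_gyration(cube) == pytest.approx(np.sqrt(3.0))

    def test_rg_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((3, 3)), subset=np.array([], dtype=int))

    def test_static_trajectory_summary(self):
        top = make_ca_topology(4)
        frame = _random_points(4, seed=9)
        traj = Trajectory(top, np.stack([frame] * 3))
        M = pairwise_rmsd(traj, np.arange(4))
        a = upgma_cut(M, 1.0)
        (s,) = cluster_summary(traj, a, rmsd=M, mass_mode="unit")
        assert s.population_fraction == 1.0
        assert s.rg_sd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(s.rmsf, 0.0, atol=1e-12)

    def test_population_fractions_sum_to_one(self, three_state_trajectory):
        traj, _ = three_state_trajectory
        M = pairwise_rmsd(traj, traj.topology.ca_indices())
        a = relabel_by_rg(traj, upgma_cut(M, 0.5))
        summaries = cluster_summary(traj, a, rmsd=M)
        assert sum(s.population_fraction for s in summaries) == pytest.approx(1.0)
        rgs = [s.rg_mean for s in summaries]
        assert rgs == sorted(rgs)  # cluster ids ordered by increasing Rg

    def test_medoid_permutation_invariance(self, three_state_trajectory):
        traj, _ = three_state_trajectory
        M = pairwise_rmsd(traj, traj.topology.ca_indices())
        members = np.arange(0, 30)
        med = medoid_frame(M, members)
        rng = np.random.default_rng(0)
        perm = rng.permutation(members)
        assert medoid_frame(M, perm) == med


class TestEssentialDynamics:
    def test_single_axis_motion_one_mode(self):
        top = make_ca_topology(4)
        base = _random_points(4, seed=10) * 5
        frames = []
        for a in np.linspace(-1, 1, 11):
            f = base.copy()
            f[0, 0] += a  # one atom moves along x only
            frames.append(f)
        traj = Trajectory(top, np.array(frames))
        w, V, extremes = essential_dynamics(traj, np.arange(4), align=False)
        assert (w > 1e-10 * w[0]).sum() == 1
        assert extremes[0] == (0, 10) or extremes[0] == (10, 0)

    def test_trace_identity_and_orthonormality(self, three_state_trajectory):
        traj, _ = three_state_trajectory
        ca = traj.topology.ca_indices()
        w, V, _ = essential_dynamics(traj, ca)
        from abdyn.clustering import align_frames

        coords = align_frames(traj.coords, traj.coords[0], ca)
        mean = coords.mean(axis=0)
        coords = align_frames(coords, mean, ca)[:, ca, :]
        X = coords.reshape(traj.n_frames, -1)
        total_var = ((X - X.mean(axis=0)) ** 2).sum() / (traj.n_frames - 1)
        assert w.sum() == pytest.approx(total_var, rel=1e-8)
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_single_frame_rejected(self):
        top = make_ca_topology(3)
        traj = Trajectory(top, _random_points(3, seed=0)[None])
        with pytest.raises(ValueError):
            essential_dynamics(traj, np.arange(3))
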