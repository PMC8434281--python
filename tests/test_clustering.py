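"""Superposition, pairwise RMSD, greedy neighbour-count clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from zincturn.clustering import (
    MotifClustering,
    cluster_summary,
    gromos_cluster,
    kabsch_superpose,
    pairwise_rmsd,
)
from zincturn.conformation import TorsionProfile


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        rot, t, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(18, 3)) * 4
        true_rot = Rotation.random(random_state=2).as_matrix()
        y = x @ true_rot.T + np.array([3.0, -1.0, 2.0])
        rot, t, rmsd = kabsch_superpose(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        """Minimized RMSD agrees with scipy's quaternion-based alignment."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            x = rng.normal(size=(18, 3)) * 3
            y = x + rng.normal(size=(18, 3)) * 0.5
            _, _, ours = kabsch_superpose(x, y)
            xc = x - x.mean(axis=0)
            yc = y - y.mean(axis=0)
            _, rssd = Rotation.align_vectors(xc, yc)
            oracle = rssd / np.sqrt(len(x))
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        y = x * np.array([1.0, 1.0, -1.0])
        rot, _, rmsd = kabsch_superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1  # a reflection cannot be absorbed

    def test_degenerate_inputs_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)


class TestPairwiseRmsd:
    def test_single_item(self):
        mat = pairwise_rmsd([np.random.default_rng(0).normal(size=(18, 3))])
        assert mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_symmetry_zero_diagonal_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        sets = [rng.normal(size=(18, 3)) for _ in range(5)]
        mat = pairwise_rmsd(sets)
        assert np.allclose(mat, mat.T, atol=1e-12)
        assert np.allclose(np.diag(mat), 0.0)
        perm = [3, 1, 4, 0, 2]
        mat_p = pairwise_rmsd([sets[i] for i in perm])
        assert np.allclose(mat_p, mat[np.ix_(perm, perm)], atol=1e-9)

    def test_noise_driven_rmsd_matches_monte_carlo_expectation(self):
        # two copies of one motif with isotropic sd-0.1 noise: E[RMSD^2] = 6 sd^2
        # (before superposition; fitting removes ~6/3n of it)
        rng = np.random.default_rng(6)
        base = rng.normal(size=(18, 3)) * 4
        sd = 0.1
        vals = []
        for _ in range(300):
            a = base + rng.normal(scale=sd, size=base.shape)
            b = base + rng.normal(scale=sd, size=base.shape)
            _, _, r = kabsch_superpose(a, b)
            vals.append(r**2)
        expected = 6 * sd**2 * (1 - 6 / (3 * len(base)))
        assert np.mean(vals) == pytest.approx(expected, rel=0.1)


def brute_force_gromos(matrix, cutoff):
    """Literal re-statement of the greedy algorithm, kept deliberately dumb."""
    n = matrix.shape[0]
    remaining = set(range(n))
    clusters, outliers = [], []
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if j != i and matrix[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in remaining if j != best and matrix[best, j] <= cutoff)
        if members:
            clusters.append((best, members))
        else:
            outliers.append(best)
        remaining -= {best, *members}
    clusters.sort(key=lambda c: (-(1 + len(c[1])), c[0]))
    return clusters, sorted(outliers)


class TestGromos:
    def test_worked_example(self):
        # 5 items: 1-2-3 chained at 0.2/0.35, 4-5 at 0.3 (0-indexed: 0..4)
        big = 10.0
        mat = np.full((5, 5), big)
        np.fill_diagonal(mat, 0.0)
        for i, j, d in [(0, 1, 0.2), (1, 2, 0.2), (0, 2, 0.35), (3, 4, 0.3)]:
            mat[i, j] = mat[j, i] = d
        res = gromos_cluster(mat, cutoff=0.4)
        # items 0,1,2 all have two neighbours; the documented tie rule
        # (lowest input index) makes 0 the centroid
        assert res.clusters[0] == (0, [1, 2])
        assert res.clusters[1] == (3, [4])
        assert res.outliers == []

    def test_all_far_apart_every_item_is_an_outlier(self):
        mat = np.full((4, 4), 5.0)
        np.fill_diagonal(mat, 0.0)
        res = gromos_cluster(mat, cutoff=0.4)
        assert res.clusters == [] and res.outliers == [0, 1, 2, 3]

    def test_single_item_is_an_outlier(self):
        res = gromos_cluster(np.zeros((1, 1)), cutoff=0.4)
        assert res.outliers == [0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = int(rng.integers(1, 9))
            d = rng.uniform(0.0, 1.0, size=(n, n))
            mat = (d + d.T) / 2
            np.fill_diagonal(mat, 0.0)
            cutoff = float(rng.uniform(0.1, 0.8))
            ours = gromos_cluster(mat, cutoff)
            ref_clusters, ref_outliers = brute_force_gromos(mat, cutoff)
            assert [(c, m) for c, m in ours.clusters] == ref_clusters
            assert ours.outliers == ref_outliers

    def test_partition_property(self):
        rng = np.random.default_rng(12)
        n = 30
        d = rng.uniform(0, 1, size=(n, n))
        mat = (d + d.T) / 2
        np.fill_diagonal(mat, 0)
        res = gromos_cluster(mat, cutoff=0.3)
        seen = sorted([res.clusters[i][0] for i in range(len(res.clusters))]
                      + [m for _, mm in res.clusters for m in mm]
                      + res.outliers)
        assert seen == list(range(n))
        # every member within cutoff of its centroid
        for c, members in res.clusters:
            assert all(mat[c, m] <= 0.3 for m in members)


class TestClusterSummary:
    def _profile(self, chi_cys, chi_his=0.0):
        return TorsionProfile(-60, -40, -60, -40, -60, -40, chi_cys, chi_his)

    def test_circular_mean_wraparound(self):
        clustering = MotifClustering(clusters=[(0, [1])], outliers=[], cutoff=0.4)
        profiles = [self._profile(175.0), self._profile(-179.0)]
        rows = cluster_summary(clustering, profiles)
        assert rows[0]["chi1_cys_mean"] == pytest.approx(178.0, abs=1e-6)

    def test_singleton_summary(self):
        clustering = MotifClustering(clusters=[], outliers=[0], cutoff=0.4)
        rows = cluster_summary(clustering, [self._profile(72.0, -75.0)])
        assert rows[0]["size"] == 1
        assert rows[0]["chi1_cys_mean"] == pytest.approx(72.0)
        assert rows[0]["chi1_cys_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_cluster_means_recovered(self):
        rng = np.random.default_rng(13)
        true = dict(phi1=-63, psi1=-26, phi2=-91, psi2=-34, phi3=-116, psi3=10,
                    chi1_cys=177, chi1_his=-61)
        profiles = []
        for _ in range(16):
            jit = {k: ((v + rng.normal(0, 5) + 180) % 360) - 180
                   for k, v in true.items()}
            profiles.append(TorsionProfile(**jit))
        clustering = MotifClustering(clusters=[(0, list(range(1, 16)))],
                                     outliers=[], cutoff=0.4)
        rows = cluster_summary(clustering, profiles)
        for key, target in true.items():
            measured = rows[0][f"{key}_mean"]
            delta = abs(((measured - target) + 180) % 360 - 180)
            assert delta < 3.0, key
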