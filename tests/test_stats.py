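"""Tests of the spatial summary statistics against brute-force oracles
and closed forms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormswarm.dataset import TrajectoryDataset
from wormswarm.fixtures import generate_fixtures
from wormswarm.stats import (
    branch_length_distribution,
    dispersion_and_kurtosis,
    knn_density,
    pair_correlation,
    single_linkage_merge_distances,
    summarize_dataset,
    velocity_neighbor_correlation,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_pair_counts(points, edges, side):
    """O(n^2) python-loop pair counting with minimum-image distances."""
    counts = np.zeros(len(edges) - 1)
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            d = points[i] - points[j]
            d = d - side * np.round(d / side)
            r = float(np.hypot(*d))
            b = np.searchsorted(edges, r, side="right") - 1
            if 0 <= b < len(counts):
                counts[b] += 1
    return counts


def brute_single_linkage(points):
    """O(n^3) agglomeration: repeatedly merge the closest pair of clusters
    under the single-linkage (minimum pairwise distance) criterion."""
    clusters = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(
                    float(np.hypot(*(points[i] - points[j])))
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.sort(np.array(merges))


# ---------------------------------------------------------------------------
# knn density
# ---------------------------------------------------------------------------

class TestKnnDensity:
    def test_six_neighbours_on_unit_circle(self):
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.vstack(
            [[0.0, 0.0], np.column_stack([np.cos(ang), np.sin(ang)]),
             [[5.0, 5.0], [-4.0, 3.0]]]
        )
        assert knn_density(pts, k=6, focal_index=0) == pytest.approx(6 / np.pi)

    def test_k1_two_points(self):
        assert knn_density(np.array([[0.0, 0.0], [2.0, 0.0]]), k=1,
                           focal_index=0) == pytest.approx(1 / (4 * np.pi))

    def test_insufficient_points(self):
        with pytest.raises(ValueError, match="at least"):
            knn_density(np.zeros((5, 2)), k=6)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(0, 2 * np.pi))
    def test_rigid_motion_invariance(self, tx, ty, ang):
        pts = np.random.default_rng(0).uniform(0, 5, size=(20, 2))
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = pts @ R.T + [tx, ty]
        assert np.allclose(knn_density(pts, k=6), knn_density(moved, k=6))


# ---------------------------------------------------------------------------
# S1
# ---------------------------------------------------------------------------

class TestPairCorrelation:
    edges = np.arange(0.0, 4.0 + 1e-9, 0.1)

    def test_csr_is_flat_at_one(self):
        rng = np.random.default_rng(42)
        frames = [rng.uniform(0, 8, size=(1000, 2)) for _ in range(3)]
        s1 = pair_correlation(frames, self.edges, side=8.0)
        assert np.all(np.abs(s1[1:] - 1.0) < 0.1)  # +-10% at >=1e3 points

    def test_two_points_single_bin(self):
        pts = np.array([[1.0, 1.0], [1.0, 2.25]])  # distance 1.25
        s1 = pair_correlation([pts], self.edges, side=8.0)
        nz = np.nonzero(s1)[0]
        assert len(nz) == 1
        assert self.edges[nz[0]] <= 1.25 < self.edges[nz[0] + 1]

    def test_agrees_with_brute_force_counting(self):
        """Optimised implementation matches O(n^2) loop counting exactly."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 8, size=(200, 2))
        obs = brute_pair_counts(pts, self.edges, side=8.0)
        s1 = pair_correlation([pts], self.edges, side=8.0)
        # reconstruct observed counts from the returned ratios
        from wormswarm.stats import _torus_disc_area

        expected = 200 * 199 / 2 * np.diff(_torus_disc_area(self.edges, 8.0)) / 64.0
        assert np.allclose(s1 * expected, obs)

    def test_duplicated_points_flagged(self):
        pts = np.zeros((10, 2)) + 1.0
        with pytest.warns(UserWarning, match="coincident"):
            s1 = pair_correlation([pts], self.edges, side=8.0)
        assert s1[0] > 100  # first bin diverges

    def test_bounded_domain_csr_flat(self):
        rng = np.random.default_rng(3)
        frames = [rng.uniform(0, 5, size=(800, 2)) for _ in range(2)]
        s1 = pair_correlation(
            frames, np.arange(0, 2 + 1e-9, 0.2), domain=(0, 5, 0, 5), rng=0
        )
        assert np.all(np.abs(s1 - 1.0) < 0.15)


# ---------------------------------------------------------------------------
# S2
# ---------------------------------------------------------------------------

class TestBranchLengths:
    def test_hand_computed_1d(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        merges = np.sort(single_linkage_merge_distances(pts))
        assert np.allclose(merges, [1.0, 2.0])

    def test_n_minus_one_merges(self):
        pts = np.random.default_rng(0).uniform(0, 5, size=(23, 2))
        assert len(single_linkage_merge_distances(pts)) == 22

    def test_two_tight_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 0.07, size=(10, 2))
        b = rng.uniform(0, 0.07, size=(10, 2)) + [5.0, 0.0]
        merges = np.sort(single_linkage_merge_distances(np.vstack([a, b])))
        assert merges[-1] == pytest.approx(5.0, abs=0.2)
        assert np.all(merges[:-1] <= 0.1)

    def test_agrees_with_cubic_oracle(self):
        pts = np.random.default_rng(9).uniform(0, 4, size=(40, 2))
        fast = np.sort(single_linkage_merge_distances(pts))
        assert np.allclose(fast, brute_single_linkage(pts))

    def test_histogram_sums_to_one(self):
        frames = [np.random.default_rng(i).uniform(0, 8, (30, 2)) for i in range(4)]
        s2 = branch_length_distribution(frames, np.arange(0, 8.1, 0.2))
        assert s2.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# S3 / S4
# ---------------------------------------------------------------------------

class TestDispersionKurtosis:
    def test_gaussian_moments(self):
        rng = np.random.default_rng(11)
        frames = [rng.normal(0, 1.0, size=(20000, 2))]
        s3, s4 = dispersion_and_kurtosis(frames)
        assert s3 == pytest.approx(1.0, rel=0.05)
        assert s4 == pytest.approx(3.0, rel=0.05)

    def test_uniform_kurtosis_nine_fifths(self):
        rng = np.random.default_rng(13)
        frames = [rng.uniform(-1, 1, size=(50000, 2))]
        _, s4 = dispersion_and_kurtosis(frames)
        assert s4 == pytest.approx(1.8, rel=0.03)

    def test_heavy_tailed_exceeds_uniform(self):
        rng = np.random.default_rng(17)
        uniform = [rng.uniform(0, 8, size=(200, 2))]
        clustered = [np.vstack([
            rng.normal(4, 0.1, size=(180, 2)), rng.uniform(0, 8, size=(20, 2))
        ])]
        _, s4_u = dispersion_and_kurtosis(uniform)
        _, s4_c = dispersion_and_kurtosis(clustered)
        assert s4_c > s4_u

    def test_degenerate_frames_skipped(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s3, _ = dispersion_and_kurtosis(
                [np.ones((5, 2)), np.random.default_rng(0).normal(size=(50, 2))]
            )
        assert s3 > 0


# ---------------------------------------------------------------------------
# velocity-neighbour correlation
# ---------------------------------------------------------------------------

class TestVelocityNeighborCorrelation:
    bins = np.array([0.0, 1.0, 2.0])

    def _pair_dataset(self, step):
        # worm 0 moves by `step` each frame; worm 1 stays at (0.5, 0)
        c = np.zeros((3, 2, 2))
        c[:, 1] = [0.5, 0.0]
        c[:, 0, 0] = np.arange(3) * step
        return TrajectoryDataset(times=np.arange(1.0, 4.0), centroids=c)

    def test_towards_neighbour_plus_one(self):
        ds = self._pair_dataset(step=0.01)
        out = velocity_neighbor_correlation(ds, self.bins)
        assert out[0] == pytest.approx(1.0)

    def test_away_from_neighbour_minus_one(self):
        ds = self._pair_dataset(step=-0.01)
        out = velocity_neighbor_correlation(ds, self.bins)
        assert out[0] == pytest.approx(-1.0)

    def test_isotropic_uncorrelated(self):
        rng = np.random.default_rng(23)
        F, N = 30, 100
        c = np.cumsum(rng.normal(0, 0.05, size=(F, N, 2)), axis=0) + \
            rng.uniform(0, 8, size=(1, N, 2))
        ds = TrajectoryDataset(times=np.arange(1.0, F + 1.0),
                               centroids=np.mod(c, 8.0), arena_side=8.0)
        out = velocity_neighbor_correlation(ds, np.arange(0, 2.1, 0.5))
        assert np.all(np.abs(out) < 0.05)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

class TestSummarizeDataset:
    def test_deterministic(self):
        ds = generate_fixtures("clustered", seed=2)
        a = summarize_dataset(ds, rng=0)
        b = summarize_dataset(ds, rng=0)
        assert np.array_equal(a.s1, b.s1, equal_nan=True)
        assert np.array_equal(a.s2, b.s2)
        assert a.s3 == b.s3 and a.s4 == b.s4

    def test_clustered_vs_uniform_orderings(self):
        clustered = summarize_dataset(generate_fixtures("clustered", seed=4))
        uniform = summarize_dataset(generate_fixtures("uniform", seed=4))
        assert clustered.s1_small_r_mean() > uniform.s1_small_r_mean()
        assert clustered.s3 < uniform.s3

    def test_json_round_trip(self):
        from wormswarm.stats import SummaryStatSet

        st = summarize_dataset(generate_fixtures("uniform", seed=1))
        rt = SummaryStatSet.from_json(st.to_json())
        assert np.allclose(rt.s1, st.s1, equal_nan=True)
        assert rt.s3 == pytest.approx(st.s3)
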