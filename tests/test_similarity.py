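"""Distances, clustering, Mantel tests, same-vs-different analysis."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beecalim.similarity import (
    euclidean_distance,
    mantel_test,
    mean_distance_matrix,
    pairwise_distances,
    same_vs_different,
    ward_clustering,
)
from beecalim.types import DistanceMatrix, Mask, ResponseMap, ValidationError


def rmap(values, mask=None, stimulus="o", bee="b", pres=1):
    values = np.asarray(values, dtype=float)
    mask = mask or Mask(np.ones(values.shape, dtype=bool))
    return ResponseMap(values, mask, bee, stimulus, pres)


class TestEuclideanDistance:
    def test_identical_maps_distance_zero(self, rng):
        a = rmap(rng.standard_normal((4, 4)))
        assert euclidean_distance(a, a) == 0.0

    def test_delta_at_k_pixels_closed_form(self):
        base = np.zeros((4, 4))
        shifted = base.copy()
        delta, k = 2.5, 5
        shifted.ravel()[:k] += delta
        assert euclidean_distance(rmap(base), rmap(shifted)) == pytest.approx(
            delta * math.sqrt(k)
        )

    def test_matches_scalar_loop(self, rng):
        a, b = rng.standard_normal((3, 3)), rng.standard_normal((3, 3))
        total = 0.0
        for y in range(3):
            for x in range(3):
                total += (a[y, x] - b[y, x]) ** 2
        assert abs(euclidean_distance(rmap(a), rmap(b)) - math.sqrt(total)) < 1e-12

    def test_squared_mode_is_square_of_distance(self, rng):
        a = rmap(rng.standard_normal((3, 3)))
        b = rmap(rng.standard_normal((3, 3)))
        d = euclidean_distance(a, b)
        assert euclidean_distance(a, b, squared=True) == pytest.approx(d**2)

    def test_mask_mismatch_rejected(self, rng):
        a = rmap(np.zeros((3, 3)))
        b = rmap(np.zeros((3, 3)), mask=Mask(np.eye(3, dtype=bool)))
        with pytest.raises(ValidationError):
            euclidean_distance(a, b)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms(self, seed):
        r = np.random.default_rng(seed)
        mask = Mask(r.random((4, 4)) > 0.3) if r.random() > 0.5 else None
        if mask is not None and not mask.include.any():
            mask = None
        maps = [rmap(r.standard_normal((4, 4)), mask=mask) for _ in range(3)]
        a, b, c = maps
        dab = euclidean_distance(a, b)
        assert dab >= 0
        assert dab == euclidean_distance(b, a)
        assert dab <= euclidean_distance(a, c) + euclidean_distance(c, b) + 1e-9


class TestPairwiseDistances:
    def test_sixteen_odorants_give_120_pairs(self, rng):
        maps = [rmap(rng.standard_normal((4, 4)), stimulus=f"o{i}") for i in range(16)]
        dm = pairwise_distances(maps)
        assert dm.values.shape == (16, 16)
        assert dm.condensed().size == 120

    def test_identical_pair_zero_matrix(self, rng):
        vals = rng.standard_normal((3, 3))
        dm = pairwise_distances([rmap(vals, stimulus="a"), rmap(vals, stimulus="b")])
        assert np.all(dm.values == 0.0)

    def test_matches_all_pairs_loop(self, rng):
        maps = [rmap(rng.standard_normal((3, 3)), stimulus=f"o{i}") for i in range(4)]
        dm = pairwise_distances(maps)
        for i, j in itertools.combinations(range(4), 2):
            assert dm.values[i, j] == pytest.approx(
                euclidean_distance(maps[i], maps[j])
            )

    def test_duplicate_labels_rejected(self, rng):
        maps = [rmap(rng.standard_normal((3, 3)), stimulus="same") for _ in range(2)]
        with pytest.raises(ValidationError):
            pairwise_distances(maps)


class TestMeanDistanceMatrix:
    def test_single_matrix_is_identity_operation(self, rng):
        x = rng.random((3, 3))
        dm = DistanceMatrix((x + x.T) - np.diag(np.diag(x + x.T)), ["a", "b", "c"])
        mean, sem = mean_distance_matrix([dm])
        np.testing.assert_allclose(mean.values, dm.values)
        assert np.all(sem.values == 0.0)

    def test_two_matrix_mean_and_sem(self):
        d2 = DistanceMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), ["a", "b"])
        d4 = DistanceMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]), ["a", "b"])
        mean, sem = mean_distance_matrix([d2, d4])
        assert mean.values[0, 1] == pytest.approx(3.0)
        assert sem.values[0, 1] == pytest.approx(1.0)

    def test_matches_entrywise_loop(self, rng):
        mats = []
        for _ in range(5):
            x = np.triu(rng.random((4, 4)), k=1)
            mats.append(DistanceMatrix(x + x.T, list("abcd")))
        mean, _ = mean_distance_matrix(mats)
        for i in range(4):
            for j in range(4):
                expected = sum(m.values[i, j] for m in mats) / 5.0
                assert mean.values[i, j] == pytest.approx(expected)

    def test_label_mismatch_rejected(self):
        a = DistanceMatrix(np.zeros((2, 2)), ["a", "b"])
        b = DistanceMatrix(np.zeros((2, 2)), ["a", "c"])
        with pytest.raises(ValidationError):
            mean_distance_matrix([a, b])


class TestSameVsDifferent:
    @staticmethod
    def build(per_values):
        """per_values: {(bee, stim, pres): flat pixel list}."""
        return {
            k: rmap(np.asarray(v, dtype=float).reshape(1, -1), stimulus=k[1],
                    bee=k[0], pres=k[2])
            for k, v in per_values.items()
        }

    def test_hand_worked_two_bee_two_odor_dataset(self):
        data = self.build(
            {
                ("b1", "x", 1): [0.0, 0.0],
                ("b1", "x", 2): [1.0, 0.0],  # same-odor dist 1
                ("b1", "y", 1): [3.0, 0.0],
                ("b1", "y", 2): [3.0, 4.0],  # same-odor dist 4
                ("b2", "x", 1): [0.0, 0.0],
                ("b2", "x", 2): [0.0, 2.0],  # same-odor dist 2
                ("b2", "y", 1): [6.0, 0.0],
                ("b2", "y", 2): [6.0, 8.0],  # same-odor dist 8
            }
        )
        res = same_vs_different(data)
        # bee1 same mean: (1+4)/2 = 2.5
        # bee1 different pairs (x_p, y_q): |(0,0)-(3,0)|=3, |(0,0)-(3,4)|=5,
        #   |(1,0)-(3,0)|=2, |(1,0)-(3,4)|=sqrt(4+16)=sqrt(20)
        b1_diff = (3 + 5 + 2 + math.sqrt(20)) / 4
        assert res.same_mean[0] == pytest.approx(2.5)
        assert res.different_mean[0] == pytest.approx(b1_diff)
        # closed-form paired t on the two per-bee differences
        d = res.same_mean - res.different_mean
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(2))
        assert res.t == pytest.approx(t_expected)
        assert res.df == 1

    def test_presentation_label_swap_invariance(self, rng):
        data = {}
        for bee in ("b1", "b2", "b3"):
            for stim in ("x", "y", "z"):
                for p in (1, 2):
                    data[(bee, stim, p)] = rng.standard_normal(4)
        res1 = same_vs_different(self.build(data))
        swapped = {(b, s, 3 - p): v for (b, s, p), v in data.items()}
        res2 = same_vs_different(self.build(swapped))
        np.testing.assert_allclose(res1.same_mean, res2.same_mean)
        np.testing.assert_allclose(res1.different_mean, res2.different_mean)
        assert res1.t == pytest.approx(res2.t)

    def test_zero_noise_same_distances_vanish(self, rng):
        data = {}
        for bee in ("b1", "b2"):
            for stim in ("x", "y"):
                v = rng.standard_normal(4)
                data[(bee, stim, 1)] = v
                data[(bee, stim, 2)] = v.copy()
        res = same_vs_different(self.build(data))
        assert np.all(res.same_mean == 0.0)
        assert np.all(res.different_mean > 0.0)

    def test_missing_presentation_rejected(self, rng):
        data = self.build({("b1", "x", 1): [1.0], ("b1", "y", 1): [2.0],
                           ("b1", "y", 2): [3.0]})
        with pytest.raises(ValidationError, match="missing presentation"):
            same_vs_different(data)


def brute_force_ward(points):
    """Greedy Ward agglomeration from raw coordinates, evaluating the
    within-cluster variance increase of every candidate merge."""
    clusters = [[i] for i in range(len(points))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            merged = clusters[i] + clusters[j]

            def ess(members):
                pts = points[members]
                return ((pts - pts.mean(axis=0)) ** 2).sum()

            cost = ess(merged) - ess(clusters[i]) - ess(clusters[j])
            if best is None or cost < best[0]:
                best = (cost, i, j)
        _, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j])))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] + clusters[j]
        ]
    return merges


class TestWardClustering:
    def test_two_items_merge_at_their_distance(self):
        dm = DistanceMatrix(np.array([[0.0, 7.0], [7.0, 0.0]]), ["a", "b"])
        dendro = ward_clustering(dm)
        assert dendro.heights[0] == pytest.approx(7.0)

    def test_line_points_match_brute_force_agglomeration(self):
        points = np.array([[0.0], [1.0], [10.0], [11.0]])
        diffs = points[:, None, 0] - points[None, :, 0]
        dm = DistanceMatrix(np.abs(diffs), ["p0", "p1", "p2", "p3"])
        dendro = ward_clustering(dm)
        oracle = brute_force_ward(points)
        # first two merges join {0,1} and {10,11}
        assert oracle[0] == (frozenset({0}), frozenset({1}))
        assert oracle[1] == (frozenset({2}), frozenset({3}))
        merged_pairs = {
            frozenset(dendro.linkage[k, :2].astype(int)) for k in range(2)
        }
        assert merged_pairs == {frozenset({0, 1}), frozenset({2, 3})}

    def test_heights_nondecreasing_on_random_metric_input(self, rng):
        for _ in range(10):
            pts = rng.standard_normal((8, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix(d, [f"p{i}" for i in range(8)])
            h = ward_clustering(dm).heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_single_item_rejected(self):
        with pytest.raises(ValidationError):
            ward_clustering(DistanceMatrix(np.zeros((1, 1)), ["a"]))


def random_dm(rng, n=4, labels=None):
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(d, labels or [f"o{i}" for i in range(n)])


class TestMantel:
    def test_self_comparison(self, rng):
        dm = random_dm(rng, n=10)
        res = mantel_test(dm, dm, n_permutations=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_affine_transform_gives_r_one(self, rng):
        dm = random_dm(rng, n=8)
        values = 0.3 + 2.0 * dm.values
        np.fill_diagonal(values, 0.0)
        affine = DistanceMatrix(values, dm.labels)
        res = mantel_test(dm, affine, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_matches_monte_carlo(self, rng):
        d1, d2 = random_dm(rng, n=4), random_dm(rng, n=4)
        exact = mantel_test(d1, d2)  # 4! = 24 <= cap: exhaustive
        assert exact.exhaustive and exact.n_permutations == 24
        mc = mantel_test(d1, d2, n_permutations=10000, seed=3, exhaustive_cap=1)
        # binomial error at 10^4 draws
        se = math.sqrt(exact.p * (1 - exact.p) / 10000)
        assert abs(mc.p - exact.p) < 4 * se + 2e-4

    def test_r_agrees_with_scikit_bio(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        d1, d2 = random_dm(rng, n=10), random_dm(rng, n=10)
        res = mantel_test(d1, d2, n_permutations=99, seed=0)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(d1.values, d1.labels), SkbioDM(d2.values, d2.labels),
            permutations=0,
        )
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        flat = DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        with pytest.raises(ValidationError):
            mantel_test(flat, random_dm(rng, n=4, labels=list("abcd")))

    def test_label_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            mantel_test(random_dm(rng, 4, list("abcd")), random_dm(rng, 4, list("abce")))
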