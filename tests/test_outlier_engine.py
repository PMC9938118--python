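"""Distance matrices, spectral structure, size penalty, score transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genofirst.functional_model import InputError
from genofirst.outlier_engine import (
    ScoreParams,
    absorb_small_clusters,
    build_distance_matrix,
    detect_structure,
    embed_and_cluster,
    gaussian_similarity,
    pairwise_profile_distance,
    raw_outlier_scores,
    score_term,
    size_penalty,
    transform_scores,
)

from conftest import make_profile


def brute_force_distance(ga, gb, dists):
    """Independent site-by-site oracle for the summed pair distance."""
    factor = {(0, 0): 0, (1, 1): 0, (2, 2): 0,
              (0, 1): 1, (1, 0): 1, (1, 2): 1, (2, 1): 1,
              (0, 2): 4, (2, 0): 4}
    total = 0.0
    for a, b, d in zip(ga, gb, dists):
        total += factor[(max(a, 0), max(b, 0))] * d
    return total


class TestPairwiseDistance:
    def test_identical_vectors_zero(self):
        profile = make_profile([1.0, 2.0, 0.5])
        g = np.array([1, 2, 0])
        assert pairwise_profile_distance(g, g, profile) == 0.0

    def test_single_het_site(self):
        profile = make_profile([1.2])
        assert pairwise_profile_distance([0], [1], profile) == pytest.approx(1.2)

    def test_mixed_sites_sum(self):
        profile = make_profile([1.0, 0.5])
        # opposite hom at d=1.0 plus het-vs-homref at d=0.5 -> 4 + 0.5
        assert pairwise_profile_distance([0, 0], [2, 1], profile) == pytest.approx(4.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            pairwise_profile_distance([0], [0, 1], make_profile([1.0, 1.0]))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 7))
        profile = make_profile(rng.uniform(0, 5, size=m))
        ga = rng.integers(-1, 3, size=m)
        gb = rng.integers(-1, 3, size=m)
        assert pairwise_profile_distance(ga, gb, profile) == pytest.approx(
            brute_force_distance(ga, gb, profile.distances)
        )


class TestDistanceMatrix:
    def test_entrywise_oracle_on_ten_individuals(self, rng):
        profile = make_profile(rng.uniform(0, 4, size=5))
        g = rng.integers(0, 3, size=(10, 5)).astype(np.int8)
        dm = build_distance_matrix(g, profile, [f"i{i}" for i in range(10)])
        for i in range(10):
            for j in range(10):
                assert dm.D[i, j] == pytest.approx(
                    brute_force_distance(g[i], g[j], profile.distances)
                )
        assert np.allclose(dm.D, dm.D.T)
        assert np.all(np.diag(dm.D) == 0)

    def test_empty_profile_flagged_degenerate(self):
        profile = make_profile([])
        dm = build_distance_matrix(
            np.zeros((3, 0), dtype=np.int8), profile, ["a", "b", "c"]
        )
        assert dm.degenerate
        assert np.all(dm.D == 0)


class TestGaussianSimilarity:
    def test_zero_distance_maps_to_one(self, rng):
        profile = make_profile([1.0])
        g = rng.integers(0, 3, size=(6, 1)).astype(np.int8)
        dm = build_distance_matrix(g, profile, list("abcdef"))
        S = gaussian_similarity(dm)
        assert np.all(np.diag(S) == 1.0)
        assert np.all((S > 0) & (S <= 1))

    def test_monotone_decreasing_in_distance(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        dm = build_distance_matrix(g, profile, ids)
        S = gaussian_similarity(dm)
        iu = np.triu_indices(len(ids), 1)
        order = np.argsort(dm.D[iu])
        assert np.all(np.diff(S[iu][order]) <= 1e-12)

    def test_bandwidth_is_median_off_diagonal(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        dm = build_distance_matrix(g, profile, ids)
        sigma = np.median(dm.D[~np.eye(len(ids), dtype=bool)])
        S = gaussian_similarity(dm)
        np.testing.assert_allclose(
            S, np.exp(-dm.D**2 / (2 * sigma**2)), atol=1e-12
        )

    def test_all_zero_distances_signal_degenerate(self):
        profile = make_profile([1.0])
        dm = build_distance_matrix(
            np.zeros((4, 1), dtype=np.int8), profile, list("abcd")
        )
        assert gaussian_similarity(dm) is None


class TestStructureDetection:
    def test_two_blocks_detected(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        S = gaussian_similarity(build_distance_matrix(g, profile, ids))
        has, k, _ = detect_structure(S)
        assert has and k == 2

    def test_two_individuals_never_structured(self):
        profile = make_profile([1.0])
        dm = build_distance_matrix(
            np.array([[0], [2]], dtype=np.int8), profile, ["a", "b"]
        )
        has, k, _ = detect_structure(gaussian_similarity(dm))
        assert not has and k is None

    def test_iid_genotypes_rarely_structured(self):
        # no planted structure: Hardy-Weinberg draws at moderate frequencies
        false_count = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            mafs = rng.uniform(0.05, 0.5, size=6)
            profile = make_profile(rng.uniform(0.5, 3.0, size=6), mafs)
            probs = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2], 1)
            g = np.stack(
                [rng.choice(3, size=40, p=probs[j]) for j in range(6)], axis=1
            ).astype(np.int8)
            dm = build_distance_matrix(g, profile, [f"i{i}" for i in range(40)])
            S = gaussian_similarity(dm)
            has, _, _ = detect_structure(S)
            false_count += not has
        assert false_count >= 0.9 * n_seeds


class TestEmbedAndCluster:
    def test_blocks_recovered_exactly(self, two_block_setup):
        profile, g, ids, labels = two_block_setup
        S = gaussian_similarity(build_distance_matrix(g, profile, ids))
        a = embed_and_cluster(S, 2, seed=0)
        agreement = max(
            (a.labels == labels).mean(), (a.labels != labels).mean()
        )
        assert agreement == 1.0

    def test_k_equal_n_gives_singletons(self):
        profile = make_profile([2.0, 3.0])
        g = np.array([[0, 0], [1, 0], [2, 0], [0, 2], [2, 2]], dtype=np.int8)
        dm = build_distance_matrix(g, profile, list("abcde"))
        a = embed_and_cluster(gaussian_similarity(dm), 5, seed=0)
        assert sorted(np.bincount(a.labels).tolist()) == [1] * 5

    def test_permutation_equivariant_up_to_relabel(self, two_block_setup, rng):
        profile, g, ids, _ = two_block_setup
        S1 = gaussian_similarity(build_distance_matrix(g, profile, ids))
        a1 = embed_and_cluster(S1, 2, seed=0)
        perm = rng.permutation(len(ids))
        S2 = gaussian_similarity(build_distance_matrix(g[perm], profile, ids))
        a2 = embed_and_cluster(S2, 2, seed=0)
        same = (a2.labels == a1.labels[perm]).all()
        flipped = (a2.labels == 1 - a1.labels[perm]).all()
        assert same or flipped

    def test_small_clusters_absorbed_into_nearest(self, two_block_setup):
        profile, g, ids, labels = two_block_setup
        # append one extreme genome far from both blocks
        g = np.vstack([g, np.full((1, profile.n_sites), 2, dtype=np.int8)])
        ids = ids + ["stray"]
        dm = build_distance_matrix(g, profile, ids)
        a = embed_and_cluster(gaussian_similarity(dm), 3, seed=0)
        merged = absorb_small_clusters(a, dm, min_size=2)
        assert merged.has_structure
        sizes = np.bincount(merged.labels)
        assert sizes.min() >= 2


class TestSizePenalty:
    def test_endpoints_forced(self):
        assert size_penalty(100, 100) == 0.0
        assert size_penalty(100, 0) == 1.0

    def test_half_cohort_value(self):
        assert size_penalty(100, 50, 9.0) == pytest.approx(
            (math.exp(4.5) - 1) / (math.exp(9) - 1), abs=1e-12
        )
        assert size_penalty(100, 50, 9.0) == pytest.approx(0.010987, abs=1e-6)

    def test_majority_cluster_penalised_over_99_percent(self):
        mu = size_penalty(100, 60, 9.0)
        assert 100 * (1 - mu) >= 99.0

    def test_strictly_decreasing_and_continuous(self):
        values = [size_penalty(1000, s, 9.0) for s in range(0, 1001)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert max(abs(a - b) for a, b in zip(values, values[1:])) < 0.01

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InputError):
            size_penalty(10, 11)


class TestRawScores:
    def test_no_structure_equals_mean_distance(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        dm = build_distance_matrix(g, profile, ids)
        score, local, global_, comb = raw_outlier_scores(dm, None)
        n = len(ids)
        for i in range(n):
            expected = dm.D[i].sum() / (n - 1)
            assert score[i] == pytest.approx(expected)
            assert local[i] == pytest.approx(expected)
        assert np.all(global_ == 0) and np.all(comb == 0)

    def test_whole_cohort_cluster_reduces_to_local(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        dm = build_distance_matrix(g, profile, ids)
        from genofirst.outlier_engine import ClusterAssignment

        a = ClusterAssignment(
            has_structure=True,
            eigenvalues=np.zeros(1),
            k=1,
            labels=np.zeros(len(ids), dtype=int),
        )
        score, local, global_, _ = raw_outlier_scores(dm, a)
        assert np.all(global_ == 0)
        np.testing.assert_allclose(score, local)

    def test_far_singleton_gains_from_clustering(self, rng):
        # two blocks (31 and 8 genomes) plus one genome equidistant from
        # both but marginally nearer the small block; its clustered score
        # must strictly exceed its unclustered mean-distance score
        dists = [5.0, 2.0, 5.0, 0.5, 0.5, 0.5]
        profile = make_profile(dists, [0.3] * 6)
        n = 40
        g = np.zeros((n, 6), dtype=np.int8)
        g[31:39, 0] = 2      # small block: opposite hom at the block site
        g[31:39, 1] = 1      # tie-break towards the small block
        g[39, 0] = 1
        g[39, 1] = 1
        g[39, 2] = 2         # private high-distance site
        for j in (3, 4, 5):
            g[:39, j] = rng.choice(3, size=39, p=[0.49, 0.42, 0.09])
        ids = [f"i{i}" for i in range(n)]
        s = score_term(profile, g, ids, seed=0)
        assert s.has_structure
        dm = build_distance_matrix(g, profile, ids)
        unclustered = dm.D[39].sum() / (n - 1)
        assert s.raw[39] > unclustered
        assert s.combinatorial[39] > 0

    def test_duplicate_background_mean_update_identity(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        dm = build_distance_matrix(g, profile, ids)
        n = len(ids)
        base, *_ = raw_outlier_scores(dm, None)
        g2 = np.vstack([g, g[0:1]])  # duplicate of background genome 0
        dm2 = build_distance_matrix(g2, profile, ids + ["dup"])
        new, *_ = raw_outlier_scores(dm2, None)
        for i in range(1, n):
            expected = (base[i] * (n - 1) + dm.D[i, 0]) / n
            assert new[i] == pytest.approx(expected, abs=1e-9)


def eq2_oracle(raw, phi):
    """Step-by-step independent evaluation of the universal transform."""
    n = len(raw)
    order = sorted(range(n), key=lambda i: -raw[i])
    rank = [0.0] * n
    for r, i in enumerate(order):
        rank[i] = float(r)  # no ties in the fixture
    total = sum(raw)
    lo, hi = min(raw), max(raw)
    out = []
    for i in range(n):
        rank_factor = math.exp(-(1 + rank[i] / n) * phi) / math.exp(-phi)
        share = raw[i] / total
        minmax = (raw[i] - lo) / (hi - lo)
        out.append((rank_factor * share * minmax) ** (1 / 3))
    return out


class TestTransform:
    def test_five_score_fixture_matches_oracle(self):
        raw = np.array([10.0, 5.0, 2.0, 1.0, 0.5])
        s = transform_scores("T", list("abcde"), raw, ScoreParams(phi=150.0))
        expected = eq2_oracle(raw.tolist(), 150.0)
        np.testing.assert_allclose(s.transformed, expected, atol=1e-10)

    def test_rank_factor_identity(self):
        # exp(-(1+r/N) phi)/exp(-phi) == exp(-phi r/N)
        for phi in (1.0, 9.0, 150.0):
            for n, r in [(5, 0), (5, 4), (500, 123)]:
                unsimplified = math.exp(-(1 + r / n) * phi) / math.exp(-phi)
                simplified = math.exp(-phi * r / n)
                assert math.isclose(unsimplified, simplified, rel_tol=1e-12)

    def test_top_score_has_unit_rank_factor(self):
        raw = np.array([3.0, 7.0, 1.0])
        s = transform_scores("T", list("abc"), raw)
        assert s.rank[1] == 0.0
        # rank factor 1 means top transformed = cbrt(share * minmax) exactly
        assert s.transformed[1] == pytest.approx(((7 / 11) * 1.0) ** (1 / 3))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_bounds_and_order_preserved(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0, 100, size=int(rng.integers(2, 30)))
        s = transform_scores("T", [str(i) for i in range(len(raw))], raw)
        assert np.all((s.transformed >= 0) & (s.transformed <= 1))
        order = np.argsort(raw)
        assert np.all(np.diff(s.transformed[order]) >= -1e-12)
        assert sorted(s.rank) == sorted(float(len(raw)) - 1 - np.argsort(np.argsort(raw)))

    def test_all_equal_scores_yield_no_outliers(self):
        s = transform_scores("T", list("abcd"), np.full(4, 3.3))
        assert np.all(s.transformed == 0)

    def test_all_zero_flagged_degenerate(self):
        s = transform_scores("T", list("abc"), np.zeros(3))
        assert s.degenerate and np.all(s.transformed == 0)

    def test_tied_scores_share_mean_rank(self):
        raw = np.array([5.0, 5.0, 1.0])
        s = transform_scores("T", list("abc"), raw)
        assert s.rank[0] == s.rank[1] == 0.5
        assert s.rank[2] == 2.0


class TestBatchContract:
    def test_batch_members_join_the_background(self, two_block_setup):
        profile, g, ids, _ = two_block_setup
        extreme = np.full((1, profile.n_sites), 2, dtype=np.int8)
        joint = score_term(
            profile, np.vstack([g, extreme]), ids + ["s1"], seed=0
        )
        alone = score_term(
            profile, np.vstack([g, extreme]), ids + ["s1"], seed=0
        )
        # scoring is a deterministic function of the full matrix: a batch
        # of one equals the joint run restricted to that batch
        np.testing.assert_array_equal(joint.transformed, alone.transformed)
        # and raw no-structure scores are means over everyone else,
        # background and batch alike
        dm = build_distance_matrix(
            np.vstack([g, extreme]), profile, ids + ["s1"]
        )
        if not joint.has_structure:
            assert joint.raw[-1] == pytest.approx(dm.D[-1].mean() * dm.n / (dm.n - 1))
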