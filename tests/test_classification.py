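"""Ablation-based variant roles, outlier types, frequency classes."""

import itertools
import math

import numpy as np
import pytest

from genofirst.classification import (
    CONTRIBUTION_TOL,
    FrequencyClass,
    Role,
    VariantRole,
    ablate_and_rescore,
    classify_outlier_type,
    classify_variant_roles,
    explain_call,
    frequency_class,
)
from genofirst.functional_model import InputError, Zygosity
from genofirst.outlier_engine import ScoreParams, score_term

from conftest import make_profile


def cohort_with_subject(dists, subject_genotype, others, mafs=None):
    """Small cohort: `others` rows of background plus the subject last."""
    profile = make_profile(dists, mafs)
    g = np.vstack([others, subject_genotype]).astype(np.int8)
    ids = [f"b{i}" for i in range(len(others))] + ["subject"]
    return profile, g, ids


class TestFrequencyClass:
    @pytest.mark.parametrize(
        "maf,zyg,expected",
        [
            (0.004, Zygosity.HET, FrequencyClass.RARE),
            (0.009, Zygosity.HOM_ALT, FrequencyClass.RARE),
            (0.005, Zygosity.HET, FrequencyClass.LOW_FREQUENCY),  # boundary
            (0.03, Zygosity.HOM_ALT, FrequencyClass.LOW_FREQUENCY),
            (0.01, Zygosity.HET, FrequencyClass.COMMON),  # boundary
            (0.05, Zygosity.HOM_ALT, FrequencyClass.COMMON),  # boundary
            (0.10, Zygosity.HET, FrequencyClass.COMMON),
        ],
    )
    def test_bands(self, maf, zyg, expected):
        assert frequency_class(maf, zyg) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            frequency_class(0.6, Zygosity.HET)


class TestAblation:
    def test_excluding_nothing_reproduces_score(self):
        profile, g, ids = cohort_with_subject(
            [10.0], [2], np.zeros((9, 1)), mafs=[0.01]
        )
        s = score_term(profile, g, ids, seed=0)
        rescored = ablate_and_rescore(9, profile, g, ids, [], seed=0)
        assert rescored == s.transformed[9]

    def test_excluding_only_variant_matches_reference_genome(self):
        profile, g, ids = cohort_with_subject(
            [10.0, 1.0],
            [2, 0],
            np.array([[0, 1]] + [[0, 0]] * 8),
            mafs=[0.01, 0.2],
        )
        rescored = ablate_and_rescore(9, profile, g, ids, [0], seed=0)
        g_ref = g.copy()
        g_ref[9, 0] = 0
        s = score_term(profile, g_ref, ids, seed=0)
        assert rescored == s.transformed[9]

    def test_inputs_not_mutated(self):
        profile, g, ids = cohort_with_subject([10.0], [2], np.zeros((9, 1)))
        before = g.copy()
        ablate_and_rescore(9, profile, g, ids, [0], seed=0)
        np.testing.assert_array_equal(g, before)


class TestVariantRoles:
    def test_single_variant_outlier_is_required(self):
        profile, g, ids = cohort_with_subject(
            [10.0], [2], np.zeros((9, 1)), mafs=[0.001]
        )
        s = score_term(profile, g, ids, seed=0)
        roles = classify_variant_roles(
            9, profile, g, ids, float(s.transformed[9]), seed=0
        )
        assert [r.role for r in roles] == [Role.REQUIRED]
        assert classify_outlier_type(roles) == "1-a"

    def test_dominant_plus_minor_gives_required_and_contributing(self):
        # site 0: private opposite-hom, site 1: a shared low-impact allele
        others = np.zeros((9, 2), dtype=np.int8)
        others[:4, 1] = 1
        profile, g, ids = cohort_with_subject(
            [10.0, 1.0], [2, 1], others, mafs=[0.001, 0.2]
        )
        s = score_term(profile, g, ids, seed=0)
        roles = classify_variant_roles(
            9, profile, g, ids, float(s.transformed[9]), seed=0
        )
        assert {r.variant_id: r.role for r in roles} == {
            "v0": Role.REQUIRED, "v1": Role.CONTRIBUTING
        }
        assert classify_outlier_type(roles) == "1-b"

    def test_redundant_variants_contribute_but_are_not_required(self):
        # either private opposite-hom site alone keeps the subject on top;
        # a third background allele breaks the scale-invariance of the
        # transform so each ablation strictly lowers the score
        others = np.zeros((9, 3), dtype=np.int8)
        others[0, 2] = 1
        profile, g, ids = cohort_with_subject(
            [10.0, 10.0, 0.5], [2, 2, 0], others, mafs=[0.001, 0.001, 0.2]
        )
        s = score_term(profile, g, ids, seed=0)
        roles = {
            r.variant_id: r.role
            for r in classify_variant_roles(
                9, profile, g, ids, float(s.transformed[9]), seed=0
            )
        }
        assert roles["v0"] == roles["v1"] == Role.CONTRIBUTING
        assert roles["v2"] == Role.NONE  # not carried

    def test_order_invariant(self):
        others = np.zeros((9, 2), dtype=np.int8)
        others[:4, 1] = 1
        profile, g, ids = cohort_with_subject(
            [10.0, 1.0], [2, 1], others, mafs=[0.001, 0.2]
        )
        s = score_term(profile, g, ids, seed=0)
        fwd = classify_variant_roles(9, profile, g, ids, float(s.transformed[9]), seed=0)
        # rebuild with sites in reverse order
        rev_profile = make_profile([1.0, 10.0], [0.2, 0.001])
        # variant ids are positional in make_profile: map v0<->v1
        rev = classify_variant_roles(
            9, rev_profile, g[:, ::-1], ids,
            float(score_term(rev_profile, g[:, ::-1], ids, seed=0).transformed[9]),
            seed=0,
        )
        assert {r.role for r in fwd} == {r.role for r in rev}


class TestOutlierType:
    def mk(self, spec):
        return [
            VariantRole(f"v{i}", role, 0.0, drop)
            for i, (role, drop) in enumerate(spec)
        ]

    def test_type_1a(self):
        roles = self.mk([(Role.REQUIRED, 0.5), (Role.NONE, 0.0)])
        assert classify_outlier_type(roles) == "1-a"

    def test_type_1b(self):
        roles = self.mk([(Role.REQUIRED, 0.5), (Role.CONTRIBUTING, 0.05)])
        assert classify_outlier_type(roles) == "1-b"

    def test_type_2a_dominated_by_one_variant(self):
        roles = self.mk(
            [(Role.CONTRIBUTING, 0.5), (Role.CONTRIBUTING, 0.1),
             (Role.CONTRIBUTING, 0.1)]
        )
        assert classify_outlier_type(roles) == "2-a"

    def test_type_2b_multiple_required(self):
        roles = self.mk([(Role.REQUIRED, 0.3)] * 3)
        assert classify_outlier_type(roles) == "2-b"

    def test_three_necessary_variants_classified_2b_end_to_end(self):
        # subject carries three het variants; three background genomes each
        # carry two of them, so any single ablation drops the subject into
        # a tie and kills the call
        others = np.zeros((9, 3), dtype=np.int8)
        others[0] = [1, 1, 0]
        others[1] = [1, 0, 1]
        others[2] = [0, 1, 1]
        profile, g, ids = cohort_with_subject(
            [5.0, 5.0, 5.0], [1, 1, 1], others, mafs=[0.004] * 3
        )
        s = score_term(profile, g, ids, seed=0)
        assert s.transformed[9] >= 0.022
        roles = classify_variant_roles(
            9, profile, g, ids, float(s.transformed[9]), seed=0
        )
        assert all(r.role == Role.REQUIRED for r in roles)
        assert classify_outlier_type(roles) == "2-b"

    def test_no_effect_is_inconsistent(self):
        with pytest.raises(InputError):
            classify_outlier_type(self.mk([(Role.NONE, 0.0)]))


def oracle_scores(g, dists, phi=150.0):
    """Independent no-structure scoring: brute-force mean distance plus a
    step-by-step transform with mean-tie descending ranks."""
    factor = {(0, 0): 0, (1, 1): 0, (2, 2): 0, (0, 1): 1, (1, 0): 1,
              (1, 2): 1, (2, 1): 1, (0, 2): 4, (2, 0): 4}
    n = len(g)
    raw = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            if i == j:
                continue
            total += sum(
                factor[(int(a), int(b))] * d for a, b, d in zip(g[i], g[j], dists)
            )
        raw.append(total / (n - 1))
    total = sum(raw)
    if total == 0:
        return [0.0] * n
    lo, hi = min(raw), max(raw)
    out = []
    for i in range(n):
        less = sum(1 for x in raw if x > raw[i])
        ties = sum(1 for x in raw if x == raw[i])
        rank = less + (ties - 1) / 2
        rank_factor = math.exp(-(1 + rank / n) * phi) / math.exp(-phi)
        minmax = (raw[i] - lo) / (hi - lo) if hi > lo else 0.0
        out.append((rank_factor * (raw[i] / total) * minmax) ** (1 / 3))
    return out


class TestExhaustiveSubsetOracle:
    def test_roles_agree_with_brute_force_over_all_subsets(self):
        rng = np.random.default_rng(7)
        m, n = 6, 8
        dists = rng.uniform(0.5, 2.0, size=m)
        # moderate frequencies: at maf 0.5 the hom-ref and hom-alt ablation
        # effects cancel in expectation, putting drops on a knife edge
        mafs = rng.uniform(0.1, 0.25, size=m)
        profile = make_profile(dists, mafs)
        probs = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2], 1)
        g = np.stack(
            [rng.choice(3, size=n, p=probs[j]) for j in range(m)], axis=1
        ).astype(np.int8)
        g[-1] = 2  # the subject is an across-the-board carrier
        ids = [f"i{i}" for i in range(n)]
        thr = 0.022

        # oracle evaluation of every one of the 2^6 ablation subsets
        oracle_by_subset = {}
        for r in range(m + 1):
            for subset in itertools.combinations(range(m), r):
                ga = g.copy()
                ga[-1, list(subset)] = 0
                oracle_by_subset[subset] = oracle_scores(ga, dists)[-1]

        base = oracle_by_subset[()]
        assert base >= thr
        expected = {}
        for v in range(m):
            ablated = oracle_by_subset[(v,)]
            if ablated < thr:
                expected[f"v{v}"] = Role.REQUIRED
            elif base - ablated > CONTRIBUTION_TOL:
                expected[f"v{v}"] = Role.CONTRIBUTING
            else:
                expected[f"v{v}"] = Role.NONE

        s = score_term(profile, g, ids, seed=0)
        assert float(s.transformed[-1]) == pytest.approx(base, abs=1e-10)
        roles = classify_variant_roles(
            len(ids) - 1, profile, g, ids, float(s.transformed[-1]), seed=0
        )
        assert {r.variant_id: r.role for r in roles} == expected


class TestCombinatorialContribution:
    def test_zero_without_structure(self):
        profile, g, ids = cohort_with_subject(
            [10.0], [2], np.zeros((9, 1)), mafs=[0.001]
        )
        s = score_term(profile, g, ids, seed=0)
        assert not s.has_structure
        assert np.all(s.combinatorial == 0)

    def test_conditional_rarity_yields_positive_contribution(self):
        # co-occurring common variants define a subgroup; the subject adds
        # an allele common overall but absent within that subgroup
        from genofirst.simulate import PlantSpec, SimulationConfig, generate_world

        cfg = SimulationConfig(
            seed=3, n_background=200, n_subjects=4, n_terms=60, n_domains=20,
            plants=(PlantSpec("combinatorial"),),
        )
        world = generate_world(cfg)
        (truth,) = world.truth
        profile = world.build_profile(truth.term)
        s = score_term(
            profile, world.profile_genotypes(profile), world.individuals, seed=3
        )
        i = world.individuals.index(truth.subject)
        assert s.has_structure
        assert s.combinatorial[i] > 0

    def test_explain_call_reports_classes_and_contribution(self):
        profile, g, ids = cohort_with_subject(
            [10.0], [2], np.zeros((9, 1)), mafs=[0.001]
        )
        s = score_term(profile, g, ids, seed=0)
        call = explain_call(9, profile, g, ids, s, seed=0)
        assert call.outlier_type == "1-a"
        assert call.combinatorial_contribution == 0.0
        assert call.frequency_classes == (FrequencyClass.RARE,)
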