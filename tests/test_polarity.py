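"""Tests of net-regulation scoring and cross-study axis quantification."""

from __future__ import annotations

import numpy as np
import pytest

import txaxis as tx
from samoracle import brute_pearson


def make_calls(up=(), down=(), universe=None):
    """A synthetic DECallSet with the given up/down gene IDs."""
    if universe is None:
        universe = sorted(set(up) | set(down))
    d, q, labels = [], [], []
    for g in universe:
        if g in up:
            d.append(5.0), q.append(0.001), labels.append("up")
        elif g in down:
            d.append(-5.0), q.append(0.001), labels.append("down")
        else:
            d.append(0.1), q.append(1.0), labels.append("none")
    return tx.DECallSet(
        gene_ids=tuple(universe),
        d_scores=np.array(d),
        pooled_se=np.ones(len(universe)),
        s0=0.1,
        q_values=np.array(q),
        calls=tuple(labels),
        target_fdr=0.05,
        n_permutations=100,
        seed=0,
    )


def matrix_from(scores, names=None, studies=None, reference=None):
    scores = np.asarray(scores, dtype=float)
    names = names or [f"P{i}" for i in range(scores.shape[0])]
    if reference is None:
        reference = names[0]
    studies = studies or [f"st{j}" for j in range(scores.shape[1])]
    return tx.PathwayStudyMatrix(tuple(names), tuple(studies), scores, reference)


class TestNetRegulation:
    def test_direct_formula(self):
        universe = [f"g{i}" for i in range(100)]
        up = set(universe[:41])
        down = set(universe[41:100])  # 41 up + 59 down = 100 regulated
        calls = make_calls(up=up, down=down, universe=universe)
        sets = tx.GeneSetCollection(
            {"OXPHOS": frozenset(universe[:8])}, reference_name="OXPHOS"
        )
        profile = tx.net_regulation(calls, sets)
        assert profile.total_regulated == 100
        assert profile.score("OXPHOS") == pytest.approx(100 * 8 / 100)

    def test_six_up_two_down_of_hundred_regulated(self):
        universe = [f"g{i}" for i in range(200)]
        up = set(universe[:50])
        down = set(universe[50:100])
        pathway = frozenset(list(up)[:6] + list(down)[:2] + universe[150:160])
        calls = make_calls(up=up, down=down, universe=universe)
        sets = tx.GeneSetCollection({"OXPHOS": pathway})
        profile = tx.net_regulation(calls, sets)
        assert profile.score("OXPHOS") == pytest.approx(4.0)

    def test_pathway_without_calls_scores_zero(self):
        universe = [f"g{i}" for i in range(100)]
        calls = make_calls(up=set(universe[:25]), down=set(universe[25:50]), universe=universe)
        sets = tx.GeneSetCollection({"OXPHOS": frozenset(universe[60:70])})
        assert tx.net_regulation(calls, sets).score("OXPHOS") == 0.0

    def test_all_down_in_one_pathway_hits_minus_hundred(self):
        universe = [f"g{i}" for i in range(60)]
        down = set(universe[:20])
        calls = make_calls(down=down, universe=universe)
        sets = tx.GeneSetCollection({"OXPHOS": frozenset(down)})
        assert tx.net_regulation(calls, sets).score("OXPHOS") == pytest.approx(-100.0)

    def test_no_regulation_scores_zero_everywhere(self):
        universe = [f"g{i}" for i in range(30)]
        calls = make_calls(universe=universe)
        sets = tx.GeneSetCollection({"OXPHOS": frozenset(universe[:5])})
        profile = tx.net_regulation(calls, sets)
        assert profile.total_regulated == 0
        assert np.all(profile.net_scores == 0)

    def test_scores_bounded_on_random_calls(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(300)]
        for _ in range(10):
            labels = rng.choice(["up", "down", "none"], size=300, p=[0.2, 0.2, 0.6])
            up = {g for g, l in zip(universe, labels) if l == "up"}
            down = {g for g, l in zip(universe, labels) if l == "down"}
            members = rng.choice(universe, size=50, replace=False)
            sets = tx.GeneSetCollection(
                {"OXPHOS": frozenset(members), "other": frozenset(universe[:17])}
            )
            profile = tx.net_regulation(make_calls(up, down, universe), sets)
            assert np.all(np.abs(profile.net_scores) <= 100)
            assert np.all(
                np.abs(profile.n_up - profile.n_down) <= profile.total_regulated
            )


class TestSimilarityOrdering:
    def test_reference_first_negated_row_last_of_defined(self):
        ref = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rows = np.vstack([ref, -ref, ref * 0.5 + 1, np.full(5, 7.0)])
        m = matrix_from(rows, names=["OXPHOS", "neg", "pos", "flat"], reference="OXPHOS")
        ordering = tx.sort_by_reference_similarity(m)
        names = [n for n, _ in ordering]
        assert names[0] == "OXPHOS" and ordering[0][1] == 1.0
        assert names[1] == "pos" and ordering[1][1] == pytest.approx(1.0)
        assert names[2] == "neg" and ordering[2][1] == pytest.approx(-1.0)
        assert names[3] == "flat" and np.isnan(ordering[3][1])

    def test_matches_brute_force_pearson_ordering(self, rng):
        scores = rng.uniform(-50, 50, size=(6, 5))
        m = matrix_from(scores)
        ordering = tx.sort_by_reference_similarity(m)
        expected = sorted(
            (
                (name, brute_pearson(scores[i], scores[0])[0])
                for i, name in enumerate(m.pathway_names)
                if name != "P0"
            ),
            key=lambda t: (-t[1], t[0]),
        )
        assert [n for n, _ in ordering[1:]] == [n for n, _ in expected]
        for (_, r_got), (_, r_exp) in zip(ordering[1:], expected):
            assert r_got == pytest.approx(r_exp, abs=1e-10)

    def test_needs_three_studies_and_reference_variance(self):
        with pytest.raises(ValueError):
            tx.sort_by_reference_similarity(matrix_from(np.ones((3, 2))))
        with pytest.raises(tx.UndefinedCorrelationError):
            tx.sort_by_reference_similarity(matrix_from(np.ones((3, 5))))


class TestAxisFraction:
    def test_perfect_copies_give_fraction_one(self):
        ref = np.array([1.0, -2.0, 3.0, 0.5, -1.0])
        m = matrix_from(np.vstack([ref] * 5 + [ref * -2]))
        assert tx.axis_fraction(m) == 1.0

    def test_matches_brute_force_on_random_matrix(self, rng):
        scores = rng.uniform(-40, 40, size=(8, 6))
        m = matrix_from(scores)
        expected = sum(
            brute_pearson(scores[i], scores[0])[1] < 0.05 for i in range(1, 8)
        ) / 7
        assert tx.axis_fraction(m) == pytest.approx(expected)

    def test_null_matrix_fraction_matches_alpha(self):
        fracs = []
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            m = matrix_from(rng.normal(0, 10, size=(51, 20)))
            fracs.append(tx.axis_fraction(m, alpha=0.05))
        mean = np.mean(fracs)
        sd3 = 3 * np.sqrt(0.05 * 0.95 / (50 * 20))
        assert abs(mean - 0.05) <= sd3

    def test_undefined_rows_count_as_not_significant(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        m = matrix_from(np.vstack([ref, np.zeros(4), ref]))
        assert tx.axis_fraction(m) == pytest.approx(0.5)

    def test_too_few_studies_rejected(self):
        with pytest.raises(ValueError):
            tx.axis_fraction(matrix_from(np.arange(9.0).reshape(3, 3)))


class TestCrossStudyCorrelation:
    def test_identity_and_symmetry(self, rng):
        scores = rng.uniform(-30, 30, size=(4, 6))
        m = matrix_from(scores)
        r_self, p_self = tx.cross_study_correlation(m, "P1", "P1")
        assert r_self == 1.0 and p_self == 0.0
        ab = tx.cross_study_correlation(m, "P1", "P2")
        ba = tx.cross_study_correlation(m, "P2", "P1")
        assert ab == ba

    def test_antithetic_rows_strongly_negative(self, rng):
        a = rng.uniform(-30, 30, size=8)
        b = -a + rng.normal(0, 1e-3, size=8)
        m = matrix_from(np.vstack([a, b, a * 0.3]))
        r, p = tx.cross_study_correlation(m, "P0", "P1")
        assert r < -0.99
        assert r == pytest.approx(brute_pearson(a, b)[0], abs=1e-10)
        assert p == pytest.approx(brute_pearson(a, b)[1], rel=1e-8)

    def test_zero_variance_row_raises_explicitly(self):
        m = matrix_from(np.vstack([np.arange(5.0), np.full(5, 2.0)]))
        with pytest.raises(tx.UndefinedCorrelationError):
            tx.cross_study_correlation(m, "P0", "P1")

    def test_unknown_pathway_raises(self, rng):
        m = matrix_from(rng.uniform(-5, 5, size=(3, 5)))
        with pytest.raises(KeyError):
            tx.cross_study_correlation(m, "P0", "nope")


class TestStacking:
    def test_stack_requires_matching_pathways(self):
        universe = [f"g{i}" for i in range(20)]
        calls = make_calls(up=set(universe[:5]), universe=universe)
        a = tx.net_regulation(calls, tx.GeneSetCollection({"OXPHOS": frozenset(universe[:5])}))
        b = tx.net_regulation(
            calls,
            tx.GeneSetCollection(
                {"OXPHOS": frozenset(universe[:5]), "extra": frozenset(universe[5:9])}
            ),
        )
        with pytest.raises(ValueError):
            tx.stack_profiles([a, b], ["s1", "s2"])
        m = tx.stack_profiles([a, a, a], ["s1", "s2", "s3"])
        assert m.scores.shape == (1, 3)
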