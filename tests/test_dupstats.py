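"""Tests for duplication statistics and the structured birthday problem."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcid import (
    CollisionModel,
    decode_id,
    expected_duplicate_pairs,
    explain_nonduplication,
    id_duplication_stats,
    pair_match_probability,
    pattern_duplication_stats,
    percent_half_up,
)


def brute_force_pattern_stats(keys):
    """Independent oracle: per-item membership test by pairwise comparison."""
    dup_items = [k for k in keys if sum(k == other for other in keys) >= 2]
    patterns = set(keys)
    dup_patterns = {k for k in patterns if sum(k == other for other in keys) >= 2}
    return len(keys), len(patterns), len(dup_patterns), len(dup_items)


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (43, 89, 48.3),
            (17, 89, 19.1),
            (2, 89, 2.2),
            (2, 890, 0.2),
            (888, 890, 99.8),
        ],
    )
    def test_printed_percentages(self, num, den, expected):
        """One-decimal half-up rounding reproduces the printed study values."""
        assert percent_half_up(num, den) == expected

    def test_half_up_not_half_even(self):
        # 1/400 = 0.25%: half-up gives 0.3 where banker's would give 0.2
        assert percent_half_up(1, 400) == 0.3

    def test_bad_denominator(self):
        with pytest.raises(ValueError):
            percent_half_up(1, 0)


class TestPatternDuplication:
    def test_small_example(self):
        report = pattern_duplication_stats(["KS", "KS", "TT", "AB"])
        assert report.n_items == 4
        assert report.n_patterns == 3
        assert report.n_duplicated_patterns == 1
        assert report.n_items_in_duplicated == 2
        assert report.percent_items_in_duplicated == 50.0

    def test_study_scale_initials_multiset(self):
        """46 singleton patterns plus 16 shared ones covering 43 members."""
        keys = [f"S{i:02d}" for i in range(46)]
        # 16 duplicated patterns holding 43 items: eleven triples + five pairs
        for i in range(11):
            keys += [f"T{i}"] * 3
        for i in range(5):
            keys += [f"P{i}"] * 2
        report = pattern_duplication_stats(keys)
        assert report.n_items == 89
        assert report.n_items_in_duplicated == 43
        assert report.n_patterns == 62
        assert report.n_duplicated_patterns == 16
        assert report.percent_items_in_duplicated == 48.3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pattern_duplication_stats([])

    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=8))
    def test_matches_brute_force(self, keys):
        report = pattern_duplication_stats(keys)
        n, pats, dup_pats, dup_items = brute_force_pattern_stats(keys)
        assert report.n_items == n
        assert report.n_patterns == pats
        assert report.n_duplicated_patterns == dup_pats
        assert report.n_items_in_duplicated == dup_items
        # accounting identities
        assert report.n_singletons + report.n_items_in_duplicated == report.n_items
        assert report.n_singletons + report.n_duplicated_patterns == report.n_patterns

    @given(st.lists(st.tuples(st.sampled_from("ab"), st.sampled_from("xy")),
                    min_size=1, max_size=8))
    def test_refining_the_key_never_adds_duplicates(self, pairs):
        coarse = pattern_duplication_stats([a for a, _ in pairs])
        fine = pattern_duplication_stats(pairs)
        assert fine.n_items_in_duplicated <= coarse.n_items_in_duplicated


class TestIDDuplication:
    @staticmethod
    def distinct_ids(n):
        """n grammatically valid, pairwise distinct canonical codes."""
        out = []
        for serial, minute in itertools.product(range(100), range(60)):
            out.append(f"DKS35{serial:02d}0101{minute:02d}0MK")
            if len(out) == n:
                return out
        raise ValueError("n too large for this generator")

    def test_study_scale_one_duplicate_pair(self):
        ids = self.distinct_ids(889)
        ids.append(ids[0])  # the single complete duplication
        stats = id_duplication_stats(ids)
        assert stats.n_complete_duplicates == 2
        assert stats.percent_duplicates == 0.2
        assert stats.n_unique == 888
        assert stats.percent_unique == 99.8

    def test_all_distinct(self):
        stats = id_duplication_stats(self.distinct_ids(10))
        assert stats.n_complete_duplicates == 0
        assert stats.percent_unique == 100.0

    def test_all_copies(self):
        stats = id_duplication_stats(["DKS35010101010MK"] * 5)
        assert stats.n_complete_duplicates == 5
        assert stats.n_unique == 0

    def test_display_and_canonical_forms_compare_equal(self):
        stats = id_duplication_stats(["DKS3501-0101010MK", "DKS35010101010MK"])
        assert stats.n_complete_duplicates == 2

    def test_invalid_id_names_the_line(self):
        with pytest.raises(ValueError, match="line 2"):
            id_duplication_stats(["DKS35010101010MK", "XKS35010101010MK"])


class TestExplainNonduplication:
    def test_minute_only(self):
        fields = explain_nonduplication("PKS35010101010MK", "PKS35010101020MK")
        assert fields == ["minute"]

    def test_casualty_initial_only(self):
        fields = explain_nonduplication("PKS35010101010MK", "PKS35010101010MS")
        assert fields == ["casualty_initial"]

    def test_identical_means_complete_duplication(self):
        assert explain_nonduplication("PKS35010101010MK", "PKS35010101010MK") == []

    def test_positional_order(self):
        a = decode_id("DKS35010101010MK")
        b = decode_id("NKS35010101050MK")
        assert explain_nonduplication(a, b) == ["job", "minute"]


def enumerate_match_probability(model, fields):
    """Oracle: exhaustive sum over the joint support of two draws."""
    names = list(fields)
    dists = [model.fields[f] for f in names]
    total = 0.0
    for combo_a in itertools.product(*[d.items() for d in dists]):
        for combo_b in itertools.product(*[d.items() for d in dists]):
            if all(a[0] == b[0] for a, b in zip(combo_a, combo_b)):
                total += math.prod(p for _, p in combo_a) * math.prod(p for _, p in combo_b)
    return total


class TestCollisionModel:
    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CollisionModel({"x": {"a": 0.5, "b": 0.4}})

    def test_uniform_two_values(self):
        model = CollisionModel({"x": {"a": 0.5, "b": 0.5}})
        assert pair_match_probability(model) == pytest.approx(0.5)

    def test_two_independent_uniform_fields(self):
        model = CollisionModel(
            {"x": {"a": 0.5, "b": 0.5}, "y": {"c": 0.5, "d": 0.5}}
        )
        assert pair_match_probability(model) == pytest.approx(0.25)

    def test_deterministic_fields_give_one(self):
        model = CollisionModel({"x": {"a": 1.0}, "y": {"c": 1.0}})
        assert pair_match_probability(model) == 1.0

    def test_unknown_field_rejected(self):
        model = CollisionModel({"x": {"a": 1.0}})
        with pytest.raises(KeyError):
            pair_match_probability(model, ["y"])

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4),
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=4),
    )
    def test_matches_exhaustive_enumeration(self, w1, w2):
        d1 = {i: w / sum(w1) for i, w in enumerate(w1)}
        d2 = {i: w / sum(w2) for i, w in enumerate(w2)}
        model = CollisionModel({"a": d1, "b": d2})
        p = pair_match_probability(model)
        assert p == pytest.approx(enumerate_match_probability(model, ["a", "b"]))
        # adding a field can only shrink the match probability
        assert p <= pair_match_probability(model, ["a"]) + 1e-12


class TestExpectedDuplicatePairs:
    def test_certain_match(self):
        model = CollisionModel({"x": {"a": 1.0}})
        assert expected_duplicate_pairs(model, 2) == 1.0

    def test_scales_as_number_of_pairs(self):
        model = CollisionModel({"x": {"a": 0.5, "b": 0.5}})
        assert expected_duplicate_pairs(model, 2) == pytest.approx(0.5)
        assert expected_duplicate_pairs(model, 5) == pytest.approx(10 * 0.5)

    def test_small_n_rejected(self):
        model = CollisionModel({"x": {"a": 1.0}})
        with pytest.raises(ValueError):
            expected_duplicate_pairs(model, 1)

    def test_against_monte_carlo(self):
        """Structured birthday problem vs direct simulation, n=6, 1e5 reps."""
        rng = np.random.default_rng(2018)
        model = CollisionModel(
            {
                "initial": {"S": 0.4, "K": 0.3, "T": 0.2, "M": 0.1},
                "job": {"D": 0.5, "N": 0.5},
            }
        )
        n, reps = 6, 100_000
        draws_initial = rng.choice(4, size=(reps, n), p=[0.4, 0.3, 0.2, 0.1])
        draws_job = rng.choice(2, size=(reps, n), p=[0.5, 0.5])
        counts = np.zeros(reps)
        for i, j in itertools.combinations(range(n), 2):
            counts += (draws_initial[:, i] == draws_initial[:, j]) & (
                draws_job[:, i] == draws_job[:, j]
            )
        expected = expected_duplicate_pairs(model, n)
        se = counts.std(ddof=1) / math.sqrt(reps)
        assert abs(counts.mean() - expected) <= 3 * se
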