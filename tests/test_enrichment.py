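"""Weighted-KS enrichment score against an independent cumulative-walk oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirconnect import (
    ResponseSignature,
    UndefinedEnrichmentError,
    directional_scores,
    enrichment_score,
)
from conftest import brute_force_es, make_pattern


class TestWorkedExamples:
    def test_single_top_hit_saturates_to_one(self):
        pat = make_pattern([5.0, 3.0, 1.0, -2.0, -4.0])
        res = enrichment_score({"g0"}, pat)
        assert res.es == 1.0 and res.arg_position == 1

    def test_single_bottom_hit_saturates_to_minus_one(self):
        pat = make_pattern([5.0, 3.0, 1.0, -2.0, -4.0])
        res = enrichment_score({"g4"}, pat)
        assert res.es == -1.0 and res.arg_position == 4

    def test_weighted_walk_example(self):
        # stats [2, 1, -1, -2], hits at positions 1 and 3:
        # running sum [2/3, 1/6, 1/2, 0] -> ES = 2/3 at position 1
        pat = make_pattern([2.0, 1.0, -1.0, -2.0])
        res = enrichment_score({"g0", "g2"}, pat, keep_running_sum=True)
        np.testing.assert_allclose(
            res.running_sum, [2 / 3, 1 / 6, 1 / 2, 0.0], atol=1e-12
        )
        assert res.es == pytest.approx(2 / 3) and res.arg_position == 1


class TestErrorPaths:
    def test_empty_intersection_undefined(self):
        pat = make_pattern([1.0, -1.0])
        with pytest.raises(UndefinedEnrichmentError, match="no probe-set member"):
            enrichment_score({"absent"}, pat)

    def test_full_coverage_undefined(self):
        pat = make_pattern([1.0, -1.0])
        with pytest.raises(UndefinedEnrichmentError, match="entire pattern"):
            enrichment_score({"g0", "g1"}, pat)

    def test_members_absent_from_pattern_are_dropped(self):
        pat = make_pattern([2.0, 1.0, -1.0, -2.0])
        with_extra = enrichment_score({"g0", "g2", "nope"}, pat)
        without = enrichment_score({"g0", "g2"}, pat)
        assert with_extra.es == without.es

    def test_all_zero_weights_fall_back_to_unweighted(self):
        pat = make_pattern([1.0, 0.0, 0.0, -1.0])
        with pytest.warns(UserWarning, match="unweighted"):
            res = enrichment_score({"g1", "g2"}, pat, p=1.0)
        expected, _ = brute_force_es([False, True, True, False],
                                     [1.0, 0.0, 0.0, -1.0], p=0.0)
        assert res.es == pytest.approx(expected)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", range(2, 9))
    def test_exhaustive_subsets_match_brute_force(self, n, rng):
        stats = np.sort(rng.normal(size=n))[::-1]
        pat = make_pattern(stats)
        for mask in itertools.product([False, True], repeat=n):
            if not any(mask) or all(mask):
                continue
            members = {pat.probe_ids[i] for i in range(n) if mask[i]}
            res = enrichment_score(members, pat)
            expected, pos = brute_force_es(list(mask), stats)
            assert res.es == pytest.approx(expected, abs=1e-12)
            assert res.arg_position == pos


@st.composite
def pattern_and_subset(draw):
    n = draw(st.integers(min_value=3, max_value=40))
    stats = draw(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False),
            min_size=n, max_size=n,
        )
    )
    k = draw(st.integers(min_value=1, max_value=n - 1))
    idx = draw(st.permutations(list(range(n))))
    return sorted(stats, reverse=True), set(idx[:k])


class TestProperties:
    @settings(max_examples=150, derandomize=True)
    @given(pattern_and_subset())
    def test_score_bounded(self, case):
        stats, subset = case
        pat = make_pattern(stats)
        members = {pat.probe_ids[i] for i in subset}
        total_weight = sum(abs(stats[i]) for i in subset)
        if total_weight == 0:
            return  # fallback path tested separately
        res = enrichment_score(members, pat)
        assert -1.0 <= res.es <= 1.0

    @settings(max_examples=100, derandomize=True)
    @given(pattern_and_subset(), st.floats(min_value=0.1, max_value=10))
    def test_scale_invariance(self, case, scale):
        stats, subset = case
        if sum(abs(s) for s in (stats[i] for i in subset)) == 0:
            return
        pat = make_pattern(stats)
        scaled = make_pattern([s * scale for s in stats])
        members = {pat.probe_ids[i] for i in subset}
        a = enrichment_score(members, pat).es
        b = enrichment_score(members, scaled).es
        assert a == pytest.approx(b, abs=1e-9)

    def test_unweighted_reversal_negates_score(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            stats = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            subset = set(rng.choice(n, size=k, replace=False).tolist())
            pat = make_pattern(stats)
            rev = make_pattern(-stats[::-1], probe_ids=pat.probe_ids[::-1])
            members = {pat.probe_ids[i] for i in subset}
            fwd = enrichment_score(members, pat, p=0.0, keep_running_sum=True)
            if abs(fwd.running_sum.max() + fwd.running_sum.min()) < 1e-9:
                continue  # exact tie: both walks take the positive branch
            b = enrichment_score(members, rev, p=0.0).es
            assert fwd.es == pytest.approx(-b, abs=1e-12)

    def test_weighted_negate_and_reverse_negates_score(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            stats = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            subset = set(rng.choice(n, size=k, replace=False).tolist())
            pat = make_pattern(stats)
            rev = make_pattern(-stats[::-1], probe_ids=pat.probe_ids[::-1])
            members = {pat.probe_ids[i] for i in subset}
            fwd = enrichment_score(members, pat, p=1.0, keep_running_sum=True)
            if abs(fwd.running_sum.max() + fwd.running_sum.min()) < 1e-9:
                continue  # (near-)tie: sign choice is convention, not symmetry
            b = enrichment_score(members, rev, p=1.0).es
            assert fwd.es == pytest.approx(-b, abs=1e-9)


class TestDirectionalScores:
    def test_planted_extremes(self, rng):
        stats = np.sort(rng.normal(size=100))[::-1]
        pat = make_pattern(stats)
        sig = ResponseSignature(
            "x", set(pat.probe_ids[:10]), set(pat.probe_ids[-10:])
        )
        es_up, es_down = directional_scores(sig, pat)
        assert es_up > 0.8
        assert es_down < -0.8

    def test_empty_direction_yields_none(self, rng):
        pat = make_pattern(np.sort(rng.normal(size=20))[::-1])
        sig = ResponseSignature("x", set(), {pat.probe_ids[-1]})
        es_up, es_down = directional_scores(sig, pat)
        assert es_up is None and es_down is not None

    def test_no_overlap_in_either_direction_raises(self, rng):
        pat = make_pattern(np.sort(rng.normal(size=20))[::-1])
        sig = ResponseSignature("x", {"zz1"}, {"zz2"})
        with pytest.raises(UndefinedEnrichmentError, match="neither direction"):
            directional_scores(sig, pat)

    def test_random_scores_always_bounded(self, rng):
        for _ in range(200):
            n = 200
            stats = np.sort(rng.normal(size=n))[::-1]
            pat = make_pattern(stats)
            chosen = rng.choice(n, size=30, replace=False)
            sig = ResponseSignature(
                "x",
                {pat.probe_ids[i] for i in chosen[:15]},
                {pat.probe_ids[i] for i in chosen[15:]},
            )
            es_up, es_down = directional_scores(sig, pat)
            assert -1 <= es_up <= 1 and -1 <= es_down <= 1
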