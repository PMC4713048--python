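"""Fold-change, SAM and amplitude statistics and their signatures."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirconnect import (
    DomainError,
    ValidationError,
    amplitude,
    amplitude_signature,
    build_signature,
    fold_change_signature,
    sam_d,
    sam_signature,
)
from conftest import make_profile

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestAmplitude:
    def test_twofold_boundaries_exact(self):
        # a = 2/3 corresponds exactly to t = 2c, and -2/3 to t = c/2
        assert amplitude(2.0, 1.0) == pytest.approx(2.0 / 3.0, abs=0)
        assert amplitude(1.0, 2.0) == pytest.approx(-2.0 / 3.0, abs=0)

    def test_equal_expression_is_zero(self):
        assert amplitude(5.0, 5.0) == 0.0

    @pytest.mark.parametrize("t,c", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_non_positive_rejected(self, t, c):
        with pytest.raises(DomainError):
            amplitude(t, c)

    @settings(max_examples=200, derandomize=True)
    @given(t=positive, c=positive)
    def test_antisymmetry_and_range(self, t, c):
        a = amplitude(t, c)
        assert a == -amplitude(c, t)
        assert -2.0 < a < 2.0

    @settings(max_examples=200, derandomize=True)
    @given(t=positive, c=positive)
    def test_boundary_agrees_with_fold_change(self, t, c):
        # t/c >= 2 if and only if a >= 2/3 (same boundary, both directions)
        a = amplitude(t, c)
        assert (t / c >= 2.0) == (a >= 2.0 / 3.0) or np.isclose(t / c, 2.0)


class TestFoldChangeSignature:
    def test_threshold_enumeration(self):
        # ratios 4, 2, 1, 0.5, 0.25 against a unit control
        t = np.array([4.0, 2.0, 1.0, 0.5, 0.25])
        c = np.ones(5)
        prof = make_profile(np.column_stack([t, c]), ["treatment", "control"])
        sig, pat = fold_change_signature(prof)
        assert sig.up_probes == {"P0000", "P0001"}
        assert sig.down_probes == {"P0003", "P0004"}
        assert pat.probe_ids == ["P0000", "P0001", "P0002", "P0003", "P0004"]

    def test_weak_ratios_give_empty_signature_full_pattern(self):
        prof = make_profile(
            np.column_stack([np.full(10, 1.5), np.ones(10)]),
            ["treatment", "control"],
        )
        sig, pat = fold_change_signature(prof)
        assert sig.is_empty
        assert len(pat) == 10

    def test_replicated_design_redirected_to_sam(self):
        prof = make_profile(np.ones((5, 4)) + 1, ["treatment"] * 2 + ["control"] * 2)
        with pytest.raises(ValidationError, match="sam"):
            fold_change_signature(prof)

    def test_non_positive_values_rejected(self):
        prof = make_profile(
            np.column_stack([[1.0, -2.0], [1.0, 1.0]]), ["treatment", "control"]
        )
        with pytest.raises(DomainError):
            fold_change_signature(prof)


class TestSamD:
    def test_zero_variance_uses_fudge_constant_only(self):
        # mean difference 2, s = 0, s0 = 0.5 -> d = 4
        assert sam_d([3, 3, 3], [1, 1, 1], s0=0.5) == pytest.approx(4.0)

    def test_equal_means_give_zero(self):
        assert sam_d([1, 2, 3], [3, 2, 1], s0=0.7) == 0.0

    def test_doubling_s0_halves_d_when_s_is_zero(self):
        d1 = sam_d([3, 3, 3], [1, 1, 1], s0=0.5)
        d2 = sam_d([3, 3, 3], [1, 1, 1], s0=1.0)
        assert d1 == pytest.approx(2 * d2)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError, match="fold-change"):
            sam_d([3.0], [1.0, 2.0], s0=0.1)


class TestSamSignature:
    def test_null_data_calls_almost_nothing(self):
        fracs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # < 10 assignments at 2v2
            for seed in range(8):
                rng = np.random.default_rng(seed)
                prof = make_profile(
                    rng.normal(8, 1, size=(500, 4)),
                    ["treatment", "control"] * 2,
                )
                sig, _ = sam_signature(prof, seed=seed)
                fracs.append(sum(sig.sizes()) / 500)
        assert np.median(fracs) <= 0.05

    def test_planted_probes_recovered(self):
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = rng.normal(8, 1, size=(1000, 6))
            values[:20, :3] += 5.0  # 5-sigma shift in the treatment class
            prof = make_profile(values, ["treatment"] * 3 + ["control"] * 3)
            sig, _ = sam_signature(prof, seed=seed)
            recovered.append(len(sig.up_probes & {f"P{i:04d}" for i in range(20)}))
        assert np.median(recovered) >= 18

    def test_pattern_statistic_matches_sam_d(self, rng):
        values = rng.normal(8, 1, size=(50, 6))
        prof = make_profile(values, ["treatment"] * 3 + ["control"] * 3)
        sig, pat = sam_signature(prof)
        s0 = sig.thresholds["s0"]
        by_probe = dict(zip(pat.probe_ids, pat.stat))
        d = sam_d(values[:, :3], values[:, 3:], s0=s0)
        for probe, di in zip(prof.probe_ids, d):
            assert by_probe[probe] == pytest.approx(di, rel=1e-12)

    def test_too_few_assignments_warns_and_enumerates(self, rng):
        prof = make_profile(
            rng.normal(8, 1, size=(30, 4)), ["treatment", "control"] * 2
        )
        with pytest.warns(UserWarning, match="enumerating"):
            sam_signature(prof)


class TestAmplitudeSignature:
    def test_threshold_enumeration_at_two_thirds(self):
        # amplitudes 1.0, 0.7, 0.0, -0.7, -1.0: boundary is strict
        a = np.array([1.0, 0.7, 0.0, -0.7, -1.0])
        c = np.ones(5)
        t = c * (2 + a) / (2 - a)  # invert a(t, c)
        prof = make_profile(
            np.column_stack([t, c]), ["treatment", "control"],
            kind="small_molecule",
        )
        sig, pat = amplitude_signature(prof)
        assert sig.up_probes == {"P0000", "P0001"}
        assert sig.down_probes == {"P0003", "P0004"}
        np.testing.assert_allclose(pat.stat, np.sort(a)[::-1], atol=1e-12)

    def test_no_change_gives_empty_signature(self):
        prof = make_profile(
            np.column_stack([np.ones(5), np.ones(5)]),
            ["treatment", "control"], kind="small_molecule",
        )
        sig, _ = amplitude_signature(prof)
        assert sig.is_empty

    def test_swapping_classes_reverses_pattern_and_swaps_sets(self, rng):
        values = rng.lognormal(5, 1, size=(40, 2))
        fwd = make_profile(values, ["treatment", "control"], kind="small_molecule")
        rev = make_profile(values, ["control", "treatment"], kind="small_molecule")
        sig_f, pat_f = amplitude_signature(fwd)
        sig_r, pat_r = amplitude_signature(rev)
        assert sig_f.up_probes == sig_r.down_probes
        assert sig_f.down_probes == sig_r.up_probes
        assert pat_f.probe_ids == pat_r.probe_ids[::-1]
        np.testing.assert_allclose(pat_f.stat, -pat_r.stat[::-1], atol=1e-12)


class TestDispatch:
    def test_unreplicated_mirna_takes_fold_change(self):
        prof = make_profile(
            np.abs(np.random.default_rng(0).normal(8, 1, (20, 2))) + 1,
            ["treatment", "control"],
        )
        sig, _ = build_signature(prof)
        assert sig.method == "fold_change"

    def test_replicated_mirna_takes_sam(self, rng):
        prof = make_profile(
            rng.normal(8, 1, (20, 6)), ["treatment"] * 3 + ["control"] * 3
        )
        sig, _ = build_signature(prof)
        assert sig.method == "sam"

    def test_small_molecule_takes_amplitude(self, rng):
        prof = make_profile(
            rng.lognormal(5, 1, (20, 2)), ["treatment", "control"],
            kind="small_molecule",
        )
        sig, _ = build_signature(prof)
        assert sig.method == "amplitude"


def test_equal_statistics_rank_lexicographically():
    from mirconnect import RankedResponsePattern

    pat = RankedResponsePattern.from_scores(["b", "a", "c"], [1.0, 1.0, 2.0])
    assert pat.probe_ids == ["c", "a", "b"]
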