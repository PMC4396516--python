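"""Anchor detection, individualized band derivation, relative power, ratio,
risk classification and tertile stratification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphaband.bands import (AnchorFrequencies, DegenerateAnchorsError,
                             alpha_ratio, classify_risk, derive_bands,
                             detect_anchors, relative_band_power,
                             tertile_split, BandPowerProfile)
from alphaband.simulate import EegSimConfig, ValidationError, generate_recording
from alphaband.spectra import STANDARD_GRID, spectrum_from_recording

from conftest import make_collapsed


def bump_spectrum(iaf=10.0, trough=7.0):
    """1/f trend + Gaussian alpha bump: known anchors by construction."""
    f = STANDARD_GRID
    power = 1.0 / f + 2.0 * np.exp(-0.5 * ((f - iaf) / 0.8) ** 2)
    return make_collapsed(power), f, power


class TestDetectAnchors:
    def test_constructed_spectrum_recovers_known_anchors(self):
        cs, f, power = bump_spectrum(iaf=10.0)
        # independent grid-search oracle on the constructed curve
        alpha = (f >= 5) & (f <= 14)
        iaf_oracle = f[alpha][np.argmax(power[alpha])]
        anchors = detect_anchors(cs)
        assert anchors.iaf == iaf_oracle == 10.0
        tf_win = (f >= 3) & (f <= anchors.iaf - 1)
        tf_oracle = f[tf_win][np.argmin(power[tf_win])]
        assert anchors.tf == tf_oracle == 7.0
        assert not anchors.quality_flags

    def test_monotone_decreasing_spectrum_flags_edge_peak(self):
        cs = make_collapsed(np.linspace(10, 1, 87))
        anchors = detect_anchors(cs)
        assert anchors.iaf == 5.0
        assert "no-local-peak" in anchors.quality_flags

    def test_flat_trough_is_flagged(self):
        f = STANDARD_GRID
        power = 2.0 * np.exp(-0.5 * ((f - 10.0) / 0.8) ** 2) + 1.0
        power[(f >= 6.0) & (f <= 7.0)] = 0.5  # plateau trough
        anchors = detect_anchors(make_collapsed(power))
        assert anchors.tf == 7.0  # tie-break: highest frequency
        assert "flat-trough" in anchors.quality_flags

    def test_too_close_anchors_raise(self):
        """Narrowing the TF search gap can put the trough within 1 Hz of the
        peak; band derivation would collapse, so detection refuses."""
        f = STANDARD_GRID
        power = np.ones(87)
        power[f == 10.0] = 5.0  # peak
        power[f == 9.5] = 0.1   # trough right next to it
        with pytest.raises(DegenerateAnchorsError):
            detect_anchors(make_collapsed(power), tf_search_gap=0.5)
        # with the default 1 Hz guard the same spectrum is fine
        anchors = detect_anchors(make_collapsed(power))
        assert anchors.iaf - anchors.tf >= 1.0

    def test_degenerate_window_raises(self):
        f = STANDARD_GRID
        power = np.ones(87)
        power[f == 5.0] = 5.0
        with pytest.raises(DegenerateAnchorsError):
            detect_anchors(make_collapsed(power), tf_search_lo=4.5)


class TestDeriveBands:
    def test_cohort_mean_anchors_reproduce_printed_band_set(self):
        """TF=6.9/IAF=10.9 give delta 2.9-4.9, theta 4.9-6.9, alpha1 6.9-8.9,
        alpha2 8.9-10.9, alpha3 10.9-12.9 Hz."""
        scheme = derive_bands(AnchorFrequencies(tf=6.9, iaf=10.9))
        expected = {"delta": (2.9, 4.9), "theta": (4.9, 6.9),
                    "alpha1": (6.9, 8.9), "alpha2": (8.9, 10.9),
                    "alpha3": (10.9, 12.9)}
        for name, (lo, hi) in expected.items():
            got = scheme.intervals()[name]
            assert got[0] == pytest.approx(lo) and got[1] == pytest.approx(hi)

    def test_midpoint_arithmetic(self):
        scheme = derive_bands(AnchorFrequencies(tf=6.0, iaf=10.0))
        assert scheme.mid == 8.0
        assert scheme.alpha1 == (6.0, 8.0)
        assert scheme.alpha2 == (8.0, 10.0)

    def test_alpha_subbands_have_equal_width(self):
        scheme = derive_bands(AnchorFrequencies(tf=7.0, iaf=9.0))
        w1 = scheme.alpha1[1] - scheme.alpha1[0]
        w2 = scheme.alpha2[1] - scheme.alpha2[0]
        assert w1 == w2 == 1.0

    def test_delta_truncated_at_spectral_floor(self):
        scheme = derive_bands(AnchorFrequencies(tf=5.0, iaf=10.0))
        assert scheme.truncated_delta
        assert scheme.delta[0] == 2.0

    @given(tf=st.floats(4.0, 8.0), gap=st.floats(1.5, 6.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bands_contiguous_and_ordered_for_any_anchor_pair(self, tf, gap):
        iaf = min(tf + gap, 14.0)
        scheme = derive_bands(AnchorFrequencies(tf=tf, iaf=iaf))
        seq = [scheme.delta, scheme.theta, scheme.alpha1, scheme.alpha2,
               scheme.alpha3]
        for (a_lo, a_hi), (b_lo, b_hi) in zip(seq, seq[1:]):
            assert a_hi == pytest.approx(b_lo)
        for name, (lo, hi) in scheme.intervals().items():
            if name == "delta" and scheme.truncated_delta:
                assert lo <= hi  # truncation at 2 Hz may empty the band
            else:
                assert lo < hi
        assert (scheme.alpha1[1] - scheme.alpha1[0]) == pytest.approx(
            scheme.alpha2[1] - scheme.alpha2[0])


class TestRelativePower:
    def test_flat_spectrum_gives_unity_everywhere(self):
        scheme = derive_bands(AnchorFrequencies(tf=6.0, iaf=10.0))
        profile = relative_band_power(make_collapsed(np.full(87, 3.7)), scheme)
        for band, value in profile.relative_power.items():
            assert value == pytest.approx(1.0)
        assert profile.alpha_ratio == pytest.approx(1.0)
        assert profile.risk_label == "middle"

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_normalization_conservation_for_arbitrary_spectra(self, seed):
        """Mean of per-bin relative power over 2-45 Hz is exactly 1."""
        power = np.random.default_rng(seed).uniform(0.01, 10.0, 87)
        rel = power / power.mean()
        assert rel.mean() == pytest.approx(1.0)
        scheme = derive_bands(AnchorFrequencies(tf=6.0, iaf=10.0))
        profile = relative_band_power(make_collapsed(power), scheme)
        assert all(v >= 0 for v in profile.relative_power.values())

    def test_piecewise_constant_spectrum_matches_hand_arithmetic(self):
        """Band values equal hand-computed means of per-bin relative power."""
        f = STANDARD_GRID
        power = np.ones(87)
        power[(f >= 2.0) & (f < 4.0)] = 4.0    # delta bins for tf=6
        power[(f >= 4.0) & (f < 6.0)] = 2.0    # theta
        power[(f >= 6.0) & (f < 8.0)] = 1.0    # alpha1
        power[(f >= 8.0) & (f < 10.0)] = 5.0   # alpha2
        power[(f >= 10.0) & (f <= 12.0)] = 10.0  # alpha3 (closed)
        mean_power = sum(power) / 87.0
        scheme = derive_bands(AnchorFrequencies(tf=6.0, iaf=10.0))
        profile = relative_band_power(make_collapsed(power), scheme)
        assert profile.relative_power["delta"] == pytest.approx(4.0 / mean_power)
        assert profile.relative_power["theta"] == pytest.approx(2.0 / mean_power)
        assert profile.relative_power["alpha1"] == pytest.approx(1.0 / mean_power)
        assert profile.relative_power["alpha2"] == pytest.approx(5.0 / mean_power)
        assert profile.relative_power["alpha3"] == pytest.approx(10.0 / mean_power)
        assert profile.alpha_ratio == pytest.approx(2.0)

    def test_bin_at_iaf_belongs_to_alpha3_not_alpha2(self):
        f = STANDARD_GRID
        power = np.ones(87)
        power[f == 10.0] = 100.0  # exactly at IAF
        scheme = derive_bands(AnchorFrequencies(tf=6.0, iaf=10.0))
        profile = relative_band_power(make_collapsed(power), scheme)
        assert profile.relative_power["alpha3"] > profile.relative_power["alpha2"]


class TestAlphaRatio:
    def test_simple_division(self):
        p = BandPowerProfile(relative_power={"alpha2": 0.10, "alpha3": 0.13})
        assert alpha_ratio(p) == pytest.approx(1.3)

    def test_zero_alpha2_is_undefined(self):
        p = BandPowerProfile(relative_power={"alpha2": 0.0, "alpha3": 1.0})
        with pytest.raises(ValidationError):
            alpha_ratio(p)

    def test_boosted_upper_alpha_content_raises_ratio_above_one(self):
        """A recording with extra 11-13 Hz power versus 9-11 Hz yields a
        high ratio; the mirror configuration yields a low one."""
        boosted = EegSimConfig(duration=60.0, iaf_true=9.0, alpha_power=1.0,
                               theta_freq=12.0, theta_power=3.0, seed=21)
        _, cs, _ = spectrum_from_recording(generate_recording(boosted))
        scheme = derive_bands(AnchorFrequencies(tf=7.0, iaf=11.0))
        high = relative_band_power(cs, scheme)
        plain = EegSimConfig(duration=60.0, iaf_true=10.0, alpha_power=3.0,
                             theta_power=0.5, seed=21)
        _, cs2, _ = spectrum_from_recording(generate_recording(plain))
        low = relative_band_power(cs2, derive_bands(AnchorFrequencies(tf=7.0, iaf=11.0)))
        assert high.alpha_ratio > 1.0 > low.alpha_ratio


class TestClassifyRisk:
    @pytest.mark.parametrize("ratio, label", [
        (0.9, "low"), (1.08, "middle"), (1.29, "high"),  # group-mean ratios
        (0.99, "low"), (1.00, "middle"), (1.16, "middle"), (1.17, "high"),
    ])
    def test_printed_cutoffs(self, ratio, label):
        assert classify_risk(ratio) == label

    def test_smallest_high_ratio_on_fine_grid_is_1_17(self):
        grid = np.round(np.arange(0.50, 1.50 + 1e-9, 0.01), 2)
        high = [r for r in grid if classify_risk(r) == "high"]
        assert min(high) == pytest.approx(1.17)

    @given(st.floats(0.0, 5.0, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_total_partition_and_monotonicity(self, ratio):
        label = classify_risk(ratio)
        assert label in {"low", "middle", "high"}
        order = {"low": 0, "middle": 1, "high": 2}
        assert order[classify_risk(ratio)] <= order[classify_risk(ratio + 0.5)]

    def test_non_finite_ratio_rejected(self):
        with pytest.raises(ValidationError):
            classify_risk(float("nan"))
        with pytest.raises(ValidationError):
            classify_risk(-0.1)


class TestTertileSplit:
    def test_one_to_nine_splits_into_equal_thirds(self):
        values = list(range(1, 10))
        q1, q2, labels = tertile_split(values)
        # oracle: brute-force sort and linear-interpolation quantiles
        assert q1 == pytest.approx(np.quantile(values, 1 / 3))
        assert q2 == pytest.approx(np.quantile(values, 2 / 3))
        assert labels.count("low") == labels.count("middle") == labels.count("high") == 3

    def test_order_invariance(self, rng):
        values = rng.uniform(0.7, 1.6, 74)
        q1, q2, labels = tertile_split(values)
        perm = rng.permutation(len(values))
        q1p, q2p, _ = tertile_split(values[perm])
        assert (q1, q2) == (q1p, q2p)

    def test_cohort_near_study_cutoffs_mostly_agrees_with_fixed_rule(self):
        """74 ratios whose empirical tertiles sit near 1.00/1.17 give the
        same label as the fixed cutoffs for >= 90% of subjects."""
        rng = np.random.default_rng(42)
        ratios = np.concatenate([
            rng.uniform(0.77, 0.98, 25),  # low third
            rng.uniform(1.00, 1.16, 24),  # middle third
            rng.uniform(1.17, 1.52, 25),  # high third
        ])
        _, _, tertile_labels = tertile_split(ratios)
        fixed = [classify_risk(r) for r in ratios]
        agree = np.mean([a == b for a, b in zip(tertile_labels, fixed)])
        assert agree >= 0.90

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            tertile_split([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            tertile_split([1.0, 2.0])
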