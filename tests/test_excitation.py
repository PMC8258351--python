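"""Excitation front end: band levels, fixed filters, excitation patterns,
threshold matching."""

import numpy as np
import pytest

from binloud.config import AUDIOMETRIC_FREQS_HZ, default_config
from binloud.datatypes import StimulusSpec
from binloud.excitation import (EarPeriphery, apply_fixed_filters,
                                compute_excitation, free_field_threshold_db,
                                match_thresholds, modeled_threshold_db,
                                segment_frequencies, stimulus_band_levels,
                                temporal_integration, _ltass_shape)

CFG = default_config(n_segments=200)
NF = len(AUDIOMETRIC_FREQS_HZ)


def _nh_ear(post=None):
    z = np.zeros(NF)
    return EarPeriphery(z, z, z, post)


def _lnn_sl(center_hz, level_db, ear_cfg=CFG):
    stim = StimulusSpec(kind="LNN", center_freq_hz=center_hz,
                        presentation="left")
    freqs, levels = stimulus_band_levels(stim, level_db, ear_cfg)
    sl = levels - free_field_threshold_db(freqs)
    return freqs, sl


class TestBandLevels:
    def test_lnn_single_band(self):
        stim = StimulusSpec(kind="LNN", center_freq_hz=1000.0,
                            presentation="left")
        freqs, levels = stimulus_band_levels(stim, 60.0, CFG)
        finite = np.isfinite(levels)
        assert finite.sum() == 1
        assert freqs[finite][0] == 1000.0
        assert levels[finite][0] == 60.0

    def test_ifn_power_normalization(self):
        stim = StimulusSpec(kind="IFN", presentation="diotic")
        _, levels = stimulus_band_levels(stim, 65.0, CFG)
        total = 10 * np.log10(np.nansum(10 ** (levels / 10)))
        assert total == pytest.approx(65.0, abs=0.01)

    def test_ifn_shape_matches_shipped_table(self):
        stim = StimulusSpec(kind="IFN", presentation="diotic")
        freqs, levels = stimulus_band_levels(stim, 70.0, CFG)
        tf, tv = _ltass_shape()
        for f, v in zip(tf, tv):
            idx = np.argmin(np.abs(freqs - f))
            if np.isclose(freqs[idx], f):
                # band differences must reproduce the table differences
                ref = np.argmin(np.abs(freqs - 1000.0))
                got = levels[idx] - levels[ref]
                want = v - tv[list(tf).index(1000.0)]
                assert got == pytest.approx(want, abs=0.1)

    def test_uen_band(self):
        stim = StimulusSpec(kind="UEN", presentation="left")
        freqs, levels = stimulus_band_levels(stim, 55.0, CFG)
        finite = np.isfinite(levels)
        assert freqs[finite][0] == pytest.approx(1370.0)


class TestFixedFilters:
    def test_frontal_incidence_diotic(self):
        freqs = np.array([250.0, 1000.0, 4000.0])
        left, right = apply_fixed_filters(freqs, np.array([60.0, 60, 60]), 0.0)
        np.testing.assert_array_equal(left, right)

    def test_azimuth_mirror_symmetry(self):
        freqs = np.array([250.0, 1000.0, 4000.0])
        lv = np.array([60.0, 55.0, 50.0])
        l_pos, r_pos = apply_fixed_filters(freqs, lv, 60.0)
        l_neg, r_neg = apply_fixed_filters(freqs, lv, -60.0)
        np.testing.assert_allclose(l_pos, r_neg)
        np.testing.assert_allclose(r_pos, l_neg)

    def test_invalid_azimuth(self):
        with pytest.raises(ValueError):
            apply_fixed_filters(np.array([1000.0]), np.array([60.0]), 30.0)


class TestComputeExcitation:
    def test_zero_loss_high_level_contiguous_region(self):
        freqs, sl = _lnn_sl(1000.0, 80.0)
        frame = compute_excitation(_nh_ear(), freqs, sl, CFG)
        pos = frame.y > 0
        assert pos.any()
        idx = np.nonzero(pos)[0]
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))  # contiguous
        cf = segment_frequencies(CFG)
        peak = cf[np.argmax(frame.y)]
        assert 700 < peak < 1500

    def test_stimulus_at_audiometric_threshold_silent(self):
        hl = np.array([20.0, 25, 30, 35, 40, 45])
        ear = match_thresholds(hl, CFG)
        freqs, sl = _lnn_sl(1000.0, float(free_field_threshold_db([1000.0])[0] + 30.0))
        frame = compute_excitation(ear, freqs, sl, CFG)
        assert np.all(frame.y == 0.0)

    def test_post_gain_scales_supra_threshold_only(self):
        freqs, sl = _lnn_sl(1000.0, 70.0)
        base = compute_excitation(_nh_ear(), freqs, sl, CFG).y
        boosted = compute_excitation(
            _nh_ear(post=np.full(NF, 6.0)), freqs, sl, CFG).y
        zero = base == 0
        np.testing.assert_array_equal(boosted[zero], 0.0)
        np.testing.assert_allclose(boosted[~zero],
                                   base[~zero] * 10 ** 0.6, rtol=1e-9)

    def test_post_gain_never_changes_zero_set(self):
        freqs, sl = _lnn_sl(2000.0, 45.0)
        y0 = compute_excitation(_nh_ear(), freqs, sl, CFG).y
        y1 = compute_excitation(_nh_ear(post=np.full(NF, 18.0)), freqs, sl,
                                CFG).y
        np.testing.assert_array_equal(y0 == 0, y1 == 0)

    def test_monotone_damage(self):
        freqs, sl = _lnn_sl(1000.0, 75.0)
        z = np.zeros(NF)
        prev = None
        for ohc in (0.0, 10.0, 20.0, 30.0):
            ear = EarPeriphery(np.full(NF, ohc), np.full(NF, ohc), z, z)
            y = compute_excitation(ear, freqs, sl, CFG).y
            if prev is not None:
                assert np.all(y <= prev + 1e-12)
            prev = y

    def test_bandwidth_nondecreasing_in_level(self):
        widths = []
        for level in (20.0, 40.0, 60.0, 80.0, 100.0):
            freqs, sl = _lnn_sl(1000.0, level)
            y = compute_excitation(_nh_ear(), freqs, sl, CFG).y
            widths.append(int(np.sum(y > 0)))
        assert np.all(np.diff(widths) >= 0)


class TestMatchThresholds:
    def test_zero_audiogram_zero_losses(self):
        ear = match_thresholds(np.zeros(NF), CFG)
        assert np.all(ear.ohc_loss_db == 0)
        assert np.all(ear.ihc_attenuation_db == 0)

    def test_split_rule_arithmetic(self):
        hl = np.array([0.0, 0, 40.0, 0, 0, 0])
        ear = match_thresholds(hl, CFG)  # cap is 35 dB
        assert ear.ohc_loss_db[2] == 35.0
        assert ear.ihc_attenuation_db[2] == 5.0

    def test_closed_loop_threshold_match(self):
        hl = np.array([15.0, 25.0, 40.0, 50.0, 60.0, 55.0])
        ear = match_thresholds(hl, CFG)
        for f, target in zip(AUDIOMETRIC_FREQS_HZ, hl):
            thr = modeled_threshold_db(ear, f, CFG)
            expect = float(free_field_threshold_db([f])[0]) + target
            assert thr == pytest.approx(expect, abs=1.0)

    def test_unrepresentable_loss_lists_frequencies(self):
        hl = np.array([0.0, 0, 120.0, 0, 0, 0])
        with pytest.raises(ValueError, match="1000"):
            match_thresholds(hl, CFG)


def test_temporal_integration_steady_state():
    """A constant band envelope passes through the integrator unchanged
    (up to the settling of the low-pass)."""
    env = np.full((2000, 2), 60.0)
    out = temporal_integration(env, 1000.0, CFG)
    np.testing.assert_allclose(out[-1], [60.0, 60.0], atol=1e-6)
    # onset is smoothed: early frames are below the steady state
    assert out.shape[1] == 2
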