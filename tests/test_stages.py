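"""Gain stages: bandwidth estimator, monaural gain, binaural summation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from binloud.config import default_config
from binloud.stages import (BinauralStageParams, bandwidth_estimator,
                            binaural_combine, binaural_difference,
                            monaural_gain, simplified_binaural)

N = 1000


def _vec(nonzero_idx, value=1.0, n=N):
    y = np.zeros(n)
    y[np.asarray(nonzero_idx)] = value
    return y


class TestBandwidthEstimator:
    def test_single_nonzero_segment_is_zero(self):
        # a narrowband signal at threshold excites one segment only
        assert abs(bandwidth_estimator(_vec([137], 3.0))) < 1e-12

    def test_two_equal_segments_closed_form(self):
        expected = N / (2 * (N - 2)) - N / (2 * (N - 1))
        w = bandwidth_estimator(_vec([100, 700], 2.0))
        assert w == pytest.approx(expected, rel=1e-9)
        assert w == pytest.approx(5.0e-4, rel=5e-3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 1, 50) * (rng.uniform(0, 1, 50) > 0.5)
        assert bandwidth_estimator(7.0 * y) == pytest.approx(
            bandwidth_estimator(y), rel=1e-12)

    def test_conventions(self):
        cfg = default_config()
        assert bandwidth_estimator(np.zeros(10)) == 0.0
        assert bandwidth_estimator(np.full(10, 2.0)) == cfg.w_max

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bandwidth_estimator(np.array([1.0, -0.1]))


class TestMonauralGain:
    def test_beta_zero_is_identity(self):
        y = np.abs(np.random.default_rng(1).normal(size=40))
        np.testing.assert_array_equal(monaural_gain(y, 0.0), y)

    def test_gain_factor_follows_estimator(self):
        # broadband-ish vector: Z/Y must equal 1 + beta * W elementwise
        y = np.abs(np.random.default_rng(2).normal(size=60)) + 0.1
        w = y.mean() / np.abs(y - y.mean()).mean() - 0.5 / (1 - 1 / y.size)
        z = monaural_gain(y, 0.1)
        np.testing.assert_allclose(z, (1 + 0.1 * w) * y, rtol=1e-12)

    def test_single_segment_unaffected_by_beta(self):
        y = _vec([3], 2.5, n=100)
        np.testing.assert_allclose(monaural_gain(y, 1.7), y, atol=1e-12)

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            monaural_gain(np.array([1.0, 1.0, 0.0, 0.0]), -4.0)


class TestBinauralDifference:
    def test_equal_signals_give_one(self):
        z = np.full(5, 2.0)
        np.testing.assert_array_equal(binaural_difference(z, z), np.ones(5))

    def test_monaural_gives_zero(self):
        z = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(binaural_difference(z, np.zeros(3)),
                                      np.zeros(3))

    def test_arithmetic(self):
        v = binaural_difference(np.array([3.0]), np.array([1.0]))
        assert v[0] == pytest.approx(0.5)

    def test_both_zero_convention(self):
        assert binaural_difference(np.zeros(2), np.zeros(2)).tolist() == [0, 0]


class TestBinauralCombine:
    def test_classical_sum_when_parameters_zero(self):
        rng = np.random.default_rng(4)
        z_l, z_r = rng.uniform(0, 2, 20), rng.uniform(0, 2, 20)
        out = binaural_combine(z_l, z_r, BinauralStageParams(0.0, 0.0))
        np.testing.assert_array_equal(out.z_b, z_l + z_r)

    def test_average_nh_inhibition_single_segment(self):
        z = _vec([0], 1.0, n=1)
        out = binaural_combine(z, z, BinauralStageParams(-0.273, 0.0))
        assert out.z_b[0] == pytest.approx(1.454)

    def test_monaural_passthrough(self):
        z_l = np.array([0.5, 1.5, 0.0])
        out = binaural_combine(z_l, np.zeros(3), BinauralStageParams(-0.4, 0.3))
        np.testing.assert_array_equal(out.z_b, z_l)

    def test_internal_loudness_is_segment_mean(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(0, 1, 30)
        out = binaural_combine(z, z, BinauralStageParams(-0.2, 0.0))
        assert out.internal_loudness == pytest.approx(out.z_b.mean())

    def test_negative_gain_names_segment(self):
        z = np.array([1.0, 1.0])
        with pytest.raises(ValueError, match="segment"):
            binaural_combine(z, z, BinauralStageParams(alpha_b=2.0, beta_b=-9.0))

    @given(st.floats(-0.5, 0.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_equal_inputs_follow_corrected_ratio(self, alpha):
        """For identical inputs the binaural/monaural ratio is 2 (1 + alpha)."""
        z = np.full(10, 0.8)
        out = binaural_combine(z, z, BinauralStageParams(alpha, 0.0))
        assert out.internal_loudness / z.mean() == pytest.approx(
            2.0 * (1.0 + alpha), rel=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        z_l, z_r = rng.uniform(0, 2, 25), rng.uniform(0, 2, 25)
        p = BinauralStageParams(-0.3, 0.1)
        a = binaural_combine(z_l, z_r, p)
        b = binaural_combine(z_r, z_l, p)
        np.testing.assert_array_equal(a.z_b, b.z_b)
        np.testing.assert_array_equal(a.v, b.v)
        assert a.internal_loudness == b.internal_loudness

    def test_diotic_output_monotone_in_parameters(self):
        rng = np.random.default_rng(7)
        z = rng.uniform(0.1, 2, 40)
        outs = [binaural_combine(z, z, BinauralStageParams(a, 0.0)).internal_loudness
                for a in (-0.5, -0.25, 0.0, 0.3)]
        assert np.all(np.diff(outs) > 0)
        w_b = binaural_combine(z, z, BinauralStageParams(0.0, 0.0)).w_b
        assert w_b > 0
        outs_b = [binaural_combine(z, z, BinauralStageParams(-0.2, b)).internal_loudness
                  for b in (0.0, 0.2, 0.5)]
        assert np.all(np.diff(outs_b) > 0)

    def test_binaural_not_softer_than_monaural_for_equal_inputs(self):
        z = np.full(12, 1.3)
        out = binaural_combine(z, z, BinauralStageParams(-0.5, 0.0))
        assert out.internal_loudness >= z.mean()


class TestSimplifiedBinaural:
    @pytest.mark.parametrize("n_l, n_r, alpha, expected", [
        (1.0, 0.1, -0.25, 1.05),     # large interaural difference
        (1.0, 1.0, 0.0, 2.0),        # classical additive summation
        (1.0, 1.0, -0.36, 1.28),     # average NH inhibition
        (1.0, 1.0, -0.5, 1.0),       # bound: binaural equals monaural
    ])
    def test_worked_examples(self, n_l, n_r, alpha, expected):
        assert simplified_binaural(n_l, n_r, alpha) == pytest.approx(
            expected, abs=1e-9)

    def test_zero_inputs(self):
        assert simplified_binaural(0.0, 0.0, -0.25) == 0.0

    def test_bound_enforced(self):
        with pytest.raises(ValueError):
            simplified_binaural(1.0, 1.0, -0.6)

    def test_matches_full_stage_on_scalars(self):
        for n_l, n_r, a in [(0.8, 0.2, -0.3), (1.0, 1.0, 0.1), (2.0, 0.0, -0.5)]:
            full = binaural_combine(np.array([n_l]), np.array([n_r]),
                                    BinauralStageParams(a, 0.0))
            assert simplified_binaural(n_l, n_r, a) == pytest.approx(
                full.z_b[0], rel=1e-12)


def _oracle_pipeline(y_l, y_r, beta_l, beta_r, alpha_b, beta_b):
    """Independent plain-Python re-implementation of the monaural and
    binaural stages for cross-checking."""
    def w_of(vec):
        n = len(vec)
        mean = sum(vec) / n
        mad = sum(abs(v - mean) for v in vec) / n
        return mean / mad - 0.5 / (1 - 1 / n)

    z_l = [(1 + beta_l * w_of(y_l)) * v for v in y_l]
    z_r = [(1 + beta_r * w_of(y_r)) * v for v in y_r]
    s = [a + b for a, b in zip(z_l, z_r)]
    w_b = w_of(s)
    z_b = []
    for a, b, t in zip(z_l, z_r, s):
        v = 0.0 if t == 0 else 1 - abs(a - b) / t
        z_b.append((1 + alpha_b * v + beta_b * v * w_b) * t)
    return z_b, sum(z_b) / len(z_b)


def test_pipeline_matches_brute_force_oracle():
    """Elementwise re-implementation of the stage equations agrees with the
    vectorized pipeline on random 10-segment inputs."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        y_l = rng.uniform(0.01, 3.0, 10)
        y_r = rng.uniform(0.01, 3.0, 10)
        beta_l, beta_r = rng.uniform(-0.1, 0.5, 2)
        alpha_b = rng.uniform(-0.5, 0.5)
        beta_b = rng.uniform(0.0, 0.2)
        z_l = monaural_gain(y_l, beta_l)
        z_r = monaural_gain(y_r, beta_r)
        out = binaural_combine(z_l, z_r, BinauralStageParams(alpha_b, beta_b))
        z_ref, i_ref = _oracle_pipeline(list(y_l), list(y_r), beta_l, beta_r,
                                        alpha_b, beta_b)
        np.testing.assert_allclose(out.z_b, z_ref, rtol=1e-12, atol=1e-12)
        assert out.internal_loudness == pytest.approx(i_ref, rel=1e-12)
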