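"""Summation ratios, alpha_B fitting, corrected ratios, performance metrics."""

import numpy as np
import pytest

from binloud.config import default_config
from binloud.loudness_function import LoudnessFunction, SoneTransform
from binloud.stages import simplified_binaural
from binloud.summation import (RatioEntry, compute_metrics, corrected_ratio,
                               fit_alpha, ratio_at_category, ratio_table,
                               RATIO_CATEGORIES)

T = SoneTransform()


def _fn_through(level, cu, slope=0.5):
    """Straight-line loudness function (equal branch slopes) passing exactly
    through (level, cu)."""
    return LoudnessFunction(level - (cu - 2.5) / slope, slope, slope)


class TestRatioAtCategory:
    def test_identical_functions_give_unity(self):
        fn = LoudnessFunction(20.0, 0.4, 0.8)
        e = ratio_at_category(fn, fn, fn, T, 25.0)
        assert e.r == pytest.approx(1.0, abs=1e-9)
        assert e.valid

    def test_constructed_symmetric_ratio(self):
        # build functions so that N_B = 1.5 and N_L = N_R = 1 at the probe
        cu_b = float(T.cu(1.5))
        cu_m = float(T.cu(1.0))
        fn_b = LoudnessFunction(20.0, 0.4, 0.8)
        level = fn_b.level(cu_b)
        fn_m = _fn_through(level, cu_m)
        e = ratio_at_category(fn_m, fn_m, fn_b, T, cu_b)
        assert e.r == pytest.approx(1.5, abs=1e-6)

    def test_asymmetric_arithmetic(self):
        cu_b = float(T.cu(1.3))
        cu_l = float(T.cu(1.0))
        cu_r = float(T.cu(0.2))
        fn_b = LoudnessFunction(25.0, 0.45, 0.8)
        level = fn_b.level(cu_b)
        e = ratio_at_category(_fn_through(level, cu_l),
                              _fn_through(level, cu_r), fn_b, T, cu_b)
        assert e.r == pytest.approx(2.0 * 1.3 / 1.2, abs=1e-6)

    def test_subthreshold_monaural_flagged_invalid(self):
        fn_b = LoudnessFunction(20.0, 0.5, 0.8)
        deaf = LoudnessFunction(200.0, 0.5, 0.8)  # far above the probe level
        e = ratio_at_category(fn_b, deaf, fn_b, T, 25.0)
        assert not e.valid


def _entries_from_alpha(alpha, pairs):
    """Measured-ratio entries generated by the sone-domain stage itself."""
    out = []
    for n_l, n_r in pairs:
        n_b = simplified_binaural(n_l, n_r, alpha)
        out.append(RatioEntry(stimulus=None, cu_category=25.0,
                              r=2 * n_b / (n_l + n_r), n_l=n_l, n_r=n_r,
                              n_b=n_b))
    return out


class TestFitAlpha:
    def test_recovers_generating_alpha(self):
        pairs = [(1.0, 1.0), (0.5, 0.4), (2.0, 1.5), (0.8, 0.8), (3.0, 0.6)]
        alpha, err = fit_alpha(_entries_from_alpha(-0.25, pairs))
        assert alpha == pytest.approx(-0.25, abs=0.01)
        assert err < 1e-10

    def test_classical_sum_gives_zero(self):
        entries = _entries_from_alpha(0.0, [(1.0, 1.0), (2.0, 2.0)])
        alpha, _ = fit_alpha(entries)
        assert alpha == pytest.approx(0.0, abs=1e-4)

    def test_bound_is_enforced(self):
        # symmetric ratios well below 1 push the optimum under the bound
        entries = [RatioEntry(None, 25.0, 0.7, 1.0, 1.0, 0.35),
                   RatioEntry(None, 30.0, 0.6, 0.5, 0.5, 0.15)]
        alpha, _ = fit_alpha(entries)
        assert alpha == -0.5

    def test_too_few_entries(self):
        with pytest.raises(ValueError):
            fit_alpha([RatioEntry(None, 25.0, 1.5, 1.0, 1.0, 1.5)])


class TestCorrectedRatio:
    @pytest.mark.parametrize("alpha, expected", [
        (0.0, 2.0), (-0.5, 1.0), (-0.36, 1.28), (0.1, 2.2)])
    def test_values(self, alpha, expected):
        assert corrected_ratio(alpha) == pytest.approx(expected, abs=1e-12)

    def test_bound(self):
        with pytest.raises(ValueError):
            corrected_ratio(-0.6)

    def test_consistency_with_fit_for_symmetric_listeners(self):
        """fit_alpha then the corrected ratio reproduces the category-mean
        measured ratio for equal loudness in both ears."""
        pairs = [(x, x) for x in (0.3, 0.8, 1.5, 3.0)]
        entries = _entries_from_alpha(-0.31, pairs)
        alpha, _ = fit_alpha(entries)
        mean_r = np.mean([e.r for e in entries])
        assert corrected_ratio(alpha) == pytest.approx(mean_r, rel=0.02)


class TestAsymmetryProperty:
    def test_measured_ratio_moves_toward_two_with_asymmetry(self):
        """With fixed binaural gain, growing interaural loudness asymmetry
        drives the measured diotic ratio monotonically toward 2."""
        alpha = -0.36
        fn_l = LoudnessFunction(20.0, 0.4, 0.8)
        level = 70.0
        ratios = []
        for shift in (0.0, 5.0, 10.0, 20.0, 30.0):
            fn_r = LoudnessFunction(20.0 + shift, 0.4, 0.8)
            n_l = float(T.sone(fn_l.cu(level)))
            n_r = float(T.sone(fn_r.cu(level)))
            n_b = simplified_binaural(n_l, n_r, alpha)
            ratios.append(2 * n_b / (n_l + n_r))
        assert np.all(np.diff(ratios) > 0)
        assert ratios[0] == pytest.approx(2 * (1 + alpha), abs=1e-9)
        assert ratios[-1] < 2.0
        assert ratios[-1] > 1.9


class TestMetrics:
    def _grid(self, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(20, 100, size=(4, 10))

    def test_perfect_prediction(self):
        m = self._grid()
        assert compute_metrics(m, m.copy()).ncc == pytest.approx(1.0, abs=1e-12)

    def test_grand_mean_prediction(self):
        m = self._grid()
        pred = np.full_like(m, m.mean())
        assert compute_metrics(m, pred).ncc == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        m = self._grid()[0:1]
        res = compute_metrics(m, m + 2.0)
        assert res.rmse == pytest.approx(2.0, abs=1e-12)
        assert res.bias == pytest.approx(+2.0, abs=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        meas = rng.uniform(10, 110, (5, 10))
        pred = meas + rng.normal(0, 4, meas.shape)
        res = compute_metrics(meas, pred, p=3)
        # independent recomputation
        grand = meas.mean()
        sse = sum((meas[s, c] - pred[s, c]) ** 2
                  for s in range(5) for c in range(10))
        sst = sum((meas[s, c] - grand) ** 2
                  for s in range(5) for c in range(10))
        ncc = 1 - sse / sst
        n = 50
        assert res.ncc == pytest.approx(ncc, abs=1e-10)
        assert res.ncc_adj == pytest.approx(
            1 - (1 - ncc) * (n - 1) / (n - 3 - 1), abs=1e-10)
        assert res.rmse == pytest.approx(np.sqrt(sse / n), abs=1e-10)
        assert res.bias == pytest.approx(float(np.mean(pred - meas)), abs=1e-10)
        assert res.rmse >= abs(res.bias)

    def test_ncc_shift_invariance(self):
        m = self._grid(2)
        pred = m + np.random.default_rng(3).normal(0, 3, m.shape)
        a = compute_metrics(m, pred).ncc
        b = compute_metrics(m + 17.0, pred + 17.0).ncc
        assert a == pytest.approx(b, abs=1e-10)

    def test_adjusted_ncc_omitted_for_single_stimulus(self):
        m = self._grid()[0:1]
        res = compute_metrics(m, m + 1.0, p=12)  # p >= n - 1
        assert res.ncc_adj is None


def test_ratio_table_covers_categories():
    fn = LoudnessFunction(20.0, 0.4, 0.8)
    entries = ratio_table({"s": (fn, fn, fn)}, T)
    assert len(entries) == len(RATIO_CATEGORIES)
    assert all(e.r == pytest.approx(1.0, abs=1e-9) for e in entries)
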