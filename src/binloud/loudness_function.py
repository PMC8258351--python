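"""Parametric categorical loudness functions and CU <-> sone transforms.

The loudness function maps presentation level (dB SPL) to categorical units
(CU, 0-50).  It consists of two straight lines -- a lower branch anchored at
the hearing threshold (2.5 CU) and an upper branch -- joined smoothly by a
quadratic Bezier arc between 15 and 35 CU whose control point sits on the
intersection of the two lines at 25 CU.  Fitting follows the BTUX recipe:
the threshold is estimated first from all raw data points and pinned at
2.5 CU, then the slopes are estimated by least squares in the level
(X) direction; if fewer than five data points lie between 35 and 50 CU the
upper slope is set to a configured fixed value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .config import ModelConfig, default_config
from .datatypes import ScalingDataset

__all__ = [
    "LoudnessFunction", "SoneTransform", "FitError",
    "fit_btux", "fit_function_to_points", "estimate_threshold_level",
]

_BEZIER_LO_CU = 15.0
_BEZIER_HI_CU = 35.0
_JUNCTION_CU = 25.0
_THRESHOLD_CU = 2.5


class FitError(RuntimeError):
    """Raised when a loudness function cannot be fitted to a dataset."""


@dataclass(frozen=True)
class LoudnessFunction:
    """Two-slope categorical loudness function with a smooth junction.

    Parameters
    ----------
    threshold_level_db : level at which loudness is 2.5 CU (hearing threshold)
    slope_lower : CU/dB of the lower branch (2.5 .. 25 CU)
    slope_upper : CU/dB of the upper branch (25 .. 50 CU)
    """

    threshold_level_db: float
    slope_lower: float
    slope_upper: float

    def __post_init__(self):
        if not (self.slope_lower > 0 and self.slope_upper > 0):
            raise ValueError("slopes must be positive")

    # characteristic levels -------------------------------------------------
    @property
    def junction_level_db(self) -> float:
        """Level where the two straight lines intersect (25 CU)."""
        return self.threshold_level_db + (_JUNCTION_CU - _THRESHOLD_CU) / self.slope_lower

    @property
    def _bezier_nodes(self):
        lcut = self.junction_level_db
        l15 = self.threshold_level_db + (_BEZIER_LO_CU - _THRESHOLD_CU) / self.slope_lower
        l35 = lcut + (_BEZIER_HI_CU - _JUNCTION_CU) / self.slope_upper
        return l15, lcut, l35

    @property
    def saturation_level_db(self) -> float:
        """Level at which the function reaches 50 CU."""
        return self.junction_level_db + (50.0 - _JUNCTION_CU) / self.slope_upper

    # evaluation ------------------------------------------------------------
    def cu(self, level_db):
        """Loudness in CU at the given level(s); clipped to [0, 50]."""
        level = np.asarray(level_db, dtype=float)
        l15, lcut, l35 = self._bezier_nodes
        lower = _THRESHOLD_CU + self.slope_lower * (level - self.threshold_level_db)
        upper = _JUNCTION_CU + self.slope_upper * (level - lcut)
        out = np.where(level <= l15, lower, upper)
        mid = (level > l15) & (level < l35)
        if np.any(mid):
            out = np.where(mid, self._bezier_cu(level), out)
        out = np.clip(out, 0.0, 50.0)
        return out if out.ndim else float(out)

    def _bezier_cu(self, level):
        """Quadratic-Bezier junction: solve x(t) = level for t, y is linear
        in t (15 + 20 t)."""
        l15, lcut, l35 = self._bezier_nodes
        a = l15 - 2.0 * lcut + l35
        b = lcut - l15
        c = l15 - np.asarray(level, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            # a t^2 + 2 b t + c = 0; x'(t) > 0 so the root in [0,1] is
            t_lin = -c / (2.0 * b)
            disc = np.maximum(b * b - a * c, 0.0)
            t_quad = (-b + np.sqrt(disc)) / np.where(a == 0.0, np.nan, a)
        t = np.where(np.isclose(a, 0.0), t_lin, t_quad)
        t = np.clip(t, 0.0, 1.0)
        return _BEZIER_LO_CU + (_BEZIER_HI_CU - _BEZIER_LO_CU) * t

    def level(self, cu):
        """Inverse mapping: level (dB) at which the function reaches ``cu``.

        Defined for 0 < cu <= 50; raises ``ValueError`` outside.
        """
        cu_arr = np.asarray(cu, dtype=float)
        if np.any(cu_arr <= 0.0) or np.any(cu_arr > 50.0):
            raise ValueError("cu must lie in (0, 50]")
        l15, lcut, l35 = self._bezier_nodes
        lower = self.threshold_level_db + (cu_arr - _THRESHOLD_CU) / self.slope_lower
        upper = lcut + (cu_arr - _JUNCTION_CU) / self.slope_upper
        out = np.where(cu_arr <= _BEZIER_LO_CU, lower, upper)
        mid = (cu_arr > _BEZIER_LO_CU) & (cu_arr < _BEZIER_HI_CU)
        if np.any(mid):
            t = (cu_arr - _BEZIER_LO_CU) / (_BEZIER_HI_CU - _BEZIER_LO_CU)
            x = ((1 - t) ** 2 * l15 + 2 * t * (1 - t) * lcut + t ** 2 * l35)
            out = np.where(mid, x, out)
        return out if out.ndim else float(out)

    # serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "threshold_level_db": self.threshold_level_db,
            "slope_lower": self.slope_lower,
            "slope_upper": self.slope_upper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoudnessFunction":
        return cls(d["threshold_level_db"], d["slope_lower"], d["slope_upper"])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LoudnessFunction":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


class SoneTransform:
    """Five-parameter cubic CU -> sone mapping.

    log10(N) is a cubic polynomial in (cu - cu_ref); the five stored
    parameters are the four polynomial coefficients and the reference
    category cu_ref.  The mapping must be strictly increasing on [0, 50];
    a non-monotone coefficient set is rejected at construction time.
    """

    def __init__(self, coeffs=None):
        if coeffs is None:
            coeffs = default_config().sone_transform_coeffs
        coeffs = tuple(float(c) for c in coeffs)
        if len(coeffs) != 5:
            raise ValueError("SoneTransform requires 5 coefficients")
        self.coeffs = coeffs
        p0, p1, p2, p3, cu_ref = coeffs
        x = np.linspace(0.0, 50.0, 501) - cu_ref
        deriv = p1 + 2 * p2 * x + 3 * p3 * x * x
        if np.any(deriv <= 0):
            raise ValueError("sone transform is not strictly increasing on [0, 50]")

    def sone(self, cu):
        """Loudness in sones for cu in [0, 50]."""
        cu_arr = np.asarray(cu, dtype=float)
        if np.any(cu_arr < 0.0) or np.any(cu_arr > 50.0):
            raise ValueError("cu must lie in [0, 50]")
        p0, p1, p2, p3, cu_ref = self.coeffs
        x = cu_arr - cu_ref
        out = 10.0 ** (p0 + p1 * x + p2 * x * x + p3 * x ** 3)
        return out if out.ndim else float(out)

    def cu(self, sone):
        """Inverse of :meth:`sone`; defined on [sone(0), sone(50)]."""
        s = np.asarray(sone, dtype=float)
        lo, hi = self.sone(0.0), self.sone(50.0)
        if np.any(s < lo * (1 - 1e-12)) or np.any(s > hi * (1 + 1e-12)):
            raise ValueError("sone value outside the representable 0-50 CU range")
        p0, p1, p2, p3, cu_ref = self.coeffs
        y = np.log10(np.clip(s, lo, hi))

        def solve_one(yv):
            roots = np.roots([p3, p2, p1, p0 - yv])
            real = roots[np.abs(roots.imag) < 1e-9].real + cu_ref
            real = real[(real >= -1e-9) & (real <= 50.0 + 1e-9)]
            if len(real) == 0:  # numerical fallback
                return optimize.brentq(
                    lambda c: np.log10(self.sone(np.clip(c, 0, 50))) - yv, 0.0, 50.0)
            return float(np.clip(real[0], 0.0, 50.0))

        out = np.vectorize(solve_one)(y)
        return out if np.ndim(sone) else float(out)

    def to_dict(self) -> dict:
        return {"coeffs": list(self.coeffs)}

    @classmethod
    def from_dict(cls, d: dict) -> "SoneTransform":
        return cls(d["coeffs"])


# ---------------------------------------------------------------------------
# BTUX-style fitting
# ---------------------------------------------------------------------------

def estimate_threshold_level(dataset: ScalingDataset, strategy: str = "auto") -> float:
    """Estimate the hearing-threshold level (the 2.5-CU anchor) from raw data.

    ``zero-crossing``
        level at which the proportion of 0-CU ("not heard") responses crosses
        50 %, linearly interpolated between adjacent tested levels.
    ``extrapolate``
        straight-line fit to the responses on the pure lower branch
        (0 < CU <= 15), solved for 2.5 CU.
    ``auto``
        zero-crossing when 0-CU responses exist, otherwise extrapolation.
    """
    levels = dataset.levels
    resp = dataset.responses
    has_zeros = np.any(resp == 0)
    if strategy == "auto":
        strategy = "zero-crossing" if has_zeros else "extrapolate"

    if strategy == "zero-crossing":
        if not has_zeros:
            raise FitError("no 0-CU responses; cannot use zero-crossing strategy")
        uniq = np.unique(levels)
        frac = np.array([np.mean(resp[levels == lv] == 0.0) for lv in uniq])
        above = frac >= 0.5
        if not above.any():
            return float(uniq[0])
        if above.all():
            raise FitError("all responses are 'not heard'; stimulus inaudible")
        i = np.max(np.nonzero(above)[0])          # last level with >= 50 % zeros
        j = i + 1 if i + 1 < len(uniq) else i     # first clearly audible level
        x0, x1 = uniq[i], uniq[j]
        f0, f1 = frac[i], frac[j]
        if f0 == f1:
            return float(0.5 * (x0 + x1))
        return float(x0 + (0.5 - f0) * (x1 - x0) / (f1 - f0))

    if strategy == "extrapolate":
        mask = (resp > 0) & (resp <= _BEZIER_LO_CU)
        if len(np.unique(levels[mask])) < 2:
            mask = resp > 0
        if len(np.unique(levels[mask])) < 2:
            raise FitError("too few supra-threshold points to estimate threshold")
        slope, intercept = np.polyfit(levels[mask], resp[mask], 1)
        if slope <= 0:
            raise FitError("non-increasing raw data; threshold undefined")
        return float((_THRESHOLD_CU - intercept) / slope)

    raise ValueError(f"unknown threshold strategy: {strategy}")


def fit_btux(dataset: ScalingDataset, config: ModelConfig | None = None,
             threshold_strategy: str = "auto",
             threshold_level_db: float | None = None) -> LoudnessFunction:
    """Fit a categorical loudness function to a scaling dataset.

    The residual of a datum is measured horizontally: the difference between
    its presentation level and the level at which the candidate function
    reaches the datum's CU value.  ``threshold_level_db`` pins the 2.5-CU
    anchor externally (e.g. at an audiogram-derived threshold) instead of
    estimating it from the raw data.  The ``least-squares`` strategy treats
    the anchor as a free parameter of the level-direction fit (robust when
    few trials fall near threshold).
    """
    cfg = config or default_config()
    if not dataset.fittable():
        raise FitError(
            f"dataset {dataset.listener_id}/{dataset.stimulus.label}: need >= 2 "
            "distinct levels with responses above 0 CU")

    free_threshold = threshold_strategy == "least-squares"
    if threshold_level_db is not None:
        thr = float(threshold_level_db)
        free_threshold = False
    elif free_threshold:
        try:
            thr = estimate_threshold_level(dataset, "auto")
        except FitError:
            thr = float(dataset.levels[dataset.responses > 0].min()) - 5.0
    else:
        thr = estimate_threshold_level(dataset, threshold_strategy)
    levels = dataset.levels
    resp = dataset.responses
    mask = resp > 0
    return fit_function_to_points(levels[mask], resp[mask], thr, cfg,
                                  fit_threshold=free_threshold)


def fit_function_to_points(levels, cu_values, threshold_level_db: float,
                           config: ModelConfig | None = None,
                           apply_upper_rule: bool = True,
                           fit_threshold: bool = False) -> LoudnessFunction:
    """Level-direction least-squares fit of the two branch slopes to
    supra-threshold (level, CU) points.

    The 2.5-CU threshold anchor is pinned at ``threshold_level_db`` unless
    ``fit_threshold`` is set, in which case it is a third free parameter
    (initialized at the given value).  When ``apply_upper_rule`` is set and
    fewer than the configured number of points lie between 35 and 50 CU,
    the upper slope is fixed to the configured constant.
    """
    cfg = config or default_config()
    levels = np.asarray(levels, float)
    resp = np.asarray(cu_values, float)
    if levels.size < 2 or np.all(resp <= 0):
        raise FitError("need at least 2 supra-threshold points")
    thr0 = float(threshold_level_db)

    n_upper = int(np.sum((resp >= _BEZIER_HI_CU) & (resp <= 50.0)))
    fix_upper = apply_upper_rule and n_upper < cfg.min_points_upper

    lo_mask = resp <= _JUNCTION_CU
    if np.sum(lo_mask) >= 2 and np.ptp(levels[lo_mask]) > 0:
        s = np.polyfit(levels[lo_mask], resp[lo_mask], 1)[0]
        m_lo0 = float(np.clip(s, *cfg.slope_bounds))
    else:
        m_lo0 = 0.4
    m_hi0 = cfg.fixed_upper_slope

    smin, smax = cfg.slope_bounds

    def unpack(params):
        if fit_threshold:
            thr = params[0]
            slopes = params[1:]
        else:
            thr = thr0
            slopes = params
        if fix_upper:
            return thr, slopes[0], cfg.fixed_upper_slope
        return thr, slopes[0], slopes[1]

    def residuals(params):
        thr, m_lo, m_hi = unpack(params)
        fn = LoudnessFunction(thr, m_lo, m_hi)
        pred = fn.level(np.clip(resp, 1e-9, 50.0))
        return levels - pred

    x0 = [m_lo0] if fix_upper else [m_lo0, m_hi0]
    lb, ub = [smin] * len(x0), [smax] * len(x0)
    if fit_threshold:
        x0 = [thr0] + x0
        lb = [levels.min() - 60.0] + lb
        ub = [levels.max() + 10.0] + ub
    sol = optimize.least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12)
    thr, m_lo, m_hi = unpack([float(v) for v in sol.x])
    return LoudnessFunction(thr, m_lo, m_hi)
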