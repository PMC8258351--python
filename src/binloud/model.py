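"""End-to-end listener loudness model: stimulus -> CU.

A :class:`ListenerModel` bundles the per-ear peripheries, the monaural
bandwidth-gain coefficients (beta_L, beta_R), the binaural stage parameters
(alpha_B, beta_B), the internal-loudness -> sone power law and the
sone -> CU transform.  :func:`predict_cu_curve` runs the complete pipeline
for a stimulus over a grid of presentation levels; :func:`predict_function`
condenses the sampled curve into a parametric loudness function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import AUDIOMETRIC_FREQS_HZ, ModelConfig, default_config
from .datatypes import Presentation, StimulusSpec
from .excitation import (AidedGainTable, EarPeriphery, compute_excitation,
                         free_field_threshold_db, interaural_level_difference_db,
                         match_thresholds, stimulus_band_levels)
from .loudness_function import LoudnessFunction, SoneTransform
from .stages import BinauralStageParams

__all__ = ["ListenerModel", "predict_cu_curve", "predict_function",
           "curve_levels_at_categories", "DegenerateCurveError"]


class DegenerateCurveError(RuntimeError):
    """The stimulus is inaudible over the whole level grid."""


@dataclass
class ListenerModel:
    """Full individual binaural loudness model.

    ``version`` records the individualization stage of the fitting
    hierarchy: 1 = peripheral losses + post gain with the average binaural
    stage, 2 = + beta_L/beta_R, 3 = + alpha_B, 4 = + beta_B.  Parameters not
    introduced by versions <= k stay at their defaults (beta = 0,
    alpha_B = -0.273).
    """

    left: EarPeriphery
    right: EarPeriphery
    beta_l: float = 0.0
    beta_r: float = 0.0
    binaural: BinauralStageParams = field(default_factory=BinauralStageParams)
    sone_transform: SoneTransform = field(default_factory=SoneTransform)
    config: ModelConfig = field(default_factory=default_config)
    version: int = 1
    listener_id: str = "listener"

    @classmethod
    def normal_hearing(cls, config: ModelConfig | None = None,
                       alpha_b: float | None = None) -> "ListenerModel":
        """Zero-loss model with the average NH binaural stage."""
        cfg = config or default_config()
        zeros = np.zeros(len(AUDIOMETRIC_FREQS_HZ))
        ear = lambda: match_thresholds(zeros, cfg)
        ab = cfg.alpha_b_default if alpha_b is None else alpha_b
        return cls(left=ear(), right=ear(),
                   binaural=BinauralStageParams(alpha_b=ab),
                   sone_transform=SoneTransform(cfg.sone_transform_coeffs),
                   config=cfg)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "listener_id": self.listener_id,
            "version": self.version,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
            "beta_l": self.beta_l,
            "beta_r": self.beta_r,
            "alpha_b": self.binaural.alpha_b,
            "beta_b": self.binaural.beta_b,
            "sone_transform": self.sone_transform.to_dict(),
            "sone_scale": self.config.sone_scale,
            "sone_exponent": self.config.sone_exponent,
        }

    @classmethod
    def from_dict(cls, d: dict, config: ModelConfig | None = None) -> "ListenerModel":
        cfg = config or default_config()
        cfg.sone_scale = d.get("sone_scale", cfg.sone_scale)
        cfg.sone_exponent = d.get("sone_exponent", cfg.sone_exponent)
        return cls(
            listener_id=d.get("listener_id", "listener"),
            version=d.get("version", 1),
            left=EarPeriphery.from_dict(d["left"]),
            right=EarPeriphery.from_dict(d["right"]),
            beta_l=d.get("beta_l", 0.0),
            beta_r=d.get("beta_r", 0.0),
            binaural=BinauralStageParams(d.get("alpha_b", cfg.alpha_b_default),
                                         d.get("beta_b", 0.0)),
            sone_transform=SoneTransform.from_dict(d["sone_transform"]),
            config=cfg,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path, config: ModelConfig | None = None) -> "ListenerModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh), config)


# ---------------------------------------------------------------------------
# vectorized stage helpers (levels x segments matrices)
# ---------------------------------------------------------------------------

def _bandwidth_rows(y: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Bandwidth estimator W per row of a (levels, segments) matrix, with the
    same conventions as :func:`binloud.stages.bandwidth_estimator`."""
    n = y.shape[-1]
    mean = y.mean(axis=-1)
    mad = np.abs(y - mean[..., None]).mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = mean / mad - 0.5 / (1.0 - 1.0 / n)
    w = np.where(mean == 0.0, 0.0, np.where(mad == 0.0, cfg.w_max, w))
    return np.minimum(w, cfg.w_max)


def _binaural_rows(z_l: np.ndarray, z_r: np.ndarray,
                   params: BinauralStageParams, cfg: ModelConfig) -> np.ndarray:
    """Internal loudness per row after the binaural summation stage."""
    s = z_l + z_r
    w_b = _bandwidth_rows(s, cfg)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = 1.0 - np.abs(z_l - z_r) / s
    v = np.where(s == 0.0, 0.0, v)
    gain = 1.0 + params.alpha_b * v + params.beta_b * v * w_b[..., None]
    if np.any(gain < 0.0):
        raise ValueError("binaural gain factor negative; check alpha_B/beta_B")
    return (gain * s).mean(axis=-1)


# ---------------------------------------------------------------------------
# forward prediction
# ---------------------------------------------------------------------------

def _ear_spectra_spl(stim: StimulusSpec, levels_db: np.ndarray,
                     cfg: ModelConfig,
                     aided_gains: dict | None) -> tuple[np.ndarray, dict]:
    """Per-ear band spectra in dB SPL at the eardrum for each overall level.

    Chain per ear: source spectrum -> interaural level difference of the
    simulated azimuth -> (aided) per-band level-dependent compensation gain.
    Returns ``(band_freqs, {"left": (L,B), "right": (L,B)})``.
    """
    levels_db = np.atleast_1d(np.asarray(levels_db, float))
    freqs, unit = stimulus_band_levels(stim, 0.0, cfg)
    spec = unit[None, :] + levels_db[:, None]          # (L, B) dB SPL
    ild = interaural_level_difference_db(freqs)
    out = {}
    for side in ("left", "right"):
        s = spec.copy()
        if stim.azimuth_deg != 0.0:
            sign = 1.0 if stim.azimuth_deg > 0 else -1.0
            s = s + (sign if side == "right" else -sign) * ild[None, :] / 2.0
        if stim.aided:
            if not aided_gains or side not in aided_gains:
                raise ValueError("aided stimulus requires per-ear aided gains")
            table: AidedGainTable = aided_gains[side]
            finite = np.isfinite(s)
            g = np.zeros_like(s)
            g[finite] = table.gain(np.broadcast_to(freqs, s.shape)[finite],
                                   s[finite])
            s = s + g
        out[side] = s
    return freqs, out


def internal_loudness_curve(model: ListenerModel, stim: StimulusSpec,
                            levels_db: np.ndarray,
                            aided_gains: dict | None = None) -> np.ndarray:
    """Internal loudness I (mean combined excitation) per presentation level."""
    cfg = model.config
    freqs, spectra = _ear_spectra_spl(stim, levels_db, cfg, aided_gains)
    at = free_field_threshold_db(freqs)
    pres = Presentation(stim.presentation)
    n_levels = spectra["left"].shape[0]

    def ear_output(side: str, ear: EarPeriphery, beta: float) -> np.ndarray:
        sl = spectra[side] - at[None, :]
        y = compute_excitation(ear, freqs, sl, cfg).y
        w = _bandwidth_rows(y, cfg)
        factor = 1.0 + beta * w
        if np.any(factor < 0.0):
            raise ValueError(f"monaural gain factor negative (beta={beta})")
        return factor[:, None] * y

    if pres in (Presentation.LEFT, Presentation.DIOTIC):
        z_l = ear_output("left", model.left, model.beta_l)
    else:
        z_l = None
    if pres in (Presentation.RIGHT, Presentation.DIOTIC):
        z_r = ear_output("right", model.right, model.beta_r)
    else:
        z_r = None
    if z_l is None:
        z_l = np.zeros_like(z_r)
    if z_r is None:
        z_r = np.zeros_like(z_l)
    return _binaural_rows(z_l, z_r, model.binaural, cfg)


def predict_cu_curve(model: ListenerModel, stim: StimulusSpec,
                     levels_db: np.ndarray,
                     aided_gains: dict | None = None) -> np.ndarray:
    """Predicted loudness in CU per presentation level (0 below threshold)."""
    cfg = model.config
    i_m = internal_loudness_curve(model, stim, levels_db, aided_gains)
    sones = cfg.sone_scale * np.power(np.maximum(i_m, 0.0), cfg.sone_exponent,
                                      where=i_m > 0, out=np.zeros_like(i_m))
    return _sone_to_cu_clipped(model.sone_transform, sones)


def _sone_to_cu_clipped(t: SoneTransform, sones: np.ndarray) -> np.ndarray:
    """Vectorized sone -> CU via a dense cached grid; sones at or below the
    0-CU loudness map to 0, above the 50-CU loudness to 50."""
    grid = _transform_grid(t)
    cu_grid, logn_grid = grid
    with np.errstate(divide="ignore"):
        logn = np.log10(np.where(sones > 0, sones, np.nan))
    cu = np.interp(logn, logn_grid, cu_grid, left=0.0, right=50.0)
    cu = np.where(sones <= 10.0 ** logn_grid[0], 0.0, cu)
    return np.nan_to_num(cu, nan=0.0)


_GRID_CACHE: dict[tuple, tuple] = {}


def _transform_grid(t: SoneTransform):
    key = t.coeffs
    if key not in _GRID_CACHE:
        cu = np.linspace(0.0, 50.0, 4001)
        _GRID_CACHE[key] = (cu, np.log10(t.sone(cu)))
    return _GRID_CACHE[key]


def curve_levels_at_categories(levels_db: np.ndarray, cu: np.ndarray,
                               categories) -> np.ndarray:
    """Level (dB) at which a sampled monotone CU curve reaches each category.

    Linear interpolation inside the sampled range; linear extrapolation with
    the local end slope outside it (so fitting errors keep a gradient when a
    candidate model does not reach a category on the grid).
    """
    levels_db = np.asarray(levels_db, float)
    cu = np.asarray(cu, float)
    categories = np.asarray(categories, float)
    pos = cu > 0
    if pos.sum() < 2 or cu[pos].max() - cu[pos].min() < 1e-9:
        raise DegenerateCurveError("curve has no usable dynamic range")
    x = cu[pos]
    y = levels_db[pos]
    x, idx = np.unique(x, return_index=True)
    y = y[idx]
    out = np.interp(categories, x, y)
    # manual linear extrapolation at both ends
    if x.size >= 2:
        lo_slope = (y[1] - y[0]) / max(x[1] - x[0], 1e-9)
        hi_slope = (y[-1] - y[-2]) / max(x[-1] - x[-2], 1e-9)
        below = categories < x[0]
        above = categories > x[-1]
        out = np.where(below, y[0] + lo_slope * (categories - x[0]), out)
        out = np.where(above, y[-1] + hi_slope * (categories - x[-1]), out)
    return out


def invert_cu_curve(model: ListenerModel, stim: StimulusSpec,
                    targets_cu, aided_gains: dict | None = None,
                    grid_cu: tuple | None = None,
                    n_local: int = 9) -> np.ndarray:
    """Levels at which the model's CU output reaches each target.

    A coarse grid supplies brackets that are refined in one extra model
    evaluation on dense local sub-grids; near very steep (strongly
    recruiting) thresholds plain grid interpolation can be several dB off,
    so the refinement matters.  ``grid_cu`` optionally reuses an already
    computed ``(levels, cu)`` pair for the coarse pass.
    """
    cfg = model.config
    if grid_cu is None:
        grid = cfg.level_grid()
        cu = predict_cu_curve(model, stim, grid, aided_gains)
    else:
        grid, cu = grid_cu
    targets = np.atleast_1d(np.asarray(targets_cu, float))
    approx = curve_levels_at_categories(grid, cu, targets)
    cu_mono = np.maximum.accumulate(cu)
    idx = np.searchsorted(cu_mono, targets)
    in_range = (idx > 0) & (idx < grid.size)
    idx_c = np.clip(idx, 1, grid.size - 1)
    lo = grid[idx_c - 1]
    hi = grid[idx_c]
    local = np.linspace(lo, hi, n_local, axis=-1)        # (targets, n_local)
    cu_local = predict_cu_curve(model, stim, local.ravel(), aided_gains)
    cu_local = cu_local.reshape(local.shape)
    out = np.empty_like(targets)
    for k in range(targets.size):
        seg = np.maximum.accumulate(cu_local[k])
        out[k] = np.interp(targets[k], seg, local[k])
    # targets outside the sampled range keep the extrapolated grid estimate
    return np.where(in_range, out, approx)


def predict_function(model: ListenerModel, stim: StimulusSpec,
                     levels_db: np.ndarray | None = None,
                     aided_gains: dict | None = None) -> LoudnessFunction:
    """Condense the sampled level -> CU curve into a parametric loudness
    function: free-threshold least-squares fit to the exact category levels
    (the same estimator that condenses measured scaling data, so measured
    and modeled functions are comparable)."""
    from .loudness_function import fit_function_to_points

    cfg = model.config
    if levels_db is None:
        levels_db = cfg.level_grid()
    cu = predict_cu_curve(model, stim, levels_db, aided_gains)
    cats = np.arange(5.0, 55.0, 5.0)
    anchors = curve_levels_at_categories(levels_db, cu,
                                         np.concatenate(([2.5], cats)))
    exact = invert_cu_curve(model, stim, cats, aided_gains,
                            grid_cu=(np.asarray(levels_db, float), cu))
    return fit_function_to_points(exact, cats, anchors[0], cfg,
                                  apply_upper_rule=False, fit_threshold=True)
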