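"""Excitation front end: from a stimulus specification to internal excitation.

The front end converts a stimulus (third-octave band levels at the eardrum)
into the per-segment internal excitation Y over N equidistant basilar-
membrane segments that feeds the gain stages.  It is a functional,
stationary excitation-pattern model: band energy is spread along a
logarithmic place-frequency axis with a level-dependent upper slope, passed
through a compressive input/output function whose compression weakens
toward linear growth as outer-hair-cell (OHC) loss grows, attenuated by the
inner-hair-cell (IHC) loss, zeroed below a constant internal threshold, and
amplified by the post gain.  For the stationary noises used throughout, a
single steady-state frame replaces the 200-Hz frame sequence; a first-order
temporal integrator is provided for time-varying band envelopes so the
frame interface remains usable.

Shipped reference tables (CSV, representative constructed values):

``ear_weighting.csv``
    free-field hearing-threshold curve of median normal hearing; the
    outer/middle-ear and correction filters are folded into this curve, so
    audiogram values in dB HL offset it directly.
``ifn_ltass_female_synthetic.csv``
    synthetic stand-in for the female long-term-average speech spectrum used
    to shape the broadband IF noise.
``ild_60deg_synthetic.csv``
    synthetic stand-in for the frequency-dependent interaural level
    differences of a +/-60 degree source in the horizontal plane.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .config import AUDIOMETRIC_FREQS_HZ, ModelConfig, default_config
from .datatypes import StimulusKind, StimulusSpec

__all__ = [
    "EarPeriphery", "ExcitationFrame", "AidedGainTable",
    "third_octave_centers", "free_field_threshold_db",
    "stimulus_band_levels", "apply_fixed_filters", "compute_excitation",
    "match_thresholds", "modeled_threshold_db", "temporal_integration",
    "segment_frequencies",
]

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# shipped tables
# ---------------------------------------------------------------------------

def _load_table(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("binloud.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@lru_cache(maxsize=None)
def _ear_weighting():
    df = _load_table("ear_weighting.csv")
    return df["freq_hz"].to_numpy(float), df["threshold_db_spl"].to_numpy(float)


@lru_cache(maxsize=None)
def _ltass_shape():
    df = _load_table("ifn_ltass_female_synthetic.csv")
    return df["freq_hz"].to_numpy(float), df["rel_level_db"].to_numpy(float)


@lru_cache(maxsize=None)
def _ild_table():
    df = _load_table("ild_60deg_synthetic.csv")
    return df["freq_hz"].to_numpy(float), df["ild_db"].to_numpy(float)


def _log_interp(freqs, table_f, table_v):
    """Piecewise-linear interpolation on a log-frequency axis with constant
    extrapolation."""
    x = np.log2(np.asarray(freqs, dtype=float))
    return np.interp(x, np.log2(table_f), table_v)


def free_field_threshold_db(freqs) -> np.ndarray:
    """Median normal-hearing free-field threshold (dB SPL) at ``freqs``."""
    return _log_interp(freqs, *_ear_weighting())


def interaural_level_difference_db(freqs) -> np.ndarray:
    """|ILD| in dB for a 60-degree azimuth source, per frequency."""
    return _log_interp(freqs, *_ild_table())


def third_octave_centers() -> np.ndarray:
    """Standard third-octave band center frequencies, 50 Hz - 12.5 kHz."""
    return np.array([50, 63, 80, 100, 125, 160, 200, 250, 315, 400, 500, 630,
                     800, 1000, 1250, 1600, 2000, 2500, 3150, 4000, 5000,
                     6300, 8000, 10000, 12500], dtype=float)


_SEGMENT_CACHE: dict[tuple, np.ndarray] = {}


def segment_frequencies(config: ModelConfig | None = None) -> np.ndarray:
    """Place-frequency map: characteristic frequency of each BM segment
    (monotone, log-spaced between the configured corner frequencies)."""
    cfg = config or default_config()
    key = (cfg.place_fmin_hz, cfg.place_fmax_hz, cfg.n_segments)
    if key not in _SEGMENT_CACHE:
        _SEGMENT_CACHE[key] = np.geomspace(cfg.place_fmin_hz,
                                           cfg.place_fmax_hz, cfg.n_segments)
    return _SEGMENT_CACHE[key]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EarPeriphery:
    """Per-ear peripheral parameters on the audiometric frequency grid.

    ``ohc_loss_db`` reduces the cochlear gain (loss of compression,
    recruitment); ``ihc_attenuation_db`` is a linear attenuation ahead of
    the internal threshold; ``post_gain_db`` is linear amplification of the
    supra-threshold signal.  All are input-referred in dB and interpolated
    across segments on a log-frequency axis.
    """

    audiogram_db_hl: np.ndarray
    ohc_loss_db: np.ndarray
    ihc_attenuation_db: np.ndarray
    post_gain_db: np.ndarray = None
    freqs_hz: tuple = AUDIOMETRIC_FREQS_HZ

    def __post_init__(self):
        nf = len(self.freqs_hz)
        self.audiogram_db_hl = np.asarray(self.audiogram_db_hl, float)
        self.ohc_loss_db = np.asarray(self.ohc_loss_db, float)
        self.ihc_attenuation_db = np.asarray(self.ihc_attenuation_db, float)
        if self.post_gain_db is None:
            self.post_gain_db = np.zeros(nf)
        self.post_gain_db = np.asarray(self.post_gain_db, float)
        for name in ("audiogram_db_hl", "ohc_loss_db", "ihc_attenuation_db",
                     "post_gain_db"):
            if getattr(self, name).shape != (nf,):
                raise ValueError(f"{name} must have {nf} entries")
        if np.any(self.ohc_loss_db < 0) or np.any(self.ihc_attenuation_db < 0):
            raise ValueError("OHC and IHC losses must be non-negative")

    def to_dict(self) -> dict:
        return {
            "freqs_hz": list(self.freqs_hz),
            "audiogram_db_hl": self.audiogram_db_hl.tolist(),
            "ohc_loss_db": self.ohc_loss_db.tolist(),
            "ihc_attenuation_db": self.ihc_attenuation_db.tolist(),
            "post_gain_db": self.post_gain_db.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EarPeriphery":
        return cls(audiogram_db_hl=d["audiogram_db_hl"],
                   ohc_loss_db=d["ohc_loss_db"],
                   ihc_attenuation_db=d["ihc_attenuation_db"],
                   post_gain_db=d.get("post_gain_db"),
                   freqs_hz=tuple(d.get("freqs_hz", AUDIOMETRIC_FREQS_HZ)))


@dataclass
class ExcitationFrame:
    """Internal excitation per BM segment (one steady-state frame or a
    frames x segments matrix at the configured frame rate)."""

    y: np.ndarray
    segment_cf_hz: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.segment_cf_hz.size


@dataclass
class AidedGainTable:
    """Per-band, level-dependent insertion gains of the narrowband loudness
    compensation (the "aided" condition).

    ``gain_db[i, j]`` is the gain of band ``band_freqs_hz[i]`` at input band
    level ``input_levels_db[j]``; evaluation interpolates bilinearly (log
    frequency x level) with constant extrapolation.
    """

    band_freqs_hz: np.ndarray
    input_levels_db: np.ndarray
    gain_db: np.ndarray
    capped: bool = False

    def gain(self, freqs_hz, levels_db) -> np.ndarray:
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, float))
        levels_db = np.atleast_1d(np.asarray(levels_db, float))
        lf = np.log2(self.band_freqs_hz)
        out = np.empty(np.broadcast(freqs_hz, levels_db).shape)
        fr, lv = np.broadcast_arrays(freqs_hz, levels_db)
        for idx in np.ndindex(out.shape):
            per_band = np.array([
                np.interp(lv[idx], self.input_levels_db, self.gain_db[i])
                for i in range(len(self.band_freqs_hz))])
            out[idx] = np.interp(np.log2(fr[idx]), lf, per_band)
        return out


# ---------------------------------------------------------------------------
# stimulus -> band levels -> eardrum spectra
# ---------------------------------------------------------------------------

def stimulus_band_levels(stim: StimulusSpec, overall_level_db: float,
                         config: ModelConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Third-octave band levels (dB SPL) of a stimulus at an overall level.

    Narrowband stimuli put all energy into the band containing their center
    frequency; the broadband IF noise follows the shipped female
    speech-spectrum shape scaled so the power sum equals ``overall_level_db``.
    Returns ``(band_freqs_hz, band_levels_db)``; silent bands are -inf.
    """
    centers = third_octave_centers()
    levels = np.full(centers.size, NEG_INF)
    kind = StimulusKind(stim.kind)
    if kind in (StimulusKind.LNN, StimulusKind.UEN):
        idx = int(np.argmin(np.abs(np.log2(centers / stim.center_freq_hz))))
        centers = centers.copy()
        centers[idx] = stim.center_freq_hz  # place energy at the true center
        levels[idx] = overall_level_db
    elif kind is StimulusKind.IFN:
        tf, tv = _ltass_shape()
        shape = _log_interp(centers, tf, tv)
        shape = np.where((centers >= tf[0]) & (centers <= tf[-1]), shape, NEG_INF)
        with np.errstate(divide="ignore"):
            total = 10.0 * np.log10(np.sum(10.0 ** (shape / 10.0)))
        levels = shape + (overall_level_db - total)
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unsupported stimulus kind: {stim.kind}")
    return centers, levels


def apply_fixed_filters(band_freqs_hz: np.ndarray, band_levels_db: np.ndarray,
                        azimuth_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Fixed filter chain: sound field to per-ear sensation-referenced spectra.

    Subtracts the free-field threshold curve (outer/middle-ear transfer and
    threshold correction in one step), yielding band levels in dB above the
    normal-hearing threshold, and applies the configured interaural level
    differences for a +/-60 degree azimuth (positive azimuth favors the
    right ear); interaural phase is ignored by this energy-based front end.
    Returns ``(left, right)`` spectra.
    """
    if azimuth_deg not in (-60.0, 0.0, 60.0):
        raise ValueError("azimuth must be -60, 0 or +60 degrees")
    sl = np.asarray(band_levels_db, float) - free_field_threshold_db(band_freqs_hz)
    if azimuth_deg == 0.0:
        return sl.copy(), sl.copy()
    ild = interaural_level_difference_db(band_freqs_hz)
    sign = 1.0 if azimuth_deg > 0 else -1.0
    left = sl - sign * ild / 2.0
    right = sl + sign * ild / 2.0
    return left, right


# ---------------------------------------------------------------------------
# excitation pattern and per-segment input/output function
# ---------------------------------------------------------------------------

def _excitation_pattern_db(band_freqs_hz, band_sl_db, cfg: ModelConfig) -> np.ndarray:
    """Spread band levels (dB above NH threshold) along the place axis.

    Triangular spreading on a log-frequency axis: a fixed slope toward lower
    frequencies and an upper slope that flattens with band level (upward
    spread of masking).  Bands combine by power summation.  ``band_sl_db``
    may be 1-D (bands,) or 2-D (levels, bands); the result has segments as
    the last axis.
    """
    cf = segment_frequencies(cfg)
    band_sl_db = np.asarray(band_sl_db, float)
    squeeze = band_sl_db.ndim == 1
    sl = np.atleast_2d(band_sl_db)                      # (L, B)
    out_pow = np.zeros((sl.shape[0], cf.size))
    dist = np.log2(cf[None, :] / np.asarray(band_freqs_hz, float)[:, None])  # (B, S)
    lower_side = dist < 0
    for b in range(sl.shape[1]):
        lv = sl[:, b]                                    # (L,)
        finite = np.isfinite(lv)
        if not finite.any():
            continue
        s_up = np.maximum(cfg.spread_upper_db_per_oct_min,
                          cfg.spread_upper_db_per_oct_base
                          - cfg.spread_upper_level_coeff * np.maximum(lv, 0.0))
        slope = np.where(lower_side[b][None, :],
                         cfg.spread_lower_db_per_oct,
                         s_up[:, None])                  # (L, S)
        contrib = lv[:, None] - slope * np.abs(dist[b])[None, :]
        contrib = np.where(finite[:, None], contrib, -np.inf)
        np.add(out_pow, np.where(contrib > cfg.internal_floor_db,
                                 10.0 ** (contrib / 10.0), 0.0), out=out_pow)
    with np.errstate(divide="ignore"):
        e = 10.0 * np.log10(out_pow)
    return e[0] if squeeze else e


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def _interp_to_segments(values, freqs_hz, cfg: ModelConfig) -> np.ndarray:
    # called for every model evaluation inside fitting loops; memoized on the
    # parameter values (small keys, bounded cache)
    key = (tuple(np.asarray(values, float)), tuple(np.asarray(freqs_hz, float)),
           cfg.place_fmin_hz, cfg.place_fmax_hz, cfg.n_segments)
    hit = _INTERP_CACHE.get(key)
    if hit is not None:
        return hit
    cf = segment_frequencies(cfg)
    out = _log_interp(cf, np.asarray(freqs_hz, float), np.asarray(values, float))
    if len(_INTERP_CACHE) > 4096:
        _INTERP_CACHE.clear()
    _INTERP_CACHE[key] = out
    return out


def _io_function_db(e_db, ohc_db, cfg: ModelConfig) -> np.ndarray:
    """Compressive input/output function per segment (all in dB).

    Normal hearing compresses with the configured exponent; OHC loss shifts
    the threshold and linearizes growth (recruitment), rejoining the normal
    curve at the configured rejoin point.
    """
    c = cfg.compression_exponent
    eu = cfg.compression_rejoin_db
    slope = c * eu / np.maximum(eu - ohc_db, 1e-6)
    y_imp = slope * (e_db - ohc_db)
    y_nh = c * e_db
    return np.where(e_db >= eu, y_nh, y_imp)


def compute_excitation(ear: EarPeriphery, band_freqs_hz, band_levels_sl_db,
                       config: ModelConfig | None = None) -> ExcitationFrame:
    """Internal excitation Y per segment for a sensation-referenced spectrum.

    Pipeline per segment: excitation-pattern spreading -> OHC-controlled
    compression -> IHC pre-attenuation -> internal threshold (everything at
    or below it becomes 0) -> post gain on the supra-threshold remainder.
    ``band_levels_sl_db`` may be (bands,) or (levels, bands); Y then has the
    matching shape with segments last.
    """
    cfg = config or default_config()
    e = _excitation_pattern_db(band_freqs_hz, band_levels_sl_db, cfg)
    ohc = _interp_to_segments(ear.ohc_loss_db, ear.freqs_hz, cfg)
    ihc = _interp_to_segments(ear.ihc_attenuation_db, ear.freqs_hz, cfg)
    post = _interp_to_segments(ear.post_gain_db, ear.freqs_hz, cfg)
    y_db = _io_function_db(e, ohc, cfg)
    # IHC attenuation is input-referred; convert with the local threshold
    # slope so a d-dB IHC loss elevates the threshold by exactly d dB.
    c = cfg.compression_exponent
    eu = cfg.compression_rejoin_db
    thr_slope = c * eu / np.maximum(eu - ohc, 1e-6)
    atten_db = thr_slope * ihc
    with np.errstate(over="ignore"):
        u = 10.0 ** ((y_db - atten_db) / 10.0)
    y = (np.maximum(u - 1.0, 0.0) ** cfg.specific_loudness_exponent
         * 10.0 ** (post / 10.0))
    return ExcitationFrame(y=y, segment_cf_hz=segment_frequencies(cfg))


def temporal_integration(band_env_db: np.ndarray, fs_in_hz: float,
                         config: ModelConfig | None = None) -> np.ndarray:
    """First-order low-pass (tau = 25 ms) on band intensity envelopes,
    resampled to the 200-Hz frame rate.

    ``band_env_db``: (time, bands) band-level trajectories at ``fs_in_hz``.
    Returns (frames, bands) band levels.  Stationary stimuli elsewhere use
    the steady-state single-frame shortcut instead.
    """
    cfg = config or default_config()
    env = 10.0 ** (np.asarray(band_env_db, float) / 10.0)
    alpha = 1.0 - np.exp(-1.0 / (fs_in_hz * cfg.tau_s))
    out = np.empty_like(env)
    acc = env[0]
    for i in range(env.shape[0]):
        acc = acc + alpha * (env[i] - acc)
        out[i] = acc
    step = max(int(round(fs_in_hz / cfg.frame_rate_hz)), 1)
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(out[::step])


# ---------------------------------------------------------------------------
# threshold matching
# ---------------------------------------------------------------------------

def counteracting_post_gain_db(ear: EarPeriphery,
                               config: ModelConfig | None = None) -> np.ndarray:
    """Post gain that exactly opposes the IHC pre-attenuation at high levels.

    With this gain the supra-threshold excitation approaches the zero-loss
    model's excitation far above threshold, restoring a normal uncomfortable
    level while keeping the elevated threshold (loudness recruitment)."""
    cfg = config or default_config()
    c = cfg.compression_exponent
    eu = cfg.compression_rejoin_db
    thr_slope = c * eu / np.maximum(eu - ear.ohc_loss_db, 1e-6)
    return (cfg.specific_loudness_exponent * thr_slope
            * ear.ihc_attenuation_db)


def match_thresholds(audiogram_db_hl, config: ModelConfig | None = None,
                     ohc_fraction: float | np.ndarray = 1.0,
                     post_gain_db=None,
                     freqs_hz=AUDIOMETRIC_FREQS_HZ) -> EarPeriphery:
    """Split an audiogram into OHC and IHC loss components.

    Default rule: the OHC share takes ``ohc_fraction`` of the loss up to the
    configured maximum cochlear gain; the remainder is assigned to the IHC
    attenuation.  The construction guarantees that the modeled detection
    threshold equals the audiogram at each audiometric frequency.
    """
    cfg = config or default_config()
    hl = np.asarray(audiogram_db_hl, float)
    if hl.shape != (len(freqs_hz),):
        raise ValueError(f"audiogram must have {len(freqs_hz)} entries")
    max_loss = cfg.compression_rejoin_db - 1.0
    bad = hl >= max_loss
    if bad.any():
        raise ValueError(
            "audiogram exceeds representable loss at "
            f"{[f for f, b in zip(freqs_hz, bad) if b]} Hz")
    frac = np.broadcast_to(np.asarray(ohc_fraction, float), hl.shape)
    ohc = np.minimum(np.maximum(hl, 0.0) * frac, cfg.max_cochlear_gain_db)
    ihc = np.maximum(hl, 0.0) - ohc
    return EarPeriphery(audiogram_db_hl=hl, ohc_loss_db=ohc,
                        ihc_attenuation_db=ihc, post_gain_db=post_gain_db,
                        freqs_hz=tuple(freqs_hz))


def modeled_threshold_db(ear: EarPeriphery, center_freq_hz: float,
                         config: ModelConfig | None = None,
                         step_db: float = 0.25) -> float:
    """Detection threshold of the model for a narrowband stimulus: the first
    level (dB SPL) producing any nonzero internal excitation."""
    cfg = config or default_config()
    from .datatypes import StimulusSpec, StimulusKind

    centers = third_octave_centers()
    idx = int(np.argmin(np.abs(np.log2(centers / center_freq_hz))))
    centers = centers.copy()
    centers[idx] = center_freq_hz
    levels = np.arange(-10.0, 120.0 + step_db, step_db)
    spec = np.full((levels.size, centers.size), NEG_INF)
    spec[:, idx] = levels
    sl = spec - free_field_threshold_db(centers)[None, :]
    frame = compute_excitation(ear, centers, sl, cfg)
    audible = frame.y.sum(axis=-1) > 0.0
    if not audible.any():
        return float("inf")
    return float(levels[np.argmax(audible)])
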