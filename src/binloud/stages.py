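"""Retro-cochlear gain stages: bandwidth-dependent monaural gain and the
binaural summation stage.

Working on the per-segment internal excitation Y (one value per basilar-
membrane segment and time frame), the monaural stage applies a gain
``1 + beta * W`` where W is a dimensionless bandwidth estimator, and the
binaural stage sums the two monaural signals and applies a gain
``1 + alpha_B * V + beta_B * V * W_B`` where V in [0, 1] measures how equal
the two monaural signals are (V = 1 diotic, V = 0 monaural).  Negative
alpha_B models binaural inhibition, positive alpha_B binaural excitation.
The internal loudness of a frame is the mean of the combined excitation over
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, default_config

__all__ = [
    "MonauralStageParams", "BinauralStageParams", "BinauralFrame",
    "bandwidth_estimator", "monaural_gain", "binaural_difference",
    "binaural_combine", "simplified_binaural",
]


@dataclass(frozen=True)
class MonauralStageParams:
    """Bandwidth-gain coefficient of one monaural path (beta_L or beta_R)."""

    beta: float = 0.0


@dataclass(frozen=True)
class BinauralStageParams:
    """Overall (alpha_B) and bandwidth-dependent (beta_B) binaural gain."""

    alpha_b: float = -0.273
    beta_b: float = 0.0

    def __post_init__(self):
        if self.alpha_b < -0.5:
            raise ValueError("alpha_B must be >= -0.5 (fitting bound)")


@dataclass
class BinauralFrame:
    """Output of the binaural stage for one time frame."""

    v: np.ndarray          # per-segment binaural difference, in [0, 1]
    z_b: np.ndarray        # per-segment combined excitation
    w_b: float             # bandwidth estimate of the summed signal
    internal_loudness: float  # mean of z_b over segments


def bandwidth_estimator(y: np.ndarray, config: ModelConfig | None = None) -> float:
    """Dimensionless bandwidth estimate of a per-segment excitation vector.

    W = mean(Y) / meanAbsDev(Y) - (1/2) / (1 - 1/N).  The subtraction makes
    W exactly 0 for a vector with a single nonzero segment (a narrowband
    signal at threshold).  W is scale-invariant.  Conventions: an all-zero
    vector returns 0; a vector with vanishing mean absolute deviation
    (uniform excitation) is capped at the configured maximum.
    """
    cfg = config or default_config()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D per-segment vector")
    if np.any(y < 0):
        raise ValueError("excitation must be non-negative")
    n = y.size
    mean = y.mean()
    if mean == 0.0:
        return 0.0
    mad = np.abs(y - mean).mean()
    if mad == 0.0:
        return float(cfg.w_max)
    w = mean / mad - 0.5 / (1.0 - 1.0 / n)
    return float(min(w, cfg.w_max))


def monaural_gain(y: np.ndarray, beta: float,
                  config: ModelConfig | None = None) -> np.ndarray:
    """Apply the bandwidth-dependent monaural gain Z = (1 + beta W(Y)) Y."""
    y = np.asarray(y, dtype=float)
    w = bandwidth_estimator(y, config)
    factor = 1.0 + beta * w
    if factor < 0.0:
        raise ValueError(
            f"monaural gain factor 1 + beta*W = {factor:.4g} is negative "
            f"(beta={beta}, W={w:.4g})")
    return factor * y


def binaural_difference(z_l: np.ndarray, z_r: np.ndarray) -> np.ndarray:
    """Per-segment binaural difference V = 1 - |Z_L - Z_R| / (Z_L + Z_R).

    V = 0 wherever one (or both) side is zero, so purely monaural segments
    pass through the binaural stage unaltered.
    """
    z_l = np.asarray(z_l, dtype=float)
    z_r = np.asarray(z_r, dtype=float)
    s = z_l + z_r
    with np.errstate(invalid="ignore", divide="ignore"):
        v = 1.0 - np.abs(z_l - z_r) / s
    v = np.where(s == 0.0, 0.0, v)
    return v


def binaural_combine(z_l: np.ndarray, z_r: np.ndarray,
                     params: BinauralStageParams,
                     config: ModelConfig | None = None) -> BinauralFrame:
    """Binaural summation stage for one frame.

    The summed signal Z_L + Z_R is weighted per segment by
    ``1 + alpha_B V + beta_B V W_B``; the bandwidth estimate W_B is computed
    on the summed signal with the same estimator as in the monaural stage.
    The internal loudness of the frame is the mean of the result over
    segments.
    """
    z_l = np.asarray(z_l, dtype=float)
    z_r = np.asarray(z_r, dtype=float)
    if z_l.shape != z_r.shape:
        raise ValueError("left and right excitation must have equal shape")
    s = z_l + z_r
    w_b = bandwidth_estimator(s, config)
    v = binaural_difference(z_l, z_r)
    gain = 1.0 + params.alpha_b * v + params.beta_b * v * w_b
    bad = np.nonzero(gain < 0.0)[0]
    if bad.size:
        raise ValueError(
            f"binaural gain factor is negative at segment {int(bad[0])} "
            f"(alpha_B={params.alpha_b}, beta_B={params.beta_b}, W_B={w_b:.4g})")
    z_b = gain * s
    return BinauralFrame(v=v, z_b=z_b, w_b=w_b,
                         internal_loudness=float(z_b.mean()))


def simplified_binaural(n_l: float, n_r: float, alpha_b: float) -> float:
    """Sone-domain binaural stage used in the data-driven analysis.

    The empirically derived monaural loudness values (sones) replace the
    internal excitation signals; the bandwidth term is deactivated
    (beta_B = 0):  V = 1 - |N_L - N_R|/(N_L + N_R),
    N_B = (1 + alpha_B V) (N_L + N_R).
    """
    if n_l < 0 or n_r < 0:
        raise ValueError("monaural loudness must be non-negative")
    if alpha_b < -0.5:
        raise ValueError("alpha_B must be >= -0.5")
    s = n_l + n_r
    if s == 0.0:
        return 0.0
    v = 1.0 - abs(n_l - n_r) / s
    return (1.0 + alpha_b * v) * s
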