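"""Package-wide configuration.

All tunable constants of the model live in one :class:`ModelConfig` object
that can be overridden from a YAML file.  The defaults encode the study
conditions: a 25-ms temporal integrator running at a 200-Hz frame rate, a
basilar-membrane place axis of N = 1000 equidistant segments spanning
0.04-20 kHz, an average normal-hearing binaural gain of alpha_B = -0.273
with a fitting bound of alpha_B >= -0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Audiometric test frequencies (Hz); the free-field threshold curve that the
#: fixed outer/middle-ear and correction filters are folded into is shipped as
#: ``data/ear_weighting.csv``, so audiogram values in dB HL offset it directly.
AUDIOMETRIC_FREQS_HZ = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 6000.0)


@dataclass
class ModelConfig:
    """Numerical constants of the loudness model and its fitting procedures."""

    # -- excitation front end -------------------------------------------------
    n_segments: int = 1000          # BM segments (place axis)
    place_fmin_hz: float = 40.0     # apical end of the place map
    place_fmax_hz: float = 20000.0  # basal end of the place map
    tau_s: float = 0.025            # temporal-integration time constant
    frame_rate_hz: float = 200.0    # frame rate after temporal integration
    compression_exponent: float = 0.3   # dB/dB growth of the NH I/O function
    compression_rejoin_db: float = 100.0  # SL where impaired I/O rejoins NH
    max_cochlear_gain_db: float = 35.0    # cap on the OHC-loss share
    spread_lower_db_per_oct: float = 27.0  # excitation slope toward low freq
    spread_upper_db_per_oct_base: float = 27.0  # upper slope at low level
    spread_upper_level_coeff: float = 0.2  # upper-slope reduction per dB
    spread_upper_db_per_oct_min: float = 6.0
    internal_floor_db: float = -100.0
    #: exponent on the supra-threshold internal signal (specific-loudness
    #: compression); flattens the excitation profile across place so the
    #: bandwidth estimator separates narrowband from broadband excitation
    specific_loudness_exponent: float = 0.5

    # -- gain stages ----------------------------------------------------------
    w_max: float = 1.0e3            # cap for the bandwidth estimator
    alpha_b_default: float = -0.273  # average NH binaural gain
    alpha_b_bounds: tuple[float, float] = (-0.5, 1.0)
    beta_bounds: tuple[float, float] = (-0.5, 2.0)

    # -- loudness-function fitting (BTUX style) -------------------------------
    fixed_upper_slope: float = 0.7  # CU/dB when the 35-50 CU rule triggers
    min_points_upper: int = 5       # data points required in 35-50 CU
    slope_bounds: tuple[float, float] = (0.01, 10.0)

    # -- CU <-> sone transform ("Heeren-form", log10-cubic around 25 CU) ------
    sone_transform_coeffs: tuple[float, float, float, float, float] = (
        0.60206, 0.09, -1.6e-3, 1.8e-5, 25.0)

    # -- sone power law (internal loudness I -> sones), set by calibration ----
    sone_scale: float = 1.0
    sone_exponent: float = 1.0
    calibrated: bool = False

    # -- fitting / simulation -------------------------------------------------
    level_grid_db: tuple[float, float, float] = (0.0, 115.0, 1.5)
    aided_gain_cap_db: float = 60.0
    categories: tuple[float, ...] = tuple(float(c) for c in range(5, 55, 5))

    def level_grid(self):
        import numpy as np

        lo, hi, step = self.level_grid_db
        return np.arange(lo, hi + 0.5 * step, step)

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(**overrides) -> ModelConfig:
    """Return a fresh default configuration, optionally overridden."""
    cfg = ModelConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key: {k}")
        setattr(cfg, k, v)
    return cfg
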