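"""Virtual listeners and simulated categorical-loudness-scaling data.

The generator draws normal-hearing (NH) or hearing-impaired (HI) listener
profiles with the statistical structure of slight-to-moderate sensorineural
hearing loss studies: NH audiograms of 15 dB HL or better; HI audiograms
drawn per audiometric frequency around group means of roughly 23-61 dB HL
with left/right correlation; steeper (recruiting) loudness functions for HI
through the OHC-loss component; an individual binaural gain alpha_B whose
spread is wider for HI (including positive values, i.e. binaural
excitation).  Simulated scaling responses are the model's CU output plus
Gaussian response noise, rounded to the 11 categories.

Every dataset the generator emits can be fed straight back into the
fitting hierarchy, closing the generate -> simulate -> fit loop without any
external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import AUDIOMETRIC_FREQS_HZ, ModelConfig
from .datatypes import (LNN_CENTER_FREQS_HZ, Presentation, ScalingDataset,
                        ScalingDatum, StimulusKind, StimulusSpec)
from .excitation import AidedGainTable, match_thresholds
from .individualization import ListenerData, calibrated_config
from .loudness_function import LoudnessFunction
from .model import (ListenerModel, predict_cu_curve, predict_function,
                    DegenerateCurveError)
from .stages import BinauralStageParams

__all__ = [
    "GeneratorConfig", "ReferenceNH", "generate_profile", "simulate_scaling",
    "compute_aided_gains", "simulate_listener", "default_stimulus_set",
]

#: HI group audiogram means and standard deviations (dB HL) at the six
#: audiometric frequencies, emulating slight-to-moderate SNHL cohorts.
HI_AUDIOGRAM_MEAN_DB = (23.0, 33.0, 40.0, 48.0, 61.0, 59.0)
HI_AUDIOGRAM_SD_DB = (11.0, 12.0, 11.0, 18.0, 12.0, 17.0)


@dataclass
class GeneratorConfig:
    """Distributional assumptions of the virtual-listener generator."""

    group: str = "NH"                      # "NH" or "HI"
    seed: int = 0
    response_noise_cu: float = 3.0
    n_trials: int = 33
    interaural_correlation: float = 0.8    # audiogram left/right correlation
    # alpha_B distributions: NH narrow around the average NH inhibition,
    # HI wide including binaural excitation (alpha_B > 0)
    alpha_nh: tuple[float, float, float, float] = (-0.36, 0.08, -0.5, -0.15)
    alpha_hi: tuple[float, float, float, float] = (-0.10, 0.30, -0.5, 0.6)
    beta_range: tuple[float, float, float, float] = (0.25, 0.15, 0.0, 0.7)
    nh_audiogram_sd_db: float = 4.0
    nh_audiogram_max_db: float = 15.0
    hi_audiogram_bounds_db: tuple[float, float] = (5.0, 75.0)
    #: correlation of the audiogram deviation between adjacent audiometric
    #: frequencies (sensorineural audiograms are smooth, not notched)
    frequency_correlation: float = 0.7

    def __post_init__(self):
        if self.group not in ("NH", "HI"):
            raise ValueError("group must be 'NH' or 'HI'")


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    """Truncated normal by redraw (distribution-faithful for modest bounds)."""
    out = rng.normal(mean, sd, size=size)
    arr = np.atleast_1d(np.asarray(out, dtype=float))
    for _ in range(100):
        bad = (arr < lo) | (arr > hi)
        if not bad.any():
            break
        arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    arr = np.clip(arr, lo, hi)
    return arr if size is not None else float(arr[0])


def _smooth_z(rng, n, rho):
    """Standard-normal deviations with AR(1) correlation along frequency."""
    z = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = z[0]
    for i in range(1, n):
        out[i] = rho * out[i - 1] + np.sqrt(1.0 - rho ** 2) * z[i]
    return out


def generate_profile(gen: GeneratorConfig,
                     config: ModelConfig | None = None) -> ListenerModel:
    """Draw one ground-truth virtual listener.

    Reproducible for a fixed seed.  The audiogram is split into OHC and IHC
    components with the OHC-first rule; the post gain partially counteracts
    the IHC attenuation at high levels (restoring near-normal uncomfortable
    levels) plus an individual perturbation.
    """
    cfg = config or calibrated_config()
    rng = np.random.default_rng(gen.seed)
    nf = len(AUDIOMETRIC_FREQS_HZ)

    rho_ear = gen.interaural_correlation
    rho_f = gen.frequency_correlation
    z1 = _smooth_z(rng, nf, rho_f)
    z2 = _smooth_z(rng, nf, rho_f)
    z_right = rho_ear * z1 + np.sqrt(1 - rho_ear ** 2) * z2
    if gen.group == "NH":
        left = np.clip(5.0 + gen.nh_audiogram_sd_db * z1, -5.0,
                       gen.nh_audiogram_max_db)
        right = np.clip(5.0 + gen.nh_audiogram_sd_db * z_right, -5.0,
                        gen.nh_audiogram_max_db)
        a_mu, a_sd, a_lo, a_hi = gen.alpha_nh
    else:
        lo, hi = gen.hi_audiogram_bounds_db
        mean = np.asarray(HI_AUDIOGRAM_MEAN_DB)
        sd = np.asarray(HI_AUDIOGRAM_SD_DB)
        left = np.clip(mean + sd * z1, lo, hi)
        right = np.clip(mean + sd * z_right, lo, hi)
        a_mu, a_sd, a_lo, a_hi = gen.alpha_hi

    alpha_b = _trunc_normal(rng, a_mu, a_sd, a_lo, a_hi)
    b_mu, b_sd, b_lo, b_hi = gen.beta_range
    beta_l = _trunc_normal(rng, b_mu, b_sd, b_lo, b_hi)
    beta_r = _trunc_normal(rng, b_mu, b_sd, b_lo, b_hi)

    from .excitation import counteracting_post_gain_db

    ears = {}
    for side, hl in (("left", left), ("right", right)):
        ear = match_thresholds(hl, cfg)
        # post gain restores 50 %-100 % of the way to a normal uncomfortable
        # level, plus an individual perturbation
        comp = rng.uniform(0.5, 1.0, size=nf) * counteracting_post_gain_db(ear, cfg)
        post = np.clip(comp + rng.normal(0.0, 2.0, size=nf), -10.0, 40.0)
        ears[side] = match_thresholds(hl, cfg, post_gain_db=post)

    model = ListenerModel(left=ears["left"], right=ears["right"],
                          beta_l=float(beta_l), beta_r=float(beta_r),
                          binaural=BinauralStageParams(float(alpha_b), 0.0),
                          config=cfg, version=4,
                          listener_id=f"{gen.group}-{gen.seed}")
    return model


# ---------------------------------------------------------------------------
# reference NH functions and aided compensation gains
# ---------------------------------------------------------------------------

@dataclass
class ReferenceNH:
    """Average NH narrowband loudness functions used by the aided
    narrowband loudness compensation.  Generated from the calibrated
    zero-loss model, never hand-entered."""

    functions: dict          # center frequency (Hz) -> LoudnessFunction

    @classmethod
    def generate(cls, config: ModelConfig | None = None,
                 freqs=LNN_CENTER_FREQS_HZ) -> "ReferenceNH":
        cfg = config or calibrated_config()
        nh = ListenerModel.normal_hearing(cfg)
        fns = {}
        for f in freqs:
            stim = StimulusSpec(kind=StimulusKind.LNN, center_freq_hz=f,
                                presentation=Presentation.LEFT)
            fns[f] = predict_function(nh, stim)
        return cls(functions=fns)


def compute_aided_gains(model: ListenerModel, reference: ReferenceNH,
                        side: str = "left",
                        input_levels_db=None) -> AidedGainTable:
    """Level-dependent per-band gains restoring a listener's narrowband
    loudness to the NH reference (one ear).

    For band f and input level L the gain is the level at which the
    listener's band loudness equals the NH reference loudness at L, minus
    L.  Gains are capped at the configured maximum (flagged); levels at
    which the reference is below threshold get zero gain.
    """
    cfg = model.config
    if input_levels_db is None:
        input_levels_db = np.arange(0.0, 111.0, 5.0)
    input_levels_db = np.asarray(input_levels_db, float)
    freqs = np.array(sorted(reference.functions), dtype=float)
    pres = Presentation.LEFT if side == "left" else Presentation.RIGHT
    gains = np.zeros((freqs.size, input_levels_db.size))
    capped = False
    for i, f in enumerate(freqs):
        ref_fn = reference.functions[f]
        stim = StimulusSpec(kind=StimulusKind.LNN, center_freq_hz=f,
                            presentation=pres)
        try:
            lis_fn = predict_function(model, stim)
        except DegenerateCurveError:
            gains[i] = cfg.aided_gain_cap_db
            capped = True
            continue
        cu_ref = np.asarray(ref_fn.cu(input_levels_db))
        for j, (lv, c) in enumerate(zip(input_levels_db, cu_ref)):
            if c <= 0.0:
                gains[i, j] = 0.0
                continue
            if c >= 50.0:
                # both functions saturated: keep the 50-CU level difference
                g = lis_fn.level(50.0) - ref_fn.level(50.0)
            else:
                g = lis_fn.level(c) - lv
            if g > cfg.aided_gain_cap_db:
                g = cfg.aided_gain_cap_db
                capped = True
            gains[i, j] = g
    return AidedGainTable(band_freqs_hz=freqs, input_levels_db=input_levels_db,
                          gain_db=gains, capped=capped)


# ---------------------------------------------------------------------------
# scaling-data simulation
# ---------------------------------------------------------------------------

def simulate_scaling(model: ListenerModel, stim: StimulusSpec,
                     n_trials: int = 33, noise_cu: float = 3.0,
                     seed: int | np.random.Generator = 0,
                     aided_gains: dict | None = None) -> ScalingDataset:
    """Simulate a categorical-scaling dataset for one stimulus.

    Level placement emulates the outcome of an adaptive procedure with a
    two-phase scheme: a coarse range sweep establishes the audible range,
    then levels are stratified over the 5-50 CU span of the listener's own
    loudness function (plus a few near-threshold presentations).  The
    default of 33 trials is three near-threshold probes plus three complete
    category sweeps, so every category carries equal weight.  Responses
    are the model CU plus Gaussian noise, rounded to the 11 categories and
    clipped to [0, 50].
    """
    cfg = model.config
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    grid = cfg.level_grid()
    cu = predict_cu_curve(model, stim, grid, aided_gains)
    max_level = grid[-1]
    usable = (cu > 0).sum() >= 2 and cu[cu > 0].max() - cu[cu > 0].min() > 1e-9
    if not usable:
        warnings.warn(f"stimulus {stim.label} inaudible up to "
                      f"{max_level:.0f} dB SPL; emitting 0-CU responses")
        levels = np.linspace(max_level - 40.0, max_level, n_trials)
        data = [ScalingDatum(float(lv), 0.0) for lv in levels]
        return ScalingDataset(model.listener_id, stim, data)

    from .model import invert_cu_curve

    cats = np.arange(5.0, 55.0, 5.0)
    anchors = invert_cu_curve(model, stim, np.concatenate(([2.5], cats)),
                              aided_gains)
    l_thr, cat_levels = anchors[0], np.minimum(anchors[1:], max_level)
    near = np.array([l_thr - 4.0, l_thr - 1.0, l_thr + 1.0])
    base = np.concatenate((near, cat_levels))
    levels = list(base)
    while len(levels) < n_trials:
        k = len(levels) - len(base)
        lv = cat_levels[k % len(cat_levels)]
        if noise_cu > 0:
            lv = lv + rng.uniform(-2.0, 2.0)
        levels.append(min(lv, max_level))
    levels = np.array(levels[:n_trials])

    cu_true = predict_cu_curve(model, stim, levels, aided_gains)
    resp = cu_true + (rng.normal(0.0, noise_cu, size=levels.size)
                      if noise_cu > 0 else 0.0)
    resp = np.clip(np.round(resp / 5.0) * 5.0, 0.0, 50.0)
    data = [ScalingDatum(float(lv), float(r)) for lv, r in zip(levels, resp)]
    return ScalingDataset(model.listener_id, stim, data)


def default_stimulus_set(narrowband_freqs=LNN_CENTER_FREQS_HZ,
                         include_predictions: bool = True) -> list[StimulusSpec]:
    """Measurement conditions of a full session: monaural and diotic
    narrowband noises, aided broadband (monaural and binaural), plus the
    held-out prediction conditions (unaided broadband, +/-60 degrees)."""
    stims = []
    for f in narrowband_freqs:
        for pres in (Presentation.LEFT, Presentation.RIGHT, Presentation.DIOTIC):
            stims.append(StimulusSpec(kind=StimulusKind.LNN, center_freq_hz=f,
                                      presentation=pres))
    for pres in (Presentation.LEFT, Presentation.RIGHT, Presentation.DIOTIC):
        stims.append(StimulusSpec(kind=StimulusKind.IFN, presentation=pres,
                                  aided=True))
    if include_predictions:
        for pres in (Presentation.LEFT, Presentation.RIGHT,
                     Presentation.DIOTIC):
            stims.append(StimulusSpec(kind=StimulusKind.IFN,
                                      presentation=pres))
        for az in (-60.0, 60.0):
            stims.append(StimulusSpec(kind=StimulusKind.IFN,
                                      presentation=Presentation.DIOTIC,
                                      azimuth_deg=az, aided=True))
    return stims


def simulate_listener(profile: ListenerModel,
                      stimuli: list[StimulusSpec] | None = None,
                      n_trials: int = 33, noise_cu: float = 3.0,
                      seed: int = 0,
                      reference: ReferenceNH | None = None) -> ListenerData:
    """Simulate a complete measurement session for a virtual listener.

    Computes the listener's aided compensation gains from the ground-truth
    model against the NH reference, then simulates one scaling dataset per
    stimulus.  Returns a :class:`ListenerData` ready for the fitting
    hierarchy.
    """
    cfg = profile.config
    rng = np.random.default_rng(seed)
    if stimuli is None:
        stimuli = default_stimulus_set()
    if reference is None:
        reference = ReferenceNH.generate(cfg)
    aided = {side: compute_aided_gains(profile, reference, side)
             for side in ("left", "right")}
    datasets = []
    for stim in stimuli:
        datasets.append(simulate_scaling(
            profile, stim, n_trials=n_trials, noise_cu=noise_cu, seed=rng,
            aided_gains=aided if stim.aided else None))
    return ListenerData(listener_id=profile.listener_id,
                        audiogram_left=profile.left.audiogram_db_hl.copy(),
                        audiogram_right=profile.right.audiogram_db_hl.copy(),
                        datasets=datasets, aided_gains=aided)
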