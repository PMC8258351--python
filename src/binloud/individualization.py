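"""Individualization of the full loudness model: calibration, the four-stage
fitting hierarchy, and the statsmodels-style model/results interface.

The hierarchy adds one (set of) free parameter(s) per version, freezing the
parameters of lower versions:

1. peripheral OHC/IHC losses from the audiogram and the lower slopes of the
   monaural narrowband loudness functions, plus per-frequency post gains
   fitted per ear; average normal-hearing binaural stage (alpha_B = -0.273).
2. + bandwidth-dependent monaural gains beta_L, beta_R, fitted with the
   monaural aided broadband function added to the targets.
3. + individual overall binaural gain alpha_B, fitted to the binaural
   narrowband functions.
4. + bandwidth-dependent binaural gain beta_B, fitted jointly with alpha_B
   with the binaural aided broadband function added (up-weighted by the
   narrowband count).  "Version 3 modified" refits alpha_B alone on the
   version-4 target set.

All errors are measured in the level (X) direction: squared differences
between measured and modeled levels at the categories 5-50 CU.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .config import AUDIOMETRIC_FREQS_HZ, ModelConfig, default_config
from .datatypes import (Presentation, ScalingDataset, StimulusKind,
                        StimulusSpec, LNN_CENTER_FREQS_HZ)
from .excitation import (AidedGainTable, EarPeriphery, free_field_threshold_db,
                         match_thresholds)
from .loudness_function import LoudnessFunction, SoneTransform, fit_btux
from .model import (ListenerModel, curve_levels_at_categories,
                    internal_loudness_curve, predict_cu_curve,
                    predict_function)
from .stages import BinauralStageParams
from .summation import METRIC_CATEGORIES, MetricSet, compute_metrics

__all__ = [
    "CalibrationResult", "calibrate_transforms", "calibrated_config",
    "FitPlan", "ListenerData", "fit_version",
    "IndividualLoudnessModel", "IndividualLoudnessResults",
]

_N_FREE = {1: 0, 2: 2, 3: 3, 4: 4, "3m": 3}
_POST_GAIN_BOUNDS = (-20.0, 40.0)
_OHC_FRACTIONS = (1.0, 0.6, 0.3)


# ---------------------------------------------------------------------------
# calibration of the final transformations (internal loudness -> sone -> CU)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    sone_scale: float
    sone_exponent: float
    anchor_rmse_db: float
    config: ModelConfig


def _nh_anchor_function(cfg: ModelConfig) -> LoudnessFunction:
    """Analytic normal-hearing categorical loudness target at 1 kHz:
    threshold (2.5 CU) at the free-field threshold, "medium" (25 CU) at
    65 dB SPL, "too loud" (50 CU) at 100 dB SPL."""
    at = float(free_field_threshold_db([1000.0])[0])
    return LoudnessFunction(at, 22.5 / (65.0 - at), 25.0 / (100.0 - 65.0))


def calibrate_transforms(config: ModelConfig | None = None) -> CalibrationResult:
    """Set the power law (internal loudness -> sones) of a configuration.

    The zero-loss model's internal loudness for the monaural 1-kHz
    narrowband noise is regressed (log-log least squares) onto the sone
    values of the analytic normal-hearing anchor function, fixing the scale
    and exponent of the power law.  The calibration is deterministic and
    idempotent: it depends only on the anchor and the front-end constants,
    not on the current transform values.
    """
    cfg = config or default_config()
    anchor = _nh_anchor_function(cfg)
    transform = SoneTransform(cfg.sone_transform_coeffs)
    model = ListenerModel.normal_hearing(cfg)
    # monaural path only: alpha_B acts on diotic stimuli; the anchor is
    # referenced to monaural presentation
    stim = StimulusSpec(kind=StimulusKind.LNN, center_freq_hz=1000.0,
                        presentation=Presentation.LEFT)
    levels = cfg.level_grid()
    i_m = internal_loudness_curve(model, stim, levels)
    cu_t = np.asarray(anchor.cu(levels))
    mask = (cu_t >= 3.0) & (cu_t <= 50.0) & (i_m > 0)
    log_n = np.log10(transform.sone(cu_t[mask]))
    log_i = np.log10(i_m[mask])
    gamma, log_k = np.polyfit(log_i, log_n, 1)
    cfg.sone_exponent = float(gamma)
    cfg.sone_scale = float(10.0 ** log_k)
    cfg.calibrated = True
    cu_m = predict_cu_curve(model, stim, levels)
    lm = curve_levels_at_categories(levels, cu_m, METRIC_CATEGORIES)
    lt = anchor.level(np.asarray(METRIC_CATEGORIES))
    rmse = float(np.sqrt(np.mean((lm - lt) ** 2)))
    return CalibrationResult(cfg.sone_scale, cfg.sone_exponent, rmse, cfg)


_CAL_CACHE: dict[tuple, tuple[float, float]] = {}


def calibrated_config(**overrides) -> ModelConfig:
    """Default configuration with the power law already calibrated (cached
    per front-end constant set)."""
    cfg = default_config(**overrides)
    key = (cfg.n_segments, cfg.place_fmin_hz, cfg.place_fmax_hz,
           cfg.compression_exponent, cfg.compression_rejoin_db,
           cfg.specific_loudness_exponent, cfg.sone_transform_coeffs)
    if key not in _CAL_CACHE:
        calibrate_transforms(cfg)
        _CAL_CACHE[key] = (cfg.sone_scale, cfg.sone_exponent)
    cfg.sone_scale, cfg.sone_exponent = _CAL_CACHE[key]
    cfg.calibrated = True
    return cfg


# ---------------------------------------------------------------------------
# fit plans and listener data containers
# ---------------------------------------------------------------------------

def _mon_nb(freq, side):
    return StimulusSpec(kind=StimulusKind.LNN, center_freq_hz=freq,
                        presentation=side)


def _target_stimuli(version, narrowband_freqs=LNN_CENTER_FREQS_HZ):
    """Stimuli whose measured functions enter the fit of each version."""
    mon_nb = [_mon_nb(f, side) for side in (Presentation.LEFT, Presentation.RIGHT)
              for f in narrowband_freqs]
    mon_bb = [StimulusSpec(kind=StimulusKind.IFN, presentation=side, aided=True)
              for side in (Presentation.LEFT, Presentation.RIGHT)]
    dio_nb = [_mon_nb(f, Presentation.DIOTIC) for f in narrowband_freqs]
    dio_bb = [StimulusSpec(kind=StimulusKind.IFN,
                           presentation=Presentation.DIOTIC, aided=True)]
    if version == 1:
        return mon_nb
    if version == 2:
        return mon_nb + mon_bb
    if version == 3:
        return dio_nb
    if version in (4, "3m"):
        return dio_nb + dio_bb
    raise ValueError(f"unknown model version: {version}")


@dataclass
class FitPlan:
    """Target datasets and weights for one version of the hierarchy.

    Broadband functions are up-weighted by the number of narrowband stimuli
    in the fit so narrowband and broadband data contribute equally.
    """

    version: int | str
    stimuli: list = field(default_factory=list)
    weights: dict = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def for_version(cls, version, narrowband_freqs=LNN_CENTER_FREQS_HZ,
                    seed=None) -> "FitPlan":
        stimuli = _target_stimuli(version, narrowband_freqs)
        n_nb = len(narrowband_freqs)
        weights = {s: (float(n_nb) if s.kind is StimulusKind.IFN else 1.0)
                   for s in stimuli}
        return cls(version=version, stimuli=stimuli, weights=weights, seed=seed)


@dataclass
class ListenerData:
    """Measurement record of one listener: raw scaling datasets plus the
    audiograms and (for aided conditions) the per-ear compensation gains."""

    listener_id: str
    audiogram_left: np.ndarray
    audiogram_right: np.ndarray
    datasets: list[ScalingDataset] = field(default_factory=list)
    aided_gains: dict | None = None      # {"left": AidedGainTable, "right": ...}
    _functions: dict = field(default_factory=dict, repr=False)

    def dataset_for(self, stim: StimulusSpec) -> ScalingDataset | None:
        for ds in self.datasets:
            if ds.stimulus == stim:
                return ds
        return None

    def has_function(self, stim: StimulusSpec) -> bool:
        """A dataset exists and supports a loudness-function fit (an
        inaudible condition yields only 0-CU responses and is skipped)."""
        ds = self.dataset_for(stim)
        return ds is not None and ds.fittable()

    def function_for(self, stim: StimulusSpec,
                     config: ModelConfig | None = None) -> LoudnessFunction:
        """BTUX-fitted measured loudness function for a stimulus (cached).

        The 2.5-CU anchor is estimated by the free-threshold least-squares
        strategy: the raw-data crossing estimate rests on the few trials
        near threshold and would inject several dB of anchor noise into
        every downstream model fit.
        """
        if stim not in self._functions:
            ds = self.dataset_for(stim)
            if ds is None:
                raise KeyError(f"no dataset for stimulus {stim.label}")
            self._functions[stim] = fit_btux(
                ds, config, threshold_strategy="least-squares")
        return self._functions[stim]


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def _model_levels(model: ListenerModel, stim: StimulusSpec,
                  aided_gains, categories=METRIC_CATEGORIES) -> np.ndarray:
    """Category levels of the model's predicted parametric loudness function
    (condensed the same way as the measured functions, so measured and
    modeled levels are compared in the same space)."""
    fn = predict_function(model, stim, aided_gains=aided_gains)
    return fn.level(np.asarray(categories))


def _weighted_error(model: ListenerModel, data: ListenerData,
                    stimuli, weights) -> float:
    from .model import DegenerateCurveError

    err = 0.0
    for stim in stimuli:
        fn = data.function_for(stim, model.config)
        meas = fn.level(np.asarray(METRIC_CATEGORIES))
        try:
            pred = _model_levels(model, stim, data.aided_gains)
        except DegenerateCurveError:
            return 1e12
        err += weights.get(stim, 1.0) * float(np.sum((meas - pred) ** 2))
    return err


def _fit_version1(model: ListenerModel, data: ListenerData,
                  plan: FitPlan) -> ListenerModel:
    """Per ear and frequency: choose the OHC/IHC split that (with a fitted
    post gain) best matches the measured monaural narrowband function; the
    steeper the measured lower branch, the larger the OHC share that wins."""
    cfg = model.config
    freqs = list(AUDIOMETRIC_FREQS_HZ)
    for side, pres in (("left", Presentation.LEFT),
                       ("right", Presentation.RIGHT)):
        audiogram = (data.audiogram_left if side == "left"
                     else data.audiogram_right)
        from .excitation import counteracting_post_gain_db

        ear = match_thresholds(audiogram, cfg)
        fractions = np.ones(len(freqs))
        # frequencies without a fittable dataset keep the physiologically
        # motivated default: the post gain opposing the IHC attenuation
        post = counteracting_post_gain_db(ear, cfg)

        def err_at(i, stim, frac, g):
            trial_frac = fractions.copy()
            trial_frac[i] = frac
            trial_post = post.copy()
            trial_post[i] = g
            trial = match_thresholds(audiogram, cfg, ohc_fraction=trial_frac,
                                     post_gain_db=trial_post)
            m = _with_ear(model, side, trial)
            return _weighted_error(m, data, [stim], plan.weights)

        # pass 1: per frequency, choose the OHC share and post gain jointly;
        # pass 2: refit the post gains with all neighbours in place (the
        # periphery is interpolated across segments, so bands interact)
        for refine in (False, True):
            for i, f in enumerate(freqs):
                stim = _mon_nb(f, pres)
                if not data.has_function(stim):
                    continue
                candidates = ((fractions[i],) if refine else _OHC_FRACTIONS)
                best = None
                for frac in candidates:
                    res = optimize.minimize_scalar(
                        lambda g: err_at(i, stim, frac, g),
                        bounds=_POST_GAIN_BOUNDS, method="bounded",
                        options={"xatol": 1e-2})
                    if best is None or res.fun < best[0]:
                        best = (res.fun, frac, float(res.x))
                _, fractions[i], post[i] = best
        ear = match_thresholds(audiogram, cfg, ohc_fraction=fractions,
                               post_gain_db=post)
        model = _with_ear(model, side, ear)
    model.version = 1
    return model


def _with_ear(model: ListenerModel, side: str, ear: EarPeriphery) -> ListenerModel:
    m = copy.copy(model)
    if side == "left":
        m.left = ear
    else:
        m.right = ear
    return m


def _refit_post_gains(model: ListenerModel, data: ListenerData, side: str,
                      plan: FitPlan, passes: int = 2) -> ListenerModel:
    """Refit the per-frequency post gains of one ear on its monaural
    narrowband functions, keeping the OHC/IHC split fixed.

    Two passes: the periphery is interpolated across segments, so a band's
    curve depends on its neighbours' gains as well."""
    pres = Presentation.LEFT if side == "left" else Presentation.RIGHT
    ear = model.left if side == "left" else model.right
    post = ear.post_gain_db.copy()
    for _ in range(passes):
        for i, f in enumerate(ear.freqs_hz):
            stim = _mon_nb(f, pres)
            if not data.has_function(stim):
                continue

            def err_of_post(g):
                trial_post = post.copy()
                trial_post[i] = g
                trial = EarPeriphery(ear.audiogram_db_hl, ear.ohc_loss_db,
                                     ear.ihc_attenuation_db, trial_post,
                                     ear.freqs_hz)
                return _weighted_error(_with_ear(model, side, trial), data,
                                       [stim], plan.weights)

            res = optimize.minimize_scalar(err_of_post,
                                           bounds=_POST_GAIN_BOUNDS,
                                           method="bounded",
                                           options={"xatol": 1e-2})
            post[i] = float(res.x)
    trial = EarPeriphery(ear.audiogram_db_hl, ear.ohc_loss_db,
                         ear.ihc_attenuation_db, post, ear.freqs_hz)
    return _with_ear(model, side, trial)


_BETA_GRID = np.arange(-0.2, 1.01, 0.2)


def _fit_version2(model: ListenerModel, data: ListenerData,
                  plan: FitPlan) -> ListenerModel:
    """Joint monaural fit of beta with the post gains, per ear.

    beta and the post gains interact (the bandwidth gain also acts on the
    narrowband functions), so beta is fitted by a profiled search: for each
    candidate beta the post gains are re-fitted to the narrowband functions
    starting from the version-1 state, and the profiled error over the
    narrowband + up-weighted broadband targets is minimized.  Restarting the
    post gains from version 1 keeps the fit in the basin of the smallest
    adjustment to the lower-version solution.
    """
    cfg = model.config
    for side, pres in (("left", Presentation.LEFT),
                       ("right", Presentation.RIGHT)):
        stimuli = [s for s in plan.stimuli if s.presentation is pres
                   and data.has_function(s)]
        if not any(s.kind is StimulusKind.IFN for s in stimuli):
            continue  # no broadband data: beta stays at its default
        attr = "beta_l" if side == "left" else "beta_r"
        base = model                       # version-1 posts for this ear

        def profiled(b):
            m = copy.copy(base)
            setattr(m, attr, float(b))
            m = _refit_post_gains(m, data, side, plan)
            return _weighted_error(m, data, stimuli, plan.weights), m

        blo, bhi = cfg.beta_bounds
        grid = [b for b in _BETA_GRID if blo <= b <= bhi]
        evals = {float(b): profiled(b) for b in grid}
        best_b = min(evals, key=lambda b: evals[b][0])
        lo = max(best_b - 0.2, blo)
        hi = min(best_b + 0.2, bhi)
        res = optimize.minimize_scalar(lambda b: profiled(b)[0],
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 5e-3})
        err_fine, m_fine = profiled(float(res.x))
        if err_fine <= evals[best_b][0]:
            model = m_fine
        else:
            model = evals[best_b][1]
    model.version = 2
    return model


def _fit_version3(model: ListenerModel, data: ListenerData,
                  plan: FitPlan) -> ListenerModel:
    cfg = model.config
    stimuli = [s for s in plan.stimuli if data.has_function(s)]
    if not stimuli:
        raise ValueError("no binaural datasets available for the alpha_B fit")

    def err_of_alpha(a):
        m = copy.copy(model)
        m.binaural = BinauralStageParams(a, model.binaural.beta_b)
        return _weighted_error(m, data, stimuli, plan.weights)

    lo, hi = cfg.alpha_b_bounds
    res = optimize.minimize_scalar(err_of_alpha, bounds=(lo, hi),
                                   method="bounded", options={"xatol": 1e-5})
    cands = [(float(res.fun), float(res.x)), (err_of_alpha(lo), lo)]
    _, alpha = min(cands)
    model = copy.copy(model)
    model.binaural = BinauralStageParams(alpha, model.binaural.beta_b)
    model.version = 3 if plan.version == 3 else plan.version
    return model


def _fit_version4(model: ListenerModel, data: ListenerData,
                  plan: FitPlan) -> ListenerModel:
    cfg = model.config
    stimuli = [s for s in plan.stimuli if data.has_function(s)]

    def err(x):
        a, bb = x
        lo, hi = cfg.alpha_b_bounds
        blo, bhi = cfg.beta_bounds
        if not (lo <= a <= hi and blo <= bb <= bhi):
            return 1e12
        m = copy.copy(model)
        try:
            m.binaural = BinauralStageParams(a, bb)
            return _weighted_error(m, data, stimuli, plan.weights)
        except ValueError:
            return 1e12

    x0 = np.array([model.binaural.alpha_b, 0.0])
    res = optimize.minimize(err, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6,
                                     "maxiter": 300})
    a, bb = res.x
    if err((a, bb)) > err((x0[0], 0.0)):
        a, bb = x0[0], 0.0
    model = copy.copy(model)
    model.binaural = BinauralStageParams(float(a), float(bb))
    model.version = 4
    return model


def fit_version(model: ListenerModel, data: ListenerData,
                plan: FitPlan | None = None,
                version: int | str | None = None
                ) -> tuple[ListenerModel, MetricSet]:
    """Fit one version of the hierarchy, freezing lower-version parameters.

    Returns the updated model and the performance metrics on the stimuli
    targeted by this version's plan.
    """
    if plan is None:
        if version is None:
            raise ValueError("either plan or version is required")
        plan = FitPlan.for_version(version)
    version = plan.version
    fittable = [s for s in plan.stimuli if data.has_function(s)]
    if version == 1:
        # inaudible conditions are tolerated; each ear needs at least one
        # usable monaural narrowband function
        for pres in (Presentation.LEFT, Presentation.RIGHT):
            if not any(s.presentation is pres for s in fittable):
                raise ValueError(
                    f"fit plan requires missing stimuli: no fittable "
                    f"monaural narrowband dataset for the {pres.value} ear")

    if version == 1:
        model = _fit_version1(model, data, plan)
    elif version == 2:
        model = _fit_version2(model, data, plan)
    elif version in (3, "3m"):
        model = _fit_version3(model, data, plan)
    elif version == 4:
        model = _fit_version4(model, data, plan)
    else:
        raise ValueError(f"unknown model version: {version}")

    fitted = [s for s in plan.stimuli if data.has_function(s)]
    meas = np.array([data.function_for(s, model.config).level(
        np.asarray(METRIC_CATEGORIES)) for s in fitted])
    pred = np.array([_model_levels(model, s, data.aided_gains) for s in fitted])
    metrics = compute_metrics(meas, pred, p=_N_FREE.get(version, 0))
    return model, metrics


# ---------------------------------------------------------------------------
# statsmodels-style interface
# ---------------------------------------------------------------------------

class IndividualLoudnessModel:
    """Individual binaural loudness model for one listener's scaling data.

    Parameters
    ----------
    data : ListenerData
        Raw categorical-scaling datasets, audiograms and aided gains.
    config : ModelConfig, optional
        Calibrated configuration; an uncalibrated one is calibrated on the
        fly.
    """

    def __init__(self, data: ListenerData, config: ModelConfig | None = None):
        cfg = config or calibrated_config()
        if not cfg.calibrated:
            calibrate_transforms(cfg)
        self.config = cfg
        self.data = data

    def fit(self, version: int | str = 3,
            narrowband_freqs=LNN_CENTER_FREQS_HZ) -> "IndividualLoudnessResults":
        """Run the hierarchy up to ``version`` (1, 2, 3, 4 or "3m")."""
        order: list = [1, 2, 3, 4]
        if version == "3m":
            order = [1, 2, "3m"]
        elif version not in order:
            raise ValueError(f"unknown model version: {version}")
        else:
            order = order[: order.index(version) + 1]
        model = ListenerModel.normal_hearing(self.config)
        model.listener_id = self.data.listener_id
        metrics_by_version = {}
        for v in order:
            plan = FitPlan.for_version(v, narrowband_freqs)
            model, metrics = fit_version(model, self.data, plan)
            metrics_by_version[v] = metrics
        return IndividualLoudnessResults(self, model, metrics_by_version)


class IndividualLoudnessResults:
    """Fitted individual loudness model with prediction and diagnostics."""

    def __init__(self, model_spec: IndividualLoudnessModel,
                 model: ListenerModel, metrics_by_version: dict):
        self.spec = model_spec
        self.model = model
        self.metrics_by_version = metrics_by_version
        self.version = model.version

    # -- parameter access ----------------------------------------------------
    @property
    def params(self) -> dict:
        return {
            "beta_l": self.model.beta_l,
            "beta_r": self.model.beta_r,
            "alpha_b": self.model.binaural.alpha_b,
            "beta_b": self.model.binaural.beta_b,
            "post_gain_left_db": self.model.left.post_gain_db.tolist(),
            "post_gain_right_db": self.model.right.post_gain_db.tolist(),
            "ohc_loss_left_db": self.model.left.ohc_loss_db.tolist(),
            "ohc_loss_right_db": self.model.right.ohc_loss_db.tolist(),
        }

    # -- prediction ----------------------------------------------------------
    def predict_function(self, stim: StimulusSpec) -> LoudnessFunction:
        return predict_function(self.model, stim,
                                aided_gains=self.spec.data.aided_gains)

    def predict_cu(self, stim: StimulusSpec, levels_db) -> np.ndarray:
        return predict_cu_curve(self.model, stim, np.asarray(levels_db, float),
                                self.spec.data.aided_gains)

    def prediction_metrics(self, stimuli, p: int | None = None) -> MetricSet:
        """Metrics on an arbitrary (typically held-out) stimulus set."""
        data = self.spec.data
        meas = np.array([data.function_for(s, self.model.config).level(
            np.asarray(METRIC_CATEGORIES)) for s in stimuli])
        pred = np.array([_model_levels(self.model, s, data.aided_gains)
                         for s in stimuli])
        return compute_metrics(meas, pred,
                               p=_N_FREE[self.version] if p is None else p)

    def summary(self) -> str:
        m = self.model
        lines = [f"Individual loudness model: {m.listener_id}",
                 "=" * 48,
                 f"version:  {self.version}",
                 f"alpha_B:  {m.binaural.alpha_b:+.3f}   "
                 f"beta_B: {m.binaural.beta_b:+.3f}",
                 f"beta_L:   {m.beta_l:+.3f}   beta_R: {m.beta_r:+.3f}",
                 "",
                 "freq/Hz    OHC_L  IHC_L  post_L   OHC_R  IHC_R  post_R"]
        for i, f in enumerate(m.left.freqs_hz):
            lines.append(
                f"{f:7.0f}   {m.left.ohc_loss_db[i]:5.1f}  "
                f"{m.left.ihc_attenuation_db[i]:5.1f}  "
                f"{m.left.post_gain_db[i]:6.1f}   "
                f"{m.right.ohc_loss_db[i]:5.1f}  "
                f"{m.right.ihc_attenuation_db[i]:5.1f}  "
                f"{m.right.post_gain_db[i]:6.1f}")
        lines.append("")
        lines.append("fit metrics by version:")
        for v, met in self.metrics_by_version.items():
            adj = f"{met.ncc_adj:.3f}" if met.ncc_adj is not None else "  -  "
            lines.append(f"  v{v}: ncc={met.ncc:.3f} ncc'={adj} "
                         f"rmse={met.rmse:.2f} dB bias={met.bias:+.2f} dB")
        return "\n".join(lines)
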