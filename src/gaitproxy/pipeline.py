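"""End-to-end proxy-measurement pipeline.

Training: detect gait events from the reference forces (10 N threshold),
build the event-based membership approximation, decompose the acceleration
channels into left/right components, evaluate the degree-2 candidate
dictionary over lags 0..18, and select one polynomial moving-average model
per foot by (iterative) orthogonal forward regression.

Prediction on new data needs only the accelerations plus gait events (from
the reference force when present, mirroring insole-derived events, or
supplied externally); the fitted polynomial is evaluated sample by sample
with no output feedback.

The half-split protocol fits on the first half of a recording and
validates on the second, with the split aligned to a gait-cycle boundary
so no cycle spans it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .dictionary import build_dictionary, evaluate_dictionary
from .errors import InsufficientDataError, ParameterError, StructuralError
from .gait import (GaitEvents, decompose_acceleration, detect_gait_events,
                   event_membership, segment_cycles)
from .metrics import ErrorReport, cycle_error_report
from .ofr import NMAModel, OFRResult, StoppingRule, iofr_select, predict_nma
from .recording import TimeSeriesRecording

logger = logging.getLogger("gaitproxy")


@dataclass
class PipelineConfig:
    """Everything the fit/predict pipeline needs, serializable to YAML/JSON."""

    threshold: float = 10.0            # N, gait-event force threshold
    max_lag: int = 18                  # samples, input-lag window
    degree: int = 2                    # polynomial degree of the model class
    include_constant: bool = True
    channels: Tuple[str, ...] = ("ax", "ay", "az")
    stopping: str = "fixed_terms"
    n_terms: int = 64                  # model size under fixed_terms
    err_tolerance: float = 1e-4
    penalty: float = 1.0
    iofr_iterations: int = 1           # 0 = plain greedy OFR
    min_stance_duration: float = 0.1   # s, event-detector debounce guard
    rrmse_mode: str = "per_cycle"

    def decomposed_channels(self) -> Tuple[str, ...]:
        return tuple(f"{c}_{side}" for c in self.channels
                     for side in ("left", "right"))

    def stopping_rule(self) -> StoppingRule:
        return StoppingRule(mode=self.stopping, n_terms=self.n_terms,
                            err_tolerance=self.err_tolerance,
                            penalty=self.penalty)


@dataclass
class FitReport:
    """Structure-selection traces and bookkeeping from one training run."""

    ofr_left: OFRResult
    ofr_right: OFRResult
    events: GaitEvents
    config: PipelineConfig
    n_training_samples: int


def split_half(recording: TimeSeriesRecording,
               threshold: float = 10.0) -> Tuple[TimeSeriesRecording,
                                                 TimeSeriesRecording]:
    """Split a recording into training and test halves at a cycle boundary.

    The boundary is the left-foot initial contact closest to the midpoint,
    so no gait cycle spans the split and concatenating the halves
    reproduces the recording.
    """
    if not recording.has_grf:
        raise StructuralError("split_half needs reference vGRF to locate cycles")
    events = detect_gait_events(recording.grf_left, recording.grf_right,
                                threshold=threshold,
                                sampling_rate=recording.sampling_rate)
    ics = events.ic("left")
    if len(ics) < 4:
        raise InsufficientDataError("too few gait cycles to split")
    mid = recording.n_samples // 2
    boundary = int(ics[np.argmin(np.abs(ics - mid))])
    if boundary <= 0 or boundary >= recording.n_samples:
        raise InsufficientDataError("cycle boundary coincides with an endpoint")
    return recording.slice(0, boundary), recording.slice(boundary,
                                                         recording.n_samples)


def _decompose(recording: TimeSeriesRecording, events: GaitEvents):
    membership = event_membership(events, recording.n_samples)
    return decompose_acceleration(recording, membership)


def fit_proxy(recording: TimeSeriesRecording,
              config: Optional[PipelineConfig] = None
              ) -> Tuple[NMAModel, NMAModel, FitReport]:
    """Fit left- and right-foot vGRF models on a training recording."""
    config = config or PipelineConfig()
    if not recording.has_grf:
        raise StructuralError("training requires reference grf_left and grf_right")
    logger.info("[events] detecting gait events (threshold %.1f N)",
                config.threshold)
    events = detect_gait_events(recording.grf_left, recording.grf_right,
                                threshold=config.threshold,
                                sampling_rate=recording.sampling_rate,
                                min_run_duration=config.min_stance_duration)
    logger.info("[decompose] event membership + channel decomposition")
    signals = _decompose(recording, events)
    logger.info("[dictionary] degree %d, max lag %d", config.degree,
                config.max_lag)
    dictionary = build_dictionary(config.decomposed_channels(), config.max_lag,
                                  config.degree, config.include_constant)
    design = evaluate_dictionary(dictionary, signals)
    L = config.max_lag
    stop = config.stopping_rule()
    models, results = {}, {}
    for side, target in (("left", recording.grf_left),
                         ("right", recording.grf_right)):
        logger.info("[ofr] selecting %s-foot model", side)
        res = iofr_select(design, target[L:], stop,
                          max_iterations=config.iofr_iterations)
        results[side] = res
        models[side] = NMAModel(
            terms=[dictionary[i] for i in res.selected],
            coefficients=res.theta, max_lag=L,
            metadata={"foot": side, "n_terms": res.n_terms,
                      "sum_err": res.sum_err, "rss": res.rss,
                      "config": _config_dict(config)})
    report = FitReport(ofr_left=results["left"], ofr_right=results["right"],
                       events=events, config=config,
                       n_training_samples=recording.n_samples)
    return models["left"], models["right"], report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["channels"] = list(d["channels"])
    return d


def predict_proxy(model_left: NMAModel, model_right: NMAModel,
                  recording: TimeSeriesRecording,
                  events: Optional[GaitEvents] = None,
                  threshold: float = 10.0) -> Tuple[np.ndarray, np.ndarray]:
    """Predict both feet's vGRF from a recording's accelerations.

    Gait events (needed for the membership decomposition) are taken from
    the reference vGRF when the recording carries one, else from the
    ``events`` argument.
    """
    if events is None:
        if not recording.has_grf:
            raise StructuralError(
                "prediction needs gait events: recording has no reference "
                "vGRF, so pass events= explicitly")
        events = detect_gait_events(recording.grf_left, recording.grf_right,
                                    threshold=threshold,
                                    sampling_rate=recording.sampling_rate)
    signals = _decompose(recording, events)
    return predict_nma(model_left, signals), predict_nma(model_right, signals)


class VGRFProxyRegressor(BaseEstimator):
    """Scikit-learn-style estimator for the full proxy-measurement pipeline.

    ``fit`` consumes a :class:`TimeSeriesRecording` with reference forces;
    ``predict`` returns an (n_samples, 2) array of left/right vGRF
    predictions (NaN over the first ``max_lag`` warm-up samples).

    Parameters mirror :class:`PipelineConfig`.

    Attributes
    ----------
    model_left_, model_right_ : NMAModel
        Selected polynomial models per foot.
    report_ : FitReport
        Selection traces, detected events, configuration.
    """

    def __init__(self, threshold: float = 10.0, max_lag: int = 18,
                 degree: int = 2, include_constant: bool = True,
                 channels: Tuple[str, ...] = ("ax", "ay", "az"),
                 stopping: str = "fixed_terms", n_terms: int = 64,
                 err_tolerance: float = 1e-4, penalty: float = 1.0,
                 iofr_iterations: int = 1, min_stance_duration: float = 0.1,
                 rrmse_mode: str = "per_cycle"):
        self.threshold = threshold
        self.max_lag = max_lag
        self.degree = degree
        self.include_constant = include_constant
        self.channels = channels
        self.stopping = stopping
        self.n_terms = n_terms
        self.err_tolerance = err_tolerance
        self.penalty = penalty
        self.iofr_iterations = iofr_iterations
        self.min_stance_duration = min_stance_duration
        self.rrmse_mode = rrmse_mode

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            threshold=self.threshold, max_lag=self.max_lag, degree=self.degree,
            include_constant=self.include_constant,
            channels=tuple(self.channels), stopping=self.stopping,
            n_terms=self.n_terms, err_tolerance=self.err_tolerance,
            penalty=self.penalty, iofr_iterations=self.iofr_iterations,
            min_stance_duration=self.min_stance_duration,
            rrmse_mode=self.rrmse_mode)

    def fit(self, recording: TimeSeriesRecording, y=None):
        self.model_left_, self.model_right_, self.report_ = fit_proxy(
            recording, self._config())
        return self

    def predict(self, recording: TimeSeriesRecording,
                events: Optional[GaitEvents] = None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_left_")
        left, right = predict_proxy(self.model_left_, self.model_right_,
                                    recording, events=events,
                                    threshold=self.threshold)
        return np.column_stack([left, right])

    def evaluate(self, recording: TimeSeriesRecording,
                 events: Optional[GaitEvents] = None
                 ) -> Dict[str, ErrorReport]:
        """Predict on a labelled recording and report per-cycle errors."""
        if not recording.has_grf:
            raise StructuralError("evaluation requires reference vGRF")
        if events is None:
            events = detect_gait_events(
                recording.grf_left, recording.grf_right,
                threshold=self.threshold,
                sampling_rate=recording.sampling_rate,
                min_run_duration=self.min_stance_duration)
        pred = self.predict(recording, events=events)
        return {
            "left": cycle_error_report(pred[:, 0], recording.grf_left, events,
                                       "left", rrmse_mode=self.rrmse_mode),
            "right": cycle_error_report(pred[:, 1], recording.grf_right, events,
                                        "right", rrmse_mode=self.rrmse_mode),
        }


# ---------------------------------------------------------------------------
# Model persistence

def save_model(path, model: NMAModel) -> None:
    """Write one foot's model as JSON (terms, coefficients, max lag)."""
    with open(path, "w") as fh:
        json.dump(model.to_json(), fh, indent=1)


def load_model(path) -> NMAModel:
    with open(path) as fh:
        return NMAModel.from_json(json.load(fh))


def save_models(path, model_left: NMAModel, model_right: NMAModel) -> None:
    """Write the bilateral model pair as a single JSON file."""
    with open(path, "w") as fh:
        json.dump({"left": model_left.to_json(),
                   "right": model_right.to_json()}, fh, indent=1)


def load_models(path) -> Tuple[NMAModel, NMAModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return NMAModel.from_json(payload["left"]), NMAModel.from_json(payload["right"])
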