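"""Prediction-error metrics and statistical comparisons.

Accuracy is quantified by the root mean squared error

    RMSE = sqrt( (1/N) * sum_k (y(k) - yhat(k))^2 )

and by the relative RMSE, the RMSE normalized by the average of the two
signals' peak-to-peak amplitudes, reported in percent:

    rRMSE = 100 * RMSE / ( (ptp(y) + ptp(yhat)) / 2 ).

Errors are reported per gait cycle, per support phase (full cycle, single
support, double support) and at the three stance-curve critical points
(VP1, VP2, TR), aggregated as mean +/- SD over cycles, together with the
cross-correlation coefficient between predicted and reference force.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ParameterError
from .gait import (DegenerateShapeError, GaitEvents, extract_critical_points,
                   phase_masks, segment_cycles)


def compute_rmse(y, yhat) -> float:
    """Root mean squared error between two equal-length sequences."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ParameterError("sequences differ in length")
    if y.size == 0:
        raise DomainError("RMSE of empty sequences is undefined")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def compute_rrmse(y, yhat) -> float:
    """Relative RMSE in percent of the mean peak-to-peak amplitude."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    denom = (np.ptp(y) + np.ptp(yhat)) / 2.0
    if denom == 0:
        raise DomainError("rRMSE undefined: both signals are constant")
    return float(100.0 * compute_rmse(y, yhat) / denom)


@dataclass
class ErrorReport:
    """Per-cycle and aggregated prediction errors for one foot."""

    per_cycle: pd.DataFrame
    aggregate: Dict[str, float]
    rho: float
    n_cycles: int
    n_excluded: int
    foot: str = ""

    COLUMNS = ("rmse_full", "rrmse_full", "rrmse_single", "rrmse_double",
               "rrmse_vp1", "rrmse_vp2", "rrmse_tr")

    def to_csv(self, path) -> None:
        self.per_cycle.to_csv(path, index=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in self.COLUMNS:
            rows.append((col, self.aggregate.get(f"{col}_mean", np.nan),
                         self.aggregate.get(f"{col}_sd", np.nan)))
        return pd.DataFrame(rows, columns=["metric", "mean", "sd"])


def cycle_error_report(predicted, reference, events: GaitEvents, foot: str,
                       rrmse_mode: str = "per_cycle") -> ErrorReport:
    """Compare a predicted vGRF against its reference, cycle by cycle.

    Cycles are [IC_i, IC_{i+1}) intervals of the given foot.  Cycles that
    overlap undefined predictions (NaN, e.g. the lag warm-up) or whose
    reference stance lacks the M-shape are excluded and counted.

    Critical-point errors are per-cycle |reference - predicted| at VP1,
    VP2 and TR, normalized like the rRMSE by the mean peak-to-peak
    amplitude of the two cycle signals (in percent).  Predicted landmark
    values come from extremum analysis of the predicted cycle; if the
    prediction is too distorted for that, the predicted value at the
    reference landmark index is used.

    rrmse_mode 'per_cycle' normalizes each cycle by its own peak-to-peak
    range; 'global' uses the range of the whole evaluated segment.
    """
    if rrmse_mode not in ("per_cycle", "global"):
        raise ParameterError(f"unknown rrmse_mode {rrmse_mode!r}")
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = len(reference)
    masks = phase_masks(events, n)
    single = masks[f"single_{foot}"]
    double = masks["double"]

    valid = ~np.isnan(predicted)
    if rrmse_mode == "global":
        global_denom = (np.ptp(reference[valid]) + np.ptp(predicted[valid])) / 2.0

    fcs = events.fc(foot)
    rows: List[dict] = []
    n_excluded = 0
    for a, b in segment_cycles(events, foot):
        if b > n or not valid[a:b].all():
            n_excluded += 1
            continue
        ref_c, pred_c = reference[a:b], predicted[a:b]
        denom = ((np.ptp(ref_c) + np.ptp(pred_c)) / 2.0
                 if rrmse_mode == "per_cycle" else global_denom)
        if denom == 0:
            n_excluded += 1
            continue
        # landmark extraction runs on the stance portion [IC, FC) only —
        # swing fluctuations of the prediction are not force peaks
        after = fcs[(fcs > a) & (fcs <= b)]
        stance_end = int(after[0]) - a if len(after) else b - a
        ref_s, pred_s = ref_c[:stance_end], pred_c[:stance_end]
        try:
            cp_ref = extract_critical_points(ref_s)
        except DegenerateShapeError:
            n_excluded += 1
            continue
        try:
            cp_pred = extract_critical_points(pred_s)
            vp1_p, vp2_p, tr_p = (cp_pred.vp1_value, cp_pred.vp2_value,
                                  cp_pred.tr_value)
        except DegenerateShapeError:
            vp1_p = float(pred_s[cp_ref.vp1_index])
            vp2_p = float(pred_s[cp_ref.vp2_index])
            tr_p = float(pred_s[cp_ref.tr_index])

        row = {
            "cycle_start": a, "cycle_end": b,
            "rmse_full": compute_rmse(ref_c, pred_c),
            "rrmse_full": 100.0 * compute_rmse(ref_c, pred_c) / denom,
            "rrmse_vp1": 100.0 * abs(cp_ref.vp1_value - vp1_p) / denom,
            "rrmse_vp2": 100.0 * abs(cp_ref.vp2_value - vp2_p) / denom,
            "rrmse_tr": 100.0 * abs(cp_ref.tr_value - tr_p) / denom,
        }
        for name, mask in (("single", single), ("double", double)):
            sel = mask[a:b]
            if sel.any():
                row[f"rmse_{name}"] = compute_rmse(ref_c[sel], pred_c[sel])
                row[f"rrmse_{name}"] = 100.0 * row[f"rmse_{name}"] / denom
            else:
                row[f"rmse_{name}"] = np.nan
                row[f"rrmse_{name}"] = np.nan
        rows.append(row)

    per_cycle = pd.DataFrame(rows)
    aggregate: Dict[str, float] = {}
    for col in ErrorReport.COLUMNS:
        if len(per_cycle) and col in per_cycle:
            vals = per_cycle[col].dropna()
            aggregate[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            aggregate[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        else:
            aggregate[f"{col}_mean"] = np.nan
            aggregate[f"{col}_sd"] = np.nan

    both = valid & ~np.isnan(reference)
    if both.sum() > 1 and np.ptp(reference[both]) > 0 and np.ptp(predicted[both]) > 0:
        rho = float(np.corrcoef(reference[both], predicted[both])[0, 1])
    else:
        rho = np.nan
    return ErrorReport(per_cycle=per_cycle, aggregate=aggregate, rho=rho,
                       n_cycles=len(rows), n_excluded=n_excluded, foot=foot)


@dataclass
class ComparisonResult:
    """Two-sample pooled-variance (Student) t-test between error samples."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    mean_diff: float
    t_statistic: float
    p_value: float
    between_group_variance: float


def compare_error_samples(sample_a, sample_b) -> ComparisonResult:
    """Student's t-test (pooled variance, two-sided) between two error samples.

    Identical constant samples yield t = 0, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:  # degenerate: no spread
        t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    grand = np.concatenate([a, b]).mean()
    between = (len(a) * (a.mean() - grand) ** 2
               + len(b) * (b.mean() - grand) ** 2) / (len(a) + len(b) - 1)
    return ComparisonResult(n_a=len(a), n_b=len(b), mean_a=float(a.mean()),
                            mean_b=float(b.mean()),
                            mean_diff=float(a.mean() - b.mean()),
                            t_statistic=float(t), p_value=float(p),
                            between_group_variance=float(between))
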