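"""Gait-event detection, membership functions, and signal decomposition.

The central trick of the proxy-measurement method lives here: a single
trunk acceleration signal is split into a left-foot and a right-foot
component by point-wise multiplication with a pair of complementary
membership weights ``w_left + w_right = 1``.  The exact weights are the
per-foot share of the total vertical ground reaction force,

    w_left(k) = GRF_left(k) / (GRF_left(k) + GRF_right(k)),

but since the whole point is to predict the forces, an event-based
approximation is used at prediction time: the membership is 1 in single
support, 0 in swing, and ramps linearly across each double-support
interval.  Gait events (initial contact IC, final contact FC) are detected
from the reference force with a 10 N threshold.

All indices are 0-based and stance intervals are half-open ``[IC, FC)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import (DegenerateShapeError, DomainError, InsufficientDataError,
                     ParameterError, StructuralError, UnsupportedGaitError)

SIDES = ("left", "right")

#: minimum stance/swing run duration (s) accepted by the event detector;
#: shorter runs are treated as threshold chatter and discarded
MIN_RUN_DURATION = 0.1


@dataclass
class GaitEvents:
    """Per-foot initial-contact and final-contact sample indices.

    For each foot the events alternate IC, FC, IC, FC, ... and each stance
    ``[IC_i, FC_i)`` has positive length.
    """

    ic_left: np.ndarray
    fc_left: np.ndarray
    ic_right: np.ndarray
    fc_right: np.ndarray

    def __post_init__(self):
        for name in ("ic_left", "fc_left", "ic_right", "fc_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        for side in SIDES:
            ic, fc = self.ic(side), self.fc(side)
            if len(ic) != len(fc):
                raise StructuralError(f"{side}: {len(ic)} ICs but {len(fc)} FCs")
            if np.any(fc <= ic):
                raise StructuralError(f"{side}: stance with non-positive length")
            merged = np.empty(2 * len(ic), dtype=int)
            merged[0::2], merged[1::2] = ic, fc
            if np.any(np.diff(merged) <= 0):
                raise StructuralError(f"{side}: events do not alternate/increase")

    def ic(self, side: str) -> np.ndarray:
        return self.ic_left if side == "left" else self.ic_right

    def fc(self, side: str) -> np.ndarray:
        return self.fc_left if side == "left" else self.fc_right

    def stance_mask(self, side: str, n_samples: int) -> np.ndarray:
        """Boolean mask, True where the given foot is on the ground."""
        mask = np.zeros(n_samples, dtype=bool)
        for a, b in zip(self.ic(side), self.fc(side)):
            mask[max(a, 0):min(b, n_samples)] = True
        return mask

    def to_frame(self):
        import pandas as pd
        rows = []
        for side in SIDES:
            for idx in self.ic(side):
                rows.append((side, "IC", int(idx)))
            for idx in self.fc(side):
                rows.append((side, "FC", int(idx)))
        df = pd.DataFrame(rows, columns=["foot", "event_type", "sample_index"])
        return df.sort_values(["foot", "sample_index"], ignore_index=True)

    @classmethod
    def from_frame(cls, df) -> "GaitEvents":
        def grab(side, kind):
            sel = (df["foot"] == side) & (df["event_type"] == kind)
            return np.sort(df.loc[sel, "sample_index"].to_numpy(dtype=int))
        return cls(grab("left", "IC"), grab("left", "FC"),
                   grab("right", "IC"), grab("right", "FC"))


@dataclass
class MembershipPair:
    """Complementary left/right weights in [0, 1] with w_left + w_right = 1."""

    w_left: np.ndarray
    w_right: np.ndarray

    def __post_init__(self):
        self.w_left = np.asarray(self.w_left, dtype=float)
        self.w_right = np.asarray(self.w_right, dtype=float)
        if self.w_left.shape != self.w_right.shape:
            raise StructuralError("membership sequences differ in length")


@dataclass
class DecomposedSignals:
    """The six left/right acceleration components used as model inputs."""

    channels: Dict[str, np.ndarray] = field(default_factory=dict)

    CHANNEL_NAMES = ("ax_left", "ax_right", "ay_left", "ay_right",
                     "az_left", "az_right")

    def __post_init__(self):
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise StructuralError("decomposed channels differ in length")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def names(self) -> List[str]:
        return list(self.channels)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.channels)


@dataclass
class CriticalPoints:
    """Stance-curve landmarks: first peak (VP1), trough (TR), second peak (VP2)."""

    vp1_value: float
    vp2_value: float
    tr_value: float
    vp1_index: int
    vp2_index: int
    tr_index: int


def detect_gait_events(grf_left, grf_right, threshold: float = 10.0,
                       sampling_rate: float = 128.0,
                       min_run_duration: float = MIN_RUN_DURATION) -> GaitEvents:
    """Detect IC/FC events from bilateral vGRF with a force threshold.

    IC is the first sample of a maximal run with force >= threshold; FC is
    the first sample after the run, i.e. stance is ``[IC, FC)``.  Runs of
    stance or swing shorter than ``min_run_duration`` seconds are treated
    as sensor chatter: short swing gaps are bridged, then short stance
    blips are dropped.
    """
    if threshold < 0:
        raise ParameterError("threshold must be nonnegative")
    grf_left = np.asarray(grf_left, dtype=float)
    grf_right = np.asarray(grf_right, dtype=float)
    if grf_left.shape != grf_right.shape:
        raise StructuralError("grf_left and grf_right differ in length")
    if np.any(grf_left < 0) or np.any(grf_right < 0):
        raise DomainError("vGRF must be nonnegative")

    guard = int(round(min_run_duration * sampling_rate))
    out = {}
    for side, grf in (("left", grf_left), ("right", grf_right)):
        on = grf >= threshold
        ic, fc = _runs_from_mask(on, guard)
        out[f"ic_{side}"], out[f"fc_{side}"] = ic, fc
    return GaitEvents(**out)


def _runs_from_mask(on: np.ndarray, guard: int) -> Tuple[np.ndarray, np.ndarray]:
    """Maximal True runs of ``on`` after debouncing, as (starts, stops)."""
    starts, stops = _mask_edges(on)
    # bridge swing gaps shorter than the guard (interior gaps only)
    for i in range(len(starts) - 1):
        if starts[i + 1] - stops[i] < guard:
            stops[i] = -1  # mark merged
    keep = stops != -1
    merged_starts, merged_stops = [], []
    cur_start = None
    for s, e, k in zip(starts, stops, keep):
        if cur_start is None:
            cur_start = s
        if k:
            merged_starts.append(cur_start)
            merged_stops.append(e)
            cur_start = None
    # drop stance blips shorter than the guard
    ic, fc = [], []
    for s, e in zip(merged_starts, merged_stops):
        if e - s >= guard:
            ic.append(s)
            fc.append(e)
    return np.asarray(ic, dtype=int), np.asarray(fc, dtype=int)


def _mask_edges(on: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    padded = np.concatenate(([False], on, [False]))
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def exact_membership(grf_left, grf_right) -> MembershipPair:
    """Force-ratio membership: w_left = GRF_left / (GRF_left + GRF_right).

    Where both forces are zero the ratio is undefined; those samples carry
    the last defined value forward (0.5 before any defined sample).
    """
    grf_left = np.asarray(grf_left, dtype=float)
    grf_right = np.asarray(grf_right, dtype=float)
    if grf_left.shape != grf_right.shape:
        raise StructuralError("grf_left and grf_right differ in length")
    if np.any(grf_left < 0) or np.any(grf_right < 0):
        raise DomainError("vGRF must be nonnegative")
    total = grf_left + grf_right
    defined = total > 0
    w_left = np.full(len(total), 0.5)
    w_left[defined] = grf_left[defined] / total[defined]
    w_left = _carry_forward(w_left, defined, fill=0.5)
    return MembershipPair(w_left=w_left, w_right=1.0 - w_left)


def _carry_forward(values: np.ndarray, defined: np.ndarray, fill: float) -> np.ndarray:
    if defined.all():
        return values
    idx = np.where(defined, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    out = np.where(idx >= 0, values[np.maximum(idx, 0)], fill)
    return out


def event_membership(events: GaitEvents, n_samples: int) -> MembershipPair:
    """Event-based approximation of the force-ratio membership.

    w_left is 1 in left single support, 0 in left swing, and ramps
    linearly from 1 at the contralateral IC down to 0 at the ipsilateral
    FC (and symmetrically back up) across each double-support interval.
    w_right is the complement, so the pair always sums to 1.

    Samples where neither foot is in stance are permitted only at the
    recording boundaries (before the first and after the last event),
    where the nearest defined value is extended; an interior flight
    phase raises :class:`UnsupportedGaitError`.
    """
    stance_l = events.stance_mask("left", n_samples)
    stance_r = events.stance_mask("right", n_samples)
    neither = ~stance_l & ~stance_r
    if neither.any():
        starts, stops = _mask_edges(neither)
        for s, e in zip(starts, stops):
            if s != 0 and e != n_samples:
                raise UnsupportedGaitError(
                    f"both feet airborne over [{s}, {e}); walking data expected")

    w_left = np.where(stance_l & ~stance_r, 1.0, 0.0)
    # ramps: down across [right IC, left FC), up across [left IC, right FC)
    _apply_ramps(w_left, events, n_samples, down=True)
    _apply_ramps(w_left, events, n_samples, down=False)
    # boundary fill where neither foot has a detected stance
    defined = stance_l | stance_r
    if not defined.all():
        w_left = _carry_forward(w_left, defined, fill=np.nan)
        # leading undefined block: copy first defined value backwards
        first = np.argmax(defined)
        w_left[:first] = w_left[first]
    return MembershipPair(w_left=w_left, w_right=1.0 - w_left)


def _apply_ramps(w_left: np.ndarray, events: GaitEvents, n_samples: int,
                 down: bool) -> None:
    """Write the double-support linear ramps of w_left in place.

    A ramp spans [IC of the arriving foot, FC of the standing foot) and is
    applied only when the arriving foot's stance outlasts the standing
    foot's — otherwise (e.g. a stance truncated at a recording boundary)
    the overlap is the tail of the opposite double support.
    """
    if down:   # right arrives during a left stance: w_left 1 -> 0 at left FC
        arriving = zip(events.ic("right"), events.fc("right"))
        stances = list(zip(events.ic("left"), events.fc("left")))
    else:      # left arrives during a right stance: w_left 0 -> 1 at right FC
        arriving = zip(events.ic("left"), events.fc("left"))
        stances = list(zip(events.ic("right"), events.fc("right")))
    for ic, fc in arriving:
        for a, b in stances:
            if a <= ic < b and fc > b:
                span = b - ic
                ks = np.arange(ic, min(b, n_samples))
                frac = (ks - ic) / span
                w_left[ks] = (1.0 - frac) if down else frac
                break


def decompose_acceleration(recording, membership: MembershipPair) -> DecomposedSignals:
    """Split each acceleration axis into left/right components.

    a_left = a * w_left and a_right = a * w_right, point-wise, so the two
    components always reconstruct the original signal exactly.
    """
    n = recording.n_samples
    if len(membership.w_left) != n:
        raise StructuralError(
            f"membership length {len(membership.w_left)} != recording length {n}")
    channels = {}
    for axis in ("ax", "ay", "az"):
        a = getattr(recording, axis)
        channels[f"{axis}_left"] = a * membership.w_left
        channels[f"{axis}_right"] = a * membership.w_right
    return DecomposedSignals(channels=channels)


def segment_cycles(events: GaitEvents, foot: str) -> List[Tuple[int, int]]:
    """Half-open gait-cycle ranges [IC_i, IC_{i+1}) for one foot."""
    ics = events.ic(foot)
    return [(int(a), int(b)) for a, b in zip(ics[:-1], ics[1:])]


def extract_critical_points(cycle_grf) -> CriticalPoints:
    """Locate VP1 (first stance peak), TR (trough), VP2 (second peak).

    VP1 is the first interior local maximum, VP2 the last, and TR the
    minimum strictly between them; ties break toward the earlier index.
    A stance with fewer than two local maxima raises
    :class:`DegenerateShapeError` carrying the single extremum found.
    """
    y = np.asarray(cycle_grf, dtype=float)
    if len(y) < 3:
        raise DegenerateShapeError("cycle too short for extremum analysis")
    interior = np.arange(1, len(y) - 1)
    is_max = (y[interior] >= y[interior - 1]) & (y[interior] > y[interior + 1])
    maxima = interior[is_max]
    if len(maxima) < 2:
        ext = None
        if len(maxima) == 1:
            ext = (float(y[maxima[0]]), int(maxima[0]))
        raise DegenerateShapeError(
            f"expected M-shaped stance with two peaks, found {len(maxima)}",
            extremum=ext)
    vp1_idx, vp2_idx = int(maxima[0]), int(maxima[-1])
    between = y[vp1_idx:vp2_idx + 1]
    tr_off = int(np.argmin(between))
    tr_idx = vp1_idx + tr_off
    return CriticalPoints(
        vp1_value=float(y[vp1_idx]), vp2_value=float(y[vp2_idx]),
        tr_value=float(y[tr_idx]), vp1_index=vp1_idx, vp2_index=vp2_idx,
        tr_index=tr_idx)


def phase_masks(events: GaitEvents, n_samples: int) -> Dict[str, np.ndarray]:
    """Boolean masks for single support (per foot), double support, swing.

    The three support masks partition total stance time:
    single_left = left stance and right swing, single_right symmetric,
    double = both feet in stance.  ``swing_left``/``swing_right`` mark each
    foot airborne.
    """
    stance_l = events.stance_mask("left", n_samples)
    stance_r = events.stance_mask("right", n_samples)
    return {
        "single_left": stance_l & ~stance_r,
        "single_right": stance_r & ~stance_l,
        "double": stance_l & stance_r,
        "swing_left": ~stance_l,
        "swing_right": ~stance_r,
    }
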