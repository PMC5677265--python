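"""Seeded synthetic gait data with the statistical structure the proxy
method assumes.

Two generation modes are provided:

* **biomechanical mode** — bilateral M-shaped stance vGRF profiles (two
  vertical peaks VP1/VP2 bracketing a trough TR), alternating feet with a
  double-support overlap, stride-to-stride timing and amplitude jitter,
  and trunk-style acceleration channels coupled to the total force through
  a fixed anticipatory kernel, so that a degree-2 polynomial moving-average
  model over a short lag window can recover the force from acceleration
  history.  This is the end-to-end plausibility workload.

* **oracle mode** — six decomposed input channels generated directly as
  gated noise, with the vGRF outputs computed *exactly* from a known
  polynomial model.  This is the ground truth for structure/parameter
  recovery tests: the selection algorithm should find exactly the
  generating terms.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .dictionary import Monomial
from .errors import InsufficientDataError, ParameterError
from .gait import DecomposedSignals, GaitEvents, event_membership
from .recording import TimeSeriesRecording

#: standard gravity, m/s^2 — baseline of the vertical acceleration channel
GRAVITY = 9.81

#: scale (m/s^2) of the trunk-acceleration fluctuation per unit of relative
#: total-force deviation; typical trunk vertical accelerations in walking
#: are a few m/s^2 for force excursions of a few tenths of body weight
ACCEL_COUPLING = 3.0

#: fixed anticipatory coupling kernel: ax(k) = ACCEL_COUPLING * sum_j
#: KERNEL[j] * dev(k + LEADS[j]) with dev the relative total-force
#: fluctuation.  The kernel is minimum phase (inverse impulse response
#: decays like 0.5^j), so the force is causally recoverable from a short
#: window of past accelerations — the delays the lag analysis should find.
COUPLING_KERNEL = (0.6, 0.25, 0.15)
COUPLING_LEADS = (2, 1, 0)


@dataclass
class GaitTemplateParams:
    """Parameters of the bilateral stance-force template.

    Defaults describe typical adult self-paced walking: 1.1 s gait cycle,
    62% stance, 10% double support, 700 N body weight with loading and
    push-off peaks at 1.10 and 1.05 body weight and a mid-stance trough at
    0.75 body weight.
    """

    cycle_duration: float = 1.1           # s
    stance_fraction: float = 0.62         # of the cycle
    double_support_fraction: float = 0.10  # of the cycle
    body_weight: float = 700.0            # N
    peak1_amp: float = 770.0              # N, loading-response peak (VP1)
    peak2_amp: float = 735.0              # N, push-off peak (VP2)
    trough_amp: float = 525.0             # N, mid-stance trough (TR)
    timing_jitter_sd: float = 0.0         # s, stride-to-stride event jitter
    amplitude_jitter_sd: float = 0.0      # relative fraction on peak/trough
    noise_sd: float = 0.0                 # m/s^2, white noise on acceleration

    def __post_init__(self):
        if not (0 < self.double_support_fraction < self.stance_fraction < 1):
            raise ParameterError(
                "need 0 < double_support_fraction < stance_fraction < 1")
        # both double-support intervals implied by the timing must be positive
        if 2 * self.stance_fraction - self.double_support_fraction - 1 <= 0:
            raise ParameterError(
                "timing implies a flight phase: require "
                "2*stance_fraction - double_support_fraction > 1")
        if not (min(self.peak1_amp, self.peak2_amp) > self.trough_amp > 0):
            raise ParameterError("need peak amplitudes > trough_amp > 0")
        if self.cycle_duration <= 0 or self.body_weight <= 0:
            raise ParameterError("cycle_duration and body_weight must be positive")
        for name in ("timing_jitter_sd", "amplitude_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")


#: force (N) at the first and last stance sample: the template jumps from 0
#: to this value at heel strike and back at toe-off, as real contact forces
#: rise abruptly; kept above the 10 N event threshold so threshold-detected
#: events coincide with the true contact samples
STANCE_EDGE_FORCE = 20.0


def _stance_template(n: int, p1: float, tr: float, p2: float) -> np.ndarray:
    """M-shaped stance profile on n samples.

    Piecewise raised-cosine segments rise from the heel-strike edge force
    to the first peak at 25% of stance, blend down to the trough at 50%,
    up to the second peak at 75%, and back toward the edge force at
    toe-off.  The curve is C1 at the junctions and attains exactly
    (p1, tr, p2) at the three landmarks.
    """
    off = min(STANCE_EDGE_FORCE, 0.5 * tr)
    s = np.arange(n) / n
    y = np.empty(n)
    q1, q2, q3 = s < 0.25, (s >= 0.25) & (s < 0.5), (s >= 0.5) & (s < 0.75)
    q4 = s >= 0.75
    y[q1] = off + (p1 - off) * (1 - np.cos(np.pi * s[q1] / 0.25)) / 2
    y[q2] = tr + (p1 - tr) * (1 + np.cos(np.pi * (s[q2] - 0.25) / 0.25)) / 2
    y[q3] = tr + (p2 - tr) * (1 - np.cos(np.pi * (s[q3] - 0.5) / 0.25)) / 2
    y[q4] = off + (p2 - off) * (1 + np.cos(np.pi * (s[q4] - 0.75) / 0.25)) / 2
    return y


def generate_vgrf_profiles(params: GaitTemplateParams, n_cycles: int, seed: int,
                           sampling_rate: float = 128.0
                           ) -> Tuple[np.ndarray, np.ndarray, GaitEvents]:
    """Bilateral stance vGRF sequences plus the true gait events.

    The left foot strikes at multiples of the cycle duration; the right
    foot is offset by (stance - double_support) of a cycle so the leading
    double support lasts exactly the configured fraction.  Stances whose
    final contact would fall beyond the recording are omitted.  The vGRF is
    zero throughout swing and nonnegative everywhere.
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    T = params.cycle_duration
    n_samples = int(round(n_cycles * T * fs))
    stance_len = int(round(params.stance_fraction * T * fs))
    offset = (params.stance_fraction - params.double_support_fraction) * T

    out = {}
    events = {}
    for side, t0 in (("left", 0.0), ("right", offset)):
        grf = np.zeros(n_samples)
        ics, fcs = [], []
        for i in range(n_cycles):
            t_ic = max(i * T + t0 + rng.normal(0, params.timing_jitter_sd), 0.0)
            ic = int(round(t_ic * fs))
            length = stance_len + int(round(rng.normal(0, params.timing_jitter_sd) * fs))
            fc = ic + max(length, 4)
            if fc > n_samples or ic < 0:
                continue
            jit = 1.0 + rng.normal(0, params.amplitude_jitter_sd, size=3)
            p1 = params.peak1_amp * jit[0]
            p2 = params.peak2_amp * jit[1]
            tr = min(params.trough_amp * jit[2], 0.95 * min(p1, p2))
            grf[ic:fc] = _stance_template(fc - ic, p1, tr, p2)
            ics.append(ic)
            fcs.append(fc)
        out[side] = grf
        events[side] = (ics, fcs)
    true_events = GaitEvents(ic_left=events["left"][0], fc_left=events["left"][1],
                             ic_right=events["right"][0], fc_right=events["right"][1])
    return out["left"], out["right"], true_events


def _advance(x: np.ndarray, j: int) -> np.ndarray:
    """x shifted forward by j samples (x[k] -> x[k+j]); end padded with last value."""
    if j == 0:
        return x
    out = np.empty_like(x)
    out[:-j] = x[j:]
    out[-j:] = x[-1]
    return out


def generate_biomech_recording(params: GaitTemplateParams, n_cycles: int,
                               seed: int, sampling_rate: float = 128.0
                               ) -> TimeSeriesRecording:
    """Synthetic recording with acceleration channels coupled to the vGRF.

    The vertical-ish channel ``ax`` carries the force information: with
    dev(k) the relative fluctuation of the total force about body weight,

        ax(k) = ACCEL_COUPLING * (0.6 dev(k+2) + 0.25 dev(k+1) + 0.15 dev(k)),

    i.e. the acceleration *leads* the force by about two samples, so the
    force at k is recoverable from accelerations at lags >= 2 — mirroring
    the short accelerometer-to-force delays the method exploits.  ``az``
    is gravity plus a small seeded stride harmonic (its decomposed halves
    carry the stance-weighting information) and ``ay`` is a seeded
    step-frequency harmonic carrying no force information.  White Gaussian
    noise of sd ``params.noise_sd`` is added to each acceleration channel.
    """
    grf_l, grf_r, events = generate_vgrf_profiles(params, n_cycles, seed,
                                                  sampling_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n = len(grf_l)
    t = np.arange(n) / sampling_rate
    dev = (grf_l + grf_r) / params.body_weight - 1.0

    ax = ACCEL_COUPLING * sum(w * _advance(dev, j)
                              for w, j in zip(COUPLING_KERNEL, COUPLING_LEADS))
    stride_hz = 1.0 / params.cycle_duration
    phase_az, phase_ay = rng.uniform(0, 2 * np.pi, size=2)
    az = GRAVITY + 0.2 * np.sin(2 * np.pi * stride_hz * t + phase_az)
    ay = 0.5 * np.sin(2 * np.pi * 2 * stride_hz * t + phase_ay)
    if params.noise_sd > 0:
        ax = ax + rng.normal(0, params.noise_sd, n)
        ay = ay + rng.normal(0, params.noise_sd, n)
        az = az + rng.normal(0, params.noise_sd, n)
    return TimeSeriesRecording(
        sampling_rate=sampling_rate, ax=ax, ay=ay, az=az,
        grf_left=grf_l, grf_right=grf_r,
        metadata={"generator": "biomech", "seed": int(seed),
                  "n_cycles": int(n_cycles)})


# ---------------------------------------------------------------------------
# Oracle mode

@dataclass
class OracleModelSpec:
    """A known polynomial (degree <= 2) input-only model used as ground truth."""

    terms: List[Monomial]
    coefficients: np.ndarray
    max_lag: int = 18

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.terms) != len(self.coefficients):
            raise ParameterError("terms and coefficients differ in length")
        for term in self.terms:
            if term.degree > 2:
                raise ParameterError(f"monomial degree {term.degree} > 2: {term}")
            if term.max_lag > self.max_lag:
                raise ParameterError(f"term lag exceeds max_lag: {term}")


def generate_oracle_recording(
        spec: Union[OracleModelSpec, Tuple[OracleModelSpec, OracleModelSpec]],
        n_samples: int, seed: int,
        params: Optional[GaitTemplateParams] = None,
        sampling_rate: float = 128.0
) -> Tuple[DecomposedSignals, np.ndarray, np.ndarray]:
    """Decomposed inputs as gated noise; vGRF computed exactly from ``spec``.

    The six channels are independent unit Gaussian sequences multiplied by
    alternating left/right stance gates (the event-based membership of a
    jitter-free gait pattern), which gives them the on/off temporal
    structure of real decomposed signals without the circular dependence
    on the very forces being generated.  ``spec`` may be a single model
    (used for both feet) or a (left, right) pair.  The outputs are exact
    polynomial evaluations — they may be negative; oracle data exists for
    recovery tests, not biomechanical plausibility.
    """
    spec_l, spec_r = spec if isinstance(spec, tuple) else (spec, spec)
    max_lag = max(spec_l.max_lag, spec_r.max_lag)
    if n_samples <= max_lag + 10:
        raise InsufficientDataError("need n_samples > max_lag + 10")
    params = params or GaitTemplateParams()
    rng = np.random.default_rng(seed)

    # jitter-free gait pattern for the gates
    n_cycles = max(int(np.ceil(n_samples / (params.cycle_duration * sampling_rate))),
                   2) + 1
    _, _, events = generate_vgrf_profiles(params, n_cycles, seed=0,
                                          sampling_rate=sampling_rate)
    membership = event_membership(events, max(n_samples, int(round(
        n_cycles * params.cycle_duration * sampling_rate))))
    gate = {"left": membership.w_left[:n_samples],
            "right": membership.w_right[:n_samples]}

    channels = {}
    for axis in ("ax", "ay", "az"):
        for side in ("left", "right"):
            channels[f"{axis}_{side}"] = rng.standard_normal(n_samples) * gate[side]
    signals = DecomposedSignals(channels=channels)

    def evaluate(s: OracleModelSpec) -> np.ndarray:
        out = np.zeros(n_samples)
        if s.terms:
            acc = np.zeros(n_samples - max_lag)
            for term, c in zip(s.terms, s.coefficients):
                acc += c * term.evaluate(signals, max_lag)
            out[max_lag:] = acc
        return out

    return signals, evaluate(spec_l), evaluate(spec_r)


def noise_sd_for_fraction(params: GaitTemplateParams, n_cycles: int, seed: int,
                          fraction: float, sampling_rate: float = 128.0) -> float:
    """Acceleration noise sd equal to ``fraction`` of the noiseless ``ax``
    fluctuation (standard deviation about its mean).

    Used to pose conditions like "5% additive noise" in channel units.
    """
    clean = GaitTemplateParams(**{**params.__dict__, "noise_sd": 0.0})
    rec = generate_biomech_recording(clean, n_cycles, seed, sampling_rate)
    return float(fraction * np.std(rec.ax - rec.ax.mean()))
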