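# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `gaitproxy`, at the level of detail a maintainer or
reviewer needs to judge what the package's tests do and do not show.

## Model and assumptions

The estimand is the vertical ground reaction force of each foot during
walking, reconstructed from the three acceleration channels of one
trunk-mounted sensor sampled at a common rate (default 128 Hz). The model
class is the input-only subclass of polynomial dynamic models (nonlinear
moving average / discrete Volterra): the output at sample `k` is a
multivariate polynomial of total degree ≤ 2 in the input channels at lags
0..L. Assumptions inherited by everything downstream:

* **Walking only.** At least one foot is always on the ground. Interior
  flight phases raise an error rather than produce silent nonsense.
* **Short input memory.** The dependence of force on acceleration history
  is captured within L = 18 samples (~140 ms at 128 Hz). The
  `max_lag_by_crosscorrelation` analysis is provided to check this on new
  data.
* **Degree-2 sufficiency.** The `nonlinearity_test` diagnostic (squared
  input vs. linear-residual correlation) distinguishes linear from
  nonlinear dependence; degree 2 is the model class boundary, enforced by
  the dictionary builder.
* **Events available at prediction time.** The left/right decomposition
  needs gait events. They are taken from the reference force when
  present, or supplied externally (e.g. from an additional shank/pelvis
  sensor); the package does not detect events from acceleration alone.

## Membership construction

Exact membership is the per-foot share of the total force; where both
forces are zero the ratio is undefined and the last defined value is
carried forward (0.5 before any defined sample). The event-based
approximation is 1 in single support, 0 in swing, linear in between:
value 1 at the contralateral initial contact, reaching 0 at the
ipsilateral final contact, evaluated at integer samples. A double-support
ramp is applied only when the arriving foot's stance outlasts the
standing foot's; this guards against stances truncated at recording
boundaries, where the overlap is the tail of the opposite double support.
All indices are 0-based, stance intervals are half-open `[IC, FC)`.

Event detection uses a force threshold (default 10 N): IC is the first
sample of a maximal run at or above threshold, FC the first sample below
it. Runs shorter than 0.1 s (stance or swing) are treated as sensor
chatter and bridged/dropped; the guard can be disabled for toy traces.

## Structure selection

`_frols` implements forward regression with orthogonal least squares:
all remaining candidates are deflated against each newly selected
orthogonal column (modified Gram–Schmidt, running norm/inner-product
updates), candidates are ranked by error reduction ratio, and ties break
toward the lowest column index. Coefficients are recovered by
back-substitution through the unit upper-triangular Gram–Schmidt factor
and therefore agree with a direct least-squares fit on the selected
support to near machine precision (asserted in tests at 1e-8 relative).

A candidate is skipped as degenerate when its post-orthogonalization
energy falls below 1e-14 of its original energy. This threshold is the
practical roundoff floor: with incremental float64 updates an exactly
dependent column retains ~1e-16 of its energy as noise, so a tighter
criterion would fail to flag exact duplicates.

Stopping rules: a fixed model size (default 64 terms, the model size used
at full scale), an explained-energy threshold on `1 − ΣERR`, or a
BIC-like penalized criterion. The fixed size is the default because the
alternatives' tuning constants are themselves arbitrary; all three are
exposed.

**Iterative refinement.** The iOFR variant implemented here re-runs the
forward search once per term of the current model with that term forced
in first, accepts the restart with the smallest residual sum of squares
at equal model size if strictly better, and repeats to convergence (or a
sweep cap). Published descriptions of iterated forward selection differ
in scheduling details; this restart-with-best-acceptance form was chosen
because it is simple, monotone in RSS by construction, and demonstrably
escapes greedy traps (the test suite constructs decoy-column instances
where plain greedy selection provably cannot reach the best 3-term
subset and checks that the refinement does).

Two models are fitted independently, one per foot, against the same
six-channel dictionary.

## Synthetic data generator

The generator produces the study conditions for all end-to-end tests.

* **Stance template.** Two raised-cosine peaks at 25 % and 75 % of stance
  and a cosine-blended trough at 50 %, C1 at the junctions, attaining
  exactly the configured (VP1, TR, VP2) amplitudes at the landmarks. The
  curve starts and ends at a 20 N edge force (real contact forces rise
  abruptly at heel strike); the edge value sits above the 10 N event
  threshold so threshold-detected events coincide with the true contact
  samples.
* **Timing.** Defaults: 1.1 s cycle, 62 % stance, 10 % double support,
  700 N body weight, peaks 770/735 N, trough 525 N — typical adult
  self-paced walking. The right foot is offset by
  (stance − double-support) of a cycle, which makes the leading double
  support exactly the configured fraction; the trailing double support is
  then (2·stance − double-support − 1) of a cycle (14 % vs 10 % at the
  defaults). Stride-to-stride Gaussian jitter perturbs event times and
  the three landmark amplitudes.
* **Acceleration coupling.** With `dev(k)` the relative fluctuation of
  total force about body weight, the force-carrying channel is
  `ax(k) = 3.0 · (0.6·dev(k+2) + 0.25·dev(k+1) + 0.15·dev(k))` m/s².
  The kernel is fixed (never fitted) and minimum-phase, so the force is
  causally recoverable from a short window of *past* accelerations —
  the inverse impulse response decays like 0.5^j, well inside the lag-18,
  degree-2 model class. `az` is gravity plus a small (0.2 m/s²) seeded
  stride harmonic — its decomposed halves carry the stance weighting —
  and `ay` is a 0.5 m/s² step-frequency harmonic carrying no force
  information. White Gaussian noise of configurable SD is added per
  acceleration channel; "5 % noise" conditions set the SD to 5 % of the
  noiseless `ax` fluctuation via `noise_sd_for_fraction`.
* **Oracle mode.** The six decomposed inputs are generated directly as
  unit Gaussian noise gated by the alternating stance pattern, and the
  outputs are exact evaluations of a known polynomial model. This
  bypasses the circularity (decomposition needs the forces) and gives
  ground truth for structure-recovery tests.

What the generator does **not** emulate: turning, stairs or terrain;
sensor-orientation drift and soft-tissue artifact; insole measurement
noise and calibration error; asymmetric or pathological gait; any
musculoskeletal dynamics. Passing end-to-end tests therefore show that
the pipeline is correct and that the estimator recovers relationships of
the assumed class at realistic signal scales — not that real outdoor
recordings will reach the same error levels.

## Error analysis

RMSE and relative RMSE follow the standard definitions (rRMSE = RMSE over
the mean of the two signals' peak-to-peak amplitudes, in percent).
Per-cycle reports normalize each cycle by its own peak-to-peak range by
default (`rrmse_mode="per_cycle"`); a whole-segment normalizer is
available (`"global"`). Critical-point errors are the per-cycle absolute
landmark differences normalized like the rRMSE by the cycle's mean
peak-to-peak amplitude; landmark extraction runs on the stance portion of
each cycle only (swing-phase wiggles of a prediction are not force
peaks), with the predicted value at the reference landmark index as a
fallback when the predicted stance is too distorted for extremum
analysis. An alternative reduction — rRMSE across the cycle-indexed
landmark sequences — was rejected because its normalizer (the spread of
peak values across cycles) vanishes for steady gait and makes the metric
explode precisely when the data are cleanest.

The first `max_lag` samples of any evaluation segment have undefined
lagged inputs; predictions there are NaN and cycles touching them are
excluded and counted. Group comparisons use the pooled-variance
(Student) two-sample t-test, two-sided; two zero-variance samples with
equal means report p = 1 by convention.

The linearity diagnostic reports the classic ±1.96/√N band per lag, but
its binary verdict uses a Bonferroni-adjusted band across the L+1 lags:
with 19 lags a per-lag 5 % rule would flag most *correct* linear models,
so the family-wise rate is controlled instead.

## Problem sizes

Full-scale runs (end-to-end benchmark, acceptance script) use 104
synthetic gait cycles (~14,600 samples at 128 Hz), half-split at a cycle
boundary, the full 6,670-term dictionary, and plain greedy selection of
64 terms (32 in the test suite); refinement sweeps are enabled only on
the smaller structure-recovery problems, where their cost (one full
forward search per model term per sweep) is negligible. Oracle-recovery
runs use 500 samples, which is ample for exact recovery at machine
precision on noiseless data. These sizes are the package's chosen
benchmark conditions; accuracy at them is summarized by
`scripts/acceptance.py`.

## Known limitations

* Models are subject-specific by design; nothing here supports pooling
  across subjects beyond refitting.
* The iOFR restart schedule explores only single forced first terms;
  pathological dictionaries can in principle defeat it (one of the
  25 randomized decoy instances in the acceptance script does at some
  seeds).
* Event-based membership is exact only outside double support; the
  double-support approximation error is the dominant noiseless error
  source and is irreducible within this decomposition.
* The CSV reader trusts its header comment for the sampling rate; there
  is no unit inference.
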