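# Methods

## The forecasting problem

Four kinematic channels sampled at a fixed rate — thigh linear acceleration
(Y₁, m/s²), shank linear acceleration (Y₂, m/s²), thigh angular velocity
(X₃, deg/s) and shank angular velocity (X₄, deg/s) — are observed over many
walking strides. Given the last `W_in` samples of all four channels, the
model predicts the next `W_out` samples of all four. At 100 Hz, `W_out = 5`
corresponds to a 50 ms forecast horizon and `W_out = 10` to 100 ms. A stride
is the interval between two successive heel strikes of the same foot.

Generalisation across people is the hard part: the model is trained on all
subjects but one and evaluated on the held-out subject's final stride
(leave-one-subject-out, structural — the last subject index is always the
held-out one).

## Synthetic gait generator

Real motion-capture data for this task are not freely redistributable, so the
`synth` module emulates their statistical structure. Each channel of each
stride is a truncated Fourier series over the stride cycle,

    x_f(φ) = Σ_{k=1}^{K} A_{f,k} · m_{f,k} · sin(k·φ + φ_{f,k} + δ_{f,k}),

with φ ∈ [0, 2π) spanning one stride. Population-level coefficients
(`A_{f,k}`, `φ_{f,k}`) are drawn once per configuration: relative harmonic
amplitudes fall off as 1/k (gait kinematics are dominated by the first few
stride harmonics), scaled per channel by `amplitude_scales`. Inter-subject
structure enters as one multiplicative amplitude factor
`m_{f,k} ~ N(1, σ_subj)` and one additive phase offset
`δ_{f,k} ~ N(0, π·σ_subj)` radians per channel per harmonic per subject —
two interpretable knobs that reproduce the cross-subject generalisation
challenge. Stride timing jitters via per-stride durations
`~ N(μ, σ_dur)` rounded to whole samples, and i.i.d. Gaussian sensor noise is
added per channel.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `sample_rate` | 100 Hz | the rate the target protocol states; configurable because capture systems differ (150 Hz capture hardware is common) |
| `stride_duration_mean` | 1.7 s | 170 samples per stride at 100 Hz, the canonical test-stride length |
| `strides_per_subject` | 533 | 5 training subjects × 533 = 2,665 training strides at full scale |
| `n_subjects` | 6 | five train + one held-out |
| `n_harmonics` | 4 | low-order harmonics approximate segment kinematics well while keeping difficulty controllable |
| `amplitude_scales` | (3, 5, 150, 300) | rough peak magnitudes of treadmill walking at ~5 km/h: a few m/s² of segment acceleration, O(100) deg/s of sagittal angular velocity, shank > thigh |
| `subject_variation_sd` | 0.1 | ~10% amplitude and ~18° phase spread across subjects |
| `stride_duration_sd` | 0.03 s | ±3 samples of stride-timing jitter |
| `noise_sd` | 2% of each scale | broadband sensor/soft-tissue noise |

All randomness flows from one root seed through per-subject seed streams
(`SeedSequence(seed, spawn_key=(1, subject))`), so output is bit-reproducible
and adding a subject never perturbs earlier subjects.

What the generator does **not** emulate: within-stride waveform asymmetries
beyond what 4 harmonics express, gait events (double support, toe-off)
as distinct dynamics, fatigue/drift over a session, correlated (pink)
sensor noise, or any musculoskeletal constraint linking the four channels.
Passing tests on this data therefore show that the pipeline learns and
generalises across subject-level amplitude/phase/timing variation of
band-limited quasi-periodic signals — not that it attains any particular
accuracy on real walking data.

## Preprocessing

* **Low-pass**: 2nd-order Butterworth applied forward and backward
  (`filtfilt`) — 4th-order zero-phase magnitude response, the biomechanics
  convention, so gait-event timing is not shifted. Default cutoff 15 Hz.
  The synthetic generator is band-limited by construction (≤ 4/1.7 ≈ 2.4 Hz),
  so the pipeline leaves filtering off unless asked.
* **z-scores**: population (n) divisor; the n vs n−1 difference is
  negligible at these sample counts and the population convention makes
  `fit∘apply` exactly idempotent. Parameters are fit on the **training
  subjects only** and re-applied to the test subject — a deliberate
  leakage-avoiding choice even where upstream tooling normalises before
  splitting. Exact inverse provided; round-trip is identity to 1e−9.
* **Derivatives**: central differences (one-sided at the ends) for first
  order, second central difference (ends replicated) for second order —
  second-order accurate, stateless, length-preserving.

## Windowing

`n_windows = ⌊(M − W_in − W_out)/W_out⌋ + 1`; window *i* starts at
`i·W_out`. The slide is locked to the output size, so consecutive target
windows tile `[W_in, W_in + n·W_out)` exactly and `stitch_targets` is an
exact inverse. A trailing remainder that cannot fill a full window is
dropped, never padded (padding would fabricate data; the canonical 170/5 and
170/10 geometries divide evenly anyway). Windowing is applied per subject
series only — windows never straddle subject boundaries, whose
discontinuities are artefacts. Indexing is 0-based and half-open everywhere.

## Forecaster

NumPy implementation: forward pass, exact backpropagation through time, and
Adam, verified against numerical differentiation during development.

* **Architecture**: encoder LSTM → final hidden state (the fixed-length
  encoding) → repeat `W_out` times → decoder LSTM returning the full
  sequence → shared per-step linear layer to 4 outputs.
* **Cells**: the production cell is the standard gated LSTM of mainstream
  frameworks — sigmoid gates, configurable cell activation (default ReLU),
  biases present with the forget-gate bias initialised to 1, Glorot-uniform
  weights. The bias-free **peephole** cell (diagonal weights from the memory
  state into all three gates; input/forget gates peek at the previous state,
  the output gate at the updated state) is implemented separately as a
  reference oracle and cross-checked in the tests against an independently
  coded textbook cell. The production model deliberately omits peepholes:
  that is what the mainstream frameworks this architecture is normally built
  in actually execute, and the discrepancy between the equations usually
  cited and the cell usually run is worth preserving explicitly.
* **Training**: MAE loss (its subgradient `sign(err)/n` at zero), Adam with
  lr 1e−3, β₁ 0.9, β₂ 0.999, batches of 100 windows reshuffled each epoch
  from a seeded stream, fixed epoch count, no validation split or early
  stopping by default (a `grad_clip` global-norm option exists, off by
  default). Non-finite loss raises `TrainingDivergedError` with the epoch.
* **Whole-stride forecasting**: the model is primed with `W_in` measured
  samples from the preceding stride and slides across the test stride in
  steps of `W_out`; each input window contains *measured* samples (the
  default, consistent with evaluating over a recorded stride), predictions
  are stitched and de-normalised. A `recursive=True` mode feeds predictions
  back instead, for free-running forecasts; no fidelity claim is attached to
  it.

## Evaluation

MAE, MSE and Pearson CC per channel. MSE is reported in squared units
(m²/s⁴, deg²/s²), the dimensionally consistent choice, even though
performance tables in this literature sometimes print MSE with unsquared
unit labels. "Whole-stride" metrics pool all stitched samples per channel
(matching visual whole-stride comparisons), not per-window averages;
first-window metrics use only the first `W_out` predicted samples. A
constant series makes CC undefined and raises `DegenerateDataError` — a
silent 0 could masquerade as a poor-but-valid score. The input-window sweep
retrains one model per size `{5,…,40}` with the same config seed (differences
between sizes are then architectural, not sampling noise); multi-seed
replication is available by calling it repeatedly with reseeded configs.

## Experiment scale

The full-scale configuration (2,665 training strides, 50 epochs, 100-unit
layers) is the package default. Tests and `scripts/acceptance.py` run a
scaled-down version of the same experiment — 6 subjects × 30 strides, noise
at 0.5% of each amplitude scale, 32-unit encoder/decoder, 20 epochs, five
seeds where medians are asserted — chosen so the whole suite completes in
minutes on one CPU while preserving the experiment's shape (leave-one-
subject-out split, 25-sample priming, 5- and 10-sample horizons). At this
scale the trained model reaches whole-stride CC > 0.97 per channel and
whole-stride MAE grows from horizon 5 to horizon 10, the qualitative
degradation expected as the forecast reaches deeper into the future.

## Known limitations

* The NumPy trainer is single-threaded and CPU-bound; full-scale training is
  minutes-to-hours, not seconds.
* ReLU cell activations can diverge at high learning rates (no saturation);
  the error is explicit and `grad_clip` or `activation="tanh"` are the
  remedies.
* The generator's band-limited harmonics make the forecasting task easier
  than raw double-differentiated displacement (which amplifies
  high-frequency noise); absolute error levels here do not transfer to real
  IMU data.
* Metrics are reported on the de-normalised scale by default; comparisons
  against normalised-scale numbers require applying the z-score parameters.
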