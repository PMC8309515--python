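# Methods

`imukin` studies whether hip and knee sagittal flexion during level-ground
running can be predicted from a single tibia-mounted inertial sensor, using a
small 1D convolutional network trained on treadmill running, and whether the
gyroscope or the accelerometer is the better regressor for that
treadmill-to-overground transfer. Because the human recordings such a study
rests on are not publicly available, the package pairs the analysis pipeline
with a synthetic gait generator that reproduces the statistical structure the
analysis assumes; every result the package reports is computed on simulated
cohorts.

## The regression model

The network maps a 0.6 s window of one regressor channel, sampled at 100 Hz
(60 samples), to the joint angle at the window's center sample:

    Input (60, 1)
    Conv1D 50 filters, kernel 3, stride 1, no padding  -> (58, 50)
    Conv1D 50                                          -> (56, 50)
    MaxPool 2                                          -> (28, 50)
    Conv1D 100                                         -> (26, 100)
    Conv1D 100                                         -> (24, 100)
    Flatten                                            -> 2400
    Dense 100 (ReLU)  ->  Dense 1 (linear)

All hidden activations are ReLU, weights are Glorot-normal initialized, the
loss is mean squared error, and the optimizer is Adam (learning rate 0.001,
batch size 512, 50 epochs, epsilon 1e-7). There is no validation split or
early stopping: the epoch count is fixed, and one independent model is fitted
per (joint × channel × evaluation fold). Targets are kept separate per joint
rather than learned jointly; nothing beyond the gyroscope's fixed /100
rescale standardizes inputs or outputs.

The network is implemented directly on NumPy (im2col convolutions, float32)
rather than through a deep-learning framework. For a model this small that
costs little speed and buys exact reproducibility: training is
bit-deterministic given a seed on a fixed BLAS. A finite-difference check in
the test suite validates the backpropagation against central differences in
float64.

## Regressors and signal preparation

Two univariate regressors are compared, chosen to be robust to sensor
orientation: the accelerometer's tibia-aligned y component, used as-is, and
the gyroscope's sagittal resultant sqrt(gx² + gz²), divided by 100 to bring
hundreds of deg/s into the accelerometer's numerical range so the same
fixed-epoch recipe converges for both.

Preparation steps, in order:

1. **Synchronization.** Both systems record three stomps in a quiet
   preamble. The offset between the sensor clock and the kinematics clock is
   the mean difference of the detected pulse-centroid triplets; pulses are
   detected as sustained robust outlier runs (6×MAD threshold, runs merged
   across gaps < 0.1 s, single-sample exceedances discarded) within the first
   10 s. Recovery is accurate to well under one 100 Hz sample.
2. **Resampling.** Sensor channels (500 Hz) are zero-phase low-passed
   (4th-order Butterworth, 40 Hz cutoff — far above gait content, so no
   phase or amplitude distortion of the signal band) and decimated 5:1, then
   interpolated onto the kinematics timestamps shifted by the recovered
   offset.
3. **Segmentation.** Each 3 min session drops 15 s head and tail buffers;
   the steady-state remainder splits into 60/60/30 s segments and the first
   60 s segment is used (training for the four treadmill speeds, testing for
   level ground). The plan is a parameter, so scaled-down runs shrink
   sessions without touching the defaults.
4. **Framing.** Windows of 60 samples advance by 1 sample (N = L − 59
   frames per segment); the target is the angle at the window's 31st sample
   (the center, samples [i, i+60) → target i+30). Frames are built per
   segment and then pooled in ascending speed order, so no window straddles a
   splice between speeds or participants.

## Evaluation

Six statistics compare an actual level-ground trace y with its prediction ŷ:

- **R²** = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)², over all points;
- **ROM** = max y − min y, from the actual trace only (normalization should
  not depend on model output);
- **RMSE** and **STD** of residuals at gait-event peaks — the knee's small
  stance-phase flexion peak and the hip's per-cycle flexion maximum — with
  STD using the sample convention (ddof = 1) given the small event counts;
- **NRMSE** and **NSTD**, the former two as percentages of ROM.

Peak events are found with the same detector on both traces: per-cycle major
maxima locate the gait cycles (autocorrelation estimates the stride period;
major peaks must clear the trace midline at 0.6 stride spacing), and for the
knee the stance event is the most prominent interior maximum strictly between
consecutive swing peaks. Actual and predicted events pair greedily by nearest
time within ±0.25 s — about a third of a running stride, so cross-cycle
mismatches are excluded — and each event is used at most once. A prediction
too poor to exhibit gait events yields zero pairs; the report then carries
NaN peak statistics and is flagged rather than aborting the study. NSTD
mirrors NRMSE (peak residual STD over ROM); the alternative all-points
reading of its prose definition is internally inconsistent with the residual
formula it accompanies, and the peak-based reading is used throughout.

Two schemes are run: intraparticipant (train on a participant's four
treadmill segments, 4 min of data; test on their level-ground segment) and
interparticipant leave-one-out (train on the pooled treadmill frames of all
other participants, ordered by participant index; test on the held-out
participant's level-ground segment — n folds for n participants). Channel
comparisons are two-tailed paired t-tests per (scheme, joint, parameter)
across participants, significant at p < 0.05, with mean R² labelled on the
Schober scale (bins at 0.10/0.40/0.70/0.90, implemented as half-open
intervals so every magnitude in [0, 1] gets a label).

## The synthetic cohort

Each participant is a profile of gait morphology and sensor coupling drawn
once from physiological ranges: knee minimum 8–15°, stance peak 38–48°, swing
peak 95–115° (ROM ≈ 85–105°), hip −25–−15° to 35–45° (ROM ≈ 55–70°), cadence
78–88 strides/min at 2.5 m/s rising linearly with speed (3–5 strides/min per
m/s), stride-period jitter CV 1–3%, and per-channel sensor noise. The knee
curve is two well-separated Gaussian bumps per stride (stance then swing);
the hip is a raised cosine peaking in late swing. Per-stride amplitude
variability is deliberately larger for the hip (CV 6%) than the knee (2%),
encoding the field observation that knee trajectories are the more consistent
and hence more predictable — this is what makes simulated knee R² exceed hip
R².

IMU channels are deterministic functionals of the knee curve: gyroscope
components are proportional to its angular velocity (so the x–z resultant is
|dθ/dt| times a per-participant gain near 1), and accelerometer components to
its angular acceleration plus a constant gravity projection of 9.6 m/s² on
the tibia-aligned y axis, plus white Gaussian noise. The protocol simulated
per participant: four 3 min treadmill sessions at 2.0/2.5/3.0/3.5 m/s and one
3 min level-ground session at a preferred speed drawn from N(2.44, 0.34) m/s
truncated to (1.5, 3.5).

Surface compliance is the study's key manipulation: on the treadmill the
*dynamic* accelerometer content is multiplied by 0.85 and a small
belt-vibration noise floor (0.2 m/s²) is added, while gyroscope content is
untouched. No quantitative characterization of this attenuation exists, so
the factor is a free simulation parameter; 0.85 was chosen so the
accelerometer remains a clearly usable regressor (held-out R² well above the
"strong" threshold) yet measurably behind the gyroscope after the
treadmill-to-overground transfer — the qualitative pattern the analysis is
designed to detect. At much stronger attenuation the accelerometer's transfer
collapses entirely, which mismatches how real accelerometer models behave.

Each session opens with an 8 s quiet-standing preamble containing three
synchronization stomps (40 ms rectangular pulses at 2.0/3.5/5.0 s, amplitude
5× the dynamic signal RMS on accel-y and 15° on the knee trace), counted
inside the session duration so the sample-count arithmetic stays exact; in
the full protocol the preamble falls inside the discarded 15 s head buffer.
The sensor clock lags the kinematics clock by a uniform random offset in
[0, 0.5] s, which the synchronizer must recover.

**What the simulator does not emulate:** soft-tissue artifact, sensor
orientation drift, magnetometer disturbance, foot-strike impact transients,
asymmetry, fatigue drift, and any hip dynamics not phase-locked to the knee.
Passing tests therefore demonstrate that the pipeline recovers the structure
it assumes — not that the trained network would reach the same accuracy on
real recordings.

## Problem sizes and numerical choices

Training-based tests and the acceptance script run a scaled-down
configuration chosen as the smallest that still exercises the full protocol
structure: 4 participants, 30 s sessions (10 s head buffer covering the
preamble, one 16 s analysis segment, 4 s tail) — about 6 200 training frames
intraparticipant and 18 500 per leave-one-out fold. The channel comparison
(gyro vs. accel) runs at 5 epochs per model, where its margin is already
stable across master seeds.

Comparing the two *schemes* at a scaled-down epoch count needs one extra
control: a leave-one-out fold sees (n−1)× the frames per epoch, so at equal
epochs the inter models receive several times more optimizer steps and the
comparison measures training length, not scheme. In the full protocol this
does not arise — 50 epochs put both schemes at their plateau. The scaled-down
scheme comparison therefore trains both schemes to near-plateau under a
matched optimizer-step budget (intra 12 epochs vs. inter 4 epochs for n = 4,
via `StudyConfig.inter_epochs`), where the within-participant advantage —
models exploiting a person's idiosyncratic sensor coupling and cadence — is
cleanly visible. The full-protocol defaults (10 participants, 3 min sessions,
50 epochs for both schemes) remain available through `StudyConfig()` and the
CLI.

Other numerical choices: a single master seed fans out independent
`SeedSequence`-derived seeds per participant, session and model fold, so any
cell can be re-run in isolation; the partial final mini-batch is trained on;
degenerate inputs fail loudly (constant actual trace → undefined R², zero ROM
→ undefined normalization, zero-variance paired differences → degenerate
test) except for the flagged zero-matched-peaks case above. Peak locations
are found on a lightly smoothed copy (Savitzky–Golay, window 7, order 2) but
values are read from the raw trace at the located sample.

## Known limitations

- The simulator's accel/gyro contrast is put in by construction (surface
  attenuation of dynamic acceleration); the package can show the pipeline
  *detects* such a contrast, not that real treadmills produce one.
- Training at full scale (50 epochs × 23 941 frames × 40 models) is a
  multi-hour CPU run; the shipped configurations are sized for minutes.
- The NumPy network trains on a single CPU thread; no GPU path exists.
- Hip predictions lean entirely on phase coupling to the knee-driven
  regressor; real hip kinematics carry independent degrees of freedom the
  single-channel regressor cannot see.
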