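# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `etorque`, in the order the pipeline uses them.

## Inverse-dynamics torque labels and the sign convention

The label oracle models the forearm+hand as a single rigid segment rotating
about the elbow at lever arm `l₃ + r₂` (forearm length plus elbow-cylinder
radius):

    T = m·(l₃+r₂)²·β″ − m·g·(l₃+r₂)·sin β

`lagrange_torque` implements this formula verbatim for whatever bending
angle β it is given.  The package's convention is that the *attitude-sensor*
bending angle is the negative of the anatomical flexion angle, so the
pipeline evaluates the formula at β = −flexion, giving

    T = m·g·l·sin(flexion) − m·l²·flexion″

This makes the torque demanded from the flexors positive — holding a flexed
posture against gravity requires positive torque, and the mean torque over
a flexion–extension cycle is positive (≈ 2.7 N·m for the default subject),
consistent with the positive mean actual torques reported for this kind of
protocol.  `biomech.required_active_torque` packages the convention.

The default subject is the mean of a seven-subject able-bodied cohort:
body mass 66.5 kg, upper arm 30.9 cm, forearm 26.45 cm, hand 18.7 cm.  The
moved mass defaults to the standard anthropometric forearm+hand fraction,
m = 0.022 × body mass ≈ 1.46 kg, and r₂ defaults to 3.5 cm; both are
configuration values.  g is fixed at 9.8 m/s².

## Hill-model cross-check

The Hill pathway computes only the active contractile force — the assist
controller needs the wearer's *active* torque, so the parallel elastic term
defaults to zero (a flag restores it).  Activation uses the static
exponential nonlinearity a(u) = (e^{Au}−1)/(e^{A}−1) with shape factor
A ∈ [−5, 0); the default A = −2 is a mid-range choice since no value is
standard.  Force–length is the Gaussian exp(−(l̄−1)²/0.45), force–velocity
falls from 1 (isometric) to 0 at 10 optimal lengths/s shortening and
plateaus at 1.4·F₀ eccentrically — standard Thelen-style constants, all
exposed as arguments.  Fiber kinematics follow a rigid-tendon geometry:
musculotendon length changes linearly with joint angle at a constant moment
arm (biceps 30 mm, brachioradialis 25 mm, triceps 21 mm — generic
adult-scale configuration values, not subject claims), referenced so fibers
sit at optimum at 60° flexion.  The Hill torque is *not* used for training;
tests only require that it rises and falls together with the Lagrangian
demand on the same trial (correlation > 0.8), which is what a
physiologically sensible active-torque trace must do.

## Synthetic data generator

The generator emulates the facts known about this recording setup — EMG
amplitudes of 0.1–5 mV with dominant spectral content between 50 and 150 Hz,
50 Hz mains contamination, elbow cycles spanning 0–120°, EMG sampled at
1200 Hz and angles at 100 Hz — under a deliberately simple model:

* **Trajectory**: raised cosine per cycle, default period 4 s (the movement
  tempo is a free choice; 4 s is a comfortable rehabilitation pace), 240
  cycles per study.
* **Excitation**: the flexor envelope is the positive part of the required
  active torque normalized by its peak; the extensor envelope the negative
  part; the brachioradialis follows the biceps at 70 % synergy plus small
  independent noise.  This linear torque→excitation map means the *inverse*
  problem the network faces is shaped by the pipeline's own nonlinearities.
* **EMG**: Gaussian white noise bandpassed to 50–150 Hz, normalized to unit
  peak, amplitude-modulated by the envelope (full excitation → 5 mV), plus
  a 0.2 mV 50 Hz mains tone (so the notch filter is genuinely exercised)
  and 20 µV white sensor noise.

What the generator does **not** model: motor-unit statistics, conduction
velocity, skin-motion artifacts, electrode lift-off, fatigue-induced
spectral compression, angle-sensor noise, or inter-cycle tempo variability.
Passing the synthetic study therefore shows that the pipeline's machinery is
correct and self-consistent — not that the accuracy figures transfer to
real subjects.

## Preprocessing

Butterworth bandpass 20–500 Hz of order 4 and a second-order 50 Hz notch
with quality factor 30 (only the filter family and corner frequencies are
standard; order and Q are package choices).  Offline processing applies both
forward–backward (zero phase) to preserve EMG–angle alignment; the streaming
emulator uses the same filters causally with carried state.  Windows are
25 ms, non-overlapping (30 EMG samples at 1200 Hz).  Because a window spans
only 2.5 angle samples, angle and velocity are linearly interpolated to
window centres instead of decimating the EMG.  Velocity uses central
differences offline and backward differences in the streaming path (causal
and extension-invariant).

## Feature fusion

PCA is performed on the correlation matrix (standardized features): the
published eigenvalue spectra for this feature set sum to 8, which identifies
standardization, and the contribution rate of component i is λᵢ/8 × 100 %.
Loading signs are fixed by making each column's largest-magnitude entry
positive.  k = 5 components are retained by default (the documented
cumulative contribution at k = 5 is 99.98 %); a cumulative-threshold rule is
available for other datasets.  Standardization statistics and loadings are
learned on the training split only and reused everywhere else to avoid
leakage.  iEMG defaults to the rectified mean, since the plain windowed mean
of zero-mean bandpassed EMG is ≈ 0; the literal un-rectified mode ships
behind a flag.

## Network and training

Topology is fixed at 5-3-1 with tansig on both layers.  The bounded output
forces target scaling: torque min–max (from the training split) is mapped to
[−0.9, 0.9], the margin keeping targets away from saturation; the scaler is
stored in the model file.  Training is full batch.  The adaptive rule is

    Δω(k) = η(k)·[(1−μ)·g(k) + μ·g(k−1)],  η(k) = 2^λ·η(k−1),
    λ = sign⟨g(k), g(k−1)⟩

with λ the sign of the *inner product* of flattened gradients — a scalar, so
η stays scalar; λ = 0 leaves η unchanged, and parameters move against the
gradient.  Defaults: μ = 0.9, η₀ = 0.01, η clamped to [10⁻⁵, 1] (the
doubling rule needs a ceiling), 3000 epochs max, MSE goal 10⁻³ on scaled
targets.  Early stopping: training halts once the validation MSE has not
improved for 50 consecutive epochs (patience), and the best-validation
parameters are returned.  Divergence (non-finite loss) raises an error
reporting the epoch and rate.

PSO initialization encodes all 22 free parameters per particle; 100
particles, c₁ = c₂ = 2, 2000 iterations, inertia decaying linearly 0.9→0.4,
positions in ±5, velocities clamped to ±1.  c₂ is not separately documented
anywhere, so it defaults symmetric with c₁.  Fitness is the training-split
MSE; for large synthetic datasets it is estimated on a fixed random
subsample of 2048 windows — larger than the entire dataset of the original
protocol (1680 samples) — which keeps the 2000-iteration swarm tractable on
one CPU without changing the swarm constants.  Whether fitness should use
training or validation MSE is not documented; training MSE keeps the
validation set untouched for early stopping.

## Assist control

The assist command is magnitude × direction: `clamp(ratio·|τ_active|, 0,
τ_max) · sign(β̇)`, with a 2 deg/s velocity deadband (prevents direction
chatter near turn-around), assist fully suppressed in any window whose
velocity magnitude exceeds the configured maximum (the safest reading of an
over-speed constraint), and current = τ/k_t with configurable torque
constant.  Whether the assist ratio should multiply the signed torque or
its magnitude is ambiguous in principle; magnitude-with-separate-direction
was chosen and is noted here rather than presented as the only reading.

## Problem sizes and determinism

The canonical study (`pipeline.run_study`) uses 240 cycles × 160 windows =
38 400 windows (23 040 train / 7 680 validation / 7 680 test) and runs in
about a minute on one CPU; the test suite repeats it for the default seed
and ten alternative seeds.  All randomness flows from explicit
`numpy.random.default_rng` seeds: a fixed seed reproduces the dataset,
split, swarm and training history bit-for-bit.

## Known limitations

* The synthetic study is easier than real life: within a run every cycle
  follows the same noiseless trajectory, so angle and velocity alone nearly
  determine the torque.  Real tempo variability would lean harder on the
  EMG features.
* The scalar-λ adaptive rate can limit-cycle near sharp minima (it never
  anneals if consecutive gradients stay correlated); on hard realizable toy
  problems roughly one seed in ten plateaus above the 10⁻³ goal.
* The Hill pathway's musculoskeletal geometry (constant moment arms, rigid
  tendon, fixed pennation) is deliberately minimal — adequate for a
  trend-level cross-check, not for subject-specific force estimates.
* File formats are plain text and scale comfortably to the study sizes
  here; very long recordings would warrant a binary container.
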