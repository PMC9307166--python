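# Methods

This note documents the models implemented in `magstimcal`, the defaults and
units, the design decisions taken where the problem left room, and what the
synthetic data do and do not establish about real hardware.

## Conventions

Right-handed setup coordinates, origin at the nominal specimen position.
Geometry in meters, magnetic fields in microtesla, control voltages in volts,
coil currents in amperes, MEA positions in micrometers, extracellular signals
in microvolts, time in seconds.  Every stochastic routine takes an explicit
seed (package default 20220722); nothing draws from global random state.

## Coil fields

Loops are evaluated with the exact finite-segment Biot–Savart expression
`B = μ₀I/4π · (a×b)(|a|+|b|) / (|a||b|(|a||b| + a·b))` summed over the
polyline; a square loop is four segments (exact), a circular loop is
discretised into 1440 segments, at which the midpoint field of a pair at
`d = r` agrees with the closed form `(8/5√5)·μ₀nI/r` to better than 1e-6
relative (convergence is verified by segment doubling in the tests).
Evaluation closer than 1e-4 of the loop size to a conductor raises a
singularity error: such points are numerically meaningless in this model.

**Square-pair spacing.** The homogeneity-optimal separation nulls the second
axial derivative of the pair field at the midpoint.  With the on-axis field
of a square loop `f(z) ∝ 1/((4z²+a²)√(4z²+2a²))`, the second derivative is
formed analytically from the log-derivative and the root is bracketed with
Brent's method over `d/a ∈ [0.3, 0.8]`; the root is unique there and equals
`d/a = 0.54451`.  Published treatments commonly quote `0.5452`; the ≈0.13%
difference is within the bracketing tolerance of graphical/tabulated
optimisations but not of this criterion, so the package returns the computed
root and does not hard-code the literature value.  Tests check agreement
with 0.5452 at 1% and the nulled curvature against a finite-difference
oracle.

**Distortion sources.** Hard sources are fixed point dipoles.  Soft sources
carry an effective polarizability volume χ (m³): the induced moment is
`m = χ·B_applied/μ₀`, where `B_applied` is the field at the source from
coils, hard sources and the ambient field, excluding the source itself — a
single-scattering approximation; full magnetostatic self-consistency (and
hysteresis, finite-element geometry, coil heating) is out of scope.  A
χ of 1e-4 m³ at 30 mm from the center reproduces the qualitative behavior of
a ~500 g steel bar near a recording chamber: tens-of-percent stimulus errors
before recalibration and a few percent residual spatial inhomogeneity after.

**Blanking.** An anti-serially wired (double-wrapped) pair contributes an
exact zero field by construction, not by numerical cancellation: the two
parallel windings carry opposite currents everywhere.

## Magnetometer model and calibration

Forward model of a consumer AMR sensor: `V_raw = V_bias + (1/g)·W·Bₛ` with
`Bₛ` the ambient field rotated into the sensor frame, per-axis Gaussian noise
added in field units, conversion at `g` (nT/LSB), rounding to integer LSB and
clipping to ±32767 (clipping warns rather than raises, as the hardware would
simply saturate).  Defaults: `g = 7.85` nT/LSB, noise 0.54 uT per axis (the
64× oversampling floor), ±200 uT full scale, 200 Hz output.

Rotation trajectories are either i.i.d. uniform on SO(3) (the idealised
"arbitrary rotation") or a smooth random walk with bounded per-step angle.
The standard 3-minute, 200 Hz session is 36000 samples.

**Ellipsoid fit.** The raw data of a rotated sensor lie on an ellipsoid.  The
general quadric `xᵀAx + bᵀx + c = 0` is fitted by direct algebraic least
squares (smallest right singular vector of the 10-column design), chosen over
iterative geometric fitting for determinism and freedom from initialisation.
The center gives `V_bias`; the symmetric-positive-definite square root of the
normalised quadratic form gives `W⁻¹`.  Two ambiguities are resolved by
convention and documented because they are intrinsic, not incidental:

- *Rotation*: only `WᵀW` is identifiable from magnitudes, so `W⁻¹` is made
  symmetric PD.  Symmetric-PD ground truths are then recovered exactly;
  general ground truths up to a left orthogonal factor (tested).
- *Scale*: only the product `g·W⁻¹` is identifiable, so `W⁻¹` is normalised
  to unit determinant and the scale is absorbed into `g`, fixed so calibrated
  radii average the reference magnitude.

Near-coplanar data (planar rotations) raise a rank error instead of returning
an ill-conditioned fit.  `fit_rms` is the relative rms spread of calibrated
radii.  Residual statistics report magnitude residuals `|B| − B_ref` (mean,
std, std as % of reference); per-component residuals can be formed by the
caller, but magnitude residuals are the default interpretation throughout.
With the default noise the post-calibration residual std is ≈0.54 uT — the
per-axis noise projected onto the field direction; the small excess over
that seen on real hardware (≈0.55 uT) contains calibration error the noise
simulation does not model.  The oversampling model is plain white-noise
averaging, `σ(k) = σ₆₄·√(64/k)`, which matches the measured 64×/256×/512×
floors and is ~2% below the measured 128× value.

## Coil driver

Static transfer `I = divider·U/R_shunt` is exactly linear; clipping at the
±3 A current limit or at voltage compliance (supply − 4 V dropout, across the
coil resistance) is flagged, not raised.  The minimum supply for a target
current is `I·R + dropout` (the worked 1 A / 5 Ω case: 9 V; 5 V by Ohm's law
alone), and amplifier heat at steady state is `(V_supply − |U_coil|)·|I|`,
with supply power = coil + amplifier dissipation as an exact identity.

The closed loop is abstracted as a canonical second-order system in
(ζ, ω_n) with the physical slew ceiling `|di/dt| ≤ (supply − dropout)/L`.
This is a stated approximation: the real compensation trimmer and amplifier
pole structure are unknown, but the observable behavior — ~15% overshoot,
2%-band settling below 500 us, the U/L slew bound — pins the abstraction.
Defaults: ζ = 0.517 (15% overshoot via `exp(−πζ/√(1−ζ²))`), ω_n chosen
numerically so the 2% settling time is 400 us.  When the slew clamp never
engages the trace is the analytic step response; otherwise RK4 integration
with the derivative state clamped.  The settling band (±2%) is a package
definition; the source behavior is only stated as "steady state".

Sham blanking returns the same current (hence the same dissipated power) in
both polarities and a field scale factor of exactly 0 in anti-serial wiring;
the residual field is then whatever constant background `B_const` the setup
model carries.

## Setup calibration

`B_eff = B_const + D·U` with `D` in uT/V.  Calibration voltages are a
deterministic Fibonacci-lattice sphere (no seed needed; near-uniform for any
n ≥ 4) of default radius 2 V — the driver's linear range comfortably covers
this, and the source material does not state the amplitude actually used.
Each Cartesian component is fitted by OLS with intercept, so `B_const` is
estimated jointly by default; measuring it directly at zero voltage is
equivalent for noise-free data and supported by simply including U = 0
points.  Inversion refuses a `D` with condition number above 1e6 unless
forced, since silently inverting a degenerate gain matrix commands huge
currents.  Because the distortion chain is affine at a fixed position,
calibrate-then-command is an exact identity for noise-free measurements
(tested at 1e-9 uT); residual errors in practice are measurement noise and
position dependence.

The homogeneity scan fits at the grid center and commands a 44-vector 50 uT
sphere at each of 5×5 positions spaced 500 um, reporting the per-position
mean Euclidean error as % of 50 uT.  Probe targets are held out from the
calibration set (162 calibration voltages vs 44 probe vectors) — whether the
original verification reused its calibration vectors is unknown, so held-out
evaluation is the default and reuse is possible by passing the same set.
For the exemplary geometry (223/400/162 mm sides, 32/53/19 turns, optimal
spacing, 1 A/V drivers) the worst-position error is ~2e-6%, far below the
~1% bound measured on hardware, whose error budget is dominated by sensor
noise and residual setup distortion rather than coil geometry.

## MEA artifact lab

Sampling rate 20 kHz (not stated by the source; it must exceed twice the
2 kHz band edge).  The 512-electrode layout is hexagonal packing filling
1890 × 900 um (32 columns × 16 rows, alternate rows offset); the commercial
array's exact geometry is not public, so this is a stand-in with the same
count and extent.  Recordings are band-passed 80 Hz–2 kHz with a
second-order Butterworth applied forward–backward (zero-phase; peak
latencies move by at most one sample, tested).

**Spikes.** A cell is a soma position, peak amplitude (150–400 uV in the
default scenario), a straight axon, and a biphasic kernel (Gaussian
derivative, σ = 0.2 ms, zero integral).  Per-electrode amplitude decays as
`1/(1+(d/λ)²)` from the nearest point of the soma–axon path with λ = 30 um,
tapering to 40% of the somatic amplitude along the axon; latency is the
arc length over a 1 m/s conduction velocity.  These are free parameters
chosen to produce the qualitative structure of real electrical images
(strong somatic signal, delayed axonal signal), not fitted to data.

**Artifacts.** The magnetic stimulus is a random walk over the 12 icosahedron
vertices at 50 uT, one vertex per 200 ms, consecutive vertices always
distinct.  At each transition a dB/dt-shaped kernel (Gaussian pulse,
σ = 0.3 ms, the derivative of a smooth field step) is added *simultaneously*
on all electrodes with peak `(c·ΔB)·scale_e`; the per-electrode scale
defaults to uniform (no routing dependence was apparent on hardware; a
variation hook exists but is unvalidated).  Noise-free transition images are
exactly antisymmetric under transition reversal and exactly linear in ΔB
(R² = 1, tested); the axis fit regresses the spatially averaged signed peak
on the three ΔB components and normalises the coefficients.  The default
planted axis (−0.74, 0.67, 0.07) reflects a planar array coupling mostly to
x/y field changes.

**Classification.** Spread index = fraction of electrodes whose peak exceeds
30% of the array maximum; latency dispersion = std (ms) of peak latencies
over those electrodes.  An image is an artifact if spread > 0.5 *and*
dispersion < 0.2 ms; otherwise a spike.  These thresholds and the statistic
itself are package definitions — the separation statistic used for the
original hardware data is not specified — so the claim tested here is that
*this* statistic separates the two synthetic populations, not that it
replicates a published one.  With a single supra-threshold electrode the
dispersion is undefined (NaN) but the tiny spread already labels the event a
spike; this is precisely the single-electrode ambiguity in which an artifact
waveform can resemble a spike.  Only an all-zero image is unclassifiable.
The default scenario (367 spike images vs 144 artifact images, residual
image noise 1 uV) is built directly from the image models above with
vectorised feature extraction; over 200 seeds the populations are disjoint
in spread (spikes ≤ ~0.04, artifacts = 1.0) and the ROC area is exactly 1.

The spike-triggered average uses a 120 Hz frame log: flat at the stimulus
mean for events independent of the stimulus (artifact times), and
reproducing a planted kernel for a stimulus-driven cell.

## What the synthetic data do not show

The generators emulate the *mechanisms* (affine distortion, white sensor
noise, simultaneous band-limited induction, propagating spikes).  They do not
contain temperature drift, sensor cross-axis effects beyond `W`, nonlinear
(saturating) soft iron, electrode impedance variation, real spike-sorting
errors, or biological response variability.  Passing tests therefore
establish the correctness and internal consistency of the algorithms under
the stated models, and the achievable precision when those models hold — not
the hardware's measured error budget, which includes contributions the
models deliberately leave out.

## Problem sizes

Defaults were chosen as the realistic session sizes for each task: 36000
samples (3 min at 200 Hz) for sensor calibration, 162 calibration voltages
and 44 probe vectors at 50 uT for the coil system, 5×5 positions at 500 um,
and 367 + 144 images per classification scenario over 200 seeds.  The
acceptance script and the test suite run these sizes as-is.
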