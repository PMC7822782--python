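# Methods

## Problem

Shear-wave elastography infers tissue stiffness from the speed of transverse
mechanical waves: for an incompressible soft solid of density ρ and Young's
modulus E, the shear-wave speed is c_s = sqrt(E / (3ρ)). Optical coherence
tomography (OCT) observes these waves interferometrically — sub-wavelength
axial displacement u_z shifts the phase of the complex OCT signal by
4πn/λ₀ · u_z — so a fast volumetric OCT scanner watching a continuously
excited phantom records a 4D movie of the propagating wave field. This
package implements an end-to-end pipeline that regresses the gelatin
concentration of tissue-mimicking phantoms directly from such 4D phase
movies with a spatiotemporal convolutional network, alongside a classical
two-position time-of-flight (ToF) estimator, and — because the experimental
dataset is not public — a physics-based simulator that generates the study
conditions synthetically with analytically known ground truth.

## Synthetic acquisition model

A needle driven by a piezo actuator at f = 100 Hz acts as a vertical line
source. The axial displacement at lateral distance r from the needle is
modelled as a cylindrically spreading harmonic wave

    u_z(r, t) = A (r / r_ref)^(−q) exp(−α r) sin(2π f (t − r / c_s)),

with geometric decay exponent q = 0.5, optional exponential attenuation α
(default 0), reference distance r_ref = 1 mm and source amplitude A
(default 100 nm at r_ref). The wave is assumed uniform along depth (line
source), with no reflections, mode conversion or dispersion. The voxel phase
is

    φ = wrap( s · u_z + φ₀(x, y) + ε ),   s = 4πn/λ₀ (n = 1.35, λ₀ = 1315 nm),

where φ₀ ~ U(−π, π) is a static per-A-scan speckle-like baseline (constant in
time, so temporal unwrapping is genuinely exercised) and ε is i.i.d. Gaussian
phase noise. Intensity volumes carry a smooth surface peak at a randomly
drawn depth with sub-surface decay and 10% static speckle, so surface
detection operates on realistic profiles. The full-scale geometry is
3 × 3 × 2 mm scanned as 32 × 32 × 470 voxels at 831 volumes/s, 90 volumes
per position; phantoms cover seven gelatin concentrations (5–20% in
2.5-point steps) whose Young's moduli follow the power law E(c) = a·c^b
calibrated through the two indentation endpoints (5%, 21 kPa) and
(20%, 119 kPa) — the only stiffness values the study states. Six phantoms
per concentration are scanned at a grid of lateral positions.

What the generator does *not* emulate: speckle decorrelation, depth-dependent
signal attenuation and phase noise growth, scanner galvo artifacts,
compressional waves, surface refraction, reverberation from boundaries, and
any stiffness-dependent viscous damping. Passing the recovery experiment on
this generator therefore demonstrates that the pipeline extracts wave-speed
information from clean traveling-wave phase patterns — not that it would
reach the same accuracy on experimental data.

## Preprocessing

1. **Surface detection** — per A-scan, intensity is boxcar-smoothed along
   depth (5 px) and the argmax taken (ties toward smaller depth); the lower
   median over all A-scans of the temporal-mean volume gives one surface
   index per sequence.
2. **Depth crop** — 250 px (full scale) beneath the surface, half-open
   0-based range [surface, surface + 250).
3. **Temporal unwrapping** — per voxel along time only:
   out[t] = out[t−1] + wrap(in[t] − in[t−1]). No spatial unwrapping.
4. **Resize** — trilinear interpolation to 32³ (full scale), after
   unwrapping, because interpolating wrapped phase across a 2π jump is
   meaningless.

An optional step subtracts the per-voxel temporal mean, removing the static
speckle baseline φ₀. It is off by default (matching a pipeline that feeds
the network nothing but unwrapped phase); the desk-scale recovery study
enables it (see below).

## Network

A DenseNet-style 4D spatiotemporal regressor: a stem of four 3⁴
convolutions (8 channels each at full scale), three dense blocks of three
layers with growth rate 8 (each layer = batch norm → ReLU → conv,
pre-activation ordering), stride-2 average-pooling transitions over all four
spatiotemporal axes between blocks (axes of extent 1 pass through), then
batch norm → ReLU → global average pooling → a single linear output in
percent. Kernel size 3 on every axis with zero "same" padding; He-normal
initialization, deterministic under a seed. Input is a 10 × 32³ crop (one
channel).

Because no deep-learning framework is assumed, the network is pure NumPy
with hand-written backpropagation. The 4D convolution is evaluated in the
frequency domain: operands are padded to n + k − 1 per axis so the circular
product of real FFTs is the exact linear correlation; channels are
contracted with a batched matrix product per frequency bin. The same
formulation yields the weight gradient (cross-correlation of the output
gradient with the input, alias-free at that padding) and the input gradient
(plain convolution with the kernel) from one spectrum per array per step.
The public `conv4d` runs at double precision; network layers use
single-precision FFTs. A direct four-fold nested summation serves as the
test oracle, and end-to-end gradients are checked against central finite
differences.

## Training and evaluation protocol

1000 Adam steps (β₁ = 0.9, β₂ = 0.999), batch 13, MSE loss on raw percent
labels. Each batch item is a random contiguous 10-volume crop of a uniformly
drawn (with replacement) training sequence. Data are split at phantom
granularity — all scan positions of a phantom stay together — with 4/1/1
phantoms per concentration for train/validation/test. Validation MAE is
measured every 50 steps (evaluation mode, frozen batch-norm statistics, all
ordered crops per sequence — a lower-variance selection signal than a single
crop) and the best checkpoint restored. Evaluation averages
predictions over ordered non-overlapping 10-volume crops (the trailing
remainder is discarded). Metrics: MAE ± SD of absolute errors over
sequences, rMAE = MAE divided by the population SD of the distinct target
concentrations (5.0 p.p. for the seven balanced targets), Pearson
correlation of predictions vs targets, a per-concentration table and a
per-position mean-estimate grid. A constant prediction vector makes the PCC
undefined; it is reported as NaN with a warning, never coerced to 0.
Predictions are clipped to [0, 100] at reporting time only.

The learning rate is not stated by the protocol; it is treated as the free
optimization hyperparameter and selected on the validation partition
(default 1e−2 — raw percent targets need larger steps than the usual 1e−3
when the head starts near zero). A constant 1e−2 leaves the late-training
trajectory oscillating violently (validation MAE swinging by an order of
magnitude between checkpoints), so the default schedule anneals the step
size cosine-wise to 10% of its initial value over the run; "constant"
remains available.

## Desk-scale recovery study

Full-scale sequences are too heavy for routine single-CPU runs, so the
recovery experiment uses a scaled-down preset chosen once: the same
3 × 3 × 2 mm FOV at 16 × 16 × 64 voxels, 30 volumes per sequence, a 3 × 3
grid of 9 scan positions (FOV corner offsets 0.5–3.5 mm from the needle),
7 concentrations × 6 phantoms, crop depth 32 px, resize target 8³, and a
reduced network (stem width 6, growth 6, ~140 k parameters). Measurement
imperfections are represented by phase noise of SD 0.05 rad and a 3%
relative per-phantom stiffness jitter (gelatin batch variability); the
jitter alone puts a floor of ≈0.2 p.p. on the achievable MAE. Training
follows the protocol above unchanged.

The static speckle baseline φ₀ dominates the desk-scale input variance and
lets a small network memorize training sequences by their speckle pattern
instead of learning the wave: with raw unwrapped phase the validation MAE
never beats a constant predictor. The desk study therefore enables the
temporal-mean-subtraction preprocessing option, after which every voxel
carries only the traveling-wave oscillation. This choice was made on the
validation partition, is recorded in the run configuration hash, and is the
one deliberate departure from the "nothing but unwrapped phase" default.

## Time-of-flight baseline

Depth-averaged unwrapped-phase traces (middle third of the cropped depth)
are taken at two probe A-scans on a common ray from the source (within 5°),
the far probe second. The travel-time delay is the argmax of their
*unbiased* normalized cross-correlation — per-lag overlap normalization
removes the triangular taper that would otherwise bias the peak toward zero
lag by ≈1/(N ω²) samples, a material error at 8.3 samples per 100 Hz period —
restricted to lags consistent with a shear-speed prior of [0.5, 10] m/s
(which also resolves the period ambiguity of continuous excitation), with
sub-sample refinement by maximizing a cubic-spline interpolant of the
correlation. A 3-point parabola was rejected: its ~5% multiplicative bias on
fractional lags would exhaust the 5% physics-oracle tolerance on its own.
Estimates with non-positive delay or peak correlation below 0.5 raise an
error. Speed maps back to concentration through E = 3ρc² and the inverse of
the calibrated power law; implied concentrations outside (0, 100] are
clamped with a warning. The estimator receives the true source position, so
it bounds rather than matches the network's task difficulty.

## Numerical choices and degenerate inputs

- Phase wrapping uses the half-open convention (−π, π].
- Surface/crop indices are 0-based, ranges half-open; depth increases away
  from the scanner.
- Resampling places target samples at linspace(0, n−1, m), so constants and
  per-axis linear ramps are reproduced exactly.
- Average pooling drops a trailing odd sample; axes of extent 1 pass
  through unpooled.
- Batch norm: momentum 0.9, ε = 1e−5; evaluation uses running statistics.
- All stored arrays are float32; metadata float64. A single global seed fans
  out to per-stage seeds via SeedSequence([seed, stage counter]), so stages
  are independently reproducible; datasets are deterministic at byte level.
- Divergent training (non-finite loss) aborts with a diagnostic rather than
  continuing.

## Known limitations

- The simulator's wave model is kinematic, not elastodynamic; it carries
  speed information but no near-field, boundary or viscoelastic effects.
- The 4D network is trained for exactly 1000 steps with no early stopping
  beyond best-validation checkpointing; on the desk preset this is minutes
  of CPU time, but accuracy is not saturated.
- Published headline accuracies from the experimental dataset cannot be
  reproduced here; the desk-scale study is an analogue on cleaner synthetic
  data, not a replication.
- The ToF baseline assumes a known propagation direction; off-ray probe
  pairs are rejected rather than handled.
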