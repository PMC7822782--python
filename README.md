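# oce4d

4D deep learning for volumetric optical coherence elastography (OCE), on
synthetic shear-wave phantoms.

Soft-tissue stiffness can be read off the speed of shear waves: for an
incompressible medium, c_s = sqrt(E / (3ρ)). A fast volumetric OCT scanner
(831 volumes/s, 3 × 3 × 2 mm field of view) watching a gelatin phantom under
continuous 100 Hz needle excitation records a 4D movie whose interferometric
phase carries the traveling wave. This package implements, end to end:

- **`oce4d.simulate`** — a physics-based generator of such 4D acquisitions
  with analytically known ground truth: a cylindrical harmonic wave
  u_z = A (r/r_ref)^(−½) e^(−αr) sin(2πf(t − r/c_s)), phase
  φ = wrap(4πn/λ₀ · u_z + φ₀ + ε), gelatin stiffness following the power law
  E(c) through the indentation calibration points (5%, 21 kPa) and
  (20%, 119 kPa), seven concentrations × six phantoms × a grid of scan
  positions.
- **`oce4d.preprocess`** — surface detection (intensity peak), 250 px depth
  crop, per-voxel temporal phase unwrapping, trilinear resize to the network
  input shape.
- **`oce4d.net4d`** — a DenseNet-style 4D spatiotemporal regressor (4-layer
  stem, three dense blocks of three layers, growth rate 8, stride-2
  average-pooling transitions, batch norm + ReLU, global average pooling,
  linear percent output) in pure NumPy with hand-written backpropagation;
  the 4D convolution is an exact FFT-domain correlation, tested against a
  brute-force four-fold nested sum.
- **`oce4d.training`** — the training protocol (1000 Adam steps, batch 13,
  MSE, random 10-volume temporal crops, phantom-level 4/1/1 split) and the
  evaluation metrics (MAE, rMAE relative to the 5.0 p.p. target SD, Pearson
  correlation, per-concentration table, per-position heat-map grid).
- **`oce4d.tof`** — the classical two-position time-of-flight baseline:
  cross-correlation travel-time delay between two probe A-scans on a ray
  from the source, which doubles as the independent physics check of the
  simulator.

## Worked example

The desk-scale study — same field of view at 16 × 16 × 64 voxels, 30 volumes
per sequence, 9 scan positions, 7 concentrations × 6 phantoms, a reduced
network (~140 k parameters) — runs in minutes on one CPU:

```bash
oce4d run --seed 1 --out run/
```

which simulates 378 sequences, preprocesses them to 30 × 8³ unwrapped-phase
tensors, trains on 4 phantoms per concentration, and evaluates the held-out
test phantoms:

```
n_crops=1: MAE 0.416 p.p., rMAE 0.083, PCC 0.995
n_crops=3: MAE 0.294 p.p., rMAE 0.059, PCC 0.997
```

Reading: from a single 10-volume input (≈12 ms of acquisition), the gelatin
concentration of never-seen phantoms is predicted to 0.42 percentage points
on average, with 99.5% Pearson correlation to the truth; averaging the three
available ordered crops tightens the error further. `run/metrics.json`
holds the full report (per-concentration means, provenance, seeds) and
`run/positions_ncrops*.csv` the per-position estimate grids.

The same library surface is scriptable:

```python
import numpy as np
from oce4d import (ExcitationSpec, ScanGeometry, SimConfig, make_phantom,
                   synth_wave_field)
from oce4d.tof import estimate_shear_speed

geom = ScanGeometry(raw_shape_px=(16, 16, 64), n_volumes=90)
sim = SimConfig(surface_depth_px_range=(8, 16))
seq = synth_wave_field(make_phantom(12.5, "demo"), ExcitationSpec(), geom,
                       sim, position_mm=(1.0, -0.05),
                       rng=np.random.default_rng(0))
est = estimate_shear_speed(seq, (0.0, 0.0),
                           ((1.28, 0.04), (3.72, 0.04)), crop_depth_px=32)
print(f"{est.speed_m_s:.2f} m/s vs analytic {seq.phantom.shear_speed_m_s:.2f}")
```

which prints `4.78 m/s vs analytic 4.69` — the classical estimator recovers
the simulated shear speed to about 2%, bounding what the network should
extract from the same data.

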