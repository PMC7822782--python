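"""Physics-based synthetic generator for 4D shear-wave OCE sequences.

A needle driven by a piezo actuator acts as a vertical line source emitting a
continuous cylindrical shear wave into a gelatin phantom. The axial
displacement observed by the scanner at lateral distance ``r`` from the needle
is

    u_z(r, t) = A (r / r_ref)^(-q) exp(-alpha r) sin(2 pi f (t - r / c_s))

with geometric decay exponent ``q`` (0.5 for a cylindrical wavefront),
optional exponential attenuation ``alpha``, and shear speed
``c_s = sqrt(E / (3 rho))``. The interferometric phase of each voxel is the
displacement scaled by 4 pi n / lambda0, offset by a static speckle-like
per-A-scan baseline, perturbed by Gaussian noise, and wrapped to (-pi, pi].

Gelatin stiffness is mapped from mass concentration through a power law
calibrated on two mechanical-indentation endpoints: 21 kPa at 5% and 119 kPa
at 20%.
"""
from __future__ import annotations

import math
from collections.abc import Iterator, Sequence
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .types import (
    ExcitationSpec,
    PhantomSpec,
    RawVolumeSequence,
    ScanGeometry,
    SimConfig,
    wrap_phase,
)

#: Calibration endpoints of the concentration -> Young's modulus power law.
CALIBRATION_POINTS_PCT_KPA = ((5.0, 21.0), (20.0, 119.0))

#: The seven gelatin mass concentrations of the phantom study (%).
STUDY_CONCENTRATIONS_PCT = (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)

_POWER_B = math.log(119.0 / 21.0) / math.log(20.0 / 5.0)
_POWER_A = 21.0 / 5.0**_POWER_B

#: Reference distance at which ExcitationSpec.amplitude_nm is defined (mm).
REFERENCE_DISTANCE_MM = 1.0


def concentration_to_elasticity(c: float | np.ndarray) -> float | np.ndarray:
    """Young's modulus E(c) in kPa for gelatin mass concentration ``c`` in %.

    Power law ``E = a c^b`` through the calibration endpoints
    (5%, 21 kPa) and (20%, 119 kPa); strictly increasing on (0, 100].
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0) or np.any(c_arr > 100):
        raise ConfigurationError(f"concentration must be in (0, 100]: {c}")
    out = _POWER_A * c_arr**_POWER_B
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def elasticity_to_concentration(e_kpa: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`concentration_to_elasticity` (kPa -> %)."""
    e_arr = np.asarray(e_kpa, dtype=float)
    if np.any(e_arr <= 0):
        raise ConfigurationError(f"Young's modulus must be > 0: {e_kpa}")
    out = (e_arr / _POWER_A) ** (1.0 / _POWER_B)
    return float(out) if np.isscalar(e_kpa) or e_arr.ndim == 0 else out


def elasticity_to_shear_speed(
    e_kpa: float | np.ndarray, rho_kg_m3: float = 1000.0
) -> float | np.ndarray:
    """Shear-wave speed c_s = sqrt(E / (3 rho)) for an incompressible solid.

    ``E`` is in kPa, ``rho`` in kg/m^3; the result is in m/s.
    """
    e_arr = np.asarray(e_kpa, dtype=float)
    if np.any(e_arr <= 0) or rho_kg_m3 <= 0:
        raise ConfigurationError("E and rho must be > 0")
    out = np.sqrt(e_arr * 1e3 / (3.0 * rho_kg_m3))
    return float(out) if np.isscalar(e_kpa) or e_arr.ndim == 0 else out


def make_phantom(
    concentration_pct: float,
    phantom_id: str,
    density_kg_m3: float = 1000.0,
    heterogeneity_scale: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PhantomSpec:
    """Create a phantom at the calibrated stiffness for its concentration.

    With ``heterogeneity_scale > 0`` the Young's modulus is jittered by a
    relative Gaussian factor (one draw per phantom), emulating batch-to-batch
    variability of gelatin preparation; the concentration label is unchanged.
    """
    e = concentration_to_elasticity(concentration_pct)
    if heterogeneity_scale > 0:
        if rng is None:
            raise ConfigurationError("heterogeneity_scale > 0 requires an rng")
        factor = 1.0 + heterogeneity_scale * rng.standard_normal()
        e = float(e) * max(factor, 0.05)
    return PhantomSpec(
        concentration_pct=float(concentration_pct),
        youngs_modulus_kpa=float(e),
        phantom_id=phantom_id,
        density_kg_m3=density_kg_m3,
        heterogeneity_scale=heterogeneity_scale,
    )


def _lateral_distances_mm(
    geometry: ScanGeometry,
    position_mm: tuple[float, float],
    needle_mm: tuple[float, float],
) -> np.ndarray:
    """(X, Y) grid of voxel-centre distances to the needle, clamped away from 0."""
    px, py, _ = geometry.pitch_mm
    nx, ny, _ = geometry.raw_shape_px
    x = position_mm[0] + (np.arange(nx) + 0.5) * px
    y = position_mm[1] + (np.arange(ny) + 0.5) * py
    dx = x[:, None] - needle_mm[0]
    dy = y[None, :] - needle_mm[1]
    r = np.hypot(dx, dy)
    return np.maximum(r, min(px, py))


def _intensity_profile(
    geometry: ScanGeometry, surface_px: int, rng: np.random.Generator
) -> np.ndarray:
    """Static (X, Y, Z) intensity volume: surface peak plus sub-surface decay."""
    nx, ny, nz = geometry.raw_shape_px
    z = np.arange(nz, dtype=float)
    sigma = max(2.0, 0.006 * nz)
    decay = max(10.0, 0.15 * nz)
    profile = (
        0.05
        + np.exp(-0.5 * ((z - surface_px) / sigma) ** 2)
        + 0.4 * np.exp(-(z - surface_px) / decay) * (z >= surface_px)
    )
    speckle = 1.0 + 0.1 * rng.standard_normal((nx, ny, nz))
    return np.maximum(profile[None, None, :] * speckle, 0.0)


def synth_wave_field(
    phantom: PhantomSpec,
    excitation: ExcitationSpec,
    geometry: ScanGeometry,
    sim: SimConfig,
    position_mm: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> RawVolumeSequence:
    """Simulate one 4D acquisition of the continuous shear-wave field.

    All randomness (surface depth, static phase offsets, speckle, phase noise)
    is drawn from ``rng`` (or a generator seeded with ``sim.rng_seed``), so
    identical configurations and seeds produce bit-identical sequences.
    """
    if rng is None:
        rng = np.random.default_rng(sim.rng_seed)
    lo, hi = sim.surface_depth_px_range
    if hi >= geometry.raw_shape_px[2]:
        raise ConfigurationError(
            f"surface depth range {sim.surface_depth_px_range} exceeds depth axis "
            f"{geometry.raw_shape_px[2]}"
        )
    surface_px = int(rng.integers(lo, hi + 1))

    r_mm = _lateral_distances_mm(geometry, position_mm, excitation.needle_position_mm)
    c_s = phantom.shear_speed_m_s
    f = excitation.frequency_hz
    amp_m = excitation.amplitude_nm * 1e-9
    envelope = (
        amp_m
        * (r_mm / REFERENCE_DISTANCE_MM) ** (-sim.geometric_decay_exponent)
        * np.exp(-sim.attenuation_np_per_mm * r_mm)
    )
    t = geometry.times_s  # (T,)
    delay_s = (r_mm * 1e-3) / c_s  # (X, Y)
    u_z = envelope[None] * np.sin(
        2.0 * np.pi * f * (t[:, None, None] - delay_s[None])
    )  # (T, X, Y)

    phi0 = rng.uniform(-np.pi, np.pi, size=r_mm.shape)  # static per A-scan
    phase = sim.phase_scale_rad_per_m * u_z + phi0[None]
    nz = geometry.raw_shape_px[2]
    phase = np.broadcast_to(phase[..., None], (*phase.shape, nz)).copy()
    if sim.phase_noise_sd_rad > 0:
        phase += rng.normal(0.0, sim.phase_noise_sd_rad, size=phase.shape)
    phase = wrap_phase(phase).astype(np.float32)

    intensity = _intensity_profile(geometry, surface_px, rng).astype(np.float32)
    intensity = np.broadcast_to(
        intensity[None], (geometry.n_volumes, *intensity.shape)
    ).copy()

    return RawVolumeSequence(
        intensity=intensity,
        phase_rad=phase,
        geometry=geometry,
        position_mm=tuple(position_mm),
        phantom=phantom,
        surface_depth_px=surface_px,
    )


def make_dataset(
    concentrations_pct: Sequence[float],
    phantoms_per_conc: int,
    positions_mm: Sequence[tuple[float, float]],
    geometry: ScanGeometry,
    excitation: ExcitationSpec,
    sim: SimConfig,
    heterogeneity_scale: float = 0.0,
    seed: int | None = None,
) -> Iterator[RawVolumeSequence]:
    """Yield one sequence per (concentration, phantom, position), lazily.

    The label of each sequence is its phantom's gelatin concentration.
    Randomness is fanned out from ``seed`` (default ``sim.rng_seed``) through
    a spawned stream per phantom and per sequence, so the dataset is
    deterministic regardless of consumption order.
    """
    if not concentrations_pct or not positions_mm or phantoms_per_conc < 1:
        raise ConfigurationError("need >= 1 concentration, position and phantom")
    base = int(sim.rng_seed if seed is None else seed)
    seen_ids: set[str] = set()
    for ci, conc in enumerate(concentrations_pct):
        for pi in range(phantoms_per_conc):
            # one stream per phantom (stiffness jitter), one per sequence
            phantom_rng = np.random.default_rng(np.random.SeedSequence([base, ci, pi]))
            phantom = make_phantom(
                conc,
                phantom_id=f"c{conc:05.2f}_p{pi}",
                heterogeneity_scale=heterogeneity_scale,
                rng=phantom_rng if heterogeneity_scale > 0 else None,
            )
            if phantom.phantom_id in seen_ids:
                raise ConfigurationError(f"duplicate phantom id {phantom.phantom_id}")
            seen_ids.add(phantom.phantom_id)
            for qi, pos in enumerate(positions_mm):
                seq_rng = np.random.default_rng(
                    np.random.SeedSequence([base, ci, pi, qi])
                )
                yield synth_wave_field(
                    phantom, excitation, geometry, sim, pos, rng=seq_rng
                )


@dataclass(frozen=True)
class DeskPreset:
    """Scaled-down study conditions for full-pipeline runs on one CPU.

    Emulates the structure of the phantom study (7 concentrations, continuous
    100 Hz excitation, multiple lateral positions per phantom) at reduced
    spatial sampling: 16 x 16 x 64 voxels over the same 3 x 3 x 2 mm FOV,
    30 volumes per sequence, and a 3 x 3 grid of 9 scan positions around the
    needle. Phase noise of 0.05 rad and 3% relative stiffness jitter per
    phantom stand in for measurement noise and gelatin batch variability.
    """

    geometry: ScanGeometry = ScanGeometry(
        fov_mm=(3.0, 3.0, 2.0), raw_shape_px=(16, 16, 64), volume_rate_hz=831.0,
        n_volumes=30,
    )
    excitation: ExcitationSpec = ExcitationSpec(
        frequency_hz=100.0, needle_position_mm=(0.0, 0.0), amplitude_nm=100.0
    )
    sim: SimConfig = SimConfig(
        phase_noise_sd_rad=0.05, surface_depth_px_range=(8, 28)
    )
    concentrations_pct: tuple[float, ...] = STUDY_CONCENTRATIONS_PCT
    phantoms_per_conc: int = 2
    heterogeneity_scale: float = 0.03
    crop_depth_px: int = 32
    target_shape: tuple[int, int, int] = (8, 8, 8)

    @property
    def positions_mm(self) -> tuple[tuple[float, float], ...]:
        offsets = (0.5, 2.0, 3.5)
        return tuple((ox, oy) for ox in offsets for oy in offsets)

    def sequences(self, seed: int) -> Iterator[RawVolumeSequence]:
        return make_dataset(
            list(self.concentrations_pct),
            self.phantoms_per_conc,
            list(self.positions_mm),
            self.geometry,
            self.excitation,
            self.sim,
            heterogeneity_scale=self.heterogeneity_scale,
            seed=seed,
        )


def desk_preset(phantoms_per_conc: int = 2, **overrides) -> DeskPreset:
    """The desk-scale preset; ``phantoms_per_conc=6`` gives the 4/1/1 split."""
    return replace(DeskPreset(), phantoms_per_conc=phantoms_per_conc, **overrides)
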