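"""Core domain types for the simulated OCE acquisition.

Conventions: axes are ordered (t, x, y, z) with z the depth axis pointing away
from the scanner; indices are 0-based and ranges half-open; lateral coordinates
are in millimetres in a global frame whose origin is the shear-wave needle
unless stated otherwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

#: Interferometric phase per metre of axial displacement, 4*pi*n/lambda0 for a
#: swept source at 1315 nm in a medium of refractive index 1.35.
DEFAULT_PHASE_SCALE_RAD_PER_M = 4.0 * math.pi * 1.35 / 1315e-9


@dataclass(frozen=True)
class ScanGeometry:
    """Field of view and sampling of one volumetric acquisition.

    The defaults mirror a high-speed swept-source setup scanning a
    3 x 3 x 2 mm volume as 32 x 32 x 470 voxels at 831 volumes per second,
    recording 90 consecutive volumes per position.
    """

    fov_mm: tuple[float, float, float] = (3.0, 3.0, 2.0)
    raw_shape_px: tuple[int, int, int] = (32, 32, 470)
    volume_rate_hz: float = 831.0
    n_volumes: int = 90

    def __post_init__(self) -> None:
        if len(self.fov_mm) != 3 or len(self.raw_shape_px) != 3:
            raise ConfigurationError("fov_mm and raw_shape_px must have 3 axes")
        if any(e <= 0 for e in self.fov_mm):
            raise ConfigurationError(f"non-positive FOV extent: {self.fov_mm}")
        if any(int(n) != n or n <= 0 for n in self.raw_shape_px):
            raise ConfigurationError(f"non-positive voxel count: {self.raw_shape_px}")
        if self.volume_rate_hz <= 0:
            raise ConfigurationError("volume_rate_hz must be > 0")
        if self.n_volumes <= 0:
            raise ConfigurationError("n_volumes must be > 0")

    @property
    def pitch_mm(self) -> tuple[float, float, float]:
        """Voxel pitch per axis (mm)."""
        p = tuple(f / n for f, n in zip(self.fov_mm, self.raw_shape_px))
        if not all(np.isfinite(p)) or any(v <= 0 for v in p):
            raise ConfigurationError(f"invalid voxel pitch {p}")
        return p

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each volume (s), first volume at t = 0."""
        return np.arange(self.n_volumes) / self.volume_rate_hz


@dataclass(frozen=True)
class ExcitationSpec:
    """Continuous harmonic excitation applied through a needle line source."""

    frequency_hz: float = 100.0
    needle_position_mm: tuple[float, float] = (0.0, 0.0)
    #: peak axial displacement at the 1 mm reference distance
    amplitude_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ConfigurationError("frequency_hz must be > 0")
        if self.amplitude_nm < 0:
            raise ConfigurationError("amplitude_nm must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """A gelatin phantom with known mechanical ground truth.

    ``shear_speed_m_s`` must equal ``sqrt(E / (3 rho))`` (incompressible
    medium, E in Pa); the constructor enforces this to machine precision.
    """

    concentration_pct: float
    youngs_modulus_kpa: float
    phantom_id: str
    density_kg_m3: float = 1000.0
    shear_speed_m_s: float = field(default=None)  # type: ignore[assignment]
    heterogeneity_scale: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.concentration_pct <= 100.0:
            raise ConfigurationError(
                f"concentration must be in (0, 100]: {self.concentration_pct}"
            )
        if self.youngs_modulus_kpa <= 0:
            raise ConfigurationError("youngs_modulus_kpa must be > 0")
        if self.density_kg_m3 <= 0:
            raise ConfigurationError("density_kg_m3 must be > 0")
        if self.heterogeneity_scale < 0:
            raise ConfigurationError("heterogeneity_scale must be >= 0")
        expected = math.sqrt(self.youngs_modulus_kpa * 1e3 / (3.0 * self.density_kg_m3))
        if self.shear_speed_m_s is None:
            object.__setattr__(self, "shear_speed_m_s", expected)
        elif not math.isclose(self.shear_speed_m_s, expected, rel_tol=1e-12):
            raise ConfigurationError(
                f"shear_speed_m_s={self.shear_speed_m_s} inconsistent with "
                f"sqrt(E/(3 rho))={expected}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic acquisition that the physics does not fix."""

    phase_scale_rad_per_m: float = DEFAULT_PHASE_SCALE_RAD_PER_M
    phase_noise_sd_rad: float = 0.0
    surface_depth_px_range: tuple[int, int] = (60, 180)
    geometric_decay_exponent: float = 0.5
    attenuation_np_per_mm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_scale_rad_per_m <= 0:
            raise ConfigurationError("phase_scale_rad_per_m must be > 0")
        if self.phase_noise_sd_rad < 0:
            raise ConfigurationError("phase_noise_sd_rad must be >= 0")
        lo, hi = self.surface_depth_px_range
        if not (0 <= lo <= hi):
            raise ConfigurationError(
                f"invalid surface_depth_px_range {self.surface_depth_px_range}"
            )
        if self.attenuation_np_per_mm < 0:
            raise ConfigurationError("attenuation_np_per_mm must be >= 0")

    def validate_against(self, geometry: ScanGeometry, crop_depth_px: int = 250) -> None:
        """Check the surface-depth range leaves ``crop_depth_px`` voxels below."""
        z = geometry.raw_shape_px[2]
        lo, hi = self.surface_depth_px_range
        if hi + crop_depth_px > z:
            raise ConfigurationError(
                f"surface depth up to {hi} px leaves fewer than {crop_depth_px} px "
                f"of the {z} px depth axis"
            )


@dataclass
class RawVolumeSequence:
    """A time-ordered stack of (intensity, wrapped phase) volumes.

    ``position_mm`` is the lateral offset of the FOV corner relative to the
    needle. Phase values lie in (-pi, pi].
    """

    intensity: np.ndarray  # (T, X, Y, Z), non-negative
    phase_rad: np.ndarray  # (T, X, Y, Z), wrapped to (-pi, pi]
    geometry: ScanGeometry
    position_mm: tuple[float, float]
    phantom: PhantomSpec
    surface_depth_px: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.intensity.shape != self.phase_rad.shape:
            raise DataError(
                f"intensity shape {self.intensity.shape} != phase shape "
                f"{self.phase_rad.shape}"
            )
        expected = (self.geometry.n_volumes, *self.geometry.raw_shape_px)
        if self.phase_rad.shape != expected:
            raise DataError(
                f"sequence shape {self.phase_rad.shape} does not match geometry "
                f"{expected}"
            )

    @property
    def sequence_id(self) -> str:
        px, py = self.position_mm
        return f"{self.phantom.phantom_id}@x{px:+.3f}y{py:+.3f}"

    @property
    def label_pct(self) -> float:
        return self.phantom.concentration_pct


def wrap_phase(phase: np.ndarray | float) -> np.ndarray:
    """Wrap phase values to the half-open interval (-pi, pi]."""
    out = np.mod(np.asarray(phase) + np.pi, 2.0 * np.pi) - np.pi
    # mod yields [-pi, pi); move the lower boundary to +pi
    return np.where(out == -np.pi, np.pi, out)
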