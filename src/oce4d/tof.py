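"""Classical two-position time-of-flight shear-wave-speed estimation.

The conventional approach to wave-based elastography: observe the wave at two
positions a known distance apart along its propagation direction, estimate the
travel-time delay, and divide. Here the probe signals are depth-averaged
unwrapped-phase time traces, the delay is the argmax of their normalized
cross-correlation restricted to lags consistent with a physiological speed
prior, and sub-sample resolution comes from maximizing a cubic-spline
interpolant of the correlation. Because the excitation is continuous and
harmonic, the admissible-lag window is what resolves the period ambiguity.

This estimator doubles as the physics oracle for the simulator: on noiseless
synthetic data it must recover sqrt(E / (3 rho)).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.signal import correlate

from .errors import ClampedRangeWarning, ConfigurationError, UnreliableEstimateError
from .preprocess import PhaseSequence, crop_depth, detect_surface, unwrap_temporal
from .simulate import elasticity_to_concentration
from .types import RawVolumeSequence, ScanGeometry

import warnings

#: Physiological prior on soft-tissue shear-wave speed (m/s); resolves the
#: lag ambiguity of the continuous harmonic excitation.
SPEED_PRIOR_M_S = (0.5, 10.0)

QUALITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class SpeedEstimate:
    """A two-position travel-time estimate of the shear-wave speed."""

    speed_m_s: float
    lag_s: float
    separation_mm: float
    quality: float  # peak normalized cross-correlation in [0, 1]
    lag_samples_int: int  # integer-sample lag before sub-sample refinement


def _normalized_xcorr(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased normalized cross-correlation of zero-mean copies of a and b.

    Each lag is normalized by its overlap length, removing the triangular
    taper of the raw correlation (which would bias the peak toward zero lag).
    Positive lags mean b is delayed relative to a.
    """
    n = a.size
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.mean(a**2) * np.mean(b**2))
    if denom == 0:
        raise UnreliableEstimateError("a probe trace is constant")
    lags = np.arange(-(n - 1), b.size)
    overlap = np.minimum(n - np.abs(lags), n)
    r = correlate(b, a, mode="full") / (denom * np.maximum(overlap, n // 4))
    return lags, r


def estimate_lag(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    fs_hz: float,
    lag_window_s: tuple[float, float],
) -> tuple[int, float, float]:
    """(integer lag, refined lag in samples, quality) within the window.

    The coarse lag is the argmax of the normalized cross-correlation over
    integer lags inside the window; refinement maximizes a cubic-spline
    interpolant of the correlation within one sample of the coarse peak.
    """
    lags, r = _normalized_xcorr(trace_a, trace_b)
    lo = lag_window_s[0] * fs_hz
    hi = lag_window_s[1] * fs_hz
    sel = (lags >= np.floor(lo)) & (lags <= np.ceil(hi))
    if not np.any(sel):
        raise UnreliableEstimateError(
            f"no admissible lag in window {lag_window_s} s at {fs_hz} Hz"
        )
    sel_lags = lags[sel]
    sel_r = r[sel]
    k = int(np.argmax(sel_r))
    int_lag = int(sel_lags[k])
    spline = CubicSpline(lags.astype(float), r)
    lo_b = max(int_lag - 1, lags[0])
    hi_b = min(int_lag + 1, lags[-1])
    res = minimize_scalar(
        lambda t: -spline(t), bounds=(lo_b, hi_b), method="bounded",
        options={"xatol": 1e-6},
    )
    refined = float(np.clip(res.x, max(lo, lo_b), min(hi, hi_b)))
    quality = float(np.clip(spline(refined), 0.0, 1.0))
    return int_lag, refined, quality


def _probe_trace(
    phase_unwrapped: np.ndarray, ix: int, iy: int
) -> np.ndarray:
    """Depth-averaged time trace over the middle third of the depth axis."""
    nz = phase_unwrapped.shape[-1]
    z0, z1 = nz // 3, max(2 * nz // 3, nz // 3 + 1)
    return phase_unwrapped[:, ix, iy, z0:z1].mean(axis=-1)


def _probe_index(
    geometry: ScanGeometry,
    shape: tuple[int, int],
    position_mm: tuple[float, float],
    probe_mm: tuple[float, float],
) -> tuple[int, int]:
    """Nearest (x, y) voxel of a global-frame lateral coordinate."""
    fx, fy = geometry.fov_mm[0], geometry.fov_mm[1]
    nx, ny = shape
    ix = int(round((probe_mm[0] - position_mm[0]) / (fx / nx) - 0.5))
    iy = int(round((probe_mm[1] - position_mm[1]) / (fy / ny) - 0.5))
    if not (0 <= ix < nx and 0 <= iy < ny):
        raise ConfigurationError(f"probe {probe_mm} mm lies outside the FOV")
    return ix, iy


def estimate_shear_speed(
    sequence: RawVolumeSequence | PhaseSequence,
    source_position_mm: tuple[float, float],
    probe_pair_mm: tuple[tuple[float, float], tuple[float, float]],
    geometry: ScanGeometry | None = None,
    position_mm: tuple[float, float] | None = None,
    crop_depth_px: int | None = None,
    speed_prior_m_s: tuple[float, float] = SPEED_PRIOR_M_S,
    ray_tolerance_deg: float = 5.0,
) -> SpeedEstimate:
    """Estimate the shear-wave speed from two probe positions on a source ray.

    Probe coordinates are lateral positions (mm) in the global needle frame;
    both must lie inside the FOV and on a common ray from the source (within
    ``ray_tolerance_deg``), the far probe second. Raises
    :class:`UnreliableEstimateError` when the delay is non-positive or the
    peak correlation falls below 0.5.
    """
    if isinstance(sequence, RawVolumeSequence):
        geometry = sequence.geometry
        position_mm = sequence.position_mm
        surface = detect_surface(sequence.intensity.mean(axis=0))
        nz = geometry.raw_shape_px[2]
        depth = crop_depth_px if crop_depth_px is not None else min(250, nz - surface)
        phase = unwrap_temporal(crop_depth(sequence.phase_rad, surface, depth))
        lateral_shape = geometry.raw_shape_px[:2]
    else:
        if geometry is None or position_mm is None:
            raise ConfigurationError(
                "PhaseSequence input needs explicit geometry and position_mm"
            )
        phase = sequence.phase_unwrapped_rad
        lateral_shape = phase.shape[1:3]
    if phase.shape[0] < 4:
        raise ConfigurationError("need several volumes to correlate")

    p1, p2 = (np.asarray(p, dtype=float) for p in probe_pair_mm)
    s = np.asarray(source_position_mm, dtype=float)
    v1, v2 = p1 - s, p2 - s
    r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if r1 == 0 or r2 == 0:
        raise ConfigurationError("probes must not coincide with the source")
    cosang = float(np.clip(np.dot(v1, v2) / (r1 * r2), -1.0, 1.0))
    if np.degrees(np.arccos(cosang)) > ray_tolerance_deg:
        raise ConfigurationError("probes are not on a common ray from the source")
    if r2 <= r1:
        raise ConfigurationError("second probe must be farther from the source")
    separation_mm = float(np.linalg.norm(p2 - p1))
    if separation_mm == 0:
        raise ConfigurationError("probe separation must be positive")

    ia = _probe_index(geometry, lateral_shape, position_mm, tuple(p1))
    ib = _probe_index(geometry, lateral_shape, position_mm, tuple(p2))
    ta = _probe_trace(phase, *ia)
    tb = _probe_trace(phase, *ib)

    lag_window = (
        separation_mm * 1e-3 / speed_prior_m_s[1],
        separation_mm * 1e-3 / speed_prior_m_s[0],
    )
    fs = geometry.volume_rate_hz
    int_lag, refined, quality = estimate_lag(ta, tb, fs, lag_window)
    lag_s = refined / fs
    if lag_s <= 0:
        raise UnreliableEstimateError(f"non-positive delay {lag_s} s")
    if quality < QUALITY_THRESHOLD:
        raise UnreliableEstimateError(f"peak correlation {quality:.3f} < 0.5")
    return SpeedEstimate(
        speed_m_s=separation_mm * 1e-3 / lag_s,
        lag_s=lag_s,
        separation_mm=separation_mm,
        quality=quality,
        lag_samples_int=int_lag,
    )


def speed_to_concentration(speed_m_s: float, rho_kg_m3: float = 1000.0) -> float:
    """Map a shear speed back to a gelatin concentration (percent).

    Inverts c_s = sqrt(E / (3 rho)) and the calibrated power law E(c). Values
    implying a concentration outside (0, 100] are clamped, with a
    :class:`ClampedRangeWarning`.
    """
    if speed_m_s <= 0:
        raise ConfigurationError("speed must be > 0")
    e_kpa = 3.0 * rho_kg_m3 * speed_m_s**2 / 1e3
    c = float(elasticity_to_concentration(e_kpa))
    if c > 100.0 or c <= 0.0:
        warnings.warn(
            f"implied concentration {c:.2f}% outside (0, 100]; clamped",
            ClampedRangeWarning,
        )
        c = min(max(c, np.nextafter(0.0, 1.0)), 100.0)
    return c
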