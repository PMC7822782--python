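"""Raw sequence -> network-ready unwrapped phase tensor.

The chain is: detect the phantom surface as an intensity peak on the
temporal-mean volume, crop a fixed number of voxels beneath it along depth,
unwrap the phase temporally per voxel, and resize each volume to the network
input shape by trilinear interpolation. No other processing is applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .errors import CropError, DataError, SurfaceDetectionError
from .types import RawVolumeSequence, ScanGeometry

DEFAULT_CROP_DEPTH_PX = 250
DEFAULT_TARGET_SHAPE = (32, 32, 32)


@dataclass
class PhaseSequence:
    """Preprocessed, temporally unwrapped phase ready for the regressor."""

    phase_unwrapped_rad: np.ndarray  # (T, *target_shape)
    surface_index_px: int
    source_geometry: ScanGeometry
    label_pct: float | None = None
    position_mm: tuple[float, float] | None = None
    phantom_id: str | None = None

    @property
    def n_volumes(self) -> int:
        return self.phase_unwrapped_rad.shape[0]


def detect_surface(intensity_volume: np.ndarray, smooth_px: int = 5) -> int:
    """Locate the phantom surface depth in an (X, Y, Z) intensity volume.

    Each A-scan is smoothed along depth with a boxcar of ``smooth_px`` voxels
    and its argmax taken (ties resolved toward smaller depth); the per-scan
    indices are aggregated with the lower median, giving one integer surface
    index per volume.
    """
    vol = np.asarray(intensity_volume)
    if vol.ndim != 3 or vol.size == 0:
        raise SurfaceDetectionError(f"expected a non-empty 3D volume, got {vol.shape}")
    if not np.all(np.isfinite(vol)):
        raise SurfaceDetectionError("intensity volume contains non-finite values")
    if not np.any(vol):
        raise SurfaceDetectionError("intensity volume is identically zero")
    smoothed = uniform_filter1d(vol.astype(float), size=smooth_px, axis=-1, mode="nearest")
    idx = np.argmax(smoothed, axis=-1).ravel()  # argmax: first occurrence = shallower
    idx.sort()
    return int(idx[(idx.size - 1) // 2])  # lower median


def crop_depth(
    volume: np.ndarray, surface: int, depth_px: int = DEFAULT_CROP_DEPTH_PX
) -> np.ndarray:
    """Keep ``depth_px`` voxels at depths [surface, surface + depth_px).

    Works on any array whose last axis is depth (a single volume or a whole
    sequence).
    """
    z = volume.shape[-1]
    if surface < 0 or depth_px <= 0:
        raise CropError(f"invalid surface={surface} or depth_px={depth_px}")
    if surface + depth_px > z:
        raise CropError(
            f"cannot crop {depth_px} px below surface {surface}: depth axis has "
            f"{z} px, short by {surface + depth_px - z}"
        )
    return volume[..., surface : surface + depth_px]


def unwrap_temporal(phase: np.ndarray) -> np.ndarray:
    """Unwrap phase along the leading (time) axis, per voxel.

    out[0] = in[0]; out[t] = out[t-1] + wrap_to_pi(in[t] - in[t-1]), so
    consecutive differences never exceed pi in magnitude and frame t depends
    only on frames <= t.
    """
    arr = np.asarray(phase)
    if arr.shape[0] < 1:
        raise DataError("need at least one frame")
    if not np.all(np.isfinite(arr)):
        raise DataError("phase contains non-finite values")
    return np.unwrap(arr.astype(float, copy=False), axis=0)


def resize_volume(volume: np.ndarray, target: tuple[int, int, int] = DEFAULT_TARGET_SHAPE) -> np.ndarray:
    """Trilinearly resample an (X, Y, Z) volume onto ``target``.

    Sample points are placed at ``linspace(0, n-1, m)`` per axis, so constants
    and per-axis linear ramps are reproduced exactly.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3 or any(e <= 0 for e in vol.shape):
        raise DataError(f"expected a 3D volume, got shape {vol.shape}")
    axes = [np.linspace(0.0, n - 1.0, m) for n, m in zip(vol.shape, target)]
    grid = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(vol, np.stack(grid), order=1, mode="nearest")


def resize_sequence(sequence: np.ndarray, target: tuple[int, int, int] = DEFAULT_TARGET_SHAPE) -> np.ndarray:
    """Apply :func:`resize_volume` to every frame of a (T, X, Y, Z) stack."""
    return np.stack([resize_volume(frame, target) for frame in sequence])


def preprocess_sequence(
    raw: RawVolumeSequence,
    depth_px: int = DEFAULT_CROP_DEPTH_PX,
    target: tuple[int, int, int] = DEFAULT_TARGET_SHAPE,
    subtract_temporal_mean: bool = False,
) -> PhaseSequence:
    """Run the full preprocessing chain on one raw sequence.

    The surface is detected once on the temporal-mean intensity volume and the
    same crop offset reused for all frames; unwrapping precedes resizing
    because interpolating wrapped phase across a 2 pi discontinuity is
    meaningless. Setting ``subtract_temporal_mean`` removes the static phase
    baseline per voxel (off by default: the wave signal alone is the input).
    """
    surface = detect_surface(raw.intensity.mean(axis=0))
    cropped = crop_depth(raw.phase_rad, surface, depth_px)
    unwrapped = unwrap_temporal(cropped)
    if subtract_temporal_mean:
        unwrapped = unwrapped - unwrapped.mean(axis=0, keepdims=True)
    resized = resize_sequence(unwrapped, target).astype(np.float32)
    return PhaseSequence(
        phase_unwrapped_rad=resized,
        surface_index_px=surface,
        source_geometry=raw.geometry,
        label_pct=raw.label_pct,
        position_mm=raw.position_mm,
        phantom_id=raw.phantom.phantom_id,
    )
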