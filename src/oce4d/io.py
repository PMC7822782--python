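"""Persistence of raw and preprocessed sequence collections.

HDF5 layout: one group per sequence under ``/sequences/<id>`` holding the
``intensity`` and ``phase`` (raw) or ``phase_unwrapped`` (preprocessed)
datasets, with geometry, phantom, position and seed metadata as attributes.
Files ending in ``.npz`` use a flat fallback layout with the same keys. All
float arrays are stored at 32-bit; metadata at full precision.
"""
from __future__ import annotations

import json
from collections.abc import Iterable
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError, SchemaError
from .preprocess import PhaseSequence
from .types import PhantomSpec, RawVolumeSequence, ScanGeometry


def _geometry_attrs(g: ScanGeometry) -> dict:
    return {
        "fov_mm": list(g.fov_mm),
        "raw_shape_px": list(g.raw_shape_px),
        "volume_rate_hz": g.volume_rate_hz,
        "n_volumes": g.n_volumes,
    }


def _geometry_from_attrs(a: dict) -> ScanGeometry:
    return ScanGeometry(
        fov_mm=tuple(float(v) for v in a["fov_mm"]),
        raw_shape_px=tuple(int(v) for v in a["raw_shape_px"]),
        volume_rate_hz=float(a["volume_rate_hz"]),
        n_volumes=int(a["n_volumes"]),
    )


def _phantom_attrs(p: PhantomSpec) -> dict:
    return {
        "concentration_pct": p.concentration_pct,
        "youngs_modulus_kpa": p.youngs_modulus_kpa,
        "density_kg_m3": p.density_kg_m3,
        "phantom_id": p.phantom_id,
        "heterogeneity_scale": p.heterogeneity_scale,
    }


def _phantom_from_attrs(a: dict) -> PhantomSpec:
    return PhantomSpec(
        concentration_pct=float(a["concentration_pct"]),
        youngs_modulus_kpa=float(a["youngs_modulus_kpa"]),
        density_kg_m3=float(a["density_kg_m3"]),
        phantom_id=str(a["phantom_id"]),
        heterogeneity_scale=float(a["heterogeneity_scale"]),
    )


def save_sequences(
    collection: Iterable[RawVolumeSequence],
    path: str | Path,
    config_hash: str | None = None,
) -> int:
    """Write raw sequences; returns the number written.

    Raises :class:`ConfigurationError` on duplicate sequence ids.
    """
    path = Path(path)
    if path.suffix == ".npz":
        return _save_npz(collection, path, config_hash)
    seen: set[str] = set()
    n = 0
    with h5py.File(path, "w") as f:
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash
        root = f.create_group("sequences")
        for seq in collection:
            sid = seq.sequence_id
            if sid in seen:
                raise ConfigurationError(f"duplicate sequence id {sid}")
            seen.add(sid)
            g = root.create_group(sid)
            g.create_dataset("intensity", data=seq.intensity.astype(np.float32))
            g.create_dataset("phase", data=seq.phase_rad.astype(np.float32))
            for k, v in _geometry_attrs(seq.geometry).items():
                g.attrs[f"geometry/{k}"] = v
            for k, v in _phantom_attrs(seq.phantom).items():
                g.attrs[f"phantom/{k}"] = v
            g.attrs["position_mm"] = list(seq.position_mm)
            if seq.surface_depth_px is not None:
                g.attrs["surface_depth_px"] = seq.surface_depth_px
            if seq.seed is not None:
                g.attrs["seed"] = seq.seed
            n += 1
    return n


def load_sequences(path: str | Path) -> list[RawVolumeSequence]:
    path = Path(path)
    if path.suffix == ".npz":
        return _load_npz(path)
    out: list[RawVolumeSequence] = []
    with h5py.File(path, "r") as f:
        if "sequences" not in f:
            raise SchemaError("file has no /sequences group")
        for sid in sorted(f["sequences"]):
            g = f["sequences"][sid]
            for key in ("intensity", "phase"):
                if key not in g:
                    raise SchemaError(f"sequence {sid} is missing dataset '{key}'")
            attrs = dict(g.attrs)
            geometry = _geometry_from_attrs(
                {k.split("/", 1)[1]: attrs[k] for k in attrs if k.startswith("geometry/")}
            )
            phantom = _phantom_from_attrs(
                {k.split("/", 1)[1]: attrs[k] for k in attrs if k.startswith("phantom/")}
            )
            out.append(
                RawVolumeSequence(
                    intensity=g["intensity"][()],
                    phase_rad=g["phase"][()],
                    geometry=geometry,
                    position_mm=tuple(float(v) for v in attrs["position_mm"]),
                    phantom=phantom,
                    surface_depth_px=(
                        int(attrs["surface_depth_px"])
                        if "surface_depth_px" in attrs
                        else None
                    ),
                    seed=int(attrs["seed"]) if "seed" in attrs else None,
                )
            )
    return out


def _save_npz(collection, path: Path, config_hash: str | None) -> int:
    arrays: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    n = 0
    for seq in collection:
        sid = seq.sequence_id
        if f"{sid}/phase" in arrays:
            raise ConfigurationError(f"duplicate sequence id {sid}")
        arrays[f"{sid}/intensity"] = seq.intensity.astype(np.float32)
        arrays[f"{sid}/phase"] = seq.phase_rad.astype(np.float32)
        meta[sid] = {
            "geometry": _geometry_attrs(seq.geometry),
            "phantom": _phantom_attrs(seq.phantom),
            "position_mm": list(seq.position_mm),
            "surface_depth_px": seq.surface_depth_px,
            "seed": seq.seed,
        }
        n += 1
    header = {"sequences": meta, "config_hash": config_hash}
    np.savez_compressed(
        path, __meta__=np.frombuffer(json.dumps(header).encode(), np.uint8), **arrays
    )
    return n


def _load_npz(path: Path) -> list[RawVolumeSequence]:
    out = []
    with np.load(path) as npz:
        if "__meta__" not in npz.files:
            raise SchemaError("npz file has no __meta__ record")
        header = json.loads(bytes(npz["__meta__"]).decode())
        for sid, m in sorted(header["sequences"].items()):
            for key in ("intensity", "phase"):
                if f"{sid}/{key}" not in npz.files:
                    raise SchemaError(f"sequence {sid} is missing dataset '{key}'")
            out.append(
                RawVolumeSequence(
                    intensity=npz[f"{sid}/intensity"],
                    phase_rad=npz[f"{sid}/phase"],
                    geometry=_geometry_from_attrs(m["geometry"]),
                    phantom=_phantom_from_attrs(m["phantom"]),
                    position_mm=tuple(m["position_mm"]),
                    surface_depth_px=m.get("surface_depth_px"),
                    seed=m.get("seed"),
                )
            )
    return out


def save_phase_sequences(
    collection: Iterable[PhaseSequence], path: str | Path, config_hash: str | None = None
) -> int:
    """Write preprocessed phase sequences (``/sequences/<id>/phase_unwrapped``)."""
    path = Path(path)
    n = 0
    seen: set[str] = set()
    with h5py.File(path, "w") as f:
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash
        root = f.create_group("sequences")
        for i, seq in enumerate(collection):
            sid = (
                f"{seq.phantom_id}@x{seq.position_mm[0]:+.3f}y{seq.position_mm[1]:+.3f}"
                if seq.phantom_id is not None and seq.position_mm is not None
                else f"seq{i:05d}"
            )
            if sid in seen:
                raise ConfigurationError(f"duplicate sequence id {sid}")
            seen.add(sid)
            g = root.create_group(sid)
            g.create_dataset(
                "phase_unwrapped", data=seq.phase_unwrapped_rad.astype(np.float32)
            )
            g.attrs["surface_index_px"] = seq.surface_index_px
            for k, v in _geometry_attrs(seq.source_geometry).items():
                g.attrs[f"geometry/{k}"] = v
            if seq.label_pct is not None:
                g.attrs["label_pct"] = seq.label_pct
            if seq.position_mm is not None:
                g.attrs["position_mm"] = list(seq.position_mm)
            if seq.phantom_id is not None:
                g.attrs["phantom_id"] = seq.phantom_id
            n += 1
    return n


def load_phase_sequences(path: str | Path) -> list[PhaseSequence]:
    out = []
    with h5py.File(path, "r") as f:
        if "sequences" not in f:
            raise SchemaError("file has no /sequences group")
        for sid in sorted(f["sequences"]):
            g = f["sequences"][sid]
            if "phase_unwrapped" not in g:
                raise SchemaError(f"sequence {sid} is missing dataset 'phase_unwrapped'")
            attrs = dict(g.attrs)
            geometry = _geometry_from_attrs(
                {k.split("/", 1)[1]: attrs[k] for k in attrs if k.startswith("geometry/")}
            )
            out.append(
                PhaseSequence(
                    phase_unwrapped_rad=g["phase_unwrapped"][()],
                    surface_index_px=int(attrs["surface_index_px"]),
                    source_geometry=geometry,
                    label_pct=float(attrs["label_pct"]) if "label_pct" in attrs else None,
                    position_mm=(
                        tuple(float(v) for v in attrs["position_mm"])
                        if "position_mm" in attrs
                        else None
                    ),
                    phantom_id=str(attrs["phantom_id"]) if "phantom_id" in attrs else None,
                )
            )
    return out


def read_config_hash(path: str | Path) -> str | None:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            header = json.loads(bytes(npz["__meta__"]).decode())
        return header.get("config_hash")
    with h5py.File(path, "r") as f:
        v = f.attrs.get("config_hash")
    return None if v is None else str(v)
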