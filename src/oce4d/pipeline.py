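"""End-to-end orchestration: simulate -> preprocess -> split -> train -> evaluate.

A single global seed fans out to per-stage seeds through a counter-based
scheme (``SeedSequence([seed, stage_counter])``), so every stage is
independently reproducible. Artifacts carry a hash of the configuration that
produced them; resuming from a preprocessing artifact with a different hash is
refused.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .io import load_phase_sequences, read_config_hash, save_phase_sequences
from .net4d import ModelSpec, build_model, save_checkpoint
from .preprocess import preprocess_sequence
from .simulate import STUDY_CONCENTRATIONS_PCT, DeskPreset, desk_preset, make_dataset
from .training import SplitSpec, TrainConfig, evaluate, split_by_phantom, train
from .types import ExcitationSpec, ScanGeometry, SimConfig

_STAGE = {"simulate": 0, "split": 1, "train": 2}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "run"
    phantoms_per_conc: int = 6
    concentrations_pct: tuple[float, ...] = STUDY_CONCENTRATIONS_PCT
    geometry: ScanGeometry = field(default_factory=lambda: DeskPreset().geometry)
    excitation: ExcitationSpec = field(default_factory=lambda: DeskPreset().excitation)
    sim: SimConfig = field(default_factory=lambda: DeskPreset().sim)
    positions_mm: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: DeskPreset().positions_mm
    )
    heterogeneity_scale: float = DeskPreset().heterogeneity_scale
    crop_depth_px: int = DeskPreset().crop_depth_px
    target_shape: tuple[int, int, int] = DeskPreset().target_shape
    subtract_temporal_mean: bool = False
    model: ModelSpec | None = None
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    #: None -> single-crop plus the largest available ordered-crop count
    eval_n_crops: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.sim.validate_against(self.geometry, self.crop_depth_px)
        if self.train_cfg.sequence_length > self.geometry.n_volumes:
            raise ConfigurationError(
                f"sequence_length {self.train_cfg.sequence_length} exceeds "
                f"n_volumes {self.geometry.n_volumes}"
            )
        if self.split.total > self.phantoms_per_conc:
            raise ConfigurationError(
                f"split needs {self.split.total} phantoms per concentration, "
                f"dataset has {self.phantoms_per_conc}"
            )
        max_crops = self.geometry.n_volumes // self.train_cfg.sequence_length
        if self.eval_n_crops is None:
            self.eval_n_crops = (1,) if max_crops == 1 else (1, max_crops)
        if any(n < 1 or n > max_crops for n in self.eval_n_crops):
            raise ConfigurationError(
                f"eval_n_crops {self.eval_n_crops} outside [1, {max_crops}]"
            )
        if self.model is None:
            self.model = ModelSpec(
                input_shape=(self.train_cfg.sequence_length, *self.target_shape),
                stem_channels=6,
                growth_rate=6,
            )

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "phantoms_per_conc": self.phantoms_per_conc,
            "concentrations_pct": list(self.concentrations_pct),
            "geometry": asdict(self.geometry),
            "excitation": asdict(self.excitation),
            "sim": asdict(self.sim),
            "positions_mm": [list(p) for p in self.positions_mm],
            "heterogeneity_scale": self.heterogeneity_scale,
            "crop_depth_px": self.crop_depth_px,
            "target_shape": list(self.target_shape),
            "subtract_temporal_mean": self.subtract_temporal_mean,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        kwargs: dict = {}
        for key in ("seed", "outdir", "phantoms_per_conc", "heterogeneity_scale",
                    "crop_depth_px", "subtract_temporal_mean"):
            if key in raw:
                kwargs[key] = raw[key]
        if "concentrations_pct" in raw:
            kwargs["concentrations_pct"] = tuple(raw["concentrations_pct"])
        if "positions_mm" in raw:
            kwargs["positions_mm"] = tuple(tuple(p) for p in raw["positions_mm"])
        if "target_shape" in raw:
            kwargs["target_shape"] = tuple(raw["target_shape"])
        for key, cls_ in (
            ("geometry", ScanGeometry),
            ("excitation", ExcitationSpec),
            ("sim", SimConfig),
            ("split", SplitSpec),
        ):
            if key in raw:
                d = dict(raw[key])
                for tup_key in ("fov_mm", "raw_shape_px", "needle_position_mm",
                                "surface_depth_px_range"):
                    if tup_key in d:
                        d[tup_key] = tuple(d[tup_key])
                kwargs[key] = cls_(**d)
        if "train" in raw:
            kwargs["train_cfg"] = TrainConfig(**raw["train"])
        if "model" in raw:
            d = dict(raw["model"])
            if "input_shape" in d:
                d["input_shape"] = tuple(d["input_shape"])
            kwargs["model"] = ModelSpec(**d)
        if "eval_n_crops" in raw:
            kwargs["eval_n_crops"] = tuple(raw["eval_n_crops"])
        return cls(**kwargs)


def desk_run_config(seed: int, outdir: str = "run", phantoms_per_conc: int = 6,
                    **overrides) -> RunConfig:
    """The desk-scale study configuration (see :class:`DeskPreset`).

    Unlike the full-scale default, the desk study subtracts the per-voxel
    temporal mean during preprocessing: at this reduced scale the static
    speckle phase baseline otherwise dominates the input variance and a
    small network memorizes sequences instead of learning the wave.
    """
    preset = desk_preset(phantoms_per_conc=phantoms_per_conc)
    kwargs = dict(
        subtract_temporal_mean=True,
        seed=seed,
        outdir=outdir,
        phantoms_per_conc=phantoms_per_conc,
        geometry=preset.geometry,
        excitation=preset.excitation,
        sim=preset.sim,
        positions_mm=preset.positions_mm,
        heterogeneity_scale=preset.heterogeneity_scale,
        crop_depth_px=preset.crop_depth_px,
        target_shape=preset.target_shape,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def simulate_and_preprocess(config: RunConfig, phases_path: Path, verbose=False):
    """Stream the synthetic dataset through preprocessing and persist it."""
    sim_seed = stage_seed(config.seed, "simulate")

    def phase_iter():
        for raw in make_dataset(
            list(config.concentrations_pct),
            config.phantoms_per_conc,
            list(config.positions_mm),
            config.geometry,
            config.excitation,
            config.sim,
            heterogeneity_scale=config.heterogeneity_scale,
            seed=sim_seed,
        ):
            yield preprocess_sequence(
                raw,
                depth_px=config.crop_depth_px,
                target=config.target_shape,
                subtract_temporal_mean=config.subtract_temporal_mean,
            )

    n = save_phase_sequences(phase_iter(), phases_path, config.config_hash())
    if verbose:
        print(f"wrote {n} preprocessed sequences to {phases_path}")
    return n


def run_pipeline(config: RunConfig, verbose: bool = False) -> dict:
    """Execute all stages; returns (and writes) the metrics report.

    If the preprocessing artifact already exists with a matching config hash,
    simulation and preprocessing are skipped; a mismatched hash aborts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phases_path = outdir / "phases.h5"
    stage = "simulate"
    try:
        if phases_path.exists():
            found = read_config_hash(phases_path)
            if found != config.config_hash():
                raise ConfigurationError(
                    f"existing {phases_path} was produced by config {found}, "
                    f"current hash is {config.config_hash()}; refusing to resume"
                )
            if verbose:
                print(f"reusing {phases_path} (hash {found})")
        else:
            simulate_and_preprocess(config, phases_path, verbose)
        dataset = load_phase_sequences(phases_path)

        stage = "split"
        split = SplitSpec(
            train_phantoms_per_conc=config.split.train_phantoms_per_conc,
            val_phantoms_per_conc=config.split.val_phantoms_per_conc,
            test_phantoms_per_conc=config.split.test_phantoms_per_conc,
            rng_seed=stage_seed(config.seed, "split"),
        )
        parts = split_by_phantom(dataset, split)

        stage = "train"
        train_cfg = dataclasses.replace(
            config.train_cfg, rng_seed=stage_seed(config.seed, "train")
        )
        model = build_model(config.model, seed=train_cfg.rng_seed)
        history = train(model, parts.train, parts.val, train_cfg, verbose=verbose)
        save_checkpoint(outdir / "best.ckpt.npz", model,
                        extra={"best_val_mae": history.best_val_mae})

        stage = "evaluate"
        report: dict = {
            "provenance": {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE},
                "package_version": __version__,
                "python": platform.python_version(),
                "n_parameters": model.n_parameters,
            },
            "history": {
                "best_val_mae": history.best_val_mae,
                "best_iteration": history.best_iteration,
                "final_train_loss": history.train_loss[-1],
            },
            "metrics": {},
        }
        for n_crops in config.eval_n_crops:
            metrics = evaluate(model, parts.test, n_crops=n_crops,
                               length=config.train_cfg.sequence_length)
            report["metrics"][f"n_crops={n_crops}"] = metrics.to_dict()
            metrics.per_position.to_csv(outdir / f"positions_ncrops{n_crops}.csv")
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except Exception as exc:
        try:
            wrapped = type(exc)(f"pipeline stage '{stage}' failed: {exc}")
        except Exception:
            raise exc
        raise wrapped from exc
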