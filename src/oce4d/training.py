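"""Training protocol, phantom-level splitting, and evaluation metrics.

Training follows the study protocol: 1000 Adam steps on an MSE loss with
batches of 13 subsequences of 10 volumes, each drawn by randomly cropping a
length-10 temporal window from a uniformly sampled training sequence. Data are
split at phantom granularity (all scan positions of a phantom travel
together); evaluation averages predictions over ordered, non-overlapping
temporal crops.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CropError, TrainingDivergedError
from .net4d import Model4D, Param
from .preprocess import PhaseSequence


@dataclass(frozen=True)
class TrainConfig:
    """The optimization protocol: 1000 iterations, batch 13, Adam, MSE."""

    iterations: int = 1000
    batch_size: int = 13
    sequence_length: int = 10
    learning_rate: float = 1e-2
    #: "cosine" anneals the step size to lr_final_factor * learning_rate over
    #: the run, damping the late-training oscillation of a hot constant rate;
    #: "constant" disables annealing.
    lr_schedule: str = "cosine"
    lr_final_factor: float = 0.1
    rng_seed: int = 0
    val_every: int = 50

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.iterations < 1 or self.sequence_length < 1:
            raise ConfigurationError("iterations, batch_size, sequence_length >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ConfigurationError(f"unknown lr_schedule {self.lr_schedule!r}")
        if not 0.0 < self.lr_final_factor <= 1.0:
            raise ConfigurationError("lr_final_factor must be in (0, 1]")

    def lr_at(self, iteration: int) -> float:
        """Learning rate for 1-based ``iteration``."""
        if self.lr_schedule == "constant" or self.iterations == 1:
            return self.learning_rate
        frac = (iteration - 1) / (self.iterations - 1)
        lo = self.lr_final_factor * self.learning_rate
        return lo + 0.5 * (self.learning_rate - lo) * (1 + np.cos(np.pi * frac))


@dataclass(frozen=True)
class SplitSpec:
    """Phantom counts per concentration for the train/val/test partitions."""

    train_phantoms_per_conc: int = 4
    val_phantoms_per_conc: int = 1
    test_phantoms_per_conc: int = 1
    rng_seed: int = 0

    @property
    def total(self) -> int:
        return (
            self.train_phantoms_per_conc
            + self.val_phantoms_per_conc
            + self.test_phantoms_per_conc
        )


@dataclass
class Partitions:
    train: list[PhaseSequence]
    val: list[PhaseSequence]
    test: list[PhaseSequence]


def _phantom_ids(seqs: list[PhaseSequence]) -> set[str]:
    return {s.phantom_id for s in seqs}


def split_by_phantom(dataset: list[PhaseSequence], spec: SplitSpec) -> Partitions:
    """Randomly partition sequences at phantom granularity.

    Every concentration contributes exactly the configured phantom counts to
    each partition; all positions of one phantom land in the same partition.
    Deterministic under ``spec.rng_seed``.
    """
    by_conc: dict[float, dict[str, list[PhaseSequence]]] = {}
    for seq in dataset:
        by_conc.setdefault(seq.label_pct, {}).setdefault(seq.phantom_id, []).append(seq)
    rng = np.random.default_rng(spec.rng_seed)
    train: list[PhaseSequence] = []
    val: list[PhaseSequence] = []
    test: list[PhaseSequence] = []
    for conc in sorted(by_conc):
        phantoms = sorted(by_conc[conc])
        if len(phantoms) != spec.total:
            raise ConfigurationError(
                f"concentration {conc}: {len(phantoms)} phantoms, split needs "
                f"{spec.total}"
            )
        order = rng.permutation(len(phantoms))
        ids = [phantoms[i] for i in order]
        n_tr, n_va = spec.train_phantoms_per_conc, spec.val_phantoms_per_conc
        for pid in ids[:n_tr]:
            train.extend(by_conc[conc][pid])
        for pid in ids[n_tr : n_tr + n_va]:
            val.extend(by_conc[conc][pid])
        for pid in ids[n_tr + n_va :]:
            test.extend(by_conc[conc][pid])
    parts = Partitions(train, val, test)
    leaks = (
        (_phantom_ids(train) & _phantom_ids(val))
        | (_phantom_ids(train) & _phantom_ids(test))
        | (_phantom_ids(val) & _phantom_ids(test))
    )
    assert not leaks, f"phantom ids leak across partitions: {leaks}"
    return parts


def random_temporal_crop(
    sequence: PhaseSequence, length: int, rng: np.random.Generator
) -> np.ndarray:
    """A contiguous length-``length`` window with uniformly random start."""
    t = sequence.n_volumes
    if t < length:
        raise CropError(f"sequence has {t} volumes, need {length}")
    start = int(rng.integers(0, t - length + 1))
    return sequence.phase_unwrapped_rad[start : start + length]


def ordered_crops(sequence: PhaseSequence, length: int) -> list[np.ndarray]:
    """Consecutive non-overlapping windows; the trailing remainder is dropped."""
    t = sequence.n_volumes
    if t < length:
        raise CropError(f"sequence has {t} volumes, need {length}")
    return [
        sequence.phase_unwrapped_rad[i * length : (i + 1) * length]
        for i in range(t // length)
    ]


class Adam:
    """Standard Adam with bias correction."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_mae: list[tuple[int, float]] = field(default_factory=list)
    best_iteration: int = -1
    best_val_mae: float = np.inf


def _batch(
    partition: list[PhaseSequence],
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.integers(0, len(partition), size=config.batch_size)
    crops = [random_temporal_crop(partition[i], config.sequence_length, rng) for i in idx]
    labels = np.array([partition[i].label_pct for i in idx], dtype=np.float32)
    return np.stack(crops), labels


def _val_mae(model: Model4D, partition: list[PhaseSequence], length: int) -> float:
    # all ordered crops per sequence: a less noisy checkpoint-selection signal
    preds = np.array(
        [predict_sequence(model, s, s.n_volumes // length, length)
         for s in partition]
    )
    targets = np.array([s.label_pct for s in partition])
    return float(np.mean(np.abs(preds - targets)))


def train(
    model: Model4D,
    train_partition: list[PhaseSequence],
    val_partition: list[PhaseSequence],
    config: TrainConfig,
    verbose: bool = False,
) -> TrainHistory:
    """Optimize the model in place; the best-validation state is restored.

    Each iteration samples ``batch_size`` training sequences uniformly with
    replacement, crops a random length-10 window from each, and takes one Adam
    step on the MSE between predicted and true concentrations. Validation MAE
    (evaluation mode, single leading crop) is checked every ``val_every``
    steps and the best checkpoint kept.
    """
    if not train_partition or not val_partition:
        raise ConfigurationError("train and val partitions must be non-empty")
    for s in train_partition:
        if s.n_volumes < config.sequence_length:
            raise ConfigurationError(
                f"sequence_length {config.sequence_length} exceeds recorded "
                f"length {s.n_volumes}"
            )
    rng = np.random.default_rng(config.rng_seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    history = TrainHistory()
    best_state = model.copy_state()
    for it in range(1, config.iterations + 1):
        x, y = _batch(train_partition, config, rng)
        model.zero_grad()
        pred = model.forward(x, training=True)
        err = pred - y
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise TrainingDivergedError(f"non-finite training loss at iteration {it}")
        history.train_loss.append(loss)
        model.backward(2.0 * err / err.size)
        opt.lr = config.lr_at(it)
        opt.step()
        if it % config.val_every == 0 or it == config.iterations:
            vmae = _val_mae(model, val_partition, config.sequence_length)
            history.val_mae.append((it, vmae))
            if vmae < history.best_val_mae:
                history.best_val_mae = vmae
                history.best_iteration = it
                best_state = model.copy_state()
            if verbose:
                print(f"iter {it:5d}  train MSE {loss:9.4f}  val MAE {vmae:6.3f}")
    model.load_state_arrays(best_state)
    return history


def predict_sequence(
    model: Model4D, sequence: PhaseSequence, n_crops: int, length: int = 10
) -> float:
    """Mean evaluation-mode prediction over the first ``n_crops`` ordered crops."""
    crops = ordered_crops(sequence, length)
    if n_crops < 1 or n_crops > len(crops):
        raise CropError(f"n_crops={n_crops} not in [1, {len(crops)}]")
    batch = np.stack(crops[:n_crops])
    preds = model.forward(batch, training=False)
    return float(np.mean(preds))


@dataclass
class EvalMetrics:
    """Accuracy summary of a trained regressor on held-out sequences.

    ``rmae`` is the MAE divided by the population standard deviation of the
    distinct target concentrations; ``pcc`` is the Pearson correlation of
    predictions against targets (NaN when predictions are constant).
    """

    mae_pp: float
    mae_sd_pp: float
    rmae: float
    rmae_sd: float
    pcc: float
    n_sequences: int
    per_concentration: pd.DataFrame
    per_position: pd.DataFrame
    predictions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "mae_pp": self.mae_pp,
            "mae_sd_pp": self.mae_sd_pp,
            "rmae": self.rmae,
            "rmae_sd": self.rmae_sd,
            "pcc": self.pcc,
            "n_sequences": self.n_sequences,
            "per_concentration": self.per_concentration.to_dict(orient="list"),
        }


def rmae_from_mae(mae: float, target_concentrations: np.ndarray) -> float:
    """MAE relative to the population SD of the distinct target values."""
    sd = float(np.std(np.unique(np.asarray(target_concentrations, dtype=float))))
    if sd == 0:
        raise ConfigurationError("targets are single-valued; rMAE undefined")
    return mae / sd


def evaluate(
    model: Model4D,
    test_partition: list[PhaseSequence],
    n_crops: int = 1,
    length: int = 10,
) -> EvalMetrics:
    """Per-sequence crop-averaged predictions and the accuracy summary."""
    if not test_partition:
        raise ConfigurationError("test partition is empty")
    rows = []
    for seq in test_partition:
        pred = predict_sequence(model, seq, n_crops, length)
        rows.append(
            {
                "phantom_id": seq.phantom_id,
                "position_x_mm": None if seq.position_mm is None else seq.position_mm[0],
                "position_y_mm": None if seq.position_mm is None else seq.position_mm[1],
                "target_pct": seq.label_pct,
                "prediction_pct": float(np.clip(pred, 0.0, 100.0)),
                "prediction_raw": pred,
            }
        )
    df = pd.DataFrame(rows)
    abs_err = np.abs(df["prediction_raw"] - df["target_pct"]).to_numpy()
    mae = float(abs_err.mean())
    mae_sd = float(abs_err.std())
    target_sd = float(np.std(np.unique(df["target_pct"].to_numpy())))
    if target_sd == 0:
        warnings.warn("single-valued targets: rMAE and PCC undefined", RuntimeWarning)
        rmae = rmae_sd = pcc = float("nan")
    else:
        rmae = mae / target_sd
        rmae_sd = mae_sd / target_sd
        preds = df["prediction_raw"].to_numpy()
        if np.std(preds) == 0:
            warnings.warn("constant predictions: PCC undefined", RuntimeWarning)
            pcc = float("nan")
        else:
            pcc = float(np.corrcoef(preds, df["target_pct"].to_numpy())[0, 1])
    per_conc = (
        df.groupby("target_pct")
        .agg(
            mean_estimation_pct=("prediction_raw", "mean"),
            mean_abs_error_pp=(
                "prediction_raw",
                lambda p: float(np.mean(np.abs(p - df.loc[p.index, "target_pct"]))),
            ),
            sd_pp=("prediction_raw", lambda p: float(np.std(p))),
            n=("prediction_raw", "size"),
        )
        .reset_index()
    )
    if df["position_x_mm"].isna().any():
        per_pos = pd.DataFrame()  # positions unknown; grid not constructible
    else:
        per_pos = position_heatmap(df)
    return EvalMetrics(
        mae_pp=mae,
        mae_sd_pp=mae_sd,
        rmae=rmae,
        rmae_sd=rmae_sd,
        pcc=pcc,
        n_sequences=len(df),
        per_concentration=per_conc,
        per_position=per_pos,
        predictions=df,
    )


def position_heatmap(predictions: pd.DataFrame) -> pd.DataFrame:
    """Mean estimate per scan position as an (x offsets) x (y offsets) grid.

    ``predictions`` needs columns position_x_mm, position_y_mm and
    prediction_raw (or prediction_pct). Positions without data are NaN.
    """
    col = "prediction_raw" if "prediction_raw" in predictions else "prediction_pct"
    if predictions["position_x_mm"].isna().any():
        raise ConfigurationError("every prediction must carry its scan position")
    return predictions.pivot_table(
        index="position_x_mm", columns="position_y_mm", values=col, aggfunc="mean",
        dropna=False,
    )
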