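"""Split hygiene, temporal cropping, the training loop, and metrics."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from oce4d import (
    ModelSpec,
    PhaseSequence,
    ScanGeometry,
    SplitSpec,
    TrainConfig,
    build_model,
    evaluate,
    ordered_crops,
    position_heatmap,
    predict_sequence,
    random_temporal_crop,
    rmae_from_mae,
    split_by_phantom,
    train,
)
from oce4d.errors import ConfigurationError, CropError


def _phase_seq(label, phantom_id, position=(0.0, 0.0), t=30, shape=(4, 4, 4),
               seed=0):
    rng = np.random.default_rng(seed)
    geom = ScanGeometry(raw_shape_px=(8, 8, 48), n_volumes=t)
    return PhaseSequence(
        phase_unwrapped_rad=rng.normal(size=(t, *shape)).astype(np.float32),
        surface_index_px=10,
        source_geometry=geom,
        label_pct=label,
        position_mm=position,
        phantom_id=phantom_id,
    )


def _toy_dataset(concs=(5.0, 10.0), phantoms=3, positions=2):
    out = []
    for c in concs:
        for p in range(phantoms):
            for q in range(positions):
                out.append(
                    _phase_seq(c, f"c{c}_p{p}", position=(float(q), 0.0),
                               seed=hash((c, p, q)) % 2**31)
                )
    return out


class TestSplit:
    def test_counts_disjointness_and_position_cohesion(self):
        data = _toy_dataset(phantoms=6, positions=4)
        spec = SplitSpec(4, 1, 1, rng_seed=5)
        parts = split_by_phantom(data, spec)
        for conc in (5.0, 10.0):
            assert sum(s.label_pct == conc for s in parts.train) == 4 * 4
            assert sum(s.label_pct == conc for s in parts.val) == 4
            assert sum(s.label_pct == conc for s in parts.test) == 4
        ids = lambda part: {s.phantom_id for s in part}
        assert not ids(parts.train) & ids(parts.val)
        assert not ids(parts.train) & ids(parts.test)
        assert not ids(parts.val) & ids(parts.test)

    def test_deterministic_under_seed(self):
        data = _toy_dataset(phantoms=6)
        a = split_by_phantom(data, SplitSpec(4, 1, 1, rng_seed=3))
        b = split_by_phantom(data, SplitSpec(4, 1, 1, rng_seed=3))
        assert [s.phantom_id for s in a.test] == [s.phantom_id for s in b.test]

    def test_insufficient_phantoms_rejected(self):
        data = _toy_dataset(phantoms=3)
        with pytest.raises(ConfigurationError):
            split_by_phantom(data, SplitSpec(4, 1, 1))


class TestTemporalCrops:
    def test_random_crop_window_and_bounds(self, rng):
        seq = _phase_seq(10.0, "p", t=90)
        crop = random_temporal_crop(seq, 10, rng)
        assert crop.shape[0] == 10

    def test_full_sequence_when_lengths_match(self, rng):
        seq = _phase_seq(10.0, "p", t=10)
        crop = random_temporal_crop(seq, 10, rng)
        assert np.array_equal(crop, seq.phase_unwrapped_rad)

    def test_start_distribution_uniform(self):
        """90-volume sequences admit 81 distinct length-10 starts; the
        empirical distribution over 10^4 draws passes a chi-squared test."""
        seq = _phase_seq(10.0, "p", t=90, shape=(1, 1, 1))
        marked = np.arange(90, dtype=np.float32)
        seq.phase_unwrapped_rad = marked[:, None, None, None]
        rng = np.random.default_rng(99)
        starts = [int(random_temporal_crop(seq, 10, rng)[0, 0, 0, 0])
                  for _ in range(10_000)]
        counts = np.bincount(starts, minlength=81)
        assert counts.size == 81 and counts.min() > 0
        _, p = chisquare(counts)
        assert p > 0.01

    @pytest.mark.parametrize("t, n", [(90, 9), (10, 1), (95, 9)])
    def test_ordered_crop_counts(self, t, n):
        seq = _phase_seq(10.0, "p", t=t)
        crops = ordered_crops(seq, 10)
        assert len(crops) == n
        assert all(c.shape[0] == 10 for c in crops)

    def test_too_short_sequence_rejected(self, rng):
        seq = _phase_seq(10.0, "p", t=8)
        with pytest.raises(CropError):
            ordered_crops(seq, 10)
        with pytest.raises(CropError):
            random_temporal_crop(seq, 10, rng)


def _tiny_model(t=10, shape=(4, 4, 4)):
    spec = ModelSpec(input_shape=(t, *shape), stem_layers=1, stem_channels=2,
                     n_blocks=2, layers_per_block=1, growth_rate=2)
    return build_model(spec, 0)


class TestTrainLoop:
    def test_overfits_single_sequence(self):
        seq = _phase_seq(10.0, "p", t=12, seed=1)
        model = _tiny_model(t=10)
        cfg = TrainConfig(iterations=200, batch_size=4, sequence_length=10,
                          learning_rate=1e-2, rng_seed=0, val_every=50)
        hist = train(model, [seq], [seq], cfg)
        initial = np.mean(hist.train_loss[:5])
        final = np.mean(hist.train_loss[-5:])
        assert final < 0.1 * initial

    def test_same_seed_identical_loss_curves(self):
        data = [_phase_seq(c, f"p{c}", t=12, seed=int(c)) for c in (5.0, 10.0)]
        curves = []
        for _ in range(2):
            model = _tiny_model(t=10)
            cfg = TrainConfig(iterations=20, batch_size=3, sequence_length=10,
                              learning_rate=1e-3, rng_seed=7, val_every=10)
            hist = train(model, data, data, cfg)
            curves.append(hist.train_loss)
        assert curves[0] == curves[1]

    def test_empty_partition_rejected(self):
        with pytest.raises(ConfigurationError):
            train(_tiny_model(), [], [_phase_seq(5.0, "p")], TrainConfig())


class TestPredictionAveraging:
    def test_mean_of_crop_predictions(self):
        model = _tiny_model(t=10)
        seq = _phase_seq(10.0, "p", t=30, seed=2)
        crops = ordered_crops(seq, 10)
        singles = [float(model.forward(c[None], training=False)[0]) for c in crops]
        avg = predict_sequence(model, seq, n_crops=3, length=10)
        assert avg == pytest.approx(np.mean(singles), rel=1e-6)
        assert predict_sequence(model, seq, 1, 10) == pytest.approx(singles[0],
                                                                    rel=1e-6)

    def test_too_many_crops_rejected(self):
        with pytest.raises(CropError):
            predict_sequence(_tiny_model(t=10), _phase_seq(10.0, "p", t=30), 4, 10)


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def forward(self, batch, training=False):
        return np.full(batch.shape[0], self.value)


class _OracleModel:
    """Predicts the label encoded in the sequence (perfect predictor)."""

    def forward(self, batch, training=False):
        return batch[:, 0, 0, 0, 0].astype(float)


def _labelled_dataset():
    out = []
    for c in (5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0):
        seq = _phase_seq(c, f"p{c}", position=(c, 0.0), t=10)
        seq.phase_unwrapped_rad[...] = c  # encode the label in the data
        out.append(seq)
    return out


class TestEvaluate:
    def test_perfect_predictor(self):
        metrics = evaluate(_OracleModel(), _labelled_dataset(), n_crops=1)
        assert metrics.mae_pp == pytest.approx(0.0, abs=1e-9)
        assert metrics.rmae == pytest.approx(0.0, abs=1e-9)
        assert metrics.pcc == pytest.approx(1.0)

    def test_rmae_is_mae_over_target_sd(self):
        targets = np.array([5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0])
        assert np.std(targets) == pytest.approx(5.0)
        for mae, rmae in [(0.715, 0.143), (0.675, 0.135), (0.655, 0.131)]:
            assert rmae_from_mae(mae, targets) == pytest.approx(rmae, abs=5e-4)

    def test_constant_predictor_mae_and_undefined_pcc(self):
        """A constant prediction at the mean target has MAE equal to the mean
        absolute deviation of the balanced targets (30/7 p.p.) and no defined
        correlation."""
        with pytest.warns(RuntimeWarning, match="constant predictions"):
            metrics = evaluate(_ConstantModel(12.5), _labelled_dataset(), n_crops=1)
        assert metrics.mae_pp == pytest.approx(30.0 / 7.0)
        assert np.isnan(metrics.pcc)

    def test_per_concentration_table(self):
        metrics = evaluate(_OracleModel(), _labelled_dataset(), n_crops=1)
        tbl = metrics.per_concentration
        assert list(tbl["target_pct"]) == [5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0]
        assert np.allclose(tbl["mean_estimation_pct"], tbl["target_pct"])


class TestPositionHeatmap:
    def test_single_and_averaged_cells(self):
        df = pd.DataFrame(
            {
                "position_x_mm": [0.0, 0.0, 1.0],
                "position_y_mm": [0.0, 0.0, 1.0],
                "prediction_raw": [9.0, 11.0, 5.0],
            }
        )
        grid = position_heatmap(df)
        assert grid.loc[0.0, 0.0] == pytest.approx(10.0)
        assert grid.loc[1.0, 1.0] == pytest.approx(5.0)
        assert np.isnan(grid.loc[0.0, 1.0])  # unvisited position flagged missing
        assert grid.shape == (2, 2)


class TestAveragingContractsSpread:
    def test_multi_crop_variance_not_larger(self):
        """Averaging ordered-crop predictions cannot increase the spread of
        per-sequence predictions for a fixed model."""
        model = _tiny_model(t=10)
        seqs = [_phase_seq(10.0, "p", t=30, seed=s) for s in range(12)]
        p1 = np.array([predict_sequence(model, s, 1, 10) for s in seqs])
        p3 = np.array([predict_sequence(model, s, 3, 10) for s in seqs])
        assert p3.var() <= p1.var() * 1.05
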