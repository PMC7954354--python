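"""Loss, splitting, cross-validation and the training/evaluation loops."""

import numpy as np
import pytest

import oracles
from spinecodec import nn
from spinecodec.models import build_model, parse_name
from spinecodec.training import (History, TrainSpec, bce_loss, evaluate,
                                 kfold, reports_table, split_dataset, train,
                                 TABLE_COLUMNS)
from spinecodec.metrics import mean_report

TINY = dict(depth=3, base_channels=8)


# -- bce --------------------------------------------------------------------

def test_bce_closed_forms():
    assert bce_loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.0, abs=1e-6)
    assert bce_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(np.log(2), abs=1e-7)


def test_bce_matches_elementwise_loop(rng):
    for _ in range(10):
        p = rng.random((4, 7))
        t = (rng.random((4, 7)) > 0.5).astype(float)
        assert bce_loss(p, t) == pytest.approx(oracles.bce_loop(p, t), abs=1e-6)


def test_bce_shape_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_bce_nonnegative_and_zero_iff_exact(rng):
    p = rng.random((5, 5))
    t = (rng.random((5, 5)) > 0.5).astype(float)
    assert bce_loss(p, t) > 0
    assert bce_loss(t, t) == pytest.approx(0.0, abs=1e-5)


# -- splits -----------------------------------------------------------------

def test_split_sizes_and_determinism():
    plan = split_dataset(200, (8, 1, 1), seed=0)
    assert (len(plan.train), len(plan.val), len(plan.test)) == (160, 20, 20)
    assert split_dataset(200, (8, 1, 1), seed=0) == plan
    assert split_dataset(200, (8, 1, 1), seed=1) != plan
    small = split_dataset(10, (8, 1, 1), seed=0)
    assert (len(small.train), len(small.val), len(small.test)) == (8, 1, 1)
    combined = sorted(plan.train + plan.val + plan.test)
    assert combined == list(range(200))


def test_split_rejects_tiny_datasets():
    with pytest.raises(ValueError, match="at least"):
        split_dataset(5, (8, 1, 1))


def test_kfold_partitions():
    folds = kfold(10, 5, seed=0)
    assert len(folds) == 5
    all_test = sorted(i for _, test in folds for i in test)
    assert all_test == list(range(10))
    for tr, te in folds:
        assert len(te) == 2
        assert sorted(tr + te) == list(range(10))
    sizes = sorted(len(te) for _, te in kfold(203, 5, seed=3))
    assert sizes == [40, 40, 41, 41, 41]
    with pytest.raises(ValueError, match="folds"):
        kfold(3, 5)
    assert kfold(20, 5, seed=7) == kfold(20, 5, seed=7)


# -- training loop ----------------------------------------------------------

def test_one_epoch_smoke(phantom_fixture):
    model = build_model(parse_name("U-Net", seed=0, **TINY))
    model, hist = train(model, phantom_fixture[:2],
                        TrainSpec(max_epochs=1, batch_size=2, seed=0))
    assert len(hist) == 1
    assert np.isfinite(hist.train_loss[0])


def test_training_is_seed_deterministic(phantom_fixture):
    def run():
        model = build_model(parse_name("U-Net", seed=0, **TINY))
        _, hist = train(model, phantom_fixture[:4],
                        TrainSpec(max_epochs=2, batch_size=2, seed=0))
        return hist.train_loss

    assert run() == run()


def test_empty_dataset_rejected():
    model = build_model(parse_name("U-Net", **TINY))
    with pytest.raises(ValueError, match="empty"):
        train(model, [], TrainSpec(max_epochs=1))
    with pytest.raises(ValueError, match="empty"):
        evaluate(model, [])


def test_evaluate_perfect_and_constant_models(phantom_fixture):
    dataset = phantom_fixture[:3]

    class Perfect:
        def __init__(self):
            self._i = 0

        def predict(self, x):
            mask = dataset[self._i].mask
            self._i += 1
            return mask[None, None].astype(np.float32)

    reports, mean = evaluate(Perfect(), dataset)
    assert mean.dice == 1.0 and mean.bf_score == 1.0

    class Background:
        def predict(self, x):
            return np.zeros_like(x)

    _, mean_bg = evaluate(Background(), dataset)
    assert mean_bg.sensitivity == 0.0


def test_evaluate_mean_is_average_of_per_image(phantom_fixture):
    model = build_model(parse_name("U-Net", seed=1, **TINY))
    reports, mean = evaluate(model, phantom_fixture[:4])
    recomputed = mean_report(reports)
    assert mean.dice == pytest.approx(recomputed.dice)
    assert mean.bf_score == pytest.approx(recomputed.bf_score)


def test_reports_table_has_published_column_order(phantom_fixture):
    model = build_model(parse_name("U-Net", seed=1, **TINY))
    reports, mean = evaluate(model, phantom_fixture[:2])
    table = reports_table(reports, mean, parameters=1234)
    assert list(table.columns) == ["id"] + TABLE_COLUMNS
    assert table.iloc[-1]["id"] == "mean"
    assert table["Parameters"].iloc[0] == 1234


def test_history_jsonl_round_trip(tmp_path, phantom_fixture):
    model = build_model(parse_name("U-Net", seed=0, **TINY))
    _, hist = train(model, phantom_fixture[:2],
                    TrainSpec(max_epochs=2, batch_size=2, seed=0),
                    val_dataset=phantom_fixture[2:3])
    path = tmp_path / "history.jsonl"
    hist.to_jsonl(path)
    import json
    lines = [json.loads(l) for l in path.read_text().splitlines()]
    assert len(lines) == 2
    assert lines[0]["epoch"] == 1
    assert "val" in lines[0]
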