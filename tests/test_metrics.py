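"""Evaluation metrics against independently coded brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from spinecodec.errors import ShapeError
from spinecodec.metrics import (BFConfig, ConfusionCounts, bf_score, binarize,
                                confusion_counts, evaluate_pair,
                                extract_boundary, mean_report, region_metrics,
                                score_mask_folders)

FIELDS6 = ("accuracy", "sensitivity", "specificity", "precision",
           "dice", "jaccard")


def random_mask(rng, shape=(32, 32), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)


# -- binarize ---------------------------------------------------------------

def test_binarize_threshold_and_tie_rule(rng):
    prob = rng.random((16, 16))
    prob[0, 0] = 0.5
    mask = binarize(prob, 0.5)
    # per-pixel loop oracle
    for i in range(16):
        for j in range(16):
            assert mask[i, j] == (1 if prob[i, j] >= 0.5 else 0)
    assert mask[0, 0] == 1  # tie goes to foreground
    assert binarize(np.full((3, 3), 0.9)).all()


def test_binarize_rejects_out_of_range():
    with pytest.raises(ValueError):
        binarize(np.array([[1.5]]))


# -- confusion counts -------------------------------------------------------

def test_confusion_counts_basic_cases():
    ones = np.ones((4, 4), np.uint8)
    c = confusion_counts(ones, ones)
    assert (c.tp, c.fp, c.fn, c.tn) == (16, 0, 0, 0)
    c = confusion_counts(1 - ones, ones)
    assert c.tp == 0 and c.tn == 0 and c.fn == 16
    with pytest.raises(ShapeError, match="4, 4"):
        confusion_counts(ones, np.ones((3, 3), np.uint8))


def test_confusion_counts_match_double_loop(rng):
    for _ in range(5):
        p, t = random_mask(rng), random_mask(rng)
        c = confusion_counts(p, t)
        want = oracles.region_metrics_loop(p, t)
        got = region_metrics(c)
        for f in FIELDS6:
            assert abs(getattr(got, f) - want[f]) < 1e-12
        assert c.total == p.size


# -- region metrics ---------------------------------------------------------

def test_region_metrics_worked_example():
    rep = region_metrics(ConfusionCounts(tp=8, fp=2, fn=2, tn=88))
    assert rep.accuracy == pytest.approx(0.96)
    assert rep.dice == pytest.approx(0.8)
    assert rep.jaccard == pytest.approx(2 / 3)
    assert rep.sensitivity == pytest.approx(0.8)
    assert rep.precision == pytest.approx(0.8)


def test_perfect_and_empty_predictions():
    perfect = region_metrics(ConfusionCounts(10, 0, 0, 90))
    assert all(getattr(perfect, f) == 1.0 for f in FIELDS6)
    both_empty = region_metrics(ConfusionCounts(0, 0, 0, 64))
    assert both_empty.dice == both_empty.jaccard == 1.0
    assert both_empty.sensitivity == both_empty.precision == 1.0
    miss = region_metrics(ConfusionCounts(0, 0, 5, 59))
    assert miss.sensitivity == 0.0 and miss.dice == 0.0
    assert miss.precision == 0.0  # empty prediction against non-empty truth


def test_dice_jaccard_identity(rng):
    for _ in range(200):
        tp, fp, fn, tn = rng.integers(0, 50, 4)
        if tp + fp + fn + tn == 0:
            continue
        rep = region_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
        assert rep.dice == pytest.approx(2 * rep.jaccard / (1 + rep.jaccard))
        assert rep.dice >= rep.jaccard


# -- boundary extraction ----------------------------------------------------

def test_boundary_of_filled_square_excludes_interior():
    mask = np.ones((3, 3), np.uint8)
    b = extract_boundary(mask)
    assert b.sum() == 8 and not b[1, 1]


def test_boundary_edge_cases():
    single = np.zeros((5, 5), np.uint8)
    single[2, 2] = 1
    assert extract_boundary(single).sum() == 1
    assert extract_boundary(np.zeros((4, 4), np.uint8)).sum() == 0


@pytest.mark.parametrize("connectivity", [4, 8])
def test_boundary_matches_neighbourhood_loop(rng, connectivity):
    for _ in range(5):
        m = random_mask(rng, (16, 16))
        got = extract_boundary(m, connectivity)
        want = oracles.boundary_loop(m, connectivity)
        assert set(zip(*np.nonzero(got))) == want


# -- bf score ---------------------------------------------------------------

def test_bf_score_identity_and_disjoint():
    m = np.zeros((16, 16), np.uint8)
    m[4:10, 5:12] = 1
    assert bf_score(m, m) == 1.0
    a = np.zeros((16, 16), np.uint8)
    b = np.zeros((16, 16), np.uint8)
    a[2, 2] = 1
    b[2, 12] = 1  # 10 px apart, theta=2
    assert bf_score(a, b) == 0.0
    assert bf_score(np.zeros_like(m), np.zeros_like(m)) == 1.0
    assert bf_score(m, np.zeros_like(m)) == 0.0


def test_bf_score_shifted_square_matches_allpairs_oracle():
    a = np.zeros((16, 16), np.uint8)
    a[4:12, 4:12] = 1
    b = np.roll(a, 1, axis=1)
    got = bf_score(a, b)
    want = oracles.bf_score_allpairs(a, b, theta=2.0)
    assert got == pytest.approx(want, abs=1e-12)


def test_bf_score_monotone_in_theta(rng):
    a, b = random_mask(rng), random_mask(rng)
    scores = [bf_score(a, b, BFConfig(theta=t)) for t in (0.5, 1, 2, 4, 8)]
    assert scores == sorted(scores)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metric_symmetries(seed):
    rng = np.random.default_rng(seed)
    a, b = random_mask(rng, (12, 12)), random_mask(rng, (12, 12))
    ra, rb = region_metrics(confusion_counts(a, b)), region_metrics(confusion_counts(b, a))
    assert ra.dice == pytest.approx(rb.dice)
    assert ra.jaccard == pytest.approx(rb.jaccard)
    assert ra.accuracy == pytest.approx(rb.accuracy)
    assert ra.sensitivity == pytest.approx(rb.precision)
    assert bf_score(a, b) == pytest.approx(bf_score(b, a))
    for f in FIELDS6:
        assert 0 <= getattr(ra, f) <= 1


# -- composition ------------------------------------------------------------

def test_evaluate_pair_composes_the_pipeline(rng):
    truth = random_mask(rng)
    perfect = evaluate_pair(truth.astype(float), truth)
    assert all(getattr(perfect, f) == 1.0 for f in FIELDS6)
    assert perfect.bf_score == 1.0
    background = evaluate_pair(np.zeros_like(truth, dtype=float), truth)
    assert background.sensitivity == 0.0 and background.bf_score == 0.0


def test_mean_report_is_arithmetic_average(rng):
    reports = [evaluate_pair(rng.random((8, 8)), random_mask(rng, (8, 8)))
               for _ in range(4)]
    mean = mean_report(reports)
    assert mean.dice == pytest.approx(np.mean([r.dice for r in reports]))
    assert mean.bf_score == pytest.approx(np.mean([r.bf_score for r in reports]))


def test_score_mask_folders_round_trip(tmp_path, rng):
    from PIL import Image
    (tmp_path / "pred").mkdir()
    (tmp_path / "truth").mkdir()
    for i in range(3):
        t = random_mask(rng, (16, 16))
        p = t.copy()
        p[0, 0] ^= 1
        Image.fromarray(p * 255).save(tmp_path / "pred" / f"s{i}.png")
        Image.fromarray(t * 255).save(tmp_path / "truth" / f"s{i}.png")
    table = score_mask_folders(tmp_path / "pred", tmp_path / "truth",
                               out_csv=tmp_path / "scores.csv")
    assert list(table["id"])[-1] == "mean"
    assert len(table) == 4
    assert (tmp_path / "scores.csv").exists()
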