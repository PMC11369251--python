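"""Fusion classifier: losses, metrics, agreement statistics, rendering."""

import itertools
import math

import numpy as np
import pytest

from pahisto import nn, stepff
from pahisto.nn import Tensor
from pahisto.tiling import TileGrid, ImageTile


# --------------------------------------------------------------------------- #
# focal loss
# --------------------------------------------------------------------------- #

def test_focal_reduces_to_cross_entropy_at_gamma_zero():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.05, 0.95, 32)
    y = rng.integers(0, 2, 32)
    ce = -np.mean(np.where(y == 1, np.log(p), np.log(1 - p)))
    assert stepff.focal_loss(p, y, gamma=0.0, alpha=1.0) == pytest.approx(ce)


def test_focal_loss_vanishes_for_confident_correct_predictions():
    p = np.array([0.9999, 0.0001])
    y = np.array([1, 0])
    assert stepff.focal_loss(p, y) < 1e-6


def test_focal_loss_matches_formula_oracle():
    rng = np.random.default_rng(1)
    p = rng.uniform(0.05, 0.95, 16)
    y = rng.integers(0, 2, 16)
    gamma, alpha = 2.0, 0.5
    pt = np.where(y == 1, p, 1 - p)
    expect = np.mean(-alpha * (1 - pt) ** gamma * np.log(pt))
    assert stepff.focal_loss(p, y, gamma, alpha) == pytest.approx(expect)


def test_focal_logits_version_agrees_with_probability_version():
    rng = np.random.default_rng(2)
    logits = rng.normal(size=(12, 2)).astype(np.float32)
    y = rng.integers(0, 2, 12)
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    expect = stepff.focal_loss(probs[:, 1], y)
    got = float(stepff._focal_from_logits(Tensor(logits), y, 2.0, 0.5).data)
    assert got == pytest.approx(expect, rel=1e-5)


# --------------------------------------------------------------------------- #
# classification metrics
# --------------------------------------------------------------------------- #

def test_metrics_all_correct():
    m = stepff.classification_metrics([0, 1, 1, 0], [0, 1, 1, 0])
    assert m == {"accuracy": 1.0, "f1": 1.0, "precision": 1.0, "recall": 1.0}


def test_metrics_confusion_matrix_arithmetic():
    # TP=5 FP=1 FN=2 TN=2
    y_true = [1] * 5 + [0] * 1 + [1] * 2 + [0] * 2
    y_pred = [1] * 5 + [1] * 1 + [0] * 2 + [0] * 2
    m = stepff.classification_metrics(y_true, y_pred)
    assert m["precision"] == pytest.approx(5 / 6)
    assert m["recall"] == pytest.approx(5 / 7)
    assert m["f1"] == pytest.approx(10 / 13)
    assert m["accuracy"] == pytest.approx(7 / 10)


def test_metrics_degenerate_precision_warns_and_reports_zero():
    with pytest.warns(UserWarning, match="precision"):
        m = stepff.classification_metrics([1, 1, 0], [0, 0, 0])
    assert m["precision"] == 0.0
    with pytest.raises(ValueError):
        stepff.classification_metrics([], [])


# --------------------------------------------------------------------------- #
# model contracts
# --------------------------------------------------------------------------- #

def test_extract_dfv_shapes_and_determinism():
    model = stepff.StepFFModel(base_width=2, seed=0)
    rng = np.random.default_rng(3)
    pah = rng.integers(0, 256, (32, 32), dtype=np.uint8)
    vhe = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    segv = rng.normal(size=6)
    for modality, inp in (("pah", pah), ("vhe", vhe), ("seg", segv)):
        v1 = stepff.extract_dfv(model, modality, inp)
        v2 = stepff.extract_dfv(model, modality, inp)
        assert v1.shape == (16,)
        assert np.array_equal(v1, v2)
    batch = stepff.extract_dfv(model, "seg", rng.normal(size=(5, 6)))
    assert batch.shape == (5, 16)
    with pytest.raises(ValueError):
        stepff.extract_dfv(model, "histology", pah)


def test_zero_weight_seg_branch_yields_zero_dfv():
    model = stepff.StepFFModel(base_width=2, seed=0)
    model.seg_fc.weight.data[:] = 0.0
    model.seg_fc.bias.data[:] = 0.0
    assert np.all(stepff.extract_dfv(model, "seg", np.ones(6)) == 0.0)


def test_dfv_serialization_round_trip(tmp_path):
    model = stepff.StepFFModel(base_width=2, seed=4)
    rng = np.random.default_rng(5)
    vhe = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    before = stepff.extract_dfv(model, "vhe", vhe)
    nn.save_state(tmp_path / "m.npz", model)
    clone = stepff.StepFFModel(base_width=2, seed=99)
    nn.load_state(tmp_path / "m.npz", clone)
    assert np.array_equal(before, stepff.extract_dfv(clone, "vhe", vhe))


def test_fuse_predict_probability_semantics():
    model = stepff.StepFFModel(base_width=2, seed=6)
    rng = np.random.default_rng(7)
    pah = rng.integers(0, 256, (32, 32), dtype=np.uint8)
    vhe = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    p = stepff.fuse_predict(model, pah, vhe, np.zeros(6))
    assert 0.0 <= p <= 1.0
    # symmetric zero head -> exactly 0.5
    model.head.weight.data[:] = 0.0
    model.head.bias.data[:] = 0.0
    assert stepff.fuse_predict(model, pah, vhe, np.zeros(6)) == 0.5
    with pytest.raises(ValueError, match="VHE"):
        stepff.fuse_predict(model, pah_tile=pah, seg_features=np.zeros(6))


def test_fuse_predict_matches_manual_forward_on_seg_only():
    model = stepff.StepFFModel(base_width=2, modalities=("seg",), seed=8)
    feats = np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5])
    dfv = feats @ model.seg_fc.weight.data + model.seg_fc.bias.data
    logits = dfv @ model.head.weight.data + model.head.bias.data
    expect = float(np.exp(logits[1]) / np.exp(logits).sum())
    got = stepff.fuse_predict(model, seg_features=feats)
    assert got == pytest.approx(expect, rel=1e-5)


def test_normalizer_stats_and_degenerate_guard():
    rng = np.random.default_rng(9)
    f = rng.normal(3.0, 2.0, size=(40, 6))
    f[:, 2] = 7.0  # constant feature
    norm = stepff.SegFeatureNormalizer().fit(f)
    z = norm.transform(f)
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
    keep = [i for i in range(6) if i != 2]
    assert np.allclose(z[:, keep].std(axis=0), 1.0, atol=1e-9)
    assert norm.sd[2] == 1.0
    with pytest.raises(RuntimeError):
        stepff.SegFeatureNormalizer().transform(f)


# --------------------------------------------------------------------------- #
# cross-validation mechanics
# --------------------------------------------------------------------------- #

def seg_only_records(n=40, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        label = i % 2
        mu = 3.0 if label else -3.0
        recs.append({"seg": rng.normal(mu, 1.0, 6), "label": label})
    return recs


def test_stratified_folds_balanced_and_exclusive():
    labels = np.array([0, 1] * 25)
    folds = stepff._stratified_folds(labels, 5, np.random.default_rng(0))
    all_idx = np.concatenate(folds)
    assert sorted(all_idx) == list(range(50))
    for f in folds:
        assert (labels[f] == 1).sum() == 5
        assert (labels[f] == 0).sum() == 5


def test_grouped_folds_co_assign_shared_groups():
    labels = np.array([0, 0, 1, 1] * 5)
    groups = np.repeat(np.arange(10), 2)
    folds = stepff._stratified_folds(labels, 5, np.random.default_rng(1),
                                     groups=groups)
    for f in folds:
        gs = groups[f]
        for g in np.unique(gs):
            assert (groups == g).sum() == (gs == g).sum()


def test_train_stepff_separable_seg_features_and_determinism():
    recs = seg_only_records()
    cfg = stepff.StepFFTrainConfig(base_width=2, modalities=("seg",),
                                   epochs=400, patience=40, batch_size=4,
                                   folds=5, seed=2)
    r1 = stepff.train_stepff(recs, cfg)
    assert r1["mean_metrics"]["accuracy"] >= 0.9
    r2 = stepff.train_stepff(recs, cfg)
    assert r1["metrics"].equals(r2["metrics"])
    for f1, f2 in zip(r1["folds"], r2["folds"]):
        assert np.array_equal(f1, f2)


def test_normalizer_fitted_per_training_fold_without_leakage():
    recs = seg_only_records()
    cfg = stepff.StepFFTrainConfig(base_width=2, modalities=("seg",),
                                   epochs=5, patience=0, batch_size=16,
                                   folds=5, seed=3)
    res = stepff.train_stepff(recs, cfg)
    feats = np.stack([np.asarray(r["seg"], float) for r in recs])
    for f, test_idx in enumerate(res["folds"]):
        train_idx = np.setdiff1d(np.arange(len(recs)), test_idx)
        expect_mean = feats[train_idx].mean(axis=0)
        assert np.allclose(res["normalizers"][f].mean, expect_mean)


def test_train_stepff_requires_both_classes_per_fold():
    recs = [{"seg": np.zeros(6), "label": 0} for _ in range(10)]
    recs += [{"seg": np.ones(6), "label": 1} for _ in range(2)]
    cfg = stepff.StepFFTrainConfig(modalities=("seg",), folds=5, seed=0)
    with pytest.raises(ValueError, match="lacks a class"):
        stepff.train_stepff(recs, cfg)


# --------------------------------------------------------------------------- #
# probability map
# --------------------------------------------------------------------------- #

def make_grid(n_tiles, ts=16):
    tiles = [ImageTile(np.zeros((ts, ts), np.uint8), origin=(0, i * ts),
                       modality="PROB") for i in range(n_tiles)]
    return TileGrid(tiles, canvas_size=(ts, ts * n_tiles), tile_size=ts,
                    stride=ts)


def test_probability_map_endpoints_exact():
    grid = make_grid(2)
    out = stepff.probability_map([0.0, 1.0], grid)
    assert np.all(out[:, :16] == np.array([0, 0, 255]))      # blue at p=0
    assert np.all(out[:, 16:] == np.array([128, 0, 128]))    # purple at p=1


def test_probability_map_midpoint_and_canvas():
    grid = make_grid(1)
    out = stepff.probability_map([0.5], grid)
    assert out.shape == (16, 16, 3)
    assert np.all(out == np.array([64, 0, 192]))  # channelwise midpoint
    with pytest.raises(ValueError):
        stepff.probability_map([1.5], grid)
    with pytest.raises(ValueError):
        stepff.probability_map([0.1, 0.2], grid)


def test_probability_map_overlap_averages():
    ts = 16
    tiles = [ImageTile(np.zeros((ts, ts), np.uint8), origin=(0, 0), modality="PROB"),
             ImageTile(np.zeros((ts, ts), np.uint8), origin=(0, 8), modality="PROB")]
    grid = TileGrid(tiles, canvas_size=(ts, 24), tile_size=ts, stride=8)
    out = stepff.probability_map([0.0, 1.0], grid)
    assert np.all(out[:, :8] == np.array([0, 0, 255]))
    assert np.all(out[:, 16:] == np.array([128, 0, 128]))
    assert np.all(out[:, 8:16] == np.array([64, 0, 192]))


# --------------------------------------------------------------------------- #
# agreement statistics
# --------------------------------------------------------------------------- #

def test_kappa_perfect_agreement_and_disagreement():
    assert stepff.cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
    assert stepff.cohens_kappa([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(-1.0)


def test_kappa_hand_computed_2x2_table():
    # a=40 agree-0, b=5, c=5, d=50 agree-1
    ra = np.array([0] * 40 + [0] * 5 + [1] * 5 + [1] * 50)
    rb = np.array([0] * 40 + [1] * 5 + [0] * 5 + [1] * 50)
    n = 100
    p_o = 90 / n
    p_e = (45 / n) * (45 / n) + (55 / n) * (55 / n)
    assert stepff.cohens_kappa(ra, rb) == pytest.approx((p_o - p_e) / (1 - p_e))


def test_kappa_exhaustive_against_sklearn_oracle():
    from sklearn.metrics import cohen_kappa_score

    for a, b, c, d in itertools.product(range(6), repeat=4):
        n = a + b + c + d
        if n == 0:
            continue
        ra = np.array([0] * (a + b) + [1] * (c + d))
        rb = np.array([0] * a + [1] * b + [0] * c + [1] * d)
        mine = stepff.cohens_kappa(ra, rb)
        theirs = cohen_kappa_score(ra, rb)
        if math.isnan(theirs):
            assert mine == 1.0  # both raters constant and equal (p_e = 1)
        else:
            assert mine == pytest.approx(theirs, abs=1e-12)


def test_kappa_constant_equal_raters_defined_as_one():
    assert stepff.cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0


def test_fleiss_kappa_known_cases():
    # all raters always agree -> 1
    m = np.array([[3, 0], [0, 3], [3, 0]])
    assert stepff.fleiss_kappa(m) == 1.0
    # canonical worked example (Fleiss 1971-style): computed by hand below
    m = np.array([[1, 2], [2, 1], [3, 0], [0, 3]])
    r = 3
    p_i = ((m**2).sum(axis=1) - r) / (r * (r - 1))
    p_bar = p_i.mean()
    p_j = m.sum(axis=0) / (m.shape[0] * r)
    p_e = (p_j**2).sum()
    assert stepff.fleiss_kappa(m) == pytest.approx((p_bar - p_e) / (1 - p_e))
    with pytest.raises(ValueError):
        stepff.fleiss_kappa(np.array([[2, 0], [1, 1], [3, 0]]))  # ragged raters
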