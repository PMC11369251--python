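"""U-Net segmentation and morphometric feature extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage, stats

from pahisto import segmentation as seg, synthetic as syn
from pahisto.tiling import invert_intensity
from conftest import dice_coefficient


def lattice_disk_mask(shape, disks):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, bool)
    for (cy, cx), r in disks:
        mask |= np.hypot(yy - cy, xx - cx) <= r
    return mask.astype(np.uint8)


# --------------------------------------------------------------------------- #
# loss
# --------------------------------------------------------------------------- #

def test_bce_dice_perfect_prediction_near_zero():
    mask = lattice_disk_mask((32, 32), [((16, 16), 6)])
    assert seg.bce_dice_loss(mask.astype(float), mask) < 1e-3


def test_bce_dice_uniform_half_has_ln2_bce_term():
    mask = lattice_disk_mask((32, 32), [((16, 16), 6)]).astype(float)
    probs = np.full_like(mask, 0.5)
    inter = (probs * mask).sum()
    dice = (2 * inter + 1) / (probs.sum() + mask.sum() + 1)
    assert seg.bce_dice_loss(probs, mask) == pytest.approx(
        math.log(2) + 1 - dice, abs=1e-9)


def test_bce_dice_matches_term_oracle_on_random_inputs():
    rng = np.random.default_rng(0)
    probs = rng.uniform(0.01, 0.99, (16, 16))
    mask = (rng.uniform(size=(16, 16)) > 0.6).astype(float)
    bce = -(mask * np.log(probs) + (1 - mask) * np.log(1 - probs)).mean()
    dice = (2 * (probs * mask).sum() + 1) / (probs.sum() + mask.sum() + 1)
    assert seg.bce_dice_loss(probs, mask) == pytest.approx(bce + 1 - dice,
                                                           abs=1e-9)
    with pytest.raises(ValueError):
        seg.bce_dice_loss(probs, mask[:8])


# --------------------------------------------------------------------------- #
# minimum enclosing circle
# --------------------------------------------------------------------------- #

def test_min_enclosing_circle_known_cases():
    cy, cx, r = seg.min_enclosing_circle([(2.0, 3.0)])
    assert (cy, cx, r) == (2.0, 3.0, 0.0)
    cy, cx, r = seg.min_enclosing_circle([(0, 0), (0, 4)])
    assert (cy, cx) == (0.0, 2.0) and r == pytest.approx(2.0)
    # equilateral-ish triangle: circumcircle
    pts = [(0.0, 0.0), (0.0, 2.0), (2.0, 1.0)]
    cy, cx, r = seg.min_enclosing_circle(pts)
    for p in pts:
        assert math.hypot(p[0] - cy, p[1] - cx) <= r + 1e-7


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(1, 25))
def test_min_enclosing_circle_contains_all_points_and_is_tight(seed, n):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 50, size=(n, 2))
    cy, cx, r = seg.min_enclosing_circle(pts)
    d = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
    assert np.all(d <= r + 1e-6)
    # tightness: no strictly smaller circle centred at the centroid covers all
    assert r <= d.max() + 1e-6 or n == 1


# --------------------------------------------------------------------------- #
# feature extraction
# --------------------------------------------------------------------------- #

def test_extract_features_empty_and_single_disk():
    f = seg.extract_features(np.zeros((32, 32), np.uint8))
    assert f.cell_count == 0
    assert math.isnan(f.cell_area) and math.isnan(f.mean_distance)
    one = lattice_disk_mask((64, 64), [((32, 32), 5)])
    f = seg.extract_features(one)
    assert f.cell_count == 1
    assert f.cell_area == 81.0
    assert math.isnan(f.mean_distance)


def test_extract_features_three_disks_geometry():
    disks = [((20, 20), 5), ((20, 60), 5), ((60, 20), 5)]
    mask = lattice_disk_mask((80, 80), disks)
    f = seg.extract_features(mask)
    assert f.cell_count == 3
    assert f.cell_area == pytest.approx(81.0)
    assert f.mean_distance == pytest.approx(40.0, abs=0.2)  # NN distance 40 each
    fa = seg.extract_features(mask, distance="allpairs")
    expect_allpairs = (40 + 40 + 40 * math.sqrt(2)) / 3
    assert fa.mean_distance == pytest.approx(expect_allpairs, abs=0.3)


def brute_force_components(mask, min_area):
    """Independent 8-connected labeling through scipy.ndimage."""
    labels, n = ndimage.label(mask > 0, structure=np.ones((3, 3)))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return sorted(a for a in areas if a >= min_area)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_extract_features_matches_exhaustive_labeling(seed):
    rng = np.random.default_rng(seed)
    mask = (rng.uniform(size=(64, 64)) > 0.82).astype(np.uint8)
    mask = ndimage.binary_dilation(mask, iterations=1).astype(np.uint8)
    for min_area in (1, 10):
        f = seg.extract_features(mask, min_area=min_area)
        areas = brute_force_components(mask, min_area)
        assert f.cell_count == len(areas)
        if areas:
            assert f.cell_area == pytest.approx(float(np.mean(areas)))


def test_features_invariant_to_translation_and_flips():
    disks = [((18, 14), 4), ((40, 44), 6)]
    mask = lattice_disk_mask((64, 64), disks)
    f0 = seg.extract_features(mask)
    rolled = np.roll(np.roll(mask, 5, axis=0), -3, axis=1)
    for variant in (rolled, mask[::-1], mask[:, ::-1]):
        f = seg.extract_features(np.ascontiguousarray(variant))
        assert f.cell_count == f0.cell_count
        assert f.cell_area == pytest.approx(f0.cell_area)
        assert f.mean_distance == pytest.approx(f0.mean_distance, abs=1e-6)


def test_count_nonincreasing_in_min_area():
    rng = np.random.default_rng(3)
    mask = (rng.uniform(size=(64, 64)) > 0.85).astype(np.uint8)
    counts = [seg.extract_features(mask, min_area=m).cell_count
              for m in (1, 2, 5, 10, 20)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_count_recovery_slope_for_nonoverlapping_nuclei():
    """Regressing extracted count on ground-truth scene count gives a slope
    in [0.8, 1.1] when nuclei cannot overlap (separation factor > 1)."""
    params = syn.SceneParams(separation_factor=1.15, noise_sd=0.0)
    truth, measured = [], []
    for s in range(40):
        label = syn.CANCEROUS if s % 2 else syn.NONCANCEROUS
        scene = syn.generate_scene(params, label, (128, 128), seed=s)
        truth.append(scene.count)
        measured.append(seg.extract_features(
            syn.render_mask(scene).pixels, min_area=10).cell_count)
    slope = stats.linregress(truth, measured).slope
    assert 0.8 <= slope <= 1.1


# --------------------------------------------------------------------------- #
# IQR fencing
# --------------------------------------------------------------------------- #

def test_iqr_filter_cases():
    const = [5.0] * 8
    assert list(seg.iqr_filter(const)) == const
    vals = list(range(1, 10)) + [1000]
    kept = seg.iqr_filter(vals)
    assert 1000 not in kept
    assert list(kept) == list(range(1, 10))       # order preserved, subset
    q1, q3 = np.percentile(vals, [25, 75])
    lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
    assert all(lo <= v <= hi for v in kept)
    assert seg.iqr_filter([]).size == 0


# --------------------------------------------------------------------------- #
# network training / inference (shared session runs)
# --------------------------------------------------------------------------- #

def test_unet_output_matches_input_dims():
    model = seg.UNet(base_width=2, seed=0)
    for size in (32, 64):
        probs = model.predict_probs(np.zeros((size, size), np.uint8))
        assert probs.shape == (size, size)
        assert probs.min() >= 0 and probs.max() <= 1


def test_unet_overfits_small_dataset(unet_overfit_run):
    model, pairs = unet_overfit_run["model"], unet_overfit_run["pairs"]
    dices = [dice_coefficient(seg.predict_mask(model, img, tta=False), m)
             for img, m in pairs]
    assert np.mean(dices) >= 0.95


def test_unet_generalizes_to_held_out_tiles(unet_heldout_run):
    model, test = unet_heldout_run["model"], unet_heldout_run["test"]
    dices = [dice_coefficient(seg.predict_mask(model, img, tta=True), m)
             for img, m in test]
    assert np.mean(dices) >= 0.80


def test_unet_training_is_seed_deterministic():
    items = syn.generate_dataset(2, canvas_size=(64, 64), seed=33)
    pairs = [(invert_intensity(it.pah.pixels), it.mask.pixels) for it in items]
    cfg = seg.UNetTrainConfig(batch_size=2, epochs=3, patience=0,
                              val_fraction=0.0, seed=9)
    hists = []
    for _ in range(2):
        model = seg.UNet(base_width=2, seed=9)
        _, h = seg.train_unet(pairs, model, cfg, val_dataset=[])
        hists.append(h["train_loss"])
    assert hists[0] == hists[1]


def test_train_unet_rejects_empty_dataset():
    with pytest.raises(ValueError):
        seg.train_unet([], seg.UNet(base_width=2, seed=0))


def test_tta_prediction_invariant_to_input_flip(unet_overfit_run):
    model = unet_overfit_run["model"]
    img = unet_overfit_run["pairs"][0][0]
    base = seg.predict_mask(model, img, tta=True)
    flipped = seg.predict_mask(model, np.ascontiguousarray(img[:, ::-1]),
                               tta=True)
    assert np.array_equal(base, flipped[:, ::-1])


def test_threshold_on_constant_probs():
    class ConstModel:
        def predict_probs(self, image):
            return np.full(np.asarray(image).shape[:2], 0.4)

    mask = seg.predict_mask(ConstModel(), np.zeros((16, 16), np.uint8),
                            tta=True, threshold=0.5)
    assert not mask.any()
    mask = seg.predict_mask(ConstModel(), np.zeros((16, 16), np.uint8),
                            tta=False, threshold=0.3)
    assert mask.all()


# --------------------------------------------------------------------------- #
# feature tables
# --------------------------------------------------------------------------- #

def test_feature_table_ground_truth_path_matches_direct_extraction():
    items = syn.generate_dataset(5, canvas_size=(64, 64), seed=17)
    masks = [it.mask.pixels for it in items]
    labels = [it.label for it in items]
    table = seg.feature_table([it.pah.pixels for it in items], masks=masks,
                              labels=labels, modality="MASK")
    assert len(table) == len(items)
    for i, m in enumerate(masks):
        f = seg.extract_features(m)
        row = table.iloc[i]
        assert row["cell_count"] == f.cell_count
        if f.cell_count:
            assert row["cell_area"] == pytest.approx(f.cell_area)
    summary = seg.class_summary(table, fence=True)
    assert (summary[syn.CANCEROUS]["cell_count"]
            > summary[syn.NONCANCEROUS]["cell_count"])
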