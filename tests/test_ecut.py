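"""Unpaired-translation model: loss oracles, attribution, contracts."""

import math

import numpy as np
import pytest

from pahisto import ecut, nn
from pahisto.nn import Tensor
from pahisto.tiling import crop_tiles, stitch_tiles


# --------------------------------------------------------------------------- #
# adversarial loss
# --------------------------------------------------------------------------- #

def test_adversarial_loss_optima_and_oracle():
    real = np.ones((1, 1, 4, 4))
    fake = np.zeros((1, 1, 4, 4))
    assert ecut.adversarial_loss(real, fake, "discriminator") == 0.0
    assert ecut.adversarial_loss(None, np.ones((2, 3)), "generator") == 0.0
    rng = np.random.default_rng(0)
    r, f = rng.normal(size=(2, 5, 5))
    expect_d = 0.5 * (((r - 1) ** 2).mean() + (f**2).mean())
    assert ecut.adversarial_loss(r, f, "discriminator") == pytest.approx(expect_d)
    assert ecut.adversarial_loss(None, f, "generator") == pytest.approx(
        ((f - 1) ** 2).mean())
    with pytest.raises(ValueError):
        ecut.adversarial_loss(r, f, "both")


# --------------------------------------------------------------------------- #
# PatchNCE
# --------------------------------------------------------------------------- #

def nce_brute_force(q, k, tau):
    """Independent softmax/cross-entropy evaluation over cosine similarities."""
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    kn = k / np.linalg.norm(k, axis=1, keepdims=True)
    logits = qn @ kn.T / tau
    losses = []
    for i in range(len(q)):
        p = np.exp(logits[i] - logits[i].max())
        p /= p.sum()
        losses.append(-np.log(p[i]))
    return float(np.mean(losses))


def test_patchnce_uniform_similarity_equals_log_n():
    q = np.ones((5, 3))
    assert ecut.patchnce_loss(q, q.copy()) == pytest.approx(math.log(5), abs=1e-6)


def test_patchnce_perfect_positive_is_near_zero():
    # positive similarity 1, negatives 0, tau=0.07, N=256
    n, d = 256, 8
    q = np.zeros((n, d))
    q[:, 0] = 1.0
    negs = np.zeros((n, n - 1, d))
    negs[:, :, 1] = 1.0  # orthogonal to every query
    loss = ecut.patchnce_loss(q, q.copy(), negs, temperature=0.07)
    closed = -math.log(math.exp(1 / 0.07) / (math.exp(1 / 0.07) + 255))
    assert loss == pytest.approx(closed, abs=1e-6)
    assert loss < 1e-3


@pytest.mark.parametrize("n,d", [(4, 6), (16, 10)])
def test_patchnce_matches_brute_force(n, d):
    rng = np.random.default_rng(1)
    q = rng.normal(size=(n, d))
    k = rng.normal(size=(n, d))
    for tau in (0.07, 0.5):
        assert ecut.patchnce_loss(q, k, temperature=tau) == pytest.approx(
            nce_brute_force(q, k, tau), abs=1e-6)


def test_patchnce_rejects_dimension_mismatch():
    with pytest.raises(ValueError):
        ecut.patchnce_loss(np.ones((4, 3)), np.ones((5, 3)))


# --------------------------------------------------------------------------- #
# total objective
# --------------------------------------------------------------------------- #

def test_total_loss_combination_arithmetic():
    assert ecut.combine_terms(1, 2, 4, 3) == 7  # adv + (nceX+nceY)/2 + sal
    cfg = ecut.ECUTLossConfig(weight_saliency=0.0)
    assert ecut.combine_terms(1, 2, 4, 3, cfg) == 4  # saliency ablated -> CUT
    cfg2 = ecut.ECUTLossConfig(weight_adv=2.0, weight_nce=0.5, weight_saliency=1.5)
    assert ecut.combine_terms(1, 2, 4, 3, cfg2) == pytest.approx(2 + 1.5 + 4.5)


def test_total_loss_breakdown_accounts_for_total():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    y = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
    gen = ecut.ResnetGenerator(base_width=4, seed=0)
    disc = ecut.PatchDiscriminator(base_width=4, seed=1)
    cfg = ecut.ECUTLossConfig(n_patches=16, nce_dim=16)
    sampler = ecut._PatchSampler(gen.feature_channels, cfg.nce_dim, seed=2)
    total, terms = ecut.ecut_total_loss(x, y, gen, disc, cfg, sampler=sampler,
                                        rng=np.random.default_rng(3))
    assert terms["total"] == pytest.approx(
        ecut.combine_terms(terms["adv"], terms["nce_x"], terms["nce_y"],
                           terms["saliency"], cfg), rel=1e-5)
    # saliency weight 0 reproduces the CUT objective term-by-term
    cfg0 = ecut.ECUTLossConfig(n_patches=16, nce_dim=16, weight_saliency=0.0)
    total0, terms0 = ecut.ecut_total_loss(x, y, gen, disc, cfg0, sampler=sampler,
                                          rng=np.random.default_rng(3))
    for key in ("adv", "nce_x", "nce_y", "saliency"):
        assert terms0[key] == pytest.approx(terms[key], rel=1e-5)
    assert terms0["total"] == pytest.approx(terms["total"] - terms["saliency"],
                                            rel=1e-5)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        ecut.ECUTLossConfig(weight_adv=-1)
    with pytest.raises(ValueError):
        ecut.ECUTLossConfig(temperature=0)


# --------------------------------------------------------------------------- #
# integrated gradients
# --------------------------------------------------------------------------- #

class LinearScorer:
    def __init__(self, w):
        self.w = w

    def __call__(self, x):
        return (x * Tensor(self.w)).sum()


def test_integrated_gradients_exact_for_linear_scorer():
    rng = np.random.default_rng(4)
    w = rng.normal(size=(1, 3, 8, 8)).astype(np.float32)
    img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
    for steps in (1, 7, 50):
        attr = ecut.integrated_gradients(LinearScorer(w), img, steps=steps)
        x = ecut._to_net(img)
        assert np.allclose(attr, (w * x)[0], atol=1e-5)


def test_integrated_gradients_constant_scorer_is_zero():
    class Const:
        def __call__(self, x):
            return (x * 0.0).sum() + Tensor(3.0)

    img = np.random.default_rng(5).integers(0, 256, (8, 8, 3), dtype=np.uint8)
    attr = ecut.integrated_gradients(Const(), img, steps=5)
    assert np.allclose(attr, 0.0)


def test_integrated_gradients_completeness_on_discriminator(
        small_trained_discriminator):
    """Completeness axiom: attributions sum to F(x) - F(baseline) within 5%
    at 50 steps, on a small trained discriminator."""
    disc = small_trained_discriminator["discriminator"]
    img = small_trained_discriminator["tiles"][0]
    attr = ecut.integrated_gradients(disc, img, steps=50)
    x = Tensor(ecut._to_net(img))
    with nn.no_grad():
        fx = float(disc(x).mean().data)
        f0 = float(disc(Tensor(np.zeros_like(x.data))).mean().data)
    residual = abs(attr.sum() - (fx - f0)) / (abs(fx - f0) + 1e-12)
    assert residual < 0.05


# --------------------------------------------------------------------------- #
# training properties (shared tiny run)
# --------------------------------------------------------------------------- #

def test_training_decreases_generator_loss(ecut_tiny_run):
    hist = ecut_tiny_run["history"]
    assert hist["total_g"][-1] < hist["total_g"][0]


def test_training_history_reports_every_term(ecut_tiny_run):
    hist = ecut_tiny_run["history"]
    for key in ("adv_g", "adv_d", "nce_x", "nce_y", "saliency", "total_g"):
        assert len(hist[key]) == 30
        assert all(math.isfinite(v) for v in hist[key])


def test_training_improves_saliency_preservation(ecut_tiny_run):
    from conftest import saliency_iou

    trained = saliency_iou(ecut_tiny_run["generator"], ecut_tiny_run["src"])
    assert trained > ecut_tiny_run["iou_untrained"]


def test_same_seed_reproduces_history_bitwise(ecut_tiny_run):
    src, tgt = ecut_tiny_run["src"], ecut_tiny_run["tgt"]
    cfg = ecut.ECUTLossConfig(n_patches=32, nce_dim=32)
    histories = []
    for _ in range(2):
        tc = ecut.TrainConfig(epochs=2, lr_constant_epochs=1, seed=11)
        g = ecut.ResnetGenerator(base_width=4, seed=11)
        d = ecut.PatchDiscriminator(base_width=4, seed=12)
        _, _, _, h = ecut.train_ecut(src[:4], tgt[:4], g, d, cfg, tc)
        histories.append(h)
    assert histories[0]["total_g"] == histories[1]["total_g"]
    assert histories[0]["adv_d"] == histories[1]["adv_d"]


def test_train_rejects_empty_domain():
    with pytest.raises(ValueError):
        ecut.train_ecut([], [np.zeros((8, 8, 3), np.uint8)])


# --------------------------------------------------------------------------- #
# inference, serialization, scale
# --------------------------------------------------------------------------- #

def test_generator_is_fully_convolutional():
    gen = ecut.ResnetGenerator(base_width=4, seed=0)
    disc = ecut.PatchDiscriminator(base_width=4, seed=1)
    for size in (64, 128):
        img = np.zeros((size, size, 3), np.uint8)
        out = gen.translate(img)
        assert out.shape == (size, size, 3)
        assert disc.score(img) == pytest.approx(disc.score(img))


def test_virtual_stain_preserves_grid_layout(ecut_tiny_run):
    gen = ecut_tiny_run["generator"]
    slide = np.random.default_rng(6).integers(0, 256, (96, 96, 3), dtype=np.uint8)
    grid = crop_tiles(slide, 64, 0.5, modality="PAH")
    vhe = ecut.virtual_stain(gen, grid)
    assert [t.origin for t in vhe.tiles] == [t.origin for t in grid.tiles]
    stitched = stitch_tiles(vhe)
    assert stitched.shape == slide.shape


def test_virtual_stain_rejects_single_channel():
    gen = ecut.ResnetGenerator(base_width=4, seed=0)
    grid = crop_tiles(np.zeros((64, 64), np.uint8), 64, 0.0)
    with pytest.raises(ValueError, match="3-channel"):
        ecut.virtual_stain(gen, grid)


def test_identity_generator_passthrough():
    class Identity:
        def translate(self, img):
            return img

    slide = np.random.default_rng(7).integers(0, 256, (64, 64, 3), dtype=np.uint8)
    grid = crop_tiles(slide, 32, 0.0)
    out = stitch_tiles(ecut.virtual_stain(Identity(), grid))
    assert np.array_equal(out, slide)


def test_checkpoint_round_trip_bitwise(tmp_path, ecut_tiny_run):
    gen = ecut_tiny_run["generator"]
    img = ecut_tiny_run["src"][0]
    before = gen.translate(img)
    path = tmp_path / "gen.npz"
    ecut.save_checkpoint(path, gen, ecut_tiny_run["discriminator"],
                         ecut_tiny_run["sampler"])
    loaded, meta = ecut.load_checkpoint(path)
    assert meta["base_width"] == gen.base_width
    after = loaded.translate(img)
    assert np.array_equal(before, after)
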