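"""Shared fixtures.

The expensive training runs (tiny GAN training, U-Net fits, cross-validated
classifier training, the end-to-end pipeline) are session-scoped so that
property tests and acceptance tests measure the same single run instead of
retraining.
"""

from __future__ import annotations

import numpy as np
import pytest

from pahisto import ecut, segmentation as seg, stepff, synthetic as syn
from pahisto import nn as nn_mod
from pahisto.saliency import saliency_mask
from pahisto.tiling import downsample_2x, invert_intensity, stack_to_3ch


def dice_coefficient(a, b) -> float:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * np.logical_and(a, b).sum() / denom


def saliency_iou(generator, src_tiles) -> float:
    """Mean IoU between input and output saliency masks over source tiles."""
    ious = []
    for s in src_tiles:
        out = generator.translate(s)
        m_in = saliency_mask(s.astype(float).mean(axis=2), 90) > 0.5
        m_out = saliency_mask(out, 170) > 0.5
        union = np.logical_or(m_in, m_out).sum()
        inter = np.logical_and(m_in, m_out).sum()
        ious.append(inter / union if union else 1.0)
    return float(np.mean(ious))


@pytest.fixture(scope="session")
def tile_dataset_64():
    """16 scenes (8 per class) at 64 px with all three renders."""
    return syn.generate_dataset(8, canvas_size=(64, 64), seed=7)


@pytest.fixture(scope="session")
def ecut_tiny_run(tile_dataset_64):
    """30-epoch unpaired training on 16 tiles per domain (desk profile)."""
    items = tile_dataset_64
    src = [stack_to_3ch(invert_intensity(it.pah.pixels)) for it in items]
    tgt = [it.he.pixels for it in items]
    loss_cfg = ecut.ECUTLossConfig(n_patches=64, nce_dim=64)
    g0 = ecut.ResnetGenerator(base_width=8, seed=1)
    iou_untrained = saliency_iou(g0, src)
    train_cfg = ecut.TrainConfig(epochs=30, lr_constant_epochs=15, seed=1)
    disc = ecut.PatchDiscriminator(base_width=8, seed=2)
    gen, disc, sampler, history = ecut.train_ecut(
        src, tgt, g0, disc, loss_cfg, train_cfg)
    return {"generator": gen, "discriminator": disc, "sampler": sampler,
            "history": history, "src": src, "tgt": tgt,
            "iou_untrained": iou_untrained, "loss_cfg": loss_cfg}


class NormFreeDiscriminator(nn_mod.Module):
    """Small patch discriminator without normalization layers.

    Its score is piecewise linear in the input, so a 50-step path integral is
    an accurate quadrature — the right instrument for checking the
    integrated-gradients completeness axiom.  (The full patch discriminator
    uses instance norm, which concentrates path-gradient mass in a thin layer
    near the black baseline; see docs/methods.md.)
    """

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.c1 = nn_mod.Conv2d(3, 8, 4, stride=2, padding=1, rng=rng)
        self.c2 = nn_mod.Conv2d(8, 16, 4, stride=2, padding=1, rng=rng)
        self.c3 = nn_mod.Conv2d(16, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x):
        h = self.c1(x).leaky_relu(0.2)
        h = self.c2(h).leaky_relu(0.2)
        return self.c3(h)


@pytest.fixture(scope="session")
def small_trained_discriminator(tile_dataset_64):
    """Norm-free discriminator trained for 40 adversarial steps."""
    items = tile_dataset_64
    src = [stack_to_3ch(invert_intensity(it.pah.pixels)) for it in items]
    tgt = [it.he.pixels for it in items]
    disc = NormFreeDiscriminator(seed=3)
    opt = nn_mod.Adam(disc.parameters(), lr=2e-4, betas=(0.5, 0.999))
    from pahisto.nn import Tensor

    for step in range(40):
        d_real = disc(Tensor(ecut._to_net(tgt[step % len(tgt)])))
        d_fake = disc(Tensor(ecut._to_net(src[step % len(src)])))
        loss = ecut.adversarial_loss(d_real, d_fake, "discriminator")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return {"discriminator": disc, "tiles": tgt}


@pytest.fixture(scope="session")
def unet_overfit_run():
    """Capacity check: fit 8 synthetic 64-px tiles to convergence."""
    items = syn.generate_dataset(4, canvas_size=(64, 64), seed=21)
    pairs = [(invert_intensity(it.pah.pixels), it.mask.pixels) for it in items]
    cfg = seg.UNetTrainConfig(lr=1e-4, batch_size=1, epochs=300, patience=0,
                              val_fraction=0.0, augment_flips=False, seed=5)
    model = seg.UNet(base_width=8, seed=5)
    model, history = seg.train_unet(pairs, model, cfg, val_dataset=[])
    return {"model": model, "pairs": pairs, "history": history}


@pytest.fixture(scope="session")
def unet_heldout_run():
    """Generalization check: 16 training tiles, 8 held out."""
    items = syn.generate_dataset(12, canvas_size=(64, 64), seed=21)
    pairs = [(invert_intensity(it.pah.pixels), it.mask.pixels) for it in items]
    train, test = pairs[:16], pairs[16:]
    cfg = seg.UNetTrainConfig(lr=1e-4, batch_size=2, epochs=300, patience=25,
                              val_fraction=0.2, augment_flips=True, seed=5)
    model = seg.UNet(base_width=8, seed=5)
    model, history = seg.train_unet(train, model, cfg)
    return {"model": model, "train": train, "test": test, "history": history}


def _stepff_records(n_per_class=100, seed=11):
    """Default synthetic dataset prepared for classification: 128-px scenes,
    2x-downsampled twice to 32-px network inputs, ground-truth-mask features."""
    items = syn.generate_dataset(n_per_class, canvas_size=(128, 128), seed=seed)
    records = []
    for it in items:
        f = seg.extract_features(it.mask.pixels, min_area=10)
        sf = [f.cell_area if np.isfinite(f.cell_area) else 0.0,
              float(f.cell_count),
              f.mean_distance if np.isfinite(f.mean_distance) else 128.0]
        records.append({
            "pah": downsample_2x(downsample_2x(invert_intensity(it.pah.pixels))),
            "vhe": downsample_2x(downsample_2x(it.he.pixels)),
            "seg": sf * 2,
            "label": 1 if it.label == syn.CANCEROUS else 0,
        })
    return records


@pytest.fixture(scope="session")
def stepff_records():
    return _stepff_records()


def _stepff_cfg(modalities=stepff.ALL_MODALITIES, seed=3):
    return stepff.StepFFTrainConfig(base_width=2, epochs=120, patience=12,
                                    batch_size=32, folds=5, seed=seed,
                                    modalities=modalities)


@pytest.fixture(scope="session")
def stepff_cv_fused(stepff_records):
    return stepff.train_stepff(stepff_records, _stepff_cfg())


@pytest.fixture(scope="session")
def stepff_cv_singles(stepff_records):
    out = {}
    for mods in (("pah",), ("vhe",)):
        out[mods[0]] = stepff.train_stepff(stepff_records, _stepff_cfg(mods))
    return out


@pytest.fixture(scope="session")
def stepff_cv_permuted(stepff_records):
    rng = np.random.default_rng(99)
    perm = rng.permutation([r["label"] for r in stepff_records])
    shuffled = [dict(r, label=int(l)) for r, l in zip(stepff_records, perm)]
    return stepff.train_stepff(shuffled, _stepff_cfg())


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The smoke pipeline executed twice from the same seed (determinism)."""
    from pahisto.config import desk_profile
    from pahisto.pipeline import run_pipeline

    manifests, dirs = [], []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"pipe_{tag}")
        cfg = desk_profile(seed=1, out_dir=str(out))
        cfg.verbosity = 0
        manifests.append(run_pipeline(cfg))
        dirs.append(out)
    return {"manifests": manifests, "dirs": dirs}
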