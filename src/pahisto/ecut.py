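"""Contrastive unpaired translation with saliency supervision (E-CUT).

Translates label-free (inverted, 3-channel-stacked) tiles into H&E-style
tiles without paired training data.  One ResNet-style generator and one
70x70-receptive-field patch discriminator are trained with

    total = l_adv + (l_PatchNCE(X) + l_PatchNCE(Y)) / 2 + l_Saliency

* ``l_adv``           — least-squares GAN objective;
* ``l_PatchNCE``      — InfoNCE over matched encoder-feature patches of the
  input and the translated output (the Y term is the identity pass G(y),
  discouraging unnecessary changes);
* ``l_Saliency``      — L1 distance between the soft-threshold saliency mask
  of the source tile and that of the translated tile, keeping nuclear
  structure where the unpaired objective alone could drop it.

The discriminator additionally supports integrated-gradients attribution so
training can be inspected: which input pixels drive the real/fake decision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .saliency import SaliencyThresholds, saliency_mask
from .tiling import ImageTile, TileGrid

__all__ = [
    "ResnetGenerator", "PatchDiscriminator", "ECUTLossConfig", "TrainConfig",
    "adversarial_loss", "patchnce_loss", "combine_terms", "ecut_total_loss",
    "train_ecut", "integrated_gradients", "virtual_stain",
    "save_checkpoint", "load_checkpoint",
]


# --------------------------------------------------------------------------- #
# networks
# --------------------------------------------------------------------------- #

class _ResBlock(nn.Module):
    def __init__(self, ch, rng):
        self.c1 = nn.Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.n1 = nn.InstanceNorm2d(ch)
        self.c2 = nn.Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.n2 = nn.InstanceNorm2d(ch)

    def forward(self, x):
        h = self.n1(self.c1(x)).relu()
        return x + self.n2(self.c2(h))


class ResnetGenerator(nn.Module):
    """Fully convolutional generator: two downsampling stages, nine residual
    blocks, two upsampling stages; output spatial dims equal input dims.

    ``base_width`` is 64 at full scale; the desk profile uses 8.
    """

    N_BLOCKS = 9

    def __init__(self, base_width: int = 64, in_ch: int = 3, out_ch: int = 3,
                 n_blocks: int = 9, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = base_width
        self.base_width = base_width
        self.n_blocks = n_blocks
        self.head = nn.Conv2d(in_ch, w, 7, padding=3, rng=rng)
        self.head_norm = nn.InstanceNorm2d(w)
        self.down1 = nn.Conv2d(w, 2 * w, 3, stride=2, padding=1, rng=rng)
        self.down1_norm = nn.InstanceNorm2d(2 * w)
        self.down2 = nn.Conv2d(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng)
        self.down2_norm = nn.InstanceNorm2d(4 * w)
        self.blocks = nn.ModuleList(_ResBlock(4 * w, rng) for _ in range(n_blocks))
        self.up1 = nn.Conv2d(4 * w, 2 * w, 3, padding=1, rng=rng)
        self.up1_norm = nn.InstanceNorm2d(2 * w)
        self.up2 = nn.Conv2d(2 * w, w, 3, padding=1, rng=rng)
        self.up2_norm = nn.InstanceNorm2d(w)
        self.tail = nn.Conv2d(w, out_ch, 7, padding=3, rng=rng)

    # encoder feature taps used by PatchNCE: input, head, down1, down2,
    # and the middle residual block
    @property
    def feature_channels(self):
        w = self.base_width
        return [3, w, 2 * w, 4 * w, 4 * w]

    def encode(self, x: Tensor) -> list[Tensor]:
        feats = [x]
        h = self.head_norm(self.head(x)).relu()
        feats.append(h)
        h = self.down1_norm(self.down1(h)).relu()
        feats.append(h)
        h = self.down2_norm(self.down2(h)).relu()
        feats.append(h)
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if i == self.n_blocks // 2:
                feats.append(h)
        return feats

    def forward(self, x: Tensor, return_feats: bool = False):
        feats = [x]
        h = self.head_norm(self.head(x)).relu()
        feats.append(h)
        h = self.down1_norm(self.down1(h)).relu()
        feats.append(h)
        h = self.down2_norm(self.down2(h)).relu()
        feats.append(h)
        mid = None
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if i == self.n_blocks // 2:
                mid = h
        feats.append(mid)
        h = self.up1_norm(self.up1(h.upsample2x())).relu()
        h = self.up2_norm(self.up2(h.upsample2x())).relu()
        out = self.tail(h).tanh()
        return (out, feats) if return_feats else out

    def translate(self, image: np.ndarray) -> np.ndarray:
        """uint8 HxWx3 -> uint8 HxWx3 through the generator."""
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("generator input must be 3-channel")
        x = Tensor(_to_net(image))
        with nn.no_grad():
            y = self(x)
        return _to_uint8(y.data[0])


class PatchDiscriminator(nn.Module):
    """PatchGAN classifier: a score map whose every element sees a 70x70
    input patch; works on any input size >= 70 (smaller inputs yield patches
    that see the whole zero-padded field).  Scalar score = map mean."""

    RECEPTIVE_FIELD = 70

    def __init__(self, base_width: int = 64, in_ch: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = base_width
        self.base_width = base_width
        self.c1 = nn.Conv2d(in_ch, w, 4, stride=2, padding=1, rng=rng)
        self.c2 = nn.Conv2d(w, 2 * w, 4, stride=2, padding=1, rng=rng)
        self.n2 = nn.InstanceNorm2d(2 * w)
        self.c3 = nn.Conv2d(2 * w, 4 * w, 4, stride=2, padding=1, rng=rng)
        self.n3 = nn.InstanceNorm2d(4 * w)
        self.c4 = nn.Conv2d(4 * w, 8 * w, 4, stride=1, padding=1, rng=rng)
        self.n4 = nn.InstanceNorm2d(8 * w)
        self.c5 = nn.Conv2d(8 * w, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).leaky_relu(0.2)
        h = self.n2(self.c2(h)).leaky_relu(0.2)
        h = self.n3(self.c3(h)).leaky_relu(0.2)
        h = self.n4(self.c4(h)).leaky_relu(0.2)
        return self.c5(h)

    def score(self, image: np.ndarray) -> float:
        with nn.no_grad():
            return float(self(Tensor(_to_net(np.asarray(image)))).data.mean())


def _to_net(image: np.ndarray) -> np.ndarray:
    """uint8 HxWxC (or HxW) -> float32 (1,C,H,W) in [-1, 1]."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[:, :, None]
    return (img.transpose(2, 0, 1)[None] / 127.5) - 1.0


def _to_uint8(chw: np.ndarray) -> np.ndarray:
    img = (np.clip(chw, -1.0, 1.0) + 1.0) * 127.5
    return np.rint(img).astype(np.uint8).transpose(1, 2, 0)


# --------------------------------------------------------------------------- #
# losses
# --------------------------------------------------------------------------- #

def adversarial_loss(disc_scores_real, disc_scores_fake, side: str):
    """Least-squares GAN objective on discriminator score maps.

    discriminator side: mean((real - 1)^2 + fake^2) / 2
    generator side:     mean((fake - 1)^2)

    Accepts numpy arrays (returns float) or Tensors (returns a Tensor so the
    loss participates in backprop).
    """
    tensor_mode = isinstance(disc_scores_fake, Tensor)
    fake = disc_scores_fake if tensor_mode else np.asarray(disc_scores_fake, float)
    if side == "generator":
        loss = ((fake - 1.0) ** 2).mean()
    elif side == "discriminator":
        real = disc_scores_real if isinstance(disc_scores_real, Tensor) \
            else np.asarray(disc_scores_real, float)
        loss = (((real - 1.0) ** 2).mean() + (fake**2).mean()) * 0.5
    else:
        raise ValueError("side must be 'generator' or 'discriminator'")
    return loss if tensor_mode else float(loss)


def _l2norm(t: Tensor, eps: float = 1e-10) -> Tensor:
    return t * (((t * t).sum(axis=-1, keepdims=True) + eps) ** -0.5)


def _nce_from_logits(logits: Tensor, positive_index: np.ndarray) -> Tensor:
    shift = logits.data.max(axis=-1, keepdims=True)
    z = logits - Tensor(shift)
    lse = z.exp().sum(axis=-1).log()
    pos = z[np.arange(z.shape[0]), positive_index]
    return (lse - pos).mean()


def patchnce_loss(query_feats, positive_feats, negative_feats=None,
                  temperature: float = 0.07):
    """InfoNCE over patch features (cosine similarity / temperature).

    query/positive: (N, d) matched rows.  If ``negative_feats`` is None the
    negatives for query i are the other N-1 positives (the CUT internal-patch
    scheme); otherwise an explicit (N, M, d) bank is used.  Accepts numpy
    arrays or Tensors; returns float or Tensor accordingly.
    """
    tensor_mode = isinstance(query_feats, Tensor)
    q = query_feats if tensor_mode else Tensor(np.asarray(query_feats))
    k = positive_feats if isinstance(positive_feats, Tensor) \
        else Tensor(np.asarray(positive_feats))
    if q.shape != k.shape or q.ndim != 2:
        raise ValueError("query and positive features must both be (N, d)")
    qn, kn = _l2norm(q), _l2norm(k)
    n = q.shape[0]
    if negative_feats is None:
        logits = (qn @ kn.transpose((1, 0))) * (1.0 / temperature)
        loss = _nce_from_logits(logits, np.arange(n))
    else:
        neg = negative_feats if isinstance(negative_feats, Tensor) \
            else Tensor(np.asarray(negative_feats))
        if neg.ndim != 3 or neg.shape[0] != n or neg.shape[2] != q.shape[1]:
            raise ValueError("negatives must be (N, M, d)")
        nn_ = _l2norm(neg)
        pos_logit = (qn * kn).sum(axis=-1, keepdims=True)
        neg_logit = (nn_ @ qn.reshape(n, q.shape[1], 1)).reshape(n, neg.shape[1])
        logits = nn.concat([pos_logit, neg_logit], axis=1) * (1.0 / temperature)
        loss = _nce_from_logits(logits, np.zeros(n, dtype=int))
    return loss if tensor_mode else float(loss.data)


@dataclass
class ECUTLossConfig:
    weight_adv: float = 1.0
    weight_nce: float = 1.0
    weight_saliency: float = 1.0
    temperature: float = 0.07
    n_patches: int = 256
    nce_dim: int = 256
    thresholds: SaliencyThresholds = field(default_factory=SaliencyThresholds)

    def __post_init__(self):
        if min(self.weight_adv, self.weight_nce, self.weight_saliency) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class TrainConfig:
    epochs: int = 400
    lr: float = 2e-4
    lr_constant_epochs: int = 200
    betas: tuple = (0.5, 0.999)
    batch_size: int = 1
    augment_hflip: bool = True
    seed: int = 0
    snapshot_every: int | None = None   # epochs between saliency/IG snapshots
    snapshot_per_step: bool = False


def combine_terms(adv: float, nce_x: float, nce_y: float, sal: float,
                  cfg: ECUTLossConfig | None = None):
    """total = w_adv * adv + w_nce * (nce_x + nce_y)/2 + w_sal * sal."""
    cfg = cfg or ECUTLossConfig()
    return (cfg.weight_adv * adv + cfg.weight_nce * (nce_x + nce_y) * 0.5
            + cfg.weight_saliency * sal)


class _PatchSampler(nn.Module):
    """Per-tap 2-layer projection heads mapping sampled patch features to the
    shared embedding space."""

    def __init__(self, channels: list[int], dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.heads = nn.ModuleList()
        for c in channels:
            self.heads.append(nn.Sequential(
                nn.Linear(c, dim, rng=rng), nn.ReLU(),
                nn.Linear(dim, dim, rng=rng)))

    def sample(self, feats: list[Tensor], n_patches: int,
               rng: np.random.Generator | None = None,
               ids: list[np.ndarray] | None = None):
        """Project n_patches random spatial locations per tap.  Returns the
        projected (N, dim) tensors and the location ids (so the second image
        of a pair reuses identical locations)."""
        out, out_ids = [], []
        for li, f in enumerate(feats):
            _, c, h, w = f.shape
            flat = f.reshape(c, h * w).transpose((1, 0))
            if ids is not None:
                idx = ids[li]
            else:
                n = min(n_patches, h * w)
                idx = np.sort(rng.choice(h * w, size=n, replace=False))
            out.append(self.heads[li](flat[idx]))
            out_ids.append(idx)
        return out, out_ids


def _saliency_term(x_img_255: np.ndarray, gen_out: Tensor,
                   thr: SaliencyThresholds) -> Tensor:
    """Differentiable L1 between the source saliency mask (constant) and the
    mask of the generated tile (through the tanh output, rescaled to 0-255)."""
    src_mask = saliency_mask(x_img_255, thr.x_threshold, thr.slope)
    y255 = (gen_out + 1.0) * 127.5
    gray = y255.mean(axis=1)                     # (N, H, W) channel average
    m = 1.0 - ((gray - thr.y_threshold) * thr.slope).sigmoid()
    return (m - Tensor(src_mask[None])).abs().mean()


def ecut_total_loss(x_img: np.ndarray, y_img: np.ndarray,
                    generator: ResnetGenerator,
                    discriminator: PatchDiscriminator,
                    cfg: ECUTLossConfig | None = None,
                    sampler: "_PatchSampler | None" = None,
                    rng: np.random.Generator | None = None):
    """Generator-side objective on one unpaired (x, y) pair of uint8 tiles.

    Returns (total: Tensor, breakdown: dict of floats).  The breakdown always
    satisfies total = combine_terms(adv, nce_x, nce_y, saliency, cfg).
    """
    cfg = cfg or ECUTLossConfig()
    rng = rng or np.random.default_rng(0)
    sampler = sampler or _PatchSampler(generator.feature_channels, cfg.nce_dim)
    xt, yt = Tensor(_to_net(x_img)), Tensor(_to_net(y_img))
    fake, feats_x = generator(xt, return_feats=True)
    adv = adversarial_loss(None, discriminator(fake), side="generator")
    feats_fake = generator.encode(fake)
    k_x, ids = sampler.sample(feats_x, cfg.n_patches, rng)
    q_fake, _ = sampler.sample(feats_fake, cfg.n_patches, ids=ids)
    nce_x = sum((patchnce_loss(q, k, temperature=cfg.temperature)
                 for q, k in zip(q_fake, k_x)),
                start=Tensor(0.0)) * (1.0 / len(k_x))
    idt, feats_y = generator(yt, return_feats=True)
    feats_idt = generator.encode(idt)
    k_y, ids_y = sampler.sample(feats_y, cfg.n_patches, rng)
    q_idt, _ = sampler.sample(feats_idt, cfg.n_patches, ids=ids_y)
    nce_y = sum((patchnce_loss(q, k, temperature=cfg.temperature)
                 for q, k in zip(q_idt, k_y)),
                start=Tensor(0.0)) * (1.0 / len(k_y))
    x255 = np.asarray(x_img, dtype=np.float64)
    if x255.ndim == 3:
        x255 = x255.mean(axis=2)
    sal = _saliency_term(x255, fake, cfg.thresholds)
    total = (cfg.weight_adv * adv + cfg.weight_nce * (nce_x + nce_y) * 0.5
             + cfg.weight_saliency * sal)
    breakdown = {"adv": float(adv.data), "nce_x": float(nce_x.data),
                 "nce_y": float(nce_y.data), "saliency": float(sal.data),
                 "total": float(total.data)}
    return total, breakdown


# --------------------------------------------------------------------------- #
# training
# --------------------------------------------------------------------------- #

def train_ecut(source_tiles, target_tiles,
               generator: ResnetGenerator | None = None,
               discriminator: PatchDiscriminator | None = None,
               loss_cfg: ECUTLossConfig | None = None,
               train_cfg: TrainConfig | None = None,
               snapshot_dir=None):
    """Alternating GAN training on unpaired uint8 tile lists.

    Returns (generator, discriminator, sampler, history).  The history maps
    term name -> per-epoch mean, and optionally carries saliency-mask and
    attribution snapshots.  Fixed seeds reproduce it bitwise.
    """
    if len(source_tiles) == 0 or len(target_tiles) == 0:
        raise ValueError("both domains must contain at least one tile")
    loss_cfg = loss_cfg or ECUTLossConfig()
    tc = train_cfg or TrainConfig()
    generator = generator or ResnetGenerator(seed=tc.seed)
    discriminator = discriminator or PatchDiscriminator(
        base_width=max(4, generator.base_width), seed=tc.seed + 1)
    sampler = _PatchSampler(generator.feature_channels, loss_cfg.nce_dim,
                            seed=tc.seed + 2)
    rng = np.random.default_rng(tc.seed + 3)
    g_params = generator.parameters() + sampler.parameters()
    opt_g = nn.Adam(g_params, lr=tc.lr, betas=tc.betas)
    opt_d = nn.Adam(discriminator.parameters(), lr=tc.lr, betas=tc.betas)
    history: dict = {k: [] for k in
                     ("adv_g", "adv_d", "nce_x", "nce_y", "saliency", "total_g")}
    history["snapshots"] = []
    n_steps = min(len(source_tiles), len(target_tiles))
    for epoch in range(tc.epochs):
        lr = nn.linear_decay_lr(epoch, tc.lr, tc.lr_constant_epochs, tc.epochs)
        opt_g.lr = lr
        opt_d.lr = lr
        xs_order = rng.permutation(len(source_tiles))[:n_steps]
        ys_order = rng.permutation(len(target_tiles))[:n_steps]
        sums = {k: 0.0 for k in ("adv_g", "adv_d", "nce_x", "nce_y",
                                 "saliency", "total_g")}
        for xi, yi in zip(xs_order, ys_order):
            x_img = np.asarray(source_tiles[xi])
            y_img = np.asarray(target_tiles[yi])
            if tc.augment_hflip:    # flips drawn independently per domain
                if rng.random() < 0.5:
                    x_img = np.ascontiguousarray(x_img[:, ::-1])
                if rng.random() < 0.5:
                    y_img = np.ascontiguousarray(y_img[:, ::-1])
            # -- discriminator update
            with nn.no_grad():
                fake_detached = generator(Tensor(_to_net(x_img)))
            d_real = discriminator(Tensor(_to_net(y_img)))
            d_fake = discriminator(Tensor(fake_detached.data))
            d_loss = adversarial_loss(d_real, d_fake, side="discriminator")
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()
            # -- generator (+ projection heads) update
            total, terms = ecut_total_loss(x_img, y_img, generator,
                                           discriminator, loss_cfg,
                                           sampler=sampler, rng=rng)
            if not math.isfinite(terms["total"]):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}")
            opt_g.zero_grad()
            total.backward()
            opt_g.step()
            sums["adv_d"] += float(d_loss.data)
            sums["adv_g"] += terms["adv"]
            sums["nce_x"] += terms["nce_x"]
            sums["nce_y"] += terms["nce_y"]
            sums["saliency"] += terms["saliency"]
            sums["total_g"] += terms["total"]
        for k, v in sums.items():
            history[k].append(v / n_steps)
        if tc.snapshot_every and (epoch % tc.snapshot_every == 0
                                  or epoch == tc.epochs - 1):
            _store_snapshot(history, snapshot_dir, epoch, source_tiles[0],
                            generator, discriminator, loss_cfg)
    return generator, discriminator, sampler, history


def _store_snapshot(history, snapshot_dir, epoch, x_img, generator,
                    discriminator, loss_cfg):
    x_img = np.asarray(x_img)
    out = generator.translate(x_img)
    thr = loss_cfg.thresholds
    m_in = saliency_mask(x_img.astype(np.float64).mean(axis=2), thr.x_threshold,
                         thr.slope)
    m_out = saliency_mask(out, thr.y_threshold, thr.slope)
    attr = integrated_gradients(discriminator, out, steps=8)
    history["snapshots"].append({"epoch": epoch})
    if snapshot_dir is not None:
        from pathlib import Path

        from .tiling import write_image

        d = Path(snapshot_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_image(d / f"epoch{epoch:04d}_saliency_in.png",
                    (m_in * 255).astype(np.uint8))
        write_image(d / f"epoch{epoch:04d}_saliency_out.png",
                    (m_out * 255).astype(np.uint8))
        a = np.abs(attr).sum(axis=0)
        amax = a.max() or 1.0
        write_image(d / f"epoch{epoch:04d}_attribution.png",
                    (a / amax * 255).astype(np.uint8))
        write_image(d / f"epoch{epoch:04d}_vhe.png", out)


# --------------------------------------------------------------------------- #
# attribution and inference
# --------------------------------------------------------------------------- #

def integrated_gradients(discriminator, image, steps: int = 50,
                         baseline=None) -> np.ndarray:
    """Integrated-gradients attribution of the mean discriminator score.

    IG_i = (x_i - b_i) * mean_{k=1..steps} dF/dx_i at b + (k/steps)(x - b);
    the default baseline is the zero (black) image.  ``image`` is uint8 HxWxC
    (or an already normalized (1,C,H,W) float array); the attribution is
    returned as a (C, H, W) float array in the normalized input space.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    img = np.asarray(image)
    x = img.astype(np.float32) if img.ndim == 4 else _to_net(img)
    b = np.zeros_like(x) if baseline is None else np.asarray(baseline, np.float32)
    if b.shape != x.shape:
        b = _to_net(baseline)
    grad_sum = np.zeros_like(x)
    for k in range(1, steps + 1):
        xk = Tensor(b + (k / steps) * (x - b), requires_grad=True)
        score = discriminator(xk).mean()
        score.backward()
        grad_sum += xk.grad
    return ((x - b) * grad_sum / steps)[0]


def virtual_stain(generator, pah_tiles: TileGrid) -> TileGrid:
    """Translate every tile of a (3-channel) grid; origins are preserved so
    the stitched output lines up with the stitched input."""
    out_tiles = []
    for tile in pah_tiles.tiles:
        if tile.pixels.ndim != 3 or tile.pixels.shape[2] != 3:
            raise ValueError("virtual_stain expects 3-channel tiles "
                             "(use stack_to_3ch first)")
        out = generator.translate(tile.pixels)
        out_tiles.append(ImageTile(out, origin=tile.origin, modality="VHE"))
    return TileGrid(out_tiles, canvas_size=pah_tiles.canvas_size,
                    tile_size=pah_tiles.tile_size, stride=pah_tiles.stride,
                    padded_size=pah_tiles.padded_size,
                    pad_value=pah_tiles.pad_value)


def save_checkpoint(path, generator: ResnetGenerator,
                    discriminator: PatchDiscriminator | None = None,
                    sampler=None, extra_meta: dict | None = None):
    """Self-describing .npz checkpoint (architecture meta + parameters)."""
    bundle = nn.Module()
    bundle.generator = generator
    meta = {"base_width": generator.base_width, "n_blocks": generator.n_blocks,
            **(extra_meta or {})}
    if discriminator is not None:
        bundle.discriminator = discriminator
        meta["disc_base_width"] = discriminator.base_width
    if sampler is not None:
        bundle.sampler = sampler
    nn.save_state(path, bundle, meta=meta)


def load_checkpoint(path) -> tuple[ResnetGenerator, dict]:
    import json as _json

    with np.load(path) as z:
        header = _json.loads(bytes(z["__header__"]).decode())
        keys = [k for k in z.files if k != "__header__"]
        state = {k: z[k] for k in keys}
    meta = header["meta"]
    generator = ResnetGenerator(base_width=meta["base_width"],
                                n_blocks=meta["n_blocks"])
    gstate = {k[len("generator."):]: v for k, v in state.items()
              if k.startswith("generator.")}
    generator.load_state_dict(gstate)
    return generator, meta
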