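"""Stepwise deep-feature-fusion classification (StepFF) and agreement stats.

Each modality contributes a 16-dimensional deep feature vector (DFV):

* the label-free (PAH) tile through a 1-channel ResNet-style backbone,
* the virtually stained (VHE) tile through a 3-channel backbone,
* the six morphometric features (area/count/distance from PAH and VHE
  segmentations), z-normalized with training-fold statistics, through a
  linear map.

The three DFVs are concatenated in the fixed order (PAH || VHE || SEG) into a
48-dimensional vector and a final fully connected layer produces two logits
(noncancerous, cancerous) under focal loss.  Training uses stratified
five-fold cross-validation with the normalizer refitted per training fold.
Single- and dual-modality ablations use the same machinery with a shorter
fused vector.

The module also houses the per-tile cancer-probability map renderer and the
inter-rater kappa statistics used to compare gradings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .tiling import ImageTile, TileGrid, stitch_tiles

__all__ = [
    "StepFFModel", "StepFFTrainConfig", "SegFeatureNormalizer",
    "focal_loss", "extract_dfv", "fuse_predict", "train_stepff",
    "classification_metrics", "probability_map", "cohens_kappa",
    "fleiss_kappa",
]

DFV_DIM = 16
PROB_BLUE = (0, 0, 255)      # p = 0
PROB_PURPLE = (128, 0, 128)  # p = 1


# --------------------------------------------------------------------------- #
# backbone
# --------------------------------------------------------------------------- #

class _BasicBlock(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.n1 = nn.BatchNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, padding=1, rng=rng)
        self.n2 = nn.BatchNorm2d(cout)
        self.proj = (nn.Conv2d(cin, cout, 1, stride=stride, rng=rng)
                     if (stride != 1 or cin != cout) else None)

    def forward(self, x):
        h = self.n1(self.c1(x)).relu()
        h = self.n2(self.c2(h))
        skip = self.proj(x) if self.proj is not None else x
        return (h + skip).relu()


class ResNetBackbone(nn.Module):
    """ResNet-18-style backbone: four stages of two basic blocks each, global
    average pooling to an ``8 * base_width``-dim embedding (512 at the
    classic width 64; the desk profile uses width 4 -> 32)."""

    def __init__(self, in_ch: int = 3, base_width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = base_width
        self.in_ch = in_ch
        self.base_width = base_width
        self.stem = nn.Conv2d(in_ch, w, 3, padding=1, rng=rng)
        self.stem_norm = nn.BatchNorm2d(w)
        stages = []
        cin = w
        for si, cout in enumerate([w, 2 * w, 4 * w, 8 * w]):
            stride = 1 if si == 0 else 2
            stages.append(_BasicBlock(cin, cout, stride, rng))
            stages.append(_BasicBlock(cout, cout, 1, rng))
            cin = cout
        self.stages = nn.ModuleList(stages)
        self.embed_dim = 8 * w

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"backbone expects {self.in_ch} channel(s), "
                             f"got {x.shape[1]}")
        h = self.stem_norm(self.stem(x)).relu()
        for blk in self.stages:
            h = blk(h)
        return h.mean(axis=(2, 3))


# --------------------------------------------------------------------------- #
# normalizer and model
# --------------------------------------------------------------------------- #

class SegFeatureNormalizer:
    """Per-feature z-normalization of the 6 morphometric features, fitted on
    the training fold only.  Degenerate (constant) features get sd = 1."""

    def __init__(self):
        self.mean = None
        self.sd = None

    def fit(self, features: np.ndarray) -> "SegFeatureNormalizer":
        f = np.asarray(features, dtype=np.float64)
        self.mean = f.mean(axis=0)
        sd = f.std(axis=0, ddof=0)
        sd[sd < 1e-8] = 1.0
        self.sd = sd
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("normalizer not fitted")
        return (np.asarray(features, dtype=np.float64) - self.mean) / self.sd


ALL_MODALITIES = ("pah", "vhe", "seg")


class StepFFModel(nn.Module):
    """Modality branches -> 16-dim DFVs -> concatenation -> 2-logit head."""

    def __init__(self, base_width: int = 64, modalities=ALL_MODALITIES,
                 seed: int = 0, seg_dim: int = 6):
        self.modalities = tuple(modalities)
        if not self.modalities:
            raise ValueError("at least one modality required")
        rng = np.random.default_rng(seed + 17)
        self.base_width = base_width
        self.seg_dim = seg_dim
        if "pah" in self.modalities:
            self.pah_backbone = ResNetBackbone(1, base_width, seed=seed)
            self.pah_fc = nn.Linear(self.pah_backbone.embed_dim, DFV_DIM, rng=rng)
        if "vhe" in self.modalities:
            self.vhe_backbone = ResNetBackbone(3, base_width, seed=seed + 1)
            self.vhe_fc = nn.Linear(self.vhe_backbone.embed_dim, DFV_DIM, rng=rng)
        if "seg" in self.modalities:
            self.seg_fc = nn.Linear(seg_dim, DFV_DIM, rng=rng)
        self.head = nn.Linear(DFV_DIM * len(self.modalities), 2, rng=rng)

    def dfvs(self, pah=None, vhe=None, seg=None) -> list[Tensor]:
        out = []
        for m in self.modalities:
            if m == "pah":
                if pah is None:
                    raise ValueError("pah modality configured but no PAH input")
                out.append(self.pah_fc(self.pah_backbone(pah)))
            elif m == "vhe":
                if vhe is None:
                    raise ValueError("vhe modality configured but no VHE input")
                out.append(self.vhe_fc(self.vhe_backbone(vhe)))
            else:
                if seg is None:
                    raise ValueError("seg modality configured but no features")
                out.append(self.seg_fc(seg))
        return out

    def forward(self, pah=None, vhe=None, seg=None) -> Tensor:
        fused = nn.concat(self.dfvs(pah, vhe, seg), axis=1)
        return self.head(fused)


def _img_to_net(img: np.ndarray, channels: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if channels == 1:
        if img.ndim == 3:
            img = img.mean(axis=2)
        img = img[None]
    else:
        img = img.transpose(2, 0, 1)
    return img / 127.5 - 1.0


def extract_dfv(model: StepFFModel, modality: str, inputs) -> np.ndarray:
    """16-dim DFV(s) for one modality; deterministic for fixed weights.

    ``inputs`` is a single image / 6-vector (already normalized for seg) or a
    batch thereof; returns (16,) or (n, 16).
    """
    single = False
    if modality in ("pah", "vhe"):
        ch = 1 if modality == "pah" else 3
        arr = np.asarray(inputs)
        if arr.ndim in (2, 3) and not (modality == "vhe" and arr.ndim == 4):
            if modality == "pah" and arr.ndim == 2:
                arr, single = arr[None], True
            elif modality == "vhe" and arr.ndim == 3:
                arr, single = arr[None], True
        x = Tensor(np.stack([_img_to_net(a, ch) for a in arr]))
        model.set_training(False)
        with nn.no_grad():
            if modality == "pah":
                out = model.pah_fc(model.pah_backbone(x))
            else:
                out = model.vhe_fc(model.vhe_backbone(x))
    elif modality == "seg":
        arr = np.asarray(inputs, dtype=np.float32)
        if arr.ndim == 1:
            arr, single = arr[None], True
        model.set_training(False)
        with nn.no_grad():
            out = model.seg_fc(Tensor(arr))
    else:
        raise ValueError(f"unknown modality {modality!r}")
    res = out.data
    return res[0] if single else res


def fuse_predict(model: StepFFModel, pah_tile=None, vhe_tile=None,
                 seg_features=None, normalizer: SegFeatureNormalizer | None = None
                 ) -> float:
    """Cancer probability in [0, 1] for a single tile (softmax over the two
    logits; the cancerous-class probability is returned).  Every modality the
    model was configured with must be supplied."""
    kwargs = {}
    if "pah" in model.modalities:
        if pah_tile is None:
            raise ValueError("model requires a PAH tile")
        kwargs["pah"] = Tensor(_img_to_net(pah_tile, 1)[None])
    if "vhe" in model.modalities:
        if vhe_tile is None:
            raise ValueError("model requires a VHE tile")
        kwargs["vhe"] = Tensor(_img_to_net(vhe_tile, 3)[None])
    if "seg" in model.modalities:
        if seg_features is None:
            raise ValueError("model requires segmentation features")
        feats = np.asarray(seg_features, dtype=np.float64)[None]
        if normalizer is not None:
            feats = normalizer.transform(feats)
        kwargs["seg"] = Tensor(feats.astype(np.float32))
    model.set_training(False)
    with nn.no_grad():
        logits = model(**kwargs).data[0]
    z = logits - logits.max()
    p = np.exp(z)
    p /= p.sum()
    return float(p[1])


# --------------------------------------------------------------------------- #
# losses and metrics
# --------------------------------------------------------------------------- #

def focal_loss(probs, labels, gamma: float = 2.0, alpha: float = 0.5) -> float:
    """mean over samples of -alpha (1 - p_t)^gamma log p_t, where p_t is the
    predicted probability of the true class.  ``probs`` is the cancerous-class
    probability per sample; with gamma=0, alpha=1 this is cross-entropy."""
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels)
    pt = np.where(y == 1, p, 1.0 - p)
    pt = np.clip(pt, 1e-12, 1.0)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


def _focal_from_logits(logits: Tensor, labels: np.ndarray, gamma: float,
                       alpha: float) -> Tensor:
    shift = logits.data.max(axis=1, keepdims=True)
    z = logits - Tensor(shift)
    logp = z - z.exp().sum(axis=1, keepdims=True).log()
    idx = (np.arange(len(labels)), np.asarray(labels, dtype=int))
    logp_t = logp[idx]
    p_t = logp_t.exp()
    return ((1.0 - p_t).clip(0.0, 1.0) ** gamma * logp_t).mean() * (-alpha)


def classification_metrics(y_true, y_pred) -> dict:
    """Accuracy, F1, precision, recall with the cancerous class (1) positive.
    Degenerate denominators yield 0 with a warning."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be equal-length, non-empty")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    acc = (tp + tn) / y_true.size

    def _safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    prec = _safe(tp, tp + fp, "precision")
    rec = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * prec * rec, prec + rec, "f1") if (prec + rec) else 0.0
    return {"accuracy": acc, "f1": f1, "precision": prec, "recall": rec}


# --------------------------------------------------------------------------- #
# training
# --------------------------------------------------------------------------- #

@dataclass
class StepFFTrainConfig:
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    batch_size: int = 32
    epochs: int = 1000
    patience: int = 10
    folds: int = 5
    gamma: float = 2.0
    alpha: float = 0.5
    augment_flips: bool = True
    val_fraction: float = 0.2
    base_width: int = 64
    modalities: tuple = ALL_MODALITIES
    seg_dim: int = 6
    seed: int = 0


def _stratified_folds(labels: np.ndarray, n_folds: int, rng,
                      groups=None) -> list[np.ndarray]:
    """Stratified fold assignment; samples sharing a group id are co-assigned
    (tiles that share pixels through overlapping crops must not straddle the
    train/test boundary)."""
    labels = np.asarray(labels)
    if groups is None:
        groups = np.arange(len(labels))
    groups = np.asarray(groups)
    fold_of_group: dict = {}
    uniq = []
    seen = set()
    for g, y in zip(groups, labels):
        if g not in seen:
            seen.add(g)
            uniq.append((g, y))
    by_class: dict = {}
    for g, y in uniq:
        by_class.setdefault(int(y), []).append(g)
    for y, gs in sorted(by_class.items()):
        gs = list(gs)
        order = rng.permutation(len(gs))
        for i, oi in enumerate(order):
            fold_of_group[gs[oi]] = i % n_folds
    folds = [np.where([fold_of_group[g] == f for g in groups])[0]
             for f in range(n_folds)]
    return folds


def _batch_tensors(records, idx, modalities, normalizer, rng=None,
                   augment=False):
    kwargs = {}
    if "pah" in modalities or "vhe" in modalities:
        flips = None
        if augment:
            flips = [(rng.random() < 0.5, rng.random() < 0.5) for _ in idx]

        def _maybe_flip(img, i):
            if flips is None:
                return img
            fh, fv = flips[i]
            if fh:
                img = img[:, ::-1]
            if fv:
                img = img[::-1]
            return np.ascontiguousarray(img)

        if "pah" in modalities:
            kwargs["pah"] = Tensor(np.stack(
                [_img_to_net(_maybe_flip(np.asarray(records[j]["pah"]), i), 1)
                 for i, j in enumerate(idx)]))
        if "vhe" in modalities:
            kwargs["vhe"] = Tensor(np.stack(
                [_img_to_net(_maybe_flip(np.asarray(records[j]["vhe"]), i), 3)
                 for i, j in enumerate(idx)]))
    if "seg" in modalities:
        feats = np.stack([np.asarray(records[j]["seg"], dtype=np.float64)
                          for j in idx])
        kwargs["seg"] = Tensor(normalizer.transform(feats).astype(np.float32))
    return kwargs


def _predict_labels(model, records, idx, normalizer):
    probs = [fuse_predict(model,
                          pah_tile=records[j].get("pah"),
                          vhe_tile=records[j].get("vhe"),
                          seg_features=records[j].get("seg"),
                          normalizer=normalizer)
             for j in idx]
    return (np.asarray(probs) >= 0.5).astype(int), np.asarray(probs)


def train_stepff(records, cfg: StepFFTrainConfig | None = None, groups=None):
    """Stratified k-fold cross-validated training.

    ``records`` is a sequence of dicts with keys among {"pah", "vhe", "seg"}
    plus "label" (0 noncancerous / 1 cancerous).  Returns a dict with
    per-fold models, normalizers, a metrics table (one row per fold), the
    metric means, and the per-record out-of-fold cancer probabilities.
    """
    import pandas as pd

    cfg = cfg or StepFFTrainConfig()
    labels = np.asarray([int(r["label"]) for r in records])
    rng = np.random.default_rng(cfg.seed)
    folds = _stratified_folds(labels, cfg.folds, rng, groups=groups)
    for f, test_idx in enumerate(folds):
        present = set(labels[test_idx].tolist())
        if present != {0, 1}:
            raise ValueError(f"fold {f} lacks a class; need >= {cfg.folds} "
                             "samples per class")
    rows, models, normalizers = [], [], []
    oof_probs = np.full(len(records), np.nan)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(records)), test_idx)
        # early-stopping split inside the training portion
        tr_rng = np.random.default_rng(cfg.seed * 1000 + f)
        n_val = max(2, int(round(cfg.val_fraction * len(train_idx))))
        order = tr_rng.permutation(len(train_idx))
        val_idx = train_idx[order[:n_val]]
        fit_idx = train_idx[order[n_val:]]
        normalizer = SegFeatureNormalizer()
        if "seg" in cfg.modalities:
            normalizer.fit(np.stack([np.asarray(records[j]["seg"], float)
                                     for j in train_idx]))
        model = StepFFModel(cfg.base_width, cfg.modalities,
                            seed=cfg.seed * 100 + f, seg_dim=cfg.seg_dim)
        opt = nn.Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
        best_val, best_state, bad = math.inf, model.state_dict(), 0
        for _epoch in range(cfg.epochs):
            model.set_training(True)
            ep_order = tr_rng.permutation(fit_idx)
            for s in range(0, len(ep_order), cfg.batch_size):
                bidx = ep_order[s : s + cfg.batch_size]
                kwargs = _batch_tensors(records, bidx, cfg.modalities,
                                        normalizer, rng=tr_rng,
                                        augment=cfg.augment_flips)
                logits = model(**kwargs)
                loss = _focal_from_logits(logits, labels[bidx], cfg.gamma,
                                          cfg.alpha)
                if not math.isfinite(float(loss.data)):
                    raise FloatingPointError("non-finite StepFF loss")
                opt.zero_grad()
                loss.backward()
                opt.step()
            model.set_training(False)
            with nn.no_grad():
                vkw = _batch_tensors(records, val_idx, cfg.modalities,
                                     normalizer)
                vlogits = model(**vkw)
                vloss = float(_focal_from_logits(vlogits, labels[val_idx],
                                                 cfg.gamma, cfg.alpha).data)
            if vloss < best_val - 1e-6:
                best_val, best_state, bad = vloss, model.state_dict(), 0
            else:
                bad += 1
                if cfg.patience and bad >= cfg.patience:
                    break
        model.load_state_dict(best_state)
        preds, probs = _predict_labels(model, records, test_idx, normalizer)
        oof_probs[test_idx] = probs
        m = classification_metrics(labels[test_idx], preds)
        m["fold"] = f
        rows.append(m)
        models.append(model)
        normalizers.append(normalizer)
    table = pd.DataFrame(rows)[["fold", "accuracy", "f1", "precision", "recall"]]
    means = {k: float(table[k].mean())
             for k in ("accuracy", "f1", "precision", "recall")}
    return {"models": models, "normalizers": normalizers, "folds": folds,
            "metrics": table, "mean_metrics": means, "oof_probs": oof_probs}


# --------------------------------------------------------------------------- #
# probability map and agreement
# --------------------------------------------------------------------------- #

def probability_map(tile_probs, tile_grid: TileGrid) -> np.ndarray:
    """Render per-tile cancer probabilities as an RGB slide: each tile is the
    linear blend blue (p=0) -> purple (p=1), merged with overlap averaging."""
    probs = np.asarray(tile_probs, dtype=np.float64)
    if len(probs) != len(tile_grid.tiles):
        raise ValueError("one probability per tile required")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    blue = np.asarray(PROB_BLUE, np.float64)
    purple = np.asarray(PROB_PURPLE, np.float64)
    ts = tile_grid.tile_size
    color_tiles = []
    for p, tile in zip(probs, tile_grid.tiles):
        color = blue + p * (purple - blue)
        px = np.broadcast_to(color, (ts, ts, 3)).astype(np.float64).copy()
        color_tiles.append(ImageTile(px, origin=tile.origin, modality="PROB"))
    grid = TileGrid(color_tiles, canvas_size=tile_grid.canvas_size,
                    tile_size=ts, stride=tile_grid.stride,
                    padded_size=tile_grid.padded_size)
    out = stitch_tiles(grid)   # float path
    return np.copysign(np.floor(np.abs(out) + 0.5), out).astype(np.uint8)


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa; 1 for identical ratings, -1 for complete disagreement
    with balanced marginals.  If expected agreement is 1 (both raters constant
    and equal) kappa is defined as 1."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("ratings must be equal-length and non-empty")
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float((a == b).mean())
    p_e = sum(float((a == c).mean()) * float((b == c).mean()) for c in cats)
    if abs(1.0 - p_e) < 1e-12:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def fleiss_kappa(ratings_matrix) -> float:
    """Fleiss' kappa for >= 3 raters.  ``ratings_matrix`` is (n_items,
    n_categories) counts with a constant row sum (raters per item)."""
    m = np.asarray(ratings_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("ratings matrix must be (n_items, n_categories)")
    raters = m.sum(axis=1)
    if not np.allclose(raters, raters[0]) or raters[0] < 2:
        raise ValueError("every item needs the same number (>= 2) of raters")
    r = raters[0]
    p_i = ((m**2).sum(axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    p_j = m.sum(axis=0) / (m.shape[0] * r)
    p_e = float((p_j**2).sum())
    if abs(1.0 - p_e) < 1e-12:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)
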