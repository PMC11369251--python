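"""U-Net nucleus segmentation and contour-based morphometric features.

The segmentation network is a conventional U-Net (four contraction and four
expansion levels with skip connections) trained with the sum of binary
cross-entropy and Dice losses.  Inference optionally applies test-time
augmentation (averaging probability maps over the four axis flips).

Feature extraction turns a binary nucleus mask into the per-tile triple used
downstream for classification: mean nucleus area (px^2), nucleus count, and
mean intercellular distance (px).  Nuclei are 8-connected components with at
least ``min_area`` pixels; each nucleus centre is the centre of its minimum
enclosing circle, and the distance feature defaults to the mean
nearest-neighbour centre distance (an all-pairs mean is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from . import nn
from .nn import Tensor

__all__ = [
    "UNet", "UNetTrainConfig", "SegmentationFeatures", "bce_dice_loss",
    "train_unet", "predict_mask", "extract_features", "iqr_filter",
    "feature_table", "min_enclosing_circle",
]


# --------------------------------------------------------------------------- #
# network
# --------------------------------------------------------------------------- #

class _DoubleConv(nn.Module):
    def __init__(self, cin, cout, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, padding=1, rng=rng)
        self.n1 = nn.InstanceNorm2d(cout)
        self.c2 = nn.Conv2d(cout, cout, 3, padding=1, rng=rng)
        self.n2 = nn.InstanceNorm2d(cout)

    def forward(self, x):
        x = self.n1(self.c1(x)).relu()
        return self.n2(self.c2(x)).relu()


class UNet(nn.Module):
    """Four-down / four-up U-Net; output logits at input resolution.

    ``base_width`` scales every stage (64 matches the classic architecture;
    the desk-scale profile uses 8).  1-channel input is accepted by stacking
    to 3 channels at call time.
    """

    def __init__(self, base_width: int = 8, in_ch: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = base_width
        self.base_width = base_width
        self.in_ch = in_ch
        widths = [w, 2 * w, 4 * w, 8 * w]
        self.enc = nn.ModuleList()
        c = in_ch
        for cw in widths:
            self.enc.append(_DoubleConv(c, cw, rng))
            c = cw
        self.bottleneck = _DoubleConv(c, 16 * w, rng)
        self.up_convs = nn.ModuleList()
        self.dec = nn.ModuleList()
        c = 16 * w
        for cw in reversed(widths):
            self.up_convs.append(nn.Conv2d(c, cw, 3, padding=1, rng=rng))
            self.dec.append(_DoubleConv(2 * cw, cw, rng))
            c = cw
        self.head = nn.Conv2d(c, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] == 1:
            x = nn.concat([x, x, x], axis=1)
        skips = []
        for enc in self.enc:
            x = enc(x)
            skips.append(x)
            x = x.avg_pool2d(2)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up_convs, self.dec, reversed(skips)):
            x = up(x.upsample2x())
            x = dec(nn.concat([x, skip], axis=1))
        return self.head(x)

    def predict_probs(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one HxW or HxWxC uint8 image."""
        x = _to_net_input(image)
        with nn.no_grad():
            logits = self(Tensor(x))
        return _sigmoid(logits.data[0, 0])


def _to_net_input(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None, None]
    else:
        img = img.transpose(2, 0, 1)[None]
    return img / 127.5 - 1.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


# --------------------------------------------------------------------------- #
# losses and training
# --------------------------------------------------------------------------- #

def bce_dice_loss(pred_probs, target_mask, eps: float = 1.0) -> float:
    """Binary cross-entropy plus (1 - Dice), equally weighted, on probability
    maps (plain arrays; the training loop uses the differentiable logits
    version internally).  Dice uses additive smoothing ``eps``."""
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target_mask, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch between prediction and mask")
    pc = np.clip(p, 1e-7, 1 - 1e-7)
    bce = float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
    inter = float((p * t).sum())
    dice = (2 * inter + eps) / (float(p.sum() + t.sum()) + eps)
    return bce + (1.0 - dice)


def _bce_dice_logits(logits: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    t = Tensor(target)
    bce = (logits.softplus() - t * logits).mean()
    probs = logits.sigmoid()
    inter = (probs * t).sum()
    dice = (inter * 2.0 + eps) / (probs.sum() + float(target.sum()) + eps)
    return bce + (1.0 - dice)


@dataclass
class UNetTrainConfig:
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    batch_size: int = 64
    epochs: int = 300
    patience: int = 20          # early stop after this many non-improving epochs
    augment_flips: bool = True
    val_fraction: float = 0.2
    seed: int = 0


def train_unet(dataset, model: UNet | None = None,
               cfg: UNetTrainConfig | None = None,
               val_dataset=None):
    """Train a U-Net on (image, mask) pairs.

    ``dataset`` is a sequence of (uint8 image, binary mask) tuples.  A
    validation split is carved from the dataset unless ``val_dataset`` is
    given; the best-validation-loss parameters are restored before returning.
    Returns (model, history) where history has per-epoch train/val losses.
    """
    cfg = cfg or UNetTrainConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model = model or UNet(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    items = list(dataset)
    if val_dataset is None:
        n_val = max(1, int(round(cfg.val_fraction * len(items)))) \
            if len(items) > 1 else 0
        order = rng.permutation(len(items))
        val_items = [items[i] for i in order[:n_val]]
        train_items = [items[i] for i in order[n_val:]] or items
    else:
        train_items, val_items = items, list(val_dataset)
    opt = nn.Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    history = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = model.state_dict()
    bad_epochs = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_items))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_items[i] for i in order[start : start + cfg.batch_size]]
            xs, ts = [], []
            for img, mask in batch:
                img = np.asarray(img)
                mask = np.asarray(mask)
                if cfg.augment_flips:
                    if rng.random() < 0.5:
                        img, mask = img[:, ::-1], mask[:, ::-1]
                    if rng.random() < 0.5:
                        img, mask = img[::-1], mask[::-1]
                xs.append(_to_net_input(np.ascontiguousarray(img))[0])
                ts.append(np.ascontiguousarray(mask, dtype=np.float32))
            x = Tensor(np.stack(xs))
            t = np.stack(ts)[:, None]
            logits = model(x)
            loss = _bce_dice_logits(logits, t)
            if not np.isfinite(loss.item()):
                raise FloatingPointError("non-finite loss during U-Net training")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        if val_items:
            vl = []
            for img, mask in val_items:
                probs = model.predict_probs(np.asarray(img))
                vl.append(bce_dice_loss(probs, np.asarray(mask)))
            val_loss = float(np.mean(vl))
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if cfg.patience and bad_epochs >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return model, history


def predict_mask(model: UNet, image: np.ndarray, tta: bool = True,
                 threshold: float = 0.5) -> np.ndarray:
    """Binary mask prediction; with TTA the probability maps of the four axis
    flips are inverse-transformed and averaged before thresholding."""
    image = np.asarray(image)
    if not tta:
        return (model.predict_probs(image) >= threshold).astype(np.uint8)
    acc = np.zeros(image.shape[:2], dtype=np.float64)
    for fh in (False, True):
        for fv in (False, True):
            img = image
            if fh:
                img = img[:, ::-1]
            if fv:
                img = img[::-1]
            p = model.predict_probs(np.ascontiguousarray(img))
            if fh:
                p = p[:, ::-1]
            if fv:
                p = p[::-1]
            acc += p
    return (acc / 4.0 >= threshold).astype(np.uint8)


# --------------------------------------------------------------------------- #
# morphometry
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SegmentationFeatures:
    cell_area: float      # mean nucleus area, px^2 (nan if count == 0)
    cell_count: int
    mean_distance: float  # mean intercellular distance, px (nan if count < 2)

    def as_tuple(self):
        return (self.cell_area, self.cell_count, self.mean_distance)


def _circle_from(points):
    """Exact circle through 1, 2, or 3 points."""
    if len(points) == 0:
        return (0.0, 0.0, 0.0)
    if len(points) == 1:
        return (points[0][0], points[0][1], 0.0)
    if len(points) == 2:
        (ay, ax), (by, bx) = points
        cy, cx = (ay + by) / 2.0, (ax + bx) / 2.0
        return (cy, cx, math.hypot(ay - cy, ax - cx))
    (ay, ax), (by, bx), (cy_, cx_) = points
    d = 2.0 * (ax * (by - cy_) + bx * (cy_ - ay) + cx_ * (ay - by))
    if abs(d) < 1e-12:
        # collinear: fall back to the widest pair
        pairs = [(points[0], points[1]), (points[0], points[2]),
                 (points[1], points[2])]
        return max((_circle_from(list(p)) for p in pairs), key=lambda c: c[2])
    ux = ((ax**2 + ay**2) * (by - cy_) + (bx**2 + by**2) * (cy_ - ay)
          + (cx_**2 + cy_**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx_ - bx) + (bx**2 + by**2) * (ax - cx_)
          + (cx_**2 + cy_**2) * (bx - ax)) / d
    return (uy, ux, math.hypot(ay - uy, ax - ux))


def _in_circle(c, p, tol=1e-7):
    return math.hypot(p[0] - c[0], p[1] - c[1]) <= c[2] + tol


def min_enclosing_circle(points, seed: int = 0):
    """Smallest enclosing circle (Welzl's algorithm) of (row, col) points;
    returns (center_row, center_col, radius)."""
    pts = [tuple(map(float, p)) for p in points]
    if not pts:
        raise ValueError("no points")
    rng = np.random.default_rng(seed)
    rng.shuffle(pts)
    c = None
    for i, p in enumerate(pts):
        if c is not None and _in_circle(c, p):
            continue
        c = (p[0], p[1], 0.0)
        for j, q in enumerate(pts[: i + 1]):
            if _in_circle(c, q):
                continue
            c = _circle_from([p, q])
            for r in pts[: j + 1]:
                if not _in_circle(c, r):
                    c = _circle_from([p, q, r])
    return c


def extract_features(mask: np.ndarray, min_area: int = 10,
                     distance: str = "nearest") -> SegmentationFeatures:
    """Morphometric features of a binary nucleus mask.

    Components are 8-connected; those below ``min_area`` pixels are treated
    as speckle.  ``distance`` selects the nearest-neighbour mean (default) or
    the all-pairs mean of centre distances.
    """
    mask = np.asarray(mask) > 0
    labels = measure.label(mask, connectivity=2)
    centers, areas = [], []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        areas.append(float(region.area))
        cy, cx, _r = min_enclosing_circle(region.coords)
        centers.append((cy, cx))
    count = len(areas)
    if count == 0:
        return SegmentationFeatures(float("nan"), 0, float("nan"))
    area = float(np.mean(areas))
    if count < 2:
        return SegmentationFeatures(area, count, float("nan"))
    pts = np.asarray(centers)
    if distance == "nearest":
        tree = cKDTree(pts)
        dists, _ = tree.query(pts, k=2)
        mean_dist = float(dists[:, 1].mean())
    elif distance == "allpairs":
        diff = pts[:, None, :] - pts[None, :, :]
        dmat = np.hypot(diff[..., 0], diff[..., 1])
        iu = np.triu_indices(count, k=1)
        mean_dist = float(dmat[iu].mean())
    else:
        raise ValueError("distance must be 'nearest' or 'allpairs'")
    return SegmentationFeatures(area, count, mean_dist)


def iqr_filter(values):
    """Retain values inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (linear-interpolation
    quartiles); order is preserved."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        return arr
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return arr[(arr >= lo) & (arr <= hi)]


def feature_table(tiles, model: UNet | None = None, masks=None,
                  labels=None, modality: str = "VHE", min_area: int = 10,
                  tta: bool = True):
    """Per-tile feature rows as a pandas DataFrame.

    Masks can be predicted with ``model`` or supplied directly via ``masks``
    (the ground-truth bypass used for oracle checks).  Undefined features are
    emitted as NaN (empty cells on CSV export).
    """
    import pandas as pd

    if masks is None:
        if model is None:
            raise ValueError("provide a trained model or precomputed masks")
        masks = [predict_mask(model, np.asarray(t), tta=tta) for t in tiles]
    rows = []
    for i, mask in enumerate(masks):
        f = extract_features(mask, min_area=min_area)
        rows.append({"tile_id": i, "modality": modality,
                     "label": labels[i] if labels is not None else "",
                     "cell_area": f.cell_area, "cell_count": f.cell_count,
                     "mean_distance": f.mean_distance})
    return pd.DataFrame(rows)


def class_summary(table, fence: bool = True):
    """Per-class mean of each feature, with or without IQR fencing."""
    out = {}
    for label, grp in table.groupby("label"):
        stats = {}
        for colname in ("cell_area", "cell_count", "mean_distance"):
            vals = grp[colname].dropna().to_numpy(dtype=float)
            if fence and vals.size:
                vals = iqr_filter(vals)
            stats[colname] = float(np.mean(vals)) if vals.size else float("nan")
        out[label] = stats
    return out
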