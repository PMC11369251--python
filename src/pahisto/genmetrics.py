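"""Distribution-level generation metrics: FID and KID with pluggable features.

FID is the Fréchet distance between Gaussians fitted to two embedding sets:

    d^2 = ||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2})

computed here via symmetric eigendecompositions with negative-eigenvalue
clipping (tr((S_a S_b)^{1/2}) = tr((S_a^{1/2} S_b S_a^{1/2})^{1/2})).  KID is
the block-averaged unbiased MMD^2 estimator with the polynomial kernel
k(x, y) = (x.y / d + 1)^3.

Embeddings come from an injected extractor.  The ``lightweight-test``
extractor is a fixed-seed random convolutional projection needing no
pretrained weights; numbers comparable to published Inception-based scores
require the standard pretrained Inception extractor, which this package does
not ship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureSet", "fid", "kid", "extract_features",
           "LightweightExtractor"]


@dataclass
class FeatureSet:
    features: np.ndarray  # (n, d)
    extractor_id: str = "unknown"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be an (n, d) matrix")

    @property
    def n(self):
        return self.features.shape[0]

    @property
    def d(self):
        return self.features.shape[1]


def _as_features(x) -> np.ndarray:
    return x.features if isinstance(x, FeatureSet) else np.asarray(x, dtype=np.float64)


def _sqrtm_psd(mat: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, clipping negatives."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(features_a, features_b) -> float:
    a, b = _as_features(features_a), _as_features(features_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("FID needs at least 2 samples per set")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    sa = np.cov(a, rowvar=False)
    sb = np.cov(b, rowvar=False)
    sa = np.atleast_2d(sa)
    sb = np.atleast_2d(sb)
    ra = _sqrtm_psd(sa)
    cross = _sqrtm_psd(ra @ sb @ ra)
    val = float(np.sum((mu_a - mu_b) ** 2) + np.trace(sa) + np.trace(sb)
                - 2.0 * np.trace(cross))
    return max(val, 0.0)


def _poly_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def kid(features_a, features_b, n_blocks: int = 10,
        block_size: int | None = None, seed: int = 0) -> float:
    """Unbiased MMD^2 with the cubic polynomial kernel, averaged over blocks
    of subsampled features (block_size defaults to min(n_a, n_b, 1024))."""
    a, b = _as_features(features_a), _as_features(features_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    na, nb = a.shape[0], b.shape[0]
    if block_size is None:
        block_size = min(na, nb, 1024)
    if block_size > na or block_size > nb:
        raise ValueError("block size exceeds the number of samples")
    if block_size < 2:
        raise ValueError("block size must be >= 2")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_blocks):
        xa = a[rng.choice(na, block_size, replace=False)]
        xb = b[rng.choice(nb, block_size, replace=False)]
        m = block_size
        kxx = _poly_kernel(xa, xa)
        kyy = _poly_kernel(xb, xb)
        kxy = _poly_kernel(xa, xb)
        sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
        sum_yy = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
        sum_xy = kxy.mean()
        vals.append(sum_xx + sum_yy - 2.0 * sum_xy)
    return float(np.mean(vals))


def mmd2_unbiased(a: np.ndarray, b: np.ndarray) -> float:
    """Single-block unbiased MMD^2 on the full sets (no subsampling)."""
    a, b = _as_features(a), _as_features(b)
    m, n = a.shape[0], b.shape[0]
    kxx = _poly_kernel(a, a)
    kyy = _poly_kernel(b, b)
    kxy = _poly_kernel(a, b)
    return float((kxx.sum() - np.trace(kxx)) / (m * (m - 1))
                 + (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
                 - 2.0 * kxy.mean())


class LightweightExtractor:
    """Fixed-seed random convolutional projection producing d-dim embeddings.

    A bank of random 5x5 filters is applied to each (resized) image; the
    embedding concatenates the spatial mean and standard deviation of the
    rectified responses.  Deterministic given (seed, n_filters, resize).
    """

    def __init__(self, seed: int = 0, n_filters: int = 16, resize: int = 32):
        rng = np.random.default_rng(seed)
        self.filters = rng.normal(0, 1, size=(n_filters, 3, 5, 5)).astype(np.float64)
        self.resize = resize
        self.id = f"lightweight-test(seed={seed},f={n_filters},r={resize})"

    def _prep(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        if img.ndim == 2:
            img = np.repeat(img[:, :, None], 3, axis=2)
        h, w = img.shape[:2]
        ry = np.clip((np.arange(self.resize) * h / self.resize).astype(int), 0, h - 1)
        rx = np.clip((np.arange(self.resize) * w / self.resize).astype(int), 0, w - 1)
        return img[np.ix_(ry, rx)] / 127.5 - 1.0

    def __call__(self, images) -> FeatureSet:
        from scipy.signal import fftconvolve

        feats = []
        for img in images:
            x = self._prep(img)  # (r, r, 3)
            per = []
            for f in self.filters:
                resp = sum(fftconvolve(x[:, :, c], f[c], mode="valid")
                           for c in range(3))
                resp = np.maximum(resp, 0.0)
                per.extend([resp.mean(), resp.std()])
            feats.append(per)
        return FeatureSet(np.asarray(feats), extractor_id=self.id)


def extract_features(images, extractor: str | object = "lightweight-test",
                     seed: int = 0) -> FeatureSet:
    """Embed a list of images.  ``extractor`` is either a callable or the name
    of a built-in; only ``lightweight-test`` is shipped (the standard
    pretrained Inception extractor is documented but not bundled)."""
    if len(images) < 2:
        raise ValueError("need at least 2 images for distribution metrics")
    if callable(extractor):
        return extractor(images)
    if extractor == "lightweight-test":
        return LightweightExtractor(seed=seed)(images)
    if extractor == "standard-inception":
        raise NotImplementedError(
            "the standard pretrained Inception extractor requires downloaded "
            "weights; inject a callable extractor instead")
    raise ValueError(f"unknown extractor {extractor!r}")
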