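"""Soft-threshold saliency masks and the saliency (L1) loss.

A saliency mask marks the "information-bearing" pixels of a histology tile —
in practice the dark nuclei of an inverted label-free image or of a
(virtually) stained image.  The mask is a steep per-pixel sigmoid of
intensity:

    m(v) = 1 - sigmoid((v - threshold) * slope)

On the 8-bit 0-255 scale with the default slope of 100 this is effectively a
hard indicator ``v < threshold`` (softened only in an ~0.1-level band around
the threshold), but it stays differentiable so it can serve as a training
loss.  Default thresholds: 90 for the label-free (source) domain and 170 for
the stained (target) domain after grayscale conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["SaliencyThresholds", "saliency_mask", "rgb_to_gray", "saliency_loss"]


@dataclass(frozen=True)
class SaliencyThresholds:
    x_threshold: float = 90.0
    y_threshold: float = 170.0
    slope: float = 100.0

    def __post_init__(self):
        if not (0 <= self.x_threshold <= 255 and 0 <= self.y_threshold <= 255):
            raise ValueError("thresholds must lie on the 0-255 intensity scale")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Unweighted three-channel average (not luma weighting)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("rgb_to_gray expects an HxWx3 image")
    return image.astype(np.float64).mean(axis=2)


def saliency_mask(image: np.ndarray, threshold: float,
                  slope: float = 100.0) -> np.ndarray:
    """Per-pixel ``1 - sigmoid((v - threshold) * slope)`` on the 0-255 scale.

    3-channel input is first converted with :func:`rgb_to_gray`.  Inputs that
    look float-normalized to [0,1] while the threshold is on the 8-bit scale
    are rejected rather than silently producing an all-ones mask.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        image = rgb_to_gray(image)
    v = image.astype(np.float64)
    if v.size and v.max() <= 1.0 and threshold > 1.0:
        raise ValueError(
            "image appears normalized to [0,1] but the threshold is on the "
            "0-255 scale; rescale the image first")
    return 1.0 - expit((v - float(threshold)) * float(slope))


def saliency_loss(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Mean absolute difference between two saliency masks."""
    mask_x = np.asarray(mask_x, dtype=np.float64)
    mask_y = np.asarray(mask_y, dtype=np.float64)
    if mask_x.shape != mask_y.shape:
        raise ValueError(f"shape mismatch: {mask_x.shape} vs {mask_y.shape}")
    return float(np.abs(mask_x - mask_y).mean())
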