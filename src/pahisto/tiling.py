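"""Whole-slide <-> tile conversion and intensity pre/post-processing.

Conventions (fixed once, used by every module):
* coordinates are 0-based, row-major; tile windows are half-open
  ``[r, r + tile_size) x [c, c + tile_size)``;
* images are padded with a constant (white by default, matching the inverted
  / H&E-style domain) up to the next full stride multiple, and the padding is
  recorded in the grid and removed on stitching;
* stitching accumulates in float64 and averages by per-pixel cover count;
  the final 8-bit conversion rounds half away from zero, which makes the
  crop -> stitch round trip exact on integer inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ImageTile", "TileGrid", "crop_tiles", "stitch_tiles", "invert_intensity",
    "downsample_2x", "stack_to_3ch", "tissue_coverage",
    "read_image", "write_image", "preprocess_raw",
]

MODALITIES = {"PAH", "VHE", "HE", "MASK", "PROB"}


@dataclass
class ImageTile:
    """A single tile: 8-bit pixels (H, W) or (H, W, 3), or float maps for PROB."""

    pixels: np.ndarray
    origin: tuple = (0, 0)
    modality: str = "PAH"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("tile pixels must be non-empty")
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("tile origin must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class TileGrid:
    tiles: list
    canvas_size: tuple          # original (unpadded) canvas H, W
    tile_size: int
    stride: int
    padded_size: tuple = None   # canvas after padding
    pad_value: int = 255

    def __post_init__(self):
        if self.padded_size is None:
            self.padded_size = tuple(self.canvas_size)


def crop_tiles(image: np.ndarray, tile_size: int = 512, overlap: float = 0.5,
               modality: str = "PAH", pad_value: int = 255) -> TileGrid:
    """Crop an image into overlapping tiles.

    The stride is ``tile_size * (1 - overlap)``; the image is padded with
    ``pad_value`` so that an integer number of strides covers each axis.
    """
    image = np.asarray(image)
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    stride = int(round(tile_size * (1.0 - overlap)))
    stride = max(stride, 1)
    h, w = image.shape[:2]

    def _padded(extent: int) -> int:
        if extent <= tile_size:
            return tile_size
        n = int(np.ceil((extent - tile_size) / stride))
        return tile_size + n * stride

    ph, pw = _padded(h), _padded(w)
    if (ph, pw) != (h, w):
        pad_spec = [(0, ph - h), (0, pw - w)] + [(0, 0)] * (image.ndim - 2)
        image = np.pad(image, pad_spec, constant_values=pad_value)
    tiles = []
    for r in range(0, ph - tile_size + 1, stride):
        for c in range(0, pw - tile_size + 1, stride):
            tiles.append(ImageTile(image[r : r + tile_size, c : c + tile_size].copy(),
                                   origin=(r, c), modality=modality))
    return TileGrid(tiles, canvas_size=(h, w), tile_size=tile_size,
                    stride=stride, padded_size=(ph, pw), pad_value=pad_value)


def stitch_tiles(grid: TileGrid) -> np.ndarray:
    """Overlap-averaged stitching: sum tile values per pixel, divide by the
    cover count, crop padding, and round half away from zero back to uint8
    (float tiles are returned as float64 without rounding)."""
    if not grid.tiles:
        raise ValueError("empty grid")
    ph, pw = grid.padded_size
    t0 = grid.tiles[0].pixels
    is_float = np.issubdtype(t0.dtype, np.floating)
    extra = () if t0.ndim == 2 else (t0.shape[2],)
    acc = np.zeros((ph, pw) + extra, dtype=np.float64)
    cover = np.zeros((ph, pw), dtype=np.int64)
    for tile in grid.tiles:
        r, c = tile.origin
        th, tw = tile.pixels.shape[:2]
        acc[r : r + th, c : c + tw] += tile.pixels
        cover[r : r + th, c : c + tw] += 1
    if (cover == 0).any():
        raise ValueError("stitch: some canvas pixels are covered by no tile")
    cov = cover if acc.ndim == 2 else cover[..., None]
    out = acc / cov
    h, w = grid.canvas_size
    out = out[:h, :w]
    if is_float:
        return out
    return np.copysign(np.floor(np.abs(out) + 0.5), out).astype(np.uint8)


def invert_intensity(tile):
    """8-bit intensity inversion v -> 255 - v (an involution)."""
    if isinstance(tile, ImageTile):
        return ImageTile(255 - tile.pixels, tile.origin, tile.modality)
    return 255 - np.asarray(tile, dtype=np.uint8)


def downsample_2x(image: np.ndarray) -> np.ndarray:
    """Area-averaging 2x downsample; odd extents are edge-replicated first,
    so output dims are ceil(input/2). 8-bit inputs round half up."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2")
    pad = [(0, h % 2), (0, w % 2)] + [(0, 0)] * (image.ndim - 2)
    img = np.pad(image, pad, mode="edge").astype(np.float64)
    hh, ww = img.shape[0] // 2, img.shape[1] // 2
    blocks = img.reshape((hh, 2, ww, 2) + img.shape[2:])
    out = blocks.mean(axis=(1, 3))
    if np.issubdtype(image.dtype, np.integer):
        return np.floor(out + 0.5).astype(image.dtype)
    return out


def stack_to_3ch(tile):
    """Replicate a 1-channel tile into identical R=G=B channels."""
    if isinstance(tile, ImageTile):
        if tile.pixels.ndim != 2:
            raise ValueError("stack_to_3ch expects a 1-channel tile")
        return ImageTile(np.repeat(tile.pixels[:, :, None], 3, axis=2),
                         tile.origin, tile.modality)
    arr = np.asarray(tile)
    if arr.ndim != 2:
        raise ValueError("stack_to_3ch expects a 1-channel image")
    return np.repeat(arr[:, :, None], 3, axis=2)


def tissue_coverage(tile, background_level: float, tolerance: float = 10.0) -> float:
    """Fraction of pixels deviating from the background level by more than
    `tolerance` (for 3-channel tiles: in any channel).  Tiles with coverage
    below a cut (the exclusion rule uses 0.2) are treated as non-tissue."""
    px = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
    dev = np.abs(px.astype(np.float64) - float(background_level)) > tolerance
    if dev.ndim == 3:
        dev = dev.any(axis=2)
    return float(dev.mean())


def preprocess_raw(image: np.ndarray, contrast_stretch: tuple | None = None,
                   median_filter: int | None = None,
                   background_subtract: float | None = None) -> np.ndarray:
    """Optional raw-image conditioning (percentile contrast stretch, median
    filter, background-level subtraction).  All steps default to off."""
    img = np.asarray(image).astype(np.float64)
    if background_subtract is not None:
        img = np.clip(img - background_subtract, 0, None)
    if median_filter is not None and median_filter > 1:
        from scipy.ndimage import median_filter as mf

        img = mf(img, size=median_filter)
    if contrast_stretch is not None:
        lo, hi = np.percentile(img, contrast_stretch)
        if hi > lo:
            img = (img - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_image(path, image: np.ndarray):
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image))


def write_grid_manifest(grid: TileGrid, tile_dir, prefix: str = "tile") -> Path:
    """Write grid tiles as PNGs plus a CSV manifest describing the layout."""
    tile_dir = Path(tile_dir)
    tile_dir.mkdir(parents=True, exist_ok=True)
    manifest = tile_dir / "grid.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["path", "row", "col", "tile_size", "stride",
                     "canvas_h", "canvas_w", "padded_h", "padded_w", "pad_value"])
        for tile in grid.tiles:
            name = f"{prefix}_r{tile.origin[0]:06d}_c{tile.origin[1]:06d}.png"
            write_image(tile_dir / name, tile.pixels)
            wr.writerow([name, tile.origin[0], tile.origin[1], grid.tile_size,
                         grid.stride, *grid.canvas_size, *grid.padded_size,
                         grid.pad_value])
    return manifest


def read_grid_manifest(manifest_path, modality: str = "PAH") -> TileGrid:
    manifest_path = Path(manifest_path)
    tiles, meta = [], None
    with open(manifest_path) as fh:
        for row in csv.DictReader(fh):
            meta = row
            px = read_image(manifest_path.parent / row["path"])
            tiles.append(ImageTile(px, origin=(int(row["row"]), int(row["col"])),
                                   modality=modality))
    if meta is None:
        raise ValueError("empty grid manifest")
    return TileGrid(tiles, canvas_size=(int(meta["canvas_h"]), int(meta["canvas_w"])),
                    tile_size=int(meta["tile_size"]), stride=int(meta["stride"]),
                    padded_size=(int(meta["padded_h"]), int(meta["padded_w"])),
                    pad_value=int(meta["pad_value"]))
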