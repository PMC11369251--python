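"""Whole-slide tiling, overlap-averaged stitching, and saliency masks.

Crops a random 700 x 900 "slide" into 512-px tiles with 50% overlap (padding
to the next stride multiple), stitches it back, and reports the
reconstruction error (exact for integer images).  Then shows the
soft-threshold saliency mask that the staining loss uses: ~1 on nuclei,
~0 on background, 0.5 exactly at the threshold intensity.
"""

import numpy as np

from pahisto import synthetic as syn
from pahisto.saliency import saliency_mask
from pahisto.tiling import crop_tiles, invert_intensity, stitch_tiles, tissue_coverage

rng = np.random.default_rng(0)
slide = rng.integers(0, 256, (700, 900), dtype=np.uint8)
grid = crop_tiles(slide, tile_size=512, overlap=0.5)
print(f"700x900 slide -> padded to {grid.padded_size}, {len(grid.tiles)} tiles "
      f"(stride {grid.stride})")
restored = stitch_tiles(grid)
err = np.abs(restored.astype(int) - slide.astype(int)).max()
print(f"crop -> stitch max reconstruction error: {err} intensity levels")

scene = syn.generate_scene(syn.SceneParams(), syn.CANCEROUS, (128, 128), seed=3)
pah = invert_intensity(syn.render_pah(scene).pixels)  # white background domain
mask = saliency_mask(pah, threshold=90, slope=100)
print(f"saliency mask: mean={mask.mean():.3f} "
      f"(fraction of the tile the loss treats as nuclear foreground)")
he = syn.render_he(scene).pixels
coverage = tissue_coverage(he, background_level=250, tolerance=15)
print(f"tissue coverage of the stained render: {coverage:.3f} "
      f"(tiles under 0.2 would be excluded from grading)")
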