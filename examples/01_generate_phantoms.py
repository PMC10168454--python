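"""Render chest-radiograph-like phantoms and inspect their statistics.

Phantoms stand in for finding-free chest x-rays: a bright mediastinal
band, two darker lung fields, rib bands, blur and sensor noise, with
per-image jitter.  They carry no disease signal by construction.
"""

import numpy as np

from shortcutscope import PhantomParams, generate_phantom, generate_pool

params = PhantomParams(side=64, seed=7)
img = generate_phantom(params)
print(f"one phantom: {img.height}x{img.width}, intensities "
      f"[{img.pixels.min()}, {img.pixels.max()}], mean {img.pixels.mean():.1f}")

pool = generate_pool(100, params)
means = np.array([p.pixels.mean() for p in pool])
print(f"pool of {len(pool)}: per-image mean intensity "
      f"{means.mean():.1f} +/- {means.std():.1f}")
# The spread comes from seeded exposure/geometry jitter: natural-looking
# acquisition variation, but identically distributed for every image.
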