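"""Generate a fluoroscopy-like synthetic scene and describe what is in it.

The generator draws smooth random curves (cubic splines rasterized to
8-connected pixel chains), dilates them to the wire width, darkens them on a
smooth noisy background, and knocks out gap segments so parts of the wire
are invisible — the conditions under which the pipeline must work.
"""

import numpy as np

from wiretrace import SceneConfig, make_sample

cfg = SceneConfig(height=256, width=256, n_curves=1, curve_width=3,
                  contrast=0.3, noise_sigma=0.08, gap_rate=2.0, seed=7)
sample = make_sample(cfg)

curve = sample.curves[0]
print(f"image: {sample.image.shape}, intensities in "
      f"[{sample.image.min():.2f}, {sample.image.max():.2f}]")
print(f"ground-truth curve: {len(curve)} px, mask foreground "
      f"{100 * sample.mask.mean():.2f}% of pixels")
print(f"visible fragments after gap insertion: {len(sample.fragmented_curves)} "
      f"({sum(len(f) for f in sample.fragmented_curves)} of {len(curve)} px visible)")
# The foreground fraction (~0.3-1%) is the extreme class imbalance that the
# coarse-to-fine design and the class-balanced losses are built for.
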