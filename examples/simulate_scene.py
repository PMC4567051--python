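"""Generate a synthetic six-class crop scene and inspect its structure.

Builds a 96x96-pixel scene of 8x8-pixel fields with the confusable
six-class preset (cotton dominant), then prints the class inventory and
the per-class NDVI peak statistics.
"""

import numpy as np

from cropfuse import generate_scene, preset_config

config = preset_config("bole6", seed=42)
cube, labels, objects = generate_scene(config)

print(f"scene: {cube.values.shape[0]} pixels x {cube.values.shape[1]} dates "
      f"(DOY {cube.doys[0]}-{cube.doys[-1]}), "
      f"{len(np.unique(objects.object_id))} fields")
for k, name in enumerate(labels.class_names, start=1):
    mask = labels.labels == k
    peaks = cube.values[mask].max(axis=1)
    print(f"  {name:<13} {mask.sum():>5} px   "
          f"peak NDVI {peaks.mean():.2f} +/- {peaks.std():.2f}")

# Each line shows how many pixels a crop occupies and the mean/SD of its
# per-pixel seasonal NDVI maximum: cotton peaks highest (~0.8), grape is
# the most variable, and the two wheat classes green up earliest.
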