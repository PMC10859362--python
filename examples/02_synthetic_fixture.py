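"""Generate a seeded synthetic image set and inspect its structure.

Each class is a distinct (shape, hue) family drawn on a white background
with jittered pose, size and pixel noise — a deterministic, linearly
separable stand-in for class-per-folder photo datasets such as Fruit-360.
"""

import numpy as np

from fruitnet import FixtureSpec, SplitSpec, generate_fixture, stratified_split

spec = FixtureSpec(num_classes=5, images_per_class=40, image_size=100, seed=7)
ds = generate_fixture(spec)
print(f"{len(ds)} images, classes: {ds.class_names}")

train_set, val_set = stratified_split(ds, SplitSpec(fractions=(0.8, 0.2), seed=7))
print(f"train {len(train_set)} / val {len(val_set)}; "
      f"per-class val counts {np.bincount(val_set.labels)}")
# Re-running with the same seed reproduces every pixel byte-for-byte.
again = generate_fixture(spec)
print("byte-identical rerun:", all(a.tobytes() == b.tobytes()
                                   for a, b in zip(ds.images, again.images)))
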