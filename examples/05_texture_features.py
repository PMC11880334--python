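"""GLCM texture features separate burn depths by surface roughness.

For each of two source planes — luminance L and chroma magnitude — the
descriptor holds GLCM contrast and correlation of the plane and of its
square (averaged over the 0/45/90/135-degree offsets) plus the plane mean:
10 values per image. Deeper burn tissue is rougher at the pixel scale, so
its GLCM contrast is higher.
"""

import numpy as np

from burnscope import feature_vector, generate_dataset, rgb_to_luv
from burnscope.texture import FEATURE_NAMES

ds = generate_dataset(n=18, seed=42, size=(64, 64))
feats = np.stack([feature_vector(rgb_to_luv(im)).values for im in ds.images])

print("feature order:", ", ".join(FEATURE_NAMES))
for cls, name in ((1, "superficial"), (2, "dermal"), (3, "deep")):
    sel = ds.labels == cls
    print(f"{name:12s} L-contrast {feats[sel, 0].mean():.3f} +- {feats[sel, 0].std():.3f}"
          f"   L-mean {feats[sel, 4].mean():6.2f}")
print("L-contrast increases monotonically with burn depth (rougher texture),")
print("and L-mean decreases (deeper tissue is darker) - the two signals the")
print("classifiers rely on.")
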