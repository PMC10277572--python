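"""Rotational polar slicing and slice-wise deep feature extraction.

A full plane through the centroid's z-axis is rotated in 10° steps,
giving 36 nearest-neighbor 224×224 slices of a partition.  Each slice
passes through a frozen convolutional backbone (256×7×7 map), global
average pooling gives 36×256, and an elementwise max across slices
yields one 256-vector per partition.
"""

import numpy as np

from shellrad import (
    ConvBackbone,
    PhantomConfig,
    extract_deep,
    generate_cohort,
    make_sphere_mask,
)
from shellrad.polar import replicate_channels, rotational_slices

subject = generate_cohort(PhantomConfig(n_per_class=2, seed=0)).subjects[0]
mask = make_sphere_mask(subject.volume, subject.centroid, 15.0)

stack = rotational_slices(subject.volume, mask, angle_step=10.0,
                          slice_size=(224, 224))
print(f"polar stack: {stack.n_slices} slices of {stack.slice_size}")
mirror = np.array_equal(stack.slices[0], stack.slices[18][:, ::-1])
print(f"slice at 180° is the mirror of slice at 0°: {mirror}")

backbone = ConvBackbone(seed=0)
channeled = replicate_channels(stack)        # (36, 3, 224, 224) in [0, 1]
per_slice = backbone(channeled).mean(axis=(2, 3))
print(f"per-slice pooled maps: {per_slice.shape}")

fv = extract_deep(channeled, backbone)
v = fv.values.to_numpy()
print(f"deep vector: {len(fv)} features, "
      f"min {v.min():.4f}, max {v.max():.4f}, mean {v.mean():.4f}")
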