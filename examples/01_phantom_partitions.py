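"""Generate a phantom cohort and partition a subject into radial shells.

The partitioning needs only a centroid annotation, no tumor segmentation:
five concentric half-open shells [0,3), [3,6), [6,9), [9,12), [12,15) mm
tile the 15 mm sphere around the centroid exactly.
"""

import numpy as np

from shellrad import (
    PhantomConfig,
    generate_cohort,
    make_shell_mask,
    make_sphere_mask,
)
from shellrad.partition import DEFAULT_INTERVALS, interval_tag

cohort = generate_cohort(PhantomConfig(n_per_class=2, seed=0))
subject = cohort.subjects[0]
print(f"subject {subject.patient_id}: volume {subject.volume.shape}, "
      f"centroid {np.round(subject.centroid, 2)} mm, label {subject.label}")

union = np.zeros(subject.volume.shape, dtype=bool)
for lo, hi in DEFAULT_INTERVALS:
    mask = make_shell_mask(subject.volume, subject.centroid, lo, hi)
    hu = subject.volume.data[mask.mask]
    print(f"  {interval_tag(lo, hi):>12}: {mask.voxel_count:5d} voxels, "
          f"mean {hu.mean():7.1f} HU")
    union |= mask.mask

sphere = make_sphere_mask(subject.volume, subject.centroid, 15.0)
print(f"  shells tile the 15 mm sphere exactly: "
      f"{np.array_equal(union, sphere.mask)} ({sphere.voxel_count} voxels)")
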