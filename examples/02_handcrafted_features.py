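"""Extract the 1688-feature handcrafted vector from one shell partition.

The bank is 14 shape features of the partition mask plus 93 intensity/
texture features (18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM,
5 NGTDM) on the original image and 17 filtered variants (8 wavelet,
5 Laplacian-of-Gaussian, square, square root, logarithm, exponential).
"""

from shellrad import (
    HCConfig,
    PhantomConfig,
    extract_handcrafted,
    generate_cohort,
    make_shell_mask,
)

subject = generate_cohort(PhantomConfig(n_per_class=2, seed=0)).subjects[0]
mask = make_shell_mask(subject.volume, subject.centroid, 9.0, 12.0)

fv = extract_handcrafted(subject.volume, mask, HCConfig())
print(f"partition {fv.partition_tag}: {len(fv)} features "
      f"(config {HCConfig().n_features})")

for name in (
    "original_shape_MeshVolume",
    "original_shape_Sphericity",
    "original_firstorder_Mean",
    "original_firstorder_Entropy",
    "original_glcm_JointEntropy",
    "original_gldm_LargeDependenceEmphasis",
    "wavelet-HHH_firstorder_Variance",
    "log-sigma-3mm_firstorder_Mean",
):
    print(f"  {name:45s} {fv.values[name]:12.4f}")
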