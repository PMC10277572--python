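"""Handcrafted radiomic feature extraction for one masked partition.

Under the default configuration each partition yields exactly **1688**
named features: 14 shape descriptors computed once on the mask, plus 93
intensity/texture features (18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM) on each of 18 image variants — the original image, 8
wavelet subbands, Laplacian-of-Gaussian at 5 scales, and the square,
square-root, logarithm and exponential intensity remaps:
``14 + 93 × 18 = 1688``.

Texture matrices use a fixed bin width of 25 HU (the common CT radiomics
convention), 26-connectivity, and direction averaging.  Feature names are
``<variant>_<class>_<feature>``; the caller appends the partition tag so
fused matrices have globally unique columns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ..partition import PartitionMask, interval_tag
from ..volume_io import Volume
from ._filters import iter_image_variants, variant_names
from ._firstorder import FIRSTORDER_NAMES, firstorder_features
from ._shape import SHAPE_NAMES, shape_features
from ._texture import (
    TEXTURE_NAMES,
    discretize,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["HCConfig", "FeatureVector", "extract_handcrafted", "feature_names"]

_CLASS_SIZES = {
    "firstorder": len(FIRSTORDER_NAMES),
    "glcm": len(TEXTURE_NAMES["glcm"]),
    "glrlm": len(TEXTURE_NAMES["glrlm"]),
    "glszm": len(TEXTURE_NAMES["glszm"]),
    "gldm": len(TEXTURE_NAMES["gldm"]),
    "ngtdm": len(TEXTURE_NAMES["ngtdm"]),
}


@dataclass(frozen=True)
class HCConfig:
    """Configuration of the handcrafted extraction.

    Defaults are pinned so the full bank counts exactly 1688 features.
    ``reduced()`` gives an original-image-only configuration (107 features)
    for desk-scale experiments where the filtered variants add little.
    """

    bin_width: float = 25.0
    filters: tuple[str, ...] = (
        "original", "wavelet", "log", "square", "squareroot",
        "logarithm", "exponential",
    )
    wavelet: str = "coif1"
    log_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    classes: tuple[str, ...] = (
        "firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm",
    )
    shape: bool = True
    gldm_alpha: float = 0.0
    filter_margin: int = 10  # voxels of context kept around the mask bbox

    @classmethod
    def reduced(cls) -> "HCConfig":
        return cls(filters=("original",))

    @property
    def n_features(self) -> int:
        per_variant = sum(_CLASS_SIZES[c] for c in self.classes)
        return (len(SHAPE_NAMES) if self.shape else 0) + per_variant * len(
            variant_names(self)
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureVector:
    """Named scalar features for one partition of one subject."""

    values: pd.Series
    kind: str  # "handcrafted" | "deep"
    partition_tag: str

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            bad = self.values.index[~np.isfinite(self.values.to_numpy(dtype=float))]
            raise ValueError(f"non-finite feature values: {list(bad[:5])}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def names(self) -> list[str]:
        return list(self.values.index)

    def with_partition_suffix(self) -> pd.Series:
        """Feature values with the partition tag appended to every name."""
        s = self.values.copy()
        s.index = [f"{n}_{self.partition_tag}" for n in s.index]
        return s


def feature_names(config: HCConfig | None = None) -> list[str]:
    """The ordered names the extractor emits under a configuration."""
    config = config or HCConfig()
    names: list[str] = []
    if config.shape:
        names.extend(f"original_shape_{n}" for n in SHAPE_NAMES)
    for variant in variant_names(config):
        for cls in config.classes:
            cls_names = (
                FIRSTORDER_NAMES if cls == "firstorder" else TEXTURE_NAMES[cls]
            )
            names.extend(f"{variant}_{cls}_{n}" for n in cls_names)
    return names


def _bbox_slices(mask: np.ndarray, margin: int, shape) -> tuple[slice, ...]:
    out = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(i for i in range(3) if i != ax))
        idx = np.nonzero(proj)[0]
        out.append(slice(max(0, idx[0] - margin), min(shape[ax], idx[-1] + 1 + margin)))
    return tuple(out)


def extract_handcrafted(
    v: Volume, m: PartitionMask, config: HCConfig | None = None
) -> FeatureVector:
    """Extract the handcrafted feature vector of one masked partition.

    Deterministic given (volume, mask, config).  The volume must be
    isotropic and the mask must contain at least two voxels.  Filters see
    the mask bounding box plus ``filter_margin`` voxels of surrounding
    context, so neighbouring tissue informs the filtered variants just as
    it would on a full image.
    """
    config = config or HCConfig()
    if not v.is_isotropic(v.spacing[0]) or not np.allclose(v.spacing, v.spacing[0]):
        raise ValueError("volume must be isotropic; resample first")
    if m.mask.shape != v.data.shape:
        raise ValueError("mask is not aligned to the volume")
    if m.voxel_count < 2:
        raise ValueError(
            f"degenerate mask ({m.voxel_count} voxel(s)); need at least 2"
        )

    sl = _bbox_slices(m.mask, config.filter_margin, v.data.shape)
    sub_img = np.asarray(v.data[sl], dtype=float)
    sub_mask = m.mask[sl]
    voxel_volume = float(np.prod(v.spacing))

    # Tight bbox of the mask inside the margin crop, for texture matrices.
    tight = _bbox_slices(sub_mask, 0, sub_mask.shape)
    n_voxels = int(sub_mask.sum())

    feats: dict[str, float] = {}
    if config.shape:
        for name, val in shape_features(sub_mask, v.spacing).items():
            feats[f"original_shape_{name}"] = val

    for variant, image in iter_image_variants(sub_img, config, v.spacing):
        xm = image[sub_mask]
        levels = discretize(xm, config.bin_width)
        ng = int(levels.max())
        g = np.zeros(sub_mask[tight].shape, dtype=np.int64)
        g[sub_mask[tight]] = discretize(image[tight][sub_mask[tight]], config.bin_width)
        for cls in config.classes:
            if cls == "firstorder":
                vals = firstorder_features(xm, voxel_volume, config.bin_width)
            elif cls == "glcm":
                vals = glcm_features(g, ng)
            elif cls == "glrlm":
                vals = glrlm_features(g, ng, n_voxels)
            elif cls == "glszm":
                vals = glszm_features(g, ng, n_voxels)
            elif cls == "gldm":
                vals = gldm_features(g, ng, config.gldm_alpha)
            elif cls == "ngtdm":
                vals = ngtdm_features(g, ng)
            else:
                raise ValueError(f"unknown feature class {cls!r}")
            for name, val in vals.items():
                feats[f"{variant}_{cls}_{name}"] = float(val)

    tag = interval_tag(*m.interval)
    return FeatureVector(pd.Series(feats), kind="handcrafted", partition_tag=tag)
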