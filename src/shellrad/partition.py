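"""Concentric sphere/shell partitioning around a tumor centroid.

The pipeline replaces tumor segmentation with a fixed radial decomposition:
a central 0–3 mm ball and concentric 3 mm shells out to 15 mm, all centered
on a manually annotated centroid.  Membership is decided per voxel by the
Euclidean distance between the voxel *center* and the centroid in physical
coordinates, with half-open intervals ``[r_lo, r_hi)`` so the shells tile
the ball without overlap.  Centroids are not snapped to voxel centers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_INTERVALS",
    "ShellSpec",
    "PartitionMask",
    "make_shell_mask",
    "make_sphere_mask",
    "crop_partition",
    "interval_tag",
]

#: The study's radial decomposition: 3 mm boundaries from 0 to 15 mm.
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (0.0, 3.0),
    (3.0, 6.0),
    (6.0, 9.0),
    (9.0, 12.0),
    (12.0, 15.0),
)


def interval_tag(r_lo: float, r_hi: float) -> str:
    """Canonical strategy tag for one radial interval, e.g. ``shell_9_12``."""
    return f"shell_{r_lo:g}_{r_hi:g}".replace(".", "p")


@dataclass(frozen=True)
class ShellSpec:
    """An ordered set of non-overlapping radial intervals ``[r_lo, r_hi)`` in mm."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for r_lo, r_hi in self.intervals:
            if not (0 <= r_lo < r_hi):
                raise ValueError(f"invalid interval [{r_lo}, {r_hi})")
            if r_lo < prev_hi - 1e-12:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_hi = r_hi

    @property
    def r_max(self) -> float:
        return self.intervals[-1][1]

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(interval_tag(lo, hi) for lo, hi in self.intervals)


@dataclass
class PartitionMask:
    """Binary mask for one radial interval, aligned to an isotropic volume."""

    mask: np.ndarray  # bool, same shape as the volume
    interval: tuple[float, float]  # [r_lo, r_hi) mm
    centroid: np.ndarray  # (x, y, z) mm

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def r_max(self) -> float:
        return float(self.interval[1])


def _distance_grid(v: Volume, centroid: np.ndarray) -> np.ndarray:
    """Euclidean distance (mm) from each voxel center to the centroid."""
    axes = [v.voxel_centers_axis(ax) - centroid[ax] for ax in range(3)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def make_shell_mask(
    v: Volume, centroid, r_lo: float, r_hi: float
) -> PartitionMask:
    """Mask of voxels whose center-to-centroid distance d satisfies r_lo <= d < r_hi.

    Shells that extend beyond the volume boundary are truncated with a
    logged warning so peripheral tumors remain processable.
    """
    centroid = np.asarray(centroid, dtype=float)
    if not (0 <= r_lo < r_hi):
        raise ValueError(f"require 0 <= r_lo < r_hi, got [{r_lo}, {r_hi})")
    if not v.contains_point(centroid):
        raise ValueError(f"centroid {centroid} lies outside the volume bounds")
    d = _distance_grid(v, centroid)
    mask = (d >= r_lo) & (d < r_hi)
    lo = v.origin
    hi = v.origin + (np.asarray(v.shape) - 1) * v.spacing
    if np.any(centroid - r_hi < lo - 1e-9) or np.any(centroid + r_hi > hi + 1e-9):
        logger.warning(
            "shell [%g, %g) mm around %s truncated at the volume boundary",
            r_lo, r_hi, centroid,
        )
    return PartitionMask(mask, (float(r_lo), float(r_hi)), centroid)


def make_sphere_mask(v: Volume, centroid, r: float) -> PartitionMask:
    """Mask of the full ball of radius ``r`` (the image-fusion partition).

    Equals the voxelwise union of shells tiling ``[0, r)``.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    return make_shell_mask(v, centroid, 0.0, r)


def crop_partition(v: Volume, m: PartitionMask, fill: float = -1024.0) -> Volume:
    """Masked crop of a partition: volume values inside the mask, ``fill`` outside.

    The output covers the cube ``[-r_max, r_max]`` around the centroid
    (clipped at the volume boundary) so every partition of a given outer
    radius has a comparable physical footprint.  Default fill is air
    (−1024 HU), the conventional CT out-of-field value.
    """
    if m.mask.shape != v.data.shape:
        raise ValueError(
            f"mask shape {m.mask.shape} does not match volume shape {v.data.shape}"
        )
    r = m.r_max
    lo_idx = np.zeros(3, dtype=int)
    hi_idx = np.zeros(3, dtype=int)
    for ax in range(3):
        centers = v.voxel_centers_axis(ax)
        inside = np.nonzero(np.abs(centers - m.centroid[ax]) <= r)[0]
        if inside.size == 0:
            raise ValueError("partition cube does not intersect the volume")
        lo_idx[ax], hi_idx[ax] = inside[0], inside[-1] + 1
    sl = tuple(slice(lo, hi) for lo, hi in zip(lo_idx, hi_idx))
    out = np.full([hi - lo for lo, hi in zip(lo_idx, hi_idx)], float(fill))
    sub_mask = m.mask[sl]
    out[sub_mask] = v.data[sl][sub_mask]
    origin = v.origin + lo_idx * v.spacing
    return Volume(out, v.spacing.copy(), origin)


def partition_metadata(
    patient_id: str, masks: dict[str, PartitionMask]
) -> pd.DataFrame:
    """Per-partition voxel counts as a tidy table (for logging/export)."""
    rows = [
        {
            "patient_id": patient_id,
            "interval": f"[{m.interval[0]:g},{m.interval[1]:g})",
            "voxel_count": m.voxel_count,
        }
        for m in masks.values()
    ]
    return pd.DataFrame(rows, columns=["patient_id", "interval", "voxel_count"])
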