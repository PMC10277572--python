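"""Rotational polar-coordinate slicing of a masked partition.

A plane containing the z-axis through the centroid is rotated about that
axis in fixed angular steps (default 10°, hence 36 slices).  Each slice is
the full cross-section of the masked, filled partition with that plane —
the maximal chord section, since the plane passes through the centroid —
sampled with nearest-neighbor interpolation onto a fixed H×W grid spanning
``[-r_max, r_max]`` in both the in-plane radial axis and z.  Every patient
and partition therefore yields a stack of identical shape regardless of
tumor size, which is what lets a frozen CNN backbone consume it.

Because each slice is a full plane, the slice at azimuth θ+180° is the
left-right mirror of the slice at θ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .partition import PartitionMask
from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "PolarStack",
    "rotational_slices",
    "replicate_channels",
    "DEFAULT_HU_WINDOW",
]

#: HU window used to normalize slices before feeding the CNN backbone.
DEFAULT_HU_WINDOW: tuple[float, float] = (-1024.0, 400.0)


@dataclass
class PolarStack:
    """Fixed-size stack of rotational cross-sections (HU values)."""

    slices: np.ndarray  # (n, H, W)
    angle_step: float  # degrees
    r_max: float  # mm
    centroid: np.ndarray  # (x, y, z) mm

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, H, W) array")
        n = self.slices.shape[0]
        if abs(n * self.angle_step - 360.0) > 1e-9:
            raise ValueError(
                f"{n} slices at {self.angle_step}° do not cover 360° exactly"
            )

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_size(self) -> tuple[int, int]:
        return self.slices.shape[1], self.slices.shape[2]


def rotational_slices(
    v: Volume,
    m: PartitionMask,
    angle_step: float = 10.0,
    slice_size: tuple[int, int] = (224, 224),
    fill: float = -1024.0,
) -> PolarStack:
    """Sample the masked partition on planes rotated about the z-axis.

    Slice ``k`` lies at azimuth ``θ = k * angle_step``.  Rows index z, columns
    index the signed in-plane radial coordinate; both span
    ``[-r_max, r_max]`` with symmetric pixel centers, so pixel pitch is
    ``2 * r_max / H`` mm.  Values come from the nearest voxel of the volume;
    samples outside the mask or the grid take ``fill``.
    """
    if angle_step <= 0 or abs(round(360.0 / angle_step) * angle_step - 360.0) > 1e-9:
        raise ValueError(f"angle_step {angle_step}° must divide 360° exactly")
    if m.mask.shape != v.data.shape:
        raise ValueError("mask is not aligned to the volume")
    H, W = slice_size
    n = int(round(360.0 / angle_step))
    r = m.r_max
    if m.voxel_count == 0:
        logger.warning("degenerate (empty) partition mask: returning all-fill stack")
        return PolarStack(
            np.full((n, H, W), float(fill)), float(angle_step), r, m.centroid
        )

    # Symmetric sample positions so the θ and θ+180° slices mirror exactly.
    s = (np.arange(W) - (W - 1) / 2.0) * (2.0 * r / W)  # in-plane radial, mm
    z = (np.arange(H) - (H - 1) / 2.0) * (2.0 * r / H)  # mm

    thetas = np.deg2rad(np.arange(n) * angle_step)
    # Physical sample points for all slices: shape (n, H, W, 3).
    cos_t = np.cos(thetas)[:, None, None]
    sin_t = np.sin(thetas)[:, None, None]
    sg = s[None, None, :]
    zg = z[None, :, None]
    px = m.centroid[0] + sg * cos_t + 0.0 * zg
    py = m.centroid[1] + sg * sin_t + 0.0 * zg
    pz = m.centroid[2] + 0.0 * sg + zg + 0.0 * cos_t

    idx = []
    inside = np.ones(px.shape, dtype=bool)
    for ax, coord in enumerate((px, py, pz)):
        i = np.round((coord - v.origin[ax]) / v.spacing[ax]).astype(int)
        inside &= (i >= 0) & (i < v.shape[ax])
        idx.append(np.clip(i, 0, v.shape[ax] - 1))
    valid = inside & m.mask[idx[0], idx[1], idx[2]]
    out = np.where(valid, v.data[idx[0], idx[1], idx[2]], float(fill))
    return PolarStack(out, float(angle_step), r, m.centroid)


def normalize_window(
    slices: np.ndarray, window: tuple[float, float] = DEFAULT_HU_WINDOW
) -> np.ndarray:
    """Clip to an HU window and map its ends affinely to [0, 1]."""
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"invalid HU window {window}")
    return (np.clip(slices, lo, hi) - lo) / (hi - lo)


def replicate_channels(
    stack: PolarStack,
    n_channels: int = 3,
    window: tuple[float, float] = DEFAULT_HU_WINDOW,
) -> np.ndarray:
    """Window-normalize and replicate each slice into identical channels.

    Returns an (n, n_channels, H, W) float array in [0, 1] ready for a
    frozen image backbone expecting multi-channel input.
    """
    norm = normalize_window(stack.slices, window)
    return np.repeat(norm[:, None, :, :], n_channels, axis=1)
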