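"""Volume and cohort-table I/O.

CT volumes are held as a lightweight :class:`Volume` — a 3D array of
Hounsfield units indexed ``[i, j, k]`` along (x, y, z), together with the
physical voxel spacing and origin in millimetres.  All downstream geometry
(shell masks, polar slicing) works in physical coordinates, so volumes are
first resampled to an isotropic 1 mm grid; the 3 mm shell boundaries are
then scanner-independent.

NIfTI is the canonical on-disk format.  Only axis-aligned orientations are
supported: the affine rotation part must be diagonal (up to sign).  Cohort
tables are CSV with columns ``patient_id,x_mm,y_mm,z_mm,label,cohort``,
coordinates in the NIfTI physical frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Volume",
    "CentroidRecord",
    "load_volume",
    "save_volume",
    "resample_isotropic",
    "read_centroid_table",
    "write_centroid_table",
]


@dataclass
class Volume:
    """A 3D scalar grid (HU) with physical spacing and origin in mm."""

    data: np.ndarray
    spacing: np.ndarray  # (sx, sy, sz), mm per voxel
    origin: np.ndarray  # physical coordinate of voxel (0, 0, 0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three strictly positive values")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> np.ndarray:
        """Physical extent per axis (voxel count x spacing)."""
        return np.asarray(self.shape) * self.spacing

    def is_isotropic(self, target_mm: float = 1.0, atol: float = 1e-6) -> bool:
        return bool(np.allclose(self.spacing, target_mm, atol=atol))

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def contains_point(self, point_mm: np.ndarray) -> bool:
        """Whether a physical point lies within the voxel-center bounding box."""
        p = np.asarray(point_mm, dtype=float)
        lo = self.origin
        hi = self.origin + (np.asarray(self.shape) - 1) * self.spacing
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))


@dataclass
class CentroidRecord:
    """One row of the cohort table: a tumor centroid with its response label."""

    patient_id: str
    centroid: np.ndarray  # (x, y, z) mm, physical frame
    label: int  # 1 = response, 0 = non-response
    cohort_tag: str = "dataset1"

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (3,):
            raise ValueError("centroid must be a 3-vector (mm)")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def load_volume(path) -> Volume:
    """Read a 3D NIfTI image into a :class:`Volume`.

    The affine must be axis-aligned (diagonal rotation part up to sign);
    intensities are passed through untouched.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise OSError(f"could not read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path!r}")
    affine = img.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if not np.allclose(off_diag, 0, atol=1e-4):
        raise ValueError(f"only axis-aligned volumes are supported ({path!r})")
    spacing = np.abs(np.diag(rot))
    origin = affine[:3, 3].astype(float)
    # Flip axes with negative direction so index order matches physical order.
    for ax in range(3):
        if rot[ax, ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + rot[ax, ax] * (data.shape[ax] - 1)
    return Volume(np.ascontiguousarray(data), spacing, origin)


def save_volume(v: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI with a diagonal affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(v.spacing)
    affine[:3, 3] = v.origin
    nib.save(nib.Nifti1Image(v.data, affine), str(path))


def resample_isotropic(
    v: Volume, target_mm: float = 1.0, interpolation: str = "linear"
) -> Volume:
    """Resample a volume onto an isotropic grid of ``target_mm`` voxels.

    Physical extent is preserved to within one voxel: the output size per
    axis is ``round(extent_mm / target_mm)``.  Interpolation is ``linear``
    for intensities (default) or ``nearest`` for masks/labels.  Already
    isotropic volumes are returned with an unchanged grid shape.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    orders = {"linear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if v.is_isotropic(target_mm):
        return Volume(v.data.copy(), np.full(3, float(target_mm)), v.origin.copy())
    new_shape = np.maximum(1, np.round(v.extent_mm() / target_mm).astype(int))
    # Sample at new voxel centers expressed in old index coordinates; both
    # grids share the same physical first-voxel-center (origin).
    coords = np.meshgrid(
        *[
            (np.arange(n) * target_mm) / v.spacing[ax]
            for ax, n in enumerate(new_shape)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        v.data.astype(float, copy=False),
        np.stack(coords),
        order=orders[interpolation],
        mode="nearest",
    )
    return Volume(out, np.full(3, float(target_mm)), v.origin.copy())


_TABLE_COLUMNS = ["patient_id", "x_mm", "y_mm", "z_mm", "label", "cohort"]


def read_centroid_table(path) -> list[CentroidRecord]:
    """Read a cohort CSV into centroid records."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns and c != "cohort"]
    if missing:
        raise ValueError(f"centroid table {path!r} lacks columns: {missing}")
    if "cohort" not in df.columns:
        df["cohort"] = "dataset1"
    return [
        CentroidRecord(
            patient_id=row.patient_id,
            centroid=np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float),
            label=int(row.label),
            cohort_tag=str(row.cohort),
        )
        for row in df.itertuples()
    ]


def write_centroid_table(records: list[CentroidRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "x_mm": r.centroid[0],
            "y_mm": r.centroid[1],
            "z_mm": r.centroid[2],
            "label": r.label,
            "cohort": r.cohort_tag,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)
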