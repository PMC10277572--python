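"""Seeded phantom cohorts with class-discriminative texture in a radial band.

Each phantom is a 64³ volume at 1 mm spacing: an air background (−1024 HU),
a soft-tissue ball, and a quasi-spherical tumor whose boundary is perturbed
by a smooth random field so that radial shells genuinely mix intratumoral
and peritumoral voxels.  For the "response" class, voxels whose distance to
the centroid falls inside ``signal_band`` receive additional band-limited
(smoothed Gaussian) noise of amplitude ``effect`` HU — a heterogeneity
contrast, the kind of signal run-length/dependence texture features pick
up.  With ``effect = 0`` the two classes are draws from the same
distribution.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import (
    CentroidRecord,
    Volume,
    load_volume,
    read_centroid_table,
    save_volume,
    write_centroid_table,
)

__all__ = ["PhantomConfig", "SyntheticSubject", "SyntheticCohort",
           "generate_cohort", "write_cohort", "load_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the phantom cohort.

    Defaults emulate the target population at desk scale: tumor radii are
    drawn uniformly from 8–14 mm (a ~21 mm mean diameter), the whole 15 mm
    partition range fits in a 64³ grid at 1 mm, and the responder texture
    signal sits in the 9–12 mm band.
    """

    n_per_class: int = 40
    grid_size: int = 64
    spacing_mm: float = 1.0
    tumor_radius_mm: tuple[float, float] = (8.0, 14.0)
    signal_band: tuple[float, float] = (9.0, 12.0)
    effect: float = 60.0  # HU amplitude of the responder band texture
    noise_sd: float = 20.0  # HU, i.i.d. noise inside the soft-tissue ball
    base_hu: float = 40.0  # tumor soft-tissue attenuation
    tissue_hu: float = -100.0  # surrounding tissue attenuation
    tissue_radius_mm: float = 26.0
    boundary_amp_mm: float = 1.5  # tumor boundary perturbation scale
    texture_sigma_vox: float = 1.5  # smoothing of the planted band texture
    centroid_jitter_mm: float = 0.4  # annotation off-center, sub-voxel
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least 2 subjects per class")
        lo, hi = self.signal_band
        if not (0.0 <= lo < hi <= 15.0):
            raise ValueError(f"signal band [{lo}, {hi}) must lie within [0, 15)")
        # The 15 mm ball plus margin must fit in the grid.
        half_extent = self.grid_size * self.spacing_mm / 2.0
        if half_extent < 15.0 + 2 * self.spacing_mm:
            raise ValueError("grid too small to contain the 15 mm ball with margin")


@dataclass
class SyntheticSubject:
    patient_id: str
    volume: Volume
    centroid: np.ndarray  # (x, y, z) mm
    label: int

    @property
    def record(self) -> CentroidRecord:
        return CentroidRecord(self.patient_id, self.centroid, self.label, "synthetic")


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    config: PhantomConfig

    def labels(self) -> pd.Series:
        return pd.Series({s.patient_id: s.label for s in self.subjects}, name="label")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": s.patient_id,
                    "x_mm": s.centroid[0],
                    "y_mm": s.centroid[1],
                    "z_mm": s.centroid[2],
                    "label": s.label,
                }
                for s in self.subjects
            ]
        )


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit standard deviation."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _make_subject(
    pid: str, label: int, cfg: PhantomConfig, rng: np.random.Generator
) -> SyntheticSubject:
    n = cfg.grid_size
    sp = cfg.spacing_mm
    center = (np.array([n, n, n]) - 1) / 2.0 * sp
    jitter = rng.uniform(-cfg.centroid_jitter_mm, cfg.centroid_jitter_mm, size=3)
    centroid = center + jitter

    ax = [np.arange(n) * sp - centroid[i] for i in range(3)]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij", sparse=True)
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)

    r0 = rng.uniform(*cfg.tumor_radius_mm)
    boundary = _smooth_unit_field(rng, (n, n, n), sigma=6.0)
    tumor = dist < (r0 + cfg.boundary_amp_mm * boundary)
    tissue = dist < cfg.tissue_radius_mm

    data = np.full((n, n, n), -1024.0)
    data[tissue] = cfg.tissue_hu
    data[tumor] = cfg.base_hu
    data[tissue] += rng.normal(0.0, cfg.noise_sd, size=int(tissue.sum()))

    # Planted heterogeneity: responders get extra band-limited texture in
    # the signal band.  Drawn for every subject so that effect = 0 leaves
    # the classes identically distributed and the RNG stream aligned.
    texture = _smooth_unit_field(rng, (n, n, n), sigma=cfg.texture_sigma_vox)
    lo, hi = cfg.signal_band
    band = (dist >= lo) & (dist < hi) & tissue
    if label == 1:
        data[band] += cfg.effect * texture[band]

    vol = Volume(data, np.full(3, sp), np.zeros(3))
    return SyntheticSubject(pid, vol, centroid, label)


def generate_cohort(cfg: PhantomConfig | None = None) -> SyntheticCohort:
    """Generate a balanced, seeded phantom cohort."""
    cfg = cfg or PhantomConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    subjects: list[SyntheticSubject] = []
    children = ss.spawn(2 * cfg.n_per_class)
    idx = 0
    for label in (1, 0):
        for k in range(cfg.n_per_class):
            rng = np.random.default_rng(children[idx])
            group = "resp" if label else "nonresp"
            subjects.append(_make_subject(f"{group}_{k:03d}", label, cfg, rng))
            idx += 1
    return SyntheticCohort(subjects, cfg)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort directory: NIfTI volumes, centroids.csv, ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for s in cohort.subjects:
        save_volume(s.volume, out / f"{s.patient_id}.nii.gz")
        records.append(s.record)
    write_centroid_table(records, out / "centroids.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=2, default=list)


def load_cohort(cohort_dir) -> SyntheticCohort:
    """Read back a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    table = d / "centroids.csv"
    if not table.exists():
        raise FileNotFoundError(f"no centroids.csv in {d}")
    gt = d / "ground_truth.json"
    if gt.exists():
        with open(gt) as fh:
            raw = json.load(fh)
        for key in ("tumor_radius_mm", "signal_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = PhantomConfig(**raw)
    else:
        cfg = PhantomConfig()
    subjects = [
        SyntheticSubject(
            rec.patient_id,
            load_volume(d / f"{rec.patient_id}.nii.gz"),
            rec.centroid,
            rec.label,
        )
        for rec in read_centroid_table(table)
    ]
    return SyntheticCohort(subjects, cfg)
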