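"""Gray-level texture matrices and their features (3D, 26-connectivity).

Five matrix families over a fixed-bin-width discretized image:

* GLCM  — co-occurrence of gray-level pairs at unit offset, symmetric,
          features averaged over the 13 unique directions (24 features);
* GLRLM — run lengths of equal gray level along each direction, features
          averaged over the 13 directions (16 features);
* GLSZM — sizes of 26-connected equal-gray-level zones (16 features);
* GLDM  — per-voxel dependence counts: neighbors within ``alpha`` gray
          levels of the center, dependence size = count + 1 (14 features);
* NGTDM — per-gray-level summed deviation from the mean of in-mask
          neighbors (5 features).

Inputs are a discretized gray array ``g`` over the mask bounding box with
0 outside the mask and levels ``1..Ng`` inside.  All features are finite
for every non-empty mask, including constant regions (conventional values
are substituted where a definition degenerates).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "discretize",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "TEXTURE_NAMES",
]

_EPS = np.finfo(float).eps

#: The 13 unique direction vectors of the 26-neighborhood (antipodes folded).
_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

TEXTURE_NAMES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray levels 1..Ng, anchored at the region minimum."""
    v = np.asarray(values, dtype=float)
    return (np.floor((v - v.min()) / bin_width)).astype(np.int64) + 1


def _offset_views(g: np.ndarray, off: tuple[int, int, int]):
    """Aligned (source, destination) views of ``g`` under a unit offset."""
    src, dst = [], []
    for ax, o in enumerate(off):
        n = g.shape[ax]
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return g[tuple(src)], g[tuple(dst)]


# ---------------------------------------------------------------- GLCM

def _glcm_matrix(g: np.ndarray, ng: int, off: tuple[int, int, int]) -> np.ndarray:
    a, b = _offset_views(g, off)
    a, b = a.ravel(), b.ravel()
    keep = (a > 0) & (b > 0)
    if not np.any(keep):
        return np.zeros((ng, ng))
    c = np.bincount((a[keep] - 1) * ng + (b[keep] - 1), minlength=ng * ng)
    c = c.reshape(ng, ng).astype(float)
    return c + c.T  # symmetric


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))

    # Sum and difference distributions.
    psum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    ksum = np.arange(2, 2 * ng + 1)
    pdiff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)
    kdiff = np.arange(ng)
    da = float(np.sum(kdiff * pdiff))

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pxy = np.outer(px, px)
    nz2 = pxy > 0
    hxy1 = float(-np.sum(p[nz2] * np.log2(pxy[nz2])))
    hxy2 = float(-np.sum(pxy[nz2] * np.log2(pxy[nz2])))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))

    if sigma2 > 0:
        correlation = float((np.sum(ii * jj * p) - mu * mu) / sigma2)
    else:
        correlation = 1.0

    # Maximal correlation coefficient: sqrt of the second eigenvalue of Q.
    lv = px > 0
    if lv.sum() > 1:
        psub = p[np.ix_(lv, lv)]
        pxs = px[lv]
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(np.clip(ev[1], 0.0, 1.0)))
    else:
        mcc = 1.0

    off_diag = ii != jj
    inv_var = float(np.sum(p[off_diag] / (ii[off_diag] - jj[off_diag]) ** 2))
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -np.sum(pdiff[pdiff > 0] * np.log2(pdiff[pdiff > 0]))
        ),
        "DifferenceVariance": float(np.sum((kdiff - da) ** 2 * pdiff)),
        "JointEnergy": float(np.sum(p * p)),
        "JointEntropy": hxy,
        "Imc1": float((hxy - hxy1) / hx) if hx > 0 else 0.0,
        "Imc2": float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0.0)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ksum * psum)),
        "SumEntropy": float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0]))),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def glcm_features(g: np.ndarray, ng: int) -> dict[str, float]:
    """Co-occurrence features averaged over the 13 unique directions."""
    acc: dict[str, float] = {k: 0.0 for k in GLCM_NAMES}
    used = 0
    for off in _DIRECTIONS:
        c = _glcm_matrix(g, ng, off)
        total = c.sum()
        if total == 0:
            continue
        feats = _glcm_single(c / total)
        for k in GLCM_NAMES:
            acc[k] += feats[k]
        used += 1
    if used == 0:  # pathological: no co-occurring in-mask pair in any direction
        return {k: 0.0 for k in GLCM_NAMES}
    return {k: v / used for k, v in acc.items()}


# ---------------------------------------------------------------- GLRLM

def _runs_along(g: np.ndarray, off: tuple[int, int, int]):
    """Gray level and length of every run along direction ``off``.

    Voxels are ordered line-by-line using integer line keys: for the first
    axis ``a`` with a nonzero step, ``step = index_a * off_a`` advances along
    the line and ``key_j = index_j - step * off_j`` is constant on it.
    """
    a = next(ax for ax in range(3) if off[ax] != 0)
    idx = np.indices(g.shape).reshape(3, -1)
    step = idx[a] * off[a]
    keys = [idx[j] - step * off[j] for j in range(3) if j != a]
    order = np.lexsort((step, keys[1], keys[0]))
    v = g.ravel()[order]
    k0 = keys[0][order]
    k1 = keys[1][order]
    newline = (k0[1:] != k0[:-1]) | (k1[1:] != k1[:-1])
    boundary = np.flatnonzero(newline | (v[1:] != v[:-1]))
    starts = np.concatenate(([0], boundary + 1))
    ends = np.concatenate((boundary, [v.size - 1]))
    gray = v[starts]
    lengths = ends - starts + 1
    keep = gray > 0
    return gray[keep], lengths[keep]


def _distribution_features(
    gray: np.ndarray,
    size: np.ndarray,
    ng: int,
    n_voxels: int,
    names: tuple[str, ...],
    prefix_small: str,
) -> dict[str, float]:
    """Shared feature formulas for run-length / size-zone / dependence matrices.

    ``gray`` and ``size`` list one entry per run/zone/voxel with its gray
    level i and its length/size/dependence j; all three families share the
    same functional forms in (i, j).
    """
    n = gray.size
    if n == 0:
        return {k: 0.0 for k in names}
    w = np.ones(n) / n  # each entry equally weighted
    gi = gray.astype(float)
    sj = size.astype(float)

    per_gray = np.bincount(gray, minlength=ng + 1)[1:].astype(float)
    per_size = np.bincount(size).astype(float)
    mean_g = float(np.sum(w * gi))
    mean_s = float(np.sum(w * sj))

    # Joint probabilities for the entropy term.
    joint = np.unique(gray * (size.max() + 1) + size, return_counts=True)[1] / n

    small = prefix_small  # e.g. "ShortRun", "SmallArea", "SmallDependence"
    large = {"ShortRun": "LongRun", "SmallArea": "LargeArea",
             "SmallDependence": "LargeDependence"}[prefix_small]
    mid = {"ShortRun": "RunLength", "SmallArea": "SizeZone",
           "SmallDependence": "Dependence"}[prefix_small]
    midvar = {"ShortRun": "Run", "SmallArea": "Zone",
              "SmallDependence": "Dependence"}[prefix_small]
    midperc = {"ShortRun": "RunPercentage", "SmallArea": "ZonePercentage",
               "SmallDependence": None}[prefix_small]
    entropy_name = {"ShortRun": "RunEntropy", "SmallArea": "ZoneEntropy",
                    "SmallDependence": "DependenceEntropy"}[prefix_small]
    lowg = {"ShortRun": "LowGrayLevelRunEmphasis", "SmallArea": "LowGrayLevelZoneEmphasis",
            "SmallDependence": "LowGrayLevelEmphasis"}[prefix_small]
    highg = {"ShortRun": "HighGrayLevelRunEmphasis", "SmallArea": "HighGrayLevelZoneEmphasis",
             "SmallDependence": "HighGrayLevelEmphasis"}[prefix_small]

    out = {
        f"{small}Emphasis": float(np.sum(w / sj**2)),
        f"{large}Emphasis": float(np.sum(w * sj**2)),
        "GrayLevelNonUniformity": float(np.sum(per_gray**2) / n),
        "GrayLevelNonUniformityNormalized": float(np.sum(per_gray**2) / n**2),
        f"{mid}NonUniformity": float(np.sum(per_size**2) / n),
        f"{mid}NonUniformityNormalized": float(np.sum(per_size**2) / n**2),
        "GrayLevelVariance": float(np.sum(w * (gi - mean_g) ** 2)),
        f"{midvar}Variance": float(np.sum(w * (sj - mean_s) ** 2)),
        entropy_name: float(-np.sum(joint * np.log2(joint + _EPS))),
        lowg: float(np.sum(w / gi**2)),
        highg: float(np.sum(w * gi**2)),
        f"{small}LowGrayLevelEmphasis": float(np.sum(w / (gi**2 * sj**2))),
        f"{small}HighGrayLevelEmphasis": float(np.sum(w * gi**2 / sj**2)),
        f"{large}LowGrayLevelEmphasis": float(np.sum(w * sj**2 / gi**2)),
        f"{large}HighGrayLevelEmphasis": float(np.sum(w * gi**2 * sj**2)),
    }
    if midperc is not None:
        out[midperc] = float(n / n_voxels)
    # GLDM normalized GLN shares the GLRLM/GLSZM formula but a different name slot.
    return {k: out[k] for k in names}


def glrlm_features(g: np.ndarray, ng: int, n_voxels: int) -> dict[str, float]:
    """Run-length features averaged over the 13 unique directions."""
    acc = {k: 0.0 for k in GLRLM_NAMES}
    for off in _DIRECTIONS:
        gray, lengths = _runs_along(g, off)
        feats = _distribution_features(
            gray, lengths, ng, n_voxels, GLRLM_NAMES, "ShortRun"
        )
        for k in GLRLM_NAMES:
            acc[k] += feats[k]
    return {k: v / len(_DIRECTIONS) for k, v in acc.items()}


# ---------------------------------------------------------------- GLSZM

def glszm_features(g: np.ndarray, ng: int, n_voxels: int) -> dict[str, float]:
    """Size-zone features from 26-connected equal-gray-level zones."""
    structure = np.ones((3, 3, 3), dtype=int)
    grays, sizes = [], []
    for level in range(1, ng + 1):
        binary = g == level
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        counts = np.bincount(labeled.ravel())[1:]
        grays.append(np.full(n_zones, level, dtype=np.int64))
        sizes.append(counts.astype(np.int64))
    if not grays:
        return {k: 0.0 for k in GLSZM_NAMES}
    return _distribution_features(
        np.concatenate(grays), np.concatenate(sizes), ng, n_voxels,
        GLSZM_NAMES, "SmallArea",
    )


# ---------------------------------------------------------------- GLDM

def gldm_features(
    g: np.ndarray, ng: int, alpha: float = 0.0
) -> dict[str, float]:
    """Dependence features: neighbors within ``alpha`` gray levels of the center.

    Dependence size of a voxel = 1 + number of its in-mask 26-neighbors j
    with |g_i - g_j| <= alpha (the center always depends on itself).
    """
    inmask = g > 0
    dep = np.zeros(g.shape, dtype=np.int64)
    for off in _DIRECTIONS:
        a, b = _offset_views(g, off)
        am, bm = _offset_views(inmask, off)
        hit = am & bm & (np.abs(a.astype(np.int64) - b) <= alpha)
        src_sl, dst_sl = [], []
        for ax, o in enumerate(off):
            n = g.shape[ax]
            src_sl.append(slice(0, n - o) if o >= 0 else slice(-o, n))
            dst_sl.append(slice(o, n) if o >= 0 else slice(0, n + o))
        dep[tuple(src_sl)] += hit
        dep[tuple(dst_sl)] += hit
    gray = g[inmask].astype(np.int64)
    size = dep[inmask] + 1
    return _distribution_features(
        gray, size, ng, int(inmask.sum()), GLDM_NAMES, "SmallDependence"
    )


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(g: np.ndarray, ng: int) -> dict[str, float]:
    """Neighborhood gray-tone difference features."""
    inmask = g > 0
    nsum = np.zeros(g.shape, dtype=float)
    ncnt = np.zeros(g.shape, dtype=np.int64)
    for off in _DIRECTIONS:
        src_sl, dst_sl = [], []
        for ax, o in enumerate(off):
            n = g.shape[ax]
            src_sl.append(slice(0, n - o) if o >= 0 else slice(-o, n))
            dst_sl.append(slice(o, n) if o >= 0 else slice(0, n + o))
        src_sl, dst_sl = tuple(src_sl), tuple(dst_sl)
        m_src, m_dst = inmask[src_sl], inmask[dst_sl]
        nsum[src_sl] += np.where(m_dst, g[dst_sl], 0)
        ncnt[src_sl] += m_dst
        nsum[dst_sl] += np.where(m_src, g[src_sl], 0)
        ncnt[dst_sl] += m_src
    valid = inmask & (ncnt > 0)
    nv = int(valid.sum())
    if nv == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    diff = np.abs(g[valid] - nsum[valid] / ncnt[valid])
    gray = g[valid].astype(np.int64)
    s = np.bincount(gray, weights=diff, minlength=ng + 1)[1:]
    n_i = np.bincount(gray, minlength=ng + 1)[1:].astype(float)
    p = n_i / nv
    present = p > 0
    i = np.arange(1, ng + 1, dtype=float)
    ngp = int(present.sum())

    sum_ps = float(np.sum(p * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        gi, gj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = float(
            np.sum(pi * pj * (gi - gj) ** 2) / (ngp * (ngp - 1)) * np.sum(s) / nv
        )
        busy_den = float(np.sum(np.abs(gi * pi - gj * pj)))
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        si = s[present]
        complexity = float(
            np.sum(np.abs(gi - gj) * (pi * si[:, None] + pj * si[None, :]) / (pi + pj))
            / nv
        )
        strength = (
            float(np.sum((pi + pj) * (gi - gj) ** 2)) / float(np.sum(s))
            if np.sum(s) > 0
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
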