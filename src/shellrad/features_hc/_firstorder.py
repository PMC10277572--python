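"""First-order (intensity-histogram) features of a masked region.

Eighteen descriptors of the intensity distribution of the masked voxels.
Entropy and Uniformity use the same fixed-bin-width discretization as the
texture matrices; Variance and the moment-based statistics are population
(biased) moments.  Skewness and Kurtosis are defined as 0 for a constant
region.
"""

from __future__ import annotations

import numpy as np

__all__ = ["firstorder_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    x: np.ndarray, voxel_volume_mm3: float, bin_width: float
) -> dict[str, float]:
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty intensity sample")
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    # Discretized probabilities for Entropy / Uniformity.
    edges_n = max(1, int(np.ceil((x.max() - x.min()) / bin_width)))
    counts, _ = np.histogram(x, bins=edges_n, range=(x.min(), x.min() + edges_n * bin_width))
    p = counts[counts > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if sd > 0:
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        skew, kurt = 0.0, 0.0

    energy = float(np.sum(x * x))
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume_mm3) * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x * x))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": float(np.sum(p * p)),
    }
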