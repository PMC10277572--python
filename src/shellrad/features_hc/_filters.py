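"""Image variants (filters) applied before intensity/texture feature extraction.

Eighteen variants per partition under the default configuration: the
original image, eight single-level separable wavelet subbands, five
scale-normalized Laplacian-of-Gaussian responses, and four global intensity
remaps (square, square-root, logarithm, exponential).  The remaps are
rescaled so their output range stays comparable to the input range, keeping
a fixed-bin-width discretization meaningful across variants.
"""

from __future__ import annotations

from itertools import product
from typing import Iterator

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["iter_image_variants", "variant_names"]


def _wavelet_subbands(image: np.ndarray, wavelet: str) -> Iterator[tuple[str, np.ndarray]]:
    """All 8 lo/hi separable decompositions along (x, y, z), undecimated."""
    w = pywt.Wavelet(wavelet)
    filt = {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}
    for combo in product("LH", repeat=3):
        out = image.astype(float, copy=True)
        for axis, band in enumerate(combo):
            out = ndimage.correlate1d(out, filt[band], axis=axis, mode="reflect")
        yield "wavelet-" + "".join(combo), out


def _log_variant(image: np.ndarray, sigma_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Scale-normalized Laplacian of Gaussian at one physical scale."""
    sigma_vox = sigma_mm / np.asarray(spacing, dtype=float)
    return sigma_mm**2 * ndimage.gaussian_laplace(image.astype(float), sigma_vox)


def _square(x: np.ndarray) -> np.ndarray:
    m = np.abs(x).max()
    if m == 0:
        return np.zeros_like(x, dtype=float)
    c = 1.0 / np.sqrt(m)
    return (c * x) ** 2


def _squareroot(x: np.ndarray) -> np.ndarray:
    m = np.abs(x).max()
    if m == 0:
        return np.zeros_like(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x) * m)


def _logarithm(x: np.ndarray) -> np.ndarray:
    m = np.abs(x).max()
    if m == 0:
        return np.zeros_like(x, dtype=float)
    c = m / np.log1p(m)
    return np.sign(x) * c * np.log1p(np.abs(x))


def _exponential(x: np.ndarray) -> np.ndarray:
    m = np.abs(x).max()
    c = np.log(m) / m if m > 0 else 1.0
    return np.exp(c * x)


_REMAPS = {
    "square": _square,
    "squareroot": _squareroot,
    "logarithm": _logarithm,
    "exponential": _exponential,
}


def iter_image_variants(
    image: np.ndarray, config, spacing: np.ndarray
) -> Iterator[tuple[str, np.ndarray]]:
    """Yield (variant name, filtered image) in a stable order."""
    for f in config.filters:
        if f == "original":
            yield "original", image.astype(float, copy=False)
        elif f == "wavelet":
            yield from _wavelet_subbands(image, config.wavelet)
        elif f == "log":
            for sigma in config.log_sigmas:
                yield f"log-sigma-{sigma:g}mm", _log_variant(image, sigma, spacing)
        elif f in _REMAPS:
            yield f, _REMAPS[f](image.astype(float, copy=False))
        else:
            raise ValueError(f"unknown image filter {f!r}")


def variant_names(config) -> list[str]:
    """Names of all image variants the configuration expands to."""
    names: list[str] = []
    for f in config.filters:
        if f == "original":
            names.append("original")
        elif f == "wavelet":
            names.extend("wavelet-" + "".join(c) for c in product("LH", repeat=3))
        elif f == "log":
            names.extend(f"log-sigma-{s:g}mm" for s in config.log_sigmas)
        elif f in _REMAPS:
            names.append(f)
        else:
            raise ValueError(f"unknown image filter {f!r}")
    return names
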