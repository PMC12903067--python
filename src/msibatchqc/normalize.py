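"""Classic MSI normalizations: TIC, L2, per-feature z-scores, g-log.

Per-pixel normalizations (TIC, L2) rescale each spectrum to a common total
or norm; the per-feature z-score standardizes every ion image across pixels;
the generalized logarithm ``g(x) = ln((x + sqrt(x^2 + lambda))/2)`` is a
variance-stabilizing transform that behaves like ``ln`` for large x while
staying defined (and smooth) at zero. The study default is lambda = 1e6.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datacube import Datacube

DEFAULT_GLOG_LAMBDA = 1e6


def tic_normalize(cube: Datacube) -> Datacube:
    """Divide each pixel spectrum by its total ion current (unit row sums).

    Zero-TIC pixels are left untouched with a warning.
    """
    x = cube.intensities
    tic = x.sum(axis=1)
    zero = tic == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-TIC pixels left unnormalized")
    scale = np.where(zero, 1.0, tic)
    return cube.with_intensities(x / scale[:, None], tag="tic_normalize")


def l2_normalize(cube: Datacube) -> Datacube:
    """Divide each pixel spectrum by its Euclidean norm (unit row norms)."""
    x = cube.intensities
    norm = np.linalg.norm(x, axis=1)
    zero = norm == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm pixels left unnormalized")
    scale = np.where(zero, 1.0, norm)
    return cube.with_intensities(x / scale[:, None], tag="l2_normalize")


def zscore_features(cube: Datacube) -> Datacube:
    """Standardize every feature to mean 0 and population SD 1 across pixels.

    The population (divide-by-n) standard deviation is used, matching the
    common preprocessing default. Constant features become all-zero columns
    with a warning.
    """
    x = cube.intensities
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD
    # relative threshold: accumulated rounding can leave a constant column
    # with an SD of a few ULPs instead of exactly zero
    const = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    if const.any():
        warnings.warn(f"{int(const.sum())} constant features set to zero")
    scale = np.where(const, 1.0, sd)
    z = (x - mean) / scale
    z[:, const] = 0.0
    return cube.with_intensities(z, tag="zscore_features:population_sd")


def glog(x: np.ndarray, lam: float = DEFAULT_GLOG_LAMBDA) -> np.ndarray:
    """Generalized logarithm ``ln((x + sqrt(x^2 + lambda)) / 2)``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x * x + lam)) / 2.0)


def glog_inverse(y: np.ndarray, lam: float = DEFAULT_GLOG_LAMBDA) -> np.ndarray:
    """Exact inverse of :func:`glog`: ``x = e^y - lambda / (4 e^y)``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    u = np.exp(np.asarray(y, dtype=float))
    return u - lam / (4.0 * u)


def glog_transform(cube: Datacube, lam: float = DEFAULT_GLOG_LAMBDA) -> Datacube:
    """Apply the g-log variance-stabilizing transform elementwise."""
    return cube.with_intensities(glog(cube.intensities, lam), tag=f"glog:lambda={lam:g}")
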