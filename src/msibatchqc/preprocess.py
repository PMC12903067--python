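"""Profile-spectrum preprocessing: rebinning, segmentation, peak picking.

The pipeline that turns raw profile spectra into a peak-picked datacube:
linear-interpolation rebinning onto a common fine grid (0.0008 Da default),
cosine k-means segmentation of tissue from background, a tissue mean
spectrum, gradient peak picking, selection of the top-N most intense peaks
(N = 1000 for full studies), merging of per-tissue peak lists onto a common
axis, and windowed extraction of peak intensities per pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._cluster import spherical_kmeans
from .datacube import Datacube

DEFAULT_BIN_WIDTH = 0.0008  # Da
DEFAULT_TOP_N = 1000
DEFAULT_MERGE_TOLERANCE = 0.005  # Da, several fine bins


@dataclass
class Spectrum:
    """A profile spectrum on a strictly increasing m/z axis."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(~np.isfinite(self.intensity)) or np.any(~np.isfinite(self.mz)):
            raise ValueError("spectrum contains non-finite values")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz axis must be strictly increasing")


@dataclass
class PeakList:
    """Picked peaks: apex positions/heights plus boundary bin indices."""

    mz: np.ndarray
    intensity: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.left = np.asarray(self.left, dtype=int)
        self.right = np.asarray(self.right, dtype=int)
        n = self.mz.size
        if not (self.intensity.size == self.left.size == self.right.size == n):
            raise ValueError("peak list arrays must share one length")

    def __len__(self) -> int:
        return self.mz.size


def rebin_grid(mz_range: tuple[float, float], bin_width: float) -> np.ndarray:
    """Common m/z grid ``start..end`` with the given step (end included when
    it falls on the grid to within floating-point slack)."""
    lo, hi = mz_range
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if hi <= lo:
        raise ValueError("mz_range end must exceed start")
    ratio = (hi - lo) / bin_width
    n = int(np.floor(ratio * (1 + 1e-12) + 1e-9)) + 1
    return lo + bin_width * np.arange(n)


def rebin_linear(
    spectra: list[Spectrum],
    bin_width: float = DEFAULT_BIN_WIDTH,
    mz_range: tuple[float, float] = (50.0, 1200.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation rebinning of raw spectra onto a common grid.

    Each spectrum is evaluated by linear interpolation at every grid node;
    nodes outside a spectrum's support get 0. Values at grid-coincident
    points are conserved exactly.

    Returns ``(grid_mz, matrix)`` with one row per input spectrum.
    """
    grid = rebin_grid(mz_range, bin_width)
    out = np.zeros((len(spectra), grid.size))
    for i, s in enumerate(spectra):
        if s.mz.size == 0:
            raise ValueError(f"spectrum {i} is empty")
        out[i] = np.interp(grid, s.mz, s.intensity, left=0.0, right=0.0)
    return grid, out


def mean_spectrum(cube: Datacube, mask: np.ndarray | None = None) -> Spectrum:
    """Arithmetic mean spectrum over the selected pixels (all by default)."""
    if mask is None:
        mask = np.ones(cube.n_pixels, dtype=bool)
    mask = np.asarray(mask)
    sub = cube.intensities[mask]
    if sub.shape[0] == 0:
        raise ValueError("mask selects no pixels")
    return Spectrum(mz=cube.mz.copy(), intensity=sub.mean(axis=0))


def segment_background(
    cube: Datacube, k: int = 3, seed: int | None = 0, replicates: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Segment tissue from background by cosine k-means on pixel spectra.

    All-zero pixels are dropped from clustering with a warning and flagged
    background directly. The background cluster is the one whose member
    pixels have the lowest mean TIC.

    Returns ``(labels, is_background)``; dropped pixels get label -1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = cube.intensities
    tic = x.sum(axis=1)
    nonzero = np.linalg.norm(x, axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"dropping {int((~nonzero).sum())} all-zero pixels from segmentation")
    labels = np.full(cube.n_pixels, -1, dtype=int)
    sub_labels, _ = spherical_kmeans(x[nonzero], k=k, seed=seed, replicates=replicates)
    labels[nonzero] = sub_labels
    mean_tic = np.array(
        [tic[labels == c].mean() if (labels == c).any() else np.inf for c in range(k)]
    )
    bg_cluster = int(np.argmin(mean_tic))
    is_background = (labels == bg_cluster) | ~nonzero
    return labels, is_background


def pick_peaks_gradient(s: Spectrum, min_intensity: float = 0.0) -> PeakList:
    """Pick peaks as sign changes (+ to -) of the spectrum's first difference.

    An apex is a bin where the gradient turns from rising to falling, with
    apex intensity strictly above ``min_intensity``; plateaus resolve to
    their lowest-index bin. Peak boundaries extend from the apex to the
    nearest flanking local minima (or the spectrum ends). Spectrum ends
    cannot be apexes. No smoothing is applied; callers wanting it can smooth
    beforehand (see :func:`smooth_moving_average`).
    """
    y = s.intensity
    n = y.size
    if n < 3:
        raise ValueError("spectrum must have at least 3 bins")
    apexes = _plateau_aware_apexes(y)
    keep = [i for i in apexes if y[i] > min_intensity]
    lefts, rights = [], []
    for i in keep:
        # walk downhill (non-increasing away from the apex) to the flanking
        # local minimum or the spectrum end
        l = i
        while l > 0 and y[l - 1] <= y[l]:
            l -= 1
        r = i
        while r < n - 1 and y[r + 1] <= y[r]:
            r += 1
        lefts.append(l)
        rights.append(r)
    return PeakList(
        mz=s.mz[keep],
        intensity=y[keep],
        left=np.array(lefts, dtype=int),
        right=np.array(rights, dtype=int),
    )


def _plateau_aware_apexes(y: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus resolve to their lowest index.

    A plateau touching either spectrum end is not an apex (no full sign
    change of the gradient).
    """
    n = y.size
    apexes = []
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j < n - 1 and y[j + 1] < y[i]:
                apexes.append(i)
            i = j + 1
        else:
            i += 1
    return apexes


def smooth_moving_average(s: Spectrum, window: int = 5) -> Spectrum:
    """Odd-window moving-average smoothing (optional pre-step to picking)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(s.intensity, pad, mode="edge")
    return Spectrum(mz=s.mz.copy(), intensity=np.convolve(padded, kernel, mode="valid"))


def top_n_peaks(p: PeakList, n: int = DEFAULT_TOP_N) -> PeakList:
    """Keep the *n* highest-apex peaks, re-sorted by m/z.

    Ties in apex intensity break toward lower m/z. When fewer than *n*
    peaks exist, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(p) <= n:
        order = np.argsort(p.mz, kind="stable")
    else:
        # sort by (-intensity, mz): lower m/z wins intensity ties
        rank = np.lexsort((p.mz, -p.intensity))[:n]
        order = rank[np.argsort(p.mz[rank], kind="stable")]
    return PeakList(mz=p.mz[order], intensity=p.intensity[order], left=p.left[order], right=p.right[order])


def merge_common_axis(peaklists: list[PeakList], tolerance: float = DEFAULT_MERGE_TOLERANCE) -> PeakList:
    """Merge peak lists from several tissues onto one common axis.

    Peaks across lists whose m/z centres chain within *tolerance* (single
    linkage) collapse to one peak at their intensity-weighted mean m/z with
    summed apex intensity; boundaries span the merged group.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if not peaklists:
        raise ValueError("need at least one peak list")
    mz = np.concatenate([p.mz for p in peaklists])
    inten = np.concatenate([p.intensity for p in peaklists])
    left = np.concatenate([p.left for p in peaklists])
    right = np.concatenate([p.right for p in peaklists])
    if mz.size == 0:
        return PeakList(mz=mz, intensity=inten, left=left, right=right)
    order = np.argsort(mz, kind="stable")
    mz, inten, left, right = mz[order], inten[order], left[order], right[order]
    breaks = np.flatnonzero(np.diff(mz) > tolerance)
    groups = np.split(np.arange(mz.size), breaks + 1)
    out_mz, out_int, out_l, out_r = [], [], [], []
    for g in groups:
        w = inten[g]
        out_mz.append(float(np.average(mz[g], weights=w)) if w.sum() > 0 else float(mz[g].mean()))
        out_int.append(float(w.sum()))
        out_l.append(int(left[g].min()))
        out_r.append(int(right[g].max()))
    return PeakList(
        mz=np.array(out_mz), intensity=np.array(out_int),
        left=np.array(out_l), right=np.array(out_r),
    )


def extract_peak_cube(cube: Datacube, peaks: PeakList, half_window: float) -> Datacube:
    """Collapse a profile cube to a peak cube by windowed summation.

    For each pixel and each peak, profile bins within ``apex +/- half_window``
    are summed; when windows overlap, each bin goes to its nearest apex (a
    warning is emitted). The output feature axis is the peak apex m/z.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    centers = np.asarray(peaks.mz, dtype=float)
    if centers.size == 0:
        raise ValueError("empty peak list")
    if centers.size > 1 and np.any(np.diff(centers) < 2 * half_window):
        warnings.warn("peak windows overlap; profile bins assigned to nearest apex")
    # nearest apex per profile bin
    idx = np.clip(np.searchsorted(centers, cube.mz), 0, centers.size - 1)
    left_closer = (idx > 0) & (
        np.abs(cube.mz - centers[np.maximum(idx - 1, 0)]) < np.abs(cube.mz - centers[idx])
    )
    nearest = idx - left_closer.astype(int)
    in_window = np.abs(cube.mz - centers[nearest]) <= half_window
    out = np.zeros((cube.n_pixels, centers.size))
    cols = nearest[in_window]
    sub = cube.intensities[:, in_window]
    np.add.at(out.T, cols, sub.T)
    new = cube.copy()
    new.intensities = out
    new.mz = centers.copy()
    new.provenance.append(f"extract_peak_cube:half_window={half_window}")
    new.validate()
    return new
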