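"""Wavelet + ICA removal of acquisition-order-structured batch variation.

Pixels are ordered by acquisition time and each feature's intensity series
is decomposed with an undecimated (stationary) wavelet transform, which
separates slow trends — the time scale on which batch effects and drift
live — from fast, spatially driven variation. Within every decomposition
level, independent component analysis across features isolates shared
sources; components whose time courses track the batch label (one-way
R^2 above a cutoff) are subtracted, and the series is inverse-transformed.

Removed components are subtracted from the original coefficient matrices
rather than re-synthesized from the retained ones, so with no component
flagged the corrector is an exact identity (up to wavelet round-off). Each
feature's grand mean is reattached after reconstruction.

The method's core assumption — batch effects are low-frequency in
acquisition order while biology is high-frequency — holds for randomized
injection sequences but only partially for MSI rasters, where tissue
gradients are themselves slow; the association cutoff is the guard rail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
import warnings

from .datacube import Datacube


@dataclass
class WaveicaParams:
    """Tuning knobs for :func:`waveica_correct`.

    ``wavelet`` any orthogonal PyWavelets name (Haar default); ``level``
    decomposition depth J (``None`` = min(10, floor(log2 n))); ``n_components``
    ICA components per level (``None`` = min(10, n_features)); ``cutoff``
    one-way batch-association R^2 above which a component is removed;
    ``seed`` fixes the ICA initialisation.
    """

    wavelet: str = "haar"
    level: int | None = None
    n_components: int | None = None
    cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.level is not None and self.level < 1:
            raise ValueError("level must be >= 1")
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0 <= self.cutoff <= 1:
            raise ValueError("cutoff must be in [0, 1]")


def _ica_sources(mat: np.ndarray, n_comp: int, seed: int | None) -> np.ndarray:
    """FastICA sources of a coefficient matrix with canonical whitening.

    Whitening is done here (sample-side SVD with signs fixed by each score
    column's largest-magnitude entry) rather than inside FastICA, whose sign
    convention depends on the feature order; this makes the whole corrector
    equivariant under feature permutation.
    """
    centred = mat - mat.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > max(s[0], 1e-300) * 1e-10).sum())
    c_eff = min(n_comp, rank)
    if c_eff == 0:
        return np.empty((mat.shape[0], 0))
    u_c = u[:, :c_eff]
    signs = np.sign(u_c[np.argmax(np.abs(u_c), axis=0), np.arange(c_eff)])
    scores = u_c * signs * np.sqrt(mat.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # scores already hold exactly c_eff whitened columns
        ica = FastICA(random_state=seed, max_iter=1000, whiten=False)
        return ica.fit_transform(scores)


def batch_association_r2(values: np.ndarray, batch: np.ndarray) -> float:
    """One-way ANOVA R^2 of a series against a categorical batch label."""
    values = np.asarray(values, dtype=float)
    total = ((values - values.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    within = 0.0
    for b in np.unique(batch):
        v = values[batch == b]
        within += ((v - v.mean()) ** 2).sum()
    return 1.0 - within / total


def _spearman_association(values: np.ndarray, order: np.ndarray) -> float:
    from scipy.stats import spearmanr

    rho = spearmanr(values, order).statistic
    return 0.0 if np.isnan(rho) else abs(float(rho)) ** 2


def waveica_correct(
    cube_or_matrix: Datacube | np.ndarray,
    batch: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
    params: WaveicaParams | None = None,
    association: str = "batch",
) -> Datacube | np.ndarray:
    """Remove batch-associated wavelet-domain ICA components.

    Parameters
    ----------
    cube_or_matrix
        Datacube (labels/times taken from it) or raw matrix with explicit
        ``batch`` and ``time_s``.
    association
        ``"batch"`` scores components by one-way R^2 against the batch
        label; ``"order"`` by squared Spearman correlation with acquisition
        order.
    """
    params = params or WaveicaParams()
    is_cube = isinstance(cube_or_matrix, Datacube)
    if is_cube:
        x = cube_or_matrix.intensities
        batch = cube_or_matrix.batch if batch is None else np.asarray(batch)
        time_s = cube_or_matrix.time_s if time_s is None else np.asarray(time_s)
    else:
        x = np.asarray(cube_or_matrix, dtype=float)
        if batch is None or time_s is None:
            raise ValueError("batch and time_s required for a bare matrix")
        batch = np.asarray(batch)
        time_s = np.asarray(time_s, dtype=float)
    if np.any(~np.isfinite(time_s)):
        raise ValueError("all pixels must carry finite time_s")
    n, g_total = x.shape
    level = params.level if params.level is not None else max(1, min(10, int(np.floor(np.log2(n)))))
    if n < 2**level:
        raise ValueError(f"need at least 2^J = {2 ** level} pixels for depth {level}")
    n_comp = params.n_components if params.n_components is not None else min(10, g_total)
    n_comp = min(n_comp, g_total)

    order = np.argsort(time_s, kind="stable")
    xo = x[order]
    bo = batch[order]

    # pad (edge-replicate) to a multiple of 2^J as the stationary transform requires
    block = 2**level
    n_pad = (-n) % block
    xp = np.vstack([xo, np.repeat(xo[-1:], n_pad, axis=0)]) if n_pad else xo

    coeffs = pywt.swt(xp, params.wavelet, level=level, axis=0, trim_approx=True, norm=True)

    rank_order = np.arange(n)
    for mat in coeffs:  # [approx_J, detail_J, ..., detail_1], each (n_pad_len, G)
        sources = _ica_sources(mat, n_comp, params.seed)
        for c in range(sources.shape[1]):
            s = sources[:, c]
            if association == "order":
                score = _spearman_association(s[:n], rank_order)
            else:
                score = batch_association_r2(s[:n], bo)
            if score > params.cutoff:
                # subtract the component's least-squares contribution to
                # every feature (sources are decorrelated, so per-component
                # projection is exact)
                centred = mat - mat.mean(axis=0)
                loadings = centred.T @ s / (s @ s)
                mat -= np.outer(s, loadings)

    rec = pywt.iswt(coeffs, params.wavelet, norm=True, axis=0)[:n]
    # restore each feature's grand mean, then undo the time ordering
    rec += xo.mean(axis=0) - rec.mean(axis=0)
    out = np.empty_like(rec)
    out[order] = rec
    if is_cube:
        return cube_or_matrix.with_intensities(
            out, tag=f"waveica:wavelet={params.wavelet},J={level},c={n_comp},cutoff={params.cutoff}"
        )
    return out
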