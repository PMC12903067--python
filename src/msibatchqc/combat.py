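"""Parametric empirical-Bayes location/scale batch harmonization (ComBat).

The model for a standardized intensity of feature g, pixel j in batch i is

    z_ijg = gamma_ig + delta_ig * eps_ijg,   eps ~ N(0, 1)

with a normal prior on the per-batch location gamma_ig ~ N(gamma_bar_i,
tau_bar2_i) and an inverse-gamma prior on the squared scale delta2_ig ~
InvGamma(lambda_i, theta_i). Hyperparameters are estimated from the feature
ensemble by the method of moments, the posterior conditional means
(gamma*, delta*) are found by fixed-point iteration, and the correction

    x*_ijg = sigma_g * (z_ijg - gamma*_ig) / delta*_ig + alpha_g

removes both location and scale batch effects. Because gamma*/delta* are
constant within a (batch, feature) cell, the map is affine per cell and the
within-batch structure of every ion image is preserved exactly.

Fitting produces a reusable :class:`CombatModel`, so a correction learned on
one set of pixels can be applied to further data from the same batches.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datacube import Datacube
from .normalize import glog, glog_inverse

_EPS_LOG = 1e-9


@dataclass
class CombatModel:
    """Fitted empirical-Bayes batch model.

    All per-feature arrays have length G; per-batch/feature arrays are B x G
    in the order of ``batch_levels``.
    """

    batch_levels: np.ndarray  # (B,)
    n_per_batch: np.ndarray  # (B,)
    alpha: np.ndarray  # (G,) grand mean (batch-size weighted)
    sigma: np.ndarray  # (G,) pooled residual SD
    gamma_hat: np.ndarray  # (B, G) per-batch location estimates (standardized)
    delta2_hat: np.ndarray  # (B, G) per-batch variance estimates
    gamma_star: np.ndarray  # (B, G) EB-shrunk locations
    delta2_star: np.ndarray  # (B, G) EB-shrunk variances
    gamma_bar: np.ndarray  # (B,) location prior means
    tau_bar2: np.ndarray  # (B,) location prior variances
    lambda_prior: np.ndarray  # (B,) inverse-gamma shape
    theta_prior: np.ndarray  # (B,) inverse-gamma scale
    tol: float
    n_iter: np.ndarray  # (B,) iterations used per batch
    scale: str = "linear"  # linear | log | glog
    glog_lambda: float = 0.0
    provenance: list = field(default_factory=list)


def _transform_scale(x: np.ndarray, scale: str, glog_lambda: float) -> np.ndarray:
    if scale == "linear":
        return x
    if scale == "log":
        if np.any(x <= 0):
            raise ValueError("log scale requires strictly positive intensities")
        return np.log(x)
    if scale == "glog":
        return glog(x, glog_lambda)
    raise ValueError(f"unknown scale {scale!r}")


def _inverse_scale(y: np.ndarray, scale: str, glog_lambda: float) -> np.ndarray:
    if scale == "linear":
        return y
    if scale == "log":
        return np.exp(y)
    return glog_inverse(y, glog_lambda)


def combat_fit(
    cube_or_matrix: Datacube | np.ndarray,
    batch: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    scale: str = "linear",
    glog_lambda: float = 1e6,
) -> CombatModel:
    """Estimate the parametric empirical-Bayes batch model.

    Parameters
    ----------
    cube_or_matrix
        A :class:`Datacube` (batch labels taken from the cube unless given)
        or a raw pixels x features matrix.
    batch
        Per-pixel batch labels; required for a bare matrix.
    tol, max_iter
        Convergence tolerance (max relative parameter change) and iteration
        cap of the posterior fixed-point solve.
    scale
        ``linear`` fits intensities as-is; ``log`` / ``glog`` fit on the
        transformed scale (the normality assumption is usually more
        plausible there for MSI intensities) and :func:`combat_apply` maps
        back.

    No covariates are modelled: the design is batch dummies only.
    """
    if isinstance(cube_or_matrix, Datacube):
        x = cube_or_matrix.intensities
        if batch is None:
            batch = cube_or_matrix.batch
    else:
        x = np.asarray(cube_or_matrix, dtype=float)
        if batch is None:
            raise ValueError("batch labels required for a bare matrix")
    batch = np.asarray(batch)
    if x.shape[0] != batch.shape[0]:
        raise ValueError("batch labels must match pixel count")
    if x.shape[1] < 2:
        raise ValueError("empirical-Bayes pooling needs at least 2 features")
    levels, inverse = np.unique(batch, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least 2 batches")
    n_i = np.bincount(inverse)
    if np.any(n_i < 2):
        raise ValueError("every batch needs at least 2 pixels")
    n = x.shape[0]

    y = _transform_scale(x, scale, glog_lambda)

    # least-squares fit of the batch-dummy design: fitted values are batch
    # means; the grand mean alpha is the batch-size-weighted mean, which is
    # the estimate under the constraint sum_i n_i * gamma_i = 0
    batch_means = np.vstack([y[inverse == i].mean(axis=0) for i in range(levels.size)])
    alpha = (n_i[:, None] * batch_means).sum(axis=0) / n
    resid = y - batch_means[inverse]
    sigma2 = (resid**2).sum(axis=0) / n  # pooled residual variance (divide by N)
    if np.any(sigma2 <= 0):
        bad = int(np.sum(sigma2 <= 0))
        raise ValueError(f"{bad} features have zero pooled within-batch variance")
    sigma = np.sqrt(sigma2)

    z = (y - alpha) / sigma
    B, G = levels.size, x.shape[1]
    gamma_hat = np.empty((B, G))
    delta2_hat = np.empty((B, G))
    for i in range(B):
        zi = z[inverse == i]
        gamma_hat[i] = zi.mean(axis=0)
        delta2_hat[i] = zi.var(axis=0, ddof=1)

    # method-of-moments hyperpriors from the feature ensemble
    gamma_bar = gamma_hat.mean(axis=1)
    tau_bar2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    # floor the ensemble variance so a (near-)degenerate feature ensemble
    # yields a very tight prior instead of an indeterminate one
    s2 = np.maximum(delta2_hat.var(axis=1, ddof=1), 1e-12)
    lambda_prior = (2 * s2 + m**2) / s2
    theta_prior = (m * s2 + m**3) / s2

    gamma_star = gamma_hat.copy()
    delta2_star = delta2_hat.copy()
    n_iter = np.zeros(B, dtype=int)
    for i in range(B):
        zi = z[inverse == i]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        count = 0
        change = np.inf
        while change > tol and count < max_iter:
            g_new = (n_i[i] * tau_bar2[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                n_i[i] * tau_bar2[i] + d_old
            )
            ss = ((zi - g_new) ** 2).sum(axis=0)
            d_new = (theta_prior[i] + 0.5 * ss) / (n_i[i] / 2.0 + lambda_prior[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), _EPS_LOG)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), _EPS_LOG)),
            )
            g_old, d_old = g_new, d_new
            count += 1
        gamma_star[i] = g_old
        delta2_star[i] = d_old
        n_iter[i] = count
    if np.any(delta2_star <= 0):
        raise RuntimeError("non-positive posterior scale; data degenerate")

    prov = []
    if isinstance(cube_or_matrix, Datacube):
        prov = list(cube_or_matrix.provenance)
    return CombatModel(
        batch_levels=levels,
        n_per_batch=n_i,
        alpha=alpha,
        sigma=sigma,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau_bar2=tau_bar2,
        lambda_prior=lambda_prior,
        theta_prior=theta_prior,
        tol=tol,
        n_iter=n_iter,
        scale=scale,
        glog_lambda=glog_lambda,
        provenance=prov + [f"combat_fit:scale={scale}"],
    )


def combat_apply(
    cube_or_matrix: Datacube | np.ndarray,
    model: CombatModel,
    batch: np.ndarray | None = None,
) -> Datacube | np.ndarray:
    """Remove the fitted batch effects: affine map per (batch, feature).

    The input's batch labels must be a subset of the model's. Returns the
    same container type that was passed in.
    """
    is_cube = isinstance(cube_or_matrix, Datacube)
    if is_cube:
        x = cube_or_matrix.intensities
        if batch is None:
            batch = cube_or_matrix.batch
    else:
        x = np.asarray(cube_or_matrix, dtype=float)
        if batch is None:
            raise ValueError("batch labels required for a bare matrix")
    batch = np.asarray(batch)
    level_index = {b: i for i, b in enumerate(model.batch_levels)}
    unseen = set(np.unique(batch)) - set(level_index)
    if unseen:
        raise KeyError(f"batch labels not seen at fit time: {sorted(unseen)}")
    idx = np.array([level_index[b] for b in batch])

    y = _transform_scale(x, model.scale, model.glog_lambda)
    z = (y - model.alpha) / model.sigma
    delta_star = np.sqrt(model.delta2_star)
    z_adj = (z - model.gamma_star[idx]) / delta_star[idx]
    y_adj = z_adj * model.sigma + model.alpha
    out = _inverse_scale(y_adj, model.scale, model.glog_lambda)
    if is_cube:
        return cube_or_matrix.with_intensities(out, tag=f"combat_apply:scale={model.scale}")
    return out


def combat_correct(
    cube: Datacube,
    tol: float = 1e-4,
    max_iter: int = 100,
    scale: str = "linear",
    glog_lambda: float = 1e6,
) -> tuple[Datacube, CombatModel]:
    """One-shot fit-and-apply on a cube's own batch labels."""
    model = combat_fit(cube, tol=tol, max_iter=max_iter, scale=scale, glog_lambda=glog_lambda)
    return combat_apply(cube, model), model


def save_combat_model(model: CombatModel, path: str | Path) -> Path:
    """Serialize a fitted model (self-describing, versioned pickle)."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"format": "msibatchqc.combat", "version": 1, "model": model}, fh)
    return path


def load_combat_model(path: str | Path) -> CombatModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != "msibatchqc.combat":
        raise ValueError(f"{path} is not a saved ComBat model")
    return payload["model"]
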