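"""QC-trained per-feature random-forest correction with model transfer (SERRF).

The method assumes every batch carries technical replicates of a homogeneous
QC material. For each feature g it learns, on QC pixels only, how the
feature's within-batch-standardized intensity co-varies with its most
correlated companion features; the trained forest then predicts a per-pixel
systematic-error level p_jg, and each intensity is rescaled by

    x*_jg = x_jg * m_g / p_jg

where m_g is the feature's QC median. Per-batch QC scaling constants remove
between-batch location/scale differences; the forest captures correlated
within-batch structure such as drift. Because fitting touches only QC
pixels, a trained model transfers to heterogeneous subject tissue whose own
intensities were never seen during training — training directly on
heterogeneous samples would violate the homogeneity assumption.

Half of the QC pixels train the forests; the other half is held out for
evaluating the correction (default split 50/50).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .datacube import Datacube

FLOOR_QUANTILE = 0.01  # predictions below this quantile are floored


@dataclass
class SerrfModel:
    """Fitted SERRF model: per-feature forests plus scaling bookkeeping."""

    batch_levels: np.ndarray  # (B,)
    qc_mean: np.ndarray  # (B, G) per-batch QC-train means (raw scale)
    qc_sd: np.ndarray  # (B, G) per-batch QC-train SDs (raw scale)
    qc_median: np.ndarray  # (G,) m_g, zeros excluded
    predictors: list  # per-feature arrays of predictor feature indices
    regressors: list  # per-feature fitted RandomForestRegressor
    k: int
    n_trees: int
    split_frac: float
    seed: int
    train_index: np.ndarray  # QC pixel indices used for training
    test_index: np.ndarray  # held-out QC pixel indices
    uses_timestamps: bool = False
    version: int = 1
    provenance: list = field(default_factory=list)


def _batch_index(batch: np.ndarray, levels: np.ndarray) -> np.ndarray:
    lookup = {b: i for i, b in enumerate(levels)}
    unseen = set(np.unique(batch)) - set(lookup)
    if unseen:
        raise KeyError(f"batch labels not seen at fit time: {sorted(unseen)}")
    return np.array([lookup[b] for b in batch])


def serrf_fit(
    qc_cube: Datacube | np.ndarray,
    batch: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
    k: int = 10,
    n_trees: int = 500,
    split_frac: float = 0.5,
    seed: int = 0,
    use_timestamps: bool = False,
) -> SerrfModel:
    """Train per-feature forests on (homogeneous) QC pixels.

    Parameters
    ----------
    qc_cube
        QC pixels only — pass ``cube.select(cube.tissue_mask("qc_homogeneous"))``
        for a full study cube. Heterogeneous tissue must not be included.
    k
        Number of correlated predictor features per target (the target
        itself is never its own predictor).
    n_trees, seed
        Forest size and the seed controlling both the train/test split and
        every forest.
    split_frac
        Fraction of QC pixels used for training; the rest is the held-out
        evaluation half recorded on the model.
    use_timestamps
        Append the acquisition time as an extra predictor column.
    """
    if isinstance(qc_cube, Datacube):
        x = qc_cube.intensities
        batch = qc_cube.batch if batch is None else np.asarray(batch)
        time_s = qc_cube.time_s if time_s is None else np.asarray(time_s)
    else:
        x = np.asarray(qc_cube, dtype=float)
        if batch is None:
            raise ValueError("batch labels required for a bare matrix")
        batch = np.asarray(batch)
        if time_s is None:
            time_s = np.zeros(x.shape[0])
    n, g_total = x.shape
    if k >= g_total:
        raise ValueError(f"k={k} must be smaller than the number of features {g_total}")
    if not 0 < split_frac < 1:
        raise ValueError("split_frac must be in (0, 1)")
    levels = np.unique(batch)
    idx_all = _batch_index(batch, levels)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(int(round(split_frac * n)), 1)
    train_index = np.sort(perm[:n_train])
    test_index = np.sort(perm[n_train:])

    bt = idx_all[train_index]
    for i, b in enumerate(levels):
        if (bt == i).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 QC training pixels")

    xt = x[train_index]
    B = levels.size
    qc_mean = np.empty((B, g_total))
    qc_sd = np.empty((B, g_total))
    zt = np.empty_like(xt)
    for i in range(B):
        rows = bt == i
        qc_mean[i] = xt[rows].mean(axis=0)
        sd = xt[rows].std(axis=0, ddof=1)
        qc_sd[i] = np.where(sd > 0, sd, 1.0)
        zt[rows] = (xt[rows] - qc_mean[i]) / qc_sd[i]

    # QC median per feature, zeros excluded; features observed only as zero
    # cannot be corrected multiplicatively and keep m_g = 0
    qc_median = np.empty(g_total)
    for g in range(g_total):
        vals = xt[:, g][xt[:, g] > 0]
        qc_median[g] = np.median(vals) if vals.size else 0.0

    # correlation ranking on the scaled training matrix
    zc = zt - zt.mean(axis=0)
    denom = np.sqrt((zc**2).sum(axis=0))
    denom = np.where(denom > 0, denom, 1.0)
    zu = zc / denom
    corr = zu.T @ zu  # (G, G)

    feature_cols = lambda z_rows, preds, times: (
        np.column_stack([z_rows[:, preds], times[:, None]]) if use_timestamps else z_rows[:, preds]
    )
    tt = np.asarray(time_s, dtype=float)[train_index]

    predictors: list[np.ndarray] = []
    regressors: list[RandomForestRegressor] = []
    seed_seq = np.random.SeedSequence(seed)
    feature_seeds = seed_seq.generate_state(g_total) % (2**31 - 1)
    for g in range(g_total):
        score = np.abs(corr[g]).copy()
        score[g] = -np.inf  # a feature never predicts itself
        preds = np.sort(np.argsort(-score, kind="stable")[:k])
        rf = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(feature_seeds[g]), n_jobs=1
        )
        rf.fit(feature_cols(zt, preds, tt), zt[:, g])
        predictors.append(preds)
        regressors.append(rf)

    prov = list(qc_cube.provenance) if isinstance(qc_cube, Datacube) else []
    return SerrfModel(
        batch_levels=levels,
        qc_mean=qc_mean,
        qc_sd=qc_sd,
        qc_median=qc_median,
        predictors=predictors,
        regressors=regressors,
        k=k,
        n_trees=n_trees,
        split_frac=split_frac,
        seed=seed,
        train_index=train_index,
        test_index=test_index,
        uses_timestamps=use_timestamps,
        provenance=prov + [f"serrf_fit:k={k},n_trees={n_trees},split={split_frac}"],
    )


def serrf_predict_systematic_error(
    x: np.ndarray, batch: np.ndarray, model: SerrfModel, time_s: np.ndarray | None = None
) -> np.ndarray:
    """Raw-scale predicted systematic level p_jg for every pixel/feature."""
    idx = _batch_index(np.asarray(batch), model.batch_levels)
    z = (x - model.qc_mean[idx]) / model.qc_sd[idx]
    n, g_total = x.shape
    t = np.zeros(n) if time_s is None else np.asarray(time_s, dtype=float)
    p = np.empty_like(x)
    for g in range(g_total):
        cols = z[:, model.predictors[g]]
        if model.uses_timestamps:
            cols = np.column_stack([cols, t[:, None]])
        yhat = model.regressors[g].predict(cols)
        p[:, g] = yhat * model.qc_sd[idx, g] + model.qc_mean[idx, g]
    return p


def serrf_apply(
    cube_or_matrix: Datacube | np.ndarray,
    model: SerrfModel,
    batch: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
) -> Datacube | np.ndarray:
    """Correct a cube by scaling with the predicted systematic error.

    ``x* = x * m_g / p``, with per-feature predictions floored at their 1%
    quantile (and at a small positive fraction of m_g) so occasional tiny or
    negative predictions cannot blow the ratio up. Pixels with zero raw
    intensity stay zero; features whose QC median is zero are passed through
    unchanged.
    """
    is_cube = isinstance(cube_or_matrix, Datacube)
    if is_cube:
        x = cube_or_matrix.intensities
        batch = cube_or_matrix.batch if batch is None else np.asarray(batch)
        time_s = cube_or_matrix.time_s if time_s is None else np.asarray(time_s)
    else:
        x = np.asarray(cube_or_matrix, dtype=float)
        if batch is None:
            raise ValueError("batch labels required for a bare matrix")
        batch = np.asarray(batch)
    p = serrf_predict_systematic_error(x, batch, model, time_s)
    floor = np.quantile(p, FLOOR_QUANTILE, axis=0)
    floor = np.maximum(floor, 1e-6 * np.maximum(model.qc_median, 1e-30))
    p = np.maximum(p, floor)
    m = model.qc_median
    correctable = m > 0
    out = x.copy()
    out[:, correctable] = x[:, correctable] * m[correctable] / p[:, correctable]
    if is_cube:
        return cube_or_matrix.with_intensities(out, tag="serrf_apply")
    return out


def save_serrf_model(model: SerrfModel, path: str | Path) -> Path:
    """Serialize the trained model so subject data can be corrected later."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"format": "msibatchqc.serrf", "version": model.version, "model": model}, fh)
    return path


def load_serrf_model(path: str | Path) -> SerrfModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != "msibatchqc.serrf":
        raise ValueError(f"{path} is not a saved SERRF model")
    return payload["model"]
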