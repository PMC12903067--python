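"""Pixel-by-pixel evaluation of batch effects and of correction quality.

Univariate views: per-(feature, batch) distribution moments (the numbers
behind violin plots), the between-batch variance of each feature, and
grand-mean fidelity (log-log regression of corrected vs raw feature means,
which flags intensity-scale collapse). Multivariate views: PCA variance
explained with a batch silhouette on the first two scores, cosine k-means
label images, and a 3-D t-SNE rendered as RGB. Spatial preservation
correlates raw and corrected single-ion images within each section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from ._cluster import spherical_kmeans
from .datacube import Datacube


def batch_moments(cube: Datacube) -> pd.DataFrame:
    """Per-(feature, batch) medians, quartiles, IQR, mean, variance, count.

    Percentiles use linear interpolation (type 7). These are the summary
    statistics a violin/box plot of per-batch ion images draws.
    """
    rows = []
    for b in cube.batches:
        sub = cube.intensities[cube.batch == b]
        if sub.shape[0] == 0:
            raise ValueError(f"batch {b} is empty")
        q25, q50, q75 = np.percentile(sub, [25, 50, 75], axis=0)
        for g in range(cube.n_features):
            rows.append(
                {
                    "feature": g,
                    "mz": cube.mz[g],
                    "batch": int(b),
                    "median": q50[g],
                    "q25": q25[g],
                    "q75": q75[g],
                    "iqr": q75[g] - q25[g],
                    "mean": sub[:, g].mean(),
                    "variance": sub[:, g].var(),
                    "count": sub.shape[0],
                }
            )
    return pd.DataFrame(rows)


def between_batch_variance(cube_or_matrix: Datacube | np.ndarray, batch: np.ndarray | None = None, weighted: bool = False) -> np.ndarray:
    """Per-feature variance of the batch means (population variance).

    The scalar residual-batch-effect measure: zero when all batch means
    agree. With ``weighted=True`` batch means are weighted by batch size.
    """
    if isinstance(cube_or_matrix, Datacube):
        x = cube_or_matrix.intensities
        batch = cube_or_matrix.batch if batch is None else np.asarray(batch)
    else:
        x = np.asarray(cube_or_matrix, dtype=float)
        if batch is None:
            raise ValueError("batch labels required for a bare matrix")
        batch = np.asarray(batch)
    levels = np.unique(batch)
    if levels.size < 2:
        raise ValueError("need at least 2 batches")
    means = np.vstack([x[batch == b].mean(axis=0) for b in levels])
    if weighted:
        w = np.array([(batch == b).sum() for b in levels], dtype=float)
        w /= w.sum()
        center = w @ means
        return w @ (means - center) ** 2
    return means.var(axis=0)


@dataclass
class GrandMeanFidelity:
    """Log-log agreement between corrected and raw per-feature grand means."""

    raw_means: np.ndarray
    corrected_means: np.ndarray
    slope: float
    intercept: float
    r2: float
    n_used: int


def grand_mean_fidelity(raw: Datacube | np.ndarray, corrected: Datacube | np.ndarray) -> GrandMeanFidelity:
    """Regress ln(corrected grand mean) on ln(raw grand mean) over features.

    Slope 1 with high R^2 means the correction leaves the intensity scale
    intact; slope near 0 flags collapse of all features onto one level
    (intensities of 1e6 being mapped to ~1e3 is the classic symptom).
    """
    xr = raw.intensities if isinstance(raw, Datacube) else np.asarray(raw, dtype=float)
    xc = corrected.intensities if isinstance(corrected, Datacube) else np.asarray(corrected, dtype=float)
    if xr.shape != xc.shape:
        raise ValueError("raw and corrected must have the same shape")
    mr = xr.mean(axis=0)
    mc = xc.mean(axis=0)
    ok = (mr > 0) & (mc > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 features with positive grand means")
    lr = stats.linregress(np.log(mr[ok]), np.log(mc[ok]))
    return GrandMeanFidelity(
        raw_means=mr,
        corrected_means=mc,
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r2=float(lr.rvalue**2),
        n_used=int(ok.sum()),
    )


@dataclass
class PcaBatchReport:
    variance_explained: np.ndarray  # fraction per PC, non-increasing
    scores: np.ndarray  # (n_pixels, n_pc)
    batch_silhouette: float  # on first two scores; ~0 = batches mixed


def pca_batch_report(cube_or_matrix: Datacube | np.ndarray, batch: np.ndarray | None = None, n_pc: int = 10) -> PcaBatchReport:
    """PCA (mean-centred, no prior scaling) plus a batch-mixing silhouette.

    The silhouette of pixels grouped by batch label on the first two PC
    scores (Euclidean) quantifies the separation between batch point
    clouds: near 0 when batches overlap, toward 1 when they separate.
    """
    if isinstance(cube_or_matrix, Datacube):
        x = cube_or_matrix.intensities
        batch = cube_or_matrix.batch if batch is None else np.asarray(batch)
    else:
        x = np.asarray(cube_or_matrix, dtype=float)
        if batch is None:
            raise ValueError("batch labels required for a bare matrix")
        batch = np.asarray(batch)
    n_pc = min(n_pc, x.shape[0] - 1, x.shape[1])
    if x.shape[0] <= n_pc:
        raise ValueError("need more pixels than components")
    if np.allclose(x, x[0]):
        raise ValueError("constant data has no principal components")
    pca = PCA(n_components=n_pc)
    scores = pca.fit_transform(x)
    if np.unique(batch).size > 1:
        sil = float(silhouette_score(scores[:, :2], batch, metric="euclidean"))
    else:
        sil = 0.0
    return PcaBatchReport(
        variance_explained=pca.explained_variance_ratio_,
        scores=scores,
        batch_silhouette=sil,
    )


def kmeans_image(
    cube: Datacube, k: int, seed: int | None = 0, replicates: int = 3
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Cosine k-means pixel labels plus a per-section label image.

    Returns ``(labels, {section_id: 2-D label image})``; unvisited grid
    positions are NaN in the images.
    """
    labels, _ = spherical_kmeans(cube.intensities, k=k, seed=seed, replicates=replicates)
    images = {str(sec): cube.section_image(sec, labels.astype(float)) for sec in cube.sections}
    return labels, images


def tsne_rgb(
    cube: Datacube, seed: int | None = 0, perplexity: float | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """3-D t-SNE (exact, cosine metric) min-max scaled to RGB channels.

    Returns ``(n x 3 colors in [0, 1], {section_id: H x W x 3 image})``.
    """
    n = cube.n_pixels
    if n < 10:
        raise ValueError("need at least 10 pixels")
    x = cube.intensities
    if np.allclose(x, x[0]):
        raise ValueError("constant data cannot be embedded")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    emb = TSNE(
        n_components=3,
        metric="cosine",
        method="exact",
        random_state=seed,
        perplexity=perplexity,
        init="random",
    ).fit_transform(x)
    lo, hi = emb.min(axis=0), emb.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    rgb = (emb - lo) / span
    images = {}
    for sec in cube.sections:
        chans = [cube.section_image(sec, rgb[:, c]) for c in range(3)]
        images[str(sec)] = np.stack(chans, axis=-1)
    return rgb, images


@dataclass
class SpatialPreservation:
    per_feature: pd.DataFrame  # section, feature, pearson_r (NaN = excluded)
    per_section_median: dict  # section -> median r over usable features
    n_excluded: int
    collapsed: bool  # True when no feature had a usable correlation


def spatial_preservation(
    raw: Datacube, corrected: Datacube, sections: list | None = None
) -> SpatialPreservation:
    """Pearson correlation of raw vs corrected single-ion images per section.

    Features constant in either image are excluded (counted); if every
    feature of every section is excluded the preservation score is reported
    as 0 with ``collapsed=True`` — the signature of a correction that wiped
    the spatial structure.
    """
    if raw.intensities.shape != corrected.intensities.shape:
        raise ValueError("raw and corrected must share pixels and features")
    if sections is None:
        sections = list(raw.sections)
    rows = []
    n_excluded = 0
    medians = {}
    for sec in sections:
        m = raw.section_id == sec
        a = raw.intensities[m]
        b = corrected.intensities[m]
        astd = a.std(axis=0)
        bstd = b.std(axis=0)
        ok = (astd > 0) & (bstd > 0)
        n_excluded += int((~ok).sum())
        r = np.full(raw.n_features, np.nan)
        if ok.any():
            ac = a[:, ok] - a[:, ok].mean(axis=0)
            bc = b[:, ok] - b[:, ok].mean(axis=0)
            r[ok] = (ac * bc).sum(axis=0) / (
                np.sqrt((ac**2).sum(axis=0)) * np.sqrt((bc**2).sum(axis=0))
            )
        for g in range(raw.n_features):
            rows.append({"section": str(sec), "feature": g, "pearson_r": r[g]})
        medians[str(sec)] = float(np.nanmedian(r)) if ok.any() else 0.0
    collapsed = all(np.isnan(row["pearson_r"]) for row in rows)
    if collapsed:
        medians = {k: 0.0 for k in medians}
    return SpatialPreservation(
        per_feature=pd.DataFrame(rows),
        per_section_median=medians,
        n_excluded=n_excluded,
        collapsed=collapsed,
    )


def batch_mean_correlation(cube: Datacube) -> np.ndarray:
    """Correlation matrix of per-feature batch-mean profiles (optional extra).

    Rows of the B x G batch-mean matrix of the z-standardized cube are
    correlated feature-against-feature. A non-canonical diagnostic: ions
    sharing a batch-effect fingerprint correlate strongly here.
    """
    levels = np.unique(cube.batch)
    if levels.size < 2:
        raise ValueError("need at least 2 batches")
    x = cube.intensities
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd
    bm = np.vstack([z[cube.batch == b].mean(axis=0) for b in levels])  # (B, G)
    return np.corrcoef(bm.T)


@dataclass
class EvaluationReport:
    """Bundle of the quantitative evaluation outputs for one correction."""

    between_batch_variance_raw: np.ndarray
    between_batch_variance_corrected: np.ndarray
    fidelity: GrandMeanFidelity
    pca_raw: PcaBatchReport
    pca_corrected: PcaBatchReport
    preservation: SpatialPreservation
    moments_raw: pd.DataFrame = field(repr=False, default=None)
    moments_corrected: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> dict:
        bbv_raw = float(np.median(self.between_batch_variance_raw))
        bbv_cor = float(np.median(self.between_batch_variance_corrected))
        ratios = self.between_batch_variance_corrected / np.where(
            self.between_batch_variance_raw > 0, self.between_batch_variance_raw, np.nan
        )
        return {
            "median_between_batch_variance_raw": bbv_raw,
            "median_between_batch_variance_corrected": bbv_cor,
            "median_between_batch_variance_ratio": float(np.nanmedian(ratios)),
            "grand_mean_slope": self.fidelity.slope,
            "grand_mean_r2": self.fidelity.r2,
            "pc1_variance_explained_raw": float(self.pca_raw.variance_explained[0]),
            "pc1_variance_explained_corrected": float(self.pca_corrected.variance_explained[0]),
            "batch_silhouette_raw": self.pca_raw.batch_silhouette,
            "batch_silhouette_corrected": self.pca_corrected.batch_silhouette,
            "spatial_preservation_median": self.preservation.per_section_median,
            "spatial_preservation_collapsed": self.preservation.collapsed,
        }


def evaluate_correction(raw: Datacube, corrected: Datacube, n_pc: int = 10) -> EvaluationReport:
    """Run the full quantitative comparison of a corrected cube vs its raw cube."""
    return EvaluationReport(
        between_batch_variance_raw=between_batch_variance(raw),
        between_batch_variance_corrected=between_batch_variance(corrected),
        fidelity=grand_mean_fidelity(raw, corrected),
        pca_raw=pca_batch_report(raw, n_pc=n_pc),
        pca_corrected=pca_batch_report(corrected, n_pc=n_pc),
        preservation=spatial_preservation(raw, corrected),
        moments_raw=batch_moments(raw),
        moments_corrected=batch_moments(corrected),
    )


def write_report(report: EvaluationReport, directory: str | Path, plots: bool = True) -> Path:
    """Emit an evaluation report as JSON + TSV tables (+ PNG panels).

    Percentile rule stated in the header: linear interpolation (type 7).
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    summary = {"percentile_rule": "linear interpolation (type 7)"}
    summary.update(report.summary())
    (d / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    report.moments_raw.to_csv(d / "batch_moments_raw.tsv", sep="\t", index=False)
    report.moments_corrected.to_csv(d / "batch_moments_corrected.tsv", sep="\t", index=False)
    report.preservation.per_feature.to_csv(d / "spatial_preservation.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "between_batch_variance_raw": report.between_batch_variance_raw,
            "between_batch_variance_corrected": report.between_batch_variance_corrected,
            "grand_mean_raw": report.fidelity.raw_means,
            "grand_mean_corrected": report.fidelity.corrected_means,
        }
    ).to_csv(d / "per_feature_metrics.tsv", sep="\t", index=False)
    if plots:
        _plot_panels(report, d)
    return d


def _plot_panels(report: EvaluationReport, d: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    f = report.fidelity
    ok = (f.raw_means > 0) & (f.corrected_means > 0)
    axes[0].loglog(f.raw_means[ok], f.corrected_means[ok], ".", alpha=0.6)
    lims = [f.raw_means[ok].min(), f.raw_means[ok].max()]
    axes[0].loglog(lims, lims, "k--", lw=1)
    axes[0].set_xlabel("raw grand mean")
    axes[0].set_ylabel("corrected grand mean")
    axes[0].set_title(f"grand-mean fidelity (slope {f.slope:.2f})")
    axes[1].loglog(
        np.maximum(report.between_batch_variance_raw, 1e-300),
        np.maximum(report.between_batch_variance_corrected, 1e-300),
        ".",
        alpha=0.6,
    )
    axes[1].set_xlabel("raw between-batch variance")
    axes[1].set_ylabel("corrected between-batch variance")
    axes[1].set_title("between-batch variance")
    fig.tight_layout()
    fig.savefig(d / "panels.png", dpi=120)
    plt.close(fig)


def violin_data(moments: pd.DataFrame, feature: int) -> pd.DataFrame:
    """Slice of the moments table for one feature, ordered by batch —
    the numbers a per-batch violin plot draws."""
    sub = moments[moments["feature"] == feature].sort_values("batch")
    return sub.reset_index(drop=True)
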