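"""Synthetic multi-slide MSI study generator with recorded ground truth.

The generator emulates the phenomenology of a multi-slide, multi-day MSI
study: every slide (= batch) carries a homogeneous QC section and a
heterogeneous QC tissue section; each ion's per-batch image distribution
shifts in both location (median) and spread (IQR) from batch to batch, the
shift manifesting differently for different ions; and intensities drift
smoothly with acquisition time within a batch.

The intensity model is multiplicative (log-normal):

    x_jg = exp( mu_g + ln f_g,r(j) + ln a_b(j),g + d_b(j) * t~_j + eps_jg )

with mu_g the ion's base log intensity, f_gr a per-region fold for affected
ions in heterogeneous sections (1 elsewhere), a_bg = exp(eta_b + zeta_bg)
the per-batch location factor combining a shared slide-level shift eta_b
with an ion-specific shift zeta_bg, d_b a per-batch drift slope acting on
the within-batch normalized time t~ in [0, 1], and eps ~ N(0, s_bg) noise
whose SD itself varies by batch (the IQR shifts). All latent factors are
recorded in a :class:`GroundTruth` so correctors can be scored against what
was actually planted.

Defaults mirror a 10-slide study at desk scale: B = 10 batches, one
homogeneous + one heterogeneous QC section per batch on 40 x 40 grids,
G = 100 ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datacube import Datacube
from .evaluate import between_batch_variance


@dataclass
class SynthConfig:
    """Study design and effect sizes for :func:`simulate_study`.

    All SDs are on the natural-log scale. ``region_frac`` is the fraction of
    ions that carry region structure in heterogeneous sections;
    ``batch_loc_sd_shared`` / ``batch_loc_sd_ion`` are the SDs of the shared
    (eta) and ion-specific (zeta) components of the log batch-location
    factor; ``batch_scale_sd`` jitters the per-batch noise SD (spread
    shifts); ``drift_sd`` is the SD of the per-batch drift slope;
    ``noise_sd`` the baseline multiplicative noise. ``pixel_dt_s`` seconds
    between consecutive pixels; ``batch_gap_s`` dead time between batches.
    """

    n_batches: int = 10
    n_qc_hom_sections: int = 1
    n_qc_het_sections: int = 1
    n_sample_sections: int = 0
    grid_width: int = 40
    grid_height: int = 40
    n_features: int = 100
    base_log_mean: float = 5.0
    base_log_sd: float = 1.0
    region_frac: float = 0.5
    region_fold_sd: float = 0.5
    batch_loc_sd_shared: float = 0.3
    batch_loc_sd_ion: float = 0.3
    batch_scale_sd: float = 0.3
    drift_sd: float = 0.1
    noise_sd: float = 0.2
    pixel_dt_s: float = 1.0
    batch_gap_s: float = 3600.0
    additive: bool = False

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.grid_width < 2 or self.grid_height < 2:
            raise ValueError("grid must be at least 2 x 2")
        for name in (
            "base_log_sd",
            "region_fold_sd",
            "batch_loc_sd_shared",
            "batch_loc_sd_ion",
            "batch_scale_sd",
            "drift_sd",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.region_frac <= 1:
            raise ValueError("region_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """Latent factors planted by the simulator (recovery-test oracle)."""

    mu: np.ndarray  # (G,) base log intensity
    a_bg: np.ndarray  # (B, G) batch location factors, > 0
    s_bg: np.ndarray  # (B, G) noise SDs, > 0
    d_b: np.ndarray  # (B,) drift slopes
    region_ions: np.ndarray  # bool (G,) ions carrying region structure
    region_fold: dict  # section_id -> (n_regions, G) fold matrix
    region_maps: dict  # section_id -> (H, W) int region map
    expected: np.ndarray  # (n_pixels, G) noiseless expected intensity
    config: SynthConfig = field(repr=False, default=None)


def _section_pixels(cfg: SynthConfig):
    w, h = cfg.grid_width, cfg.grid_height
    ys, xs = np.divmod(np.arange(w * h), w)  # raster order: row-major
    return xs, ys


def simulate_study(cfg: SynthConfig | None = None, seed: int = 0) -> tuple[Datacube, GroundTruth]:
    """Draw one synthetic study; same config and seed give a byte-identical cube."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    B, G = cfg.n_batches, cfg.n_features

    mu = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=G)
    eta = rng.normal(0.0, cfg.batch_loc_sd_shared, size=B)
    zeta = rng.normal(0.0, cfg.batch_loc_sd_ion, size=(B, G))
    a_bg = np.exp(eta[:, None] + zeta)
    s_bg = cfg.noise_sd * np.exp(rng.normal(0.0, cfg.batch_scale_sd, size=(B, G)))
    d_b = rng.normal(0.0, cfg.drift_sd, size=B)
    region_ions = rng.random(G) < cfg.region_frac

    xs, ys = _section_pixels(cfg)
    npix_sec = xs.size
    tissues_per_batch = (
        ["qc_homogeneous"] * cfg.n_qc_hom_sections
        + ["qc_heterogeneous"] * cfg.n_qc_het_sections
        + ["sample"] * cfg.n_sample_sections
    )

    blocks = []
    truth_folds: dict[str, np.ndarray] = {}
    truth_maps: dict[str, np.ndarray] = {}
    meta = {k: [] for k in ("x", "y", "section", "slide", "batch", "time", "tissue")}
    t_cursor = 0.0
    batch_spans = []
    for b in range(B):
        t_start = t_cursor
        for s_idx, tissue in enumerate(tissues_per_batch):
            sec_id = f"b{b + 1}_s{s_idx + 1}_{tissue}"
            log_x = np.tile(mu, (npix_sec, 1))
            if tissue != "qc_homogeneous":
                # two contiguous regions: vertical split at a random column
                split = int(round(cfg.grid_width * rng.uniform(0.35, 0.65)))
                region = (xs >= split).astype(int)
                folds = np.ones((2, G))
                folds[1, region_ions] = np.exp(
                    rng.normal(0.0, cfg.region_fold_sd, size=int(region_ions.sum()))
                )
                log_x += np.log(folds)[region]
                truth_folds[sec_id] = folds
                truth_maps[sec_id] = region.reshape(cfg.grid_height, cfg.grid_width)
            else:
                truth_folds[sec_id] = np.ones((1, G))
                truth_maps[sec_id] = np.zeros((cfg.grid_height, cfg.grid_width), dtype=int)
            blocks.append((b, sec_id, tissue, log_x))
            times = t_cursor + cfg.pixel_dt_s * np.arange(npix_sec)
            t_cursor = times[-1] + cfg.pixel_dt_s
            meta["x"].append(xs)
            meta["y"].append(ys)
            meta["section"].append(np.full(npix_sec, sec_id, dtype=object))
            meta["slide"].append(np.full(npix_sec, f"slide{b + 1}", dtype=object))
            meta["batch"].append(np.full(npix_sec, b + 1, dtype=int))
            meta["time"].append(times)
            meta["tissue"].append(np.full(npix_sec, tissue, dtype=object))
        batch_spans.append((t_start, t_cursor - cfg.pixel_dt_s))
        t_cursor += cfg.batch_gap_s

    time_s = np.concatenate(meta["time"])
    batch = np.concatenate(meta["batch"])
    n_total = time_s.size

    log_expected = np.empty((n_total, G))
    row = 0
    for (b, sec_id, tissue, log_x) in blocks:
        npx = log_x.shape[0]
        t0, t1 = batch_spans[b]
        tnorm = (time_s[row : row + npx] - t0) / max(t1 - t0, 1.0)
        log_expected[row : row + npx] = (
            log_x + np.log(a_bg[b]) + d_b[b] * tnorm[:, None]
        )
        row += npx
    eps = rng.normal(0.0, 1.0, size=(n_total, G)) * s_bg[batch - 1]
    if cfg.additive:
        expected = np.exp(log_expected)
        x = np.maximum(expected + expected * eps, 0.0)
    else:
        x = np.exp(log_expected + eps)
        expected = np.exp(log_expected)

    cube = Datacube(
        intensities=x,
        mz=100.0 + 0.5 * np.arange(G),
        pixel_x=np.concatenate(meta["x"]),
        pixel_y=np.concatenate(meta["y"]),
        section_id=np.concatenate(meta["section"]),
        slide_id=np.concatenate(meta["slide"]),
        batch=batch,
        time_s=time_s,
        tissue=np.concatenate(meta["tissue"]),
        provenance=[f"simulate_study:seed={seed}"],
    )
    truth = GroundTruth(
        mu=mu,
        a_bg=a_bg,
        s_bg=s_bg,
        d_b=d_b,
        region_ions=region_ions,
        region_fold=truth_folds,
        region_maps=truth_maps,
        expected=expected,
        config=cfg,
    )
    return cube, truth


def score_recovery(
    corrected: Datacube,
    truth: GroundTruth,
    raw: Datacube,
    location_estimates: np.ndarray | None = None,
) -> dict:
    """Score a correction against the simulator's planted factors.

    Residual batch effect: per-feature between-batch variance of the
    corrected homogeneous-QC pixels relative to the raw cube's (median
    ratio reported). Location recovery: when a corrector exposes per-batch
    location estimates (e.g. the empirical-Bayes gamma*, passed as a B x G
    array in the cube's batch-level order), their Pearson correlation with
    the centred planted log location factors ln a_bg.
    """
    if corrected.intensities.shape != raw.intensities.shape:
        raise ValueError("corrected and raw cubes must share shape")
    qc = corrected.tissue_mask("qc_homogeneous")
    if not qc.any():
        raise ValueError("no homogeneous QC pixels to score")
    bbv_raw = between_batch_variance(raw.intensities[qc], raw.batch[qc])
    bbv_cor = between_batch_variance(corrected.intensities[qc], corrected.batch[qc])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(bbv_raw > 0, bbv_cor / bbv_raw, np.nan)
    out = {
        "between_batch_variance_ratio": ratios,
        "median_ratio": float(np.nanmedian(ratios)),
    }
    if location_estimates is not None:
        est = np.asarray(location_estimates, dtype=float)
        log_a = np.log(truth.a_bg)
        if est.shape != log_a.shape:
            raise ValueError(f"location estimates shape {est.shape} != {log_a.shape}")
        # centre planted factors per feature by batch-size weights (the
        # estimable quantity under the sum-to-zero constraint)
        n_i = np.array([(raw.batch == b).sum() for b in np.unique(raw.batch)], dtype=float)
        w = n_i / n_i.sum()
        log_a_centred = log_a - (w[:, None] * log_a).sum(axis=0)
        r = np.corrcoef(est.ravel(), log_a_centred.ravel())[0, 1]
        out["location_recovery_r"] = float(r)
    return out
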