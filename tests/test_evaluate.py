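"""Evaluation metrics: moments, between-batch variance, fidelity, MVA views."""

import numpy as np
import pytest

from msibatchqc.datacube import Datacube
from msibatchqc.evaluate import (
    batch_mean_correlation,
    batch_moments,
    between_batch_variance,
    evaluate_correction,
    grand_mean_fidelity,
    kmeans_image,
    pca_batch_report,
    spatial_preservation,
    tsne_rgb,
    write_report,
)

from conftest import make_cube


def labelled_cube(values_by_batch, n_features=1):
    """Cube with one section per batch holding the given per-pixel values."""
    blocks, batches, secs = [], [], []
    for b, vals in enumerate(values_by_batch, start=1):
        v = np.asarray(vals, dtype=float)[:, None] * np.ones((1, n_features))
        blocks.append(v)
        batches.append(np.full(len(vals), b))
        secs.append(np.full(len(vals), f"s{b}", dtype=object))
    x = np.vstack(blocks)
    n = x.shape[0]
    return Datacube(
        intensities=x,
        mz=100.0 + np.arange(n_features),
        pixel_x=np.concatenate([np.arange(len(v)) for v in values_by_batch]),
        pixel_y=np.zeros(n, int),
        section_id=np.concatenate(secs),
        slide_id=np.concatenate(secs),
        batch=np.concatenate(batches),
        time_s=np.arange(n, dtype=float),
        tissue=np.full(n, "sample", dtype=object),
    )


class TestBatchMoments:
    def test_hand_computed_percentiles(self):
        cube = labelled_cube([[1, 2, 3, 4]])
        row = batch_moments(cube).iloc[0]
        # linear-interpolation (type 7) percentiles of [1,2,3,4]
        assert row["median"] == 2.5
        assert row["q25"] == 1.75
        assert row["q75"] == 3.25
        assert row["iqr"] == 1.5
        assert row["count"] == 4

    def test_identical_batches_give_identical_rows(self):
        cube = labelled_cube([[1, 5, 9], [1, 5, 9]])
        tab = batch_moments(cube)
        cols = ["median", "q25", "q75", "iqr", "mean", "variance"]
        assert tab[tab.batch == 1][cols].values == pytest.approx(
            tab[tab.batch == 2][cols].values
        )

    def test_shifting_one_batch_shifts_only_its_location_rows(self):
        base = labelled_cube([[1, 2, 3], [4, 5, 6]])
        shifted = base.copy()
        shifted.intensities[base.batch == 2] += 10.0
        t0, t1 = batch_moments(base), batch_moments(shifted)
        assert t1[t1.batch == 1].equals(t0[t0.batch == 1])
        assert t1[t1.batch == 2]["median"].iloc[0] == t0[t0.batch == 2]["median"].iloc[0] + 10
        assert t1[t1.batch == 2]["iqr"].iloc[0] == t0[t0.batch == 2]["iqr"].iloc[0]


class TestBetweenBatchVariance:
    def test_equal_means_give_zero(self):
        cube = labelled_cube([[1, 3], [0, 4]])  # both means 2
        assert between_batch_variance(cube)[0] == 0.0

    def test_population_variance_of_batch_means(self):
        cube = labelled_cube([[0, 0], [2, 2]])  # means 0 and 2
        assert between_batch_variance(cube)[0] == 1.0

    def test_invariant_under_batch_relabelling(self):
        cube = labelled_cube([[1, 2], [5, 6], [9, 9]])
        v1 = between_batch_variance(cube)
        mapping = {1: 3, 2: 1, 3: 2}
        relabel = cube.copy()
        relabel.batch = np.array([mapping[b] for b in cube.batch])
        assert np.allclose(between_batch_variance(relabel), v1)

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError, match="2 batches"):
            between_batch_variance(labelled_cube([[1, 2]]))


class TestGrandMeanFidelity:
    def test_identity_has_slope_one(self, small_cube):
        f = grand_mean_fidelity(small_cube, small_cube)
        assert f.slope == pytest.approx(1.0) and f.r2 == pytest.approx(1.0)

    def test_halving_keeps_slope_one_with_log_half_intercept(self, small_cube):
        halved = small_cube.with_intensities(small_cube.intensities * 0.5)
        f = grand_mean_fidelity(small_cube, halved)
        assert f.slope == pytest.approx(1.0)
        assert f.intercept == pytest.approx(np.log(0.5))

    def test_collapse_to_constant_gives_slope_zero(self, small_cube):
        collapsed = small_cube.with_intensities(np.full_like(small_cube.intensities, 3.0))
        f = grand_mean_fidelity(small_cube, collapsed)
        assert f.slope == pytest.approx(0.0, abs=1e-12)


class TestPcaBatchReport:
    def test_separated_batches_give_high_silhouette(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(50, 5))
        b = rng.normal(10, 0.1, size=(50, 5))
        rep = pca_batch_report(np.vstack([a, b]), batch=np.repeat([1, 2], 50), n_pc=3)
        assert rep.batch_silhouette > 0.95

    def test_iid_null_silhouette_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2000, 10))
        batch = np.repeat(np.arange(1, 5), 500)
        rep = pca_batch_report(x, batch=batch, n_pc=5)
        assert abs(rep.batch_silhouette) < 0.05

    def test_variance_explained_non_increasing_and_at_most_one(self, small_cube):
        rep = pca_batch_report(small_cube, n_pc=4)
        ve = rep.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert ve.sum() <= 1.0 + 1e-9


class TestKmeansImage:
    def planted(self):
        rng = np.random.default_rng(2)
        n = 100  # 10x10 section, left/right halves distinct
        ys, xs = np.divmod(np.arange(n), 10)
        region = (xs >= 5).astype(int)
        x = np.abs(rng.normal(0, 0.05, size=(n, 4)) + np.where(region[:, None] == 0, [5, 1, 1, 1], [1, 1, 5, 5]))
        return Datacube(
            intensities=x,
            mz=100.0 + np.arange(4),
            pixel_x=xs,
            pixel_y=ys,
            section_id=np.full(n, "a", dtype=object),
            slide_id=np.full(n, "a", dtype=object),
            batch=np.ones(n, int),
            time_s=np.arange(n, dtype=float),
            tissue=np.full(n, "sample", dtype=object),
        ), region

    def test_planted_two_region_section_recovered(self):
        cube, region = self.planted()
        labels, images = kmeans_image(cube, k=2, seed=0)
        # align label polarity before scoring
        agree = max(np.mean(labels == region), np.mean(labels == 1 - region))
        assert agree >= 0.95
        assert images["a"].shape == (10, 10)

    def test_deterministic_under_fixed_seed(self):
        cube, _ = self.planted()
        l1, _ = kmeans_image(cube, k=3, seed=4)
        l2, _ = kmeans_image(cube, k=3, seed=4)
        assert np.array_equal(l1, l2)


class TestTsneRgb:
    def test_colors_bounded_and_duplicates_close(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 5, size=(30, 6))
        x = np.vstack([base, base[:5]])  # duplicated pixels
        cube = Datacube(
            intensities=x,
            mz=100.0 + np.arange(6),
            pixel_x=np.arange(35) % 7,
            pixel_y=np.arange(35) // 7,
            section_id=np.full(35, "a", dtype=object),
            slide_id=np.full(35, "a", dtype=object),
            batch=np.ones(35, int),
            time_s=np.arange(35, dtype=float),
            tissue=np.full(35, "sample", dtype=object),
        )
        rgb, images = tsne_rgb(cube, seed=0)
        assert rgb.shape == (35, 3)
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0
        # duplicated pixels land much closer together than typical pairs
        dup = np.array([np.linalg.norm(rgb[30 + i] - rgb[i]) for i in range(5)])
        rng_pairs = rng.integers(0, 30, size=(200, 2))
        typical = np.median(
            [np.linalg.norm(rgb[i] - rgb[j]) for i, j in rng_pairs if i != j]
        )
        assert np.median(dup) < 0.5 * typical
        assert images["a"].shape == (5, 7, 3)

    def test_two_planted_populations_separate_in_color(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(0, 0.1, size=(40, 5)) + [5, 1, 1, 1, 1])
        b = np.abs(rng.normal(0, 0.1, size=(40, 5)) + [1, 1, 1, 5, 5])
        cube = Datacube(
            intensities=np.vstack([a, b]),
            mz=100.0 + np.arange(5),
            pixel_x=np.arange(80) % 8,
            pixel_y=np.arange(80) // 8,
            section_id=np.full(80, "a", dtype=object),
            slide_id=np.full(80, "a", dtype=object),
            batch=np.ones(80, int),
            time_s=np.arange(80, dtype=float),
            tissue=np.full(80, "sample", dtype=object),
        )
        rgb, _ = tsne_rgb(cube, seed=0)
        # the two populations separate in at least one channel
        gap = np.abs(rgb[:40].mean(axis=0) - rgb[40:].mean(axis=0))
        assert gap.max() > 0.3


class TestSpatialPreservation:
    def test_affine_per_section_transform_has_r_one(self, small_cube):
        corrected = small_cube.copy()
        for i, sec in enumerate(small_cube.sections):
            m = small_cube.section_id == sec
            corrected.intensities[m] = 2.5 * small_cube.intensities[m] + (i + 1) * 3.0
        sp = spatial_preservation(small_cube, corrected)
        assert all(v == pytest.approx(1.0) for v in sp.per_section_median.values())
        assert not sp.collapsed

    def test_constant_correction_reported_as_collapse(self, small_cube):
        corrected = small_cube.with_intensities(np.full_like(small_cube.intensities, 7.0))
        sp = spatial_preservation(small_cube, corrected)
        assert sp.collapsed
        assert all(v == 0.0 for v in sp.per_section_median.values())
        assert sp.n_excluded == small_cube.n_features * len(small_cube.sections)


class TestPixelOrderInvariance:
    def test_metrics_invariant_to_pixel_permutation(self, small_cube):
        rng = np.random.default_rng(5)
        perm = rng.permutation(small_cube.n_pixels)
        shuffled = small_cube.select(perm)
        assert np.allclose(between_batch_variance(shuffled), between_batch_variance(small_cube))
        t0 = batch_moments(small_cube)[["median", "iqr", "mean"]]
        t1 = batch_moments(shuffled)[["median", "iqr", "mean"]]
        assert np.allclose(t0.values, t1.values)


class TestReportRoundTrip:
    def test_full_report_written(self, tmp_path, small_cube):
        corrected = small_cube.with_intensities(small_cube.intensities * 0.9)
        rep = evaluate_correction(small_cube, corrected, n_pc=3)
        out = write_report(rep, tmp_path / "rep", plots=True)
        assert (out / "summary.json").exists()
        assert (out / "batch_moments_raw.tsv").exists()
        assert (out / "panels.png").exists()
        summary = rep.summary()
        assert summary["grand_mean_slope"] == pytest.approx(1.0)


class TestBatchMeanCorrelation:
    def test_shared_batch_fingerprint_correlates(self):
        rng = np.random.default_rng(6)
        shift = np.array([0.0, 4.0, -3.0])
        blocks = [rng.normal(10 + s, 0.2, size=(30, 4)) for s in shift]
        cube = labelled_cube([b[:, 0] for b in blocks], n_features=1)
        x = np.vstack(blocks)
        cube = Datacube(
            intensities=x,
            mz=100.0 + np.arange(4),
            pixel_x=np.tile(np.arange(30), 3),
            pixel_y=np.zeros(90, int),
            section_id=np.repeat([f"s{i}" for i in range(3)], 30).astype(object),
            slide_id=np.repeat([f"s{i}" for i in range(3)], 30).astype(object),
            batch=np.repeat([1, 2, 3], 30),
            time_s=np.arange(90, dtype=float),
            tissue=np.full(90, "sample", dtype=object),
        )
        corr = batch_mean_correlation(cube)
        assert corr.shape == (4, 4)
        assert np.all(corr > 0.99)  # all ions share one batch fingerprint
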