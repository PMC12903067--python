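"""Rebinning, segmentation, peak picking, common axis, peak extraction."""

import numpy as np
import pytest

from msibatchqc.datacube import Datacube
from msibatchqc.preprocess import (
    PeakList,
    Spectrum,
    extract_peak_cube,
    mean_spectrum,
    merge_common_axis,
    pick_peaks_gradient,
    rebin_grid,
    rebin_linear,
    segment_background,
    top_n_peaks,
)

from conftest import make_cube


def brute_force_local_maxima(y: np.ndarray, min_intensity: float = 0.0) -> list[int]:
    """Independent oracle: scan for strict local maxima, plateaus resolved
    to the lowest index; endpoints and end-touching plateaus are not peaks."""
    n = len(y)
    apexes = []
    for i in range(1, n - 1):
        if y[i] <= y[i - 1]:
            continue  # not the first bin of a rise-topped plateau
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j < n - 1 and y[j + 1] < y[i]:
            apexes.append(i)
    return [i for i in apexes if y[i] > min_intensity]


class TestRebin:
    def test_identity_on_target_grid(self):
        grid = rebin_grid((100.0, 101.0), 0.1)
        s = Spectrum(grid, np.sin(grid))
        out_grid, mat = rebin_linear([s], bin_width=0.1, mz_range=(100.0, 101.0))
        assert np.allclose(out_grid, grid)
        assert np.allclose(mat[0], s.intensity)

    def test_hand_interpolation_of_three_point_spectrum(self):
        # raw points at 10.0->0, 10.5->4, 11.0->0; grid step 0.25
        s = Spectrum([10.0, 10.5, 11.0], [0.0, 4.0, 0.0])
        grid, mat = rebin_linear([s], bin_width=0.25, mz_range=(10.0, 11.0))
        assert np.allclose(mat[0], [0.0, 2.0, 4.0, 2.0, 0.0])

    def test_outside_support_is_zero(self):
        s = Spectrum([10.4, 10.6], [1.0, 1.0])
        _, mat = rebin_linear([s], bin_width=0.2, mz_range=(10.0, 11.0))
        assert mat[0][0] == 0.0 and mat[0][-1] == 0.0

    def test_study_grid_size_for_full_mz_range(self):
        grid = rebin_grid((50.0, 1200.0), 0.0008)
        assert grid.size == int((1200 - 50) / 0.0008) + 1

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rebin_linear([Spectrum([], [])], bin_width=0.1, mz_range=(1.0, 2.0))


class TestMeanSpectrum:
    def test_single_pixel_identity(self, small_cube):
        mask = np.zeros(small_cube.n_pixels, dtype=bool)
        mask[3] = True
        assert np.allclose(mean_spectrum(small_cube, mask).intensity, small_cube.intensities[3])

    def test_two_pixel_symmetry(self, small_cube):
        cube = small_cube.copy()
        cube.intensities[0] = [0, 2, 0, 2, 0]
        cube.intensities[1] = [2, 0, 2, 0, 2]
        mask = np.zeros(cube.n_pixels, dtype=bool)
        mask[:2] = True
        assert np.allclose(mean_spectrum(cube, mask).intensity, 1.0)

    def test_equals_section_size_weighted_mean_of_section_means(self, small_cube):
        total = mean_spectrum(small_cube).intensity
        acc = np.zeros(small_cube.n_features)
        for sec in small_cube.sections:
            m = small_cube.section_id == sec
            acc += m.sum() * mean_spectrum(small_cube, m).intensity
        assert np.allclose(total, acc / small_cube.n_pixels)

    def test_empty_mask_rejected(self, small_cube):
        with pytest.raises(ValueError, match="no pixels"):
            mean_spectrum(small_cube, np.zeros(small_cube.n_pixels, dtype=bool))


class TestSegmentBackground:
    def test_two_planted_populations_perfectly_separated(self):
        rng = np.random.default_rng(5)
        tissue = rng.normal(0, 0.05, size=(30, 4)) + [5, 1, 1, 1]
        background = rng.normal(0, 0.05, size=(30, 4)) + [0.2, 0.2, 2, 2]
        x = np.abs(np.vstack([tissue, background]))
        cube = Datacube(
            intensities=x,
            mz=100.0 + np.arange(4),
            pixel_x=np.arange(60) % 10,
            pixel_y=np.arange(60) // 10,
            section_id=np.full(60, "a", dtype=object),
            slide_id=np.full(60, "a", dtype=object),
            batch=np.ones(60, dtype=int),
            time_s=np.arange(60, dtype=float),
            tissue=np.full(60, "sample", dtype=object),
        )
        labels, is_bg = segment_background(cube, k=2, seed=0)
        assert len(np.unique(labels[:30])) == 1
        assert len(np.unique(labels[30:])) == 1
        assert labels[0] != labels[30]
        # background flag goes to the lower-TIC population
        assert is_bg[30:].all() and not is_bg[:30].any()

    def test_deterministic_under_fixed_seed(self, small_cube):
        l1, b1 = segment_background(small_cube, k=3, seed=7)
        l2, b2 = segment_background(small_cube, k=3, seed=7)
        assert np.array_equal(l1, l2) and np.array_equal(b1, b2)

    def test_labels_invariant_to_per_pixel_positive_rescaling(self, small_cube):
        scaled = small_cube.copy()
        rng = np.random.default_rng(1)
        scaled.intensities = scaled.intensities * rng.uniform(0.5, 5, size=(scaled.n_pixels, 1))
        l1, _ = segment_background(small_cube, k=3, seed=0)
        l2, _ = segment_background(scaled, k=3, seed=0)
        assert np.array_equal(l1, l2)

    def test_k_exceeding_pixels_rejected(self, small_cube):
        with pytest.raises(ValueError):
            segment_background(small_cube, k=small_cube.n_pixels + 1)


class TestPickPeaks:
    def test_minimal_triangle_peak(self):
        p = pick_peaks_gradient(Spectrum([1.0, 2.0, 3.0], [0.0, 1.0, 0.0]))
        assert len(p) == 1 and p.mz[0] == 2.0 and p.intensity[0] == 1.0
        assert p.left[0] == 0 and p.right[0] == 2

    def test_monotone_spectrum_has_no_peaks(self):
        p = pick_peaks_gradient(Spectrum(np.arange(5.0), np.arange(5.0)))
        assert len(p) == 0

    def test_two_gaussians_found_within_one_bin(self):
        mz = np.linspace(100, 110, 2001)
        y = np.exp(-0.5 * ((mz - 103) / 0.2) ** 2) + 0.5 * np.exp(-0.5 * ((mz - 107) / 0.2) ** 2)
        p = pick_peaks_gradient(Spectrum(mz, y))
        assert len(p) == 2
        assert abs(p.mz[0] - 103) <= 0.006 and abs(p.mz[1] - 107) <= 0.006

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_scan_on_random_spectra(self, trial):
        rng = np.random.default_rng(trial)
        # integer-valued spectra force plateaus and ties
        y = rng.integers(0, 6, size=80).astype(float)
        mz = np.arange(80, dtype=float)
        got = pick_peaks_gradient(Spectrum(mz, y))
        expected = brute_force_local_maxima(y)
        assert got.mz.astype(int).tolist() == expected

    def test_plateau_resolves_to_lowest_index(self):
        y = np.array([0.0, 2.0, 2.0, 2.0, 0.0])
        p = pick_peaks_gradient(Spectrum(np.arange(5.0), y))
        assert len(p) == 1 and p.mz[0] == 1.0

    def test_min_intensity_filters_apexes(self):
        y = np.array([0.0, 1.0, 0.0, 5.0, 0.0])
        p = pick_peaks_gradient(Spectrum(np.arange(5.0), y), min_intensity=2.0)
        assert len(p) == 1 and p.intensity[0] == 5.0


class TestTopN:
    def make_peaks(self, intensities):
        n = len(intensities)
        return PeakList(
            mz=np.arange(n, dtype=float),
            intensity=np.asarray(intensities, dtype=float),
            left=np.zeros(n, dtype=int),
            right=np.zeros(n, dtype=int),
        )

    def test_n_larger_than_count_is_identity(self):
        p = self.make_peaks([5, 3, 1])
        out = top_n_peaks(p, n=10)
        assert np.array_equal(out.intensity, p.intensity)

    def test_ties_break_toward_lower_mz(self):
        out = top_n_peaks(self.make_peaks([5, 3, 5, 1]), n=2)
        assert out.mz.tolist() == [0.0, 2.0]

    def test_output_sorted_by_mz(self):
        rng = np.random.default_rng(0)
        p = self.make_peaks(rng.uniform(0, 10, size=50))
        out = top_n_peaks(p, n=10)
        assert np.all(np.diff(out.mz) > 0)
        # the kept apexes are the 10 largest
        assert set(out.intensity) == set(np.sort(p.intensity)[-10:])


class TestMergeCommonAxis:
    def make(self, mzs, intens):
        n = len(mzs)
        return PeakList(np.asarray(mzs, float), np.asarray(intens, float), np.zeros(n, int), np.zeros(n, int))

    def test_single_list_identity(self):
        p = self.make([100.0, 101.0], [1.0, 2.0])
        out = merge_common_axis([p], tolerance=0.005)
        assert np.allclose(out.mz, p.mz) and np.allclose(out.intensity, p.intensity)

    def test_two_identical_lists_double_intensity(self):
        p = self.make([100.0, 101.0], [1.0, 2.0])
        out = merge_common_axis([p, p], tolerance=0.005)
        assert np.allclose(out.mz, [100.0, 101.0])
        assert np.allclose(out.intensity, [2.0, 4.0])

    def test_peaks_within_tolerance_collapse_to_weighted_mean(self):
        a = self.make([100.000], [3.0])
        b = self.make([100.004], [1.0])
        out = merge_common_axis([a, b], tolerance=0.005)
        assert len(out) == 1
        assert out.mz[0] == pytest.approx(100.001)  # intensity-weighted
        assert out.intensity[0] == 4.0

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(3)
        mzs = np.sort(rng.uniform(100, 100.1, size=40))
        p = self.make(mzs, np.ones(40))
        tol = 0.004
        out = merge_common_axis([p], tolerance=tol)
        # oracle: union-find over all pairs within tolerance
        parent = list(range(40))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(40):
            for j in range(i + 1, 40):
                if abs(mzs[i] - mzs[j]) <= tol:
                    parent[find(i)] = find(j)
        n_groups = len({find(i) for i in range(40)})
        assert len(out) == n_groups

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            merge_common_axis([self.make([1.0], [1.0])], tolerance=-0.1)


class TestExtractPeakCube:
    def profile_cube(self):
        mz = np.arange(100.0, 101.0, 0.1)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, size=(6, mz.size))
        return Datacube(
            intensities=x,
            mz=mz,
            pixel_x=np.arange(6),
            pixel_y=np.zeros(6, int),
            section_id=np.full(6, "a", dtype=object),
            slide_id=np.full(6, "a", dtype=object),
            batch=np.ones(6, int),
            time_s=np.arange(6, dtype=float),
            tissue=np.full(6, "sample", dtype=object),
        )

    def peaks_at(self, centers):
        c = np.asarray(centers, float)
        return PeakList(c, np.ones_like(c), np.zeros(c.size, int), np.zeros(c.size, int))

    def test_window_covering_one_bin_returns_that_bin(self):
        cube = self.profile_cube()
        out = extract_peak_cube(cube, self.peaks_at([100.3]), half_window=0.04)
        assert np.allclose(out.intensities[:, 0], cube.intensities[:, 3])

    def test_widening_never_decreases_values(self):
        cube = self.profile_cube()
        narrow = extract_peak_cube(cube, self.peaks_at([100.3]), half_window=0.05)
        wide = extract_peak_cube(cube, self.peaks_at([100.3]), half_window=0.25)
        assert np.all(wide.intensities >= narrow.intensities - 1e-12)

    def test_window_spanning_five_bins_sums_them(self):
        cube = self.profile_cube()
        out = extract_peak_cube(cube, self.peaks_at([100.3]), half_window=0.21)
        assert np.allclose(out.intensities[:, 0], cube.intensities[:, 1:6].sum(axis=1))

    def test_overlapping_windows_assign_bins_to_nearest_apex(self):
        cube = self.profile_cube()
        with pytest.warns(UserWarning, match="overlap"):
            out = extract_peak_cube(cube, self.peaks_at([100.2, 100.4]), half_window=0.15)
        # every bin counted once: totals match a disjoint nearest-apex split
        total = out.intensities.sum(axis=1)
        in_any = np.abs(cube.mz[:, None] - np.array([100.2, 100.4])).min(axis=1) <= 0.15
        assert np.allclose(total, cube.intensities[:, in_any].sum(axis=1))
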