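"""Image-quantification primitives against brute-force oracles and planted truth."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

import oracles
from talemap.imaging import (
    DegenerateImageError,
    FocusPoint,
    ImageField,
    NucleiConfig,
    NucleusMask,
    count_foci,
    cytoplasm_rings,
    find_maxima,
    gaussian_blur,
    nc_ratio,
    normalize_ratios,
    rolling_ball_background,
    segment_nuclei,
    threshold_huang,
    threshold_otsu,
)
from talemap.synthetic import make_pla_truth, synth_nc_image, synth_pla_image


class TestRollingBall:
    def test_constant_image_corrects_to_zero(self):
        bg, corr = rolling_ball_background(np.full((32, 32), 50.0), 5)
        assert np.allclose(corr, 0)
        assert np.allclose(bg, 50.0)

    def test_spike_preserved(self):
        img = np.full((64, 64), 50.0)
        img[30, 30] = 200.0
        _, corr = rolling_ball_background(img, 15)
        expected = np.zeros_like(img)
        expected[30, 30] = 150.0
        assert np.abs(corr - expected).max() <= 1.0

    def test_equals_brute_force_opening(self, rng):
        img = np.round(rng.uniform(0, 120, (64, 64)))
        bg, corr = rolling_ball_background(img, 15)
        oracle_bg = oracles.brute_ball_opening(img, 15)
        assert np.abs(corr - (img - oracle_bg)).max() <= 1.0

    def test_corrected_nonnegative(self, rng):
        img = rng.uniform(0, 255, (48, 48))
        _, corr = rolling_ball_background(img, 8)
        assert corr.min() >= -1e-9

    def test_huge_radius_warns_and_uses_minimum(self):
        img = np.arange(16.0).reshape(4, 4)
        with pytest.warns(UserWarning):
            bg, _ = rolling_ball_background(img, 100)
        assert np.all(bg == img.min())


class TestGaussianBlur:
    def test_sigma_zero_identity(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        assert np.array_equal(gaussian_blur(img, 0), img)

    def test_delta_impulse_gives_unit_mass_kernel(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = gaussian_blur(img, 2.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert out[20, 20] == out.max()

    def test_linearity_in_intensity(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        assert np.allclose(gaussian_blur(3 * img, 1.5), 3 * gaussian_blur(img, 1.5))


class TestThresholds:
    def test_otsu_separates_bimodal(self, rng):
        img = np.full(1000, 10, dtype=np.uint8)
        img[:100] = 200
        t = threshold_otsu(img.reshape(25, 40))
        assert 10 <= t < 200

    def test_otsu_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
            assert threshold_otsu(img) == oracles.brute_otsu(img)

    def test_otsu_close_to_skimage(self, rng):
        img = np.concatenate([rng.normal(60, 10, 400), rng.normal(180, 12, 200)])
        img = np.clip(np.round(img), 0, 255).astype(np.uint8).reshape(20, 30)
        assert abs(threshold_otsu(img) - skimage_otsu(img)) <= 1

    def test_otsu_shift_invariance(self, rng):
        img = rng.integers(0, 100, (16, 16)).astype(np.int64)
        assert threshold_otsu(img + 50) == threshold_otsu(img) + 50

    def test_huang_separates_bimodal(self):
        img = np.full((20, 20), 10, dtype=np.uint8)
        img[:2] = 200
        assert 10 <= threshold_huang(img) < 200

    def test_huang_matches_exhaustive_oracle(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            assert threshold_huang(img) == oracles.brute_huang(img)

    def test_huang_symmetric_histogram_centered(self, rng):
        # symmetric bimodal histogram around 100
        img = np.concatenate([np.full(200, 60), np.full(200, 140)]).astype(np.uint8)
        rng.shuffle(img)
        t = threshold_huang(img.reshape(20, 20))
        oracle = oracles.brute_huang(img.reshape(20, 20))
        assert abs(t - oracle) <= 1
        assert 60 <= t < 140

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            threshold_otsu(np.full((8, 8), 3, dtype=np.uint8))
        with pytest.raises(DegenerateImageError):
            threshold_huang(np.full((8, 8), 3, dtype=np.uint8))


class TestFindMaxima:
    def test_flat_image_empty(self):
        assert find_maxima(np.zeros((64, 64)), 10) == []

    def test_single_gaussian_spot(self):
        yy, xx = np.mgrid[:64, :64]
        img = 100 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 8)
        pts = find_maxima(img, 20)
        assert [(p.row, p.col) for p in pts] == [(32, 32)]

    def test_seven_planted_spots(self, rng):
        yy, xx = np.mgrid[:64, :64]
        centers = [(8, 8), (8, 32), (8, 56), (32, 8), (32, 40), (56, 16), (56, 48)]
        img = rng.normal(0, 2, (64, 64))
        for r, c in centers:
            img += 80 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / 4)
        pts = find_maxima(img, 20)
        assert len(pts) == 7
        for p in pts:
            assert min(np.hypot(p.row - r, p.col - c) for r, c in centers) <= 1

    def test_matches_prominence_oracle_random(self, rng):
        for _ in range(5):
            img = rng.integers(0, 40, (24, 24)).astype(float)
            got = sorted((p.row, p.col) for p in find_maxima(img, 8))
            assert got == oracles.brute_prominent_maxima(img, 8)

    def test_plateau_merged_to_single_point(self):
        img = np.zeros((16, 16))
        img[5:8, 5:8] = 10.0
        pts = find_maxima(img, 3)
        assert [(p.row, p.col) for p in pts] == [(6, 6)]

    def test_shallow_secondary_peak_suppressed(self):
        img = np.zeros((16, 32))
        img[8, 8] = 50.0
        img[8, 20] = 45.0
        img[8, 9:20] = 41.0  # valley stays within tolerance of the lower peak
        assert [(p.row, p.col) for p in find_maxima(img, 10)] == [(8, 8)]
        # deeper valley isolates both peaks
        img[8, 9:20] = 20.0
        assert len(find_maxima(img, 10)) == 2


class TestSegmentNuclei:
    def test_single_disk_area(self):
        yy, xx = np.mgrid[:128, :128]
        img = np.where((yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2, 150.0, 5.0)
        mask = segment_nuclei(img, NucleiConfig(rolling_radius=60, sigma=1,
                                                method="otsu"))
        assert mask.n_nuclei == 1
        assert abs(mask.areas[1] - np.pi * 400) / (np.pi * 400) < 0.05

    def test_two_disjoint_disks(self):
        yy, xx = np.mgrid[:128, :128]
        img = np.full((128, 128), 5.0)
        img[(yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2] = 150
        img[(yy - 90) ** 2 + (xx - 90) ** 2 <= 15**2] = 150
        mask = segment_nuclei(img, NucleiConfig(rolling_radius=60, sigma=1))
        assert mask.n_nuclei == 2

    def test_blank_field_warns_empty(self):
        with pytest.warns(UserWarning):
            mask = segment_nuclei(np.full((64, 64), 7.0))
        assert mask.n_nuclei == 0


class TestCountFoci:
    def disk_mask(self):
        yy, xx = np.mgrid[:64, :64]
        labels = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2).astype(np.int32)
        return NucleusMask(labels, {1: int(labels.sum())}, {1: (32.0, 32.0)})

    def test_inside_outside_partition(self):
        mask = self.disk_mask()
        inside = [FocusPoint(32 + d, 32, 1.0) for d in range(-2, 3)]
        outside = [FocusPoint(2, 2, 1.0), FocusPoint(60, 60, 1.0),
                   FocusPoint(5, 55, 1.0)]
        nn, nc, per = count_foci(inside + outside, mask)
        assert (nn, nc) == (5, 3)
        assert per[1] == 5

    def test_empty_mask_all_cytoplasmic(self):
        mask = NucleusMask(np.zeros((8, 8), dtype=np.int32), {}, {})
        nn, nc, _ = count_foci([FocusPoint(1, 1, 1.0)] * 4, mask)
        assert (nn, nc) == (0, 4)

    def test_totals_permutation_invariant(self, rng):
        mask = self.disk_mask()
        pts = [FocusPoint(int(r), int(c), 1.0)
               for r, c in rng.integers(0, 64, (30, 2))]
        ref = count_foci(pts, mask)[:2]
        perm = list(pts)
        rng.shuffle(perm)
        assert count_foci(perm, mask)[:2] == ref
        assert sum(ref) == 30


class TestNCRatio:
    def test_uniform_image_ratio_one(self):
        field, truth = synth_nc_image(50.0, 50.0, noise_sd=0, seed=1)
        mask = _mask_from_truth(truth)
        ratios = nc_ratio(field, mask, cytoplasm=truth["cytoplasm_masks"])
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_four_to_one_ratio(self):
        field, truth = synth_nc_image(100.0, 25.0, noise_sd=0, seed=2)
        mask = _mask_from_truth(truth)
        ratios = nc_ratio(field, mask, cytoplasm=truth["cytoplasm_masks"])
        assert all(r == pytest.approx(4.0) for r in ratios.values())

    def test_wildtype_exceeds_mutant_median(self):
        wt_field, wt_truth = synth_nc_image(100.0, 25.0, noise_sd=5, seed=3)
        mut_field, mut_truth = synth_nc_image(30.0, 60.0, noise_sd=5, seed=4)
        cfg = NucleiConfig(rolling_radius=50, sigma=1, method="otsu")
        wt_mask = segment_nuclei(wt_field["dapi"], cfg)
        mut_mask = segment_nuclei(mut_field["dapi"], cfg)
        wt = list(nc_ratio(wt_field, wt_mask).values())
        mut = list(nc_ratio(mut_field, mut_mask).values())
        assert np.median(wt) > np.median(mut)
        normalized = normalize_ratios(
            dict(enumerate(mut)), wt, stat="median")
        assert np.median(list(normalized.values())) < 1.0

    def test_empty_cytoplasm_region_errors(self):
        field, truth = synth_nc_image(100.0, 25.0, noise_sd=0, seed=5)
        mask = _mask_from_truth(truth)
        empty = {k: np.zeros(field.shape, bool) for k in truth["cytoplasm_masks"]}
        with pytest.raises(ValueError, match="empty cytoplasm"):
            nc_ratio(field, mask, cytoplasm=empty)


def _mask_from_truth(truth) -> NucleusMask:
    masks = truth["nucleus_masks"]
    shape = next(iter(masks.values())).shape
    labels = np.zeros(shape, dtype=np.int32)
    areas, centroids = {}, {}
    for label, m in masks.items():
        labels[m] = label
        areas[label] = int(m.sum())
        rows, cols = np.nonzero(m)
        centroids[label] = (float(rows.mean()), float(cols.mean()))
    return NucleusMask(labels, areas, centroids)


class TestPlaPipeline:
    def test_high_snr_field_recovers_planted_counts(self):
        truth = make_pla_truth(n_nuclei=3, n_nuclear_foci=12, n_cyto_foci=5,
                               seed=21)
        field = synth_pla_image(truth)
        mask = segment_nuclei(field["dapi"])
        _, red = rolling_ball_background(field["red"], 50)
        foci = find_maxima(red, 20)
        nn, nc, _ = count_foci(foci, mask)
        assert (nn, nc) == (12, 5)

    def test_ring_cytoplasm_regions_exclude_nuclei(self):
        truth = make_pla_truth(seed=22)
        field = synth_pla_image(truth)
        mask = segment_nuclei(field["dapi"])
        rings = cytoplasm_rings(mask, width=5)
        for ring in rings.values():
            assert not np.any(ring & (mask.labels > 0))


class TestImageField:
    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            ImageField({"a": np.zeros((4, 4)), "b": np.zeros((5, 5))})

    def test_tiff_round_trip(self, tmp_path):
        field, _ = synth_nc_image(100.0, 25.0, noise_sd=0, seed=6)
        f = tmp_path / "field.tif"
        field.to_tiff(f, order=["dapi", "gfp"])
        back = ImageField.from_tiff(f, ["dapi", "gfp"])
        assert np.allclose(back["gfp"], field["gfp"])
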