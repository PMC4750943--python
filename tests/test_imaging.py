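"""Image-analysis operators on synthetic sections with known ground truth."""

import numpy as np
import pytest

from spherosim import imaging as im


@pytest.fixture
def clean_section():
    return im.generate_synthetic_section(n_nuclei=40, shape=(220, 220),
                                         noise=0.0, positive_fraction=0.5,
                                         seed=3)


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 0.4)
        assert np.array_equal(im.median_filter(img, 3), img)

    def test_single_bright_pixel_removed(self):
        img = np.zeros((15, 15))
        img[7, 7] = 0.9
        assert im.median_filter(img, 3).max() == 0.0

    def test_matches_bruteforce_sort_oracle(self, rng):
        img = rng.integers(0, 10, size=(12, 12)).astype(float)
        for n in (3, 5):
            a = (n - 1) // 2
            padded = np.pad(img, a, mode="symmetric")
            oracle = np.empty_like(img)
            for i in range(12):
                for j in range(12):
                    win = padded[i:i + n, j:j + n].ravel()
                    oracle[i, j] = np.sort(win)[len(win) // 2]
            assert np.array_equal(im.median_filter(img, n), oracle)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            im.median_filter(np.zeros((5, 5)), 4)

    def test_smooth_nuclei_idempotent_on_flat_regions(self):
        img = np.zeros((30, 30))
        img[5:25, 5:25] = 0.8
        once = im.smooth_nuclei(img)
        assert np.array_equal(im.smooth_nuclei(once), once)


class TestWatershed:
    def test_two_separated_blobs_two_labels(self):
        yy, xx = np.mgrid[0:80, 0:80]
        ch = 0.9 * np.exp(-((yy - 25) ** 2 + (xx - 25) ** 2) / 20) + \
             0.9 * np.exp(-((yy - 55) ** 2 + (xx - 55) ** 2) / 20)
        seg = im.watershed_segment(np.clip(ch, 0, 0.999), 0.15)
        assert seg.n_nuclei == 2

    def test_all_background(self):
        seg = im.watershed_segment(np.full((30, 30), 0.05), 0.15)
        assert seg.n_nuclei == 0

    def test_invariance_under_monotone_rescale(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ch = 0.8 * np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / 15) + \
             0.7 * np.exp(-((yy - 42) ** 2 + (xx - 40) ** 2) / 12)
        ch = np.clip(ch, 0, 0.999)
        seg1 = im.watershed_segment(ch, 0.15)
        # square preserves ordering; threshold maps to 0.15^2
        seg2 = im.watershed_segment(ch ** 2, 0.15 ** 2)
        assert np.array_equal(seg1.labels > 0, seg2.labels > 0)
        assert seg1.n_nuclei == seg2.n_nuclei


class TestClassification:
    def test_saturated_nucleus_positive(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:5, 2:5] = 1
        from skimage.measure import regionprops
        seg = im.SegmentationResult(labels, regionprops(labels))
        marker = np.ones((10, 10)) * 0.999
        assert im.classify_nuclei(seg, marker, 0.5, 0.9) == {1: True}

    def test_fraction_threshold_arithmetic(self):
        labels = np.zeros((2, 10), dtype=np.int32)
        labels[0, :10] = 1  # 10-pixel nucleus
        from skimage.measure import regionprops
        seg = im.SegmentationResult(labels, regionprops(labels))
        marker = np.zeros((2, 10))
        marker[0, 0] = 0.9  # exactly one positive pixel -> fraction 0.1
        flags = im.classify_nuclei(seg, marker, 0.5, 0.2)
        assert flags == {1: False}
        flags = im.classify_nuclei(seg, marker, 0.5, 0.1)
        assert flags == {1: True}

    def test_threshold_sweep_plateau(self, clean_section):
        # low error over a mid-range threshold plateau, high error at the
        # extremes (everything-positive / nothing-positive regimes)
        img, truth = im.generate_synthetic_section(
            n_nuclei=40, shape=(220, 220), noise=0.04,
            positive_fraction=0.5, seed=3)
        seg = im.watershed_segment(im.smooth_nuclei(img.blue), 0.15)
        gold = im.match_nuclei_to_truth(seg, truth)
        errors = {}
        for I_t in (0.01, 0.35, 0.5, 0.99):
            flags = im.classify_nuclei(seg, img.red, I_t, 0.1)
            errors[I_t] = im.compute_metrics(flags, gold).error
        assert errors[0.35] < 0.05 and errors[0.5] < 0.05
        assert errors[0.01] > 0.3  # everything positive
        assert errors[0.99] > 0.3  # nothing positive


class TestMetrics:
    def test_perfect_agreement(self):
        flags = {i: i % 2 == 0 for i in range(10)}
        m = im.compute_metrics(flags, dict(flags))
        assert m.TPR == 1.0 and m.TNR == 1.0 and m.error == 0.0

    def test_confusion_arithmetic(self):
        gold, flags = {}, {}
        k = 0
        for (f, g), n in [((True, True), 45), ((True, False), 5),
                          ((False, False), 40), ((False, True), 10)]:
            for _ in range(n):
                flags[k], gold[k] = f, g
                k += 1
        m = im.compute_metrics(flags, gold)
        assert (m.TP, m.FP, m.TN, m.FN) == (45, 5, 40, 10)
        assert m.TPR == pytest.approx(45 / 55)
        assert m.TNR == pytest.approx(40 / 45)
        assert m.error == pytest.approx(0.15)

    def test_all_flipped(self):
        gold = {i: i % 2 == 0 for i in range(10)}
        flags = {i: not v for i, v in gold.items()}
        m = im.compute_metrics(flags, gold)
        assert m.TPR == 0.0 and m.TNR == 0.0 and m.error == 1.0

    def test_label_mismatch_is_error(self):
        with pytest.raises(ValueError):
            im.compute_metrics({1: True}, {2: True})


class TestLumenAndBorder:
    def test_single_disc_border_is_annulus(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        yy, xx = np.mgrid[0:40, 0:40]
        labels[(yy - 20) ** 2 + (xx - 20) ** 2 < 36] = 1
        from skimage.measure import regionprops
        seg = im.SegmentationResult(labels, regionprops(labels))
        lumen, border = im.estimate_lumen_and_border(seg, dilations=3)
        assert lumen.sum() > (labels > 0).sum()
        assert border.sum() > 0
        assert not (border & ~lumen).any()
        # border pixels touch the background
        from scipy import ndimage
        grown = ndimage.binary_dilation(~lumen, structure=np.ones((3, 3), bool))
        assert grown[border].all()

    def test_two_overlapping_discs_single_lumen(self):
        labels = np.zeros((50, 50), dtype=np.int32)
        yy, xx = np.mgrid[0:50, 0:50]
        labels[(yy - 25) ** 2 + (xx - 20) ** 2 < 25] = 1
        labels[(yy - 25) ** 2 + (xx - 30) ** 2 < 25] = 2
        from skimage.measure import regionprops
        seg = im.SegmentationResult(labels, regionprops(labels))
        lumen, _ = im.estimate_lumen_and_border(seg)
        from skimage.measure import label as cc
        assert cc(lumen).max() == 1

    def test_interior_hole_filled(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10:30, 10:30] = 1
        labels[18:22, 18:22] = 0  # hole
        from skimage.measure import regionprops
        seg = im.SegmentationResult(labels, regionprops(labels))
        lumen, _ = im.estimate_lumen_and_border(seg, dilations=1)
        assert lumen[19, 19]


class TestVoronoiDiameter:
    def test_square_grid_closed_form(self):
        s = 10.0
        pts = np.array([[i * s, j * s] for i in range(6) for j in range(6)])
        d = im.voronoi_cell_diameter(pts)
        assert len(d) == 16  # interior points only
        assert np.allclose(d, 2 * np.sqrt(s ** 2 / np.pi))

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, size=(30, 2))
        d1 = np.sort(im.voronoi_cell_diameter(pts))
        d2 = np.sort(im.voronoi_cell_diameter(pts + 13.7))
        assert np.allclose(d1, d2)

    def test_hexagonal_packing_closed_form(self):
        s = 8.0
        pts = []
        for i in range(8):
            for j in range(8):
                pts.append([i * s + (j % 2) * s / 2, j * s * np.sqrt(3) / 2])
        d = im.voronoi_cell_diameter(np.array(pts))
        a_hex = np.sqrt(3) / 2 * s ** 2
        expect = 2 * np.sqrt(a_hex / np.pi)
        inner = d[np.abs(d - np.median(d)) < 1e-6]
        assert len(inner) > 10
        assert np.allclose(inner, expect)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            im.voronoi_cell_diameter(np.array([[0, 0], [1, 1], [2, 2],
                                               [3, 3.0]]))
        with pytest.raises(ValueError):
            im.voronoi_cell_diameter(np.zeros((3, 2)))


class TestRadialBinning:
    def test_half_open_edge_convention(self):
        df = im.radial_binning({1: 2.0, 2: 2.5}, {1: True, 2: False}, h=1.0)
        assert df.loc[df.bin == 2, "count"].item() == 2
        assert df["count"].sum() == 2

    def test_totals_and_fraction(self):
        dist = {i: float(i) for i in range(10)}
        vals = {i: i % 2 == 0 for i in range(10)}
        df = im.radial_binning(dist, vals, h=5.0)
        assert df["count"].sum() == 10
        assert df.loc[0, "fraction_positive"] == pytest.approx(3 / 5)

    def test_two_image_average_is_binwise_mean(self):
        d1 = im.radial_binning({1: 0.5}, {1: True}, h=1.0)
        d2 = im.radial_binning({1: 0.5}, {1: False}, h=1.0)
        avg = (d1["fraction_positive"] + d2["fraction_positive"]) / 2
        assert avg.iloc[0] == 0.5

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            im.radial_binning({1: 1.0}, {1: True}, h=0.0)


class TestSyntheticGenerator:
    def test_zero_noise_exact_recovery(self, clean_section):
        img, truth = clean_section
        seg = im.watershed_segment(im.smooth_nuclei(img.blue), 0.15)
        assert seg.n_nuclei == len(truth)

    def test_positive_fraction_recovered(self):
        img, truth = im.generate_synthetic_section(
            n_nuclei=80, shape=(300, 300), noise=0.01,
            positive_fraction=0.4, seed=9)
        seg = im.watershed_segment(im.smooth_nuclei(img.blue), 0.15)
        flags = im.classify_nuclei(seg, img.red, 0.35, 0.05)
        frac = np.mean(list(flags.values()))
        n = len(flags)
        ci = 3 * np.sqrt(0.4 * 0.6 / n)
        assert abs(frac - truth["positive"].mean()) <= max(ci, 0.05)

    def test_reproducible_given_seed(self):
        a, ta = im.generate_synthetic_section(seed=5)
        b, tb = im.generate_synthetic_section(seed=5)
        assert np.array_equal(a.blue, b.blue)
        assert ta.equals(tb)
        c, _ = im.generate_synthetic_section(seed=6)
        assert not np.array_equal(a.blue, c.blue)

    def test_packing_limit_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            im.generate_synthetic_section(n_nuclei=5000, shape=(64, 64),
                                          max_tries=2000)

    def test_full_pipeline_low_error(self, clean_section):
        img, truth = clean_section
        seg = im.watershed_segment(im.smooth_nuclei(img.blue), 0.15)
        gold = im.match_nuclei_to_truth(seg, truth)
        flags = im.classify_nuclei(seg, img.red, 0.35, 0.05)
        m = im.compute_metrics(flags, gold)
        assert m.error < 0.05

    def test_voronoi_recovers_lattice_spacing(self):
        # nuclei on a jittered square grid (a section through the cell
        # lattice): Voronoi diameters recover the spacing within 10%
        rng = np.random.default_rng(2)
        s = 16.0
        pts = np.array([[20 + i * s, 20 + j * s]
                        for i in range(12) for j in range(12)], float)
        pts += rng.uniform(-0.2 * s, 0.2 * s, size=pts.shape)
        d = im.voronoi_cell_diameter(pts, pixel_size=1.0)
        assert len(d) > 50
        expect = 2 * np.sqrt(s ** 2 / np.pi)
        assert np.median(d) == pytest.approx(expect, rel=0.10)
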