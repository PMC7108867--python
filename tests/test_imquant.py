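import numpy as np
import pytest
from scipy import linalg

from tissuemech import imquant as iq
from tissuemech import synth


# ---------------------------------------------------------------------------
# thresholding

class TestPhansalkar:
    def test_dim_constant_image_empty(self):
        # for a constant image s = 0; with the default constants the
        # threshold exceeds the mean whenever m < ~0.21
        img = np.full((80, 80), 40, dtype=np.uint8)
        mask = iq.local_threshold_phansalkar(img)
        assert not mask.data.any()

    def test_zero_image_empty(self):
        mask = iq.local_threshold_phansalkar(np.zeros((80, 80), dtype=np.uint8))
        assert not mask.data.any()

    def test_window_larger_than_image(self):
        with pytest.raises(iq.ImageQuantError):
            iq.local_threshold_phansalkar(np.zeros((20, 20)), radius_px=15)

    def test_recovers_synthetic_fibers(self):
        img, truth = synth.gen_matrix_image(60, 25, n_small=10, n_large=0,
                                            seed=3, small_range_um=(5, 20))
        mask = iq.local_threshold_phansalkar(img.data)
        gt = truth.label_mask > 0
        inter = (mask.data & gt).sum()
        union = (mask.data | gt).sum()
        assert inter / union >= 0.7

    def test_dark_fibers_not_recovered(self):
        """Polarity contract: the method assumes bright-on-dark signal."""
        img, truth = synth.gen_matrix_image(60, 25, n_small=10, n_large=0,
                                            seed=3, small_range_um=(5, 20))
        inverted = (255 - img.data).astype(np.uint8)
        mask = iq.local_threshold_phansalkar(inverted)
        gt = truth.label_mask > 0
        inter = (mask.data & gt).sum()
        union = (mask.data | gt).sum()
        assert inter / union < 0.2


class TestGlobalThreshold:
    def test_threshold_arithmetic(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[0, 0] = 255
        img[5, 5] = 51
        img[6, 6] = 52
        mask = iq.global_threshold_minfrac(img, frac=0.20)
        assert not mask.data[5, 5]          # 51 is not above min + 0.2*range
        assert mask.data[6, 6]
        assert mask.data[0, 0]

    def test_frac_zero_keeps_all_nonminimal(self):
        img = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        mask = iq.global_threshold_minfrac(img, frac=0.0)
        assert mask.data.sum() == 3

    def test_frac_near_one_keeps_only_maxima(self):
        img = np.array([[0, 100], [254, 255]], dtype=np.uint8)
        mask = iq.global_threshold_minfrac(img, frac=0.999)
        assert mask.data.sum() == 1
        assert mask.data[1, 1]

    def test_constant_image_raises(self):
        with pytest.raises(iq.ImageQuantError):
            iq.global_threshold_minfrac(np.full((5, 5), 7, dtype=np.uint8))


# ---------------------------------------------------------------------------
# size sorting

class TestSizeSort:
    @staticmethod
    def _mask_with_line(length_um, ppu=17.4, shape=(800, 1200), row=100):
        data = np.zeros(shape, dtype=bool)
        n = int(round(length_um * ppu))
        data[row, 50:50 + n] = True
        return data

    def test_three_classes(self):
        ppu = 17.4
        data = (self._mask_with_line(3, row=100) |
                self._mask_with_line(20, row=300) |
                self._mask_with_line(60, row=500))
        classes = iq.size_sort(iq.BinaryMask(data, ppu))
        assert classes.noise.data[100].any()
        assert classes.small.data[300].any()
        assert classes.large.data[500].any()
        # partition: classes are disjoint and cover all foreground
        union = classes.noise.data | classes.small.data | classes.large.data
        assert (union == data).all()
        assert not (classes.noise.data & classes.small.data).any()
        assert not (classes.small.data & classes.large.data).any()

    def test_empty_mask(self):
        classes = iq.size_sort(iq.BinaryMask(np.zeros((20, 20), dtype=bool)))
        assert not classes.noise.data.any()
        assert not classes.small.data.any()
        assert not classes.large.data.any()

    def test_class_recovery_on_noiseless_render(self):
        img, truth = synth.gen_matrix_image(220, 60, n_small=25, n_large=3,
                                            seed=5, large_range_um=(45, 100),
                                            small_range_um=(5, 35))
        mask = iq.BinaryMask(truth.label_mask > 0, img.pixels_per_um)
        classes = iq.size_sort(mask)
        hits = 0
        total = len(truth.size_classes)
        for label, cls in zip(range(1, total + 1), truth.size_classes):
            sel = truth.label_mask == label
            got = ("large" if classes.large.data[sel].all()
                   else "small" if classes.small.data[sel].all() else "noise")
            hits += got == cls
        assert hits / total >= 0.95


# ---------------------------------------------------------------------------
# ML distribution / AP density

def _tissue(shape, ppu=17.4):
    return iq.BinaryMask(np.ones(shape, dtype=bool), ppu)


class TestMLDistribution:
    def test_uniform_signal_flat_profile(self):
        rng = np.random.default_rng(0)
        shape = (200, 600)
        signal = iq.BinaryMask(rng.random(shape) < 0.3, 17.4)
        prof = iq.ml_distribution(signal, _tissue(shape))
        nz = prof.values[prof.values > 0]
        assert signal.data.sum() > 1e4
        assert nz.max() / nz.min() < 1.5
        assert prof.values.sum() == pytest.approx(1.0)

    def test_signal_at_reference_row(self):
        shape = (100, 400)
        data = np.zeros(shape, dtype=bool)
        data[-1, :] = True                   # reference side = max row
        prof = iq.ml_distribution(iq.BinaryMask(data, 17.4), _tissue(shape))
        assert prof.values[0] == pytest.approx(1.0)

    def test_gradient_sign_recovered(self):
        img, truth = synth.gen_matrix_image(200, 50, n_small=40, n_large=0,
                                            seed=9, ml_gradient_slope=1.5,
                                            small_range_um=(5, 15))
        signal = iq.BinaryMask(truth.label_mask > 0, img.pixels_per_um)
        prof = iq.ml_distribution(signal, _tissue(signal.data.shape,
                                                  img.pixels_per_um))
        from scipy.stats import spearmanr
        rho, _ = spearmanr(prof.positions, prof.values)
        assert rho < 0   # denser toward relative position 0

    def test_mismatched_shapes_raise(self):
        with pytest.raises(iq.ImageQuantError):
            iq.ml_distribution(iq.BinaryMask(np.zeros((5, 5), bool)),
                               iq.BinaryMask(np.zeros((6, 6), bool)))


class TestAPDensity:
    def test_uniform_coverage(self):
        rng = np.random.default_rng(1)
        shape = (100, 3000)
        signal = iq.BinaryMask(rng.random(shape) < 0.3, 17.4)
        pos, dens = iq.ap_density(signal, _tissue(shape))
        assert np.allclose(dens, 0.3, atol=0.02)
        assert pos[0] == pytest.approx(25.0)
        assert np.allclose(np.diff(pos), 50.0)

    def test_zero_signal(self):
        shape = (50, 2000)
        signal = iq.BinaryMask(np.zeros(shape, dtype=bool), 17.4)
        _, dens = iq.ap_density(signal, _tissue(shape))
        assert np.allclose(dens, 0.0)

    def test_ap_ramp_sign(self):
        rng = np.random.default_rng(2)
        shape = (100, 4000)
        ramp = np.linspace(0.1, 0.5, shape[1])
        signal = iq.BinaryMask(rng.random(shape) < ramp[None, :], 17.4)
        _, dens = iq.ap_density(signal, _tissue(shape))
        assert dens[-1] > dens[0]


# ---------------------------------------------------------------------------
# spot metrics

class TestSpotMetrics:
    def test_single_pixel(self):
        frame = np.zeros((10, 10), dtype=bool)
        frame[4, 7] = True
        m = iq.spot_metrics([frame])
        assert m.widths[0] == 0.0 and m.heights[0] == 0.0

    def test_filled_rectangle_std(self):
        w, h = 21, 11
        frame = np.zeros((40, 40), dtype=bool)
        frame[5:5 + h, 3:3 + w] = True
        m = iq.spot_metrics([frame])
        assert m.widths[0] == pytest.approx(np.sqrt((w ** 2 - 1) / 12))
        assert m.heights[0] == pytest.approx(np.sqrt((h ** 2 - 1) / 12))

    def test_empty_frame_named_in_error(self):
        ok = np.ones((5, 5), dtype=bool)
        with pytest.raises(iq.ImageQuantError, match="frame 1"):
            iq.spot_metrics([ok, np.zeros((5, 5), dtype=bool)])

    def test_normalization(self):
        a = np.zeros((30, 30), dtype=bool)
        a[10:20, 10:20] = True
        b = np.zeros((30, 30), dtype=bool)
        b[12:18, 12:18] = True
        m = iq.spot_metrics([a, b])
        assert m.widths_norm[0] == 1.0
        assert m.widths_norm[1] < 1.0

    def test_intensity_scaling_invariance(self):
        """Rescaling intensities with a matched threshold leaves the
        binarized metrics unchanged."""
        series = synth.gen_spot_series(ml_shrink_fraction=0.3, n_frames=3,
                                       seed=4)
        masks_a = [f.data > 100 for f in series.frames]
        masks_b = [(f.data.astype(float) * 0.5) > 50 for f in series.frames]
        ma = iq.spot_metrics(masks_a)
        mb = iq.spot_metrics(masks_b)
        assert np.allclose(ma.widths, mb.widths)


# ---------------------------------------------------------------------------
# displacement fields

class TestDisplacement:
    @staticmethod
    def _noise_frame(shape=(200, 260), seed=0):
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter
        return gaussian_filter(rng.random(shape), 2.0)

    def test_identical_frames_zero_vectors(self):
        a = self._noise_frame()
        fld = iq.displacement_field(a, a, iw=40, sw=80, vs=30)
        v = fld.vectors[fld.valid]
        assert np.abs(v).max() < 0.25

    @pytest.mark.parametrize("shift", [(5, 0), (0, 7), (6, 4)])
    def test_exact_integer_translation(self, shift):
        a = self._noise_frame()
        b = np.roll(a, (shift[1], shift[0]), axis=(0, 1))
        fld = iq.displacement_field(a, b, iw=40, sw=80, vs=30)
        v = fld.vectors[fld.valid]
        med = np.median(v, axis=0)
        assert med[0] == pytest.approx(shift[0], abs=0.2)
        assert med[1] == pytest.approx(shift[1], abs=0.2)

    def test_multipass_translation(self):
        a = self._noise_frame(shape=(300, 360), seed=3)
        b = np.roll(a, (0, 9), axis=(0, 1))
        fld = iq.multipass_displacement(a, b)
        v = fld.vectors[fld.valid]
        med = np.median(v, axis=0)
        assert med[0] == pytest.approx(9.0, abs=0.3)
        assert med[1] == pytest.approx(0.0, abs=0.3)

    def test_flat_patch_invalid(self):
        a = np.zeros((200, 200))
        fld = iq.displacement_field(a, a, iw=40, sw=80, vs=40)
        assert not fld.valid.any()

    def test_iw_must_be_smaller(self):
        a = self._noise_frame()
        with pytest.raises(iq.ImageQuantError):
            iq.displacement_field(a, a, iw=80, sw=80, vs=30)

    def test_rose_histogram_direction(self):
        a = self._noise_frame()
        b = np.roll(a, 8, axis=1)           # +x shift
        fld = iq.displacement_field(a, b, iw=40, sw=80, vs=30)
        angles, counts = iq.rose_histogram([fld], nbins_angle=8)
        peak = angles[np.argmax(counts)]
        assert abs(peak) < np.pi / 8 + 1e-9


# ---------------------------------------------------------------------------
# circle fit

def pratt_eigen_oracle(points: np.ndarray):
    """Independent algebraic circle fit via the generalized eigenproblem."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    z = x * x + y * y
    A = np.column_stack([z, x, y, np.ones_like(x)])
    M = A.T @ A / len(pts)
    B = np.array([[0, 0, 0, -2.0],
                  [0, 1.0, 0, 0],
                  [0, 0, 1.0, 0],
                  [-2.0, 0, 0, 0]])
    vals, vecs = linalg.eig(M, B)
    vals = np.real(vals)
    good = np.where(vals > 1e-12)[0]
    k = good[np.argmin(vals[good])]
    a, b, c, d = np.real(vecs[:, k])
    cx, cy = -b / (2 * a), -c / (2 * a)
    r = np.sqrt(b * b + c * c - 4 * a * d) / (2 * abs(a))
    return (cx, cy), r


class TestPrattCircleFit:
    def test_exact_on_circle_points(self):
        t = np.array([0.1, 1.3, 2.9, 4.4])
        pts = np.column_stack([np.cos(t), np.sin(t)])
        (cx, cy), r = iq.pratt_circle_fit(pts)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert abs(cx) < 1e-12 and abs(cy) < 1e-12

    def test_collinear_points_raise(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(iq.ImageQuantError, match="collinear"):
            iq.pratt_circle_fit(pts)

    def test_too_few_points(self):
        with pytest.raises(iq.ImageQuantError, match="At least 3"):
            iq.pratt_circle_fit(np.array([[0.0, 0.0], [1.0, 0.0]]))

    def test_noisy_arc_matches_truth_and_oracle(self):
        pts, truth = synth.gen_circle_points(center=(40.0, -20.0),
                                             radius=100.0, n=30,
                                             angular_span=np.pi,
                                             noise_sd=0.5, seed=12)
        (cx, cy), r = iq.pratt_circle_fit(pts)
        assert r == pytest.approx(truth["radius"], rel=0.02)
        (ox, oy), orad = pratt_eigen_oracle(pts)
        assert r == pytest.approx(orad, abs=1e-6)
        assert cx == pytest.approx(ox, abs=1e-6)
        assert cy == pytest.approx(oy, abs=1e-6)

    def test_rigid_motion_equivariance(self):
        pts, _ = synth.gen_circle_points(radius=5.0, n=20,
                                         angular_span=2.0, noise_sd=0.05,
                                         seed=3)
        (cx, cy), r = iq.pratt_circle_fit(pts)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        shifted = pts @ R.T + [10.0, -4.0]
        (cx2, cy2), r2 = iq.pratt_circle_fit(shifted)
        assert r2 == pytest.approx(r, rel=1e-9)
        expected = np.array([cx, cy]) @ R.T + [10.0, -4.0]
        assert cx2 == pytest.approx(expected[0], abs=1e-9)
        assert cy2 == pytest.approx(expected[1], abs=1e-9)


# ---------------------------------------------------------------------------
# ratio gradient

class TestRatioGradient:
    def test_constant_ratio_profile_flat(self):
        a, b, truth = synth.gen_ratio_pair(ratio_profile=1.5, seed=6,
                                           fiber_level=100.0)
        profA, profB, profR = iq.ratio_gradient(a.data, b.data)
        assert np.allclose(profR.values, 1.0, atol=0.02)

    def test_linear_profile_binwise_truth(self):
        a, b, truth = synth.gen_ratio_pair(
            ratio_profile=lambda u: 1.0 + 1.5 * u, seed=7, fiber_level=90.0)
        _, _, profR = iq.ratio_gradient(a.data, b.data)
        expected = truth["bin_ratios_norm"]
        assert np.allclose(profR.values, expected, rtol=0.05)

    def test_saturated_channel_raises(self):
        a = np.full((50, 100), 255, dtype=np.uint8)
        b = np.full((50, 100), 100, dtype=np.uint8)
        with pytest.raises(iq.ImageQuantError):
            iq.ratio_gradient(a, b)

    def test_saturation_exclusion(self):
        a, b, truth = synth.gen_ratio_pair(ratio_profile=1.5, seed=8,
                                           fiber_level=100.0,
                                           saturation_fraction=0.02)
        _, _, profR = iq.ratio_gradient(a.data, b.data)
        assert np.allclose(profR.values, 1.0, atol=0.05)


# ---------------------------------------------------------------------------
# region means

class TestRegionMeans:
    def test_constant_image(self):
        img = np.full((30, 30), 7, dtype=np.uint8)
        regions = [np.array([[2, 2], [12, 2], [12, 12], [2, 12]])]
        assert iq.region_means(img, regions)[0] == pytest.approx(7.0)

    def test_half_bright_half_dark(self):
        img = np.zeros((20, 40), dtype=np.uint8)
        img[:, 20:] = 200
        left = np.array([[2, 2], [15, 2], [15, 15], [2, 15]])
        right = np.array([[24, 2], [38, 2], [38, 15], [24, 15]])
        means = iq.region_means(img, [left, right])
        assert means[0] == pytest.approx(0.0)
        assert means[1] == pytest.approx(200.0)

    def test_overlapping_regions_independent(self):
        img = np.tile(np.arange(30, dtype=np.uint8), (30, 1))
        a = np.array([[0, 0], [20, 0], [20, 20], [0, 20]])
        b = np.array([[10, 10], [29, 10], [29, 29], [10, 29]])
        means = iq.region_means(img, [a, b])
        assert means[0] != means[1]

    def test_empty_region_raises(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(iq.ImageQuantError):
            iq.region_means(img, [np.array([[1.0, 1.0], [1.0, 1.0],
                                            [1.0, 1.0]])])
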