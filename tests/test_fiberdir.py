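"""Image chain, orientation histograms and normal-curve fitting."""

import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from vocalfold.fiberdir import (
    DirectionalityHistogram,
    NormalFit,
    alignment_difference,
    analyze_sample,
    directionality_histogram,
    fit_normal,
    local_gradient_orientation,
    mean_filter,
    median_filter,
    normalize_intensity,
    otsu_threshold,
    remove_small_particles,
    saturate_stretch,
)
from vocalfold.synthetic import (
    FiberPhantomSpec,
    generate_fiber_phantom,
    kappa_from_angular_sd,
)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((10, 10), 7.0)
        np.testing.assert_array_equal(median_filter(img, 2), img)

    def test_hot_pixel_removed(self):
        img = np.zeros((11, 11))
        img[5, 5] = 100.0
        assert median_filter(img, 2).max() == 0.0

    def test_matches_neighborhood_sort_oracle(self, rng):
        img = rng.uniform(size=(5, 5))
        width = 1
        got = median_filter(img, width)
        # oracle: direct per-pixel sort with edge replication
        padded = np.pad(img, width, mode="edge")
        for i in range(5):
            for j in range(5):
                window = padded[i : i + 2 * width + 1, j : j + 2 * width + 1]
                assert got[i, j] == pytest.approx(np.median(window))


class TestNormalizeAndStretch:
    def test_scaled_copies_identical_after_normalization(self, rng):
        img = rng.uniform(0.1, 1.0, size=(20, 20))
        a, b = normalize_intensity([img, 2.0 * img])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_reference_percentiles_equal(self, rng):
        imgs = [rng.uniform(0, v, size=(50, 50)) for v in (1.0, 3.7)]
        out = normalize_intensity(imgs, percentile=99.5)
        p1, p2 = (np.percentile(o, 99.5) for o in out)
        assert p1 == pytest.approx(p2, abs=1e-6)

    def test_stretch_saturates_top_fraction(self, rng):
        img = rng.uniform(size=(100, 100))
        out = saturate_stretch(img, 0.04)
        assert (out == 1.0).mean() == pytest.approx(0.04, abs=0.005)
        assert out.min() == pytest.approx(0.0, abs=1e-12)

    def test_zero_fraction_is_minmax(self, rng):
        img = rng.uniform(2.0, 5.0, size=(30, 30))
        out = saturate_stretch(img, 0.0)
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            saturate_stretch(np.ones((5, 5)), 0.04)


def _otsu_bruteforce(values, nbins=256):
    """Exhaustive between-class-variance argmax on the histogram."""
    counts, edges = np.histogram(values, bins=nbins)
    mids = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = None, -1.0
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * mids[:k]).sum() / w0
        m1 = (counts[k:] * mids[k:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, mids[k - 1 : k + 1].mean()
    return best_t


class TestOtsu:
    def test_two_level_threshold_between_levels(self):
        img = np.zeros((20, 20))
        img[:6] = 200.0
        img[6:] = 50.0
        mask = otsu_threshold(img, ignore_black=False)
        assert mask[:6].all() and not mask[6:].any()

    def test_matches_bruteforce_between_class_variance(self, rng):
        img = rng.choice([30, 80, 120, 200.0], size=(40, 40), p=[0.4, 0.3, 0.2, 0.1])
        img += rng.uniform(-5, 5, img.shape)
        t_oracle = _otsu_bruteforce(img.ravel())
        mask = otsu_threshold(img, ignore_black=False)
        # mask from the oracle threshold agrees (thresholds can differ inside
        # the same empty histogram gap without changing the mask)
        np.testing.assert_array_equal(mask, img > t_oracle)

    def test_ignore_black_invariant_to_zero_border(self, rng):
        img = rng.choice([50, 200.0], size=(30, 30))
        padded = np.pad(img, 10, constant_values=0.0)
        m1 = otsu_threshold(img, ignore_black=True)
        m2 = otsu_threshold(padded, ignore_black=True)
        np.testing.assert_array_equal(m2[10:-10, 10:-10], m1)
        assert not m2[:10].any()


def _bfs_label_filter(mask, min_area_px):
    """Independent oracle: BFS component labeling + area rule."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    h, w = mask.shape
    for i0 in range(h):
        for j0 in range(w):
            if mask[i0, j0] and not seen[i0, j0]:
                stack, comp = [(i0, j0)], []
                seen[i0, j0] = True
                while stack:
                    i, j = stack.pop()
                    comp.append((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (
                                0 <= ni < h and 0 <= nj < w
                                and mask[ni, nj] and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                if len(comp) >= min_area_px:
                    for i, j in comp:
                        out[i, j] = True
    return out


class TestParticleFilter:
    def test_exact_threshold_area_retained(self):
        # 50 um^2 at 1 um/px = 50 px: a 5x10 block survives (inclusive)
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:7, 3:13] = True
        out = remove_small_particles(mask, 50.0, pixel_size_um=1.0)
        np.testing.assert_array_equal(out, mask)

    def test_specks_removed(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[np.arange(0, 30, 5), np.arange(0, 30, 5)] = True  # isolated pixels
        out = remove_small_particles(mask, 50.0, pixel_size_um=0.5)
        assert not out.any()

    def test_matches_bfs_oracle(self, rng):
        mask = rng.uniform(size=(40, 40)) < 0.35
        pixel_size = 0.7
        min_area_px = 20.0 / pixel_size**2
        got = remove_small_particles(mask, 20.0, pixel_size)
        np.testing.assert_array_equal(got, _bfs_label_filter(mask, min_area_px))


class TestMeanFilter:
    def test_constant_unchanged(self):
        img = np.full((8, 8), 3.0)
        np.testing.assert_allclose(mean_filter(img, 3), img)

    def test_impulse_response_plateau(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = mean_filter(img, 1)
        np.testing.assert_allclose(out[3:6, 3:6], 1 / 9)
        assert out[0, 0] == 0.0

    def test_matches_convolution_oracle(self, rng):
        img = rng.uniform(size=(6, 6))
        width = 1
        got = mean_filter(img, width)
        padded = np.pad(img, width, mode="edge")
        for i in range(6):
            for j in range(6):
                window = padded[i : i + 3, j : j + 3]
                assert got[i, j] == pytest.approx(window.mean())


def _stripes(theta_deg, size=128, period=8.0):
    """Sinusoidal stripes whose ridges run along theta_deg (y-up convention)."""
    rr, cc = np.mgrid[0:size, 0:size]
    th = np.radians(theta_deg)
    # coordinate across the stripes: unit normal to the ridge direction
    u = cc * np.sin(th) + rr * np.cos(th)
    return 0.5 + 0.5 * np.cos(2 * np.pi * u / period)


class TestLocalGradientOrientation:
    def test_vertical_stripes_orientation_90(self):
        img = _stripes(90.0)
        orient = local_gradient_orientation(img)
        vals = orient[20:-20, 20:-20]
        vals = vals[np.isfinite(vals)]
        assert np.median(vals) == pytest.approx(90.0, abs=1.0)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 45.0, 120.0])
    def test_stripe_angles_recovered(self, theta):
        orient = local_gradient_orientation(_stripes(theta))
        vals = orient[20:-20, 20:-20]
        vals = vals[np.isfinite(vals)]
        d = (vals - theta + 90) % 180 - 90
        assert np.abs(np.median(d)) < 1.5

    def test_rotation_equivariance(self):
        img = _stripes(0.0, size=200)
        rot = sk_rotate(img, 45.0, resize=False)  # CCW in y-up display terms
        o = local_gradient_orientation(rot)[60:-60, 60:-60]
        vals = o[np.isfinite(o)]
        d = (vals - 45.0 + 90) % 180 - 90
        assert np.abs(np.median(d)) < 2.0

    def test_range_and_flat_image_undefined(self):
        orient = local_gradient_orientation(_stripes(70.0))
        vals = orient[np.isfinite(orient)]
        assert (vals >= 0).all() and (vals < 180).all()
        flat = local_gradient_orientation(np.ones((10, 10)))
        assert np.isnan(flat).all()


class TestHistogram:
    def test_single_orientation_single_bin(self):
        orient = np.full((10, 10), 33.3)
        h = directionality_histogram(orient, bin_width_deg=2.0)
        assert (h.counts > 0).sum() == 1
        assert h.n_pixels == 100

    def test_count_conservation_with_mask_and_nans(self, rng):
        orient = rng.uniform(0, 180, size=(30, 30))
        orient[rng.uniform(size=(30, 30)) < 0.2] = np.nan
        mask = rng.uniform(size=(30, 30)) < 0.5
        h = directionality_histogram(orient, mask)
        assert h.n_pixels == np.isfinite(orient[mask]).sum()

    def test_two_orientation_mass_ratio(self):
        orient = np.concatenate([np.full(600, 30.0), np.full(400, 120.0)])
        h = directionality_histogram(orient.reshape(20, 50))
        top = np.argsort(h.counts)[-2:]
        ratio = h.counts[top[1]] / h.counts[top[0]]
        assert ratio == pytest.approx(1.5, rel=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            directionality_histogram(np.full((5, 5), 10.0), np.zeros((5, 5), bool))


def _wrapped_normal_hist(mu, sigma, n=200_000, seed=0, bin_width=2.0):
    rng = np.random.default_rng(seed)
    vals = (mu + sigma * rng.standard_normal(n)) % 180.0
    counts, edges = np.histogram(vals, bins=int(180 / bin_width), range=(0, 180))
    return DirectionalityHistogram((edges[:-1] + edges[1:]) / 2, counts.astype(float))


class TestFitNormal:
    def test_wrapped_normal_recovery(self):
        h = _wrapped_normal_hist(30.0, 20.0)
        fit = fit_normal(h)
        assert fit.alignment_deg == pytest.approx(30.0, abs=2.0)
        assert fit.dispersion_deg == pytest.approx(20.0, rel=0.1)
        assert fit.gof > 0.95

    def test_symmetric_at_zero(self):
        h = _wrapped_normal_hist(0.0, 15.0, seed=3)
        fit = fit_normal(h)
        d = min(fit.alignment_deg, 180 - fit.alignment_deg)
        assert d < 2.0

    def test_peak_near_domain_edge_wraps(self):
        h = _wrapped_normal_hist(175.0, 10.0, seed=5)
        fit = fit_normal(h)
        d = abs(fit.alignment_deg - 175.0)
        assert min(d, 180 - d) < 2.0

    def test_near_uniform_low_gof(self, rng):
        counts = rng.poisson(1000, size=90).astype(float)
        fit = fit_normal(DirectionalityHistogram(np.arange(1, 180, 2.0), counts))
        assert fit.gof < 0.5

    def test_too_few_bins_raises(self):
        h = DirectionalityHistogram(
            np.arange(1, 180, 2.0), np.zeros(90)
        )
        with pytest.raises(ValueError):
            fit_normal(h)


class TestAlignmentDifference:
    def _fit(self, deg):
        return NormalFit(deg, 10.0, 0.9, 1.0, 0.0)

    @pytest.mark.parametrize(
        "a, b, expected", [(50, 50, 0.0), (10, 175, 15.0), (0, 90, 90.0)]
    )
    def test_circular_distance(self, a, b, expected):
        assert alignment_difference(self._fit(a), self._fit(b)) == expected


class TestAnalyzeSample:
    def test_identical_channels_zero_difference(self):
        spec = FiberPhantomSpec(
            image_size_px=384, n_fibers=150, kappa=kappa_from_angular_sd(15), seed=2
        )
        collagen, _, _ = generate_fiber_phantom(spec)
        res = analyze_sample(collagen, collagen.copy(), spec.pixel_size_um)
        assert res["alignment_difference_deg"] == pytest.approx(0.0, abs=1e-9)
        assert res["dispersion_collagen"] == pytest.approx(
            res["dispersion_elastin"], rel=1e-9
        )

    def test_phantom_pair_recovery(self):
        spec = FiberPhantomSpec(
            channel_offset_deg=4.0,
            kappa=kappa_from_angular_sd(20),
            mean_orientation_deg=70.0,
            seed=8,
        )
        collagen, elastin, truth = generate_fiber_phantom(spec)
        res = analyze_sample(collagen, elastin, spec.pixel_size_um)
        assert res["alignment_difference_deg"] == pytest.approx(4.0, abs=2.0)
        assert res["dispersion_collagen"] == pytest.approx(20.0, rel=0.25)
        assert res["gof_collagen"] > 0.9

    def test_output_schema(self):
        spec = FiberPhantomSpec(image_size_px=384, n_fibers=150, seed=3)
        collagen, elastin, _ = generate_fiber_phantom(spec)
        res = analyze_sample(collagen, elastin, spec.pixel_size_um)
        assert set(res) == {
            "alignment_difference_deg",
            "alignment_collagen_deg",
            "alignment_elastin_deg",
            "gof_collagen",
            "gof_elastin",
            "dispersion_collagen",
            "dispersion_elastin",
        }

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError):
            analyze_sample(np.ones((10, 10)), np.ones((12, 12)), 0.5)

    def test_rotation_equivariance_of_pipeline(self):
        spec = FiberPhantomSpec(
            kappa=kappa_from_angular_sd(15), mean_orientation_deg=30.0, seed=4
        )
        collagen, elastin, _ = generate_fiber_phantom(spec)
        res0 = analyze_sample(collagen, elastin, spec.pixel_size_um)
        theta = 30.0
        crop = slice(150, -150)
        rot_c = sk_rotate(collagen, theta, resize=False)[crop, crop]
        rot_e = sk_rotate(elastin, theta, resize=False)[crop, crop]
        res1 = analyze_sample(rot_c, rot_e, spec.pixel_size_um)
        d = (
            res1["alignment_collagen_deg"]
            - res0["alignment_collagen_deg"]
            - theta + 90
        ) % 180 - 90
        assert abs(d) < 2.0
        assert res1["alignment_difference_deg"] == pytest.approx(
            res0["alignment_difference_deg"], abs=2.0
        )


def test_plot_directionality_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    h = _wrapped_normal_hist(40.0, 15.0, n=50_000, seed=2)
    fit = fit_normal(h)
    from vocalfold.fiberdir import plot_directionality

    ax = plot_directionality(h, fit)
    ax.figure.savefig(tmp_path / "hist.png")
    assert (tmp_path / "hist.png").stat().st_size > 0
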