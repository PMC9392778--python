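"""Variational segmentation: edge map, region/location terms, solver."""

import numpy as np
import pytest

from hybridseg import (
    MarkerSet,
    PhantomSpec,
    VariationalParams,
    Volume,
    binarize,
    compute_edge_map,
    distance_prior,
    generate_phantom,
    intensity_model,
    segment_multiclass,
    solve_segmentation,
)
from hybridseg.variational import DegenerateStatisticsError

from conftest import dice_of


def trace_is_monotone(trace, rel=1e-6):
    t = np.asarray(trace)
    return bool(np.all(np.diff(t) <= rel * np.abs(t[:-1]) + 1e-9))


class TestEdgeMap:
    def test_constant_volume_gives_unit_indicator(self):
        g = compute_edge_map(Volume(np.full((20, 20, 20), 0.3))).g
        assert np.allclose(g, 1.0)
        assert g.min() > 0

    def test_minimum_sits_on_the_sphere_boundary(self, sphere, sphere_volume):
        g = compute_edge_map(sphere_volume).g
        z, y, x = np.mgrid[:32, :32, :32]
        dist_to_surface = np.abs(np.sqrt((z - 16.0) ** 2 + (y - 16) ** 2 + (x - 16) ** 2) - 10.0)
        assert dist_to_surface[np.unravel_index(np.argmin(g), g.shape)] <= 1.0

    def test_contrast_enhancement_deepens_weak_edges(self, sphere):
        vol = Volume(np.where(sphere, 0.3, 0.2).astype(float))
        g_on = compute_edge_map(vol, VariationalParams(enhance_contrast=True)).g
        g_off = compute_edge_map(vol, VariationalParams(enhance_contrast=False)).g
        assert g_on.min() < g_off.min()

    def test_range_is_half_open_unit_interval(self, sphere_volume):
        g = compute_edge_map(sphere_volume).g
        assert 0 < g.min() and g.max() <= 1.0


class TestIntensityModel:
    def test_two_phase_sign_separates_regions_exactly(self, sphere, sphere_volume):
        markers = MarkerSet(inside=[(16, 16, 16)], outside=[(1, 1, 1)])
        r, c_in, c_out = intensity_model(sphere_volume, markers)
        assert np.all(r[sphere] < 0)
        assert np.all(r[~sphere] > 0)

    def test_midpoint_intensity_is_a_tie(self):
        img = np.full((20, 20, 20), 0.5)
        img[:10] = 0.8
        img[10:] = 0.2
        img[10, 10, 10] = 0.5
        markers = MarkerSet(inside=[(5, 10, 10)], outside=[(15, 10, 10)])
        r, c_in, c_out = intensity_model(Volume(img), markers)
        assert (c_in, c_out) == pytest.approx((0.8, 0.2))
        assert r[10, 10, 10] == pytest.approx(0.0, abs=1e-12)

    def test_coincident_statistics_raise(self):
        vol = Volume(np.full((20, 20, 20), 0.5))
        with pytest.raises(DegenerateStatisticsError):
            intensity_model(vol, MarkerSet(inside=[(5, 5, 5)], outside=[(5, 5, 5)]))

    def test_thrombus_markers_classify_thrombus_negative(self):
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            lumen_radius_mm=3.0,
            thrombus_outer_radius_mm=8.0,
            centerline_amplitude_mm=0.0,
            noise_sigma=0.02,
            dropout_fraction=0.0,
            texture_amplitude=0.0,
            rng_seed=4,
        )
        ph = generate_phantom(spec)
        inside = [tuple(p) for p in np.argwhere(ph.truth.data == 1)[::500][:4]]
        r, _, _ = intensity_model(ph.volume, MarkerSet(inside=inside))
        frac = (r[ph.truth.data == 1] < 0).mean()
        assert frac >= 0.95


class TestDistancePrior:
    def test_zero_at_marker(self, sphere_volume):
        d = distance_prior(MarkerSet(inside=[(16, 16, 16)]), sphere_volume)
        assert d[16, 16, 16] == 0.0
        assert d.min() >= 0 and d.max() <= 1.0

    def test_radially_monotone_from_single_marker(self, sphere_volume):
        d = distance_prior(MarkerSet(inside=[(16, 16, 16)]), sphere_volume)
        line = d[16, 16, 16:]
        assert np.all(np.diff(line) >= 0)

    def test_two_markers_equal_min_of_singletons(self, sphere_volume):
        m1, m2 = (10, 10, 10), (22, 22, 22)
        d1 = distance_prior(MarkerSet(inside=[m1]), sphere_volume)
        d2 = distance_prior(MarkerSet(inside=[m2]), sphere_volume)
        d12 = distance_prior(MarkerSet(inside=[m1, m2]), sphere_volume)
        # both normalized by their own 95th percentile: compare unnormalized shape
        from scipy import ndimage

        seed = np.zeros(sphere_volume.shape, dtype=bool)
        seed[m1] = seed[m2] = True
        raw = ndimage.distance_transform_edt(~seed, sampling=sphere_volume.spacing)
        p95 = np.percentile(raw, 95)
        assert np.allclose(d12, np.clip(raw / p95, 0, 1))

    def test_marker_outside_grid_raises(self, sphere_volume):
        with pytest.raises(ValueError, match="marker"):
            distance_prior(MarkerSet(inside=[(99, 0, 0)]), sphere_volume)


class TestSolver:
    def test_high_contrast_sphere_recovery(self, sphere, sphere_volume, center_marker):
        seg = solve_segmentation(sphere_volume, center_marker)
        mask = binarize(seg).data.astype(bool)
        assert dice_of(mask, sphere) >= 0.98
        assert trace_is_monotone(seg.energy_trace)

    def test_low_contrast_noisy_sphere_recovery(self, sphere, center_marker):
        rng = np.random.default_rng(0)
        img = np.clip(np.where(sphere, 0.3, 0.2) + rng.normal(0, 0.05, sphere.shape), 0, 1)
        seg = solve_segmentation(Volume(img), center_marker)
        assert dice_of(binarize(seg).data, sphere) >= 0.90
        assert trace_is_monotone(seg.energy_trace)

    def test_zero_weights_keep_u_constant(self, sphere_volume, center_marker):
        params = VariationalParams(lambda_intensity=0.0, mu_distance=0.0)
        seg = solve_segmentation(sphere_volume, center_marker, params)
        assert np.ptp(seg.u) <= params.tol

    def test_nonconvergence_is_flagged_not_raised(self, sphere, center_marker):
        rng = np.random.default_rng(1)
        img = np.clip(np.where(sphere, 0.3, 0.2) + rng.normal(0, 0.05, sphere.shape), 0, 1)
        params = VariationalParams(max_iters=3, tol=1e-12)
        seg = solve_segmentation(Volume(img), center_marker, params)
        assert seg.converged is False

    def test_affine_intensity_rescaling_is_neutralized_by_windowing(
        self, sphere, sphere_volume, center_marker
    ):
        from hybridseg import window_and_crop

        seg_a = solve_segmentation(sphere_volume, center_marker)
        raw = Volume(200.0 + 600.0 * sphere_volume.data, intensity_units="raw")
        renorm = window_and_crop(raw, window=(200.0, 800.0))
        seg_b = solve_segmentation(renorm, center_marker)
        assert np.allclose(seg_a.u, seg_b.u, atol=1e-6)

    def test_translation_equivariance_in_the_interior(self, sphere):
        img = np.where(sphere, 0.8, 0.2).astype(float)
        shift = (2, 3, 1)
        seg_a = solve_segmentation(Volume(img), MarkerSet(inside=[(16, 16, 16)]))
        seg_b = solve_segmentation(
            Volume(np.roll(img, shift, (0, 1, 2))),
            MarkerSet(inside=[(18, 19, 17)]),
        )
        rolled = np.roll(seg_a.u, shift, (0, 1, 2))
        core = (slice(6, 26),) * 3
        assert np.allclose(seg_b.u[core], rolled[core], atol=5e-2)

    def test_stronger_location_weight_never_grows_the_mask(self, sphere, center_marker):
        img = Volume(np.where(sphere, 0.3, 0.2).astype(float))
        vols = []
        for mu in (0.0, 1.0, 4.0):
            params = VariationalParams(mu_distance=mu, tol=1e-6, max_iters=1000)
            seg = solve_segmentation(img, center_marker, params)
            vols.append(int(binarize(seg).data.sum()))
        assert vols[0] + 5 >= vols[1] + 5 >= vols[2]  # non-increasing, small solver slack


class TestBinarize:
    def test_constant_relaxations(self):
        from hybridseg.variational import SoftSegmentation

        ones = SoftSegmentation(np.ones((4, 4, 4)), (1, 1, 1))
        zeros = SoftSegmentation(np.zeros((4, 4, 4)), (1, 1, 1))
        assert binarize(ones).data.all()
        assert not binarize(zeros).data.any()

    def test_exact_threshold_is_foreground(self):
        from hybridseg.variational import SoftSegmentation

        u = np.zeros((4, 4, 4))
        u[1, 1, 1] = 0.5
        assert binarize(SoftSegmentation(u, (1, 1, 1)), theta=0.5).data[1, 1, 1] == 1


class TestMulticlass:
    @pytest.fixture(scope="class")
    def phantom(self):
        return generate_phantom(
            PhantomSpec(
                grid_shape=(32, 32, 32),
                lumen_radius_mm=3.0,
                thrombus_outer_radius_mm=8.0,
                centerline_amplitude_mm=0.0,
                noise_sigma=0.02,
                dropout_fraction=0.0,
                texture_amplitude=0.0,
                rng_seed=11,
            )
        )

    def markers(self, phantom):
        return {
            1: MarkerSet(inside=[(16, 16, 10)]),  # thrombus ring
            2: MarkerSet(inside=[(16, 16, 16)]),  # lumen core
        }

    def test_per_class_recovery(self, phantom):
        mask, _ = segment_multiclass(phantom.volume, self.markers(phantom))
        for lab in (1, 2):
            assert dice_of(mask.data == lab, phantom.truth.data == lab) >= 0.9

    def test_identical_markers_tie_to_lower_label(self, phantom):
        mk = MarkerSet(inside=[(16, 16, 16)])
        mask, segs = segment_multiclass(phantom.volume, {1: mk, 2: mk})
        assert np.array_equal(segs[1].u, segs[2].u)
        assert set(np.unique(mask.data)) <= {0, 1}

    def test_whole_mask_is_union_of_classes(self, phantom):
        mask, segs = segment_multiclass(phantom.volume, self.markers(phantom))
        params = VariationalParams()
        union = np.zeros(mask.shape, dtype=bool)
        for seg in segs.values():
            union |= seg.u >= params.theta
        assert np.array_equal(mask.data > 0, union)

    def test_missing_markers_raise(self, phantom):
        with pytest.raises(ValueError):
            segment_multiclass(phantom.volume, {})
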