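"""Camouflage metric behaviour: geometry, GabRat, histogram distances, granularity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camoseek.image_io import compose_scene
from camoseek.metrics import (
    EnergySpectrum,
    MetricConfig,
    MetricError,
    DOG_SIGMA_PER_SCALE,
    body_length,
    camo_profile,
    colour_map_diff,
    colour_mean_dist,
    fit_circle,
    gabrat,
    luminance_dist_diff,
    pattern_energy_diff,
    pattern_energy_spectrum,
    surround_region,
)
from camoseek.image_io import CalibratedImage, mask_from_region
from camoseek.synth import BackgroundGeneratorParams, CrabGeneratorParams, make_background, make_crab


def _kasa_oracle(pts):
    """Independent circle fit: solve the Kasa normal equations directly."""
    x, y = pts[:, 0], pts[:, 1]
    M = np.array(
        [
            [np.sum(x * x), np.sum(x * y), np.sum(x)],
            [np.sum(x * y), np.sum(y * y), np.sum(y)],
            [np.sum(x), np.sum(y), len(x)],
        ]
    )
    v = np.array([np.sum(x * (x * x + y * y)), np.sum(y * (x * x + y * y)), np.sum(x * x + y * y)])
    a, b, c = np.linalg.solve(M, np.array([v[0] / 1.0, v[1], v[2]]) / 1.0)
    # a = 2cx, b = 2cy, c = r^2 - cx^2 - cy^2
    cx, cy = a / 2.0, b / 2.0
    return 2.0 * np.sqrt(c + cx * cx + cy * cy)


class TestBodyLength:
    def test_perfect_circle_self_fit(self):
        th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pts = np.column_stack([10 + 50 * np.cos(th), -3 + 50 * np.sin(th)])
        assert fit_circle(pts)[2] == pytest.approx(50.0, abs=1e-9)

    @pytest.mark.parametrize(
        "outline",
        [
            np.column_stack(
                [60 * np.cos(np.linspace(0, 2 * np.pi, 300, endpoint=False)),
                 40 * np.sin(np.linspace(0, 2 * np.pi, 300, endpoint=False))]
            ),
            np.array(
                [[t, 0] for t in np.linspace(0, 80, 30)]
                + [[80, t] for t in np.linspace(0, 80, 30)]
                + [[t, 80] for t in np.linspace(80, 0, 30)]
                + [[0, t] for t in np.linspace(80, 0, 30)]
            ),
        ],
        ids=["ellipse", "square"],
    )
    def test_matches_independent_kasa_oracle(self, outline):
        _, _, r = fit_circle(outline)
        assert 2 * r == pytest.approx(_kasa_oracle(outline), rel=1e-9)

    def test_collinear_outline_rejected(self):
        pts = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 10, 20)])
        with pytest.raises(MetricError):
            fit_circle(pts)

    def test_regular_crab_diameter(self):
        img, mask = make_crab(
            CrabGeneratorParams(body_radius=30, irregularity=0.0), rng=np.random.default_rng(0)
        )
        assert body_length(mask) == pytest.approx(60.0, abs=1.0)


class TestSurroundRegion:
    def test_annulus_area(self, uniform_background):
        img, mask = make_crab(
            CrabGeneratorParams(body_radius=20, irregularity=0.0), rng=np.random.default_rng(1)
        )
        scene = compose_scene(uniform_background, img, mask, position=(100, 100), rotation_deg=0)
        blen = body_length(scene.mask_in_scene)
        ring = surround_region(scene)
        r = blen / 2.0
        expect = np.pi * ((r + blen) ** 2 - r**2)
        assert ring.sum() == pytest.approx(expect, rel=0.02)

    def test_clipped_at_frame_edge(self, uniform_background):
        img, mask = make_crab(
            CrabGeneratorParams(body_radius=20, irregularity=0.0), rng=np.random.default_rng(1)
        )
        scene = compose_scene(uniform_background, img, mask, position=(30, 30), rotation_deg=0)
        ring = surround_region(scene)
        assert ring.shape == uniform_background.shape  # clipped by construction
        assert not (ring & scene.mask_in_scene.region).any()

    def test_translation_invariant_on_uniform_field(self, uniform_background):
        img, mask = make_crab(
            CrabGeneratorParams(body_radius=18, irregularity=0.05, base_colour=(40, 2, 2)),
            rng=np.random.default_rng(2),
        )
        vals = []
        for pos in [(70, 70), (130, 110)]:
            scene = compose_scene(uniform_background, img, mask, position=pos, rotation_deg=0)
            ring = surround_region(scene)
            vals.append(
                colour_mean_dist(
                    np.dstack([scene.composited.A, scene.composited.B])[scene.mask_in_scene.region],
                    np.dstack([scene.composited.A, scene.composited.B])[ring],
                )
            )
        assert vals[0] == pytest.approx(vals[1], rel=1e-6)


@pytest.fixture(scope="module")
def paired_scenes(uniform_background):
    """Same body, same placement: solid vs high-contrast bars crossing the outline."""
    kw = dict(body_radius=24, irregularity=0.0, base_colour=(30.0, 0.0, 0.0))
    solid, m1 = make_crab(CrabGeneratorParams(**kw), rng=np.random.default_rng(3))
    bars, m2 = make_crab(
        CrabGeneratorParams(**kw, marking_style="bars-crossing-outline", marking_contrast=35, marking_scale=8),
        rng=np.random.default_rng(3),
    )
    s_solid = compose_scene(uniform_background, solid, m1, position=(100, 100), rotation_deg=0)
    s_bars = compose_scene(uniform_background, bars, m2, position=(100, 100), rotation_deg=0)
    return s_solid, s_bars


class TestGabrat:
    def test_uniform_target_on_identical_background_is_zero(self, uniform_background):
        base = tuple(
            [uniform_background.L[0, 0], uniform_background.A[0, 0], uniform_background.B[0, 0]]
        )
        img, mask = make_crab(
            CrabGeneratorParams(body_radius=24, irregularity=0.0, base_colour=base),
            rng=np.random.default_rng(4),
        )
        scene = compose_scene(uniform_background, img, mask, position=(100, 100), rotation_deg=0)
        assert gabrat(scene.composited.L, scene.mask_in_scene, 3.0) == 0.0

    def test_outline_crossing_bars_raise_disruption(self, paired_scenes):
        s_solid, s_bars = paired_scenes
        g_solid = gabrat(s_solid.composited.L, s_solid.mask_in_scene, 3.0)
        g_bars = gabrat(s_bars.composited.L, s_bars.mask_in_scene, 3.0)
        assert 0.0 <= g_solid <= 1.0 and 0.0 <= g_bars <= 1.0
        assert g_bars > g_solid

    def test_global_offset_invariance(self, paired_scenes):
        _, s_bars = paired_scenes
        g = gabrat(s_bars.composited.L, s_bars.mask_in_scene, 3.0)
        g_off = gabrat(s_bars.composited.L + 17.0, s_bars.mask_in_scene, 3.0)
        assert g_off == pytest.approx(g, abs=1e-9)

    def test_traversal_direction_and_start_invariance(self, paired_scenes):
        from camoseek.image_io import TargetMask

        _, s_bars = paired_scenes
        m = s_bars.mask_in_scene
        g = gabrat(s_bars.composited.L, m, 3.0)
        rolled = TargetMask(m.region, m.alpha, np.roll(m.outline, 57, axis=0))
        reversed_ = TargetMask(m.region, m.alpha, m.outline[::-1])
        assert gabrat(s_bars.composited.L, rolled, 3.0) == pytest.approx(g, abs=1e-6)
        assert gabrat(s_bars.composited.L, reversed_, 3.0) == pytest.approx(g, abs=1e-6)

    def test_invalid_sigma(self, paired_scenes):
        _, s_bars = paired_scenes
        with pytest.raises(MetricError):
            gabrat(s_bars.composited.L, s_bars.mask_in_scene, -1.0)


class TestHistogramDistances:
    def test_identical_sets_zero(self, rng):
        v = rng.uniform(0, 100, 1000)
        assert luminance_dist_diff(v, v.copy()) == 0.0
        ab = rng.uniform(-50, 50, (500, 2))
        assert colour_map_diff(ab, ab.copy()) == 0.0

    def test_disjoint_supports_give_two(self):
        assert luminance_dist_diff(np.full(100, 5.0), np.full(100, 95.0)) == 2.0
        assert colour_map_diff(np.full((50, 2), -40.0), np.full((50, 2), 40.0)) == 2.0

    def test_half_overlap_oracle(self, rng):
        # uniform L on [0,50] vs [25,75]: half the mass overlaps -> distance 1
        a = rng.uniform(0, 50, 100_000)
        b = rng.uniform(25, 75, 100_000)
        assert luminance_dist_diff(a, b) == pytest.approx(1.0, abs=0.02)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(0, 30, (300, 2))
        b = r.normal(10, 20, (300, 2))
        d1, d2 = colour_map_diff(a, b), colour_map_diff(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 2.0
        l1 = luminance_dist_diff(np.abs(a[:, 0]), np.abs(b[:, 0]))
        assert 0.0 <= l1 <= 2.0

    def test_empty_set_rejected(self):
        with pytest.raises(MetricError):
            luminance_dist_diff(np.array([]), np.array([1.0]))
        with pytest.raises(MetricError):
            colour_map_diff(np.empty((0, 2)), np.ones((3, 2)))

    def test_out_of_range_values_clip_into_edge_bins(self):
        # values at +/-150 land in the edge bins rather than being dropped
        d = colour_map_diff(np.full((10, 2), 150.0), np.full((10, 2), 99.9))
        assert d == 0.0


class TestColourMeanDist:
    def test_three_four_five(self):
        a = np.array([[10.0, 20.0]] * 4)
        b = np.array([[13.0, 24.0]] * 7)
        assert colour_mean_dist(a, b) == pytest.approx(5.0, abs=1e-12)

    def test_shuffle_invariance(self, rng):
        a = rng.normal(size=(100, 2))
        b = rng.normal(size=(100, 2))
        d = colour_mean_dist(a, b)
        assert colour_mean_dist(rng.permutation(a), b) == pytest.approx(d, abs=1e-12)


class TestPatternEnergy:
    def test_uniform_patch_all_zero(self):
        spec = pattern_energy_spectrum(np.full((128, 128), 42.0), np.ones((128, 128), bool))
        assert np.all(spec.energy == 0.0)

    def test_amplitude_linearity(self, rng):
        img = rng.standard_normal((128, 128))
        region = np.ones((128, 128), bool)
        e1 = pattern_energy_spectrum(img, region).energy
        e3 = pattern_energy_spectrum(3.0 * img, region).energy
        assert np.allclose(e3, 3.0 * e1, rtol=1e-9)

    @pytest.mark.parametrize("wavelength", [8.0, 16.0, 32.0])
    def test_sinusoid_peaks_at_analytic_band(self, wavelength):
        scales = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
        xx = np.arange(256)
        img = np.tile(np.sin(2 * np.pi * xx / wavelength), (256, 1))
        spec = pattern_energy_spectrum(img, np.ones((256, 256), bool), scales=scales)

        # analytic oracle: DoG amplitude response at frequency 1/wavelength
        def response(s):
            sig = DOG_SIGMA_PER_SCALE * s
            f = 1.0 / wavelength
            return np.exp(-2 * np.pi**2 * sig**2 * f**2) - np.exp(
                -2 * np.pi**2 * (2 * sig) ** 2 * f**2
            )

        analytic_peak = scales[np.argmax([response(s) for s in scales])]
        assert spec.scales[np.argmax(spec.energy)] == analytic_peak == wavelength

    def test_white_noise_positive_at_all_scales(self, rng):
        spec = pattern_energy_spectrum(rng.standard_normal((128, 128)), np.ones((128, 128), bool))
        assert np.all(spec.energy > 0)

    def test_region_too_small_rejected(self):
        region = np.zeros((64, 64), bool)
        region[0, 0] = True
        with pytest.raises(MetricError):
            pattern_energy_spectrum(np.zeros((64, 64)), region)

    def test_diff_is_l1_metric(self, rng):
        scales = np.array([2.0, 4.0, 8.0])
        specs = [EnergySpectrum(scales, np.abs(rng.normal(size=3))) for _ in range(3)]
        a, b, c = specs
        assert pattern_energy_diff(a, a) == 0.0
        assert pattern_energy_diff(a, c) <= pattern_energy_diff(a, b) + pattern_energy_diff(b, c) + 1e-12
        zero = EnergySpectrum(scales, np.zeros(3))
        assert pattern_energy_diff(a, zero) == pytest.approx(a.energy.sum())
        with pytest.raises(MetricError):
            pattern_energy_diff(a, EnergySpectrum(np.array([2.0, 4.0]), np.zeros(2)))


class TestCamoProfile:
    def test_crab_cropped_from_background_matches_well(self):
        # build the "crab" by cutting a disc out of the background itself
        rng = np.random.default_rng(11)
        bg = make_background(BackgroundGeneratorParams(), size=(256, 256), rng=rng)
        size = 61
        yy, xx = np.mgrid[0:size, 0:size]
        region = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= 24**2
        mask = mask_from_region(region)
        crop = CalibratedImage(
            L=bg.L[100 : 100 + size, 100 : 100 + size].copy(),
            A=bg.A[100 : 100 + size, 100 : 100 + size].copy(),
            B=bg.B[100 : 100 + size, 100 : 100 + size].copy(),
        )
        scene = compose_scene(bg, crop, mask, position=(130, 130), rotation_deg=0)
        prof = camo_profile(scene)
        # a patch of the background is a near-perfect statistical match
        assert prof.colour_dist_background < 2.0
        assert prof.lum_diff_background < 0.5
        assert prof.pattern_diff_background < 3.0
        assert prof.gabrat_l < 0.6

    def test_crab_area_equals_mask_count(self, uniform_background):
        img, mask = make_crab(CrabGeneratorParams(body_radius=20), rng=np.random.default_rng(6))
        scene = compose_scene(uniform_background, img, mask, position=(100, 100), rotation_deg=0)
        prof = camo_profile(scene)
        assert prof.crab_area == scene.mask_in_scene.region.sum()

    def test_stationarity_two_placements_close(self):
        # homogeneous texture: metric vector barely depends on placement
        rng = np.random.default_rng(12)
        bg = make_background(
            BackgroundGeneratorParams(dominant_grain=4.0, lum_amplitude=6.0), size=(256, 256), rng=rng
        )
        img, mask = make_crab(
            CrabGeneratorParams(body_radius=22, irregularity=0.05, base_colour=(50, -6, 10)),
            rng=np.random.default_rng(13),
        )
        p1 = camo_profile(compose_scene(bg, img, mask, position=(80, 80), rotation_deg=0))
        p2 = camo_profile(compose_scene(bg, img, mask, position=(170, 150), rotation_deg=0))
        for k in ("gabrat_l", "lum_diff_surround", "colour_map_diff_surround", "colour_dist_surround"):
            v1, v2 = getattr(p1, k), getattr(p2, k)
            assert v2 == pytest.approx(v1, rel=0.05, abs=0.3)
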