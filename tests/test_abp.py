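import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coda import CorrectionParams, GridSpec
from coda.abp import (ProjectionData, TargetSupport, attenuation_weight,
                      correct_projection, interpolate_background,
                      inverse_radon, radon_transform, run_abp, segment_target,
                      target_support)
from coda.grids import ImageGrid
from coda.recon import ReconImage


def disk_image(n=128, pitch=0.2, radius_mm=4.0, value=1.0, center=(0.0, 0.0)):
    img = ImageGrid(np.zeros((n, n)), pitch)
    X, Y = img.meshgrid()
    img.values[(X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius_mm ** 2] = value
    return img


class TestSegmentation:
    def test_two_level_image_splits_exactly(self):
        img = ImageGrid(np.where(np.arange(64 * 64).reshape(64, 64) % 7 < 2,
                                 0.9, 0.1), 0.2)
        seg = segment_target(img)
        assert np.array_equal(seg.target > 0, img.values == 0.9)
        assert np.array_equal(seg.background, np.where(img.values == 0.1,
                                                       0.1, 0.0))

    def test_partition_properties(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.0, 0.05, (64, 64))
        vals[20:30, 20:30] = 1.0
        img = ImageGrid(vals, 0.2)
        seg = segment_target(img)
        assert not np.any(seg.target * seg.background)  # disjoint supports
        assert np.allclose(seg.target + seg.background, vals)  # partition
        imax = np.unravel_index(np.argmax(vals), vals.shape)
        assert seg.target[imax] > 0  # global max belongs to the target

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_target(ImageGrid(np.full((8, 8), 0.3), 0.2))


class TestRadon:
    def test_zero_image_gives_zero_projections(self):
        proj = radon_transform(np.zeros((64, 64)), 0.2)
        assert not proj.values.any()
        assert proj.values.shape == (len(proj.rho), len(proj.theta_deg))

    def test_centered_disk_is_rotationally_invariant(self):
        img = disk_image()
        proj = radon_transform(img.values, img.pitch)
        profile_per_angle = proj.values.max(axis=0)
        # variation limited by the rasterization of the disk edge
        assert np.ptp(profile_per_angle) < 0.03 * profile_per_angle.mean()

    def test_mass_conservation_at_every_angle(self):
        img = disk_image(value=0.7)
        proj = radon_transform(img.values, img.pitch)
        mass = img.values.sum() * img.pitch ** 2
        sums = proj.values.sum(axis=0) * img.pitch
        assert np.allclose(sums, mass, rtol=0.01)

    def test_non_square_image_rejected(self):
        with pytest.raises(ValueError):
            radon_transform(np.zeros((4, 8)), 0.2)


class TestInverseRadon:
    def test_smooth_roundtrip_within_five_percent(self):
        n, pitch = 128, 0.2
        img = ImageGrid(np.zeros((n, n)), pitch)
        X, Y = img.meshgrid()
        img.values[:] = np.exp(-(X ** 2 + Y ** 2) / (2 * 3.0 ** 2))
        proj = radon_transform(img.values, pitch)
        back = inverse_radon(proj, GridSpec(n * pitch, pitch))
        err = np.linalg.norm(back.values - img.values) / np.linalg.norm(img.values)
        assert err < 0.05

    def test_zero_projections_give_zero_image(self):
        proj = radon_transform(np.zeros((64, 64)), 0.2)
        back = inverse_radon(proj, GridSpec(64 * 0.2, 0.2))
        assert np.allclose(back.values, 0.0, atol=1e-12)

    def test_disk_radius_recovered_within_one_pixel(self):
        img = disk_image(radius_mm=4.0)
        proj = radon_transform(img.values, img.pitch)
        back = inverse_radon(proj, GridSpec(128 * 0.2, 0.2))
        mid = back.values[back.n // 2]
        above = np.flatnonzero(mid > 0.5 * mid.max())
        recovered_radius = (above[-1] - above[0] + 1) * img.pitch / 2
        assert recovered_radius == pytest.approx(4.0, abs=img.pitch)

    def test_insufficient_coverage_rejected(self):
        proj = radon_transform(np.zeros((32, 32)), 0.2, n_theta=90)
        half = ProjectionData(proj.values[:, :45], proj.rho,
                              proj.theta_deg[:45], proj.pitch)
        with pytest.raises(ValueError, match="coverage"):
            inverse_radon(half, GridSpec(32 * 0.2, 0.2))


class TestTargetSupport:
    def test_zero_projections_have_empty_support(self):
        proj = radon_transform(np.zeros((64, 64)), 0.2)
        sup = target_support(proj)
        assert not sup.nonempty().any()

    def test_centered_disk_support_width_matches_diameter(self):
        img = disk_image(radius_mm=4.0)
        proj = radon_transform(img.values, img.pitch)
        sup = target_support(proj)
        widths = (sup.n - sup.m + 1) * img.pitch
        assert np.all(np.abs(widths - 8.0) <= 3 * img.pitch)

    def test_centered_disk_support_is_angle_independent(self):
        img = disk_image(radius_mm=3.0)
        proj = radon_transform(img.values, img.pitch)
        sup = target_support(proj)
        quarter = len(sup.m) // 2  # 90 degrees at the default 1-deg step... half
        assert abs(sup.m[0] - sup.m[quarter]) <= 1
        assert abs(sup.n[0] - sup.n[quarter]) <= 1

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            TargetSupport(np.array([5]), np.array([3]))


class TestInterpolateBackground:
    def row_projection(self, rows):
        rows = np.asarray(rows, dtype=float)[:, None]
        rho = np.arange(rows.shape[0]) * 0.2
        return ProjectionData(rows, rho, np.array([0.0]), 0.2)

    def test_endpoints_are_fixed(self, rng):
        rows = rng.normal(size=32)
        proj = self.row_projection(rows)
        sup = TargetSupport(np.array([5]), np.array([20]))
        out = interpolate_background(proj, sup).values[:, 0]
        assert out[5] == pytest.approx(rows[5])
        assert out[20] == pytest.approx(rows[20])

    def test_midpoint_is_average_of_endpoints(self, rng):
        rows = rng.normal(size=33)
        proj = self.row_projection(rows)
        sup = TargetSupport(np.array([6]), np.array([26]))
        out = interpolate_background(proj, sup).values[:, 0]
        assert out[16] == pytest.approx((rows[6] + rows[26]) / 2)

    def test_globally_linear_row_is_reproduced_exactly(self):
        rows = 0.3 * np.arange(40) - 2.0
        proj = self.row_projection(rows)
        sup = TargetSupport(np.array([8]), np.array([30]))
        out = interpolate_background(proj, sup).values[:, 0]
        assert np.allclose(out, rows)

    def test_single_bin_interval(self):
        rows = np.arange(10.0)
        proj = self.row_projection(rows)
        sup = TargetSupport(np.array([4]), np.array([4]))
        out = interpolate_background(proj, sup).values[:, 0]
        assert np.allclose(out, rows)

    def test_outside_support_untouched(self, rng):
        rows = rng.normal(size=32)
        proj = self.row_projection(rows)
        sup = TargetSupport(np.array([10]), np.array([20]))
        out = interpolate_background(proj, sup).values[:, 0]
        assert np.array_equal(out[:10], rows[:10])
        assert np.array_equal(out[21:], rows[21:])


class TestAttenuationWeight:
    def test_zero_projection_gives_zero_weight(self):
        row = np.zeros(16)
        row[5:10] = [0.0, 1.0, 2.0, 1.0, 0.0]
        w = attenuation_weight(row, 5, 9, math.pi / 4)
        assert w[5] == 0.0 and w[9] == 0.0

    def test_k_equals_half_pi_suppresses_everything(self):
        row = np.linspace(0, 3, 16)
        w = attenuation_weight(row, 0, 15, math.pi / 2)
        assert np.allclose(w, 0.0)

    def test_peak_weight_is_one_at_quarter_pi(self):
        row = np.array([0.0, 1.0, 4.0, 2.0, 0.0])
        w = attenuation_weight(row, 0, 4, math.pi / 4)
        assert w[2] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(k=st.floats(0.05, math.pi / 2 - 0.05))
    def test_strictly_increasing_in_projection_value(self, k):
        row = np.linspace(0.0, 5.0, 40)
        w = attenuation_weight(row, 0, 39, k)
        assert np.all(np.diff(w) > 0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            attenuation_weight(np.ones(8), 0, 7, 0.0)
        with pytest.raises(ValueError):
            attenuation_weight(np.ones(8), 0, 7, 2.0)

    def test_zero_row_max_gives_zero_weights(self):
        w = attenuation_weight(np.zeros(8), 0, 7, math.pi / 4)
        assert not w.any()


class TestCorrectProjection:
    def build(self, rng, n_rho=48, n_theta=4):
        target = np.zeros((n_rho, n_theta))
        target[15:30] = rng.uniform(0.5, 2.0, size=(15, n_theta))
        rho = np.arange(n_rho) * 0.2
        theta = np.arange(n_theta) * 45.0
        t = ProjectionData(target, rho, theta, 0.2)
        bg = ProjectionData(rng.normal(0, 0.05, (n_rho, n_theta)), rho, theta, 0.2)
        sup = TargetSupport(np.full(n_theta, 15), np.full(n_theta, 29))
        return t, bg, sup

    def test_zero_contrast_returns_background_exactly(self, rng):
        t, bg, sup = self.build(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = CorrectionParams(K=1e-12)
        out = correct_projection(t, bg, sup, params)
        assert np.allclose(out.values, bg.values, atol=1e-11)

    def test_large_contrast_constant_warns(self):
        with pytest.warns(UserWarning, match="optimal"):
            CorrectionParams(K=5.0)

    def test_attenuation_never_amplifies(self, rng):
        """With K <= 1, the retained target cannot exceed the original."""
        t, bg, sup = self.build(rng)
        out = correct_projection(t, bg, sup, CorrectionParams(K=1.0))
        added = out.values - bg.values
        assert np.all(added <= t.values + 1e-12)
        assert np.all(added >= -1e-12)

    def test_mismatched_sampling_rejected(self, rng):
        t, bg, sup = self.build(rng)
        short = ProjectionData(bg.values[:-1], bg.rho[:-1], bg.theta_deg, 0.2)
        with pytest.raises(ValueError):
            correct_projection(t, short, sup, CorrectionParams())


class TestRunAbp:
    def test_zero_image_passes_through(self):
        out = run_abp(ReconImage(np.zeros((64, 64)), 0.2))
        assert not out.values.any()

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.02, (96, 96))
        vals[40:50, 40:50] = 1.0
        img = ReconImage(vals, 0.2)
        a = run_abp(img).values
        b = run_abp(img).values
        assert np.array_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CorrectionParams(K=-1.0)
        with pytest.raises(ValueError):
            CorrectionParams(k=3.5)
        with pytest.raises(ValueError):
            CorrectionParams(rescale="other")


class TestRunCoda:
    def test_point_sources_resolved_at_seeded_locations(self):
        from scipy import ndimage
        from coda import make_point_sources
        from coda.abp import run_coda

        spec = GridSpec(30.0, 0.2)
        centers = [(0.0, 0.0), (8.0, 0.0), (0.0, -8.0)]
        ph = make_point_sources(spec, centers=centers)
        img, sino = run_coda(ph, seed=2)
        assert sino.signals.shape == (360, 2226)
        vals = np.clip(img.values, 0.0, None)
        peaks = ndimage.maximum_filter(vals, size=9)
        found = np.argwhere((vals == peaks) & (vals > 0.3 * vals.max()))
        assert len(found) == len(centers)
        for cx, cy in centers:
            j = (cx / spec.pitch) + (img.n - 1) / 2
            i = (img.n - 1) / 2 - (cy / spec.pitch)
            dist = np.min(np.hypot(found[:, 0] - i, found[:, 1] - j))
            assert dist <= 1.0

    def test_deterministic_given_seed(self):
        from coda import make_point_sources
        from coda.abp import run_coda

        spec = GridSpec(30.0, 0.2)
        ph = make_point_sources(spec, centers=[(0.0, 0.0), (6.0, 3.0)])
        a, _ = run_coda(ph, seed=5)
        b, _ = run_coda(ph, seed=5)
        assert np.array_equal(a.values, b.values)
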