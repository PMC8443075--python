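import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icrsfem.curvature import (
    CurvatureProfile,
    SurfaceProfile,
    best_fit_sphere,
    central_interpolation,
    central_value,
    curvature_change,
    peripheral_extreme,
    sagittal_power,
    zone_mean,
)
from tests.conftest import circle_points


class TestSagittalPower:
    @pytest.mark.parametrize("R", [5.0, 6.4, 7.8, 10.0])
    def test_circle_power_closed_form(self, R):
        """An arc of radius R reads (n-1)*1000/R dioptres at every station."""
        prof = SurfaceProfile.from_points(circle_points(R, x_max=min(5.0, 0.62 * R)))
        cp = sagittal_power(prof)
        np.testing.assert_allclose(cp.sagittal_power, 337.5 / R, atol=0.01)

    def test_flat_line_zero_power(self):
        x = np.linspace(-5, 5, 201)
        prof = SurfaceProfile.from_points(np.column_stack([x, np.full_like(x, 1.0)]))
        cp = sagittal_power(prof)
        np.testing.assert_allclose(cp.sagittal_power, 0.0, atol=1e-9)

    def test_keratometric_index_scaling(self):
        prof = SurfaceProfile.from_points(circle_points(7.8))
        p1 = sagittal_power(prof, n=1.3375).sagittal_power
        p2 = sagittal_power(prof, n=1.376).sagittal_power
        np.testing.assert_allclose(p2 / p1, 0.376 / 0.3375, rtol=1e-9)

    def test_profile_requires_increasing_x(self):
        with pytest.raises(ValueError):
            SurfaceProfile(points=np.array([[0.0, 0.0], [0.0, 1.0], [-1.0, 0.5]]))


class TestCentralInterpolation:
    def _cp(self, values, x=None):
        x = np.arange(-4.0, 4.0 + 1e-9, 0.025) if x is None else x
        return CurvatureProfile(radial_position=x, sagittal_power=values(x))

    def test_smooth_profile_nearly_unchanged(self):
        cp = self._cp(lambda x: np.full_like(x, 43.27))
        out = central_interpolation(cp, inner_radius=1.0)
        assert np.abs(out.sagittal_power - cp.sagittal_power).max() < 0.01

    def test_nans_inside_gap_filled(self):
        def vals(x):
            v = 40.0 + 0.5 * x
            v[np.abs(x) < 1.0] = np.nan
            return v
        out = central_interpolation(self._cp(vals), inner_radius=1.0)
        assert np.all(np.isfinite(out.sagittal_power))

    def test_linear_ramp_reproduced_exactly(self):
        cp = self._cp(lambda x: 40.0 + 2.0 * x)
        out = central_interpolation(cp, inner_radius=1.0)
        np.testing.assert_allclose(out.sagittal_power, cp.sagittal_power, atol=1e-9)

    def test_gap_wider_than_support_raises(self):
        x = np.arange(-0.5, 0.5, 0.025)
        cp = CurvatureProfile(radial_position=x, sagittal_power=np.full_like(x, 43.0))
        with pytest.raises(ValueError):
            central_interpolation(cp, inner_radius=1.0)


class TestBestFitSphere:
    def test_exact_circle_recovered(self):
        prof = SurfaceProfile.from_points(circle_points(7.8))
        radius, power = best_fit_sphere(prof, zone_diameter=10.0)
        assert radius == pytest.approx(7.8, abs=1e-9)
        assert power == pytest.approx(337.5 / 7.8, abs=1e-6)

    def test_noisy_circle_within_10_microns(self):
        rng = np.random.default_rng(7)
        prof = SurfaceProfile.from_points(
            circle_points(7.8, noise=1e-3, rng=rng))  # 1 um noise
        radius, _ = best_fit_sphere(prof, zone_diameter=10.0)
        assert radius == pytest.approx(7.8, abs=0.01)

    def test_invariant_to_ordering_and_mirror(self):
        pts = circle_points(7.8)
        r1, _ = best_fit_sphere(SurfaceProfile.from_points(pts))
        r2, _ = best_fit_sphere(SurfaceProfile.from_points(pts[::-1]))
        mirrored = pts * np.array([-1.0, 1.0])
        r3, _ = best_fit_sphere(SurfaceProfile.from_points(mirrored))
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-9)

    def test_collinear_points_rejected(self):
        x = np.linspace(-3, 3, 50)
        prof = SurfaceProfile.from_points(np.column_stack([x, 2.0 * x + 1.0]))
        with pytest.raises(ValueError):
            best_fit_sphere(prof)

    @settings(max_examples=20, deadline=None)
    @given(R=st.floats(5.0, 10.0))
    def test_power_radius_relation_property(self, R):
        prof = SurfaceProfile.from_points(circle_points(R, x_max=3.0))
        radius, power = best_fit_sphere(prof, zone_diameter=6.0)
        assert power == pytest.approx(337.5 / radius, rel=1e-9)


class TestCurvatureChange:
    def test_identical_profiles_give_zero(self):
        prof = SurfaceProfile.from_points(circle_points(7.8))
        cp = sagittal_power(prof)
        delta = curvature_change(cp, cp)
        np.testing.assert_allclose(delta.sagittal_power, 0.0, atol=1e-14)

    def test_flattening_is_negative(self):
        """Radius increase (flattening) gives a negative power change."""
        grid = np.arange(-200, 201) * 0.025
        cp_pre = sagittal_power(SurfaceProfile.from_points(circle_points(7.8)), grid=grid)
        cp_post = sagittal_power(SurfaceProfile.from_points(circle_points(9.0)), grid=grid)
        delta = curvature_change(cp_pre, cp_post)
        assert np.all(delta.sagittal_power < 0)
        assert central_value(delta) == pytest.approx(337.5 / 9.0 - 337.5 / 7.8, abs=0.02)

    def test_grid_mismatch_rejected(self):
        cp1 = sagittal_power(SurfaceProfile.from_points(circle_points(7.8)))
        grid = cp1.radial_position[:-2]
        cp2 = sagittal_power(SurfaceProfile.from_points(circle_points(7.8)), grid=grid)
        with pytest.raises(ValueError):
            curvature_change(cp1, cp2)

    def test_summaries_on_synthetic_delta(self):
        x = np.arange(-5.0, 5.0 + 1e-9, 0.025)
        v = -np.exp(-((np.abs(x) - 3.0) ** 2) / 0.1) * 10.0   # dip at |x|=3
        delta = CurvatureProfile(radial_position=x, sagittal_power=v)
        assert peripheral_extreme(delta, (1.0, 5.0)) == pytest.approx(-10.0, abs=1e-6)
        assert peripheral_extreme(delta, (1.0, 5.0), side="positive") == pytest.approx(-10.0, abs=1e-6)
        assert abs(zone_mean(delta, 4.0)) < 0.2
        assert central_value(delta) == pytest.approx(0.0, abs=1e-6)
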