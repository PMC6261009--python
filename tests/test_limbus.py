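"""Limbus detector unit tests: closed-form derivative oracles, turning-point
location, contour assembly and equivariance properties."""

import numpy as np
import pytest

import limbus3d as l3
from limbus3d.exceptions import (
    AxisMeridianInvalid,
    InsufficientCoverage,
    TooFewValidMeridians,
    WindowTooWide,
)
from limbus3d.limbus import (
    DerivativeProfile,
    LimbusModel,
    LimbusPoint,
    assemble_limbus_contour,
    axis_diameters,
    locate_limbus_point,
    meridian_derivatives,
    polar_resample,
)


def spherical_cap_field(R=7.8, r_max=7.5, step=0.05):
    ax = np.arange(-r_max, r_max + step / 2, step)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    keep = r2 <= r_max**2
    z = -(R - np.sqrt(R**2 - r2[keep]))
    return l3.HeightField(np.stack([xx[keep], yy[keep], z], axis=1))


class TestPolarResample:
    def test_sphere_sag_matches_closed_form(self):
        field = spherical_cap_field()
        mset = polar_resample(field, n_meridians=36, dr=0.05, r_max=7.0)
        j = int(round(6.8 / 0.05))
        expected = 7.8 - np.sqrt(7.8**2 - 6.8**2)
        assert mset.valid[:, j].all()
        assert np.allclose(mset.sag_mm[:, j], expected, atol=1e-3)

    def test_rotational_symmetry_of_resampled_sag(self):
        field = spherical_cap_field()
        mset = polar_resample(field, n_meridians=36, dr=0.05, r_max=7.0)
        spread = np.nanmax(mset.sag_mm, axis=0) - np.nanmin(mset.sag_mm, axis=0)
        assert np.nanmax(spread) < 1e-3

    def test_occluded_sector_samples_invalid(self):
        surf = l3.make_surface(
            l3.SurfaceTruth(), grid_step_mm=0.1, occlusion_sectors=[(150, 210, 4.0)]
        )
        mset = polar_resample(surf.field, n_meridians=360, dr=0.05, r_max=8.5)
        inside = (mset.angles_deg > 151) & (mset.angles_deg < 209)
        outer = mset.r_mm > 4.6
        assert not mset.valid[np.ix_(inside, outer)].any()
        outside = (mset.angles_deg < 148) | (mset.angles_deg > 212)
        assert mset.valid[np.ix_(outside, outer & (mset.r_mm < 9.0))].mean() > 0.99

    def test_insufficient_coverage_raises(self):
        field = spherical_cap_field(r_max=3.0)
        with pytest.raises(InsufficientCoverage):
            polar_resample(field, n_meridians=36, dr=0.05, r_max=9.0,
                           max_invalid_fraction=0.3)


class TestMeridianDerivatives:
    r = np.arange(0.0, 8.0, 0.01)

    def test_paraboloid_derivatives_exact(self):
        R = 7.8
        sag = self.r**2 / (2 * R)
        prof = meridian_derivatives(self.r, sag)
        assert np.allclose(prof.d1, self.r / R, atol=1e-6)
        assert np.allclose(prof.d2, 1.0 / R, atol=1e-6)

    def test_sphere_second_derivative_closed_form(self):
        R = 7.8
        r = np.arange(0.0, 6.0, 0.01)
        sag = R - np.sqrt(R**2 - r**2)
        prof = meridian_derivatives(r, sag, smooth_halfwidth=0.25)
        expected = R**2 / (R**2 - r**2) ** 1.5
        interior = (r > 0.5) & (r < 5.5)
        assert np.allclose(prof.d2[interior], expected[interior], atol=1e-3)
        j = int(round(4.0 / 0.01))
        assert prof.d2[j] == pytest.approx(0.2026, abs=1e-3)

    def test_constant_sag_gives_zero_derivatives(self):
        prof = meridian_derivatives(self.r, np.full_like(self.r, 2.5))
        assert np.allclose(prof.d1, 0.0, atol=1e-12)
        assert np.allclose(prof.d2, 0.0, atol=1e-12)

    def test_gap_propagates_as_invalid(self):
        sag = self.r**2 / 15.6
        valid = np.ones_like(self.r, dtype=bool)
        valid[300:340] = False
        prof = meridian_derivatives(self.r, sag, valid)
        assert not prof.valid[300:340].any()
        assert prof.valid[:300].all() and prof.valid[340:].all()

    def test_window_wider_than_any_valid_run_raises(self):
        valid = np.zeros_like(self.r, dtype=bool)
        valid[:50] = True  # 0.5 mm < 1.2 mm window
        with pytest.raises(WindowTooWide):
            meridian_derivatives(self.r, self.r**2, valid, smooth_halfwidth=0.6)


class TestLocateLimbusPoint:
    def _profile(self, d2, r=None):
        r = np.arange(0.0, 9.0, 0.01) if r is None else r
        return DerivativeProfile(
            r=r, s=np.zeros_like(r), d1=np.zeros_like(r), d2=d2,
            valid=np.ones_like(r, dtype=bool),
        )

    def test_symmetric_dip_located_at_center(self):
        r = np.arange(0.0, 9.0, 0.01)
        d2 = 0.128 - 0.3 * np.exp(-((r - 6.8) ** 2) / (2 * 0.35**2))
        pt = locate_limbus_point(self._profile(d2, r))
        assert pt.valid
        assert pt.radius_mm == pytest.approx(6.80, abs=0.01)

    def test_monotone_d2_is_invalid_not_error(self):
        r = np.arange(0.0, 9.0, 0.01)
        pt = locate_limbus_point(self._profile(0.1 + 0.01 * r, r))
        assert not pt.valid

    def test_prominence_gate(self):
        r = np.arange(0.0, 9.0, 0.01)
        d2 = 0.128 - 0.02 * np.exp(-((r - 6.8) ** 2) / (2 * 0.35**2))
        assert not locate_limbus_point(self._profile(d2, r), min_prominence=0.05).valid
        assert locate_limbus_point(self._profile(d2, r), min_prominence=0.005).valid

    def test_low_window_coverage_is_invalid(self):
        r = np.arange(0.0, 9.0, 0.01)
        d2 = 0.128 - 0.3 * np.exp(-((r - 6.8) ** 2) / (2 * 0.35**2))
        prof = self._profile(d2, r)
        prof.valid[r > 5.5] = False
        assert not locate_limbus_point(prof).valid

    def test_agrees_with_brute_force_on_analytic_sag(self):
        """Detector vs brute-force argmin of central differences at dr/10."""
        truth = l3.SurfaceTruth(limbus_radius_mm=6.6)
        dr = 0.01
        r = np.arange(0.0, 9.0, dr)
        sag = l3.meridian_sag(truth, 0.0, r).s
        prof = meridian_derivatives(r, sag)
        pt = locate_limbus_point(prof)

        rf = np.arange(0.0, 9.0, dr / 10)
        sf = l3.meridian_sag(truth, 0.0, rf).s
        d2_fd = np.gradient(np.gradient(sf, rf), rf)
        sel = (rf >= 4.5) & (rf <= 8.5)
        brute = rf[sel][np.argmin(d2_fd[sel])]
        assert pt.radius_mm == pytest.approx(brute, abs=dr)


class TestAssembleAndDiameters:
    def test_full_detection_on_coarse_surface(self, coarse_results):
        c = coarse_results.contour
        assert c.valid.all()
        assert np.allclose(c.radii_xy(), 6.8, atol=0.02)

    def test_detected_z_matches_sag_at_ring(self, coarse_results):
        truth_z = -l3.meridian_sag(l3.SurfaceTruth(), 0.0, np.array([0.0, 6.8])).s[1]
        z = coarse_results.contour.points[coarse_results.contour.valid, 2]
        assert np.allclose(z, truth_z, atol=0.01)

    def test_too_few_valid_meridians_raises(self, coarse_surface):
        mset = polar_resample(coarse_surface.field, n_meridians=36, dr=0.02)
        points = [LimbusPoint.invalid()] * 30 + [
            LimbusPoint(6.8, 1.0, True) for _ in range(6)
        ]
        with pytest.raises(TooFewValidMeridians):
            assemble_limbus_contour(mset, points)

    def test_diameters_on_planar_ring(self):
        from conftest import make_ring_contour

        d = axis_diameters(make_ring_contour(6.82))
        assert d["NT"] == pytest.approx(13.64)
        assert d["SI"] == pytest.approx(13.64)

    def test_rigid_rotation_preserves_chords(self):
        from conftest import make_ring_contour
        from limbus3d.geometry import tilt_rotation

        c = make_ring_contour(6.82)
        rot = c.points @ tilt_rotation(0.0, 2.0).T
        c2 = l3.LimbusContour3D(c.angle_deg, rot, c.valid, c.quality)
        d = axis_diameters(c2)
        assert d["NT"] == pytest.approx(13.64, abs=1e-9)

    def test_invalid_axis_meridian_raises(self):
        from conftest import make_ring_contour

        valid = np.ones(360, dtype=bool)
        valid[180] = False
        with pytest.raises(AxisMeridianInvalid):
            axis_diameters(make_ring_contour(6.8, valid=valid))


class TestEquivariance:
    def test_rotating_surface_rotates_contour(self, coarse_surface, coarse_results):
        """Z-rotation by a whole number of meridian steps rolls the radii."""
        shift_deg, n = 20, 90  # 5 meridian steps of 4 deg
        th = np.radians(shift_deg)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        field = l3.HeightField(coarse_surface.field.points @ rot.T)
        res = LimbusModel(field, n_meridians=n, dr=0.02).fit()
        rolled = np.roll(coarse_results.contour.radii_xy(), shift_deg * n // 360)
        assert np.allclose(res.contour.radii_xy(), rolled, atol=0.02)

    def test_diameters_invariant_under_small_rigid_rotation(self, coarse_results):
        from limbus3d.geometry import tilt_rotation

        truth = l3.SurfaceTruth(tilt_x_deg=2.0, tilt_y_deg=-3.0)
        surf = l3.make_surface(truth, grid_step_mm=0.1)
        res = LimbusModel(surf.field, n_meridians=90, dr=0.02).fit()
        d0 = coarse_results.axis_diameters()
        d1 = res.axis_diameters()
        assert d1["NT"] == pytest.approx(d0["NT"], abs=0.04)
        assert d1["SI"] == pytest.approx(d0["SI"], abs=0.04)


class TestModelInterface:
    def test_record_input_and_summary(self):
        record, _, _ = l3.make_eye_record(
            surface_truth=l3.SurfaceTruth(), seed=11, grid_step_mm=0.1
        )
        res = LimbusModel(record, n_meridians=90, dr=0.02).fit()
        assert res.laterality == "right"
        text = res.summary()
        assert "NT diameter" in text and "theta_x" in text

    def test_contour_plot_renders(self, coarse_results):
        import matplotlib.pyplot as plt

        ax = coarse_results.plot_contour()
        assert ax.lines
        plt.close("all")

    def test_report_includes_delta_against_wtw(self, coarse_results):
        wtw = l3.WTWContour(np.zeros(2), np.full(360, 5.9))
        rep = coarse_results.report(wtw=wtw)
        assert rep["delta"]["mean_mm"] == pytest.approx(0.9, abs=0.02)
        assert rep["limbus_nt_mm"] == pytest.approx(13.6, abs=0.05)
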