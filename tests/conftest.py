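"""Shared fixtures: synthetic scenes sized for fast unit tests plus the
full-resolution scenes reused by the acceptance tests."""

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

import limbus3d as l3
from limbus3d.limbus import LimbusModel

#: coarse settings for unit tests (fast) — full resolution is exercised in
#: tests/test_acceptance.py
COARSE = dict(n_meridians=90, dr=0.02, r_max=9.0)


def make_ring_contour(radius=6.8, z=-3.0, n=360, valid=None):
    """Planar circular contour used by geometry tests."""
    ang = np.arange(n) * 360.0 / n
    th = np.deg2rad(ang)
    pts = np.stack(
        [radius * np.cos(th), radius * np.sin(th), np.full(n, float(z))], axis=1
    )
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return l3.LimbusContour3D(ang, pts, valid, np.zeros(n))


@pytest.fixture(scope="session")
def coarse_surface():
    """Noiseless curvature-dip surface on a coarse grid."""
    truth = l3.SurfaceTruth(limbus_radius_mm=6.8)
    return l3.make_surface(truth, grid_step_mm=0.1)


@pytest.fixture(scope="session")
def coarse_results(coarse_surface):
    return LimbusModel(coarse_surface.field, **COARSE).fit()


@pytest.fixture(scope="session")
def default_image_sample():
    """Default three-population eye frame (noise sd 8, highlights on)."""
    return l3.make_eye_image(l3.ImageTruth(seed=5))


@pytest.fixture(scope="session")
def noiseless_circle_image():
    truth = l3.ImageTruth(
        iris_semi_axes_px=(295.0, 295.0), noise_sd=0.0, highlights=False
    )
    return l3.make_eye_image(truth)


# ---- full-resolution scenes shared by the acceptance tests ----------------

@pytest.fixture(scope="session")
def full_noiseless_fit():
    truth = l3.SurfaceTruth(limbus_radius_mm=6.8)
    surf = l3.make_surface(truth)
    return surf, LimbusModel(surf.field).fit()


@pytest.fixture(scope="session")
def full_noisy_fit():
    truth = l3.SurfaceTruth(limbus_radius_mm=6.8, seed=42)
    surf = l3.make_surface(truth, noise_sd_mm=0.005)
    return surf, LimbusModel(surf.field).fit()
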