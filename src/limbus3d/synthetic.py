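"""Ground-truth generators for anterior-eye surfaces and en-face images.

Surface model
-------------
A meridian sag profile is defined through its *second* radial derivative

``d2(r) = kappa(r) - A * exp(-(r - r_L)^2 / (2 sigma^2))``

and integrated twice in closed form (error functions) with ``s(0) = 0`` and
``s'(0) = 0``.  The Gaussian curvature dip of amplitude ``A`` (1/mm) and
width ``sigma`` encodes the cornea-to-sclera curvature transition: the
surface tangent gradient rises from zero at the apex to a local maximum
just before the limbal ring, softens across it, then rises again — and the
interior minimum of ``d2`` sits *exactly* at the ring radius ``r_L(theta)``
when the base curvature ``kappa`` is constant (the default), giving exact
analytic ground truth for the detector.

With ``scleral_blend=True`` the base curvature additionally relaxes from
the corneal ``1/corneal_R`` to the flatter scleral ``1/scleral_R`` through
a Gaussian-CDF blend centred on the ring.  That variant is more realistic
but the analytic ``d2`` minimum is then displaced slightly (about
``|dkappa| * sigma_b / (sqrt(2 pi) * A / sigma^2)`` mm, ~0.02 mm at the
defaults) from the blend centre; ground truth for it is *defined at the
blend centre*, and tests against it must budget for that displacement.

Image model
-----------
Three intensity populations (pupil < iris < sclera) on a 1024x1280 8-bit
frame: a pupil disc inside an iris ellipse on a scleral background, with
optional specular highlight dots emulating the profilometer's two
vertically stacked illumination spots, plus clipped Gaussian noise.  The
analytic white-to-white radius per degree is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .core import EyeImage, EyeRecord, HeightField
from .exceptions import BadParameters
from .geometry import tilt_rotation

_SQRT2 = np.sqrt(2.0)
_SQRT_PI = np.sqrt(np.pi)
_SQRT_2PI = np.sqrt(2.0 * np.pi)


# --------------------------------------------------------------------------
# truth records
# --------------------------------------------------------------------------

@dataclass
class SurfaceTruth:
    """Parameters of a synthetic anterior surface with a limbal ring.

    ``limbus_radius_mm`` may be a scalar (circular ring) or an array of 360
    per-degree radii.  Tilts are the plane-fit angles the generated ring
    reproduces exactly (see :func:`limbus3d.geometry.tilt_rotation`).
    """

    limbus_radius_mm: float | np.ndarray = 6.8
    tilt_x_deg: float = 0.0
    tilt_y_deg: float = 0.0
    dip_amplitude: float = 0.3          # 1/mm
    dip_sigma_mm: float = 0.35
    corneal_R_mm: float = 7.8
    scleral_R_mm: float = 12.0
    scleral_blend: bool = False
    blend_sigma_mm: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.limbus_radius_mm, dtype=float))
        if r.size not in (1, 360):
            raise BadParameters("limbus_radius_mm must be scalar or length 360")
        if np.any(r < 4.5) or np.any(r > 8.5):
            raise BadParameters("limbus radii must lie in [4.5, 8.5] mm")
        if self.dip_sigma_mm <= 0:
            raise BadParameters("dip_sigma_mm must be positive")
        if self.dip_amplitude <= 0:
            raise BadParameters(
                "dip_amplitude must be positive: without the curvature dip "
                "d2 has no interior local minimum"
            )
        if self.corneal_R_mm <= 0 or self.scleral_R_mm <= self.corneal_R_mm:
            raise BadParameters("need 0 < corneal_R_mm < scleral_R_mm")

    def radius_at(self, angle_deg: np.ndarray) -> np.ndarray:
        """Ring radius at arbitrary meridian angles (periodic linear interp)."""
        r = np.atleast_1d(np.asarray(self.limbus_radius_mm, dtype=float))
        ang = np.asarray(angle_deg, dtype=float) % 360.0
        if r.size == 1:
            return np.full_like(ang, r[0])
        base = np.arange(361.0)
        return np.interp(ang, base, np.concatenate([r, r[:1]]))

    def contour_points(self, n_meridians: int = 360) -> np.ndarray:
        """Analytic post-rotation 3D limbus ring (never run through a detector)."""
        theta = np.arange(n_meridians) * 360.0 / n_meridians
        rl = self.radius_at(theta)
        prof = [meridian_sag(self, theta[i], np.array([0.0, rl[i]])) for i in range(n_meridians)]
        s = np.array([p.s[1] for p in prof])
        th = np.deg2rad(theta)
        pts = np.stack([rl * np.cos(th), rl * np.sin(th), -s], axis=1)
        return pts @ tilt_rotation(self.tilt_x_deg, self.tilt_y_deg).T


@dataclass
class ImageTruth:
    """Parameters of a synthetic three-population eye image."""

    iris_semi_axes_px: tuple[float, float] = (295.0, 287.5)
    pupil_radius_px: float = 80.0
    intensities: tuple[int, int, int] = (20, 110, 220)
    noise_sd: float = 8.0
    cal_h: float = 0.02
    cal_v: float = 0.02
    shape: tuple[int, int] = (1024, 1280)
    center_offset_px: tuple[float, float] = (0.0, 0.0)
    highlights: bool = True
    highlight_offsets_px: tuple = ((0.0, -25.0), (0.0, 25.0))
    highlight_radius_px: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        p, i, s = self.intensities
        if not (0 <= p < i < s <= 255):
            raise BadParameters("need 0 <= pupil < iris < sclera <= 255")
        if self.pupil_radius_px >= min(self.iris_semi_axes_px):
            raise BadParameters("pupil must fit inside the iris ellipse")
        if self.cal_h <= 0 or self.cal_v <= 0:
            raise BadParameters("calibration factors must be positive")

    def wtw_radius_px(self, angle_deg: np.ndarray) -> np.ndarray:
        """Analytic iris-ellipse radius (px) along each pixel-space ray."""
        a, b = self.iris_semi_axes_px
        th = np.deg2rad(np.asarray(angle_deg, dtype=float))
        return a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)

    def wtw_radius_mm(self, angle_deg: np.ndarray) -> np.ndarray:
        th = np.deg2rad(np.asarray(angle_deg, dtype=float))
        scale = np.sqrt((np.cos(th) * self.cal_h) ** 2 + (np.sin(th) * self.cal_v) ** 2)
        return self.wtw_radius_px(angle_deg) * scale

    @property
    def nt_mm(self) -> float:
        return float(2.0 * self.iris_semi_axes_px[0] * self.cal_h)

    @property
    def si_mm(self) -> float:
        return float(2.0 * self.iris_semi_axes_px[1] * self.cal_v)


# --------------------------------------------------------------------------
# closed-form meridian sag
# --------------------------------------------------------------------------

def _gauss_dip_integrals(r, mu, sigma):
    """(g, I1, I2): Gaussian dip and its first/second integrals from 0."""
    t = (r - mu) / (_SQRT2 * sigma)
    t0 = (0.0 - mu) / (_SQRT2 * sigma)
    g = np.exp(-(t**2))

    def E(u):
        return u * erf(u) + np.exp(-(u**2)) / _SQRT_PI

    pref = sigma * np.sqrt(np.pi / 2.0)
    i1 = pref * (erf(t) - erf(t0))
    i2 = pref * (_SQRT2 * sigma * (E(t) - E(t0)) - erf(t0) * r)
    return g, i1, i2


def _blend_integrals(r, mu, s):
    """(Phi, B1, B2): Gaussian-CDF blend and its first/second integrals from 0."""
    def Phi(t):
        return 0.5 * (1.0 + erf(t / _SQRT2))

    def phi(t):
        return np.exp(-(t**2) / 2.0) / _SQRT_2PI

    def Q(t):
        return t * Phi(t) + phi(t)

    def F(t):
        return 0.5 * (t**2 + 1.0) * Phi(t) + 0.5 * t * phi(t)

    t = (r - mu) / s
    t0 = (0.0 - mu) / s
    b1 = s * (Q(t) - Q(t0))
    b2 = s**2 * (F(t) - F(t0)) - s * Q(t0) * r
    return Phi(t), b1, b2


@dataclass
class MeridianSag:
    """Analytic sag profile of one meridian with its radial derivatives."""

    r: np.ndarray
    s: np.ndarray
    d1: np.ndarray
    d2: np.ndarray


def meridian_sag(truth: SurfaceTruth, angle_deg: float, r: np.ndarray) -> MeridianSag:
    """Closed-form sag ``s(r)`` of the meridian at ``angle_deg`` (untilted).

    ``s`` is the double integral of the curvature profile with
    ``s(0) = 0`` and ``ds/dr(0) = 0`` by construction.

    Raises
    ------
    BadParameters
        If the curvature profile has no interior local minimum of ``d2``
        (checked analytically on a dense grid over the limbal zone).
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or (r < 0).any():
        raise BadParameters("r grid must be 1D and non-negative")
    mu = float(truth.radius_at(np.array([angle_deg]))[0])
    kc = 1.0 / truth.corneal_R_mm
    A, sig = truth.dip_amplitude, truth.dip_sigma_mm

    g, i1, i2 = _gauss_dip_integrals(r, mu, sig)
    d2 = kc - A * g
    d1 = kc * r - A * i1
    s = 0.5 * kc * r**2 - A * i2
    if truth.scleral_blend:
        dk = 1.0 / truth.scleral_R_mm - kc
        ph, b1, b2 = _blend_integrals(r, mu, truth.blend_sigma_mm)
        d2 = d2 + dk * ph
        d1 = d1 + dk * b1
        s = s + dk * b2

    # analytic existence check for the interior d2 minimum near the ring
    rr = np.linspace(max(0.0, mu - 4 * sig), mu + 4 * sig, 801)
    gg, _, _ = _gauss_dip_integrals(rr, mu, sig)
    dd = kc - A * gg
    if truth.scleral_blend:
        dd = dd + dk * _blend_integrals(rr, mu, truth.blend_sigma_mm)[0]
    interior = dd[1:-1]
    is_min = (interior < dd[:-2]) & (interior <= dd[2:])
    if not is_min.any():
        raise BadParameters("curvature dip too weak: d2 has no interior minimum")
    return MeridianSag(r=r, s=s, d1=d1, d2=d2)


def analytic_d2_minimum(truth: SurfaceTruth, angle_deg: float) -> float:
    """Location (mm) of the interior minimum of the analytic ``d2`` profile.

    Equals the ring radius exactly for the constant-base model; for the
    scleral-blend variant it is the displaced analytic argmin.
    """
    mu = float(truth.radius_at(np.array([angle_deg]))[0])
    sig = truth.dip_sigma_mm
    rr = np.linspace(max(0.0, mu - 4 * sig), mu + 4 * sig, 160001)
    prof = meridian_sag(truth, angle_deg, rr)
    return float(rr[1:-1][np.argmin(prof.d2[1:-1])])


# --------------------------------------------------------------------------
# surface and image synthesis
# --------------------------------------------------------------------------

@dataclass
class SurfaceSample:
    """A generated height field together with its resolved ground truth."""

    field: HeightField
    truth: SurfaceTruth
    truth_contour: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    occluded_meridians: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    noise_sd_mm: float = 0.0


def make_surface(
    truth: SurfaceTruth,
    grid_step_mm: float = 0.05,
    r_max_mm: float = 9.5,
    noise_sd_mm: float = 0.0,
    occlusion_sectors: tuple = (),
    layout: str = "grid",
    n_points: int | None = None,
    seed: int | None = None,
) -> SurfaceSample:
    """Sample a synthetic anterior surface on an XY layout.

    Parameters
    ----------
    occlusion_sectors : iterable of (lo_deg, hi_deg) or (lo_deg, hi_deg, r_min_mm)
        Points with polar angle inside ``[lo, hi]`` (and radius at or beyond
        ``r_min_mm``, default 0) are deleted, emulating eyelid occlusion.
        Meridians at the sector boundaries keep one-sided support; the
        integer meridians strictly inside lose theirs.
    layout : "grid" or "scattered"
        Regular grid of pitch ``grid_step_mm``, or ``n_points`` uniform
        random points in the disc of radius ``r_max_mm``.

    The surface is rotated rigidly by the truth tilts and Gaussian height
    noise of sd ``noise_sd_mm`` is added along z.  The same seed always
    reproduces the same field.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if layout == "grid":
        ax = np.arange(-r_max_mm, r_max_mm + grid_step_mm / 2, grid_step_mm)
        xx, yy = np.meshgrid(ax, ax)
        x, y = xx.ravel(), yy.ravel()
    elif layout == "scattered":
        if n_points is None:
            raise BadParameters("scattered layout requires n_points")
        rr = r_max_mm * np.sqrt(rng.random(n_points))
        th = rng.random(n_points) * 2 * np.pi
        x, y = rr * np.cos(th), rr * np.sin(th)
    else:
        raise BadParameters(f"unknown layout {layout!r}")
    r = np.hypot(x, y)
    keep = r <= r_max_mm
    x, y, r = x[keep], y[keep], r[keep]
    theta = np.degrees(np.arctan2(y, x)) % 360.0

    occluded = np.zeros(x.shape[0], dtype=bool)
    occluded_meridians = []
    for sector in occlusion_sectors:
        lo, hi = float(sector[0]) % 360.0, float(sector[1]) % 360.0
        r_min = float(sector[2]) if len(sector) > 2 else 0.0
        if lo <= hi:
            in_sector = (theta >= lo) & (theta <= hi)
            inside = [d for d in range(360) if lo < d < hi]
        else:  # wraps through 0
            in_sector = (theta >= lo) | (theta <= hi)
            inside = [d for d in range(360) if d > lo or d < hi]
        occluded |= in_sector & (r >= r_min)
        occluded_meridians.extend(inside)
    x, y, r, theta = x[~occluded], y[~occluded], r[~occluded], theta[~occluded]

    # closed-form sag with the per-point ring radius (vectorised in r and mu)
    mu = truth.radius_at(theta)
    kc = 1.0 / truth.corneal_R_mm
    A, sig = truth.dip_amplitude, truth.dip_sigma_mm
    _, _, i2 = _gauss_dip_integrals(r, mu, sig)
    s = 0.5 * kc * r**2 - A * i2
    if truth.scleral_blend:
        dk = 1.0 / truth.scleral_R_mm - kc
        s = s + dk * _blend_integrals(r, mu, truth.blend_sigma_mm)[2]
    # BadParameters surfaced through the meridian constructor's analytic check
    meridian_sag(truth, 0.0, np.array([0.0, 1.0]))

    pts = np.stack([x, y, -s], axis=1)
    pts = pts @ tilt_rotation(truth.tilt_x_deg, truth.tilt_y_deg).T
    if noise_sd_mm > 0:
        pts[:, 2] += rng.normal(0.0, noise_sd_mm, pts.shape[0])
    tilted = truth.tilt_x_deg != 0 or truth.tilt_y_deg != 0
    return SurfaceSample(
        field=HeightField(pts, grid_flag=(layout == "grid" and not tilted)),
        truth=truth,
        truth_contour=truth.contour_points(),
        occluded_meridians=np.array(sorted(set(occluded_meridians)), dtype=int),
        noise_sd_mm=noise_sd_mm,
    )


@dataclass
class ImageSample:
    """A generated eye image together with its resolved ground truth."""

    image: EyeImage
    truth: ImageTruth


def make_eye_image(truth: ImageTruth, seed: int | None = None) -> ImageSample:
    """Render the three-population eye frame described by ``truth``."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    h, w = truth.shape
    cy, cx = (h - 1) / 2.0 + truth.center_offset_px[1], (w - 1) / 2.0 + truth.center_offset_px[0]
    rows, cols = np.ogrid[:h, :w]
    dy, dx = rows - cy, cols - cx
    a, b = truth.iris_semi_axes_px
    pupil_i, iris_i, sclera_i = truth.intensities

    img = np.full((h, w), float(sclera_i))
    iris = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
    img[iris] = iris_i
    pupil = dx**2 + dy**2 <= truth.pupil_radius_px**2
    img[pupil] = pupil_i
    if truth.highlights:
        for ox, oy in truth.highlight_offsets_px:
            spot = (dx - ox) ** 2 + (dy - oy) ** 2 <= truth.highlight_radius_px**2
            img[spot] = 255.0
    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageSample(
        image=EyeImage(img, cal_h=truth.cal_h, cal_v=truth.cal_v),
        truth=truth,
    )


def make_eye_record(
    surface_truth: SurfaceTruth | None = None,
    image_truth: ImageTruth | None = None,
    laterality: str = "right",
    subject_id: str = "synthetic",
    scan_id: str = "scan-1",
    seed: int | None = None,
    **surface_kwargs,
) -> tuple[EyeRecord, SurfaceSample, ImageSample]:
    """Full synthetic eye record: surface, apex at the origin, and image."""
    surface_truth = surface_truth or SurfaceTruth()
    image_truth = image_truth or ImageTruth()
    if seed is not None:
        surface_truth = replace(surface_truth, seed=seed)
        image_truth = replace(image_truth, seed=seed + 1)
    surf = make_surface(surface_truth, **surface_kwargs)
    img = make_eye_image(image_truth)
    record = EyeRecord(
        laterality=laterality,
        height=surf.field,
        apex=np.zeros(3),
        image=img.image,
        subject_id=subject_id,
        scan_id=scan_id,
        metadata={"synthetic": True, "surface_seed": surface_truth.seed},
    )
    return record, surf, img


def make_cohort_truths(
    n_eyes: int,
    laterality: str,
    seed: int = 0,
) -> list[SurfaceTruth]:
    """Draw per-eye surface truths emulating a clinical cohort.

    Ring radii are drawn around 6.82 mm (sd 0.27, half the observed limbal
    diameter spread) and tilt angles around the side-specific means reported
    for healthy adults: right eyes (theta_x, theta_y) ~ N(-0.3, 1.35) x
    N(1.76, 0.9) degrees, left eyes N(0.77, 1.25) x N(-1.54, 0.89).
    """
    rng = np.random.default_rng(seed)
    if laterality == "right":
        mx, sx, my, sy = -0.3, 1.35, 1.76, 0.9
    else:
        mx, sx, my, sy = 0.77, 1.25, -1.54, 0.89
    truths = []
    for k in range(n_eyes):
        truths.append(
            SurfaceTruth(
                limbus_radius_mm=float(np.clip(rng.normal(6.82, 0.27), 5.8, 7.0)),
                tilt_x_deg=float(rng.normal(mx, sx)),
                tilt_y_deg=float(rng.normal(my, sy)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return truths
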