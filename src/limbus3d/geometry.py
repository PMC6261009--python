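"""Geometry of the 3D limbus contour.

Plane fit and tilt convention
-----------------------------
The limbus contour is fitted by ordinary least squares to a plane
``z = a*x + b*y + c``.  Tilt angles follow the en-face convention:

* ``theta_y = atan(a)`` — rotation about the Y axis, measured
  counter-clockwise from the +X axis in the XZ plane, so a contour that is
  *higher* (larger z) on the +X side has positive ``theta_y``;
* ``theta_x = atan(b)`` — rotation about the X axis, measured
  counter-clockwise from the +Y axis in the YZ plane.

At the 1-4 degree tilts seen at the limbus, OLS in z and total least
squares agree to well under 0.01 degrees, and OLS is trivially verifiable
by hand, so OLS is used.

Sagittal depths are read from the *raw* (unleveled) contour relative to the
apex plane z = 0, because the left/right and nasal/temporal asymmetry of
depth is itself a quantity of interest that leveling would partly remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LimbusContour3D, WTWContour, clinical_angles
from .exceptions import AxisMeridianInvalid, DegenerateContour, NoOverlap


@dataclass
class PlaneFit:
    """Least-squares plane ``z = a*x + b*y + c`` with tilt angles in degrees."""

    a: float
    b: float
    c: float
    theta_x: float
    theta_y: float
    rms_residual: float
    n_points: int

    def normal(self) -> np.ndarray:
        """Unit normal with positive Z component."""
        n = np.array([-self.a, -self.b, 1.0])
        return n / np.linalg.norm(n)


@dataclass
class DeltaMap:
    """Per-degree radial difference between limbus and WTW contours."""

    delta_mm: np.ndarray
    valid: np.ndarray
    argmax_deg: int
    argmin_deg: int

    @property
    def mean_mm(self) -> float:
        return float(self.delta_mm[self.valid].mean())

    def plot_polar(self, ax=None):
        """Polar plot of delta(theta); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        th = np.deg2rad(np.arange(360.0))
        d = np.where(self.valid, self.delta_mm, np.nan)
        ax.plot(th, d)
        ax.set_title(r"limbus $-$ WTW radial difference $\delta(\theta)$ (mm)")
        return ax


def fit_contour_plane(contour: LimbusContour3D) -> PlaneFit:
    """Fit ``z = a*x + b*y + c`` over the valid contour points.

    Raises
    ------
    DegenerateContour
        Fewer than 3 valid points, or all valid points collinear in XY.
    """
    pts = contour.points[contour.valid]
    if pts.shape[0] < 3:
        raise DegenerateContour("plane fit needs at least 3 valid points")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(pts.shape[0])])
    if np.linalg.matrix_rank(A) < 3:
        raise DegenerateContour("valid contour points are collinear")
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    a, b, c = (float(v) for v in coef)
    resid = pts[:, 2] - A @ coef
    return PlaneFit(
        a=a,
        b=b,
        c=c,
        theta_x=float(np.degrees(np.arctan(b))),
        theta_y=float(np.degrees(np.arctan(a))),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=pts.shape[0],
    )


def tilt_rotation(theta_x_deg: float, theta_y_deg: float) -> np.ndarray:
    """Rigid rotation whose fitted plane has exactly these tilt angles.

    The rotation is composed as ``Rx(psi) @ Ry(phi)`` with ``psi = theta_x``
    and ``phi = -atan(tan(theta_y) * cos(theta_x))``: applying it to a flat
    (z = const) contour and refitting recovers ``(theta_x, theta_y)`` exactly,
    including the small cross-term between the two rotations.
    """
    psi = np.radians(theta_x_deg)
    phi = -np.arctan(np.tan(np.radians(theta_y_deg)) * np.cos(psi))
    cx, sx = np.cos(psi), np.sin(psi)
    cy, sy = np.cos(phi), np.sin(phi)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return rx @ ry


def _align_normal_to_z(points: np.ndarray, normal: np.ndarray,
                       pivot: np.ndarray) -> np.ndarray:
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(normal, z)
    s = np.linalg.norm(axis)
    c = float(np.clip(normal @ z, -1.0, 1.0))
    if s < 1e-15:
        return points
    k = axis / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(np.arctan2(s, c)) * kx + (1 - c) * (kx @ kx)
    return (points - pivot) @ rot.T + pivot


def level_contour(contour: LimbusContour3D, plane: PlaneFit,
                  tol_deg: float = 1e-9, max_iter: int = 10) -> LimbusContour3D:
    """Rotate the contour rigidly so its fitted plane is normal to +Z.

    Because the plane fit minimises *vertical* residuals, a single rotation
    of a non-planar contour leaves micro-degree tilt in the refit; the
    alignment is therefore iterated (rigid rotations throughout) until the
    refitted tilt angles fall below ``tol_deg``.  Leveling an already level
    contour is the identity, and leveling is idempotent.
    """
    pts = contour.points.copy()
    pivot = pts[contour.valid].mean(axis=0)
    current = plane
    for _ in range(max_iter):
        if max(abs(current.theta_x), abs(current.theta_y)) <= tol_deg:
            break
        pts = _align_normal_to_z(pts, current.normal(), pivot)
        leveled = LimbusContour3D(
            angle_deg=contour.angle_deg.copy(),
            points=pts,
            valid=contour.valid.copy(),
            quality=contour.quality.copy(),
        )
        current = fit_contour_plane(leveled)
    return LimbusContour3D(
        angle_deg=contour.angle_deg.copy(),
        points=pts,
        valid=contour.valid.copy(),
        quality=contour.quality.copy(),
    )


def sagittal_depths(contour: LimbusContour3D, laterality: str) -> dict[str, float]:
    """|z| of the contour point on each clinical cardinal meridian (mm)."""
    out = {}
    for label, ang in clinical_angles(laterality).items():
        idx = contour.meridian_index(ang)
        if not contour.valid[idx]:
            raise AxisMeridianInvalid(f"{label} meridian ({ang} deg) is invalid")
        out[label] = float(abs(contour.points[idx, 2]))
    return out


def _resample_polar(points_xy: np.ndarray, valid: np.ndarray, origin: np.ndarray,
                    max_gap_deg: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Resample a closed boundary to per-integer-degree radii about ``origin``.

    Returns (radius_mm[360], valid[360]); an output angle is valid only when
    a valid input sample lies within ``max_gap_deg`` of it.
    """
    p = points_xy[valid] - origin[None, :]
    if p.shape[0] == 0:
        return np.zeros(360), np.zeros(360, dtype=bool)
    ang = np.degrees(np.arctan2(p[:, 1], p[:, 0])) % 360.0
    rad = np.hypot(p[:, 0], p[:, 1])
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    # periodic extension for interpolation across the 0/360 seam
    ang_ext = np.concatenate([ang - 360.0, ang, ang + 360.0])
    rad_ext = np.tile(rad, 3)
    target = np.arange(360.0)
    out = np.interp(target, ang_ext, rad_ext)
    # validity: angular distance to the nearest valid sample
    idx = np.searchsorted(ang_ext, target)
    lo = np.clip(idx - 1, 0, ang_ext.size - 1)
    hi = np.clip(idx, 0, ang_ext.size - 1)
    gap = np.minimum(np.abs(target - ang_ext[lo]), np.abs(ang_ext[hi] - target))
    return out, gap <= max_gap_deg


def radial_difference_map(
    limbus: LimbusContour3D,
    wtw: WTWContour,
    origin_policy: str = "apex",
) -> DeltaMap:
    """360-degree radial difference ``delta(theta) = r_limbus - r_wtw``.

    Both contours are re-expressed as polar radii about a common origin —
    the corneal apex (surface origin, default) or the WTW mask centroid —
    and differenced per integer degree.  ``argmax_deg``/``argmin_deg`` are
    taken over valid angles only.
    """
    if origin_policy not in ("apex", "wtw_center"):
        raise ValueError("origin_policy must be 'apex' or 'wtw_center'")
    origin = np.zeros(2) if origin_policy == "apex" else wtw.center

    r_limb, ok_limb = _resample_polar(limbus.points[:, :2], limbus.valid, origin)
    if origin_policy == "wtw_center":
        r_wtw = wtw.radius_mm
        ok_wtw = np.ones(360, dtype=bool)
    else:
        r_wtw, ok_wtw = _resample_polar(
            wtw.boundary_points(), np.ones(360, dtype=bool), origin
        )
    valid = ok_limb & ok_wtw
    if not valid.any():
        raise NoOverlap("limbus and WTW contours share no valid angle")
    delta = np.where(valid, r_limb - r_wtw, np.nan)
    vi = np.flatnonzero(valid)
    return DeltaMap(
        delta_mm=delta,
        valid=valid,
        argmax_deg=int(vi[np.argmax(delta[vi])]),
        argmin_deg=int(vi[np.argmin(delta[vi])]),
    )


def geometry_report(
    limbus: LimbusContour3D,
    wtw: WTWContour | None,
    laterality: str,
    origin_policy: str = "apex",
) -> dict:
    """Per-eye JSON-ready report: tilt, depths, diameters and the delta map."""
    from .limbus import axis_diameters  # local import to avoid a cycle

    plane = fit_contour_plane(limbus)
    report = {
        "laterality": laterality,
        "theta_x_deg": plane.theta_x,
        "theta_y_deg": plane.theta_y,
        "rms_mm": plane.rms_residual,
    }
    try:
        report["depths_mm"] = sagittal_depths(limbus, laterality)
    except AxisMeridianInvalid:
        report["depths_mm"] = None
    try:
        d = axis_diameters(limbus)
        report["limbus_nt_mm"], report["limbus_si_mm"] = d["NT"], d["SI"]
    except AxisMeridianInvalid:
        report["limbus_nt_mm"] = report["limbus_si_mm"] = None
    if wtw is not None:
        report["wtw_nt_mm"] = float(wtw.radius_mm[0] + wtw.radius_mm[180])
        report["wtw_si_mm"] = float(wtw.radius_mm[90] + wtw.radius_mm[270])
        dm = radial_difference_map(limbus, wtw, origin_policy)
        report["delta"] = {
            "argmax_deg": dm.argmax_deg,
            "argmin_deg": dm.argmin_deg,
            "mean_mm": dm.mean_mm,
        }
    return report
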