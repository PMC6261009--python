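"""3D limbus detection from anterior-surface height data.

The detector is non-parametric: the anterior surface is resampled onto a
polar grid of meridians about the apex, the sag ``s(r) = -z`` of each
meridian is differentiated twice with respect to the polar radius by local
polynomial (Savitzky-Golay) fitting, and the limbus point of the meridian
is the most prominent interior local minimum of ``d2 s / d r2`` inside a
radial search window — the turning point where the corneal curvature gives
way to the scleral curvature.  All detected points together form the 3D
limbus contour; occluded or unsupported meridians come back flagged
invalid instead of failing, so eyelid gaps never abort an eye.

Defaults: 360 meridians, radial step 0.01 mm, search window 4.5-8.5 mm
(bracketing all plausible limbal radii), smoothing half-width 0.6 mm with
cubic local polynomials.  Derivatives are evaluated from the fitted
polynomial coefficients, not by differencing smoothed data, so they are
exact on polynomials up to the fit order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial import Delaunay, cKDTree

from .core import EyeRecord, HeightField, LimbusContour3D, clinical_angles
from .exceptions import (
    AxisMeridianInvalid,
    BadParameters,
    InsufficientCoverage,
    TooFewValidMeridians,
    WindowTooWide,
)
from . import geometry


@dataclass
class MeridianSet:
    """Sag resampled onto a polar grid: ``sag[i, j] = s(angles[i], r[j])``."""

    angles_deg: np.ndarray
    r_mm: np.ndarray
    sag_mm: np.ndarray
    valid: np.ndarray

    @property
    def dr(self) -> float:
        return float(self.r_mm[1] - self.r_mm[0])

    @property
    def n_meridians(self) -> int:
        return self.angles_deg.shape[0]


@dataclass
class DerivativeProfile:
    """One meridian's sag with its first and second radial derivatives."""

    r: np.ndarray
    s: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    valid: np.ndarray


@dataclass
class LimbusPoint:
    """Per-meridian detection result; ``valid=False`` is a value, not an error."""

    radius_mm: float
    quality: float
    valid: bool

    @classmethod
    def invalid(cls) -> "LimbusPoint":
        return cls(radius_mm=np.nan, quality=0.0, valid=False)


def polar_resample(
    field: HeightField,
    n_meridians: int = 360,
    dr: float = 0.01,
    r_max: float = 9.0,
    influence_radius: float | None = None,
    max_invalid_fraction: float = 0.5,
) -> MeridianSet:
    """Interpolate the scattered surface onto a polar grid about the apex.

    Local linear (Delaunay) interpolation.  A polar sample is valid only
    when the triangle supporting it is locally dense — its longest edge is
    at most ``influence_radius`` (default: three times the median
    nearest-neighbour spacing of the input cloud).  Samples outside the
    data, and samples whose interpolation would bridge an occlusion gap
    through a long sliver triangle, are flagged invalid rather than
    silently filled.

    Raises
    ------
    InsufficientCoverage
        If more than ``max_invalid_fraction`` of all samples are invalid.
    """
    pts = field.points
    if pts.shape[0] < 4:
        raise InsufficientCoverage("too few surface points to interpolate")
    xy = pts[:, :2]
    if influence_radius is None:
        tree = cKDTree(xy)
        probe = xy[:: max(1, xy.shape[0] // 2000)]
        d, _ = tree.query(probe, k=2)
        influence_radius = 3.0 * float(np.median(d[:, 1]))

    angles = np.arange(n_meridians) * 360.0 / n_meridians
    r = np.arange(0.0, r_max + dr / 2, dr)
    th = np.deg2rad(angles)[:, None]
    qx = r[None, :] * np.cos(th)
    qy = r[None, :] * np.sin(th)
    q = np.stack([qx.ravel(), qy.ravel()], axis=1)

    tri = Delaunay(xy)
    interp = LinearNDInterpolator(tri, pts[:, 2])
    z = interp(q).reshape(n_meridians, r.size)
    # longest edge of each simplex; queries supported by long (gap-bridging
    # or hull-sliver) triangles are not trustworthy
    corners = xy[tri.simplices]
    edge = np.maximum(
        np.linalg.norm(corners[:, 0] - corners[:, 1], axis=1),
        np.maximum(
            np.linalg.norm(corners[:, 1] - corners[:, 2], axis=1),
            np.linalg.norm(corners[:, 2] - corners[:, 0], axis=1),
        ),
    )
    simplex = tri.find_simplex(q)
    supported = (simplex >= 0) & (edge[np.clip(simplex, 0, None)] <= influence_radius)
    valid = np.isfinite(z) & supported.reshape(z.shape)
    sag = np.where(valid, -z, np.nan)
    invalid_fraction = 1.0 - valid.mean()
    if invalid_fraction > max_invalid_fraction:
        raise InsufficientCoverage(
            f"{invalid_fraction:.0%} of polar samples unsupported "
            f"(limit {max_invalid_fraction:.0%})"
        )
    return MeridianSet(angles_deg=angles, r_mm=r, sag_mm=sag, valid=valid)


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], valid.astype(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def meridian_derivatives(
    r: np.ndarray,
    sag: np.ndarray,
    valid: np.ndarray | None = None,
    smooth_halfwidth: float = 0.6,
    poly_order: int = 3,
) -> DerivativeProfile:
    """Savitzky-Golay sag derivatives of one meridian.

    Each contiguous valid run at least one window long is fitted with local
    polynomials of order ``poly_order`` over windows of half-width
    ``smooth_halfwidth`` mm; ``d1`` and ``d2`` are evaluated analytically
    from the fitted coefficients.  Samples in runs shorter than the window,
    and invalid gaps, propagate as invalid.

    Raises
    ------
    WindowTooWide
        If no valid run is at least one window long.
    """
    r = np.asarray(r, dtype=float)
    sag = np.asarray(sag, dtype=float)
    if valid is None:
        valid = np.isfinite(sag)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(sag)
    dr = float(np.median(np.diff(r)))
    if not np.allclose(np.diff(r), dr, rtol=1e-6, atol=1e-12):
        raise BadParameters("r grid must be uniform")
    window = 2 * int(round(smooth_halfwidth / dr)) + 1
    window = max(window, poly_order + 2 + ((poly_order + 2) % 2 == 0))

    s_out = np.full_like(sag, np.nan)
    d1 = np.full_like(sag, np.nan)
    d2 = np.full_like(sag, np.nan)
    out_valid = np.zeros_like(valid)
    fitted_any = False
    for start, stop in _valid_runs(valid):
        if stop - start < window:
            continue
        seg = sag[start:stop]
        s_out[start:stop] = savgol_filter(seg, window, poly_order, mode="interp")
        d1[start:stop] = savgol_filter(seg, window, poly_order, deriv=1, delta=dr, mode="interp")
        d2[start:stop] = savgol_filter(seg, window, poly_order, deriv=2, delta=dr, mode="interp")
        out_valid[start:stop] = True
        fitted_any = True
    if not fitted_any:
        raise WindowTooWide(
            f"smoothing window ({window} samples) exceeds every valid span"
        )
    return DerivativeProfile(r=r, s=s_out, d1=d1, d2=d2, valid=out_valid)


def locate_limbus_point(
    profile: DerivativeProfile,
    window: tuple[float, float] = (4.5, 8.5),
    min_prominence: float = 0.05,
    min_window_coverage: float = 0.8,
    refine_halfwidth: float = 0.5,
) -> LimbusPoint:
    """Turning point of ``d2`` on one meridian.

    The limbus radius is the most prominent interior local minimum of the
    second derivative inside ``window`` (ties broken toward smaller radius,
    the corneal side), refined to sub-grid resolution by the centroid of the
    curvature dip — the ``d2`` deficit below the local baseline within
    ``refine_halfwidth`` of the discrete minimum.  Returns an invalid point
    (never raises) when the profile covers less than
    ``min_window_coverage`` of the window or no minimum reaches
    ``min_prominence`` (1/mm).
    """
    lo, hi = window
    sel = (profile.r >= lo) & (profile.r <= hi)
    n_sel = int(sel.sum())
    if n_sel < 3:
        return LimbusPoint.invalid()
    sub_valid = profile.valid[sel]
    runs = _valid_runs(sub_valid)
    if not runs:
        return LimbusPoint.invalid()
    start, stop = max(runs, key=lambda ab: ab[1] - ab[0])
    if (stop - start) < min_window_coverage * n_sel:
        return LimbusPoint.invalid()
    offset = np.flatnonzero(sel)[0] + start
    d2 = profile.d2[offset : offset + (stop - start)]
    r = profile.r[offset : offset + (stop - start)]

    peaks, props = find_peaks(-d2, prominence=min_prominence)
    if peaks.size == 0:
        return LimbusPoint.invalid()
    best = int(np.argmax(props["prominences"]))  # first of ties -> smaller r
    k = int(peaks[best])
    quality = float(props["prominences"][best])

    half = int(round(refine_halfwidth / (r[1] - r[0])))
    a, b = max(0, k - half), min(d2.size - 1, k + half)
    baseline = max(d2[a], d2[b])
    w = np.clip(baseline - d2[a : b + 1], 0.0, None)
    if w.sum() > 0:
        radius = float(np.sum(w * r[a : b + 1]) / w.sum())
    else:
        radius = float(r[k])
    return LimbusPoint(radius_mm=radius, quality=quality, valid=True)


def assemble_limbus_contour(
    mset: MeridianSet,
    points: list[LimbusPoint],
    min_valid_fraction: float = 0.5,
) -> LimbusContour3D:
    """Collect the per-meridian detections into a 3D contour.

    The sag at each detected radius is read from the meridian's resampled
    profile, so the contour point is ``(r cos t, r sin t, -s(t, r))``.
    Invalid meridians stay flagged; no silent gap filling.

    Raises
    ------
    TooFewValidMeridians
        If fewer than ``min_valid_fraction`` of meridians are valid.
    """
    n = mset.n_meridians
    if len(points) != n:
        raise BadParameters("one detection result required per meridian")
    xyz = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    quality = np.zeros(n)
    for i, pt in enumerate(points):
        if not pt.valid:
            continue
        ok = mset.valid[i]
        s = float(np.interp(pt.radius_mm, mset.r_mm[ok], mset.sag_mm[i, ok]))
        th = np.deg2rad(mset.angles_deg[i])
        xyz[i] = (pt.radius_mm * np.cos(th), pt.radius_mm * np.sin(th), -s)
        valid[i] = True
        quality[i] = pt.quality
    if valid.mean() < min_valid_fraction:
        raise TooFewValidMeridians(
            f"only {valid.sum()}/{n} meridians valid "
            f"(need {min_valid_fraction:.0%})"
        )
    return LimbusContour3D(
        angle_deg=mset.angles_deg.copy(), points=xyz, valid=valid, quality=quality
    )


def axis_diameters(contour: LimbusContour3D, laterality: str = "right") -> dict[str, float]:
    """NT and SI limbal diameters as 3D chords between opposite meridians."""
    ang = clinical_angles(laterality)
    out = {}
    for name, (a1, a2) in {
        "NT": (ang["nasal"], ang["temporal"]),
        "SI": (ang["superior"], ang["inferior"]),
    }.items():
        i, j = contour.meridian_index(a1), contour.meridian_index(a2)
        if not (contour.valid[i] and contour.valid[j]):
            raise AxisMeridianInvalid(f"{name} axis meridian invalid")
        out[name] = float(np.linalg.norm(contour.points[i] - contour.points[j]))
    return out


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class LimbusModel:
    """Non-parametric 3D limbus detector for one anterior-surface scan.

    Parameters
    ----------
    data : EyeRecord or HeightField
        Apex-centered surface (records are re-centered automatically).
    laterality : str, optional
        Required when ``data`` is a bare height field.
    """

    def __init__(
        self,
        data: EyeRecord | HeightField,
        laterality: str | None = None,
        n_meridians: int = 360,
        dr: float = 0.01,
        r_max: float = 9.0,
        window: tuple[float, float] = (4.5, 8.5),
        smooth_halfwidth: float = 0.6,
        poly_order: int = 3,
        min_prominence: float = 0.05,
        influence_radius: float | None = None,
        min_valid_fraction: float = 0.5,
    ) -> None:
        if isinstance(data, EyeRecord):
            data = data.apex_centered()
            self.field = data.height
            self.laterality = data.laterality
        else:
            self.field = data
            self.laterality = laterality or "right"
        self.params = dict(
            n_meridians=n_meridians,
            dr=dr,
            r_max=r_max,
            window=window,
            smooth_halfwidth=smooth_halfwidth,
            poly_order=poly_order,
            min_prominence=min_prominence,
            influence_radius=influence_radius,
            min_valid_fraction=min_valid_fraction,
        )

    def fit(self) -> "LimbusResults":
        p = self.params
        mset = polar_resample(
            self.field,
            n_meridians=p["n_meridians"],
            dr=p["dr"],
            r_max=p["r_max"],
            influence_radius=p["influence_radius"],
        )
        points: list[LimbusPoint] = []
        for i in range(mset.n_meridians):
            try:
                prof = meridian_derivatives(
                    mset.r_mm,
                    mset.sag_mm[i],
                    mset.valid[i],
                    smooth_halfwidth=p["smooth_halfwidth"],
                    poly_order=p["poly_order"],
                )
            except WindowTooWide:
                points.append(LimbusPoint.invalid())
                continue
            points.append(
                locate_limbus_point(
                    prof, window=p["window"], min_prominence=p["min_prominence"]
                )
            )
        contour = assemble_limbus_contour(
            mset, points, min_valid_fraction=p["min_valid_fraction"]
        )
        return LimbusResults(self, mset, contour)


class LimbusResults:
    """Fitted limbus contour with its plane, tilt angles and diameters."""

    def __init__(self, model: LimbusModel, meridians: MeridianSet,
                 contour: LimbusContour3D) -> None:
        self.model = model
        self.meridians = meridians
        self.contour = contour
        self._plane: geometry.PlaneFit | None = None

    @property
    def laterality(self) -> str:
        return self.model.laterality

    @property
    def plane(self) -> geometry.PlaneFit:
        if self._plane is None:
            self._plane = geometry.fit_contour_plane(self.contour)
        return self._plane

    @property
    def theta_x_deg(self) -> float:
        return self.plane.theta_x

    @property
    def theta_y_deg(self) -> float:
        return self.plane.theta_y

    def axis_diameters(self) -> dict[str, float]:
        return axis_diameters(self.contour, self.laterality)

    def sagittal_depths(self) -> dict[str, float]:
        return geometry.sagittal_depths(self.contour, self.laterality)

    def leveled_contour(self) -> LimbusContour3D:
        return geometry.level_contour(self.contour, self.plane)

    def delta_map(self, wtw, origin_policy: str = "apex") -> geometry.DeltaMap:
        return geometry.radial_difference_map(self.contour, wtw, origin_policy)

    def report(self, wtw=None, origin_policy: str = "apex") -> dict:
        return geometry.geometry_report(
            self.contour, wtw, self.laterality, origin_policy
        )

    def summary(self) -> str:
        c = self.contour
        radii = c.radii_xy()[c.valid]
        lines = [
            "3D limbus detection results",
            "=" * 43,
            f"laterality            {self.laterality}",
            f"valid meridians       {int(c.valid.sum())}/{c.n_meridians}",
            f"mean limbal radius    {radii.mean():8.3f} mm",
            f"radius range          {radii.min():.3f} : {radii.max():.3f} mm",
            f"tilt theta_x          {self.theta_x_deg:8.3f} deg",
            f"tilt theta_y          {self.theta_y_deg:8.3f} deg",
            f"plane RMS residual    {self.plane.rms_residual:8.4f} mm",
        ]
        try:
            d = self.axis_diameters()
            lines.append(f"NT diameter           {d['NT']:8.3f} mm")
            lines.append(f"SI diameter           {d['SI']:8.3f} mm")
        except AxisMeridianInvalid:
            lines.append("NT/SI diameters       unavailable (axis meridian invalid)")
        try:
            depths = self.sagittal_depths()
            lines.append(
                "sagittal depth (mm)   "
                + "  ".join(f"{k[0].upper()}={v:.3f}" for k, v in depths.items())
            )
        except AxisMeridianInvalid:
            lines.append("sagittal depths       unavailable (axis meridian invalid)")
        return "\n".join(lines)

    def plot_contour(self, ax=None):
        """Detected limbal radius per meridian angle; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.contour
        r = np.where(c.valid, c.radii_xy(), np.nan)
        ax.plot(c.angle_deg, r, ".", ms=3)
        ax.set_xlabel("meridian angle (deg)")
        ax.set_ylabel("limbal radius (mm)")
        return ax
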