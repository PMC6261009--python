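"""Shared containers and coordinate conventions.

Coordinate frame
----------------
The corneal apex sits at the origin with +Z toward the camera; the anterior
surface is stored with ``z <= 0`` so that the sag ``s(r) = -z`` grows from
zero at the apex.  Meridian angles are measured counter-clockwise from +X in
the en-face view, in degrees.

Clinical orientation labels depend on laterality.  In an unmirrored camera
image of the face, the nose lies toward +X for the right eye and toward -X
for the left eye, hence:

====================  ======  ======
orientation           right    left
====================  ======  ======
nasal                 0 deg   180 deg
temporal              180 deg 0 deg
superior              90 deg  90 deg
inferior              270 deg 270 deg
====================  ======  ======

This sign choice is what lets a limbus plane that is higher on the nasal
side come out with a positive Y-tilt for right eyes and a negative one for
left eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    BadCalibration,
    BadParameters,
    EmptySurface,
    MissingField,
)

#: Tolerance (mm) by which z may exceed 0 after apex-centering; a few-degree
#: whole-eye tilt lifts the surface near the apex by up to ~R(1-cos(tilt)).
APEX_Z_TOL = 0.05

LATERALITIES = ("right", "left")


def clinical_angles(laterality: str) -> dict[str, int]:
    """Map clinical orientation labels to meridian angles (degrees)."""
    if laterality not in LATERALITIES:
        raise MissingField(f"laterality must be one of {LATERALITIES}, got {laterality!r}")
    nasal = 0 if laterality == "right" else 180
    return {
        "nasal": nasal,
        "temporal": (nasal + 180) % 360,
        "superior": 90,
        "inferior": 270,
    }


@dataclass
class HeightField:
    """Scattered or gridded anterior-surface points in mm, apex-centered.

    Parameters
    ----------
    points : (N, 3) array
        ``x, y, z`` in mm.  Non-finite rows are dropped on construction.
    grid_flag : bool
        Whether the XY layout is a regular grid (informational only; all
        consumers treat the points as scattered).
    """

    points: np.ndarray
    grid_flag: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise BadParameters("height points must be an (N, 3) array")
        finite = np.isfinite(pts).all(axis=1)
        pts = pts[finite]
        if pts.shape[0] == 0:
            raise EmptySurface("no finite height points")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def max_radius(self) -> float:
        """Largest polar radius covered by the XY layout."""
        return float(np.hypot(self.points[:, 0], self.points[:, 1]).max())


@dataclass
class EyeImage:
    """8-bit grayscale en-face frame with mm/px calibration factors."""

    pixels: np.ndarray
    cal_h: float
    cal_v: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise BadParameters("image must be a 2D array")
        if px.dtype != np.uint8:
            arr = np.asarray(px, dtype=float)
            if not np.isfinite(arr).all() or arr.min() < 0 or arr.max() > 255:
                raise BadParameters("intensities must lie in [0, 255]")
            if not np.allclose(arr, np.round(arr)):
                raise BadParameters("intensities must be integer-valued")
            px = arr.astype(np.uint8)
        self.pixels = px
        for name in ("cal_h", "cal_v"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise BadCalibration(f"{name} must be positive and finite, got {val}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def principal_point(self) -> tuple[float, float]:
        """Default image/surface registration point: the frame centre (x, y px)."""
        return ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)


@dataclass
class EyeRecord:
    """One scan of one eye: height data, apex, image and identifiers."""

    laterality: str
    height: HeightField
    apex: np.ndarray
    image: EyeImage | None = None
    subject_id: str = ""
    scan_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            # never inferred silently: absent/garbled laterality is an error
            raise MissingField(f"laterality must be one of {LATERALITIES}")
        self.apex = np.asarray(self.apex, dtype=float).reshape(3)
        if not np.isfinite(self.apex).all():
            raise MissingField("apex coordinates must be finite")
        xy = self.height.points[:, :2]
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        if np.any(self.apex[:2] < lo - 1e-9) or np.any(self.apex[:2] > hi + 1e-9):
            raise BadParameters("apex XY lies outside the height-field extent")

    def apex_centered(self) -> "EyeRecord":
        """Re-express the surface with the apex at the origin (idempotent).

        Raises :class:`BadParameters` if, after centering, the surface rises
        more than :data:`APEX_Z_TOL` above the apex plane.
        """
        pts = self.height.points - self.apex[None, :]
        if pts[:, 2].max() > APEX_Z_TOL:
            raise BadParameters(
                "surface rises above the apex plane by more than "
                f"{APEX_Z_TOL} mm; apex coordinates are inconsistent"
            )
        return EyeRecord(
            laterality=self.laterality,
            height=HeightField(pts, grid_flag=self.height.grid_flag),
            apex=np.zeros(3),
            image=self.image,
            subject_id=self.subject_id,
            scan_id=self.scan_id,
            metadata=dict(self.metadata),
        )


@dataclass
class WTWContour:
    """White-to-white contour: per-degree polar radii about the mask centroid.

    ``center`` is in mm relative to the image principal point, +X right and
    +Y up; ``radius_mm[k]`` is the boundary radius along meridian ``k`` deg.
    """

    center: np.ndarray
    radius_mm: np.ndarray
    laterality: str = "right"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(2)
        self.radius_mm = np.asarray(self.radius_mm, dtype=float).reshape(-1)
        if self.radius_mm.shape[0] != 360:
            raise BadParameters("WTW contour must hold exactly 360 radii")
        if not np.isfinite(self.radius_mm).all() or (self.radius_mm <= 0).any():
            raise BadParameters("WTW radii must be positive and finite")
        if self.laterality not in LATERALITIES:
            raise MissingField(f"laterality must be one of {LATERALITIES}")

    @property
    def angle_deg(self) -> np.ndarray:
        return np.arange(360, dtype=float)

    def boundary_points(self) -> np.ndarray:
        """(360, 2) boundary points in mm about the principal point."""
        th = np.deg2rad(self.angle_deg)
        return self.center[None, :] + self.radius_mm[:, None] * np.stack(
            [np.cos(th), np.sin(th)], axis=1
        )


@dataclass
class LimbusContour3D:
    """360-degree limbus contour: one 3D point per meridian plus validity."""

    angle_deg: np.ndarray
    points: np.ndarray
    valid: np.ndarray
    quality: np.ndarray

    def __post_init__(self) -> None:
        self.angle_deg = np.asarray(self.angle_deg, dtype=float).reshape(-1)
        n = self.angle_deg.shape[0]
        self.points = np.asarray(self.points, dtype=float).reshape(n, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(n)
        self.quality = np.asarray(self.quality, dtype=float).reshape(n)
        if n < 4:
            raise BadParameters("contour needs at least 4 meridians")

    @property
    def n_meridians(self) -> int:
        return self.angle_deg.shape[0]

    def radii_xy(self) -> np.ndarray:
        """Polar radius of each contour point about the apex (XY projection)."""
        return np.hypot(self.points[:, 0], self.points[:, 1])

    def meridian_index(self, angle_deg: float) -> int:
        """Index of the meridian closest to ``angle_deg`` (must be on-grid)."""
        idx = int(np.argmin(np.abs(((self.angle_deg - angle_deg) + 180) % 360 - 180)))
        return idx
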