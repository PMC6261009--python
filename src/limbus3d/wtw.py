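"""Dynamic white-to-white (visible iris boundary) detection.

A grayscale eye frame contains three intensity populations — the pupil is
darkest, the iris intermediate, the sclera brightest — and whatever the
iris colour or room illumination, that ordering is preserved.  The
threshold separating iris from sclera is therefore found *dynamically* on
each frame: locate the three most prominent peaks of the (smoothed) light
intensity frequency spectrum, take the valley of the spectrum between the
iris and sclera peaks as the cut, keep the connected dark region around a
seed point (defaulting to the frame centre), and fill its interior holes
(pupil, specular highlight dots).  The boundary of that region is the
white-to-white contour; its per-degree radii about the mask centroid are
converted to mm with the horizontal/vertical calibration factors.

Because every quantity is derived from the frame's own histogram, adding a
constant illumination offset (without clipping) shifts the peaks and the
threshold by exactly that offset and leaves the contour unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .core import EyeImage, WTWContour, clinical_angles
from .exceptions import (
    BadParameters,
    DegenerateMask,
    EmptyRegion,
    PeakCountError,
    SeedOutsideDark,
)

#: 3-px disc (radius 1) used for the single opening that removes pixel
#: bridges between the iris region and eyelashes.
_DISC3 = ndimage.generate_binary_structure(2, 1)


@dataclass
class IntensitySpectrum:
    """Light-intensity frequency spectrum of an 8-bit frame."""

    counts: np.ndarray
    smoothed: np.ndarray
    smooth_window: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if self.counts.shape != (256,) or self.smoothed.shape != (256,):
            raise BadParameters("spectrum must hold 256 levels")


@dataclass
class PeakTriple:
    """Pupil, iris and sclera peak intensities (ascending) with prominences."""

    pupil_I: int
    iris_I: int
    sclera_I: int
    prominences: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.pupil_I < self.iris_I < self.sclera_I):
            raise PeakCountError("peak intensities must be strictly increasing")


def intensity_spectrum(image: EyeImage, smooth_window: int = 7) -> IntensitySpectrum:
    """Pixel counts per intensity level plus a centred moving average.

    The moving average uses symmetric (edge-reflecting) padding, which
    conserves the total count exactly.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise BadParameters("smooth_window must be an odd integer >= 1")
    counts = np.bincount(image.pixels.ravel(), minlength=256)
    if smooth_window == 1:
        smoothed = counts.astype(float)
    else:
        half = smooth_window // 2
        padded = np.pad(counts.astype(float), half, mode="symmetric")
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        smoothed = np.convolve(padded, kernel, mode="valid")
    return IntensitySpectrum(counts=counts, smoothed=smoothed, smooth_window=smooth_window)


def locate_colour_peaks(
    spectrum: IntensitySpectrum, min_prominence: float = 0.01
) -> PeakTriple:
    """The three most prominent peaks of the smoothed spectrum.

    ``min_prominence`` is a fraction of the global maximum.  The triple is
    returned sorted by *intensity*, not prominence: the darkest peak is the
    pupil, the middle one the iris, the brightest the sclera, regardless of
    their relative heights.

    Raises
    ------
    PeakCountError
        Fewer than three local maxima pass the prominence gate.
    """
    y = spectrum.smoothed
    # sentinel padding so maxima at levels 0 and 255 count as peaks
    padded = np.concatenate([[-1.0], y, [-1.0]])
    threshold = min_prominence * float(y.max())
    peaks, props = find_peaks(padded, prominence=threshold)
    if peaks.size < 3:
        raise PeakCountError(
            f"found {peaks.size} prominent peaks, need 3 (pupil/iris/sclera)"
        )
    order = np.argsort(props["prominences"])[::-1][:3]
    levels = np.sort(peaks[order] - 1)
    prom_by_level = {int(p - 1): float(q) for p, q in
                     zip(peaks[order], props["prominences"][order])}
    return PeakTriple(
        pupil_I=int(levels[0]),
        iris_I=int(levels[1]),
        sclera_I=int(levels[2]),
        prominences=tuple(prom_by_level[int(v)] for v in levels),
    )


def dynamic_threshold(spectrum: IntensitySpectrum, peaks: PeakTriple) -> int:
    """Valley of the smoothed spectrum between the iris and sclera peaks."""
    lo, hi = peaks.iris_I, peaks.sclera_I
    return int(lo + np.argmin(spectrum.smoothed[lo : hi + 1]))


def extract_iris_region(
    image: EyeImage,
    peaks: PeakTriple,
    seed_point: tuple[int, int] | None = None,
    highlight_cutoff: int = 250,
    spectrum: IntensitySpectrum | None = None,
    smooth_window: int = 7,
) -> np.ndarray:
    """Binary mask of the dark (iris + pupil) region containing the seed.

    Pixels below the iris/sclera valley form the dark class; a single
    opening with a 3-px disc removes pixel bridges, the 4-connected
    component containing ``seed_point`` (x, y pixels; default the frame
    centre) is kept, and interior holes — the pupil and any specular
    highlights above ``highlight_cutoff`` — are filled.

    Raises
    ------
    SeedOutsideDark
        The seed pixel falls in the bright class.
    EmptyRegion
        No dark component survives at the seed after the opening.
    """
    if spectrum is None:
        spectrum = intensity_spectrum(image, smooth_window)
    cut = dynamic_threshold(spectrum, peaks)
    dark = image.pixels < cut
    if seed_point is None:
        sx, sy = image.principal_point()
    else:
        sx, sy = seed_point
    row, col = int(round(sy)), int(round(sx))
    if not (0 <= row < image.height_px and 0 <= col < image.width_px):
        raise SeedOutsideDark("seed point outside the frame")
    # highlights inside the pupil/iris count as dark for the seed test:
    # they are interior holes by definition
    if not dark[row, col] and image.pixels[row, col] < highlight_cutoff:
        raise SeedOutsideDark(
            f"seed pixel intensity {image.pixels[row, col]} is above the "
            f"dynamic threshold {cut}"
        )
    opened = ndimage.binary_opening(dark, structure=_DISC3)
    labels, _ = ndimage.label(opened, structure=_DISC3)
    lab = labels[row, col]
    if lab == 0:
        # seed may sit in a filled highlight hole; take the label that
        # surrounds it by looking at the nearest labelled pixel
        filled_all = ndimage.binary_fill_holes(opened, structure=_DISC3)
        if not filled_all[row, col]:
            raise EmptyRegion("no dark component at the seed point")
        lab_candidates = np.bincount(labels[filled_all & (labels > 0)])
        lab = int(np.argmax(lab_candidates))
    mask = labels == lab
    return ndimage.binary_fill_holes(mask, structure=_DISC3)


def trace_wtw_contour(
    mask: np.ndarray,
    image: EyeImage,
    laterality: str = "right",
    step_px: float = 0.25,
) -> WTWContour:
    """Per-degree boundary radii of the filled mask about its centroid.

    Rays are marched outward from the centroid at ``step_px`` resolution
    (bilinear sampling of the mask); the outermost 0.5-crossing along each
    ray is the boundary, located to sub-pixel precision by linear
    interpolation.  Radii are converted to mm with the anisotropic
    calibration and the centre is expressed in mm about the principal
    point, +X right and +Y up.

    Raises
    ------
    DegenerateMask
        Fewer than 3 mask pixels, or a ray that never enters the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise DegenerateMask("mask has fewer than 3 pixels")
    cy, cx = ndimage.center_of_mass(mask)
    h, w = mask.shape
    n_steps = int(np.hypot(h, w) / step_px) + 2
    rr = np.arange(n_steps) * step_px
    th = np.deg2rad(np.arange(360.0))
    # +Y up in the en-face frame means decreasing row index
    rows = cy - np.sin(th)[:, None] * rr[None, :]
    cols = cx + np.cos(th)[:, None] * rr[None, :]
    m = ndimage.map_coordinates(
        mask.astype(np.float32),
        [rows.ravel(), cols.ravel()],
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(360, n_steps)

    inside = m >= 0.5
    if not inside[:, 0].all():
        raise DegenerateMask("mask centroid lies outside the mask")
    # outermost inside sample per ray
    last = n_steps - 1 - np.argmax(inside[:, ::-1], axis=1)
    frac = np.zeros(360)
    has_next = last + 1 < n_steps
    i0, i1 = last, np.minimum(last + 1, n_steps - 1)
    v0 = m[np.arange(360), i0]
    v1 = m[np.arange(360), i1]
    denom = v0 - v1
    ok = has_next & (denom > 1e-9)
    frac[ok] = (v0[ok] - 0.5) / denom[ok]
    r_px = (last + frac) * step_px

    scale = np.sqrt(
        (np.cos(th) * image.cal_h) ** 2 + (np.sin(th) * image.cal_v) ** 2
    )
    px, py = image.principal_point()
    center_mm = np.array([(cx - px) * image.cal_h, (py - cy) * image.cal_v])
    return WTWContour(center=center_mm, radius_mm=r_px * scale, laterality=laterality)


def wtw_axis_distances(contour: WTWContour) -> dict[str, float]:
    """NT and SI white-to-white distances (mm) across the contour centre."""
    ang = clinical_angles(contour.laterality)
    r = contour.radius_mm
    return {
        "NT": float(r[ang["nasal"]] + r[ang["temporal"]]),
        "SI": float(r[ang["superior"]] + r[ang["inferior"]]),
    }


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

class WhiteToWhiteModel:
    """Dynamic-threshold WTW detector for one calibrated eye frame."""

    def __init__(
        self,
        image: EyeImage,
        laterality: str = "right",
        smooth_window: int = 7,
        min_prominence: float = 0.01,
        seed_point: tuple[int, int] | None = None,
        highlight_cutoff: int = 250,
    ) -> None:
        self.image = image
        self.laterality = laterality
        self.params = dict(
            smooth_window=smooth_window,
            min_prominence=min_prominence,
            seed_point=seed_point,
            highlight_cutoff=highlight_cutoff,
        )

    def fit(self) -> "WTWResults":
        p = self.params
        spectrum = intensity_spectrum(self.image, p["smooth_window"])
        peaks = locate_colour_peaks(spectrum, p["min_prominence"])
        mask = extract_iris_region(
            self.image,
            peaks,
            seed_point=p["seed_point"],
            highlight_cutoff=p["highlight_cutoff"],
            spectrum=spectrum,
        )
        contour = trace_wtw_contour(mask, self.image, laterality=self.laterality)
        return WTWResults(self, spectrum, peaks, dynamic_threshold(spectrum, peaks),
                          mask, contour)


class WTWResults:
    """Fitted white-to-white contour with its spectrum diagnostics."""

    def __init__(self, model, spectrum, peaks, threshold, mask, contour) -> None:
        self.model = model
        self.spectrum: IntensitySpectrum = spectrum
        self.peaks: PeakTriple = peaks
        self.threshold: int = threshold
        self.mask: np.ndarray = mask
        self.contour: WTWContour = contour

    @property
    def laterality(self) -> str:
        return self.model.laterality

    def axis_distances(self) -> dict[str, float]:
        return wtw_axis_distances(self.contour)

    @property
    def nt_mm(self) -> float:
        return self.axis_distances()["NT"]

    @property
    def si_mm(self) -> float:
        return self.axis_distances()["SI"]

    def to_json_dict(self) -> dict:
        d = self.axis_distances()
        return {
            "laterality": self.laterality,
            "center_mm": [float(v) for v in self.contour.center],
            "peaks": {
                "pupil_I": self.peaks.pupil_I,
                "iris_I": self.peaks.iris_I,
                "sclera_I": self.peaks.sclera_I,
            },
            "threshold": self.threshold,
            "NT_mm": d["NT"],
            "SI_mm": d["SI"],
        }

    def summary(self) -> str:
        d = self.axis_distances()
        return "\n".join(
            [
                "White-to-white detection results",
                "=" * 43,
                f"laterality            {self.laterality}",
                f"pupil/iris/sclera     {self.peaks.pupil_I}/{self.peaks.iris_I}/"
                f"{self.peaks.sclera_I}",
                f"dynamic threshold     {self.threshold}",
                f"mask area             {int(self.mask.sum())} px",
                f"centre (mm)           ({self.contour.center[0]:+.3f}, "
                f"{self.contour.center[1]:+.3f})",
                f"NT distance           {d['NT']:8.3f} mm",
                f"SI distance           {d['SI']:8.3f} mm",
            ]
        )

    def plot_spectrum(self, ax=None):
        """Spectrum with the detected peaks and threshold; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.spectrum.counts, lw=0.7, alpha=0.5, label="counts")
        ax.plot(self.spectrum.smoothed, lw=1.2, label="smoothed")
        for name, level in [("pupil", self.peaks.pupil_I),
                            ("iris", self.peaks.iris_I),
                            ("sclera", self.peaks.sclera_I)]:
            ax.axvline(level, ls=":", color="k", alpha=0.6)
            ax.annotate(name, (level, ax.get_ylim()[1] * 0.9), fontsize=8)
        ax.axvline(self.threshold, color="r", ls="--", label="threshold")
        ax.set_xlabel("intensity level")
        ax.set_ylabel("pixel count")
        ax.legend()
        return ax
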