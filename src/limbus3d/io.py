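"""Reading and writing per-eye records and contour files.

Two record layouts are supported:

* **MAT container (read-only).**  Profilometer exports arrive as MATLAB v5
  ``.mat`` files whose field names vary between software versions, so the
  caller must supply a ``key_map`` naming the container fields; a
  documented guess (:data:`DEFAULT_KEY_MAP`) is provided but never applied
  implicitly.
* **Portable layout (read/write).**  A directory holding ``record.json``
  (ids, laterality, apex, calibration), ``surface.csv``
  (``x_mm,y_mm,z_mm``) and ``image.png`` (8-bit grayscale).  Loading is the
  exact inverse of saving.

Contour files are plain CSV: ``angle_deg,x_mm,y_mm,z_mm,valid`` for the 3D
limbus contour and ``angle_deg,radius_mm`` for the white-to-white contour
(the WTW centre, laterality and any other scalars ride in ``#``-comment
header lines so the column schema stays minimal).

On load, every record is re-expressed apex-centered: the apex coordinates
are subtracted so the surface satisfies the sag convention (z = 0 at the
apex, z <= 0 peripherally).  The operation is idempotent.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import EyeImage, EyeRecord, HeightField, LimbusContour3D, WTWContour
from .exceptions import (
    BadCalibration,
    IOFailure,
    MissingField,
    SchemaMismatch,
)

#: A plausible mapping of canonical fields to MAT container keys.  Field
#: names are not standardised across device software versions — always
#: check against an actual export and pass your own map.
DEFAULT_KEY_MAP = {
    "height": "Data",          # (N, 3) or {x, y, z} height data, mm
    "apex": "Apex",            # (3,) apex coordinates, mm
    "image": "Image",          # (1024, 1280) uint8 frame
    "cal_h": "CalibrationH",   # mm per pixel, horizontal
    "cal_v": "CalibrationV",   # mm per pixel, vertical
    "laterality": "Eye",       # 'right'/'left' (or 'OD'/'OS')
}

_LATERALITY_ALIASES = {
    "right": "right", "od": "right", "r": "right",
    "left": "left", "os": "left", "l": "left",
}

_LIMBUS_HEADER = "angle_deg,x_mm,y_mm,z_mm,valid"
_WTW_HEADER = "angle_deg,radius_mm"


def _norm_laterality(value) -> str:
    key = str(value).strip().lower()
    if key not in _LATERALITY_ALIASES:
        raise MissingField(f"unrecognised laterality {value!r}")
    return _LATERALITY_ALIASES[key]


# --------------------------------------------------------------------------
# eye records
# --------------------------------------------------------------------------

def save_eye_record(record: EyeRecord, path: str | Path) -> Path:
    """Write the portable record layout; returns the directory path."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "subject_id": record.subject_id,
            "scan_id": record.scan_id,
            "laterality": record.laterality,
            "apex_mm": [float(v) for v in record.apex],
            "cal_h": record.image.cal_h if record.image is not None else None,
            "cal_v": record.image.cal_v if record.image is not None else None,
            "grid_flag": bool(record.height.grid_flag),
            "metadata": record.metadata,
        }
        (path / "record.json").write_text(json.dumps(meta, indent=2))
        pd.DataFrame(
            record.height.points, columns=["x_mm", "y_mm", "z_mm"]
        ).to_csv(path / "surface.csv", index=False, float_format="%.9f")
        if record.image is not None:
            iio.imwrite(path / "image.png", record.image.pixels)
    except OSError as exc:
        raise IOFailure(f"cannot write record to {path}: {exc}") from exc
    return path


def _load_portable(path: Path) -> EyeRecord:
    meta_path = path / "record.json"
    if not meta_path.exists():
        raise MissingField(f"{meta_path} not found")
    meta = json.loads(meta_path.read_text())
    for key in ("laterality", "apex_mm"):
        if meta.get(key) is None:
            raise MissingField(f"record.json lacks {key!r}")
    surf_path = path / "surface.csv"
    if not surf_path.exists():
        raise MissingField(f"{surf_path} not found")
    df = pd.read_csv(surf_path)
    if list(df.columns) != ["x_mm", "y_mm", "z_mm"]:
        raise SchemaMismatch(f"surface.csv columns {list(df.columns)}")
    image = None
    img_path = path / "image.png"
    if img_path.exists():
        cal_h, cal_v = meta.get("cal_h"), meta.get("cal_v")
        if cal_h is None or cal_v is None:
            raise BadCalibration("image present but calibration missing")
        image = EyeImage(iio.imread(img_path), cal_h=cal_h, cal_v=cal_v)
    return EyeRecord(
        laterality=_norm_laterality(meta["laterality"]),
        height=HeightField(df.to_numpy(), grid_flag=bool(meta.get("grid_flag", False))),
        apex=np.asarray(meta["apex_mm"], dtype=float),
        image=image,
        subject_id=str(meta.get("subject_id", "")),
        scan_id=str(meta.get("scan_id", "")),
        metadata=dict(meta.get("metadata", {})),
    )


def _load_mat(path: Path, key_map: dict[str, str]) -> EyeRecord:
    from scipy.io import loadmat

    try:
        container = loadmat(path, squeeze_me=True)
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc

    def fetch(name: str, required: bool = True):
        key = key_map.get(name)
        if key is None or key not in container:
            if required:
                raise MissingField(f"container lacks mapped key for {name!r}")
            return None
        return container[key]

    height = np.asarray(fetch("height"), dtype=float)
    if height.ndim != 2 or height.shape[1] != 3:
        raise SchemaMismatch("height data must be an (N, 3) array of x, y, z mm")
    cal_h, cal_v = float(fetch("cal_h")), float(fetch("cal_v"))
    if not np.isfinite(cal_h) or not np.isfinite(cal_v) or cal_h <= 0 or cal_v <= 0:
        raise BadCalibration(f"calibration ({cal_h}, {cal_v}) invalid")
    return EyeRecord(
        laterality=_norm_laterality(fetch("laterality")),
        height=HeightField(height),
        apex=np.asarray(fetch("apex"), dtype=float),
        image=EyeImage(np.asarray(fetch("image")), cal_h=cal_h, cal_v=cal_v),
        subject_id=str(container.get(key_map.get("subject_id", ""), "")),
        scan_id=str(container.get(key_map.get("scan_id", ""), "")),
    )


def load_eye_record(path: str | Path, key_map: dict[str, str] | None = None) -> EyeRecord:
    """Load a record (portable directory or MAT container), apex-centered.

    Provenance (source path and the key map used) is stored in the record
    metadata.

    Raises
    ------
    MissingField, BadCalibration, EmptySurface, SchemaMismatch, IOFailure
    """
    path = Path(path)
    if path.is_dir():
        record = _load_portable(path)
    elif path.suffix.lower() == ".mat":
        if key_map is None:
            raise MissingField(
                "loading a MAT container requires an explicit key_map "
                "(see limbus3d.io.DEFAULT_KEY_MAP for a starting point)"
            )
        record = _load_mat(path, key_map)
    elif not path.exists():
        raise IOFailure(f"{path} does not exist")
    else:
        raise SchemaMismatch(f"unsupported record path {path}")
    record.metadata.setdefault("source", str(path))
    if key_map is not None:
        record.metadata.setdefault("key_map", dict(key_map))
    return record.apex_centered()


# --------------------------------------------------------------------------
# contours
# --------------------------------------------------------------------------

def write_limbus_contour(contour: LimbusContour3D, path: str | Path) -> Path:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(_LIMBUS_HEADER + "\n")
            for ang, (x, y, z), ok in zip(
                contour.angle_deg, contour.points, contour.valid
            ):
                if ok:
                    fh.write(f"{ang:.6f},{x:.9f},{y:.9f},{z:.9f},1\n")
                else:
                    fh.write(f"{ang:.6f},nan,nan,nan,0\n")
    except OSError as exc:
        raise IOFailure(f"cannot write contour to {path}: {exc}") from exc
    return path


def read_limbus_contour(path: str | Path) -> LimbusContour3D:
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"{path} does not exist")
    lines = [ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")]
    if not lines or lines[0].strip() != _LIMBUS_HEADER:
        raise SchemaMismatch(
            f"expected header {_LIMBUS_HEADER!r}, got {lines[0] if lines else ''!r}"
        )
    data = np.genfromtxt(lines[1:], delimiter=",")
    if data.ndim != 2 or data.shape[1] != 5:
        raise SchemaMismatch("limbus contour rows must have 5 columns")
    return LimbusContour3D(
        angle_deg=data[:, 0],
        points=data[:, 1:4],
        valid=data[:, 4] > 0.5,
        quality=np.zeros(data.shape[0]),
    )


def write_wtw_contour(contour: WTWContour, path: str | Path) -> Path:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            fh.write(f"# center_mm: {contour.center[0]:.9f} {contour.center[1]:.9f}\n")
            fh.write(f"# laterality: {contour.laterality}\n")
            fh.write(_WTW_HEADER + "\n")
            for ang, r in zip(contour.angle_deg, contour.radius_mm):
                fh.write(f"{ang:.6f},{r:.9f}\n")
    except OSError as exc:
        raise IOFailure(f"cannot write contour to {path}: {exc}") from exc
    return path


def read_wtw_contour(path: str | Path) -> WTWContour:
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"{path} does not exist")
    center = np.zeros(2)
    laterality = "right"
    lines = []
    for ln in path.read_text().splitlines():
        if ln.startswith("# center_mm:"):
            center = np.array([float(v) for v in ln.split(":")[1].split()])
        elif ln.startswith("# laterality:"):
            laterality = _norm_laterality(ln.split(":")[1])
        elif ln and not ln.startswith("#"):
            lines.append(ln)
    if not lines or lines[0].strip() != _WTW_HEADER:
        raise SchemaMismatch(
            f"expected header {_WTW_HEADER!r}, got {lines[0] if lines else ''!r}"
        )
    data = np.genfromtxt(lines[1:], delimiter=",")
    if data.ndim != 2 or data.shape[1] != 2:
        raise SchemaMismatch("WTW contour rows must have 2 columns")
    return WTWContour(center=center, radius_mm=data[:, 1], laterality=laterality)


def contour_io(
    contour: LimbusContour3D | WTWContour | None,
    path: str | Path,
    direction: str,
    kind: str | None = None,
):
    """Single entry point mirroring the spec'd read/write contract.

    ``direction`` is ``"write"`` (requires ``contour``) or ``"read"``
    (``kind`` in ``{"limbus", "wtw"}`` selects the schema; if omitted it is
    inferred from the file header).
    """
    if direction == "write":
        if isinstance(contour, LimbusContour3D):
            return write_limbus_contour(contour, path)
        if isinstance(contour, WTWContour):
            return write_wtw_contour(contour, path)
        raise SchemaMismatch("contour must be LimbusContour3D or WTWContour")
    if direction == "read":
        if kind is None:
            head = Path(path).read_text().splitlines()
            body = [ln for ln in head if ln and not ln.startswith("#")]
            kind = "limbus" if body and body[0].strip() == _LIMBUS_HEADER else "wtw"
        return read_limbus_contour(path) if kind == "limbus" else read_wtw_contour(path)
    raise ValueError("direction must be 'read' or 'write'")
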