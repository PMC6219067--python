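"""Cine series and landmark I/O.

A cine long-axis acquisition is held as a :class:`CineSeries`: a ``T x H x W``
intensity stack plus the physical calibration needed downstream — pixel
spacing in mm and the frame interval in ms.  Frame 0 is, by convention, LV
end-diastole: the reference phase for strain.

Supported containers:

* ``npz`` — the repository's canonical fixture dialect
  (keys ``frames``, ``spacing``, ``interval_ms``, ``view``, ``subject_id``).
* DICOM series directory — one secondary-capture file per frame
  (read and write; integer dtypes via PixelData, float32 via FloatPixelData).
* NIfTI — read only; spacing taken from the header, timing from the header
  only when its time unit is explicit, otherwise an override is required.

Coordinates everywhere are 0-based ``(row, col)``; row increases downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CalibrationError,
    DegenerateSeriesError,
    FormatError,
    ValidationError,
)

VIEWS = ("CH2", "CH4")

#: wall labels per view, keyed by the junction landmark they belong to
WALL_NAMES = {
    "CH4": {"junction_a": "septal", "junction_b": "lateral"},
    "CH2": {"junction_a": "anterior", "junction_b": "inferior"},
}

LANDMARK_NAMES = ("junction_a", "junction_b", "mid_posterior")

_MIN_EDGE = 32


@dataclass
class CineSeries:
    """One cine long-axis view with physical calibration.

    Parameters
    ----------
    frames
        ``(T, H, W)`` non-negative intensity stack, frame 0 = LV end-diastole.
    pixel_spacing
        ``(row_mm, col_mm)`` millimetres per pixel.
    frame_interval_ms
        Milliseconds between consecutive frames.
    view
        ``"CH2"`` (2-chamber) or ``"CH4"`` (4-chamber).
    subject_id
        Free-text identifier.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    frame_interval_ms: float
    view: str = "CH4"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 2:
            raise DegenerateSeriesError(f"need at least 2 frames, got {t}")
        if h < _MIN_EDGE or w < _MIN_EDGE:
            raise DegenerateSeriesError(
                f"frames must be at least {_MIN_EDGE}x{_MIN_EDGE}, got {h}x{w}"
            )
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if not all(s > 0 for s in self.pixel_spacing):
            raise CalibrationError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.frame_interval_ms = float(self.frame_interval_ms)
        if not self.frame_interval_ms > 0:
            raise CalibrationError(
                f"frame interval must be positive, got {self.frame_interval_ms}"
            )
        if self.view not in VIEWS:
            raise ValidationError(f"view must be one of {VIEWS}, got {self.view!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds from LV end-diastole."""
        return np.arange(self.n_frames) * self.frame_interval_ms / 1000.0


@dataclass
class LandmarkSet:
    """The three user annotations of one view, in frame-0 pixel coordinates.

    ``junction_a`` and ``junction_b`` are the atrioventricular junction points
    (mitral-annulus insertion points: septal/lateral on CH4, anterior/inferior
    on CH2); ``mid_posterior`` is the intersection of the LA posterior wall
    with the LA long axis.
    """

    view: str
    points: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValidationError(f"view must be one of {VIEWS}, got {self.view!r}")
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValidationError(f"missing landmark(s): {missing}")
        extra = [n for n in self.points if n not in LANDMARK_NAMES]
        if extra:
            raise ValidationError(f"unknown landmark(s): {extra}")
        pts = {}
        for name in LANDMARK_NAMES:
            r, c = self.points[name]
            r, c = float(r), float(c)
            if not (np.isfinite(r) and np.isfinite(c)):
                raise ValidationError(f"non-finite coordinates for {name}")
            pts[name] = (r, c)
        self.points = pts
        coords = list(pts.values())
        for i in range(3):
            for j in range(i + 1, 3):
                if coords[i] == coords[j]:
                    raise ValidationError("landmark points must be pairwise distinct")

    @property
    def wall_names(self) -> dict[str, str]:
        """Map junction landmark name -> wall label for this view."""
        return dict(WALL_NAMES[self.view])

    def validate_bounds(self, image_shape: tuple[int, int], margin: int) -> None:
        """Check every point sits inside the image with ``margin`` to spare."""
        h, w = image_shape
        for name, (r, c) in self.points.items():
            if not (margin <= r <= h - 1 - margin and margin <= c <= w - 1 - margin):
                raise ValidationError(
                    f"{name} at ({r}, {c}) violates the {margin}-px template margin "
                    f"for a {h}x{w} image"
                )


# ---------------------------------------------------------------------------
# npz dialect
# ---------------------------------------------------------------------------

def _load_npz(path: Path, overrides: dict) -> CineSeries:
    with np.load(path, allow_pickle=False) as data:
        if "frames" not in data:
            raise FormatError(f"{path}: npz fixture lacks a 'frames' key")
        frames = data["frames"]
        spacing = overrides.get("pixel_spacing") or (
            tuple(data["spacing"]) if "spacing" in data else None
        )
        interval = overrides.get("frame_interval_ms") or (
            float(data["interval_ms"]) if "interval_ms" in data else None
        )
        view = overrides.get("view") or (str(data["view"]) if "view" in data else "CH4")
        subject = overrides.get("subject_id") or (
            str(data["subject_id"]) if "subject_id" in data else ""
        )
    if spacing is None or interval is None:
        raise CalibrationError(f"{path}: spacing/interval absent and no override given")
    return CineSeries(frames, spacing, interval, view, subject)


def _save_npz(series: CineSeries, path: Path) -> None:
    np.savez(
        path,
        frames=series.frames,
        spacing=np.asarray(series.pixel_spacing, dtype=float),
        interval_ms=float(series.frame_interval_ms),
        view=series.view,
        subject_id=series.subject_id,
    )


# ---------------------------------------------------------------------------
# DICOM series directory
# ---------------------------------------------------------------------------

_INT_DTYPES = {
    np.dtype("uint8"): (8, 0),
    np.dtype("uint16"): (16, 0),
    np.dtype("int16"): (16, 1),
}


def _load_dicom_dir(path: Path, overrides: dict) -> CineSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"{path}: no DICOM files found")
    datasets = [pydicom.dcmread(f) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise FormatError(f"{path}: mixed SeriesInstanceUID ({len(uids)} series)")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise FormatError(f"{path}: mixed matrix sizes {sorted(shapes)}")
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets
                if "PixelSpacing" in ds}
    if len(spacings) > 1:
        raise CalibrationError(f"{path}: inconsistent PixelSpacing across slices")

    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    frames = []
    for ds in datasets:
        arr = ds.pixel_array
        # DICOM rescale applied once, deterministically, when present
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        if slope != 1.0 or intercept != 0.0:
            arr = arr.astype(np.float64) * slope + intercept
        frames.append(arr)
    stack = np.stack(frames)

    spacing = overrides.get("pixel_spacing")
    if spacing is None:
        if not spacings:
            raise CalibrationError(f"{path}: no PixelSpacing tag and no override")
        spacing = spacings.pop()

    interval = overrides.get("frame_interval_ms")
    if interval is None:
        ds0 = datasets[0]
        if "FrameTime" in ds0:
            interval = float(ds0.FrameTime)
        elif "NominalInterval" in ds0 and float(ds0.NominalInterval) > 0:
            interval = float(ds0.NominalInterval) / len(datasets)
        else:
            raise CalibrationError(
                f"{path}: no FrameTime/NominalInterval tag and no frame_interval_ms "
                "override; refusing to guess"
            )

    view = overrides.get("view") or str(getattr(datasets[0], "SeriesDescription", "CH4"))
    subject = overrides.get("subject_id") or str(getattr(datasets[0], "PatientID", ""))
    return CineSeries(stack, spacing, interval, view, subject)


def _save_dicom_dir(series: CineSeries, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    path.mkdir(parents=True, exist_ok=True)
    frames = series.frames
    if frames.dtype == np.float64:
        raise FormatError(
            "float64 frames cannot round-trip through DICOM; cast to float32 "
            "or an integer dtype first"
        )
    is_float = frames.dtype == np.float32
    if not is_float and frames.dtype not in _INT_DTYPES:
        raise FormatError(f"unsupported frame dtype for DICOM: {frames.dtype}")

    series_uid = generate_uid()
    study_uid = generate_uid()
    for i, frame in enumerate(frames):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "OT"
        ds.PatientID = series.subject_id or "anon"
        ds.PatientName = series.subject_id or "anon"
        ds.SeriesDescription = series.view
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = frame.shape
        # DS values are capped at 16 chars; %.10g keeps ~1e-10 relative precision
        ds.PixelSpacing = [f"{series.pixel_spacing[0]:.10g}", f"{series.pixel_spacing[1]:.10g}"]
        ds.FrameTime = f"{series.frame_interval_ms:.10g}"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        if is_float:
            ds.BitsAllocated = 32
            ds.FloatPixelData = frame.tobytes()
        else:
            bits, rep = _INT_DTYPES[frame.dtype]
            ds.BitsAllocated = bits
            ds.BitsStored = bits
            ds.HighBit = bits - 1
            ds.PixelRepresentation = rep
            ds.PixelData = frame.tobytes()
        ds.save_as(path / f"frame_{i:04d}.dcm", enforce_file_format=True)


# ---------------------------------------------------------------------------
# NIfTI (read-only)
# ---------------------------------------------------------------------------

def _load_nifti(path: Path, overrides: dict) -> CineSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 2D+t NIfTI, got shape {data.shape}")
    # NIfTI stores (x, y, t); move time first and keep (row, col) order
    frames = np.moveaxis(data, -1, 0)

    zooms = img.header.get_zooms()
    spacing = overrides.get("pixel_spacing") or (float(zooms[0]), float(zooms[1]))

    interval = overrides.get("frame_interval_ms")
    if interval is None:
        _, t_unit = img.header.get_xyzt_units()
        t_zoom = float(zooms[3]) if len(zooms) > 3 else 0.0
        if t_zoom > 0 and t_unit == "sec":
            interval = t_zoom * 1000.0
        elif t_zoom > 0 and t_unit == "msec":
            interval = t_zoom
        else:
            raise CalibrationError(
                f"{path}: NIfTI header has no explicit time unit; pass "
                "frame_interval_ms explicitly"
            )
    view = overrides.get("view") or "CH4"
    return CineSeries(frames, spacing, interval, view, overrides.get("subject_id") or "")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    if path.suffix == ".npz":
        return "npz"
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return "nifti"
    raise FormatError(f"cannot infer cine format from {path}")


def load_cine(
    path,
    format: str | None = None,
    *,
    pixel_spacing: tuple[float, float] | None = None,
    frame_interval_ms: float | None = None,
    view: str | None = None,
    subject_id: str | None = None,
) -> CineSeries:
    """Load a cine series, applying calibration overrides where metadata is absent.

    Explicit ``pixel_spacing`` / ``frame_interval_ms`` arguments always win
    over file metadata; missing calibration without an override raises
    :class:`~fastla.errors.CalibrationError` — never a silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    fmt = format or _infer_format(path)
    overrides = dict(
        pixel_spacing=pixel_spacing,
        frame_interval_ms=frame_interval_ms,
        view=view,
        subject_id=subject_id,
    )
    if fmt == "npz":
        return _load_npz(path, overrides)
    if fmt == "dicom_dir":
        return _load_dicom_dir(path, overrides)
    if fmt == "nifti":
        return _load_nifti(path, overrides)
    raise FormatError(f"unknown cine format {fmt!r}")


def save_cine(series: CineSeries, path, format: str | None = None) -> None:
    """Write a cine series as npz or a DICOM series directory."""
    path = Path(path)
    fmt = format or ("npz" if path.suffix == ".npz" else "dicom_dir")
    try:
        if fmt == "npz":
            _save_npz(series, path)
        elif fmt == "dicom_dir":
            _save_dicom_dir(series, path)
        else:
            raise FormatError(f"unknown cine format {fmt!r}")
    except (OSError, PermissionError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def load_landmarks(path) -> LandmarkSet:
    """Read a landmark annotation JSON: ``{"view": ..., "points": {...}}``."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if "view" not in doc or "points" not in doc:
        raise ValidationError(f"{path}: landmark JSON needs 'view' and 'points'")
    points = {name: tuple(xy) for name, xy in doc["points"].items()}
    return LandmarkSet(view=doc["view"], points=points)


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    doc = {
        "view": landmarks.view,
        "points": {name: list(xy) for name, xy in landmarks.points.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
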