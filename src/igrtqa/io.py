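"""Readers and writers for projection images and couch-correction records.

Supported raster formats: whitespace-delimited text matrices (lossless),
16-bit PNG/TIFF (lossless after a documented linear quantization), and
DICOM secondary capture.  Text/PNG/TIFF images carry their geometry in a
JSON sidecar written next to the raster (``<path>.json``); DICOM carries it
in the PixelSpacing and rescale tags.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .core import CouchCorrection, CouchRecordError, ImageFormatError, ProjectionImage

log = logging.getLogger(__name__)

_TEXT_SUFFIXES = {".txt", ".dat", ".mat.txt"}
_PNG_SUFFIXES = {".png"}
_TIFF_SUFFIXES = {".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}

QUANT_LEVELS = 65535  # 16-bit quantization for PNG/TIFF


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        return format_hint.lower()
    suffix = path.suffix.lower()
    if suffix in _TEXT_SUFFIXES:
        return "text"
    if suffix in _PNG_SUFFIXES:
        return "png"
    if suffix in _TIFF_SUFFIXES:
        return "tiff"
    if suffix in _DICOM_SUFFIXES:
        return "dicom"
    # fall back on the DICOM magic bytes
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            if fh.read(4) == b"DICM":
                return "dicom"
    except OSError:
        pass
    return "text"


def read_image(
    path: str | os.PathLike,
    format_hint: str | None = None,
    spacing: tuple[float, float] | None = None,
    modality: str | None = None,
) -> ProjectionImage:
    """Load a projection image from disk.

    ``spacing`` overrides any spacing found in the file; when neither is
    available a default of 1.0 mm is used and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"cannot read image: no such file {path}")
    fmt = _detect_format(path, format_hint)

    meta: dict = {}
    if fmt == "dicom":
        pixels, meta = _read_dicom(path)
    elif fmt in ("text", "png", "tiff"):
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if fmt == "text":
            try:
                pixels = np.loadtxt(path, ndmin=2)
            except ValueError as exc:
                raise ImageFormatError(f"cannot parse text matrix {path}: {exc}") from exc
        else:
            try:
                raw = np.asarray(iio.imread(path))
            except Exception as exc:  # imageio raises various things
                raise ImageFormatError(f"cannot read {fmt} image {path}: {exc}") from exc
            if raw.ndim == 3:  # collapse RGB(A) to luminance
                raw = raw[..., :3].mean(axis=-1)
            pixels = raw.astype(np.float64)
            if "quant_min" in meta:
                lo, hi = float(meta["quant_min"]), float(meta["quant_max"])
                pixels = lo + pixels * (hi - lo) / QUANT_LEVELS
    else:
        raise ImageFormatError(f"unsupported image format {fmt!r}")

    if not np.all(np.isfinite(pixels)):
        raise ImageFormatError(f"image {path} contains NaN or infinite pixels")

    if spacing is not None:
        sp = (float(spacing[0]), float(spacing[1]))
    elif "spacing" in meta:
        sp = (float(meta["spacing"][0]), float(meta["spacing"][1]))
    else:
        log.warning("no pixel spacing for %s; defaulting to 1.0 mm", path)
        sp = (1.0, 1.0)

    origin = tuple(meta.get("origin", (0.0, 0.0)))
    mod = modality or meta.get("modality", "SYNTHETIC")
    return ProjectionImage(pixels=pixels, spacing=sp, origin=origin, modality=mod)


def _read_dicom(path: Path) -> tuple[np.ndarray, dict]:
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:
        raise ImageFormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if "PixelData" not in ds:
        raise ImageFormatError(f"DICOM file {path} has no pixel data")
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    meta: dict = {}
    spacing_tag = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing_tag is not None:
        meta["spacing"] = (float(spacing_tag[0]), float(spacing_tag[1]))
    mod = str(getattr(ds, "Modality", "")).upper()
    if mod in ("DRR", "KV"):
        meta["modality"] = mod
    return pixels, meta


def write_image(
    image: ProjectionImage, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write an image to disk.

    Text is lossless; PNG/TIFF quantize linearly to 16 bits with the scale
    recorded in the sidecar (round-trip error at most range/65535); DICOM
    secondary capture records the scale in RescaleSlope/Intercept.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise ImageFormatError(f"output directory does not exist: {path.parent}")
    fmt = _detect_format(path, format)
    meta = {
        "spacing": list(image.spacing),
        "origin": list(image.origin),
        "modality": image.modality,
    }
    if fmt == "text":
        np.savetxt(path, image.pixels, fmt="%.17g")
        _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    elif fmt in ("png", "tiff"):
        lo = float(image.pixels.min())
        hi = float(image.pixels.max())
        scale = (hi - lo) or 1.0
        quant = np.round((image.pixels - lo) / scale * QUANT_LEVELS).astype(np.uint16)
        meta.update(quant_min=lo, quant_max=hi)
        ext = ".png" if fmt == "png" else ".tiff"
        iio.imwrite(path, quant, extension=ext)
        _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    elif fmt == "dicom":
        _write_dicom(image, path)
    else:
        raise ImageFormatError(f"unsupported output format {fmt!r}")


def _write_dicom(image: ProjectionImage, path: Path) -> None:
    lo = float(image.pixels.min())
    hi = float(image.pixels.max())
    scale = (hi - lo) or 1.0
    quant = np.round((image.pixels - lo) / scale * QUANT_LEVELS).astype(np.uint16)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [str(image.spacing[0]), str(image.spacing[1])]
    ds.RescaleSlope = scale / QUANT_LEVELS
    ds.RescaleIntercept = lo
    ds.PixelData = quant.tobytes()
    ds.save_as(path, enforce_file_format=True)


_COUCH_ALIASES = {
    "vert": "vert", "vertical": "vert",
    "lat": "lat", "lateral": "lat",
    "long": "long", "longitudinal": "long", "lng": "long",
    "rotation": "rotation", "yaw": "rotation", "rtn": "rotation",
    "pitch": "pitch",
}


def read_couch_record(path: str | os.PathLike) -> CouchCorrection:
    """Parse a clinical couch-correction record (JSON or ``key: value`` text).

    Rotation fields may be omitted (defaulting to zero, with a logged note);
    missing translation fields are an error.
    """
    path = Path(path)
    if not path.exists():
        raise CouchRecordError(f"no such couch record: {path}")
    text = path.read_text()
    stripped = text.lstrip()
    values: dict[str, float] = {}
    if stripped.startswith("{"):
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CouchRecordError(
                f"{path}: line {exc.lineno}: invalid JSON ({exc.msg})"
            ) from exc
        items = list(raw.items())
        lines = {k: 0 for k, _ in items}
    else:
        items = []
        lines = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = ":" if ":" in line else "=" if "=" in line else None
            if sep is None:
                raise CouchRecordError(f"{path}: line {lineno}: expected 'key: value'")
            key, _, val = line.partition(sep)
            items.append((key.strip(), val.strip()))
            lines[key.strip()] = lineno
    for key, val in items:
        canon = _COUCH_ALIASES.get(key.strip().lower())
        if canon is None:
            continue
        try:
            values[canon] = float(val)
        except (TypeError, ValueError) as exc:
            raise CouchRecordError(
                f"{path}: line {lines.get(key, 0)}: non-numeric value for {key!r}: {val!r}"
            ) from exc
    missing = [f for f in CouchCorrection.TRANSLATION_FIELDS if f not in values]
    if missing:
        raise CouchRecordError(f"{path}: missing translation field(s): {', '.join(missing)}")
    for f in CouchCorrection.ROTATION_FIELDS:
        if f not in values:
            log.info("couch record %s: %s not given, defaulting to 0", path, f)
            values[f] = 0.0
    return CouchCorrection(**values)


def write_couch_record(correction: CouchCorrection, path: str | os.PathLike) -> None:
    Path(path).write_text(json.dumps(correction.to_dict(), indent=2, sort_keys=True))
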