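"""Image and displacement-field readers/writers.

Float images travel as 16-bit integers with a stored slope/intercept, so a
write-then-read round trip is exact to one least-significant bit of the
16-bit range.  DICOM output is minimal monochrome projection radiography:
MONOCHROME2, 16 bits stored, PixelSpacing from the detector pitch, KVP and
ExposureTime taken from the acquisition settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

_MAX16 = 65535


class ImageIOError(IOError):
    """Raised with path context for unsupported or corrupt files."""


def _quantize(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    image = np.asarray(image, float)
    lo, hi = float(image.min()), float(image.max())
    slope = (hi - lo) / _MAX16 if hi > lo else 1.0
    data = np.round((image - lo) / slope).astype(np.uint16)
    return data, slope, lo


def write_image(path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Write a float image as 16-bit TIFF, PNG or DICOM by extension.

    ``metadata`` may carry ``kvp``, ``exposure_time`` (ms) and
    ``pixel_spacing`` (mm); all are embedded where the format allows.
    """
    path = Path(path)
    meta = dict(metadata or {})
    data, slope, intercept = _quantize(image)
    header = {"slope": slope, "intercept": intercept, **meta}
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, data, description=json.dumps(header))
    elif suffix == ".png":
        from PIL import Image
        from PIL.PngImagePlugin import PngInfo
        info = PngInfo()
        info.add_text("dexray", json.dumps(header))
        Image.fromarray(data.astype(np.int32), mode="I").convert("I;16").save(
            path, pnginfo=info)
    elif suffix == ".dcm":
        _write_dicom(path, data, slope, intercept, meta)
    else:
        raise ImageIOError(f"unsupported image extension {suffix!r}: {path}")


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read an image written by :func:`write_image`; returns floats plus
    the stored metadata."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile
            with tifffile.TiffFile(path) as tf:
                data = tf.asarray()
                header = json.loads(tf.pages[0].description or "{}")
        elif suffix == ".png":
            from PIL import Image
            with Image.open(path) as im:
                header = json.loads(im.info.get("dexray", "{}"))
                data = np.asarray(im, dtype=np.float64)
        elif suffix == ".dcm":
            return _read_dicom(path)
        else:
            raise ImageIOError(f"unsupported image extension {suffix!r}: {path}")
    except ImageIOError:
        raise
    except Exception as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    slope = header.pop("slope", 1.0)
    intercept = header.pop("intercept", 0.0)
    return np.asarray(data, float) * slope + intercept, header


def _write_dicom(path, data, slope, intercept, meta) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "DX"
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = data.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{intercept:.10g}"
    if "pixel_spacing" in meta:
        ps = float(meta["pixel_spacing"])
        ds.PixelSpacing = [f"{ps:.6g}", f"{ps:.6g}"]
    if "kvp" in meta:
        ds.KVP = f"{float(meta['kvp']):.6g}"
    if "exposure_time" in meta:
        ds.ExposureTime = f"{float(meta['exposure_time']):.6g}"
    ds.PixelData = data.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path) -> tuple[np.ndarray, dict]:
    import pydicom
    try:
        ds = pydicom.dcmread(path)
        data = ds.pixel_array.astype(float)
    except Exception as exc:
        raise ImageIOError(f"cannot read DICOM {path}: {exc}") from exc
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    header = {}
    if hasattr(ds, "KVP") and ds.KVP not in (None, ""):
        header["kvp"] = float(ds.KVP)
    if hasattr(ds, "ExposureTime") and ds.ExposureTime not in (None, ""):
        header["exposure_time"] = float(ds.ExposureTime)
    if hasattr(ds, "PixelSpacing"):
        header["pixel_spacing"] = float(ds.PixelSpacing[0])
    return data * slope + intercept, header


def write_field(path, field) -> None:
    """Displacement field as a two-plane 32-bit float TIFF (dy, dx)."""
    import tifffile
    dy, dx = (field.dy, field.dx) if hasattr(field, "dy") else (field[0], field[1])
    tifffile.imwrite(Path(path), np.stack([dy, dx]).astype(np.float32))


def read_field(path) -> np.ndarray:
    import tifffile
    try:
        arr = tifffile.imread(Path(path)).astype(float)
    except Exception as exc:
        raise ImageIOError(f"cannot read field {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ImageIOError(f"field file {path} must hold two planes")
    return arr
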