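"""Reading, writing and normalizing CT slices and scan volumes.

DICOM series are read one file per slice with pydicom; stored values are
mapped to Hounsfield units via the rescale slope/intercept, and slices are
ordered by axial position regardless of file enumeration order.  16-bit
grayscale PNG and ``.npy`` raw arrays are supported as first-class fallback
formats so the pipeline is testable without DICOM fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from PIL import Image

# Default intensity window: full ~4096-value CT range in Hounsfield units.
DEFAULT_LO_HU = -1024.0
DEFAULT_HI_HU = 3071.0


@dataclass
class SliceImage:
    """A single-channel intensity raster with optional spatial metadata."""

    pixels: np.ndarray
    spacing_mm: tuple | None = None
    z_position: float | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("expected single channel 2-D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ScanVolume:
    """Ordered stack of slices forming a 3-D scan (ascending z)."""

    slices: list
    slice_spacing_mm: float | None = None

    def __post_init__(self):
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError("all slices in a volume must share height/width")
        zs = [s.z_position for s in self.slices if s.z_position is not None]
        if len(zs) == len(self.slices) and len(zs) > 1:
            dz = np.diff(zs)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise ValueError("slice z positions must be strictly monotonic")

    def __len__(self) -> int:
        return len(self.slices)


@dataclass
class NormalizedSlice:
    """Pixels affinely mapped and clipped to [0, 1], with map provenance."""

    pixels: np.ndarray
    lo: float
    hi: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("normalized pixels must lie in [0, 1]")


def normalize_intensity(
    slc: SliceImage, lo: float = DEFAULT_LO_HU, hi: float = DEFAULT_HI_HU
) -> NormalizedSlice:
    """Affine map (pixels - lo) / (hi - lo), clipped to [0, 1].

    The default window (-1024, 3071) HU spans the ~4096 distinct values a CT
    stores, so the map is a fixed rescale rather than a per-slice stretch.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    out = np.clip((slc.pixels.astype(float) - lo) / (hi - lo), 0.0, 1.0)
    return NormalizedSlice(pixels=out, lo=float(lo), hi=float(hi), source_id=slc.source_id)


# ---- DICOM ------------------------------------------------------------------

def read_dicom_series(directory) -> ScanVolume:
    """Read a single-series DICOM directory into a HU-valued ScanVolume."""
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            datasets.append((p, pydicom.dcmread(str(p))))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no series found in {directory}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for _, ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"multiple series in {directory}: {sorted(map(str, uids))}")

    slices = []
    for p, ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(float) * slope + intercept
        z = float(ds.ImagePositionPatient[2]) if "ImagePositionPatient" in ds else float(
            getattr(ds, "SliceLocation", 0.0)
        )
        spacing = tuple(float(v) for v in ds.PixelSpacing) if "PixelSpacing" in ds else None
        slices.append(SliceImage(hu, spacing_mm=spacing, z_position=z, source_id=p.name))
    slices.sort(key=lambda s: s.z_position)
    zs = np.array([s.z_position for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.any(dz <= 0):
            raise ValueError("duplicate or non-monotonic slice z positions")
        spacing = float(np.mean(dz))
    else:
        spacing = None
    return ScanVolume(slices=slices, slice_spacing_mm=spacing)


def write_dicom_series(volume: ScanVolume, directory, series_uid: str | None = None) -> list:
    """Write a volume as one minimal CT DICOM file per slice (test fixtures).

    Pixels are stored as uint16 with RescaleIntercept -1024 so HU round-trip
    exactly for integer-valued inputs in [-1024, 64511].
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    written = []
    for i, s in enumerate(volume.slices):
        stored = np.round(s.pixels + 1024.0)
        if stored.min() < 0 or stored.max() > np.iinfo(np.uint16).max:
            raise ValueError("pixel values out of range for uint16 storage")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = s.pixels.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.InstanceNumber = i + 1
        z = s.z_position if s.z_position is not None else float(i)
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        if s.spacing_mm is not None:
            ds.PixelSpacing = [float(s.spacing_mm[0]), float(s.spacing_mm[1])]
        ds.PixelData = stored.astype(np.uint16).tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        written.append(path)
    return written


# ---- rasters and raw arrays -------------------------------------------------

def read_slice(path, fmt: str | None = None) -> SliceImage:
    """Read one slice from DICOM, 16-bit grayscale PNG or a .npy raw array."""
    path = Path(path)
    fmt = fmt or {".dcm": "dicom", ".png": "png16", ".npy": "raw"}.get(path.suffix.lower())
    if fmt == "dicom":
        ds = pydicom.dcmread(str(path))
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return SliceImage(ds.pixel_array.astype(float) * slope + intercept, source_id=path.name)
    if fmt == "png16":
        img = Image.open(path)
        if img.mode not in ("I", "I;16", "L"):
            raise ValueError(f"expected single channel raster, got mode {img.mode}")
        return SliceImage(np.asarray(img), source_id=path.name)
    if fmt == "raw":
        arr = np.load(path)
        if arr.ndim != 2:
            raise ValueError("expected single channel 2-D array")
        return SliceImage(arr, source_id=path.name)
    raise ValueError(f"unknown slice format {fmt!r} for {path}")


def write_slice(slc: SliceImage, path, fmt: str | None = None) -> Path:
    """Write one slice as 16-bit PNG or a .npy raw array (values unchanged)."""
    path = Path(path)
    fmt = fmt or {".png": "png16", ".npy": "raw"}.get(path.suffix.lower())
    if fmt == "png16":
        arr = np.round(slc.pixels).astype(np.uint16)
        Image.fromarray(arr.astype(np.int32), mode="I").convert("I;16").save(path)
    elif fmt == "raw":
        np.save(path, slc.pixels)
    else:
        raise ValueError(f"unknown slice format {fmt!r}")
    return path


# ---- annotation sidecars ----------------------------------------------------

def write_annotations(scan_id: str, regions: list[dict], path) -> Path:
    """Tamper annotation sidecar: {scan_id, regions: [{z_index, center_xy, box_size}]}."""
    path = Path(path)
    path.write_text(json.dumps({"scan_id": scan_id, "regions": regions}, indent=2))
    return path


def read_annotations(path) -> dict:
    data = json.loads(Path(path).read_text())
    if "scan_id" not in data or "regions" not in data:
        raise ValueError("annotation sidecar must contain scan_id and regions")
    return data
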