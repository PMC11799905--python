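"""EPID image container, coordinate conventions, and I/O.

Coordinate convention
---------------------
Pixel indices are 0-based; the *center* of pixel ``(0, 0)`` is the origin of
the raw image frame in millimetres.  ``x`` (crossplane, the leaf-travel axis)
increases with column index and ``y`` (inplane, the leaf-stacking axis)
increases with row index.  All distances are expressed in mm *at the
isocenter plane*: detector-plane pixel pitch is rescaled by SAD/SDD on read,
so with the standard SDD = SAD = 100 cm geometry detector mm equal isocenter
mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import RectBivariateSpline

__all__ = [
    "EpidImage",
    "ImagePoint",
    "read_image",
    "write_image",
    "sample_profile",
    "write_profile_csv",
]

#: metadata fields every image must carry (sidecar keys / DICOM equivalents)
REQUIRED_METADATA = ("pixel_spacing", "sdd", "gantry_angle", "collimator_angle")


@dataclass(frozen=True)
class ImagePoint:
    """A point in mm; ``origin`` documents the frame ('pixel0' or 'cax')."""

    x: float
    y: float
    origin: str = "pixel0"

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class EpidImage:
    """Integrated or cine EPID frame with acquisition geometry.

    Parameters
    ----------
    pixels
        2D array of non-negative signal values, shape (rows, cols).
    pixel_spacing
        Pixel pitch in mm *at the isocenter plane* (square pixels).
    sdd
        Source-detector distance in cm.
    gantry_angle, collimator_angle
        IEC 61217 angles in degrees, normalized to [0, 360).
    acquisition_mode
        ``"integrated"`` or ``"cine_frame"``.
    """

    pixels: np.ndarray
    pixel_spacing: float
    sdd: float
    gantry_angle: float = 0.0
    collimator_angle: float = 0.0
    acquisition_mode: str = "integrated"
    sad: float = 100.0
    _spline: RectBivariateSpline | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 64:
            raise ValueError("pixels must be a 2D grid of at least 64x64 elements")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be >= 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.sdd <= 0:
            raise ValueError("sdd must be > 0")
        self.gantry_angle = float(self.gantry_angle) % 360.0
        self.collimator_angle = float(self.collimator_angle) % 360.0
        if self.acquisition_mode not in ("integrated", "cine_frame"):
            raise ValueError(f"unknown acquisition_mode {self.acquisition_mode!r}")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def x_mm(self) -> np.ndarray:
        """Crossplane mm coordinate of each column center."""
        return np.arange(self.shape[1]) * self.pixel_spacing

    @property
    def y_mm(self) -> np.ndarray:
        """Inplane mm coordinate of each row center."""
        return np.arange(self.shape[0]) * self.pixel_spacing

    @property
    def center(self) -> ImagePoint:
        """Geometric center of the pixel grid, raw frame mm."""
        ny, nx = self.shape
        s = self.pixel_spacing
        return ImagePoint((nx - 1) / 2 * s, (ny - 1) / 2 * s)

    def mm_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """(x, y) mm -> fractional (col, row)."""
        return x / self.pixel_spacing, y / self.pixel_spacing

    def pixel_to_mm(self, col: float, row: float) -> tuple[float, float]:
        return col * self.pixel_spacing, row * self.pixel_spacing

    def contains(self, x: float, y: float) -> bool:
        return (
            0.0 <= x <= self.x_mm[-1] + 1e-9 and 0.0 <= y <= self.y_mm[-1] + 1e-9
        )

    # -- interpolation ------------------------------------------------------

    def interpolator(self) -> RectBivariateSpline:
        """Cubic bivariate spline over the pixel grid (cached)."""
        if self._spline is None:
            self._spline = RectBivariateSpline(
                self.y_mm, self.x_mm, self.pixels, kx=3, ky=3, s=0
            )
        return self._spline

    def _coefficients(self) -> np.ndarray:
        """Cached cubic B-spline coefficient grid for fast scattered lookups."""
        if getattr(self, "_coef", None) is None:
            from scipy.ndimage import spline_filter

            self._coef = spline_filter(self.pixels, order=3, mode="nearest")
        return self._coef

    def value_at(self, x, y):
        """Cubic-spline interpolated signal at mm coordinates (vectorized)."""
        from scipy.ndimage import map_coordinates

        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        coords = np.vstack(
            [y.ravel() / self.pixel_spacing, x.ravel() / self.pixel_spacing]
        )
        vals = map_coordinates(
            self._coefficients(), coords, order=3, mode="nearest", prefilter=False
        )
        return vals.reshape(x.shape) if x.shape else float(vals[0])

    def with_pixels(self, pixels: np.ndarray) -> "EpidImage":
        return replace(self, pixels=pixels, _spline=None)

    # -- metadata -----------------------------------------------------------

    def metadata(self) -> dict:
        return {
            "pixel_spacing": self.pixel_spacing,
            "sdd": self.sdd,
            "gantry_angle": self.gantry_angle,
            "collimator_angle": self.collimator_angle,
            "acquisition_mode": self.acquisition_mode,
            "sad": self.sad,
        }


# ---------------------------------------------------------------------------
# profile sampling
# ---------------------------------------------------------------------------

def sample_profile(
    img: EpidImage,
    start: ImagePoint,
    end: ImagePoint,
    step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated line profile along a straight segment.

    Returns ``(distance_mm, values)`` with distances increasing from 0 at
    ``start``.  Values come from the image's cubic-spline interpolant, so
    sub-pixel sampling is exact at pixel centers and smooth in between.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    p0, p1 = start.as_array(), end.as_array()
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("start and end must differ")
    for name, p in (("start", p0), ("end", p1)):
        if not img.contains(p[0], p[1]):
            raise ValueError(
                f"profile {name} point ({p[0]:.2f}, {p[1]:.2f}) mm is outside the image"
            )
    n = int(np.floor(length / step + 1e-9)) + 1
    dist = np.arange(n) * step
    u = (p1 - p0) / length
    xs = p0[0] + dist * u[0]
    ys = p0[1] + dist * u[1]
    return dist, img.value_at(xs, ys)


def write_profile_csv(path, dist: np.ndarray, values: np.ndarray) -> None:
    arr = np.column_stack([dist, values])
    np.savetxt(path, arr, delimiter=",", header="distance_mm,value", comments="")


# ---------------------------------------------------------------------------
# raster + sidecar dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_raster(img: EpidImage, path: Path) -> None:
    np.save(path, img.pixels)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(img.metadata(), fh, indent=1)


def _read_raster(path: Path) -> EpidImage:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar.name}: raster images need pixel_spacing, "
            "sdd, gantry_angle and collimator_angle metadata"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in REQUIRED_METADATA:
        if key not in meta:
            raise KeyError(f"missing {key} in sidecar {sidecar.name}")
    pixels = np.load(path)
    return EpidImage(
        pixels=pixels,
        pixel_spacing=float(meta["pixel_spacing"]),
        sdd=float(meta["sdd"]),
        gantry_angle=float(meta["gantry_angle"]),
        collimator_angle=float(meta["collimator_angle"]),
        acquisition_mode=meta.get("acquisition_mode", "integrated"),
        sad=float(meta.get("sad", 100.0)),
    )


# ---------------------------------------------------------------------------
# DICOM RTIMAGE dialect
# ---------------------------------------------------------------------------

_RTIMAGE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.1"


def _write_dicom(img: EpidImage, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID(_RTIMAGE_SOP_CLASS)
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.PatientName = "QA^Stakitt"
    ds.PatientID = "QA"

    peak = float(img.pixels.max())
    scale = 60000.0 / peak if peak > 0 else 1.0
    quantized = np.round(img.pixels * scale).astype(np.uint16)
    ds.Rows, ds.Columns = quantized.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = quantized.tobytes()
    ds.RescaleSlope = 1.0 / scale
    ds.RescaleIntercept = 0.0

    # geometry: ImagePlanePixelSpacing is at the detector plane
    sid_mm = img.sdd * 10.0
    sad_mm = img.sad * 10.0
    det_spacing = img.pixel_spacing * (sid_mm / sad_mm)
    ds.ImagePlanePixelSpacing = [det_spacing, det_spacing]
    ds.RTImageSID = sid_mm
    ds.RadiationMachineSAD = sad_mm
    ds.GantryAngle = img.gantry_angle
    ds.BeamLimitingDeviceAngle = img.collimator_angle
    ds.RTImageLabel = img.acquisition_mode
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path) -> EpidImage:
    import pydicom

    ds = pydicom.dcmread(path)
    for tag, name in (
        ("ImagePlanePixelSpacing", "pixel_spacing"),
        ("RTImageSID", "sdd"),
        ("GantryAngle", "gantry_angle"),
        ("BeamLimitingDeviceAngle", "collimator_angle"),
    ):
        if getattr(ds, tag, None) is None:
            raise KeyError(f"missing {name} (DICOM {tag}) in {path.name}")
    pixels = ds.pixel_array.astype(float)
    expected = int(ds.Rows) * int(ds.Columns)
    if pixels.size != expected:
        raise ValueError(f"truncated pixel data in {path.name}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    sid_mm = float(ds.RTImageSID)
    sad_mm = float(getattr(ds, "RadiationMachineSAD", 1000.0))
    det_spacing = float(ds.ImagePlanePixelSpacing[0])
    return EpidImage(
        pixels=pixels,
        pixel_spacing=det_spacing * sad_mm / sid_mm,
        sdd=sid_mm / 10.0,
        gantry_angle=float(ds.GantryAngle),
        collimator_angle=float(ds.BeamLimitingDeviceAngle),
        acquisition_mode=str(getattr(ds, "RTImageLabel", "integrated")) or "integrated",
        sad=sad_mm / 10.0,
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def write_image(img: EpidImage, path, format: str | None = None) -> Path:
    """Write an EPID image; format inferred from extension when omitted.

    ``.npy`` writes the raster + JSON sidecar dialect (lossless); ``.dcm``
    writes a DICOM RTIMAGE with pixel values quantized to 16 bits.
    """
    path = Path(path)
    fmt = format or ("dicom_rtimage" if path.suffix.lower() == ".dcm" else "raster_plus_sidecar")
    if fmt == "raster_plus_sidecar":
        _write_raster(img, path)
    elif fmt == "dicom_rtimage":
        _write_dicom(img, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_image(path, format: str | None = None) -> EpidImage:
    """Read an EPID image from the raster+sidecar or DICOM RTIMAGE dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("dicom_rtimage" if path.suffix.lower() == ".dcm" else "raster_plus_sidecar")
    if fmt == "raster_plus_sidecar":
        return _read_raster(path)
    if fmt == "dicom_rtimage":
        return _read_dicom(path)
    raise ValueError(f"unknown format {fmt!r}")
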