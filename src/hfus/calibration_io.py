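"""Image I/O and physical calibration for B-mode HFUS skin images.

The scanner geometry this package targets produces 8-bit grayscale frames
in which row index increases with depth (row 0 is nearest the probe) and
column index increases laterally across the probe face.  Pixel pitch is
anisotropic: the default calibration is 0.0023 mm/px axially and
0.0093 mm/px laterally, which reproduces the nominal ~8 mm depth and
12.8898 mm width of a full-resolution 3466x1386 frame.  Frames carry a
millimetre-graduated ruler overlay from which the axial pitch can be
re-estimated per image.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage
import tifffile

from .errors import CalibrationError, FormatError

DEFAULT_AXIAL_MM_PER_PX = 0.0023
DEFAULT_LATERAL_MM_PER_PX = 0.0093

#: Order in which named regions appear in exported tables.
ROI_ORDER = ("entry_echo", "outer_entry_echo", "upper_dermis", "lower_dermis")


def mm_to_px(mm: float, mm_per_px: float) -> int:
    """Convert a physical length to a pixel count, rounding half up.

    Round-half-up is used everywhere a band depth in mm becomes a row
    count, so 0.2 mm at 0.0023 mm/px is 87 rows (0.2/0.0023 = 86.96).
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    return int(math.floor(mm / mm_per_px + 0.5))


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel pitch of a B-mode frame.

    Parameters
    ----------
    axial_mm_per_px : float
        Pitch along rows (depth direction), mm per pixel.
    lateral_mm_per_px : float
        Pitch along columns, mm per pixel.
    source : str
        One of ``"ruler"``, ``"manifest"``, ``"default"``.
    """

    axial_mm_per_px: float = DEFAULT_AXIAL_MM_PER_PX
    lateral_mm_per_px: float = DEFAULT_LATERAL_MM_PER_PX
    source: str = "default"

    def __post_init__(self) -> None:
        for name in ("axial_mm_per_px", "lateral_mm_per_px"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")
        if self.source not in ("ruler", "manifest", "default"):
            raise ValueError(f"unknown calibration source {self.source!r}")


@dataclass(frozen=True)
class RulerRegion:
    """Column/row extent occupied by the ruler graphic (half-open)."""

    col_start: int
    col_stop: int
    row_start: int = 0
    row_stop: Optional[int] = None

    def column_mask(self, n_cols: int) -> np.ndarray:
        m = np.zeros(n_cols, dtype=bool)
        m[self.col_start : self.col_stop] = True
        return m


@dataclass
class BModeImage:
    """A 2-D 8-bit B-mode frame with physical calibration attached."""

    intensities: np.ndarray
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    ruler_region: Optional[RulerRegion] = None
    image_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError(f"expected a 2-D image, got shape {a.shape}")
        if a.dtype != np.uint8:
            if a.min() < 0 or a.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            a = a.astype(np.uint8)
        self.intensities = a

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def width_mm(self) -> float:
        """Physical lateral field width (all columns, including any ruler)."""
        return self.n_cols * self.calibration.lateral_mm_per_px

    @property
    def depth_mm(self) -> float:
        return self.n_rows * self.calibration.axial_mm_per_px

    def tissue_column_mask(self) -> np.ndarray:
        """Boolean mask of columns outside the ruler overlay."""
        m = np.ones(self.n_cols, dtype=bool)
        if self.ruler_region is not None:
            m &= ~self.ruler_region.column_mask(self.n_cols)
        return m


# ---------------------------------------------------------------------------
# image file I/O
# ---------------------------------------------------------------------------

def _read_gray(path) -> np.ndarray:
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            with PILImage.open(path) as im:
                arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # collapse equal-channel colour losslessly; refuse genuine colour
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
            raise FormatError(f"{path}: multi-channel image with unequal channels is not a B-mode frame")
        arr = rgb[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise FormatError(f"{path}: intensities outside [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def write_image(array: np.ndarray, path) -> None:
    """Write an 8-bit grayscale image (TIFF or PNG by extension)."""
    path = Path(path)
    arr = np.ascontiguousarray(np.asarray(array, dtype=np.uint8))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        PILImage.fromarray(arr, mode="L").save(path)


def load_bmode(
    path,
    manifest_entry: Optional[Mapping] = None,
    ruler_region: Optional[RulerRegion] = None,
    use_ruler: bool = False,
    tick_spacing_mm: float = 1.0,
) -> BModeImage:
    """Load a B-mode frame and resolve its calibration.

    Calibration priority: manifest-supplied pitches, then ruler estimation
    (when ``use_ruler`` and a ``ruler_region`` are given), then the scanner
    defaults.  A ruler estimate that fails falls back to the default pitch.
    """
    path = Path(path)
    arr = _read_gray(path)

    axial = lateral = None
    if manifest_entry is not None:
        axial = _manifest_float(manifest_entry, "axial_mm_per_px")
        lateral = _manifest_float(manifest_entry, "lateral_mm_per_px")
    if axial is not None and lateral is not None:
        cal = PixelCalibration(axial, lateral, source="manifest")
    else:
        cal = PixelCalibration(source="default")
        if axial is not None or lateral is not None:
            cal = PixelCalibration(
                axial if axial is not None else DEFAULT_AXIAL_MM_PER_PX,
                lateral if lateral is not None else DEFAULT_LATERAL_MM_PER_PX,
                source="manifest",
            )

    image = BModeImage(arr, calibration=cal, ruler_region=ruler_region, image_id=path.stem)

    if use_ruler and cal.source == "default" and ruler_region is not None:
        try:
            image.calibration = estimate_pixel_size_from_ruler(image, tick_spacing_mm, axis="axial")
        except CalibrationError:
            pass  # keep the default pitch when too few ticks are visible
    return image


def _manifest_float(entry: Mapping, key: str) -> Optional[float]:
    v = entry.get(key) if hasattr(entry, "get") else None
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return f if np.isfinite(f) else None


# ---------------------------------------------------------------------------
# ruler-based pixel-size estimation
# ---------------------------------------------------------------------------

def estimate_pixel_size_from_ruler(
    image: BModeImage,
    tick_spacing_mm: float,
    axis: str = "axial",
    min_peak_separation_px: int = 3,
) -> PixelCalibration:
    """Estimate pixel pitch from the graduated ruler overlay.

    The ruler strip is collapsed to a 1-D intensity profile along the
    requested axis; tick marks are profile peaks above mean + 2*std with a
    minimum separation of ``min_peak_separation_px``.  The pitch is
    ``tick_spacing_mm`` divided by the median inter-tick pixel distance.

    Raises
    ------
    CalibrationError
        If fewer than 3 ticks are detected; supply the pitch through the
        manifest in that case.
    """
    from scipy.signal import find_peaks

    if image.ruler_region is None:
        raise CalibrationError("image has no ruler_region; cannot locate the ruler strip")
    if tick_spacing_mm <= 0:
        raise ValueError("tick_spacing_mm must be positive")
    rr = image.ruler_region
    row_stop = rr.row_stop if rr.row_stop is not None else image.n_rows
    strip = image.intensities[rr.row_start : row_stop, rr.col_start : rr.col_stop].astype(float)
    if strip.size == 0:
        raise CalibrationError("ruler region is empty")

    if axis == "axial":
        profile = strip.mean(axis=1)
    elif axis == "lateral":
        profile = strip.mean(axis=0)
    else:
        raise ValueError(f"axis must be 'axial' or 'lateral', got {axis!r}")

    height = profile.mean() + 2.0 * profile.std()
    peaks, _ = find_peaks(profile, height=height, distance=min_peak_separation_px)
    if len(peaks) < 3:
        raise CalibrationError(
            f"only {len(peaks)} ruler ticks detected (need >= 3); "
            "supply axial_mm_per_px/lateral_mm_per_px via the manifest"
        )
    spacing = float(np.median(np.diff(peaks)))
    mm_per_px = tick_spacing_mm / spacing

    if axis == "axial":
        return PixelCalibration(mm_per_px, image.calibration.lateral_mm_per_px, source="ruler")
    return PixelCalibration(image.calibration.axial_mm_per_px, mm_per_px, source="ruler")


# ---------------------------------------------------------------------------
# measurement tables and manifests
# ---------------------------------------------------------------------------

def write_parameters(records: Sequence, path) -> None:
    """Write measurement records to a long-format CSV.

    One row per (image, ROI, parameter); numeric values are serialised at
    10 significant digits so a write/read round trip is value-exact at that
    precision.  Row order is deterministic: records in input order, ROIs in
    ``ROI_ORDER`` (image-level parameters first, under roi ``"global"``),
    parameters in each record's declared order.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    rows: list[dict] = []
    for rec in records:
        rows.extend(rec.to_rows())
    df = pd.DataFrame(rows)
    df["value"] = [
        "" if (v is None or (isinstance(v, float) and math.isnan(v))) else format(float(v), ".10g")
        for v in df["value"]
    ]
    df.to_csv(path, index=False)


def read_parameters(path) -> pd.DataFrame:
    """Read a long-format parameter CSV back into a DataFrame."""
    df = pd.read_csv(path, dtype={"value": float}, keep_default_na=True)
    return df


def write_record_json(record, path) -> None:
    """Write a single image's measurement record as JSON."""
    with open(path, "w") as fh:
        json.dump(record.to_dict(), fh, indent=2, allow_nan=True)


def read_manifest(path) -> pd.DataFrame:
    """Read a study manifest CSV.

    Required column: ``image_path``.  Optional: ``mask_path``,
    ``subject_id``, ``group``, ``timepoint``, ``location``,
    ``axial_mm_per_px``, ``lateral_mm_per_px``.
    """
    df = pd.read_csv(path)
    if "image_path" not in df.columns:
        raise FormatError(f"{path}: manifest must contain an image_path column")
    return df
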