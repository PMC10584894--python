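"""Per-image dermal parameters: thickness, echogenicity, pixel-fraction
statistics, surface roughness and texture.

Every quantity is computed on the native 8-bit intensities (all frames of
a study share acquisition settings, so intensity levels compare directly)
and on the native anisotropic pixel grid.

Parameters
----------
thickness
    Mean per-column entry-echo layer height, in mm.
echogenicity
    Arithmetic mean intensity of a region (0-255 scale).
nLEP / nMEP / nHEP
    Fractions of low- (0-30), medium- (50-150) and high-intensity
    (200-255) pixels in a region, normalised by the region's pixel count
    and expressed in percent, e.g. ``nLEP = 100 * n_30 / n`` — the
    normalisation makes regions of different thickness comparable.
roughness
    Ratio A/B of the polyline length of the segmented skin-surface
    boundary (A) to the lateral width it spans (B); 1 for a flat surface.
GLCM texture
    Contrast, correlation, energy and homogeneity of the gray-level
    co-occurrence matrix at a set of pixel offsets (default
    {(0,7), (5,7), (7,7)}), 128 gray levels, symmetric and normalised;
    plus the Shannon entropy of the region's quantized histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .calibration_io import ROI_ORDER, BModeImage, PixelCalibration
from .entry_echo_segmentation import LayerBoundary, LayerMask, extract_boundaries
from .errors import MeasurementError
from .roi_geometry import ROISet, ROISpec, derive_rois, roi_pixel_count


@dataclass(frozen=True)
class IntensityBand:
    """Inclusive 8-bit intensity interval."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 255):
            raise ValueError(f"band bounds must satisfy 0 <= lo <= hi <= 255, got [{self.lo}, {self.hi}]")


#: Echogenicity bands of the fraction statistics.
DEFAULT_BANDS: Dict[str, IntensityBand] = {
    "LEP": IntensityBand(0, 30),
    "MEP": IntensityBand(50, 150),
    "HEP": IntensityBand(200, 255),
}

#: (row_shift, column_shift) GLCM offsets reported separately.
DEFAULT_GLCM_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 7), (5, 7), (7, 7))


@dataclass(frozen=True)
class GLCMConfig:
    """Gray-level co-occurrence matrix configuration.

    ``offset`` is a (row_shift, column_shift) pixel displacement on the
    native grid; ``levels`` quantization bins (intensity I maps to bin
    ``floor(I * levels / 256)``).
    """

    offset: Tuple[int, int]
    levels: int = 128
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if tuple(self.offset) == (0, 0):
            raise ValueError("offset must be nonzero")


GLCM_FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass
class ParameterRecord:
    """One image's full measurement vector plus study metadata.

    Missing values are encoded as NaN.  ``texture`` is keyed
    ``roi -> "[r,c]" -> feature``.
    """

    image_id: str = ""
    subject_id: str = ""
    group: str = ""
    timepoint: str = ""
    location: str = ""
    thickness_mm: float = math.nan
    echogenicity: Dict[str, float] = field(default_factory=dict)
    intensity_ratio_upper_dermis_to_entry_echo: float = math.nan
    fractions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    nlep_upper_to_lower: float = math.nan
    roughness_edge_ratio: float = math.nan
    entropy_bits: Dict[str, float] = field(default_factory=dict)
    texture: Dict[str, Dict[str, Dict[str, float]]] = field(default_factory=dict)

    # -- serialisation ----------------------------------------------------
    def _meta(self) -> dict:
        return {
            "image_id": self.image_id,
            "subject_id": self.subject_id,
            "group": self.group,
            "timepoint": self.timepoint,
            "location": self.location,
        }

    def to_rows(self) -> list:
        """Long-format rows: one per (image, ROI, parameter)."""
        rows = []

        def add(roi, parameter, value):
            rows.append({**self._meta(), "roi": roi, "parameter": parameter,
                         "value": math.nan if value is None else float(value)})

        add("global", "thickness_mm", self.thickness_mm)
        add("global", "intensity_ratio_upper_dermis_to_entry_echo",
            self.intensity_ratio_upper_dermis_to_entry_echo)
        add("global", "nLEP_upper_to_lower", self.nlep_upper_to_lower)
        add("global", "roughness_edge_ratio", self.roughness_edge_ratio)
        for roi in ROI_ORDER:
            if roi in self.echogenicity:
                add(roi, "echogenicity", self.echogenicity[roi])
            for band, pct in self.fractions.get(roi, {}).items():
                add(roi, f"n{band}", pct)
            if roi in self.entropy_bits:
                add(roi, "entropy_bits", self.entropy_bits[roi])
            for off, feats in self.texture.get(roi, {}).items():
                for feat, v in feats.items():
                    add(roi, f"{feat}{off}", v)
        return rows

    def to_dict(self) -> dict:
        return {
            **self._meta(),
            "thickness_mm": self.thickness_mm,
            "echogenicity": self.echogenicity,
            "intensity_ratio_upper_dermis_to_entry_echo":
                self.intensity_ratio_upper_dermis_to_entry_echo,
            "fractions": self.fractions,
            "nLEP_upper_to_lower": self.nlep_upper_to_lower,
            "roughness_edge_ratio": self.roughness_edge_ratio,
            "entropy_bits": self.entropy_bits,
            "texture": self.texture,
        }


# ---------------------------------------------------------------------------
# scalar parameters
# ---------------------------------------------------------------------------

def thickness(boundary: LayerBoundary, calibration: PixelCalibration,
              aggregator: str = "mean") -> float:
    """Entry-echo layer thickness in mm.

    Per valid column the layer height is ``(bottom - top + 1)`` rows; the
    per-column heights are aggregated (mean by default, median optional)
    and scaled by the axial pitch.
    """
    if boundary.n_valid < 1:
        raise MeasurementError("thickness requires at least one valid column")
    v = boundary.valid
    heights = boundary.bottom_row[v] - boundary.top_row[v] + 1
    agg = np.median if aggregator == "median" else np.mean
    return float(agg(heights) * calibration.axial_mm_per_px)


def echogenicity(image: BModeImage, roi: np.ndarray) -> float:
    """Arithmetic mean intensity over the region, native 0-255 scale."""
    vals = image.intensities[np.asarray(roi, dtype=bool)]
    if vals.size == 0:
        raise MeasurementError("echogenicity of an empty region is undefined")
    return float(vals.mean())


def intensity_ratio(upper_dermis_mean: float, entry_echo_mean: float) -> float:
    """Upper-dermis to entry-echo mean-intensity ratio."""
    if entry_echo_mean <= 0:
        raise MeasurementError("intensity ratio undefined for zero entry-echo mean")
    return upper_dermis_mean / entry_echo_mean


def pixel_fraction(image: BModeImage, roi: np.ndarray, band: IntensityBand) -> float:
    """Percentage of region pixels with intensity in [band.lo, band.hi]."""
    vals = image.intensities[np.asarray(roi, dtype=bool)]
    if vals.size == 0:
        raise MeasurementError("pixel fraction of an empty region is undefined")
    inside = np.count_nonzero((vals >= band.lo) & (vals <= band.hi))
    return 100.0 * inside / vals.size


def lep_upper_lower_ratio(upper_nlep: float, lower_nlep: float) -> float:
    """Upper- to lower-dermis nLEP ratio; NaN when the denominator is 0."""
    if lower_nlep == 0 or math.isnan(lower_nlep) or math.isnan(upper_nlep):
        return math.nan
    return upper_nlep / lower_nlep


def surface_roughness(boundary: LayerBoundary, calibration: PixelCalibration) -> float:
    """Skin-surface roughness A/B.

    A is the physical polyline length through the per-column top-boundary
    points (runs of contiguous valid columns are summed; gaps split the
    polyline); B is the lateral pitch times the number of traversed column
    steps.  Always >= 1, with equality iff the traversed boundary is flat.
    """
    lat = calibration.lateral_mm_per_px
    ax = calibration.axial_mm_per_px
    cols = boundary.valid_columns
    if cols.size < 2:
        raise MeasurementError("roughness requires at least 2 valid columns")
    adjacent = np.diff(cols) == 1
    if not adjacent.any():
        raise MeasurementError("roughness requires at least 2 contiguous valid columns")
    drow = np.diff(boundary.top_row[cols])[adjacent]
    # normalise each step before summing: hypot(lat, 0)/lat == 1 exactly,
    # so a flat boundary yields exactly 1.0
    return float(np.mean(np.hypot(lat, drow * ax) / lat))


# ---------------------------------------------------------------------------
# texture
# ---------------------------------------------------------------------------

def quantize(intensities: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit intensities to ``levels`` bins: floor(I * levels / 256)."""
    return (intensities.astype(np.int64) * levels) // 256


def glcm(image: BModeImage, roi: np.ndarray, config: GLCMConfig) -> np.ndarray:
    """Normalised gray-level co-occurrence matrix of a region.

    Pairs (p, p + offset) are counted only when both endpoints lie inside
    the region; the transpose is added when symmetric; the matrix is
    normalised to sum 1.

    Raises :class:`MeasurementError` when the region admits no pair at
    the offset (the caller records the feature as missing).
    """
    roi = np.asarray(roi, dtype=bool)
    q = quantize(image.intensities, config.levels)
    dr, dc = config.offset
    n_rows, n_cols = roi.shape

    r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
    c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise MeasurementError(f"offset {config.offset} exceeds the image extent")
    src = roi[r0:r1, c0:c1] & roi[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if not src.any():
        raise MeasurementError(f"no pixel pairs at offset {config.offset} inside the region")
    a = q[r0:r1, c0:c1][src]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][src]
    counts = np.bincount(a * config.levels + b, minlength=config.levels ** 2).astype(float)
    p = counts.reshape(config.levels, config.levels)
    if config.symmetric:
        p = p + p.T
    return p / p.sum()


def glcm_features(p: np.ndarray, include_entropy: bool = False) -> Dict[str, float]:
    """Contrast, correlation, energy and homogeneity of a normalised GLCM.

    correlation is NaN for a constant region (zero marginal variance).
    With ``include_entropy`` the GLCM entropy ``-sum P log2 P`` is added.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(n) * pi))
    mu_j = float(np.sum(np.arange(n) * pj))
    var_i = float(np.sum((np.arange(n) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(n) - mu_j) ** 2 * pj))
    out = {
        "contrast": float(np.sum((i - j) ** 2 * p)),
        "correlation": math.nan,
        "energy": float(np.sum(p * p)),
        "homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
    }
    denom = math.sqrt(var_i * var_j)
    if denom > 0:
        out["correlation"] = float(np.sum((i - mu_i) * (j - mu_j) * p) / denom)
    if include_entropy:
        nz = p[p > 0]
        out["glcm_entropy"] = float(-np.sum(nz * np.log2(nz)))
    return out


def region_entropy(image: BModeImage, roi: np.ndarray, levels: int = 128) -> float:
    """Shannon entropy (bits) of the region's quantized histogram."""
    vals = image.intensities[np.asarray(roi, dtype=bool)]
    if vals.size == 0:
        raise MeasurementError("entropy of an empty region is undefined")
    counts = np.bincount(quantize(vals, levels), minlength=levels)
    prob = counts[counts > 0] / vals.size
    return float(-np.sum(prob * np.log2(prob)))


# ---------------------------------------------------------------------------
# full measurement
# ---------------------------------------------------------------------------

def measure_all(
    image: BModeImage,
    mask: LayerMask,
    spec: ROISpec = ROISpec(),
    bands: Optional[Mapping[str, IntensityBand]] = None,
    glcm_configs: Optional[Sequence[GLCMConfig]] = None,
    metadata: Optional[Mapping[str, str]] = None,
    glcm_levels: int = 128,
    include_glcm_entropy: bool = False,
) -> ParameterRecord:
    """Compute the full parameter vector of one frame.

    ``mask`` must already be post-processed.  Empty or degenerate regions
    yield NaN for their parameters; the result is deterministic given its
    inputs.
    """
    if not mask.mask.any():
        raise MeasurementError("mask is empty; run segmentation/post-processing first")
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    if glcm_configs is None:
        glcm_configs = [GLCMConfig(offset=o, levels=glcm_levels) for o in DEFAULT_GLCM_OFFSETS]

    boundary = extract_boundaries(mask)
    rois = derive_rois(boundary, mask, image.calibration, spec,
                       tissue_columns=image.tissue_column_mask())

    rec = ParameterRecord(image_id=image.image_id)
    if metadata:
        for key in ("image_id", "subject_id", "group", "timepoint", "location"):
            if key in metadata and metadata[key] is not None:
                setattr(rec, key, str(metadata[key]))

    rec.thickness_mm = thickness(boundary, image.calibration)
    try:
        rec.roughness_edge_ratio = surface_roughness(boundary, image.calibration)
    except MeasurementError:
        pass

    for roi_name in rois.names():
        roi = rois[roi_name]
        if roi_pixel_count(roi) == 0:
            continue
        rec.echogenicity[roi_name] = echogenicity(image, roi)
        rec.fractions[roi_name] = {
            name: pixel_fraction(image, roi, band) for name, band in bands.items()
        }
        rec.entropy_bits[roi_name] = region_entropy(image, roi, glcm_levels)
        rec.texture[roi_name] = {}
        for cfg in glcm_configs:
            key = f"[{cfg.offset[0]},{cfg.offset[1]}]"
            try:
                feats = glcm_features(glcm(image, roi, cfg), include_glcm_entropy)
            except MeasurementError:
                feats = {name: math.nan for name in GLCM_FEATURE_NAMES}
            rec.texture[roi_name][key] = feats

    if "entry_echo" in rec.echogenicity and "upper_dermis" in rec.echogenicity:
        rec.intensity_ratio_upper_dermis_to_entry_echo = intensity_ratio(
            rec.echogenicity["upper_dermis"], rec.echogenicity["entry_echo"]
        )
    if "LEP" in bands:
        up = rec.fractions.get("upper_dermis", {}).get("LEP", math.nan)
        lo = rec.fractions.get("lower_dermis", {}).get("LEP", math.nan)
        rec.nlep_upper_to_lower = lep_upper_lower_ratio(up, lo)
    return rec
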