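"""Depth-referenced measurement ROIs below the entry echo layer.

Four named regions are measured per frame, all anchored to the segmented
entry-echo boundary and expressed at fixed physical depths (skin layers
are treated as locally parallel, so each band follows the layer contour
column by column):

* ``entry_echo`` — the segmented layer itself;
* ``outer_entry_echo`` — the top 0.1 mm of the layer (outer epidermis);
* ``upper_dermis`` — the 0.2 mm band immediately below the layer (the
  subepidermal low echogenic band, SLEB, falls here in affected skin);
* ``lower_dermis`` — the 0.4 mm band below the upper dermis.

Depth-to-row conversion uses the shared round-half-up rule.  Columns
whose dermal band would run past the image bottom are excluded from that
band entirely rather than padded, so intensity statistics are never
biased by missing tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .calibration_io import ROI_ORDER, PixelCalibration, mm_to_px
from .entry_echo_segmentation import LayerBoundary, LayerMask
from .errors import GeometryError


@dataclass(frozen=True)
class ROISpec:
    """Physical depths of the measurement bands (mm)."""

    outer_band_mm: float = 0.1
    upper_dermis_mm: float = 0.2
    lower_dermis_mm: float = 0.4

    def __post_init__(self) -> None:
        for name in ("outer_band_mm", "upper_dermis_mm", "lower_dermis_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ROISet:
    """Named pixel regions of one frame, as boolean masks.

    ``truncated_columns`` records, per dermal band, the valid columns that
    were dropped because the band would exceed the image bottom.
    """

    masks: Dict[str, np.ndarray]
    truncated_columns: Dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self):
        return [n for n in ROI_ORDER if n in self.masks]


def roi_pixel_count(roi: np.ndarray) -> int:
    """Exact pixel cardinality of a region (the normaliser of every
    fraction statistic)."""
    return int(np.count_nonzero(roi))


def derive_rois(
    boundary: LayerBoundary,
    mask: LayerMask,
    calibration: PixelCalibration,
    spec: ROISpec = ROISpec(),
    tissue_columns: Optional[np.ndarray] = None,
) -> ROISet:
    """Construct the four measurement ROIs from the entry-echo boundary.

    Per valid column with layer bottom row ``b`` and depths converted at
    the axial pitch (``d02 = round(upper_dermis_mm / pitch)`` etc.):

    * upper dermis rows are ``(b, b + d02]``;
    * lower dermis rows are ``(b + d02, b + d02 + d04]``;
    * the outer band is rows ``[top, top + d01 - 1]`` clipped to the mask.

    Raises :class:`GeometryError` when the boundary has no valid columns.
    """
    n_rows, n_cols = mask.mask.shape
    valid = boundary.valid.copy()
    if tissue_columns is not None:
        valid &= np.asarray(tissue_columns, dtype=bool)
    if not valid.any():
        raise GeometryError("boundary has no valid columns")

    pitch = calibration.axial_mm_per_px
    d01 = mm_to_px(spec.outer_band_mm, pitch)
    d02 = mm_to_px(spec.upper_dermis_mm, pitch)
    d04 = mm_to_px(spec.lower_dermis_mm, pitch)

    rows = np.arange(n_rows)[:, None]
    top = boundary.top_row[None, :]
    bottom = boundary.bottom_row[None, :]
    valid_row = valid[None, :]

    entry = mask.mask & valid_row

    outer = entry & (rows >= top) & (rows <= top + d01 - 1)

    upper_fit = valid & (boundary.bottom_row + d02 <= n_rows - 1)
    upper = valid_row & upper_fit[None, :] & (rows > bottom) & (rows <= bottom + d02)

    lower_fit = valid & (boundary.bottom_row + d02 + d04 <= n_rows - 1)
    lower = valid_row & lower_fit[None, :] & (rows > bottom + d02) & (rows <= bottom + d02 + d04)

    trunc = {
        "upper_dermis": np.flatnonzero(valid & ~upper_fit),
        "lower_dermis": np.flatnonzero(valid & ~lower_fit),
    }
    return ROISet(
        masks={
            "entry_echo": entry,
            "outer_entry_echo": outer,
            "upper_dermis": upper,
            "lower_dermis": lower,
        },
        truncated_columns=trunc,
    )


def labeled_roi_image(rois: ROISet) -> np.ndarray:
    """Render the ROI set as a labelled 8-bit image for visual QC.

    Labels: 1 = entry echo, 2 = outer entry echo, 3 = upper dermis,
    4 = lower dermis (the outer band overwrites the entry echo where the
    two overlap, mirroring a colour overlay).
    """
    first = next(iter(rois.masks.values()))
    out = np.zeros(first.shape, dtype=np.uint8)
    for label, name in enumerate(ROI_ORDER, start=1):
        if name in rois.masks:
            out[rois.masks[name]] = label
    return out
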