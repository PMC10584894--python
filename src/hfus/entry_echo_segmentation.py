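"""Entry-echo-layer segmentation for B-mode HFUS skin frames.

The entry echo is the bright superficial band where the beam first meets
the skin; it serves as the epidermis proxy for every downstream
measurement.  Two routes produce its mask:

* ``load_external_mask`` ingests a binary mask from any upstream
  segmenter (e.g. a trained network);
* ``segment_entry_echo`` is a classical seeded fuzzy-connectedness
  segmenter: per image column the brightest pixel in the shallow zone is
  taken as a seed, and the mask is the set of pixels whose fuzzy
  connectedness to the seed set reaches a threshold.

Fuzzy connectedness assigns each pixel the maximum over paths to the seed
set of the minimum pairwise affinity along the path, with the affinity of
4-adjacent pixels a, b defined as ``exp(-(I(a)-I(b))^2 / (2 sigma^2))``.
The max-min path strength is computed exactly by a best-first
(Dijkstra-like) propagation.  Speckle is suppressed before affinity
computation by an edge-preserving median filter, so uniform regions and
step edges are left untouched.

Both routes share the same post-processing: foreground within a fixed
number of columns of each lateral border is discarded (acquisition
artifacts concentrate there), small connected components are removed, and
only the largest remaining component is kept — exactly one entry echo
layer exists per frame.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .calibration_io import BModeImage, _read_gray, mm_to_px
from .errors import FormatError, SegmentationError

#: 8-connectivity structuring element for component labelling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the classical entry-echo segmenter.

    sigma : intensity scale of the pairwise affinity (8-bit units).
    theta : connectedness threshold in (0, 1); higher = stricter.
    seed_depth_limit_mm : seeds are searched only this deep per column.
    min_object_px : components smaller than this are removed.
    border_px : columns excluded at each lateral border (default 20).
    median_size : square window of an optional speckle-suppressing median
        filter applied before affinity computation; 1 (default) disables
        it.  Disabled by default because median filtering replaces the
        sharp layer step edge with a ramp of intermediate values whose
        per-row increments can fall below the affinity threshold, letting
        connectedness leak across the boundary; enable it only for inputs
        with heavy uncorrelated (salt-and-pepper-like) noise.
    seed_row_tolerance_mm : seeds whose row deviates from the median
        seed row by more than this are discarded (the entry echo is a
        contiguous shallow band, so an outlying per-column maximum is a
        deep artifact, not the layer); 0 disables the filter.
    """

    sigma: float = 25.0
    theta: float = 0.5
    seed_depth_limit_mm: float = 1.5
    min_object_px: int = 200
    border_px: int = 20
    median_size: int = 1
    seed_row_tolerance_mm: float = 0.2

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")
        if self.border_px < 0:
            raise ValueError("border_px must be >= 0")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be an odd integer >= 1")


@dataclass
class LayerMask:
    """Binary entry-echo mask congruent with its image."""

    mask: np.ndarray
    provenance: str  # "external" | "internal"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.provenance not in ("external", "internal"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]


@dataclass
class LayerBoundary:
    """Per-column top/bottom rows of the entry-echo layer.

    ``top_row``/``bottom_row`` hold -1 in columns without foreground;
    ``valid`` flags columns where both exist.
    """

    top_row: np.ndarray
    bottom_row: np.ndarray
    valid: np.ndarray

    @property
    def valid_columns(self) -> np.ndarray:
        return np.flatnonzero(self.valid)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


# ---------------------------------------------------------------------------
# fuzzy connectedness
# ---------------------------------------------------------------------------

def affinity(a: np.ndarray, b: np.ndarray, sigma: float):
    """Gaussian intensity-difference affinity of pixel pairs."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return np.exp(-(d * d) / (2.0 * sigma * sigma))


def fuzzy_connectedness_map(
    image: np.ndarray,
    seeds: np.ndarray,
    sigma: float,
    valid: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Exact max-min path strength from every pixel to the seed set.

    Best-first propagation over the 4-adjacency graph: pixels are settled
    in decreasing order of connectedness, so each pixel's value is final
    when popped (the max-min analogue of Dijkstra's invariant).

    Parameters
    ----------
    image : 2-D array of intensities (any numeric dtype).
    seeds : boolean array of the same shape; must contain >= 1 seed.
    sigma : affinity scale, > 0.
    valid : optional boolean array; pixels outside it (e.g. a graphic
        overlay) are removed from the graph and keep connectedness 0.

    Returns
    -------
    2-D float array in [0, 1]; exactly 1 on the seeds.
    """
    img = np.asarray(image, dtype=float)
    seeds = np.asarray(seeds, dtype=bool)
    if img.shape != seeds.shape:
        raise ValueError("image and seeds must share a shape")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != img.shape:
            raise ValueError("valid mask and image must share a shape")
        seeds = seeds & valid
    if not seeds.any():
        raise SegmentationError("seed set is empty")
    n_rows, n_cols = img.shape
    flat = img.ravel()
    conn = np.zeros(flat.size)
    conn[seeds.ravel()] = 1.0
    two_sig2 = 2.0 * sigma * sigma
    blocked = None if valid is None else ~valid.ravel()

    heap = [(-1.0, int(i)) for i in np.flatnonzero(seeds.ravel())]
    heapq.heapify(heap)
    settled = np.zeros(flat.size, dtype=bool)
    while heap:
        neg, u = heapq.heappop(heap)
        if settled[u]:
            continue
        settled[u] = True
        cu = -neg
        r, c = divmod(u, n_cols)
        for v in _neighbors4(r, c, n_rows, n_cols):
            if settled[v] or (blocked is not None and blocked[v]):
                continue
            d = flat[u] - flat[v]
            kappa = math.exp(-(d * d) / two_sig2)
            cand = cu if kappa > cu else kappa  # min(cu, kappa)
            if cand > conn[v]:
                conn[v] = cand
                heapq.heappush(heap, (-cand, v))
    return conn.reshape(img.shape)


def _neighbors4(r: int, c: int, n_rows: int, n_cols: int):
    if r > 0:
        yield (r - 1) * n_cols + c
    if r + 1 < n_rows:
        yield (r + 1) * n_cols + c
    if c > 0:
        yield r * n_cols + c - 1
    if c + 1 < n_cols:
        yield r * n_cols + c + 1


def select_seeds(image: BModeImage, params: SegmentationParams,
                 working: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-column seeds: the brightest pixel within the shallow zone.

    Columns under the ruler overlay and columns whose shallow zone is
    entirely zero are skipped.
    """
    work = image.intensities if working is None else working
    depth_px = mm_to_px(params.seed_depth_limit_mm, image.calibration.axial_mm_per_px)
    depth_px = max(1, min(depth_px, image.n_rows))
    zone = work[:depth_px, :]
    seeds = np.zeros(image.intensities.shape, dtype=bool)
    cols = np.flatnonzero(image.tissue_column_mask())
    if cols.size == 0:
        return seeds
    rows = np.argmax(zone[:, cols], axis=0)
    keep = zone[rows, cols] > 0
    if params.seed_row_tolerance_mm > 0 and keep.any():
        tol_px = mm_to_px(params.seed_row_tolerance_mm, image.calibration.axial_mm_per_px)
        keep &= np.abs(rows - np.median(rows[keep])) <= tol_px
    seeds[rows[keep], cols[keep]] = True
    return seeds


def segment_entry_echo(image: BModeImage, params: SegmentationParams = SegmentationParams()) -> LayerMask:
    """Segment the entry echo layer by seeded fuzzy connectedness.

    Returns the raw (internal-provenance) mask of pixels whose
    connectedness to the per-column seed set is >= ``params.theta``.
    Apply :func:`postprocess_mask` before measurement.
    """
    if int(image.tissue_column_mask().sum()) < 50:
        raise SegmentationError("image has fewer than 50 non-ruler columns")
    if mm_to_px(params.seed_depth_limit_mm, image.calibration.axial_mm_per_px) < 1:
        raise SegmentationError("seed_depth_limit_mm converts to < 1 row")

    working = image.intensities.astype(float)
    if params.median_size > 1:
        working = ndimage.median_filter(working, size=params.median_size, mode="nearest")

    seeds = select_seeds(image, params, working)
    if not seeds.any():
        raise SegmentationError("no seeds found (image is zero in the seed zone)")

    valid = np.broadcast_to(image.tissue_column_mask()[np.newaxis, :],
                            image.intensities.shape)
    conn = fuzzy_connectedness_map(working, seeds, params.sigma, valid=valid)
    return LayerMask(conn >= params.theta, provenance="internal")


# ---------------------------------------------------------------------------
# post-processing and boundary extraction
# ---------------------------------------------------------------------------

def postprocess_mask(mask: LayerMask, params: SegmentationParams = SegmentationParams()) -> LayerMask:
    """Clean a raw entry-echo mask.

    Order: (1) clear ``border_px`` columns at each lateral edge;
    (2) drop 8-connected components smaller than ``min_object_px``;
    (3) if several components remain, keep only the largest.

    Idempotent.  Raises :class:`SegmentationError` when nothing survives.
    """
    m = mask.mask.copy()
    b = params.border_px
    if b > 0:
        m[:, :b] = False
        if b < m.shape[1]:
            m[:, -b:] = False
        else:
            m[:] = False

    labels, n = ndimage.label(m, structure=_STRUCT8)
    if n == 0:
        raise SegmentationError("no entry echo found after post-processing")
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= params.min_object_px) + 1
    if keep.size == 0:
        raise SegmentationError("no entry echo found after post-processing")
    if keep.size > 1:
        keep = np.array([keep[np.argmax(sizes[keep - 1])]])
    return LayerMask(np.isin(labels, keep), provenance=mask.provenance)


def extract_boundaries(mask: LayerMask) -> LayerBoundary:
    """Per-column top (shallowest) and bottom (deepest) foreground rows."""
    m = mask.mask
    if not m.any():
        raise SegmentationError("cannot extract boundaries from an empty mask")
    any_fg = m.any(axis=0)
    top = np.where(any_fg, np.argmax(m, axis=0), -1)
    bottom = np.where(any_fg, m.shape[0] - 1 - np.argmax(m[::-1, :], axis=0), -1)
    return LayerBoundary(top_row=top.astype(int), bottom_row=bottom.astype(int), valid=any_fg)


def load_external_mask(path, image: BModeImage) -> LayerMask:
    """Load a binary entry-echo mask produced by an external segmenter.

    Nonzero pixels are foreground.  Post-processing is still applied by
    the measurement pipeline before any parameter is computed.
    """
    arr = _read_gray(path)
    if arr.shape != image.intensities.shape:
        raise FormatError(
            f"{path}: mask shape {arr.shape} does not match image shape {image.intensities.shape}"
        )
    return LayerMask(arr > 0, provenance="external")
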