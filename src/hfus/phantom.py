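"""Synthetic B-mode skin phantoms with analytic ground truth.

A phantom emulates the layered appearance of a facial HFUS frame: a dim
coupling-gel zone, a bright entry-echo band bounded by wavy (sum-of-
sinusoids) contours, a darker upper dermis (SLEB-like), a brighter lower
dermis, and a millimetre-graduated ruler strip of known tick spacing.

Speckle is modelled as a spatially correlated random field with an exact
per-pixel marginal distribution: a unit-variance Gaussian field with
tunable correlation length is mapped through the Gaussian CDF to a
uniform field and then through the target distribution's quantile
function.  Because the marginal is exact, every intensity statistic of a
layer (mean, band fractions) has a closed-form expectation, which
``truth_record`` evaluates — including the effect of rounding to 8 bits
and of clipping at 255 (clipped mass lands on value 255, i.e. in the
high-echogenicity band).

Two marginals are offered.  The default is a gamma distribution (shape
12, coefficient of variation ~0.29), which matches the moderate contrast
of *display* B-mode pixels: scanners log-compress the RF envelope before
display, which strongly shrinks the envelope's relative spread.  A raw
Rayleigh marginal (the classical fully-developed-speckle envelope model,
CV 0.52) is available via ``speckle_model="rayleigh"`` for studies of
uncompressed amplitude statistics; note that with Rayleigh layer overlap
(18% of a mean-200 layer falls below 100) no intensity-difference
segmentation can trace the layer boundary reliably.

The default geometry is a scaled-down frame (400x600 px at the native
pitches, ~0.9 mm deep and ~5.6 mm wide) so the full pipeline runs in
well under a second per phantom; ``PhantomSpec.full_scale`` reproduces
the 3466x1386 acquisition geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import ndtr
from scipy.stats import gamma as gamma_dist
from scipy.stats import rayleigh as rayleigh_dist

from .calibration_io import BModeImage, PixelCalibration, RulerRegion
from .skin_parameters import (
    DEFAULT_BANDS,
    IntensityBand,
    ParameterRecord,
    lep_upper_lower_ratio,
)

#: Rayleigh mean = scale * sqrt(pi / 2).
_RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic skin frame.

    ``boundary_waviness`` is a sequence of up to 3 (amplitude_mm,
    wavelength_mm) sinusoids whose phases are drawn from the seed; the
    entry-echo bottom contour is the top contour shifted by the layer
    thickness (layers are locally parallel).  ``upper_dermis_extent_mm``
    is the depth of the dark SLEB-like layer below the entry echo; tissue
    below it is brighter lower dermis down to the frame bottom.
    """

    n_rows: int = 400
    n_cols: int = 600
    calibration: PixelCalibration = field(default_factory=PixelCalibration)
    surface_depth_mm: float = 0.15
    entry_echo_thickness_mm: float = 0.09
    upper_dermis_extent_mm: float = 0.2
    boundary_waviness: Tuple[Tuple[float, float], ...] = ((0.02, 0.8),)
    entry_echo_mean: float = 200.0
    upper_dermis_mean: float = 40.0
    lower_dermis_mean: float = 90.0
    background_mean: float = 10.0
    speckle_model: str = "gamma"  # "gamma" (display-like) | "rayleigh" (raw envelope)
    gamma_shape: float = 12.0
    speckle_correlation_px: float = 2.0
    ruler_tick_spacing_mm: float = 0.2
    ruler_width_px: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("surface_depth_mm", "entry_echo_thickness_mm", "upper_dermis_extent_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if len(self.boundary_waviness) > 3:
            raise ValueError("at most 3 boundary sinusoids are supported")
        for mean in (self.entry_echo_mean, self.upper_dermis_mean,
                     self.lower_dermis_mean, self.background_mean):
            if not 0 <= mean <= 255:
                raise ValueError("target layer means must lie in [0, 255]")
        if self.speckle_model not in ("rayleigh", "gamma"):
            raise ValueError(f"unknown speckle model {self.speckle_model!r}")
        amp = sum(a for a, _ in self.boundary_waviness)
        depth = self.n_rows * self.calibration.axial_mm_per_px
        if self.surface_depth_mm + amp + self.entry_echo_thickness_mm >= depth:
            raise ValueError("entry-echo band exceeds the image depth")

    @classmethod
    def full_scale(cls, **overrides) -> "PhantomSpec":
        """The native 3466x1386 acquisition geometry with a 1 mm ruler."""
        base = cls(n_rows=3466, n_cols=1386, surface_depth_mm=0.5,
                   boundary_waviness=((0.02, 1.5),), ruler_tick_spacing_mm=1.0,
                   ruler_width_px=40)
        return replace(base, **overrides)


@dataclass
class PhantomTruth:
    """Analytic ground truth of a generated phantom."""

    mask: np.ndarray
    top_boundary_mm: np.ndarray      # continuous top depth at column centres
    bottom_boundary_mm: np.ndarray
    thickness_mm: float
    layer_means: dict                 # target (pre-quantization) means
    roughness_ratio: float            # arc-length / width of the top contour
    phases: np.ndarray
    tissue_columns: np.ndarray


# ---------------------------------------------------------------------------
# analytic helpers
# ---------------------------------------------------------------------------

def rayleigh_band_probability(scale: float, lo: float, hi: float) -> float:
    """P(lo <= X <= hi) for a continuous Rayleigh(scale) amplitude."""
    cdf = lambda x: 1.0 - math.exp(-(x * x) / (2.0 * scale * scale)) if x > 0 else 0.0
    return cdf(hi) - cdf(lo)


def _layer_distribution(spec: PhantomSpec, mean: float):
    """Frozen scipy distribution with the requested mean."""
    if spec.speckle_model == "rayleigh":
        return rayleigh_dist(scale=mean / _RAYLEIGH_MEAN_FACTOR)
    return gamma_dist(a=spec.gamma_shape, scale=mean / spec.gamma_shape)


def quantized_band_probability(dist, band: IntensityBand) -> float:
    """P(quantized pixel value in band) after rounding and clipping at 255."""
    hi_edge = 1.0 if band.hi >= 255 else float(dist.cdf(band.hi + 0.5))
    lo_edge = 0.0 if band.lo <= 0 else float(dist.cdf(band.lo - 0.5))
    return hi_edge - lo_edge


def quantized_mean(dist) -> float:
    """Expected 8-bit pixel value after rounding and clipping at 255."""
    # value v covers [v-0.5, v+0.5); v=0 absorbs the lower tail, 255 the clip mass
    cdf_edges = np.concatenate(([0.0], dist.cdf(np.arange(255) + 0.5), [1.0]))
    probs = np.diff(cdf_edges)
    return float(np.sum(np.arange(256) * probs))


def _boundary_depth_mm(x_mm: np.ndarray, spec: PhantomSpec, phases: np.ndarray) -> np.ndarray:
    y = np.full_like(np.asarray(x_mm, dtype=float), spec.surface_depth_mm)
    for (amp, wavelength), phase in zip(spec.boundary_waviness, phases):
        y = y + amp * np.sin(2.0 * math.pi * x_mm / wavelength + phase)
    return y


def _analytic_roughness(spec: PhantomSpec, phases: np.ndarray, x0: float, x1: float) -> float:
    """Arc-length / width of the continuous top contour on [x0, x1]."""
    x = np.linspace(x0, x1, 20001)
    slope = np.zeros_like(x)
    for (amp, wavelength), phase in zip(spec.boundary_waviness, phases):
        k = 2.0 * math.pi / wavelength
        slope += amp * k * np.cos(k * x + phase)
    arc = np.trapezoid(np.sqrt(1.0 + slope * slope), x)
    return float(arc / (x1 - x0))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _correlated_uniform(shape, corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform(0,1) field with Gaussian spatial correlation and exact marginal."""
    g = rng.standard_normal(shape)
    if corr_px > 0:
        g = ndimage.gaussian_filter(g, sigma=corr_px, mode="wrap")
        # renormalise to unit variance: divide by the filter kernel's L2 norm
        size = int(8 * math.ceil(corr_px)) + 1
        delta = np.zeros((size, size))
        delta[size // 2, size // 2] = 1.0
        kernel = ndimage.gaussian_filter(delta, sigma=corr_px)
        g = g / math.sqrt(float(np.sum(kernel * kernel)))
    return ndtr(g)


def generate_phantom(spec: PhantomSpec) -> Tuple[BModeImage, PhantomTruth]:
    """Generate a phantom frame and its analytic ground truth.

    Deterministic: identical spec (including seed) gives a bit-identical
    image.  A pixel belongs to a layer when its row-centre depth lies
    within the layer's continuous bounds.
    """
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=max(1, len(spec.boundary_waviness)))

    cal = spec.calibration
    x_mm = (np.arange(spec.n_cols) + 0.5) * cal.lateral_mm_per_px
    depth_mm = (np.arange(spec.n_rows) + 0.5)[:, None] * cal.axial_mm_per_px

    top = _boundary_depth_mm(x_mm, spec, phases)
    bottom = top + spec.entry_echo_thickness_mm
    dermis_split = bottom + spec.upper_dermis_extent_mm

    in_entry = (depth_mm >= top[None, :]) & (depth_mm < bottom[None, :])
    in_upper = (depth_mm >= bottom[None, :]) & (depth_mm < dermis_split[None, :])
    in_lower = depth_mm >= dermis_split[None, :]

    layer_means = {
        "background": spec.background_mean,
        "entry_echo": spec.entry_echo_mean,
        "upper_dermis": spec.upper_dermis_mean,
        "lower_dermis": spec.lower_dermis_mean,
    }
    u = _correlated_uniform((spec.n_rows, spec.n_cols), spec.speckle_correlation_px, rng)
    # clamp away from 1.0 so heavy upper tails stay finite after ppf
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    img = np.empty((spec.n_rows, spec.n_cols), dtype=float)
    regions = {
        "background": ~(in_entry | in_upper | in_lower),
        "entry_echo": in_entry,
        "upper_dermis": in_upper,
        "lower_dermis": in_lower,
    }
    for name, region in regions.items():
        if region.any():
            img[region] = _layer_distribution(spec, layer_means[name]).ppf(u[region])
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    ruler_region = None
    tissue = np.ones(spec.n_cols, dtype=bool)
    if spec.ruler_width_px > 0:
        c0 = spec.n_cols - spec.ruler_width_px
        ruler_region = RulerRegion(col_start=c0, col_stop=spec.n_cols)
        tissue[c0:] = False
        img[:, c0:] = 0
        spacing_px = spec.ruler_tick_spacing_mm / cal.axial_mm_per_px
        offset = 10.0
        k = 0
        while True:
            row = int(round(offset + k * spacing_px))
            if row >= spec.n_rows:
                break
            img[row, c0:] = 255
            k += 1

    mask = in_entry & tissue[None, :]
    image = BModeImage(img, calibration=cal, ruler_region=ruler_region,
                       image_id=f"phantom-seed{spec.seed}")
    x_lo = (np.flatnonzero(tissue)[0]) * cal.lateral_mm_per_px
    x_hi = (np.flatnonzero(tissue)[-1] + 1) * cal.lateral_mm_per_px
    truth = PhantomTruth(
        mask=mask,
        top_boundary_mm=top,
        bottom_boundary_mm=bottom,
        thickness_mm=spec.entry_echo_thickness_mm,
        layer_means=layer_means,
        roughness_ratio=_analytic_roughness(spec, phases, x_lo, x_hi),
        phases=phases,
        tissue_columns=tissue,
    )
    return image, truth


def truth_record(truth: PhantomTruth, spec: PhantomSpec,
                 bands: Optional[dict] = None) -> ParameterRecord:
    """Expected parameter values, computed analytically from the spec.

    Thickness and roughness come from the continuous boundaries; per-ROI
    echogenicities and band fractions from the layer distribution's CDF
    with 8-bit rounding and 255-clipping accounted for.  Texture measures
    have no closed form and are left missing.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    rec = ParameterRecord(image_id=f"phantom-seed{spec.seed}-truth")
    rec.thickness_mm = truth.thickness_mm
    rec.roughness_edge_ratio = truth.roughness_ratio

    roi_layers = {
        "entry_echo": "entry_echo",
        "outer_entry_echo": "entry_echo",
        "upper_dermis": "upper_dermis",
        "lower_dermis": "lower_dermis",
    }
    for roi, layer in roi_layers.items():
        dist = _layer_distribution(spec, truth.layer_means[layer])
        rec.echogenicity[roi] = quantized_mean(dist)
        rec.fractions[roi] = {
            name: 100.0 * quantized_band_probability(dist, band)
            for name, band in bands.items()
        }
    rec.intensity_ratio_upper_dermis_to_entry_echo = (
        rec.echogenicity["upper_dermis"] / rec.echogenicity["entry_echo"]
    )
    if "LEP" in bands:
        rec.nlep_upper_to_lower = lep_upper_lower_ratio(
            rec.fractions["upper_dermis"]["LEP"], rec.fractions["lower_dermis"]["LEP"]
        )
    return rec
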