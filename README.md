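# hfus — quantitative analysis of high-frequency ultrasound skin images

High-frequency ultrasound (HFUS, ≥ 20 MHz) resolves the superficial layers of
human skin: the bright **entry echo layer** where the beam first meets the
skin (the epidermis proxy), the often hypoechoic **upper dermis** (where the
subepidermal low echogenic band, SLEB, appears in photo-aged skin), and the
brighter **lower dermis**. Dermatology and cosmetology studies — e.g. of
anti-aging therapies — need the same measurements from thousands of B-mode
frames, objectively and repeatably. This package implements that
quantification pipeline for 8-bit grayscale B-mode frames:

1. **Calibration & I/O** — TIFF/PNG frames, study manifests, and pixel-pitch
   estimation from the embedded millimetre-graduated ruler (default pitch
   0.0023 mm/px axial × 0.0093 mm/px lateral, so a native 1386-column frame
   spans 12.8898 mm).
2. **Entry-echo segmentation** — either an externally supplied mask (e.g.
   from a trained network) or a classical seeded **fuzzy connectedness**
   segmenter: per column the brightest shallow pixel seeds the layer, pixel
   affinity is κ(a,b) = exp(−(I(a)−I(b))²/2σ²) on 4-adjacent pixels, and a
   pixel belongs to the layer when its max–min path strength to the seed set
   reaches θ (computed exactly by best-first propagation). Post-processing
   crops 20 px at each lateral border (0.372 mm of a native frame), removes
   small objects and keeps the largest component.
3. **Depth-referenced ROIs** — the outer 0.1 mm of the entry echo, the
   0.2 mm upper-dermis band below the layer, and the 0.4 mm lower-dermis band
   below that, each following the layer contour column by column.
4. **Dermal parameters** per frame and ROI:
   * thickness of the entry echo layer (mm);
   * echogenicity (mean intensity) and the upper-dermis/entry-echo ratio;
   * normalised echogenic pixel fractions
     nLEP = n_[0–30]/n · 100 %, nMEP (50–150), nHEP (200–255), and the
     upper/lower-dermis nLEP ratio;
   * surface roughness A/B — boundary polyline length over lateral width;
   * GLCM texture (contrast, correlation, energy, homogeneity) at pixel
     offsets (0,7), (5,7), (7,7) with 128 gray levels, plus region entropy.
5. **Study statistics** — per-series aggregation and the repeated-measures
   sample-size/power computation: with Cohen's f² = η²/(1−η²) and m
   correlated measures, the between-group noncentrality is
   λ = f²·N·m/(1+(m−1)ρ) and power is P(F′(k−1, N−k, λ) > F_crit(α)).
6. **Phantom generator** — layered speckle phantoms with analytic ground
   truth (boundaries, thickness, layer means, band fractions, roughness), so
   every stage is testable without patient data.

## Worked example

Generate a phantom, segment it, and measure it:

```bash
hfus simulate --seed 3 --out ph.png --truth truth.json
hfus segment ph.png --out mask.png
hfus measure ph.png --mask mask.png --out rec.json
```

Selected values from `rec.json` for seed 3 (analytic truth in brackets):

```
thickness_mm                       0.0898   [0.0900]
echogenicity entry_echo            195.7
echogenicity upper_dermis          39.7     [40.0]
intensity ratio (upper/entry)      0.203
nLEP upper_dermis (%)              22.6     [21.2]
roughness_edge_ratio               1.0153
entropy_bits upper_dermis          4.54
```

The pipeline recovers the generator's layer thickness within half a percent,
the dark upper-dermis mean and its low-echogenic pixel share within sampling
error, and a roughness slightly above the continuous-boundary value (pixel
rasterisation adds small axial steps).

Sample-size planning for a two-arm longitudinal study with six repeated
measurements:

```bash
hfus power --alpha 0.05 --power 0.9 --groups 2 --measurements 6 --rho 0.53 --eta2 0.15
```

prints `required_n_total: 40` with `achieved_power: 0.913`: forty
participants (twenty per group) give 91.3 % power for the between-group main
effect.

Batch processing uses a manifest CSV (`image_path, mask_path, subject_id,
group, timepoint, location, …`) via `hfus batch manifest.csv --out
results.csv`, and `hfus aggregate` collapses frames per acquisition series.

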