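# wpbquant

Automated quantification of **Weibel-Palade bodies (WPBs)** — the
rod-shaped secretory organelles of endothelial cells that store von
Willebrand factor (VWF) — from two-channel fluorescence z-stacks, for
researchers studying how culture conditions (seeding density, incubation
time, confluency) shape WPB abundance in HUVECs and ECFCs.

The package provides, as a tested and reusable library + CLI:

- **`wpbquant.synthetic`** — a ground-truthed simulator of
  DAPI/FITC-VWF confocal fields: elliptical nuclei, capsule-shaped rods
  with the WPB morphology (0.1–0.3 µm diameter, 1–5 µm length), small
  round immature vesicles, 23-slice stacks at a 0.3 µm step, plus whole
  experiment designs (constant seeding density across 24/48/72/96 h, or
  constant 96 h incubation across 5,000/10,000/30,000 cells/cm²;
  5 slides × 9 fields × 3 experiments) and exponential growth series.
- **`wpbquant.segmentation`** — the FIJI-macro-style counting pipeline:
  per-channel z-projection → auto-contrast → 8-bit → auto-threshold
  (isodata or Otsu) → connected-component particle analysis →
  area/circularity filtering. Circularity `4πA/P²` (1 for a disc, → 0
  for rods) is what excludes small round immature vesicles while
  keeping mature rods; the default cut is `circularity ≤ 0.8`.
- **`wpbquant.quantification`** — the study's central statistic,
  per-slide pooled `WPB/nuclei = Σ WPB / Σ nuclei` over a slide's 9
  fields, confluency classification (inclusive cells-per-field cutoff:
  51 for HUVECs, 75 for ECFCs at the reference field of view,
  operationalizing ~80% surface coverage), and cohort assembly
  (by confluency / time / density / culture method).
- **`wpbquant.growth`** — doubling times
  `DT = Δt · log 2 / Δlog N` per interval and averaged per series,
  growth-curve OLS regression, the ANCOVA slope-equality F-test,
  one-way ANOVA, and paired t-tests.

## Worked example

```python
from wpbquant.synthetic import SceneSpec, render_field
from wpbquant.segmentation import count_field

spec = SceneSpec(nucleus_count=12, wpb_count=180, immature_count=40,
                 nucleus_radius_um=(3.0, 5.0), noise_sd=12.0, seed=42)
image, truth = render_field(spec)          # 2-channel 23-slice stack
counts, nuclei, wpbs = count_field(image)  # full counting pipeline
print(f"truth:    {truth.nucleus_count} nuclei, {truth.wpb_count} WPBs, "
      f"{truth.immature_count} immature vesicles")
print(f"measured: {counts.nuclei_count} nuclei, {counts.wpb_count} WPBs")
```

prints

```
truth:    12 nuclei, 180 WPBs, 40 immature vesicles
measured: 12 nuclei, 180 WPBs
```

— the pipeline recovers the exact inventory of this non-overlapping
field at SNR 10, and all 40 round immature vesicles were removed by the
circularity filter (the retained WPB particles span circularity
0.17–0.76, below the 0.8 cut).

The CLI mirrors the library:

```bash
wpbquant simulate field --config scene.yaml --seed 1 --out sim/
wpbquant simulate experiment --config design.yaml --out expt/
wpbquant quantify --in expt/ --out results/
wpbquant cohort --counts results/counts.csv --cell-type HUVEC --out cohorts/
wpbquant growth --counts growth.csv --out report/
wpbquant compare --cohorts cohorts/cohorts.csv --grouping by_confluency --out stats.json
wpbquant run-all --config run.yaml --out out/       # end-to-end
wpbquant run-all --manifest out/manifest.json --out replay/  # exact replay
```

Every run writes a `manifest.json` recording all parameters and seeds;
replaying a manifest regenerates every output byte-for-byte.

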