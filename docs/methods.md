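# Methods

## Scope and model

`wpbquant` quantifies Weibel-Palade bodies (WPBs) in endothelial
cultures from two-channel fluorescence z-stacks: a nuclei channel
(DAPI) and a VWF channel (FITC). The central statistic is the pooled
per-slide ratio

    WPB/nuclei = (Σ WPB counts over a slide's fields) / (Σ nucleus counts)

computed from 9 imaged locations per slide, with slides as the
biological replicates. Slides are classified *confluent* when their
mean nuclei per field reaches a cell-type-specific cutoff (51 cells per
field for HUVECs, 75 for ECFCs at the reference field of view), an
operationalization of a cohesive monolayer covering ~80% of the
surface. Cohorts (sub-confluent vs confluent; by incubation time; by
seeding density; by culture method) are compared with one-way ANOVA on
slide-level values.

Because no real image data ships with the package, a synthetic-data
module generates ground-truthed scenes under the same acquisition
geometry (23 z-slices, 0.3 µm step) and experiment designs
(5,000/10,000/30,000 cells/cm² at a constant 96 h; 24/48/72/96 h at a
constant 30,000 cells/cm²; ≥5 slides × 9 fields × 3 experiments), so
that every pipeline claim is tested against an exact object inventory.

## The counting pipeline

Per channel: z-projection → auto-contrast → 8-bit conversion → global
auto-threshold → connected-component labeling → area/circularity
filter.

- **Projection.** Default is the maximum-intensity projection, which
  avoids counting one organelle once per z-slice it appears in. A
  `per_slice` mode (counts summed over slices) is provided because
  slice-wise processing is an equally defensible reading of macro-style
  workflows; it systematically over-counts objects spanning slices and
  is therefore not the default.
- **Auto-contrast.** Linear stretch clipping the lowest/highest 0.35%
  of pixels (the ImageJ convention), order-preserving on unclipped
  pixels; constant images pass through unchanged.
- **Thresholding.** Isodata (iterative intermeans, ImageJ's "Default")
  is the default; Otsu (maximal between-class variance) is available
  for comparison. Both are authored here from the 256-bin histogram;
  tests cross-check Otsu against an exhaustive 256-level scan and
  against scikit-image. Because empty histogram bins make adjacent
  levels induce identical partitions, the Otsu maximizer is often a
  plateau; the implementation returns the plateau midpoint. The mask is
  `image > threshold`; a constant image yields an empty mask.
- **Noise floor** (`noise_floor_snr`, default 5). On planes whose true
  signal occupies less than the contrast-saturation share (~0.35% of
  pixels), global histogram thresholds collapse into the noise
  distribution (measured on synthetic fields: threshold − median
  ≈ 0.2–0.5 robust SD when sparse/empty vs ≈ 6 SD with ample signal)
  and flood the particle analysis with specks. The effective threshold
  is therefore never allowed below `median + 5` robust (MAD-based)
  noise SDs: sparse planes fall back to this background-exceedance
  threshold (real structures sit near the top of the stretched range),
  dense planes are untouched (their histogram threshold already
  exceeds it), and empty planes stay empty (the floor clears the noise
  maximum). Residual caveat: extremely sparse fields (~1 cell,
  < 10 rods, signal ≈ 0.03% of pixels) remain below the detection
  limit and report zero WPBs.
- **Particle analysis.** 8-connectivity by default (4 selectable).
  Areas are pixel counts × pixel_size²; perimeters use the Crofton
  (4-direction) estimator, which stays within ~10% of the analytic
  boundary for convex shapes down to a few pixels — the chain-code
  estimator collapses on thin diagonal rods and would corrupt
  circularity. Circularity is `min(1, 4πA/P²)`. Documented tolerance
  against analytic shapes: ±10% on perimeter, hence roughly ±20% on
  circularity of small objects.
- **Filters.** Nuclei: area ≥ 20 µm² (no circularity bound). WPBs:
  area ≥ 0.05 µm² and circularity ≤ 0.8. Analytic circularity of the
  WPB capsule ranges ~0.17 (5 × 0.3 µm) to ~0.64 (1 × 0.3 µm), while
  rendered immature vesicles measure ≈ 1, so 0.8 separates the
  populations with margin on both sides.
- No watershed splitting of touching nuclei is performed; validation
  scenes are non-overlapping by construction and clumping is a known
  limitation for real data.

## The synthetic scenes

Objects: nuclei as filled ellipses (semi-axes sampled 4–8 µm by
default; validation scenes use 3–5 µm so that the densest fields remain
placeable), WPBs as capsules (rectangle + semicircular caps; length
1–5 µm, width 0.1–0.3 µm), immature vesicles as discs (radius
0.2–0.45 µm). Rasterization is coverage-antialiased (per-pixel overlap
in [0, 1]) so 0.1 µm rods stay connected; each object is brightest at
its own focal slice with Gaussian axial fall-off (σ 0.6 µm for
vesicles, 2.5 µm for nuclei), followed by lateral Gaussian blur,
additive background, and Gaussian read noise clipped at zero.

Key numerical choices:

- **Pixel size** defaults to 0.11 µm (typical 60×/NA 1.0 camera
  sampling; the acquisition magnification is known but not the camera
  geometry, so this is an exposed stand-in, not an inferred value).
- **PSF σ = 0.11 µm**, the diffraction-limited value 0.21·λ/NA for
  ~520 nm emission at NA 1.0. Grids much coarser than the PSF alias
  sub-resolution rods into fragments; simulated experiments therefore
  render at 0.12 µm/px.
- **Peak-calibrated rendering.** An object's intensity parameter is the
  peak it reaches at its focal slice *after* the lateral PSF. Without
  this, peak brightness scales with physical width and 0.1 µm rods fall
  below any global histogram threshold while 0.3 µm rods saturate it.
  Peak calibration makes "SNR ≥ 5" a well-defined per-object condition
  (intensity / noise SD); the cost is that the simulator does not
  reproduce width-dependent brightness (full optical realism — 3-D
  PSF, bleed-through, photobleaching — is out of scope).
- **Placement** is rejection sampling against an occupancy mask:
  objects land fully inside the field, pairwise separated by
  ≥ 0.6 µm (smaller gaps visibly bridge under the PSF and merge
  particles), with up to 100 retries per object (300 in experiment
  scenes) and a configurable tolerated-overlap fraction for
  stress-testing. Overfull scenes raise an error naming the object and
  condition rather than silently degrading.
- **Determinism.** One seeded RNG drives each operation; identical
  seeds give bit-identical stacks, series, and experiments.

## Simulated experiments

Per condition, the expected local cell count follows exponential growth
`N(t) = density × field_area × 2^(t/DT)` (default DT 33 h for HUVECs,
26 h for ECFCs); each field draws a Poisson count around it. The WPB
yield per cell is a monotone logistic in local cells-per-field with its
midpoint at the confluency cutoff, emulating the contact-dependence of
WPB formation; the defaults (floor 6, ceiling 14) were set by a
placement-capacity analysis — at the rendered raster the densest
condition must stay below ~45% channel occupancy for non-overlapping
placement — and are deliberately below biologically reported WPB/nuclei
magnitudes. The package is validated on *count recovery*, not on
absolute WPB abundance; absolute means measured on simulations are
properties of the chosen yield curve.

The reference field of view (6.2 × 10⁴ µm², a ~249 µm square) is
derived from the growth model itself: a culture seeded at
30,000 cells/cm² with DT 33 h reaches the 51 cells/field HUVEC cutoff
at 48 h, implying that area. Experiment scenes render a smaller raster
(512 px at 0.12 µm/px, 7 slices, ~61 µm square) for tractability —
hundreds of fields per experiment — and the cells-per-field cutoff
scales proportionally with field area, preserving the 80%-coverage
semantics at any geometry.

## Growth analytics

- Interval doubling time `DT = (t₁−t₀)·log 2 / (log N₁ − log N₀)`;
  the log base cancels. Negative values (shrinking cultures) are
  returned, not errored; degenerate intervals (equal counts) are
  excluded from the series mean with a warning.
- Growth regression is OLS of raw counts (scaled to thousands by
  default) on time; a log-count option exists since exponential growth
  is the generative model. Slope equality between two series uses the
  ANCOVA homogeneity-of-slopes F-test (full model with separate slopes
  vs common slope, F(1, n−4)).
- One-way ANOVA reports F, dfs, p, and group means; zero within-group
  variance with differing means is reported explicitly as F = ∞, p = 0.
  The paired t-test handles zero-variance differences explicitly
  (identical samples → t = 0, p = 1).
- The nested structure (fields ⊂ slides ⊂ experiments) is *not*
  modeled (no mixed effects); cohort tests treat slides as independent
  replicates, a simplification noted as a limitation.

## What passing tests do and do not show

The simulator provides exact ground truth, non-overlapping objects,
Gaussian noise, and uniform staining. Passing count-recovery and
cohort-direction checks therefore demonstrates the pipeline's
correctness under those assumptions — they do not certify performance
on real micrographs with touching cells, perinuclear WPB clustering,
uneven illumination, or autofluorescence. Problem sizes used by the
test-suite and acceptance script (12–20 full-size 1024² fields; one
simulated experiment of 180 rendered 512² fields; 100–1000 Monte-Carlo
replicates for statistical calibration) are the package's validation
choices and are recorded alongside each reported number.
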