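# Methods

## Measurement model

A slice cross-section photo is modelled as a single dark, roughly
rectangular band (the slice seen edge-on) on a bright field (translucent
agarose), at arbitrary orientation. Thickness is defined *after* the band is
made vertical: each pixel row then crosses the band exactly once, and for a
rectangular segment of the mask

    T = (Σ pixel values in segment / segment rows) × pixel_size   [µm]

is the mean per-row foreground width in microns. This pixel-count statistic
is deliberately sub-pixel-free: it equals a per-row run-length count exactly
(a property the test suite asserts to machine precision), so its behaviour
under dilation, partition and rescaling is transparent. A slice is measured
on at least three segments; the protocol reports mean ± SD and flags the
slice as irregular when CV = SD/mean > 0.25. The flag is a QC signal, never
an abort: batch runs carry it in the per-image record and the log.

The divisor is the *segment's* own row count, not the whole crop's — the
only reading under which per-segment values differ and their SD measures
slice irregularity. SD uses the sample (n−1) formula by default, with
`ddof=0` available, since either convention is defensible for a three-value
display.

## Pipeline stages and their choices

**Thresholding.** The default is a triangle-seeded Ridler–Calvard (isodata)
threshold: the triangle method lands on the correct side of the dominant
background mode even when the band covers only a few percent of the frame,
and the isodata fixed point (midway between the two class means) balances
the two noise tails. Plain Otsu is also available but is not the default:
under strong class imbalance (a thin band on a large canvas) Otsu's
between-class-variance criterion can split the background mode instead of
separating band from field, inflating the mask by whole background regions.
A fixed manual threshold covers non-bimodal acquisitions. Comparison is
half-open: pixels strictly below the threshold form one class.

**Foreground orientation.** Which binary class is the slice is decided by
the minority rule (the band occupies less area than the field), with an
explicit `slice-dark`/`slice-bright` override; an exact 50/50 split raises
rather than guesses. A fixed "invert" step would silently fail on
acquisitions with the opposite polarity.

**Axis alignment.** Batch mode estimates the slice axis as the first
principal component of the foreground pixel coordinates and returns the
extreme projections *on* the axis line (real-valued). Snapping endpoints to
extreme pixels instead would pick opposite band corners and bias the angle
by up to atan(width/length). Manual endpoints (the interactive workflow's
two clicks) are accepted everywhere the PCA estimate is. Rotation uses
nearest-neighbour resampling with a 0.5 re-threshold so the mask stays
binary — bilinear interpolation would create fractional pixels that bias the
pixel-sum statistic — and enlarges the canvas (background padding) so no
foreground is cropped. An isotropic foreground (equal principal variances)
has no axis and raises.

**Segment placement.** `auto_segments` replaces the interactive three
rectangles: n (≥ 3) disjoint full-width horizontal bands, each covering
`fraction` (default 0.1) of the foreground's row extent, centred at evenly
spaced stations (25/50/75 % for n = 3). Placements that cannot be disjoint
raise. Before axis estimation the batch pipeline keeps only the largest
connected foreground component — the scripted stand-in for the interactive
crop, which removes stray debris and noise speckles.

## Study statistics

Per (step, speed) cell: n, mean, sample SD and the thickness error
`(mean − step)/step × 100 %`. The per-tissue overall error is the
unweighted mean of the defined cell errors; cells with no slices are
explicitly absent, never zeros. All statistics are carried at full
precision; comparisons against rounded published values are made at the
printed number of decimals. The bundled reference summary's overall errors
illustrate why: exact arithmetic on its printed cell errors gives 100.8875 %
(fresh liver) and 59.25 % (fresh brain) where the source prints 100.8 and
59.2 — one-decimal discrepancies consistent with the source having averaged
unrounded cell means. `datasets.overall_error_discrepancies()` reports
these, using half-up decimal rounding for the comparison (half-even would
silently accept 59.25 → 59.2).

ANOVA is fixed-effects OLS (statsmodels) — two-way with interaction when
both step size and speed vary, one-way when only step size does. Sums of
squares are Type I on balanced designs (where all types coincide) and
Type II on unbalanced ones, since real studies lose slices; cells with one
observation require the interaction to be dropped explicitly. Post-hoc
comparisons use Tukey's HSD (studentized range). The compact letter display
is the insert-and-absorb algorithm, which guarantees both directions of the
contract: two groups share a letter **iff** their adjusted p ≥ α. Whether
comparisons run over all step × speed cells jointly (`by_cell=True`, as in
per-cell bar plots) or within one factor is the caller's choice; the study
report uses cells jointly for two-factor tissues.

## Synthetic fixtures

`generate_band` renders the band analytically in rotated coordinates:
a `true_width × length` rectangle at `angle`° from vertical, per-row
independent uniform jitter U(−roughness, +roughness) on each edge, constant
band/field intensities, additive Gaussian noise. The symmetric jitter model
was chosen for its closed form: the expected per-row width — hence the
expected measured thickness — equals `true_width` exactly, which the suite
verifies by Monte Carlo (10⁴ rows, tolerance 0.1 px). The exact label mask
is returned alongside, so misclassification and recovery are measurable
without registration. One seeded generator drives jitter then noise;
identical specs are bit-identical.

What the fixtures do *not* emulate: illumination gradients, staining
texture, curved or folded slices, multiple objects, partial-volume edge
blur. Passing tests therefore demonstrate correctness of the measurement
given an approximately straight band with roughly bimodal intensities — not
robustness to every real acquisition artefact; the manual ROI/threshold/axis
overrides exist for those cases.

`generate_study` draws per-slice thicknesses from N(mean, sd²) per cell.
Normality is a fixture assumption (the reference reports only means/SDs).
Default cell size n = 6, the reference study's per-cell sample size.

## Problem sizes and tolerances in the verification suite

- End-to-end recovery: widths {5, 12, 20, 50} px × angles 0–80° in 10°
  steps, noise SD at one sixth of the band/field contrast; required accuracy
  ±1 px. Canvas side `length + width + 40` px contains every rotation.
- Thickness-statistic oracle: 200 random masks, equality to the run-length
  count at relative 10⁻¹³.
- ANOVA calibration: 1000 null replicates of a balanced 3 × 2 × 6 design;
  each effect's rejection rate must lie in 0.05 ± 0.02. The implementation
  is additionally checked against closed-form textbook sums of squares.
- Fixed-brain significance pattern: 200 studies simulated from the
  reference cell means/SDs; "step significant, speed not" must hold in
  ≥ 90 % of replicates (the expected rate is ≈ 94 %: the simulated speed
  effect is tiny but nonzero, so the non-rejection rate sits slightly below
  1 − α plus nothing).
- Letter display: 100 random p-matrices with random α; the sharing relation
  must equal the thresholded matrix exactly.

Rotation-resampling invariants use a 3 % foreground-count bound for a
there-and-back rotation and 2 % for a single alignment, reflecting
nearest-neighbour quantization on band-shaped objects.

## Known limitations

- One band per image; curved slices are measured as their vertical-aligned
  projection (no deskewing).
- No flat-field correction or denoising beyond the largest-component step.
- Fixed-effects ANOVA treats slices as independent; animal-level clustering
  (few donors per tissue) is not modelled.
- The thickness statistic has no sub-pixel edge localization by design;
  accuracy is bounded by pixel size.
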