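# slicethick

Calibrated thickness measurement of vibratome tissue slices from
cross-section images, plus the study-level statistics that turn many such
measurements into an accuracy assessment of a slicing setup.

## The problem

Vibratomes cut precision slices from soft fresh or fixed tissue (liver,
brain, ...) for organotypic culture and morphometry. The *nominal* thickness
is the stage step size, but the *actual* thickness of a hydrated slice after
sectioning and equilibration can differ substantially — soft tissue swells.
The standard way to measure the actual thickness is to embed the hydrated
slice in agarose, cut a cross-section perpendicular to its surface, and
photograph it: the slice appears as a dark band on a bright field whose width
is the slice thickness.

`slicethick` is a scriptable implementation of that image measurement and of
the downstream study statistics, for lab scientists characterizing a slicing
protocol:

1. **Binarize** the cross-section photo (triangle-seeded isodata threshold by
   default; Otsu or a fixed threshold on request) and orient the mask so the
   slice is white (1) on black (0).
2. **Align** the slice's principal axis vertically (PCA on the foreground, or
   manual endpoints) so each pixel row crosses the band once.
3. **Measure** ≥ 3 rectangular segments. Per segment, thickness is the
   pixel-sum statistic

   `T = (Σ mask pixels in segment / segment rows) × pixel size [µm]`

   i.e. the mean per-row band width in microns. The slice is reported as
   mean ± SD over segments, with an irregularity warning when the
   coefficient of variation CV = SD/mean exceeds 0.25.
4. **Summarise a study**: per (step size, speed) cell the thickness error
   `(mean − step)/step × 100 %`, per-tissue overall error (mean of cell
   errors), two-way (or one-way) fixed-effects ANOVA of thickness on step
   size and sectioning speed, and Tukey HSD post-hoc comparisons with a
   compact letter display (groups sharing a letter are not significantly
   different at α = 0.05).

A synthetic-fixture generator (`slicethick.synthetic`) renders band images
with known width, orientation, edge roughness and noise, and simulates
slice-level study tables, so the whole pipeline is testable without
microscope data. A reference summary table from a published vibratome
characterization of fresh porcine liver, fresh murine brain and PFA-fixed
murine brain ships in `slicethick.datasets`.

## Worked example

```python
import slicethick as st

# a synthetic cross-section: 25 px wide band at 35° with rough edges + noise
spec = st.BandSpec(true_width=25, length=150, angle=35, edge_roughness=1.0,
                   noise_sd=20.0, canvas=(260, 260), pixel_size=8.1, seed=7)
image, truth, meta = st.generate_band(spec)

result = st.measure_image(image)
print(f"mean = {result.mean:.1f} um, sd = {result.sd:.1f} um, "
      f"cv = {result.cv:.3f}, irregular = {result.irregular}")
```

prints

```
mean = 202.5 um, sd = 2.4 um, cv = 0.012, irregular = False
```

— the pipeline recovers the true width (25 px × 8.1 µm/px = 202.5 µm)
despite rotation, rough edges and noise, and the low CV confirms a regular
band. A study-level run on a table simulated from the PFA-fixed brain
reference cells (6 slices per cell):

```python
from slicethick.datasets import reference_study_design, PFA_BRAIN
records = st.generate_study(reference_study_design(PFA_BRAIN), seed=11)
report = st.run_study(records)
print(report["overall"])
print(report["tukey"][PFA_BRAIN].summary())
```

```
                   tissue  n_combos  overall_error_pct
0  PFA-fixed murine brain         6          38.521232

      group        mean letters
0  100/0.05  155.804920       c
1   100/0.2  167.754490       c
2  200/0.05  242.052802       b
3   200/0.2  250.421815       b
4  400/0.05  507.112824       a
5   400/0.2  538.209857       a
```

The overall error (~38.5 % here; 38.8 % in the reference summary itself)
says fixed brain slices come out ~39 % thicker than the nominal step size.
The letters group the six cells purely by step size: the two speeds always
share a letter, i.e. sectioning speed has no significant effect — the ANOVA
table in `report["anova"]` shows the same (step p < 10⁻⁶, speed p ≈ 0.16).

The same stages are available from the shell:

```sh
slicethick synth band --width 25 --angle 35 --seed 7 --out fixtures/
slicethick measure fixtures/*.png --pixel-size 8.1 --out run/
slicethick study run/measurements_labelled.csv --out report/
```

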