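# chorostrat

Stratified choroidal structure analysis for EDI-OCT B-scans: segmentation of
the three choroidal vascular sublayers — choriocapillaris (CC), Sattler's
layer (SL), Haller's layer (HL) — and binarization of each into luminal
(vessel) and stromal tissue, with the cohort statistics used in clinical
studies of choroidal aging and myopia.

The choroid supplies the outer retina and thins with age and with axial
elongation of the eye, but a plain choroidal-thickness number hides *which*
vascular layer changes. This package quantifies the internal structure: for
a 1500-μm window centered on the fovea it reports, per sublayer, the
cross-sectional area CA (mm²), the luminal area LA (dark pixels, mm²), the
stromal area SA = CA − LA, the luminal/choroidal ratio
L/C = 100·LA/CA (%), and the central thickness (μm). It is written for
researchers in ophthalmic imaging who want a reproducible, fully testable
reimplementation of this analysis — including a synthetic B-scan generator
with exact ground truth, so every stage can be validated without clinical
data.

## Method

Given a grayscale B-scan with per-image scales (μm/pixel), an annotated RPE
lower edge, choroid–scleral interface (CSI), and fovea column:

1. **ROI** — carve the fovea-centered window of width 1500 μm; the choroid
   spans rows [RPE, CSI) per column (half-open, so each pixel belongs to
   exactly one layer).
2. **Brightness floor** — average the reflectance of the three darkest
   vessel lumens of Haller's layer (automatic search, or manual
   coordinates); this is the lowest-brightness criterion.
3. **256 gradations** — map [floor, max] linearly to [0, 255].
4. **Sublayer boundaries** — OCT reflectance is dark inside lumens and
   bright in stroma, and vessel caliber grows from CC outward, so the depth
   profile of vertical intensity change drops stepwise at each boundary.
   The detector finds the trend change of that profile in an RPE-flattened
   frame, refines it per column with intensity change points (second-order
   differencing of smoothed depth traces), and fits each boundary with a
   quadratic curve `row = a·col² + b·col + c` (least squares with one
   residual-trimming pass), clipped to the ordering
   RPE ≤ CC/SL ≤ SL/HL ≤ CSI.
5. **Binarization** — a choroidal pixel is luminal iff its rescaled
   intensity falls below the lumen-referenced threshold (default), or below
   a Niblack local threshold (`method="niblack"`).
6. **Quantification** — areas are pixel counts × pixel footprint;
   CA = LA + SA holds exactly in pixel counts, as does the sublayer sum
   CA(total) = CA(CC) + CA(SL) + CA(HL).
7. **Statistics** — two-way random-effects ICC(2,1)/ICC(2,k) from the ANOVA
   mean squares, Bland–Altman fixed bias (t-based CI) and proportional bias
   (Pearson r of differences on means), Spearman rank correlation,
   standardized multiple regression of each choroidal parameter on age,
   spherical equivalent and axial length (OLS on z-scores), and
   Kruskal–Wallis across sublayers.

The synthetic-data module renders phantoms with known boundaries and lumen
masks (dark elliptical lumens, caliber growing CC → SL → HL, per-layer
lumen fractions driven to target by rejection sampling) and simulates
subject cohorts in which age and axial length exert linear effects on
sublayer thickness and lumen fraction.

## Worked example

```python
from chorostrat import PhantomSpec, PipelineConfig, generate_phantom, run_single

sample = generate_phantom(PhantomSpec(seed=7))          # truth known exactly
result = run_single(sample.image, sample.roi, PipelineConfig())
```

Running `python examples/02_segment_bscan.py` (which adds the comparison
against truth) prints:

```
boundary recovery (mean |error| in pixels):
  CC/SL: 0.11
  SL/HL: 0.17
brightness floor from reference lumens: 28.9 gray

 layer  L/C measured  L/C truth
 total          64.6       64.6
    cc          78.1       78.0
    sl          66.8       66.9
    hl          62.3       62.3
```

Both detected boundaries land within a fraction of a pixel of the planted
ones, and the measured luminal/choroidal ratios match the planted vascular
structure to ≈0.1 percentage points — the L/C ratio is highest in the
choriocapillaris and falls toward Haller's layer. The other scripts in
`examples/` demonstrate phantom generation, inter-rater reliability
(ICC/Bland–Altman), and the cohort regression that shows age thinning all
sublayers while axial elongation spares the choriocapillaris.

A thin CLI wraps the same pipeline:

```bash
chorostrat simulate phantom --seed 42 --out demo/
chorostrat segment demo/phantom.tiff demo/annotations.csv \
    --lateral-scale 3.9 --axial-scale 1.95 --out demo/results/
chorostrat pipeline --demo --seed 17 --out demo/cohort/
```

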