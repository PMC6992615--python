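# oculogas

Quantification of intraocular tamponade gas on sagittal MRI-like slice
stacks after vitrectomy.

After pars plana vitrectomy for rhegmatogenous retinal detachment, the
vitreous cavity is filled with an expansile gas bubble (20% SF6) that must
press against the retinal breaks while laser scars mature. Whether a
patient should lie prone or supine depends on *which part of the retina the
bubble actually touches* in each posture — something slit-lamp examination
cannot show with the eyes closed, but MRI can. This package reproduces that
MRI analysis as a tested, closed-loop pipeline for an eight-eye cohort:

- **gas volume** as a percentage of the vitreous cavity, from per-slice
  Otsu segmentation integrated across the stack;
- **four-part retinal gas-contact rates** (superior/inferior ×
  anterior/posterior, split at the equator 13.5 mm and the ora serrata
  7 mm posterior to the surgical limbus), as
  `contact length / part length × 100%`;
- **supraduction angle** of the pupillary axis against the
  gravity-perpendicular line, signed, in both postures;
- **cohort statistics**: mean ± SE summaries and exact small-sample rank
  tests (Wilcoxon signed-rank, Mann–Whitney U, both by full enumeration).

Because no image data are deposited for this kind of study, the package
ships a **synthetic eye phantom** with closed-form ground truth: a
spherical vitreous cavity of radius `R = (AL − 1.6 mm)/2` holding a gas
bubble bounded by a flat meniscus ⊥ gravity. The bubble is a spherical cap
whose height `h` solves `h²(3R − h) = 4 f R³` for fill fraction `f`, which
also yields analytic contact rates per retinal arc — the oracle every
pixel-level measurement is tested against.

## Worked example

Render one phantom eye (axial length 25.4 mm, 60% fill, supine, 9.5°
supraduction), then measure it back:

```python
from oculogas import EyeModel, GasBubble, ImagingParams, render_stack, segment_stack

eye = EyeModel.from_clinical(25.4, posture="supine", supraduction_deg=9.5)
stack, truth = render_stack(eye, GasBubble(0.60), ImagingParams(noise_sd=0.0),
                            "supine", 9.5)
seg = segment_stack(stack)
print(f"measured gas volume: {seg.gas_volume_pct:.1f}% (true 60.0%)")
```

prints

```
measured gas volume: 60.9% (true 60.0%)
```

The full cohort analysis is a sequence of thin drivers over the library:

```sh
python analysis/01_reproduce_tables.py      # summaries + tests of the per-case tables
python analysis/02_render_phantom_cohort.py # 16 stacks under scratch/stacks/
python analysis/03_closed_loop_measurement.py
python analysis/04_posture_comparison.py
```

`01` recomputes every printed summary (gas volume 60.1% prone / 60.0%
supine, supraduction 16.1° / 1.8°, BCVA 0.82 → 0.11 logMAR, age 59.8 y,
axial length 25.4 mm, 2.8 breaks) and the prone-vs-supine gas comparison
(Mann–Whitney exact p = 1.0). `03` reports the closed loop on the 16
case-driven phantoms: gas volume recovered within 0.82 points, supraduction
angle to machine precision, contact rates within 2.83 points of the
analytic oracle. `04` reproduces the posture effect: posterior retina is
covered prone (100.0 / 91.3% vs 7.1 / 9.5% supine), anterior retina supine
(84.1 / 89.2% vs 81.7 / 10.5% prone).

There is also a CLI (`oculogas generate / segment / cohort / stats`) for
running single stages from a shell.

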