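# Methods

## The geometric model

The vitreous cavity of a post-vitrectomy eye is modelled as a perfect
sphere. Its radius is derived from the clinically measured axial length as
`R = (AL − d)/2` with a default anterior offset `d = 1.6 mm` accounting for
the cornea and anterior chamber, which are not part of the cavity; the
offset is configurable. Sphericity is an idealization — real globes,
especially myopic ones, deviate from it — but it is what makes every
quantity below available in closed form, so that the pixel pipeline can be
validated against exact answers.

A single tamponade gas bubble floats against gravity and is bounded below
by a flat meniscus perpendicular to the gravity vector. Surface tension is
neglected: for a bubble of several millilitres the capillary length of the
gas–fluid interface (~2 mm) is small against the bubble radius, and the
interface in clinical images is visibly flat. The bubble is therefore a
spherical cap of height `h`, linked to the gas volume fraction `f`
(gas volume / cavity volume) by

    V_cap = π h² (3R − h) / 3,   i.e.   h²(3R − h) = 4 f R³ ,

which is strictly monotone in `h` on `[0, 2R]` and inverted by Brent's
method to |residual| < 1e−13 mm (round-trip `f → h → f` holds to 1e−9, the
tolerance asserted in the tests).

### Retinal partition

Measurements are made on the mid-sagittal slice, as in manual practice: a
single slice per eye, not a 3D surface-coverage computation. On that
slice's great circle the retina is split into four arcs per eye:

- the **surgical limbus** is the intersection of the line perpendicular to
  the pupillary axis through the anterior-chamber angle with the ocular
  surface. In the model the angle sits on the cavity circle at arc
  distance 6.0 mm from the corneal pole (half a ~11.7 mm white-to-white
  chord mapped to a 12 mm globe); configurable.
- the **ora serrata** and **equator** lie 7.0 mm and 13.5 mm posterior to
  the limbus, measured as *arc length along the globe surface* (not chord
  length) — consistent with how mm-from-limbus distances are used
  surgically. Meridional variation of the ora is ignored.
- per side of the pupillary axis (superior / inferior — anchored to the
  eye, not to the ground), the **posterior** part runs from the posterior
  pole (contour ∩ pupillary axis) to the equator and the **anterior** part
  from the equator to the ora serrata. Retina anterior to the ora is
  excluded. With the defaults the anterior part is exactly 6.5 mm of arc.

An arc point is in contact with gas when it lies on the gas side of the
meniscus plane; points exactly on the plane count as contact (a
measure-zero convention fixed for determinism). Contact arcs are circle ∩
half-plane intersections, so the analytic rates are exact; the test suite
confirms them against dense (10⁵-point) arc sampling to 0.1 percentage
points on randomized configurations.

### Postures and the supraduction angle

World frame: x = head-superior, y = mediolateral, z = up. Gravity is −z.
Supine, the anterior direction points up at 0°; prone, it points down;
positive supraduction rotates the cornea toward head-superior in both
postures, so the gravity-perpendicular reference flips with posture — this
matches a convention in which prone angles are all positive while supine
angles may be negative (infraduction). The printed angles are applied as a
net rotation of the globe; how much of the real rotation is eye-in-head
versus head tilt is not modelled.

## The phantom

The renderer emulates a T2-weighted sagittal acquisition: FOV 140 mm,
matrix 320×320 (0.4375 mm pixels), 3.0 mm slices with a 0.5 mm gap, stacked
along the mediolateral axis (11 slices by default, enough to cover any
clinical globe). Nominal intensities: fluid 200, gas and background air
20, scleral rim 60, with a schematic anterior segment (dark iris/IOL band
and a small bright anterior chamber drawn anterior to the cavity sphere,
leaving the rim intact). Pixels are supersampled 4×4 for partial-volume
realism, Gaussian noise (default SD 10) is added per pixel, and a Gaussian
blur (default σ = 1 px) stands in for the point-spread of a motion-robust
reconstruction — no k-space physics is simulated. Rendering is
deterministic under a fixed seed, and every stack carries a ground-truth
sidecar (per-slice cavity/gas masks, landmark coordinates, true fill and
angle).

Integrating the ground-truth masks across slices reproduces the fill
fraction to ~1.1 percentage points at worst over the clinical fill range;
the residual is midpoint sampling of the spherical cap at 3.5 mm slice
spacing, not a mask artifact.

What the phantom does **not** emulate — and hence what passing tests do
not show about real data: non-spherical globes (staphyloma), gas breakup
into multiple bubbles, vitreous hemorrhage, retinal detachment itself,
partial-volume effects of an oblique (non-mid-sagittal) slice through the
eye, intensity inhomogeneity, and motion/ghosting artifacts. One visible
consequence: with ~60% fill and ~16° prone supraduction, the spherical
model predicts high superior-anterior contact in the prone posture,
whereas the study cohort showed much lower values there — real anterior
anatomy shields that region in ways a sphere cannot. The *direction* of
every posture effect (anterior coverage better supine, posterior better
prone) is reproduced and is the quantity asserted.

## The measurement pipeline

1. **Threshold.** Otsu's method on a 256-bin histogram restricted to a
   bounding box around the eye (background air would otherwise dominate
   the class statistics). Ties in the between-class variance break toward
   the lowest threshold. The implementation is tested against exhaustive
   variance search and against scikit-image.
2. **Cavity circle.** Both the gas bubble and the scleral wall are dark,
   so the cavity cannot be delineated from the bright class alone. The
   wall itself is isolated instead: among sub-threshold pixels, those
   elevated above the background level (median + 4·MAD, floored at 8
   intensity units) form the scleral rim; its enclosed interior is the
   cavity. A circle is fitted to interior-boundary points near the wall
   (the blurred meniscus line also falls in the rim's intensity class and
   would otherwise contaminate the fit), then refined to sub-pixel
   precision by locating the radial intensity-gradient extremum along 720
   rays. Rays looking out from bright fluid anchor the radius; gas-side
   rays see the rim as a narrow bump whose gradient peak sits slightly
   inside the wall, so they enter the fit only through a shared radial
   offset that preserves their constraint on the circle's *center*. A
   fully gas-filled cavity is recognized by an annular bright component
   (the rim itself) and handled the same way.
3. **Areas.** Fluid and gas are the bright/dark classes inside the fitted
   disk — sharing one geometric boundary makes the gas/cavity ratio
   first-order insensitive to radius error. Gas area uses partial-volume
   weighting in the disk interior (blurred intensity is coverage under a
   mass-conserving kernel), which removes the whole-row quantization a
   binary count suffers when the flat interface falls near a pixel-row
   boundary; within 1.5 px of the wall, counting stays binary because
   scleral bleed would corrupt the fractions. Dark components smaller
   than 2 mm² are dropped as edge slivers; multiple kept components are
   all counted with a warning (single-bubble phantoms should have one).
4. **Gas volume percent** is the spacing-weighted ratio of summed areas,
   `100 · Σ gas_k w_k / Σ cavity_k w_k` — the ratio of sums rather than
   the mean of per-slice ratios, because for uniform spacing it equals the
   volumetric ratio. Slices without a measurable cavity are flagged and
   excluded from both sums.
5. **Slice selection** picks the slice whose fitted diameter plus the
   anterior offset is closest to the clinical axial length (ties to the
   lower index; > 2 mm mismatch is an error).
6. **Landmarks and partition** follow the model definitions on the
   measured contour (a dense polygon of the fitted circle; all contour
   operations work on arbitrary closed polylines and are tested on coarse
   polygons against cumulative segment-length oracles). Anterior-chamber
   angle landmarks come from the ground-truth sidecar — automatic angle
   detection from clinical MRI is out of scope. The pupillary axis is the
   perpendicular bisector of the angle–angle chord; the supraduction
   angle is its signed angle to the posture's perpendicular reference.
   Note the limbus construction intersects a chord at a grazing angle with
   the globe, which roughly doubles any circle-fit error at that point.
7. **Contact rates.** Two measurements are provided. The generic one
   probes the gas mask along the inward normal in half-pixel steps up to a
   tolerance (default 1.5 px ≈ 0.66 mm — the segmented fluid film versus
   true apposition is unresolvable at 0.44 mm pixels); the probe is
   deliberately directional, because an isotropic distance would spread
   contact tangentially past the meniscus ends. The pipeline's default
   instead exploits the flatness of the interface: the meniscus height is
   located to sub-pixel precision as the median of per-column vertical
   midpoint crossings inside the cavity, and contact is a side-of-plane
   test on the measured contour. This avoids the probe-depth and
   oblique-edge-blur biases near the meniscus–wall corner and agrees with
   the analytic oracle to < 3 percentage points noise-free (< 6 at noise
   SD 10) across the cohort conditions.

## Statistics

The cohort is eight eyes, so both rank tests are exact by full
enumeration: all 2^m sign assignments for the Wilcoxon signed-rank test
(m ≤ 20; zero differences dropped by default, Pratt's rule behind a flag),
all C(n, n_a) labelings for the Mann–Whitney U test (total n ≤ 20). Tied
absolute values get mid-ranks; two-sided p doubles the smaller tail,
capped at 1 — the convention under which the prone/supine gas comparison
gives exactly p = 1.0 (the rank sums of the two postures happen to be
equal). A tie-corrected, continuity-corrected normal approximation is
reported alongside. Enumeration is verified against independently coded
brute-force oracles and against scipy where scipy offers an exact mode.

For the BCVA change, exact enumeration gives p = 6/256 ≈ 0.023 and the
normal approximation 0.025; a commercial package's signed-rank statistic
with a t-based approximation can print ~0.012 for the same data. The
variants disagree numerically at n = 8 but agree on significance at the
0.05 level; both are always reported rather than asserting one convention.

The prone-vs-supine comparisons of the same eyes are paired data, yet the
study design applies the unpaired Mann–Whitney test; the pipeline
reproduces that choice for fidelity and reports the paired Wilcoxon
alongside, flagged as a methodological note.

Summary rows report mean ± SE (sample SD / √n) rounded half-up at printed
precision: 1 decimal for %, degrees, mm and years; 2 for logMAR.

## Problem sizes and determinism

The analysis scripts and acceptance run render the 16-condition cohort at
the full 320×320 acquisition matrix with 11 slices per stack, noise-free
(the deterministic condition under which the closed-loop tolerances are
defined); noisy recovery (SD 10) is exercised in the test suite on the
same geometry. Per-scenario seeds are derived from the run seed via
SHA-256, so any subset of the cohort reproduces identically; re-running
with the same manifest yields byte-identical CSVs.

## Known limitations

- The spherical cavity and schematic anterior segment make anterior
  contact rates optimistic in prone posture relative to real eyes.
- Landmark placement depends on sidecar angle coordinates; no automatic
  angle detector is provided.
- Contact analysis is 2D on one slice by design; a 3D surface-coverage
  figure would need a different (and unvalidated) acquisition model.
- Gas-volume integration inherits ~±1 point of slice-sampling error at
  3.5 mm spacing; that bound is part of the closed-loop tolerance, not
  removable by better segmentation.
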