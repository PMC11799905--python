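# Methods

This note records the measurement model, the synthetic-image model, the
numerical choices and the known limitations of the package.  Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate conventions

Pixel indices are 0-based and the center of pixel (0, 0) is the origin of
the raw image frame; `x` (crossplane, leaf travel) grows with column index,
`y` (inplane, leaf stacking) with row index.  All distances are mm at the
isocenter plane: detector pixel pitch is scaled by SAD/SDD on read, so at
the standard SDD = SAD = 100 cm geometry detector mm equal isocenter mm.
Deviations are retraction-positive: a positive value means the leaf sits
away from the gap (gap expansion), a negative value means it protrudes into
the gap.  A pair's gap deviation is the sum of its two signed leaf
deviations, checked as an exact identity in the tests.

## Test pattern

The default plan places six 20 mm wide sub-fields at crossplane centers
{−100, −60, −20, +20, +60, +100} mm (40 mm pitch), each leaf pair opened
symmetrically about the sub-field center, delivered step-and-shoot with
480 MU of a nominal 6 MV beam, with a carriage shift flagged after the
third sub-field.  Nominal tips are light-field positions; the
light/radiation discrepancy is carried entirely by the per-bank RFO
parameter at measurement time (default 0.0 mm — measuring RFO is outside
this package's scope, so synthetic work uses a zero or user-supplied value).

Comb geometry: protruding tips at ±120 mm, retracted tips at ±150 mm, the
measurement column at ±130 mm, and the comb field's inner boundary at
±118 mm.  The inner boundary is this package's choice: it leaves an 8 mm
fully shielded strip between the comb and the outermost sub-field edge
(±110 mm), so the outermost edges keep clean local minima.  Two MLC models
ship with vendor-standard layouts: `millennium120` (10×10 mm + 40×5 mm +
10×10 mm per bank) and `hdmlc` (14×5 mm + 32×2.5 mm + 14×5 mm).

## Analysis algorithm

1. **CAX**: field centers of the C90/C270 jaw pair from the midpoint of the
   two 50% crossings on central crossplane/inplane profiles (cubic-spline
   interpolated, Brent-refined); the C90/C270 average cancels jaw asymmetry.
   An inplane-then-crossplane second pass makes the same routine exact for
   circular cone fields.
2. **Sag map**: per-frame cone centers over a ≥8-frame arc, normalized to
   the frame nearest G0 (required within 5°); linear interpolation in
   gantry angle between tabulated points, with wrap-around only when the
   map covers the circle to within a 120° gap; queries outside a partial
   map's span are an error.
3. **Leaf localization**: a vertical sub-pixel profile at each comb column.
   The profile's global inplane shift is first estimated by correlating it
   with an analytic template of the retracted-teeth windows (absorbs CAX
   offset and most of any rotation at that column).  Each tooth is then
   convolved with a box of its own leaf width — a matched filter that turns
   the tooth plateau into a triangle peaking exactly at the leaf center, so
   the extremum is sharp and a symmetric kernel cannot bias it — and the
   extremum is parabola-refined inside a window of ±40% leaf width.
   Windows whose filtered contrast is below 5% of the image's dynamic
   range, or whose extremum lands on the window boundary, are "not
   located"; >20% unlocated leaves is a hard error.  A protruding tooth at
   the very end of a comb has no outer flank and cannot be located on that
   side; such leaves are anchored from the located side plus the rigid
   rotation slope of the fully located leaves.
4. **Trajectories and tips**: the line between a leaf's two comb centers is
   its trajectory.  The beam-frame crossplane coordinate is defined by one
   global direction (median trajectory slope) rather than each leaf's own
   anchors, so anchor noise cannot leak into a leaf's position in
   proportion to its inplane offset; the sampling line still follows the
   leaf's own anchors.  Profiles are averaged over five parallel lines
   spanning ±10% of the leaf width — offsets run along the edge, so a
   straight edge is not biased while the 50% crossing noise drops roughly
   with the root of the averaged pixels.  Per stakitt edge the 50% level is
   `local_min + 0.5 (local_max − local_min)` with the maximum from the
   sub-field's open window (edges inset 4 mm) and the minimum from the
   adjacent shielded window 2–10 mm outside the nominal edge; the crossing
   is searched within ±3 mm of nominal (nearest-to-nominal wins if noise
   produces several, and the event is flagged), Brent-refined to 10⁻⁷ mm on
   the spline model, RFO-corrected, and expressed relative to the
   sag-corrected CAX.  Edges with contrast below 10× the image noise are
   flagged "low contrast"; leaves whose sampled band leaves the panel are
   excluded and logged.
5. **Aggregation**: per-bank and gap means/SDs, and an out-of-tolerance
   table against an action limit of ±0.5 mm at G0 and ±1.0 mm at the other
   cardinal gantry angles (configurable); histograms use 0.05 mm bins over
   ±1 mm.

Interpolation everywhere is the interpolating cubic B-spline of the pixel
grid (exact at pixel centers), evaluated through a prefiltered coefficient
array; profile sampling defaults to 0.01 mm steps in `sample_profile` and
0.02 mm for tip profiles, with every crossing/extremum refined below the
step size, so the sampling step is not a resolution limit.

## Synthetic image model

Each collimated edge is an erf transition `edge(d) = ½(1 + erf(d/s))` with
`s = penumbra_sigma = 1.2 mm` by default (Gaussian σ ≈ 0.85 mm, 80–20%
width ≈ 1.4 mm — an in-air 6 MV EPID penumbra).  A segment's fluence is
`t + (1 − t)·open` with transmission pedestal `t = 1.5%`; the open aperture
is the jaw window minus per-leaf block windows (erf windows partition unity
across shared leaf edges, so adjacent blocks tile exactly).  The integrated
image sums the six stakitt segments and the two comb segments; additive
Gaussian noise (default SD 0.5% of the open-field plateau) is applied once
to the sum and values are clipped at zero.  The panel default is 1024×1024
at 0.39 mm/px.  No scatter kernel, glare or MU-nonlinearity is modeled: the
analysis consumes only 50% crossings and local extrema, for which the erf
edge is sufficient.  Passing closed-loop tests therefore demonstrates the
*algorithm's* geometric fidelity, not robustness to detector-specific
artifacts (ghosting, dead pixels, flood-field residuals), which are assumed
corrected upstream.

True tips are `nominal ± (leaf_error + rfo_true + gravity·backlash/2)` in
the bank's retraction direction.  The gravity factor is the sign of the
projection of gravity on the leaf-travel axis: at G90 bank A retracts and
bank B extends, reversed at G270, zero at G0/G180 — so the G90−G270 bank
mean difference reads back the full backlash.  Rotation-history hysteresis
at G0 (a clockwise-approached G0 behaving like G270) is deliberately not
modeled.  Panel sag follows `dx = a_x sin θ_g`, `dy = a_y (1 − cos θ_g)`,
zero at G0 by construction.

The radiological width modulation gives error-carrying leaves an
x-dependent symmetric shrink (alternate leaves widen) of the blocking
footprint, `d = slope·(x − x_min)/100 mm`, tapered out a few millimetres
behind the defining tip.  The taper is deliberate: the apparent-width
change is a beam-divergence effect at the stepped leaf tip, and without it
the narrowed body would open spurious interleaf leaks along the whole
travel range.  With it, a protruding error leaf's rendered tongue narrows
monotonically along travel and the measured deviation magnitude decays
across the six sub-fields — the package characterizes this sensitivity
loss; it does not correct it.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `penumbra_sigma` | 1.2 | mm (erf scale) | in-air 6 MV EPID edge width |
| `noise_sd` | 0.005 | fraction of open signal | 480 MU integrated images are low-noise |
| `transmission` | 0.015 | fraction | typical MLC leaf transmission; keeps noise clipping negligible |
| `pixel_spacing` | 0.39 | mm/px at iso | generic aS1000/aS1200-class panel |
| tip search window | ±3 | mm | covers the ±1.5 mm max test error plus penumbra without neighbor cross-talk |
| shielded window | 2–10 | mm outside nominal edge | inside the 20 mm inter-stakitt gap |
| action limit | 0.5 (G0), 1.0 (else) | mm | tighter limit practical only where gravity backlash is off-axis |

## Plan file format

Plans serialize to JSON with fields `mlc` (`name`, `leaf_widths`),
`stakitt_centers`, `stakitt_width`, `nominal_tips`
(`[stakitt][bank][leaf]`, bank 0 = A), comb geometry
(`comb_protrude_tip`, `comb_retract_tip`, `comb_column`,
`comb_inner_bound`, `comb_protrude_parity`), `carriage_shift_after`, `mu`,
`energy` and `jaw_x`.  Missing required fields raise a named error;
non-standard but analyzable plans (e.g., five stakitts) load with a
validation warning.

## Problem sizes and seeds

The test suite validates most behavior on a compact geometry (16 leaf
pairs of 5 mm on a 512² panel) that exercises identical code paths in
under a second per image; the acceptance tests and `scripts/acceptance.py`
use the full clinical geometry (Millennium120, 1024² panel), five-run
repeatability and consistency experiments, eight sensitivity magnitudes
(±0.1, ±0.5, ±1.0, ±1.5 mm on five non-adjacent inner leaves; gap errors as
half-magnitude shifts of both leaves of five adjacent pairs), and a
24-frame cone arc for the backlash use case.  Sensitivity statistics pool
all errored leaf × stakitt samples.  Every stochastic routine takes an
explicit seed; the same seed reproduces images bit for bit.

## Known limitations

* RFO is a configuration scalar per bank, not measured in-package.
* The simulator's G0 backlash term is exactly zero; real linacs show
  rotation-direction hysteresis at G0.
* DICOM RTIMAGE export quantizes pixels to 16 bits (the `.npy` + JSON
  sidecar dialect is lossless); DICOM RTPLAN authoring and TPS import are
  out of scope.
* The radiological-narrowing feature is qualitative: it reproduces the
  direction and shape of the sensitivity loss for narrow leaves, not any
  particular machine's magnitude.
* Panel non-repositioning between CAX and stakitt acquisition is enforced
  only by convention (warning on metadata mismatch), as the package never
  controls the machine.
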