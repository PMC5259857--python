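# Methods

## Scope and model

cephkit implements headless 2-D cephalometric analysis: given the pixel
coordinates of 11 named landmarks on a lateral cephalogram (Nasion, Sella,
Porion, Orbitale, Articulare, Gonion, Menton, ANS, PNS, points A and B),
it evaluates 12 linear parameters in millimetres and 6 angular parameters
in degrees. Landmark *identification* is deliberately out of scope — the
dominant error source in automated cephalometry is landmark detection, so
coordinates arrive from a file and the package owns everything downstream:
calibration, geometry, reporting and method-comparison statistics.

### Geometry

Distances are plain Euclidean lengths in pixel space. Angles are computed
from direction vectors using `atan2(|cross|, dot)` rather than the
slope-based arctangent `atan((m1 − m2)/(1 + m1·m2))`: the two agree
everywhere the latter is defined, but the slope form is singular for
vertical lines (undefined slope) and perpendicular pairs (zero
denominator), while the direction-vector form is exact there. Two angle
conventions are needed and tracked explicitly on `AngleValue`:

* **vertex-ray** angles in [0°, 180°] — SNA and SNB at Nasion, the saddle
  angle NSAr at Sella. Clinical saddle angles are ≈ 120°, unreachable
  from an undirected line-pair angle, which is why vertex angles exist as
  a separate operation.
* **line-pair** angles in [0°, 90°] — FMA (Frankfort horizontal Po–Or vs
  mandibular plane Go–Me) and PP-MP (palatal plane ANS–PNS vs mandibular
  plane), which clinically are plane intersections without an assigned
  direction.
* ANB is the **signed difference** SNA − SNB, so a retrognathic profile
  yields a negative value. Unsigned ANB would be indistinguishable for
  Class II and Class III patterns, so the signed convention is kept.

All angle magnitudes are invariant under the y-axis flip between image
coordinates (y down) and mathematical coordinates (y up); the package
fixes image convention (origin top-left, x right, y down, 0-based,
continuous).

### Calibration

Two routes map pixels to millimetres:

* **ppi mode** — an effective pixel density; for a digitised film viewed
  at a known scale it is the ratio of image to screen linear pixel counts
  (a unitless display scale factor used as the divisor pixels → inches),
  then inches × 25.4 → mm. The resolution ratio is dimensionally loose,
  so this mode is best treated as "I know my effective PPI".
* **known-distance mode** — a reference object of known physical length
  measured in pixels on the same image; `mm = px · known_mm / known_px`.
  This is the clinically standard, assumption-free route and the
  recommended one.

Both are exactly linear, agree when `known_mm/known_px = 25.4/ppi`, and
are exposed through one `CalibrationSpec`. Final unit is always mm;
angles are scale-invariant and need no calibration. Radiographic
magnification (focus–film geometry) is *not* modelled.

### Enhancement

Two filters on [0, 1] float grayscale arrays: Gaussian smoothing
(normalized kernel, reflective boundaries, `sigma = 0` is the identity)
and unsharp masking `clamp(img + amount · (img − blur(img, sigma)))`.
Defaults `sigma = 2 px`, `amount = 1.0` are conventional mild-enhancement
values; since landmarks are supplied as coordinates, enhancement is
cosmetic and no default can influence a measurement. 8/16-bit rasters
are normalised to [0, 1] on read and written back at their input depth.

### Agreement statistics

`PairedMeasurementTable` holds a complete (parameter × case) grid of
automatic and manual values. Per parameter: per-arm mean and sample SD
(n − 1), and a paired two-tailed t-test, `t = mean(d)/(sd(d)/√n)`,
df = n − 1 — paired because both methods measure the same cases.
Degenerate inputs are handled by convention: identical arms give
t = 0, p = 1; a constant nonzero difference has zero variance and is
flagged degenerate with p = 0. Study-level outputs are the maximum
absolute error split by linear/angular kind and an accuracy percentage
defined as **mean relative absolute agreement**,
`100 · (1 − mean |auto − manual| / |manual|)`, zero-valued manual cells
excluded; the definition string travels with every summary because
"accuracy" has no canonical formula in this literature. No
multiple-testing correction is applied by default (per-parameter
inference mirrors routine clinical reporting); Bonferroni is available
behind a flag.

## Synthetic studies

Real cephalograms are patient data, so the generator stands in for them.

* **Template.** A fixed 11-landmark configuration on a 1024 × 1024
  canvas, hand-constructed once by rotating rays to typical adult
  angular values (SNA 90.7°, SNB 86.6°, ANB 4.1°, FMA 33.9°, PP-MP
  33.3°, NSAr 112.8°) and frozen in source (`TEMPLATE_POINTS`); a test
  asserts each derived angle stays within ±3° of those references. At
  the default calibration (127 PPI = 0.2 mm/px) S–N ≈ 69.7 mm and
  N–Me ≈ 106.6 mm — realistic adult dimensions.
* **Placement noise.** Each case perturbs every landmark with isotropic
  Gaussian offsets, default SD 1.5 px. Isotropy is the simplest model of
  manual pointing error; real per-landmark anisotropy (e.g. Porion's
  edge ambiguity) is not modelled.
* **Manual arm.** True values come from `measure_all` on the perturbed
  landmarks; the simulated manual reading adds Gaussian noise — default
  SD 0.5 mm for distances and 1.0° for angles, the magnitude usually
  quoted as acceptable inter-method variation in cephalometry — plus an
  optional per-parameter bias for power/recovery experiments.
* **Defaults.** 30 cases (the typical size of manual-vs-digital
  agreement studies), seed 42, everything a pure function of the config
  and seed.
* **Rendering.** `render_radiograph` produces a deterministic
  radiograph-*like* image (intensity ramp, blurred ridges along the 12
  measured segments, bright landmark blobs, additive noise) purely as an
  enhancement-filter fixture. It is not anatomically realistic and no
  conclusion about detectability on real films follows from it.

Because the manual arm is generated by adding independent Gaussian noise
to truth, passing tests demonstrate statistical calibration of the
pipeline (exact type-I error, unbiased recovery), not the behaviour of
human examiners, whose errors are neither independent across parameters
nor homoscedastic.

## Numerical choices

* Angle formulas use `atan2`; perpendicular and vertical configurations
  are exact, and oracle agreement is asserted to 1e−9 degrees.
* Landmark CSV/JSON writers serialise coordinates with `repr`, so a
  write/read round trip is bit-exact and the simulate → measure →
  compare → report pipeline is byte-deterministic given a fixed seed and
  frozen timestamp (reports default to an epoch timestamp; pass a real
  one explicitly when provenance matters more than reproducibility).
* Problem sizes in the test suite and acceptance script (30-case
  studies; 112 × 18 = 2016 null parameters for the type-I check; n = 500
  for bias recovery; 32 × 32 fixtures for the dense convolution oracle)
  were chosen so each check has comfortable statistical resolution while
  the whole suite runs in seconds.
* The type-I band [0.03, 0.07] at α = 0.05 over ≥ 2000 parameters is a
  ±4 SD binomial envelope; the differences fed to the t-test are exactly
  i.i.d. Gaussian under the null, so the test size is exact by
  construction and the band tests the plumbing, not the theory.

## Known limitations

* No radiographic magnification correction or anisotropic pixel support.
* No normative-range classification of measurements (no norms shipped).
* The 11-landmark, 18-parameter registry is fixed; extended analyses
  (soft tissue, Ricketts/McNamara batteries) are out of scope.
* The accuracy percentage is sensitive to near-zero manual values (small
  ANB inflates relative error); it is reported with its definition and
  should be read alongside the absolute max-error figures.
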