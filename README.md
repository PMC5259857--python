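# cephkit

Headless 2-D cephalometric measurement for orthodontic analysis.

Cephalometry quantifies craniofacial form from a standardized side-view
skull radiograph (lateral cephalogram): named anatomical landmarks are
identified on the image, and distances and angles between them classify
the skeletal pattern and guide treatment. cephkit is the *downstream*
half of that workflow, for people who already have landmark coordinates
(from a tracing tool, a detector, or a digitizer) and need trustworthy
numbers: it converts an 11-landmark coordinate file into the standard 12
linear and 6 angular parameters with pixel-to-millimetre calibration,
enhances radiographs for viewing, generates offline HTML case reports,
and runs the paired statistics used to compare an automatic method
against manual tracing. A synthetic-study generator with known ground
truth makes the whole pipeline testable without patient data.

## The model

Landmarks `N, S, Po, Or, Ar, Go, Me, ANS, PNS, A, B` are points
(x, y) in image pixels. Linear parameters are Euclidean distances

    d = sqrt((x2 − x1)² + (y2 − y1)²)

over the 12 segments Po–Or, ANS–PNS, Me–Go, S–N, N–A, N–B, N–Me, N–ANS,
ANS–Me, S–Go, S–Ar, Ar–Go, converted to mm either by an effective pixel
density (px / PPI → inches, × 25.4) or by a known reference distance.
Angular parameters use direction vectors, θ = atan2(|u × v|, u · v),
which extends the slope form tan θ = (m1 − m2)/(1 + m1 m2) continuously
through its vertical and perpendicular singularities:

* **SNA**, **SNB** — vertex angles at Nasion (rays to S and to A / B);
  **ANB = SNA − SNB** (signed) classifies the sagittal jaw relationship.
* **NSAr** — saddle angle at Sella between rays to N and Ar.
* **FMA** — Frankfort horizontal (Po–Or) vs mandibular plane (Go–Me);
  **PP-MP** — palatal plane (ANS–PNS) vs mandibular plane.

Method comparison uses a per-parameter paired two-tailed t-test
t = mean(d)/(sd(d)/√n), df = n − 1, maximum absolute errors by kind, and
an accuracy percentage defined (and always labelled) as
100 · (1 − mean |auto − manual| / |manual|).

## Worked example

```
$ python examples/measure_case.py
case 'patient.landmarks': 11 landmarks
  Po-Or       74.02 mm
  ANS-PNS     56.00 mm
  Me-Go       84.01 mm
  S-N         69.72 mm
  ...
  SNA         90.70 deg
  SNB         86.60 deg
  ANB          4.10 deg
  FMA         33.90 deg
  PP-MP       33.30 deg
  NSAr       112.79 deg
```

S–N ≈ 70 mm is a normal adult anterior cranial base; ANB ≈ 4° sits at
the Class I/II boundary; FMA ≈ 34° indicates a slightly vertical growth
pattern. Running a full simulated 30-case agreement study:

```
$ python examples/simulate_and_compare.py
...
cases: 30, parameters flagged at alpha=0.05: 0
max |auto - manual|: 1.82 mm (linear), 2.81 deg (angular)
accuracy: 97.8%  (100 * (1 - mean over cells of |auto - manual| / |manual|); ...)
```

With no injected bias, flags at α = 0.05 are false positives and appear
for roughly 1 parameter in 20 across repeated studies.

The same operations are available from a shell:

```
cephkit simulate --n 30 --seed 42 --out study/
cephkit measure --landmarks study/case001.landmarks.json --ppi 127 \
        --out m.csv --report report.html
cephkit compare --paired study/paired.csv --out comparison.csv
cephkit enhance film.png film_sharp.png --filter unsharp --sigma 2 --amount 1
```

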