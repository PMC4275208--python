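# vesselmotion

Quantification of respiration-induced abdominal-artery motion in
monitor-phase (bolus-tracking) hepatic CT.

During a multiphase liver CT examination, a single axial slice through the
abdominal aorta is imaged repeatedly (every 3 s here) while iodinated
contrast arrives; the diagnostic scan is triggered once the mean
enhancement inside a vessel region of interest (ROI) reaches a threshold
(130 HU).  Free breathing moves the artery between frames, so a static ROI
can drift off the vessel and the enhancement measurement — and hence the
trigger — can fail.  `vesselmotion` quantifies that motion two ways and
validates one against the other:

1. **Delineation tracking** — from a per-frame binary delineation of the
   artery, the section barycenter
   `C(a, b) = (Σᵢ xᵢ / n, Σᵢ yᵢ / n)` is computed and the frame-to-frame
   displacement is `Δv = C₂ − C₁ = (a₂ − a₁, b₂ − b₁)`.
2. **Dense optical flow** — the Horn–Schunck motion vector field between
   consecutive frames, iterating
   `v⁽ⁿ⁺¹⁾ = v̄⁽ⁿ⁾ − ∇f (∇f·v̄⁽ⁿ⁾ + ∂f/∂t) / (α² + ‖∇f‖²)`
   with smoothness weight α = 5 and 100 iterations, decomposed into
   anterior–posterior (AP) and lateral (LAT) components, reduced over the
   ROI, and converted to mm (0.82 mm/pixel) and mm/s (3 s interscan time).

The two displacement series are compared with the standard
method-comparison toolkit — Pearson correlation, Passing–Bablok regression
(shifted median of pairwise slopes), and Bland–Altman limits of agreement
(bias ± 1.96 SD of differences) — via a statsmodels-style
`MethodComparison` model whose `fit()` returns an `AgreementResults`
object.  A synthetic-phantom module generates monitor-phase series (moving,
contrast-enhancing vessel with exact ground truth) so the whole pipeline is
testable without patient data, and a bolus-tracking module demonstrates how
optical-flow motion correction rescues a trigger that a static ROI misses.

Intended users: researchers in dynamic CT / medical image analysis who need
a reproducible desk-scale testbed for respiratory-motion estimation and
bolus-trigger robustness.

## Worked example

```python
import pandas as pd
from vesselmotion import default_suite
from vesselmotion.pipeline import run_motion, run_agreement

# a vessel drifting 1 px/frame; truth masks play the role of delineations
series, truth = default_suite(0)["slow_drift"]
table = run_motion(series, truth.masks)
print(table[["frame_pair", "manual_movement_mm", "ofm_movement_mm"]].round(3))

pooled = pd.concat(
    [run_motion(s, t.masks) for s, t in default_suite(0).values()],
    ignore_index=True,
)
print(run_agreement(pooled).summary())
```

The per-pair table shows the delineation-based movement at exactly
0.82 mm/pair (one pixel at 0.82 mm/pixel) with the flow-based estimate at
0.36–0.42 mm — the single-resolution solver systematically underestimates
motion of a homogeneous vessel lumen (see `docs/methods.md`).  The pooled
comparison across all seven phantom fixtures (49 frame pairs) prints

```
Method comparison (x = reference, y = test)
====================================================
n pairs                                           49
Pearson r                                     0.9383
p-value                                     2.61e-23
Passing-Bablok slope                          0.4333
  slope 95% CI                      [0.3991, 0.4676]
Passing-Bablok intercept                      0.0065
  intercept 95% CI                 [-0.0010, 0.0089]
Bland-Altman bias                            -0.8585
  limits of agreement              [-2.7468, 1.0298]
====================================================
```

i.e. the two methods rank motion nearly identically (r = 0.94) while the
flow magnitudes run low (slope < 1, negative bias), a proportional
underestimation whose origin and implications are analysed in the methods
note.

The same stages are available from a shell:

```sh
vesselmotion simulate --out phantoms            # write the fixture suite
vesselmotion motion --series phantoms/slow_drift/frames \
                    --masks phantoms/slow_drift/masks --out run1
vesselmotion agree  --table run1/motion_table.csv --out run1
vesselmotion bolus  --series phantoms/slow_drift/frames \
                    --roi phantoms/slow_drift/masks/mask_0000.png --out run1
```

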