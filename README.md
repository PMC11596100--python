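# lvtdm

Postprocessing enhancement of echocardiography cine loops for **left
ventricular (LV) thrombus detection**, plus the statistical toolkit used to
validate such a method against contrast echocardiography, and a synthetic
speckle phantom so the whole pipeline runs without clinical data.

## The problem

A thrombus forming at an akinetic LV apex (typically after anterior
myocardial infarction) is easy to miss on transthoracic echo when apical
image quality is poor; the usual fallback is injecting an ultrasound contrast
agent (e.g. SonoVue), which adds time, cost and risk for patients with renal
dysfunction or allergy. A thrombus is a *mid-tone* structure — brighter than
the dark blood pool, darker than myocardium — so a postprocessing step that
expands the mid-tone range inside the apical region of interest can make an
existing recording diagnostic without contrast.

## The method

Frames are converted from 8-bit integers to normalized intensities
`I ∈ [0, 1]` and passed through a parameterized Reinhard tone-mapping
operator applied inside the apical region of interest (ROI):

```
I_out = I_in / (I_in + A),   A > 0
```

`A` generalizes the constant 1 of the classic Reinhard curve. The slope at
the origin is `1/A`: **A < 1 steepens the low/mid-tone response (higher
contrast), A > 1 flattens it**; `A = 1` is the default and each loop may be
tuned empirically. The curve maps `[0, 1]` onto `[0, 1/(1+A)]`, so before
8-bit display quantization the output is (by default) rescaled by `(1+A)` to
restore full range. Outside the ROI, mild Gaussian smoothing is applied and
the two branches are blended with a feathered mask:

```
out = w · T(frame) + (1 − w) · S(frame)
```

The evaluation module reproduces the complete validation analysis for a
rating study of *n* patients × *k* raters with calls in
{positive, negative, nondiagnostic}: confusion counts, sensitivity,
specificity, PPV, NPV and accuracy in exact rational arithmetic, the
single-operating-point ROC area `AUC = (Se + Sp)/2`, and the tie-corrected
Friedman test (mid-ranks per patient, correction divisor
`C = 1 − Σ(t³−t) / (n·k·(k²−1))` — essential for binary ratings, which are
heavily tied).

## Worked example

```python
import numpy as np
from lvtdm import (PhantomSpec, generate_phantom, ProcessingConfig, ToneMapParams,
                   apply_lvtdm_video, normalize_intensity, build_roi_mask, measure_cnr)

loop, truth = generate_phantom(PhantomSpec(seed=0))      # 16-frame beating phantom
config = ProcessingConfig(tonemap=ToneMapParams(A=0.6))  # A < 1: boost mid-tones
roi = build_roi_mask(config.roi, loop.height, loop.width) >= 1.0
thr, cav = truth["thrombus"] & roi, truth["cavity"] & roi

before = measure_cnr(loop, thr, cav)
processed = apply_lvtdm_video([normalize_intensity(f) for f in loop.frames], config)
after = measure_cnr(processed, thr, cav)
print(f"CNR before {before:.2f}, after {after:.2f}")
```

```
CNR before 1.39, after 2.06
```

The thrombus-vs-cavity contrast-to-noise ratio
(`|μ_thrombus − μ_cavity| / σ_cavity`) inside the apical ROI rises because
the curve with `A = 0.6` expands the cavity→thrombus mid-tone separation
while compressing the bright wall clutter that dominates cavity noise over a
beating loop.

The same pipeline from the shell:

```bash
lvtdm simulate phantom_out --seed 0 --format dicom      # synthetic loop + truth masks
lvtdm process phantom_out/phantom.dcm enhanced.dcm --A 0.6
lvtdm evaluate ratings.csv --reference contrast --out report.json
```

`lvtdm evaluate` on the packaged 29-patient study fixture reports, for
observer 1 vs contrast echo: sensitivity 100%, specificity 83%, PPV 79%,
NPV 100%, accuracy 90%, AUC 0.917 (observer 2: 0.889), and a Friedman
chi-square of 4.333 (df 2, p = 0.115) across observer 1 / observer 2 /
contrast with mean ranks 2.03 / 2.09 / 1.88.

## Scope notes

The clinical triage algorithm proposed alongside the method (enhance first;
contrast echo when enhancement is positive or still non-diagnostic; cardiac
MRI for confirmation) is documentation only — this package implements the
image processing and the statistics, not clinical decision logic. Automatic
apex/ROI detection, Doppler frames, and physically accurate acoustic
simulation are out of scope; see `docs/methods.md` for the full model
description and limitations.
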