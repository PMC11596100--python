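# Methods

This note documents the models and procedures implemented in `lvtdm`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic phantom does and does not establish about real data.

## 1. Tone curve

The enhancement is the global monotone transform

    I_out = I_in / (I_in + A),   A > 0,

applied to intensities normalized to [0, 1] (8-bit values divided by 255).
Properties relied on throughout the package:

* strictly increasing in `I_in`; strictly decreasing in `A` for fixed
  `I_in > 0`;
* bounded by `1/(1+A)`;
* slope `1/A` at the origin, so `A < 1` amplifies low/mid intensities
  relative to identity and `A ≥ 1` attenuates them;
* concave everywhere, so highlights are always compressed relative to
  mid-tones. "Mid-tone expansion" is emergent from this curve shape; there
  is no separate band-pass step.

**Display rescale.** The raw curve maps full-range input onto
`[0, 1/(1+A)]`, which would visibly darken 8-bit output (maximum 128 of 255
at `A = 1`). The pipeline therefore multiplies by `(1+A)` before the single
final quantization, so the attainable maximum hits 255 while the curve shape
is preserved. The rescale is a flag (`ToneMapParams.rescale_display`,
default on); quantization is round-half-away-from-zero then clamp.

`A` is global per video (default 1.0, tuned per loop by the operator); no
automatic per-image optimization is attempted because no objective function
is defined for it.

## 2. Region of interest and blending

The apical ROI is user-supplied geometry (polygon, ellipse or rectangle) in
normalized coordinates; the default is the upper 40 % of the frame, where an
apical view displays the apex. There is no automatic apex detection.

A hard ROI edge would leave a visible seam, so the binary membership mask is
feathered by a linear ramp of the Euclidean distance to the boundary
(default width 8 px, ramping inward; 0 gives a hard mask). Each frame is
processed as

    out = w · T(frame) + (1 − w) · S(frame),  clamped to [0, 1],

with `T` the tone curve including its `(1+A)` rescale in normalized units
and `S` Gaussian smoothing (default σ = 1 px; σ = 0 disables it). The
smoothing outside the ROI is implemented as an explicit, configurable
uniform Gaussian — the simplest reading of "minor smoothing of details"
outside the region — not an intensity-adaptive kernel. All arithmetic is in
floating point; quantization happens once at the end of the pipeline.

The operation is deliberately **not idempotent**: applying it twice
compounds the curve, and the test suite pins the inequality. With σ = 0,
pixels with `w = 0` are bit-identical to the input (locality).

## 3. Video I/O

Loops are held as `(n_frames, height, width)` uint8 arrays. DICOM
(ultrasound multi-frame SOP class, uncompressed/RLE transfer syntaxes) and
numbered PNG sequences round-trip bit-exactly and are the formats the
guarantees are stated for; AVI/MP4 go through imageio's optional ffmpeg
backend and are documented lossy. MONOCHROME1 input is inverted to the
MONOCHROME2 convention; color planes are reduced to Rec. 601 luminance.
Written DICOMs derive their SOP instance UID from the pixel content, so
identical loops serialize byte-identically (end-to-end determinism). No
automatic cropping of burned-in overlays is attempted — the ROI mechanism
already restricts processing spatially. Vendor-proprietary codecs, DICOM
networking and de-identification are out of scope.

## 4. Rater evaluation

Ratings are n patients × k raters with calls in {positive, negative,
nondiagnostic}. Nondiagnostic entries are excluded pairwise for confusion
counts and listwise for the Friedman test (the packaged study fixture
contains none). Metrics are exact rationals (`fractions.Fraction`);
reporting rounds to whole percentages and AUC to 3 decimals, matching the
precision of the validation study. Ratios with zero denominators are
returned as undefined (`None`), never silently zeroed. A single operating
point yields the two-segment ROC through (0,0), (1−Sp, Se), (1,1), with
trapezoidal area `(Se + Sp)/2`.

**Friedman test.** Within each patient row the k ratings receive mid-ranks
(ties share the average rank); with column rank sums `Rj`,

    chi2_u = 12 Σ Rj² / (n k (k+1)) − 3 n (k+1),
    C      = 1 − Σ_rows Σ_tie-groups (t³ − t) / (n k (k² − 1)),
    chi2   = chi2_u / C,   df = k − 1,

with the p-value from the chi-square upper tail (for df = 2 this is
`exp(−x/2)`). Binary ratings are almost entirely ties, so `C` is far below
1 and the correction dominates the statistic. If every row is fully tied,
`C = 0`: the table carries no information and the result is flagged
degenerate (statistic 0, p 1) instead of dividing by zero. The
implementation is validated exhaustively against a brute-force oracle on all
3-category tables with n ≤ 3, k = 3, on random larger tables, and against
`scipy.stats.friedmanchisquare`.

**Study-table reconstruction.** The 29-patient validation table is
determined by its marginals — observer 1: 14 positives, observer 2: 15,
contrast reference: 11, no false negatives for either observer — up to one
free parameter: the number `a` of reference-negative patients overcalled by
*both* observers. Column rank sums (hence mean ranks 2.03 / 2.09 / 1.88)
depend only on the marginals; the tie structure, and therefore the corrected
statistic, depends on `a`. Brute force over the admissible `a ∈ {0..3}`
gives statistics 3.714 / 4.333 / 5.200 / 6.500, so `a = 1` is the unique
value consistent with the reported 4.333 and is the packaged fixture.
The three pairwise comparison p-values printed alongside the validation
study's Friedman result are not computed here: no standard pairwise
procedure (McNemar, two-proportion chi-square, rank post-hoc) reproduces
them, so their generating test is treated as unidentified.

## 5. Synthetic phantom

The phantom emulates the *appearance* of an apical-view B-mode loop, not its
acoustics: a fan-shaped sector (vertex top center, 75° default, black
outside), a dark elliptical cavity (mean reflectivity 0.05) inside a bright
myocardial band (0.75, wall thickness 0.09 of the unit square), an optional
mid-tone thrombus ellipse at the cavity apex (0.35; ordering
cavity < thrombus < myocardium is enforced — it is the premise of mid-tone
enhancement), and a low-reflectivity far-field background (0.12). Speckle is
fully developed multiplicative noise: the squared magnitude of a
unit-variance circular Gaussian field (exponential, mean 1), spatially
correlated by a 3×3 uniform point-spread kernel, with `speckle_scale`
scaling the fluctuation about the unit mean. Frames are quantized to 8 bits
exactly as an exported file would be. Walls move sinusoidally over the cycle
(default peak displacement 1.5 % of image height, 16 frames at 30 fps) —
enough to make a loop behave like a beating heart; it is not a mechanical
model. Identical seeds give bit-identical loops. Ground-truth masks are
defined at the zero-displacement phase, as a reader would trace a region
once per loop.

**What the CNR experiment shows — and a caveat worth stating.** Thrombus
conspicuity is quantified as `CNR = |μ_thrombus − μ_cavity| / σ_cavity`,
measured inside the apical ROI over all frames. Because the tone curve is
concave, its local slope at the dark cavity level always exceeds the
cavity→thrombus secant slope; on a *motionless* phantom with clean region
masks, purely multiplicative cavity noise is therefore amplified more than
the mid-tone separation expands, and this CNR strictly *decreases*. On a
beating loop the picture changes: a fixed cavity region intermittently
samples the bright moving endocardium, so cavity-sample noise is dominated
by highlight clutter, which the curve compresses (its secant over the full
cavity→myocardium span is much shallower than over the cavity→thrombus
span). The measured CNR then rises robustly (≈1.4–1.5× at `A = 0.6`,
10/10 default seeds). Passing this experiment therefore demonstrates the
enhancement mechanism under realistic cine-loop measurement conditions —
mid-tone expansion plus highlight compression — not a universal inequality
for static images; and the phantom's simplifications (no depth-dependent
resolution, no reverberation or sidelobe clutter, texture-only speckle) mean
the result is mechanistic evidence, not clinical performance.

## 6. Numerical and interface choices

* Coordinates: 0-based `(row, col)` internally; normalized `(x, y)` with
  origin top-left in configs; rasterization at pixel centers.
* Config files are YAML or JSON with keys `tonemap.A`,
  `tonemap.rescale_display`, `roi.shape`, `roi.coords`, `roi.feather_px`,
  `smoothing.sigma_px`.
* CLI exit codes: 0 success, 1 usage error, 2 data error; every run writes
  its effective parameters to a JSON run-log for provenance.
* Degenerate inputs fail loudly with a named cause (empty loops, dimension
  drift naming the frame index, zero-area ROIs warn and yield empty masks,
  constant noise regions yield NaN CNR with a warning).
* Problem sizes in the test suite (256² phantoms, 16 frames, 10 seeds;
  exhaustive Friedman checks at n ≤ 3) were chosen so the full suite runs in
  well under a minute while still exercising every guarantee; all stochastic
  tests are seeded.
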