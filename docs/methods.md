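# Methods

## Plan model and kinematics

An arc beam is modeled as an ordered control-point (CP) sequence; each
CP carries a gantry angle on the IEC 61217 scale (degrees in [0, 360),
360 normalized to 0 on read), a cumulative meterset weight, and
optionally MLC leaf positions.  The beam's total MU is the fraction
group's referenced beam meterset; per-CP weights are normalized by the
beam's final cumulative weight, which is *not* assumed to be 1 (RT Plan
files legally use non-unit final weights).

Kinematics are defined on the `#CPs − 1` inter-CP *segments*:

* `MU/CP_i = meterset · (w_{i+1} − w_i) / w_final`
* `deg/CP_i` = arc traversed from CP i to CP i+1 along the beam's stated
  rotation direction, computed as the directional difference mod 360 so
  the 0/360 crossing needs no special case;
* `MU/deg_i = MU/CP_i / deg/CP_i`.

A zero-arc segment (two CPs at the same angle) is physical — a static
segment — so its MU/deg is the sentinel `None` (undefined), excluded
from histograms and exceedance fractions but tallied separately; raising
or silently dropping would either reject legal plans or corrupt counts.
Cohort summaries report both the segment count and the CP count, since
"control points analyzed" is ambiguous between the two; exceedance uses
a strict `>`.

The critical MU/deg of a machine is `max_dose_rate / (60 · max_gantry_speed)`
(units MU/min and deg/s); above it the dose rate is saturated and MU/deg
maps one-to-one onto (inverse) gantry speed.  Defaults used throughout
for a flattened-beam TrueBeam: 600 MU/min, 6 deg/s, and a 60 MU/deg
deliverability ceiling; FFF-class machines are supported as alternative
limit configurations (e.g. 1400 MU/min).

## MU scaling

`scale_plan_mu` multiplies every beam meterset (including the static
open-field beam, so the strip/open normalization stays proportional) by
one uniform factor and leaves angles, weights and MLC positions bitwise
untouched; consequently every defined segment's MU/deg scales by exactly
that factor.  `required_scale_factor` returns the smallest factor whose
scaled maximum *strictly* exceeds the target ("surpasses", not
"reaches"); in the integer case the smallest such integer, in the
real-valued case the next representable float above `target/max`, since
the infimum is open.  Scaled plans are written by editing the template
file so only the referenced beam meterset elements (plus fresh SOP
instance UIDs) differ.

## EPID strip analysis

The strip image is divided pixelwise by the open-field image; pixels
where the open field reads below a floor (default 5% of its median,
configurable) are masked from all averages, making the division total
without affecting in-field analysis.  ROI i's sampling rectangle is
strip i's aperture eroded on every side by `margin_fraction` (default
0.25) of the strip width, keeping the sample in the flat strip core away
from penumbra; apertures come either from a layout file or by projecting
the plan's per-segment MLC openings through the imager magnification.
ROIs are ordered left to right, ROI 1 leftmost.

The deviation statistic for segment i is

```
deviation_i = (mean_i / grand_mean) · 100 − 100
```

where `grand_mean` is the **unweighted mean of the per-segment means**
(not the pooled-pixel mean).  This choice makes the zero-mean identity
`Σ deviation_i = 0` exact even with unequal ROI pixel counts, and reads
naturally as "the average reading of all segments".  Baseline
differences use the same ratio form, `(measured/baseline − 1) · 100`; at
the 1-decimal precision these values are reported to, the ratio form and
the difference-in-points form are numerically indistinguishable for the
near-unity means involved.  Internally full precision is kept; display
rounds MU/deg to 2 decimals and percentages to 1.  Baselines are the
per-ROI arithmetic mean over historical sessions, stored as JSON with
machine id and provenance; the default per-ROI tolerance is 3%.

## Synthetic fixtures

No vendor test file or clinical plan ships with the package, so
generators produce all inputs deterministically from a seeded config:

* **Vendor replica** — seven strip segments on one arc (start 179°, CW)
  plus a static open-field beam, 250 MU total.  The published
  constraints pin only the totals (7 strips, 250 MU, maximum segment
  2.272 MU/deg); the internal split — MU/deg schedule (0.25, 0.5, 1.0,
  1.25, 1.6, 2.0, 2.272) over spans (20°×6, 25°), open field 61.2 MU —
  is this package's own documented choice and does not claim to match
  the confidential vendor CP table.
* **SBRT-like cohort** — default 21 single-arc plans of 180 CPs with
  uniform 2° segments (a representative SBRT arc sampling).  Segment
  MU/deg values have lognormal shape, rescaled so that the pooled cohort
  has *exactly* the planted maximum (default 21.29 MU/deg, the clinical
  maximum the generator is anchored to) and *exactly*
  `round(0.83 · n_segments)` segments above the stock plan's 2.272
  MU/deg maximum — the planted counterparts of the clinical-cohort
  figures, which are not reproducible without the patient data.
* **EPID pairs** — a radially symmetric open-field profile (amplitude
  1000 detector units, 10% corner droop), strip image = open × strip
  mask × per-ROI factor with 2% MLC transmission elsewhere, plus seeded
  additive Gaussian noise.  Default imager: 1024×768 at 0.336 mm/pixel,
  seven 40-px strips at 100-px pitch.

Generated plans are pre-quantized to DICOM decimal-string precision at
construction, so a write → read cycle is exactly lossless and round-trip
tests can use strict equality.

What the fixtures do *not* emulate: scatter, panel lag/ghosting, flood
-field or sag corrections (assumed applied by the acquisition system),
MLC leaf-speed effects, or the site mix of any real SBRT cohort.
Passing tests therefore demonstrate the correctness of the arithmetic
and the pipeline's invariances (scale invariance, zero-mean, exact
factor recovery), not detector physics.

## Numerical choices and problem sizes

* Strict inequalities for exceedance and scaling targets; ties at a
  threshold count as "not above".
* Monotonicity of cumulative weights is enforced on read (error naming
  the CP); whole-plan validation returns findings rather than raising.
* Histogram bins default to 0.5 MU/deg starting at 0 (binning of the
  reference distribution plots is not standardized).
* Test and acceptance runs use reduced fixture sizes (small imager
  geometries, cohorts of a few plans with tens of CPs) where the check
  is size-independent; defaults (21 plans × 180 CPs, full imager) are
  exercised where the planted cohort statistics themselves are under
  test.
* Property tests (hypothesis) run derandomized; all stochastic fixtures
  take explicit seeds.

## Known limitations

* No reconstruction of instantaneous dose rate or gantry speed versus
  time (that needs delivery log files, not plans), and no MLC-speed
  test analysis.
* No automatic strip detection from image content: ROI placement is
  layout- or plan-driven.
* No absolute dosimetry, gamma analysis, or collimator/couch modeling.
* The writer edits only beam metersets; other plan edits are out of
  scope by design.
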