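# drgsqa — dose-rate / gantry-speed QA for VMAT linacs

During VMAT delivery a linac modulates dose rate, gantry speed, and MLC
positions simultaneously.  The standard dose-rate/gantry-speed (DRGS) QA
test delivers seven MLC-defined strips, each with a different dose-rate
and gantry-speed combination, and checks that the machine's output is
uniform across them.  But whether that test covers *clinically relevant*
conditions depends on its MU-per-degree range: between two control
points (CPs) of an arc plan,

```
MU/deg = (MU/CP) / (deg/CP)
```

and once MU/deg exceeds the machine's critical value

```
(MU/deg)_critical = (MU/min)_max / (60 · (deg/s)_max)
```

the dose rate saturates and the gantry must slow down.  SBRT arc plans
routinely demand far more MU/deg than the stock DRGS test plan delivers,
i.e. the stock test never exercises the slow-gantry regime those
treatments run in.

`drgsqa` is a toolkit for medical physicists that closes this gap:

* **profile** — iterate the control points of DICOM RT Plans and compute
  per-segment MU/CP, deg/CP and MU/deg; pool cohorts into histograms,
  exceedance fractions and maxima; compare against machine limits.
* **scale** — build a "modified DRGS" plan by uniformly scaling the beam
  metersets so the plan's maximum MU/deg strictly exceeds a clinical
  target (geometry untouched), with a deliverability check against the
  machine's MU/deg ceiling.
* **analyze** — re-implemented EPID strip-test analysis: divide the
  strip image by the open field, average each strip ROI, compute each
  segment's percent deviation from the all-segment mean, and difference
  segment means against a stored per-machine baseline (default
  tolerance 3% per ROI).
* **fixtures** — deterministic synthetic generators (a vendor-replica
  DRGS plan totaling 250 MU, SBRT-like arc cohorts with planted MU/deg
  distributions, and EPID strip/open pairs with known per-ROI factors)
  so every path is testable without vendor or clinical data.

## Worked example

```sh
python examples/scale_modified_drgs.py
```

```
clinical target:        21.29 MU/deg
required scale factor:  10
total MU:               250 -> 2500
max MU/deg:             2.272 -> 22.72
deliverable (<= 60 MU/deg ceiling): True
segments over ceiling:  0
```

The replica test plan tops out at 2.272 MU/deg, well short of the
21.29 MU/deg target; the smallest integer factor whose scaled maximum
surpasses the target is 10, taking the plan from 250 to 2500 MU and its
maximum segment to 22.72 MU/deg — still comfortably under the 60 MU/deg
the machine can deliver.  `examples/profile_plan_kinematics.py` shows
the cohort side (with the default synthetic cohort, 83.0% of segments
exceed the stock plan's maximum and the critical value is 1.67 MU/deg),
and `examples/analyze_epid_strips.py` runs the image analysis end to
end, recovering a planted +3% ROI response as a +2.56% deviation — the
closed-form value for one boosted strip among seven.

The same operations are available from the shell:

```sh
drgsqa fixtures --kind vendor --seed 0 --out fx/
drgsqa scale --plan fx/drgs_replica.dcm --target-mu-per-deg 21.29 --integer --out modified.dcm
drgsqa profile fx/drgs_replica.dcm --limits limits.yaml --out-dir profile/
drgsqa analyze --strip strip.dcm --open open.dcm --layout layout.json \
               --baseline baseline.json --tolerance 3
```

Exit codes: 0 pass, 1 I/O or format error, 2 QA failure.

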