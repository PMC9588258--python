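"""Per-segment MU/deg kinematics and cohort-level summaries.

During VMAT delivery the linac modulates dose rate and gantry speed
together.  MU per degree is a gantry-speed proxy: a segment between two
control points delivers

    MU/deg = (MU/CP) / (deg/CP)

and once MU/deg exceeds the machine's *critical* value

    (MU/deg)_critical = (MU/min)_max / (60 * (deg/s)_max)

the dose rate saturates and further increases in MU/deg are realized by
slowing the gantry.  A DRGS QA test therefore only probes clinically
relevant gantry speeds if its MU/deg range covers what patient plans
actually demand; this module measures both sides of that comparison.

Zero-arc segments (two CPs at the same gantry angle) are physical -- a
static segment -- so their MU/deg is the sentinel ``None`` (undefined)
and they are tallied separately rather than dropped or raised on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ArcError, EmptyCohortError, PlanValidationError
from .rtplan import ArcBeam, TreatmentPlan

#: Sentinel for an undefined MU/deg (zero-arc segment).
UNDEFINED = None


@dataclass(frozen=True)
class MachineLimits:
    """Deliverability limits of one linac.

    max_dose_rate: MU/min, maximum nominal dose rate (600 for a flattened
        TrueBeam beam; FFF beams go higher).
    max_gantry_speed: deg/s (6.0 for a TrueBeam).
    max_mu_per_deg: MU/deg the machine can deliver in one degree of arc
        (60 per TrueBeam documentation).
    """

    max_dose_rate: float
    max_gantry_speed: float
    max_mu_per_deg: float = float("inf")

    def validate(self) -> None:
        if not (self.max_dose_rate > 0 and self.max_gantry_speed > 0 and self.max_mu_per_deg > 0):
            raise PlanValidationError(f"machine limits must be strictly positive: {self}")

    @classmethod
    def from_config(cls, path: str | Path) -> "MachineLimits":
        """Load limits from a YAML/JSON-style key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        limits = cls(
            max_dose_rate=float(raw["max_dose_rate_mu_min"]),
            max_gantry_speed=float(raw["max_gantry_speed_deg_s"]),
            max_mu_per_deg=float(raw.get("max_mu_per_deg", float("inf"))),
        )
        limits.validate()
        return limits


@dataclass(frozen=True)
class SegmentKinematics:
    """Kinematics of the segment spanning CP ``segment_index`` -> +1."""

    beam_id: str
    segment_index: int
    mu_per_cp: float
    deg_per_cp: float
    mu_per_deg: float | None  # None == UNDEFINED (zero-arc segment)

    @property
    def is_defined(self) -> bool:
        return self.mu_per_deg is not None


@dataclass
class CohortSummary:
    """Pooled MU/deg distribution over a set of plans."""

    n_control_points: int
    n_segments: int
    n_undefined: int
    histogram: list[tuple[float, float, int]]
    fraction_above: dict[float, float]
    max_mu_per_deg: float

    def to_dict(self) -> dict:
        return {
            "n_control_points": self.n_control_points,
            "n_segments": self.n_segments,
            "n_undefined_segments": self.n_undefined,
            "max_mu_per_deg": self.max_mu_per_deg,
            "fraction_above": {f"{t:g}": f for t, f in self.fraction_above.items()},
            "histogram": [
                {"lo": lo, "hi": hi, "count": int(c)} for lo, hi, c in self.histogram
            ],
        }


def _require_arc(beam: ArcBeam, need_rotation: bool = False) -> None:
    if len(beam.control_points) < 2:
        raise ArcError(f"beam {beam.beam_id}: needs >= 2 control points, has {len(beam.control_points)}")
    if need_rotation and beam.rotation_direction not in ("CW", "CC"):
        raise ArcError(f"beam {beam.beam_id}: static beam (rotation NONE) has no deg/CP")


def mu_per_cp(beam: ArcBeam) -> np.ndarray:
    """MU delivered in each inter-CP segment.

    Segment i gets ``beam_meterset * (w[i+1] - w[i]) / final_weight``;
    the weights need not be normalized to 1 in the file.
    """
    _require_arc(beam)
    w = beam.cumulative_weights
    if np.any(np.diff(w) < 0):
        raise PlanValidationError(f"beam {beam.beam_id}: non-monotone cumulative weights")
    return beam.beam_meterset * np.diff(w) / beam.final_cumulative_weight


def deg_per_cp(beam: ArcBeam) -> np.ndarray:
    """Arc length (degrees) traversed in each inter-CP segment.

    The gantry always moves along the beam's stated rotation direction,
    so the arc from a to b is the directional difference mod 360; this
    handles the 0/360 crossing without branches.
    """
    _require_arc(beam, need_rotation=True)
    a = beam.gantry_angles
    if beam.rotation_direction == "CW":
        return (a[1:] - a[:-1]) % 360.0
    return (a[:-1] - a[1:]) % 360.0


def mu_per_deg(beam: ArcBeam) -> list[SegmentKinematics]:
    """Per-segment MU/deg; zero-arc segments carry ``mu_per_deg=None``."""
    mus = mu_per_cp(beam)
    degs = deg_per_cp(beam)
    out: list[SegmentKinematics] = []
    for i, (mu, deg) in enumerate(zip(mus, degs)):
        out.append(
            SegmentKinematics(
                beam_id=beam.beam_id,
                segment_index=i,
                mu_per_cp=float(mu),
                deg_per_cp=float(deg),
                mu_per_deg=float(mu / deg) if deg > 0 else UNDEFINED,
            )
        )
    return out


def critical_mu_per_deg(limits: MachineLimits) -> float:
    """MU/deg above which dose rate saturates and the gantry slows.

    Equals ``max_dose_rate / (60 * max_gantry_speed)``; with 600 MU/min
    and 6 deg/s this is 1.67 MU/deg (2 d.p.).
    """
    limits.validate()
    return limits.max_dose_rate / (60.0 * limits.max_gantry_speed)


def plan_segments(plan: TreatmentPlan) -> list[SegmentKinematics]:
    """All segments from every arc beam in a plan."""
    segs: list[SegmentKinematics] = []
    for beam in plan.arc_beams():
        segs.extend(mu_per_deg(beam))
    return segs


def plan_max_mu_per_deg(plan: TreatmentPlan) -> float:
    """Maximum defined MU/deg over all arc segments of a plan."""
    vals = [s.mu_per_deg for s in plan_segments(plan) if s.is_defined]
    if not vals:
        raise ArcError(f"plan {plan.plan_label}: no defined MU/deg segments")
    return max(vals)


def cohort_summary(
    plans: Sequence[TreatmentPlan],
    thresholds: Sequence[float] = (),
    bin_width: float = 0.5,
) -> CohortSummary:
    """Pool segment MU/deg over plans: histogram, exceedance, maximum.

    ``fraction_above[t]`` is the fraction of *defined* segments with
    MU/deg strictly greater than t.  Undefined (zero-arc) segments are
    excluded from the histogram and fractions but tallied.
    """
    values: list[float] = []
    n_undef = 0
    n_cps = 0
    for plan in plans:
        for beam in plan.arc_beams():
            n_cps += len(beam.control_points)
            for seg in mu_per_deg(beam):
                if seg.is_defined:
                    values.append(seg.mu_per_deg)
                else:
                    n_undef += 1
    if not values:
        raise EmptyCohortError("no defined arc segments in cohort")
    arr = np.asarray(values)
    top = float(np.ceil(arr.max() / bin_width) * bin_width)
    top = max(top, bin_width)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    hist = [(float(lo), float(hi), int(c)) for lo, hi, c in zip(edges[:-1], edges[1:], counts)]
    frac = {float(t): float(np.mean(arr > t)) for t in thresholds}
    return CohortSummary(
        n_control_points=n_cps,
        n_segments=len(values) + n_undef,
        n_undefined=n_undef,
        histogram=hist,
        fraction_above=frac,
        max_mu_per_deg=float(arr.max()),
    )


# ---------------------------------------------------------------------------
# tabular / graphical export


def segments_dataframe(plans: Sequence[TreatmentPlan]) -> pd.DataFrame:
    """Long-form table of every arc segment across plans."""
    rows = []
    for plan in plans:
        for beam in plan.arc_beams():
            for seg in mu_per_deg(beam):
                rows.append(
                    {
                        "plan": plan.plan_label,
                        "beam": seg.beam_id,
                        "segment": seg.segment_index,
                        "mu_per_cp": seg.mu_per_cp,
                        "deg_per_cp": seg.deg_per_cp,
                        "mu_per_deg": seg.mu_per_deg if seg.is_defined else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["plan", "beam", "segment", "mu_per_cp", "deg_per_cp", "mu_per_deg"])


def plot_histogram(
    summary: CohortSummary,
    out_path: str | Path,
    critical: float | None = None,
    markers: Mapping[str, float] | None = None,
) -> Path:
    """Render the pooled MU/deg histogram with vertical threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    lows = [lo for lo, _, _ in summary.histogram]
    counts = [c for _, _, c in summary.histogram]
    width = summary.histogram[0][1] - summary.histogram[0][0] if summary.histogram else 0.5
    ax.bar(lows, counts, width=width, align="edge", color="#4878b0", edgecolor="white")
    if critical is not None:
        ax.axvline(critical, color="gold", linestyle="--", label=f"critical {critical:.2f} MU/deg")
    for label, x in (markers or {}).items():
        ax.axvline(x, linestyle="--", label=f"{label} {x:.2f} MU/deg")
    ax.set_xlabel("MU per degree")
    ax.set_ylabel("segments")
    ax.set_title(f"MU/deg distribution ({summary.n_segments} segments)")
    ax.legend()
    out = Path(out_path)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
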