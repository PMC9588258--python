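"""MU scaling: turn a vendor DRGS plan into a "modified DRGS" plan.

Multiplying every beam meterset by a factor k, while leaving gantry
angles, cumulative weights and MLC positions untouched, multiplies every
segment's MU/deg by exactly k.  Since the arc length per strip is fixed,
the only way the machine can honor the extra MU is to slow the gantry --
which is precisely the slow-gantry-speed regime of SBRT deliveries that
the unmodified test plan never reaches.
"""

from __future__ import annotations

import copy
import math
from dataclasses import asdict, dataclass

from .errors import ArcError, PlanValidationError
from .kinematics import MachineLimits, SegmentKinematics, mu_per_deg, plan_max_mu_per_deg
from .rtplan import TreatmentPlan


@dataclass(frozen=True)
class ScalingResult:
    """Before/after summary of a uniform MU scaling."""

    factor: float
    original_total_mu: float
    scaled_total_mu: float
    original_max_mu_per_deg: float
    scaled_max_mu_per_deg: float
    deliverable: bool

    def to_dict(self) -> dict:
        return asdict(self)


def scale_plan_mu(
    plan: TreatmentPlan,
    factor: float,
    limits: MachineLimits | None = None,
) -> tuple[TreatmentPlan, ScalingResult]:
    """Scale every beam's meterset by ``factor``; geometry untouched.

    The open-field beam is scaled too, so the strip/open normalization
    of the image analysis stays proportional.  An undeliverable result
    (scaled max MU/deg above the machine ceiling) is flagged, not raised.
    """
    if not (factor > 0):
        raise PlanValidationError(f"scale factor must be > 0, got {factor}")
    orig_max = plan_max_mu_per_deg(plan)
    scaled = copy.deepcopy(plan)
    for beam in scaled.beams:
        beam.beam_meterset = beam.beam_meterset * factor
    scaled_max = plan_max_mu_per_deg(scaled)
    ceiling = limits.max_mu_per_deg if limits is not None else math.inf
    result = ScalingResult(
        factor=float(factor),
        original_total_mu=plan.total_meterset,
        scaled_total_mu=scaled.total_meterset,
        original_max_mu_per_deg=orig_max,
        scaled_max_mu_per_deg=scaled_max,
        deliverable=scaled_max <= ceiling,
    )
    return scaled, result


def required_scale_factor(
    plan: TreatmentPlan,
    target_mu_per_deg: float,
    integer_only: bool = False,
) -> float:
    """Smallest factor whose scaled maximum *strictly exceeds* the target.

    With ``integer_only`` this is the smallest integer k >= 1 with
    k * max > target (e.g. max 2.272, target 21.29 -> k = 10).  In the
    real-valued case the infimum target/max is open, so the next
    representable float above it is returned.
    """
    if not (target_mu_per_deg > 0):
        raise PlanValidationError(f"target MU/deg must be > 0, got {target_mu_per_deg}")
    orig_max = plan_max_mu_per_deg(plan)  # raises ArcError if no defined segments
    if integer_only:
        k = max(1, math.ceil(target_mu_per_deg / orig_max))
        while k * orig_max <= target_mu_per_deg:
            k += 1
        return float(k)
    f = target_mu_per_deg / orig_max
    while f * orig_max <= target_mu_per_deg:
        f = math.nextafter(f, math.inf)
    return f


def deliverability_check(plan: TreatmentPlan, limits: MachineLimits) -> list[SegmentKinematics]:
    """Segments whose MU/deg exceeds the machine's ceiling (empty == OK)."""
    offenders: list[SegmentKinematics] = []
    for beam in plan.arc_beams():
        for seg in mu_per_deg(beam):
            if seg.is_defined and seg.mu_per_deg > limits.max_mu_per_deg:
                offenders.append(seg)
    return offenders
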