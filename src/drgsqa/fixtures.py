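"""Deterministic synthetic fixtures: plans, cohorts, EPID image pairs.

No vendor test file or clinical plan ships with this package, so every
analysis path is exercised against synthetic stand-ins with known ground
truth:

* a *vendor-replica* DRGS plan — seven MLC strip segments delivered over
  an arc plus a static open-field beam, 250 MU total, with a monotone
  MU/deg schedule topping out at 2.272 MU/deg.  The internal strip
  layout (arc span and MU split per strip) is this package's own
  documented choice; only the published constraints (7 strips, 250 MU
  total, maximum segment 2.272 MU/deg) are reproduced, not the
  confidential vendor control-point table;
* an *SBRT-like cohort* — arc plans whose pooled segment MU/deg values
  follow a lognormal-shaped distribution with an exactly planted
  maximum and an exactly planted count above a threshold;
* *EPID pairs* — an open-field image with a smooth radial beam profile
  and a strip image equal to open x strip-mask x per-ROI factor, plus
  seeded additive Gaussian noise.  The planted factors are returned so
  recovery can be checked against the closed form.

Everything is a pure function of the config (seed included); generated
plans are pre-quantized to DICOM decimal-string precision so that a
write -> read cycle is exactly lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import FixtureConfigError
from .epid import EpidImage, StripLayout
from .rtplan import ArcBeam, ControlPoint, TreatmentPlan, quantize_plan


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of every synthetic generator (all defaults are usable)."""

    seed: int = 0

    # vendor-replica DRGS plan ------------------------------------------------
    total_mu: float = 250.0
    #: MU/deg schedule per strip, monotone; the last value is the plan maximum.
    strip_mu_per_deg: tuple[float, ...] = (0.25, 0.5, 1.0, 1.25, 1.6, 2.0, 2.272)
    #: arc length (deg) per strip segment
    strip_arc_spans: tuple[float, ...] = (20.0, 20.0, 20.0, 20.0, 20.0, 20.0, 25.0)
    start_angle: float = 179.0
    rotation: str = "CW"

    # imager / strip geometry -------------------------------------------------
    image_shape: tuple[int, int] = (768, 1024)
    pixel_spacing: tuple[float, float] = (0.336, 0.336)
    strip_width_px: int = 40
    strip_pitch_px: int = 100
    field_rows: tuple[int, int] = (176, 592)
    n_leaf_pairs: int = 60
    leaf_width_mm: float = 5.0

    # EPID image pair ---------------------------------------------------------
    roi_factors: tuple[float, ...] = (1.0,) * 7
    noise_sigma: float = 0.0  # detector units; open amplitude is 1000
    open_amplitude: float = 1000.0
    profile_droop: float = 0.1  # fractional falloff at the image corner
    transmission: float = 0.02  # leakage under closed MLC

    # SBRT-like cohort --------------------------------------------------------
    cohort_size: int = 21
    cps_per_plan: int = 180
    segment_span_deg: float = 2.0
    exceed_threshold: float = 2.272
    planted_fraction_above: float = 0.83
    planted_max: float = 21.29
    min_mu_per_deg: float = 0.1

    @property
    def n_strips(self) -> int:
        return len(self.strip_mu_per_deg)

    def strip_columns(self) -> list[tuple[int, int]]:
        """Half-open column bounds of each strip, centered on the imager."""
        n = self.n_strips
        center = self.image_shape[1] / 2.0
        first_center = center - (n - 1) * self.strip_pitch_px / 2.0
        out = []
        for i in range(n):
            c = first_center + i * self.strip_pitch_px
            out.append((int(round(c - self.strip_width_px / 2)), int(round(c + self.strip_width_px / 2))))
        return out

    def layout(self) -> StripLayout:
        return StripLayout(rows=self.field_rows, strips=self.strip_columns())

    def validate(self) -> None:
        if len(self.strip_arc_spans) != self.n_strips:
            raise FixtureConfigError("strip_mu_per_deg and strip_arc_spans lengths differ")
        if any(r <= 0 for r in self.strip_mu_per_deg) or any(s <= 0 for s in self.strip_arc_spans):
            raise FixtureConfigError("strip MU/deg values and arc spans must be positive")
        if sum(self.strip_arc_spans) >= 358.0:
            raise FixtureConfigError("total arc span must stay below a full rotation")
        strip_mu = [r * s for r, s in zip(self.strip_mu_per_deg, self.strip_arc_spans)]
        if sum(strip_mu) >= self.total_mu:
            raise FixtureConfigError(
                f"strip MU sum {sum(strip_mu)} leaves no MU for the open field (total {self.total_mu})"
            )
        if len(self.roi_factors) != self.n_strips:
            raise FixtureConfigError("roi_factors length must match the number of strips")
        if self.noise_sigma < 0:
            raise FixtureConfigError("noise sigma must be >= 0")
        cols = self.strip_columns()
        if any(b[0] < a[1] for a, b in zip(cols, cols[1:])):
            raise FixtureConfigError("strips overlap")
        if not (0 <= self.planted_fraction_above <= 1):
            raise FixtureConfigError("planted_fraction_above must be in [0, 1]")
        if not (self.min_mu_per_deg < self.exceed_threshold < self.planted_max):
            raise FixtureConfigError("need min_mu_per_deg < exceed_threshold < planted_max")
        if (self.cps_per_plan - 1) * self.segment_span_deg >= 360.0:
            raise FixtureConfigError("cohort arc span reaches a full rotation")


# ---------------------------------------------------------------------------
# plans


def _strip_mlc(config: FixtureConfig, col_bounds: tuple[int, int]) -> np.ndarray:
    """MLC bank positions (mm at isocenter) opening one strip aperture."""
    rows, cols = config.image_shape
    sp_r, sp_c = config.pixel_spacing
    x_lo = (col_bounds[0] - cols / 2.0) * sp_c
    x_hi = (col_bounds[1] - cols / 2.0) * sp_c
    n = config.n_leaf_pairs
    # leaf pairs whose projection covers the field row band
    lo_pair = int(round((config.field_rows[0] - rows / 2.0) * sp_r / config.leaf_width_mm + n / 2.0))
    hi_pair = int(round((config.field_rows[1] - rows / 2.0) * sp_r / config.leaf_width_mm + n / 2.0))
    bank_a = np.zeros(n)
    bank_b = np.zeros(n)
    bank_a[lo_pair:hi_pair] = x_lo
    bank_b[lo_pair:hi_pair] = x_hi
    return np.vstack([bank_a, bank_b])


def make_vendor_replica_plan(config: FixtureConfig = FixtureConfig()) -> TreatmentPlan:
    """Seven-strip DRGS arc beam plus a static open-field beam, 250 MU.

    Strip i is delivered over ``strip_arc_spans[i]`` degrees at
    ``strip_mu_per_deg[i]`` MU/deg; CP i carries strip i's MLC aperture.
    The open-field beam receives the remaining MU and does not rotate.
    """
    config.validate()
    strip_mu = [r * s for r, s in zip(config.strip_mu_per_deg, config.strip_arc_spans)]
    arc_total = float(sum(strip_mu))
    cols = config.strip_columns()

    angles = [config.start_angle]
    for span in config.strip_arc_spans:
        step = span if config.rotation == "CW" else -span
        angles.append((angles[-1] + step) % 360.0)
    weights = [0.0] + list(np.cumsum(strip_mu))

    cps = []
    for i, (ang, w) in enumerate(zip(angles, weights)):
        aperture = cols[min(i, config.n_strips - 1)]
        cps.append(
            ControlPoint(
                index=i,
                gantry_angle=ang,
                cumulative_weight=float(w),
                mlc_leaf_positions=_strip_mlc(config, aperture),
            )
        )
    arc = ArcBeam(
        beam_id="DRGS_arc",
        beam_meterset=arc_total,
        final_cumulative_weight=arc_total,
        rotation_direction="CW" if config.rotation == "CW" else "CC",
        control_points=cps,
    )
    open_mu = config.total_mu - arc_total
    open_beam = ArcBeam(
        beam_id="open_field",
        beam_meterset=open_mu,
        final_cumulative_weight=1.0,
        rotation_direction="NONE",
        control_points=[
            ControlPoint(index=0, gantry_angle=0.0, cumulative_weight=0.0),
            ControlPoint(index=1, gantry_angle=0.0, cumulative_weight=1.0),
        ],
    )
    plan = TreatmentPlan(plan_label="DRGS_replica", beams=[arc, open_beam])
    return quantize_plan(plan)


def _shaped_values(config: FixtureConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """MU/deg values with lognormal shape, planted max and exceedance count."""
    n_above = int(round(config.planted_fraction_above * n))
    if n_above < 1 or n_above > n:
        raise FixtureConfigError(f"planted count {n_above} infeasible for {n} segments")
    raw = rng.lognormal(mean=np.log(3.0), sigma=0.8, size=n)
    order = np.argsort(raw)
    values = np.empty(n)
    eps = 1e-3 * config.exceed_threshold  # keep a guard band around the threshold

    def affine(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
        if x.size == 1 or x.max() == x.min():
            return np.full(x.size, hi)
        return lo + (x - x.min()) / (x.max() - x.min()) * (hi - lo)

    below_idx = order[: n - n_above]
    above_idx = order[n - n_above:]
    if below_idx.size:
        values[below_idx] = affine(raw[below_idx], config.min_mu_per_deg, config.exceed_threshold - eps)
    values[above_idx] = affine(raw[above_idx], config.exceed_threshold + eps, config.planted_max)
    # the largest raw value maps exactly onto the planted maximum
    return values


def make_sbrt_like_cohort(config: FixtureConfig = FixtureConfig()) -> list[TreatmentPlan]:
    """Arc plans pooling to a planted MU/deg distribution.

    Every plan is a single full-modulation arc with uniform segment arc
    length; segment i's MU is (planted MU/deg) x (span).  The pooled
    cohort has exactly ``round(planted_fraction_above * n_segments)``
    segments above ``exceed_threshold`` and a maximum of ``planted_max``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_seg = config.cps_per_plan - 1
    n_total = config.cohort_size * n_seg
    values = _shaped_values(config, rng, n_total)

    plans: list[TreatmentPlan] = []
    d = config.segment_span_deg
    for k in range(config.cohort_size):
        v = values[k * n_seg : (k + 1) * n_seg]
        mu = v * d
        weights = np.concatenate([[0.0], np.cumsum(mu)])
        total = float(weights[-1])
        direction = "CW" if k % 2 == 0 else "CC"
        sign = 1.0 if direction == "CW" else -1.0
        cps = [
            ControlPoint(
                index=i,
                gantry_angle=(config.start_angle + sign * i * d) % 360.0,
                cumulative_weight=float(w),
            )
            for i, w in enumerate(weights)
        ]
        beam = ArcBeam(
            beam_id="arc1",
            beam_meterset=total,
            final_cumulative_weight=total,
            rotation_direction=direction,
            control_points=cps,
        )
        plans.append(quantize_plan(TreatmentPlan(plan_label=f"sbrt_{k + 1:02d}", beams=[beam])))
    return plans


# ---------------------------------------------------------------------------
# EPID image pairs


def _open_profile(config: FixtureConfig) -> np.ndarray:
    rows, cols = config.image_shape
    y = (np.arange(rows) - rows / 2.0)[:, None]
    x = (np.arange(cols) - cols / 2.0)[None, :]
    r2 = (y**2 + x**2) / ((rows / 2.0) ** 2 + (cols / 2.0) ** 2)
    return config.open_amplitude * (1.0 - config.profile_droop * r2)


def make_epid_pair(
    config: FixtureConfig = FixtureConfig(),
) -> tuple[EpidImage, EpidImage, dict]:
    """Strip/open EPID image pair with planted per-ROI response factors.

    The open image is a smooth radially symmetric profile; the strip
    image is the open image times the strip mask times each strip's
    planted factor (plus MLC transmission elsewhere), with independent
    seeded Gaussian noise added to both.  Returns the pair and a ground
    truth dict (``factors``, ``layout``, ``transmission``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    open_pixels = _open_profile(config)

    mask = np.full(config.image_shape, config.transmission)
    r0, r1 = config.field_rows
    for (c0, c1), factor in zip(config.strip_columns(), config.roi_factors):
        mask[r0:r1, c0:c1] = factor
    strip_pixels = open_pixels * mask

    if config.noise_sigma > 0:
        strip_pixels = strip_pixels + rng.normal(0.0, config.noise_sigma, config.image_shape)
        open_pixels = open_pixels + rng.normal(0.0, config.noise_sigma, config.image_shape)

    strip = EpidImage(strip_pixels, config.pixel_spacing, kind="STRIP", machine_id="SYN01")
    open_ = EpidImage(open_pixels, config.pixel_spacing, kind="OPEN", machine_id="SYN01")
    truth = {
        "factors": list(config.roi_factors),
        "layout": config.layout(),
        "transmission": config.transmission,
    }
    return strip, open_, truth
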