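"""Profile MU-per-degree kinematics of arc plans against machine limits.

Builds a synthetic SBRT-like cohort, pools every inter-CP segment's
MU/deg, and compares the distribution to the critical value at which a
TrueBeam saturates its dose rate and starts slowing the gantry.
"""

from drgsqa import (
    FixtureConfig,
    MachineLimits,
    cohort_summary,
    critical_mu_per_deg,
    make_sbrt_like_cohort,
    make_vendor_replica_plan,
    plan_max_mu_per_deg,
)

limits = MachineLimits(max_dose_rate=600.0, max_gantry_speed=6.0, max_mu_per_deg=60.0)
critical = critical_mu_per_deg(limits)

vendor = make_vendor_replica_plan()
vendor_max = plan_max_mu_per_deg(vendor)

cohort = make_sbrt_like_cohort(FixtureConfig(seed=0))
summary = cohort_summary(cohort, thresholds=[critical, vendor_max])

print(f"critical MU/deg (600 MU/min, 6 deg/s): {critical:.2f}")
print(f"vendor-replica test plan maximum:      {vendor_max:.3f} MU/deg")
print(f"cohort: {summary.n_segments} segments from {len(cohort)} plans")
print(f"cohort maximum MU/deg:                 {summary.max_mu_per_deg:.2f}")
print(f"fraction above critical:               {summary.fraction_above[critical]:.1%}")
print(f"fraction above the test plan's max:    {summary.fraction_above[vendor_max]:.1%}")
print()
print("Segments above the test plan's maximum are delivery conditions the")
print("unmodified QA plan never exercises - the motivation for MU scaling.")
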