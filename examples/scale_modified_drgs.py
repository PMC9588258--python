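"""Build a "modified DRGS" plan that covers SBRT-range gantry speeds.

Finds the smallest integer MU scale factor whose scaled maximum MU/deg
strictly exceeds a clinical target, applies it, and checks the scaled
plan against the machine's deliverability ceiling.
"""

from drgsqa import (
    MachineLimits,
    deliverability_check,
    make_vendor_replica_plan,
    required_scale_factor,
    scale_plan_mu,
)

limits = MachineLimits(max_dose_rate=600.0, max_gantry_speed=6.0, max_mu_per_deg=60.0)
plan = make_vendor_replica_plan()

clinical_max = 21.29  # highest MU/deg demanded by the plans being emulated
factor = required_scale_factor(plan, clinical_max, integer_only=True)
scaled, result = scale_plan_mu(plan, factor, limits=limits)

print(f"clinical target:        {clinical_max} MU/deg")
print(f"required scale factor:  {factor:g}")
print(f"total MU:               {result.original_total_mu:g} -> {result.scaled_total_mu:g}")
print(f"max MU/deg:             {result.original_max_mu_per_deg:.3f} -> {result.scaled_max_mu_per_deg:.2f}")
print(f"deliverable (<= {limits.max_mu_per_deg:g} MU/deg ceiling): {result.deliverable}")
print(f"segments over ceiling:  {len(deliverability_check(scaled, limits))}")
print()
print("Same arc geometry, 10x the MU: the gantry must rotate ~10x slower,")
print("so the test now probes the slow-gantry regime of SBRT deliveries.")
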