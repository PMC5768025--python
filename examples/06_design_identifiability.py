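"""Why the high-pressure campaign matters: design identifiability.

Compares the expected precision of (kcat, K_MO, K_MS) under the
atmospheric-only design against the combined 1 atm + 6 bar design using
Fisher information (no data generated), then demonstrates the
between-campaign activity-scaling fit on simulated degraded data.
"""

from dataclasses import replace

from titrkin import (
    FitOptions,
    GOX_REFERENCE_PARAMS,
    compare_designs,
    estimate_activity_scaling,
    generate_rate_table,
    reference_design,
)
from titrkin.synthetic import DEGRADATION_FACTOR, design_from_campaigns

truth = GOX_REFERENCE_PARAMS["titr_combined"]
atm, hp = reference_design(noise_cv=0.03)

tab = compare_designs([design_from_campaigns([atm]), design_from_campaigns([atm, hp])], truth)
tab.index = ["1 atm only", "1 atm + 6 bar"]
print("Relative standard errors (Fisher information, 3 % noise):")
print(tab.to_string(float_format=lambda x: f"{x:.3f}"))
print("Adding the 6 bar campaign roughly halves the K_MO uncertainty: the")
print("design finally reaches oxygen levels >10x above the Michaelis constant.\n")

# campaign B: same design, enzyme formulation degraded to 0.79x activity
atm0, hp0 = reference_design(noise_cv=0.0)
obs_a = generate_rate_table(atm0, truth) + generate_rate_table(hp0, truth)
obs_b = generate_rate_table(replace(atm0, degradation_factor=DEGRADATION_FACTOR), truth) + \
    generate_rate_table(replace(hp0, degradation_factor=DEGRADATION_FACTOR), truth)
res = estimate_activity_scaling(obs_a, obs_b, FitOptions(seed=0))
print(f"joint fit: shared K_MO = {res['K_MO']:.3f} mM, K_MS = {res['K_MS']:.2f} mM")
print(f"campaign activity ratio kcat_B/kcat_A = {res['ratio']:.3f} "
      f"(simulated with {DEGRADATION_FACTOR})")
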