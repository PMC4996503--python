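"""Select the reference-plane height on a synthetic phenotype cohort.

Generates 72 phantom eyes (18 per disc type) whose cpRNFLT is linear in
the rim area at a 120 µm reference plane, quantifies every eye at
60–180 µm, and shows that the sweep + disc-type-independence rule recovers
the generating height.
"""

import onhmorph as om
from onhmorph.refplane import DEFAULT_HEIGHTS

eyes = om.generate_cohort(n_per_type=18, rp_truth_height_um=120.0, seed=1)
quantified = om.quantify_cohort(eyes, DEFAULT_HEIGHTS)
sweep = om.rp_sweep(quantified)
regressions = {h: om.type_influence_regression(quantified[h], h)
               for h in DEFAULT_HEIGHTS}
selected, fallback = om.select_height(sweep, regressions)

print(f"{'height um':>9s} {'r(rim,cpRNFLT)':>15s} {'disc-type p':>12s}")
for h in DEFAULT_HEIGHTS:
    print(f"{h:9.0f} {sweep.r(h):15.3f} {regressions[h].type_p_value:12.3f}")
print(f"\nselected reference plane: {selected:.0f} um"
      + (" (fallback)" if fallback else ""))
print("The correlation peaks at the generating height and the disc-type "
      "block test is non-significant there: rim area at that height "
      "reflects axonal loss independently of disc phenotype.")
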