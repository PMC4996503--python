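"""Inter-rater reproducibility of the 20 parameters via ICC(2,1).

Simulates two raters marking the same phantom eyes — the second rater's
BMO points are jittered by ~20 µm — quantifies both sets, and reports the
per-parameter intraclass correlation.
"""

import numpy as np

import onhmorph as om

rng = np.random.default_rng(0)
eyes = om.generate_cohort(n_per_type=5, seed=0, grid_shape=(128, 128),
                          noise_sd_um=10.0)

rater_a, rater_b = {}, {}
for eye in eyes:
    rater_a[eye.eye_id] = om.quantify_disc(eye.seg, 120.0)
    bmo = eye.seg.bmo
    jittered = om.BMOPointSet(
        scan_index=bmo.scan_index, side=bmo.side,
        x_mm=bmo.x_mm + rng.normal(0, 0.02, len(bmo)),
        y_mm=bmo.y_mm + rng.normal(0, 0.02, len(bmo)),
        z_um=bmo.z_um + rng.normal(0, 20.0, len(bmo)))
    seg_b = om.SegmentationInput(bmo=jittered, ilm=eye.seg.ilm,
                                 eye_id=eye.eye_id)
    rater_b[eye.eye_id] = om.quantify_disc(seg_b, 120.0)

report = om.reproducibility_report(rater_a, rater_b, mode="inter")
print(report[["parameter", "icc", "below_threshold"]].to_string(index=False))
print("\nICC(2,1) close to 1 means the parameter is insensitive to "
      "realistic re-marking variability; values below 0.7 are flagged.")
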