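"""Quantify the 20 disc parameters of an analytic phantom.

Builds the closed-form paraboloid eye (BMO circle R = 0.9 mm, paraboloid
cup bottoming 400 µm below the BMO plane), quantifies it at a 120 µm
reference plane, and prints the measured values next to the exact ones.
"""

import numpy as np

import onhmorph as om

psi = np.arange(24) * 15.0
bmo = om.BMOPointSet(
    scan_index=np.arange(24) % 12,
    side=np.where((psi > 90) & (psi <= 270), "nasal-half", "temporal-half"),
    x_mm=0.9 * np.cos(np.radians(psi)),
    y_mm=0.9 * np.sin(np.radians(psi)),
    z_um=np.zeros(24),
)
x = np.linspace(-3, 3, 512)
y = np.linspace(3, -3, 256)
xg, yg = np.meshgrid(x, y)
ilm = om.ILMSurface(600.0 * (np.hypot(xg, yg) / 0.9) ** 2 - 400.0)
seg = om.SegmentationInput(bmo=bmo, ilm=ilm, eye_id="paraboloid")

params = om.quantify_disc(seg, rp_height_um=120.0)

exact = {
    "disc_area_mm2": np.pi * 0.81,          # pi R^2
    "cup_area_mm2": np.pi * 0.81 * 520 / 600,  # level set at 120 um
    "cd_ratio_area": 520 / 600,
    "max_cup_depth_um": 520.0,              # 400 below plane + 120 RP offset
    "avg_cup_depth_um": 260.0,              # paraboloid: mean = max / 2
}
print(f"{'parameter':26s} {'measured':>10s} {'exact':>10s}")
for name, value in exact.items():
    print(f"{name:26s} {getattr(params, name):10.4f} {value:10.4f}")
print("\nAll cup-dependent values refer to the reference plane "
      f"{params.rp_height_um:.0f} um above the BMO base plane; the "
      "sub-percent differences are grid discretisation of the 512x256 raster.")
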