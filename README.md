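# onhmorph

Optic nerve head (ONH) morphometry referenced to Bruch's membrane opening
(BMO), and objective classification of glaucomatous optic discs into
Nicolela's four phenotypes — focal ischemic (FI), myopic (MY), senile
sclerotic (SS) and generalized enlargement (GE).

Glaucomatous damage shows as cupping of the optic disc and thinning of the
neuroretinal rim, but discs come in morphologically distinct types that
confound any single measurement convention. `onhmorph` implements the
measurement chain used with swept-source OCT volumes of the ONH:

* **Geometry** — fit a *base plane* through marked BMO edge points (total
  least squares); project the BMO ring onto it to get the disc boundary;
  set a *reference plane* (RP) 60–180 µm anterior and delineate the cup as
  the region where the inner limiting membrane (ILM) surface lies below
  the RP (marching-squares level set); quantify 20 parameters: disc, cup
  and rim areas, diameters, C/D and R/D ratios, maximum/average cup depth,
  rim/disc ratio in the six HRT sectors (T/TS/NS/N/NI/TI), the rim
  decentering ratio (rim TS − rim TI)/(rim TS + rim TI), the horizontal
  disc angle, and the temporal–nasal disc height difference.
* **Reference-plane selection** — sweep RP heights, correlating rim area
  with circumpapillary RNFL thickness (cpRNFLT) and visual-field MD per
  disc type, and test per height whether disc type influences rim area
  once cpRNFLT is accounted for (OLS, 3-df partial F); select the height
  that maximises the structural correlation while staying type-independent.
* **Classification** — Wilks'-lambda stepwise discriminant selection over
  the 20 parameters, then linear discriminant analysis: the posterior
  probability of each type decides the class; validation reports the
  confusion matrix, identification rates, sensitivity/specificity,
  one-vs-rest AUCs and Cohen's kappa.
* **Reproducibility** — ANOVA-based single-measure ICCs: ICC(2,1) between
  raters, ICC(3,1) within rater.
* **Synthetic phantoms** — analytic ONH phantoms (paraboloid cup, tilt,
  notch, decentering) with closed-form ground truth for all 20 parameters,
  plus phenotype cohorts with clinically linked covariates, so the whole
  pipeline is testable without patient data.

See `docs/methods.md` for the model conventions and numerical choices.

## Worked example

```python
import numpy as np
import onhmorph as om

# an analytic eye: BMO circle R = 0.9 mm on a flat base plane, ILM is a
# paraboloid h(r) = 600 (r/0.9)^2 - 400 um over the 6x6 mm scan
psi = np.arange(24) * 15.0
bmo = om.BMOPointSet(
    scan_index=np.arange(24) % 12,
    side=np.where((psi > 90) & (psi <= 270), "nasal-half", "temporal-half"),
    x_mm=0.9 * np.cos(np.radians(psi)), y_mm=0.9 * np.sin(np.radians(psi)),
    z_um=np.zeros(24))
x = np.linspace(-3, 3, 512); y = np.linspace(3, -3, 256)
xg, yg = np.meshgrid(x, y)
ilm = om.ILMSurface(600.0 * (np.hypot(xg, yg) / 0.9) ** 2 - 400.0)
seg = om.SegmentationInput(bmo=bmo, ilm=ilm, eye_id="demo")

p = om.quantify_disc(seg, rp_height_um=120.0)
print(f"disc {p.disc_area_mm2:.3f} mm2  cup {p.cup_area_mm2:.3f} mm2  "
      f"C/D {p.cd_ratio_area:.3f}")
print(f"max depth {p.max_cup_depth_um:.0f} um  mean {p.avg_cup_depth_um:.0f} um")
```

prints

```
disc 2.545 mm2  cup 2.205 mm2  C/D 0.867
max depth 520 um  mean 260 um
```

which are the closed forms of this phantom: disc area πR² = 2.5447 mm²,
cup boundary at the 120 µm level set (radius 0.9·√(520/600) = 0.838 mm, so
cup area 2.205 mm² and C/D 0.867), maximum depth 400 + 120 = 520 µm and —
a paraboloid property — mean depth exactly half the maximum. The
sub-0.1% differences from the printed values are grid discretisation.

The scripts in `examples/` walk through each capability: phantom
quantification, the reference-plane sweep (recovers the generating 120 µm
height on a synthetic cohort), stepwise training + classification
(≈80% identification, kappa ≈ 0.7 at the published per-type effect sizes),
and the ICC reproducibility report.

A thin CLI mirrors the library: `onhmorph simulate | quantify | sweep-rp |
train | classify | icc` (see `onhmorph --help`).

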