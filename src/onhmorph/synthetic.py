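"""Parametric optic-nerve-head phantoms and synthetic cohorts.

Every downstream stage (quantification, reference-plane selection,
classification, reproducibility) is testable without patient data through
three generators:

* :func:`generate_surface` — a single analytic phantom: an elliptical BMO
  ring on a tilted base plane plus a smooth ILM bowl (paraboloid cup, flat
  rim shelf, optional inferotemporal notch and cup decentering) with
  optional i.i.d. Gaussian height noise. The paraboloid profile is chosen
  because its level sets and depth integrals have closed forms, so the
  *noise-free truth* of all 20 parameters is known exactly
  (:func:`analytic_parameters`).
* :func:`generate_cohort` — phantom cohorts of the four Nicolela disc
  phenotypes with clinical covariates tied to rim area at a known
  reference-plane height, giving the RP sweep a known optimum.
* :func:`make_classification_cohort` / :func:`make_stepwise_problem` —
  feature-level cohorts whose marginal means/SDs match the published
  per-type statistics, with the structural identities between parameters
  (rim = disc − cup, R/D = 1 − C/D, max ≥ avg depth) preserved.

Determinism: every generator is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning, so per-eye substreams are stable
when a cohort is extended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon

from . import geometry
from .geometry import PlaneFrame, _ray_crossings, _sector_masks
from .types import (
    DISC_TYPES,
    PARAMETER_NAMES,
    SIDE_NASAL,
    SIDE_TEMPORAL,
    BMOPointSet,
    DiscParameters,
    EyeRecord,
    ILMSurface,
    SegmentationInput,
    ValidationError,
)

__all__ = [
    "SyntheticDiscSpec",
    "SyntheticTruth",
    "CohortEye",
    "default_spec",
    "analytic_parameters",
    "generate_surface",
    "generate_cohort",
    "sample_disc_parameters",
    "make_classification_cohort",
    "make_stepwise_problem",
    "CPRNFLT_INTERCEPT",
    "CPRNFLT_SLOPE",
    "CPRNFLT_NOISE_SD",
    "MD_INTERCEPT",
    "MD_SLOPE",
    "MD_NOISE_SD",
]


@dataclass(frozen=True)
class SyntheticDiscSpec:
    """Generative parameters for one phantom eye.

    ``rim_height_um`` is the flat ILM shelf height above the base plane at
    and beyond the BMO; the cup floor sits ``cup_depth_um`` below that
    shelf. ``tilt_deg`` shears the whole structure about the vertical axis
    (the horizontal disc angle of the phantom equals the tilt).
    ``notch_sector``/``notch_depth_fraction`` carve a Gaussian angular
    wedge of focal rim loss; ``decentering_offset_mm`` shifts the cup
    centre along the vertical axis (negative = inferior).
    """

    disc_type: str
    disc_radius_x_mm: float = 0.90
    disc_radius_y_mm: float = 0.90
    cup_depth_um: float = 700.0
    cup_radius_fraction: float = 0.90
    rim_height_um: float = 250.0
    tilt_deg: float = 0.0
    notch_sector: Optional[str] = None
    notch_depth_fraction: float = 0.0
    decentering_offset_mm: float = 0.0
    noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disc_type not in DISC_TYPES:
            raise ValidationError(f"unknown disc type {self.disc_type!r}")
        if min(self.disc_radius_x_mm, self.disc_radius_y_mm) <= 0:
            raise ValidationError("disc radii must be positive")
        if not 0 < self.cup_radius_fraction <= 1:
            raise ValidationError("cup_radius_fraction must be in (0, 1]")
        if self.cup_depth_um <= 0 or self.rim_height_um <= 0:
            raise ValidationError("cup depth and rim height must be positive")
        if self.noise_sd_um < 0:
            raise ValidationError("noise_sd_um must be non-negative")
        if not 0 <= self.notch_depth_fraction <= 1:
            raise ValidationError("notch_depth_fraction must be in [0, 1]")
        if self.notch_sector is not None and self.notch_sector not in (
                s[0] for s in geometry.SECTORS):
            raise ValidationError(f"unknown notch sector {self.notch_sector!r}")


@dataclass
class SyntheticTruth:
    """Noise-free analytic parameters plus generative covariates."""

    params: DiscParameters
    cprnflt_um: Optional[float] = None
    md_db: Optional[float] = None


# Phenotype presets. Cup depth / radius fraction are solved from the
# published per-type mean C/D area ratio and average cup depth at the
# 120 µm reference plane (paraboloid: avg depth = depth * rho*^2 * cos(tilt)/2
# with rho*^2 = 1 - (rim - 120/cos(tilt))/depth); tilt matches the per-type
# mean horizontal disc angle. FI carries the focal inferotemporal notch,
# MY the strong tilt, SS the shallow saucer, GE the large deep round cup.
_PRESETS: dict[str, SyntheticDiscSpec] = {
    "FI": SyntheticDiscSpec(
        disc_type="FI", disc_radius_x_mm=0.850, disc_radius_y_mm=0.883,
        cup_depth_um=790.0, cup_radius_fraction=0.868, tilt_deg=3.30,
        notch_sector="TI", notch_depth_fraction=0.5,
        decentering_offset_mm=-0.040,
    ),
    "MY": SyntheticDiscSpec(
        disc_type="MY", disc_radius_x_mm=0.820, disc_radius_y_mm=0.975,
        cup_depth_um=752.0, cup_radius_fraction=0.893, tilt_deg=6.99,
        decentering_offset_mm=-0.035,
    ),
    "SS": SyntheticDiscSpec(
        disc_type="SS", disc_radius_x_mm=0.896, disc_radius_y_mm=0.896,
        cup_depth_um=645.0, cup_radius_fraction=0.943, tilt_deg=2.95,
        decentering_offset_mm=-0.040,
    ),
    "GE": SyntheticDiscSpec(
        disc_type="GE", disc_radius_x_mm=0.896, disc_radius_y_mm=0.896,
        cup_depth_um=1005.0, cup_radius_fraction=0.928, tilt_deg=2.77,
        decentering_offset_mm=-0.025,
    ),
}

_SECTOR_CENTER = {"T": 0.0, "TS": 67.5, "NS": 112.5, "N": 180.0,
                  "NI": 247.5, "TI": 292.5}
_NOTCH_SIGMA_DEG = 25.0


def default_spec(disc_type: str) -> SyntheticDiscSpec:
    """Preset phantom spec for one of the four disc phenotypes."""
    if disc_type not in _PRESETS:
        raise ValidationError(f"unknown disc type {disc_type!r}")
    return _PRESETS[disc_type]


def _notch_gain(phi_deg: np.ndarray, spec: SyntheticDiscSpec) -> np.ndarray:
    """Angular cup-radius gain g(phi) >= 1 implementing the rim notch."""
    if spec.notch_sector is None or spec.notch_depth_fraction == 0:
        return np.ones_like(np.asarray(phi_deg, dtype=float))
    center = _SECTOR_CENTER[spec.notch_sector]
    d = np.mod(np.asarray(phi_deg, dtype=float) - center + 180.0, 360.0) - 180.0
    gmax = 1.0 / spec.cup_radius_fraction
    return 1.0 + spec.notch_depth_fraction * (gmax - 1.0) * np.exp(
        -0.5 * (d / _NOTCH_SIGMA_DEG) ** 2
    )


def _bowl_heights(spec: SyntheticDiscSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Untilted ILM profile h0(x, y) in µm (before shear and noise)."""
    fa = spec.cup_radius_fraction * spec.disc_radius_x_mm
    fb = spec.cup_radius_fraction * spec.disc_radius_y_mm
    X = x / fa
    Y = (y - spec.decentering_offset_mm) / fb
    rho = np.hypot(X, Y)
    phi = np.degrees(np.arctan2(Y, X))
    g = _notch_gain(phi, spec)
    rel = rho / g
    h = np.full(np.broadcast(X, Y).shape, spec.rim_height_um, dtype=float)
    inside = rel < 1.0
    h[inside] = spec.rim_height_um - spec.cup_depth_um * (1.0 - rel[inside] ** 2)
    return h


def generate_surface(
    spec: SyntheticDiscSpec,
    grid_shape: tuple[int, int] = (256, 512),
    extent_mm: tuple[float, float] = (6.0, 6.0),
    truth_rp_um: float = 120.0,
    eye_id: str = "phantom",
) -> tuple[SegmentationInput, SyntheticTruth]:
    """Build the BMO ring + ILM grid for a spec, with its analytic truth.

    The BMO ring is 24 points at the 12 radial-scan angles on the tilted
    base plane; the ILM is the paraboloid bowl plus the shear and seeded
    i.i.d. Gaussian height noise. Identical (spec, seed) inputs produce
    bit-identical surfaces.
    """
    a, b = spec.disc_radius_x_mm, spec.disc_radius_y_mm
    fmax = spec.cup_radius_fraction * float(
        _notch_gain(np.array([_SECTOR_CENTER.get(spec.notch_sector or "T", 0.0)]),
                    spec)[0])
    if fmax > 1.0 + 1e-9:
        raise ValidationError("spec produces a cup larger than the disc")
    xe, ye = extent_mm
    if 2 * max(a, b) > min(xe, ye) * 0.9:
        raise ValidationError("disc does not fit the scan area")

    s = math.tan(math.radians(spec.tilt_deg))
    psi = np.arange(24) * 15.0
    cs, sn = np.cos(np.radians(psi)), np.sin(np.radians(psi))
    bx, by = a * cs, b * sn
    bz = 1000.0 * s * bx
    side = np.where((psi > 90.0) & (psi <= 270.0), SIDE_NASAL, SIDE_TEMPORAL)
    bmo = BMOPointSet(
        scan_index=np.arange(24) % 12, side=side,
        x_mm=bx, y_mm=by, z_um=bz, laterality="OD",
    )

    nrow, ncol = grid_shape
    x = np.linspace(-xe / 2.0, xe / 2.0, ncol)
    y = np.linspace(ye / 2.0, -ye / 2.0, nrow)
    xg, yg = np.meshgrid(x, y)
    h = _bowl_heights(spec, xg, yg) + 1000.0 * s * xg
    if spec.noise_sd_um > 0:
        rng = np.random.default_rng(spec.seed)
        h = h + rng.normal(0.0, spec.noise_sd_um, size=h.shape)
    ilm = ILMSurface(heights=h, x_extent_mm=xe, y_extent_mm=ye)
    seg = SegmentationInput(bmo=bmo, ilm=ilm, eye_id=eye_id)
    truth = SyntheticTruth(params=analytic_parameters(spec, truth_rp_um))
    return seg, truth


def _truth_polygons(spec: SyntheticDiscSpec, rp_height_um: float,
                    n_phi: int = 720):
    """Disc and cup boundary polygons in base-plane coordinates (closed form).

    The shear by ``tan(tilt)`` maps the footprint (x, y) of a point at
    height z µm to in-plane coordinates ``u = x/cos(t) + tan(t) z cos(t)/1000``,
    ``v = y``; the cup contour lies on the reference plane where the
    untilted profile equals ``rp_height / cos(t)``.
    """
    t = math.radians(spec.tilt_deg)
    cost = math.cos(t)
    s = math.tan(t)
    a, b = spec.disc_radius_x_mm, spec.disc_radius_y_mm
    f = spec.cup_radius_fraction
    phi = np.linspace(0.0, 360.0, n_phi, endpoint=False)
    cp, sp = np.cos(np.radians(phi)), np.sin(np.radians(phi))

    disc_uv = np.column_stack([a * cp / cost, b * sp])

    h_eff = rp_height_um / cost
    if h_eff >= spec.rim_height_um:
        # reference plane above the rim shelf: cup covers the whole disc
        return disc_uv, disc_uv.copy(), 1.0, h_eff
    rho_star_sq = 1.0 - (spec.rim_height_um - h_eff) / spec.cup_depth_um
    if rho_star_sq <= 0:
        return disc_uv, None, 0.0, h_eff
    rho_star = math.sqrt(rho_star_sq)
    g = _notch_gain(phi, spec)
    cx = f * a * rho_star * g * cp
    cy = spec.decentering_offset_mm + f * b * rho_star * g * sp
    du = s * cost * h_eff / 1000.0  # cup sits on the RP, shifted temporally
    cup_uv = np.column_stack([cx / cost + du, cy])
    return disc_uv, cup_uv, rho_star_sq, h_eff


def analytic_parameters(spec: SyntheticDiscSpec, rp_height_um: float,
                        step_deg: float = 1.0) -> DiscParameters:
    """Noise-free DiscParameters implied by a spec (grid-free closed forms).

    Areas and sector values come from densely sampled closed-form boundary
    curves; depths from the paraboloid's exact integrals (evaluated on a
    fine polar quadrature when the cup is notched/decentred or clipped).
    """
    t = math.radians(spec.tilt_deg)
    cost = math.cos(t)
    disc_uv, cup_uv, rho_star_sq, h_eff = _truth_polygons(spec, rp_height_um)
    disc_poly = Polygon(disc_uv)
    disc_area = disc_poly.area
    flags: list[str] = []

    was_clipped = False
    if cup_uv is None:
        cup_area = 0.0
        cup_poly = None
        flags.append("empty_cup")
    else:
        cup_poly = Polygon(cup_uv)
        if not cup_poly.within(disc_poly):
            was_clipped = True
            clipped = cup_poly.intersection(disc_poly)
            if isinstance(clipped, MultiPolygon):
                clipped = max(clipped.geoms, key=lambda p: p.area)
            cup_poly = clipped
        cup_area = cup_poly.area

    angles = np.arange(0.0, 360.0, step_deg)
    center = np.zeros(2)
    disc_r, _ = _ray_crossings(disc_uv, center, angles)
    if cup_poly is None or cup_poly.is_empty:
        cup_r = np.zeros_like(disc_r)
    else:
        cup_xy = np.asarray(cup_poly.exterior.coords)[:-1]
        cup_r, _ = _ray_crossings(cup_xy, center, angles)
    cup_r = np.clip(cup_r, 0.0, disc_r)

    masks = _sector_masks(angles)
    rd = (disc_r - cup_r) / disc_r
    rd_sector = {name: float(rd[m].mean()) for name, m in masks.items()}
    dth = math.radians(step_deg)
    wedge = 0.5 * (disc_r ** 2 - cup_r ** 2) * dth
    rim_ts, rim_ti = float(wedge[masks["TS"]].sum()), float(wedge[masks["TI"]].sum())
    tot = rim_ts + rim_ti
    if tot == 0:
        decentering = 0.0
        flags.append("degenerate_rim")
    else:
        decentering = (rim_ts - rim_ti) / tot

    max_depth, avg_depth = _truth_depths(spec, rho_star_sq, h_eff, cost,
                                         disc_uv, cup_poly, was_clipped)
    if cup_poly is None or cup_poly.is_empty:
        flags = sorted(set(flags) | {"empty_cup"})

    def extent(r: np.ndarray, ang: float) -> float:
        i = int(round(ang / step_deg)) % len(r)
        j = int(round((ang + 180.0) / step_deg)) % len(r)
        return float(r[i] + r[j])

    dia_h, dia_v = extent(disc_r, 0.0), extent(disc_r, 90.0)
    cd_area = min(cup_area / disc_area, 1.0)
    return DiscParameters(
        disc_area_mm2=disc_area,
        cup_area_mm2=cup_area,
        rim_area_mm2=disc_area - cup_area,
        disc_dia_v_mm=dia_v,
        disc_dia_h_mm=dia_h,
        cd_ratio_v=min(extent(cup_r, 90.0) / dia_v, 1.0),
        cd_ratio_h=min(extent(cup_r, 0.0) / dia_h, 1.0),
        cd_ratio_area=cd_area,
        rd_ratio_area=1.0 - cd_area,
        max_cup_depth_um=max_depth,
        avg_cup_depth_um=avg_depth,
        rd_avg_t=rd_sector["T"],
        rd_avg_ts=rd_sector["TS"],
        rd_avg_ns=rd_sector["NS"],
        rd_avg_n=rd_sector["N"],
        rd_avg_ni=rd_sector["NI"],
        rd_avg_ti=rd_sector["TI"],
        rim_decentering_ratio=decentering,
        disc_angle_h_deg=spec.tilt_deg,
        disc_height_difference_um=0.0,
        rp_height_um=float(rp_height_um),
        flags=tuple(flags),
    ).validate()


def _truth_depths(spec: SyntheticDiscSpec, rho_star_sq: float, h_eff: float,
                  cost: float, disc_uv: np.ndarray, cup_poly,
                  was_clipped: bool = False) -> tuple[float, float]:
    """Exact (max, mean) perpendicular cup depth in µm.

    Unclipped paraboloid: depth(rho) = D (rho*^2 - (rho/g)^2) cos t, whose
    area-weighted mean is exactly half the maximum for any angular gain g.
    When the reference plane is above the rim or the cup is clipped by the
    disc, the mean is evaluated by polar quadrature of the same closed form.
    """
    if cup_poly is None or cup_poly.is_empty:
        return 0.0, 0.0
    D = spec.cup_depth_um
    if h_eff >= spec.rim_height_um:
        # depth field over the whole disc: shelf depth outside the bowl
        max_depth = (h_eff - (spec.rim_height_um - D)) * cost
        mean_depth = _quadrature_mean_depth(spec, h_eff, cost, disc_uv)
        return max_depth, mean_depth
    max_depth = D * rho_star_sq * cost
    if was_clipped:
        return max_depth, _quadrature_mean_depth(spec, h_eff, cost, disc_uv)
    return max_depth, max_depth / 2.0


def _quadrature_mean_depth(spec: SyntheticDiscSpec, h_eff: float, cost: float,
                           disc_uv: np.ndarray) -> float:
    """Area-weighted mean of the closed-form depth over the clipped region."""
    a, b = spec.disc_radius_x_mm, spec.disc_radius_y_mm
    n = 600
    # sample the disc interior on a polar grid of the (untilted) footprint
    rr = (np.arange(n) + 0.5) / n
    phi = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    R, PHI = np.meshgrid(rr, phi)
    x = a * R * np.cos(PHI)
    y = b * R * np.sin(PHI)
    w = R  # polar area element (constant factors cancel in the mean)
    h0 = _bowl_heights(spec, x, y)
    depth = (h_eff - h0) * cost
    inside = depth > 0
    if not inside.any():
        return 0.0
    return float((depth[inside] * w[inside]).sum() / w[inside].sum())


# ---------------------------------------------------------------------------
# Phantom cohorts with covariates (reference-plane selection)
# ---------------------------------------------------------------------------

# Generative link from structure to the clinical covariates, documented so
# the sweep optimum is known: cpRNFLT = 40 + 55 * rim_area(at truth RP) + eps.
CPRNFLT_INTERCEPT = 40.0   # µm
CPRNFLT_SLOPE = 55.0       # µm per mm² of rim
CPRNFLT_NOISE_SD = 3.0     # µm
MD_INTERCEPT = -14.0       # dB
MD_SLOPE = 9.0             # dB per mm² of rim
MD_NOISE_SD = 2.5          # dB

_TILT_SD = {"FI": 2.78, "MY": 3.76, "SS": 2.51, "GE": 3.50}
_AGE = {"FI": (56.3, 12.4), "MY": (58.9, 12.2), "SS": (70.6, 10.9), "GE": (64.3, 9.9)}
_SE = {"FI": (-2.7, 2.7), "MY": (-3.9, 2.4), "SS": (-1.5, 1.9), "GE": (-1.5, 2.4)}
_IOP = {"FI": (12.9, 1.7), "MY": (13.1, 3.5), "SS": (13.0, 2.3), "GE": (13.2, 2.6)}


@dataclass
class CohortEye:
    """One generated eye: spec, surfaces, analytic truth and cohort row."""

    eye_id: str
    spec: SyntheticDiscSpec
    seg: SegmentationInput
    truth: SyntheticTruth
    record: EyeRecord


def _sample_spec(disc_type: str, rng: np.random.Generator,
                 noise_sd_um: float, seed: int) -> SyntheticDiscSpec:
    p = _PRESETS[disc_type]
    size = float(np.exp(rng.normal(0.0, 0.10)))
    aspect = float(np.exp(rng.normal(0.0, 0.04)))
    depth = float(np.clip(p.cup_depth_um * np.exp(rng.normal(0.0, 0.40)),
                          240.0, 2200.0))
    frac = float(np.clip(rng.normal(p.cup_radius_fraction, 0.08), 0.55, 0.97))
    tilt = float(np.clip(rng.normal(p.tilt_deg, _TILT_SD[disc_type]), 0.2, 12.0))
    dec = float(np.clip(rng.normal(p.decentering_offset_mm, 0.020), -0.12, 0.12))
    notch = (float(np.clip(rng.normal(p.notch_depth_fraction, 0.15), 0.0, 0.9))
             if p.notch_sector is not None else 0.0)
    return replace(
        p,
        disc_radius_x_mm=p.disc_radius_x_mm * size * aspect,
        disc_radius_y_mm=p.disc_radius_y_mm * size / aspect,
        cup_depth_um=depth,
        cup_radius_fraction=frac,
        tilt_deg=tilt,
        decentering_offset_mm=dec,
        notch_depth_fraction=notch,
        noise_sd_um=noise_sd_um,
        seed=seed,
    )


def generate_cohort(
    n_per_type: int,
    rp_truth_height_um: float = 120.0,
    seed: int = 0,
    grid_shape: tuple[int, int] = (128, 128),
    noise_sd_um: float = 15.0,
) -> list[CohortEye]:
    """Phantom cohort of the four phenotypes with covariates.

    cpRNFLT and MD are linear in the analytic rim area at
    ``rp_truth_height_um`` plus Gaussian noise (coefficients are the module
    constants), so rim area measured *at that height* is the structural
    quantity the covariates actually reflect — a correlation sweep over
    heights has its optimum there by construction. Per-eye cup depths are
    log-normally dispersed, which decorrelates rim areas measured at other
    heights from the truth-height rim area.
    """
    if n_per_type < 2:
        raise ValidationError("n_per_type must be >= 2")
    ss = np.random.SeedSequence(seed)
    eyes: list[CohortEye] = []
    children = ss.spawn(4 * n_per_type)
    i = 0
    for disc_type in DISC_TYPES:
        for j in range(n_per_type):
            child = children[i]
            i += 1
            rng = np.random.default_rng(child)
            surf_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)
            spec = _sample_spec(disc_type, rng, noise_sd_um, surf_seed)
            eye_id = f"{disc_type}{j:03d}"
            seg, truth = generate_surface(
                spec, grid_shape=grid_shape,
                truth_rp_um=rp_truth_height_um, eye_id=eye_id,
            )
            rim = truth.params.rim_area_mm2
            cp = max(CPRNFLT_INTERCEPT + CPRNFLT_SLOPE * rim
                     + rng.normal(0.0, CPRNFLT_NOISE_SD), 25.0)
            md = MD_INTERCEPT + MD_SLOPE * rim + rng.normal(0.0, MD_NOISE_SD)
            truth.cprnflt_um = cp
            truth.md_db = md
            record = EyeRecord(
                eye_id=eye_id,
                laterality="OD",
                disc_type=disc_type,
                cprnflt_um=cp,
                md_db=md,
                se_d=float(rng.normal(*_SE[disc_type])),
                iop_mmhg=float(rng.normal(*_IOP[disc_type])),
                age_y=float(np.clip(rng.normal(*_AGE[disc_type]), 30, 95)),
                params=truth.params,
            )
            eyes.append(CohortEye(eye_id=eye_id, spec=spec, seg=seg,
                                  truth=truth, record=record))
    return eyes


# ---------------------------------------------------------------------------
# Feature-level cohorts (classification at published effect sizes)
# ---------------------------------------------------------------------------

# Published per-type means/SDs of the measured parameters. Values sampled
# independently would violate the parameter identities (rim = disc - cup,
# R/D = 1 - C/D, max >= avg depth), so a latent-variable sampler generates a
# structurally consistent vector whose *marginals* match these statistics.
_T6 = {
    # name: {type: (mean, sd)}
    "disc_area": {"FI": (2.36, 0.41), "MY": (2.51, 0.79), "SS": (2.52, 0.59), "GE": (2.52, 0.63)},
    "cd_area":   {"FI": (0.63, 0.13), "MY": (0.66, 0.12), "SS": (0.71, 0.14), "GE": (0.75, 0.16)},
    "avg_cup":   {"FI": (330., 128.), "MY": (309., 122.), "SS": (257., 97.),  "GE": (437., 140.)},
    "max_over_avg": {"FI": (1.70, 0.15), "MY": (1.82, 0.15), "SS": (1.86, 0.15), "GE": (1.54, 0.15)},
    "dia_v":     {"FI": (0.90, 0.07), "MY": (0.93, 0.14), "SS": (0.92, 0.12), "GE": (0.91, 0.11)},
    "dia_h":     {"FI": (0.84, 0.09), "MY": (0.86, 0.15), "SS": (0.87, 0.10), "GE": (0.88, 0.12)},
    "cd_v":      {"FI": (0.87, 0.10), "MY": (0.85, 0.13), "SS": (0.87, 0.14), "GE": (0.88, 0.12)},
    "cd_h":      {"FI": (0.85, 0.09), "MY": (0.88, 0.11), "SS": (0.92, 0.09), "GE": (0.92, 0.12)},
    "angle":     {"FI": (3.30, 2.78), "MY": (6.99, 3.76), "SS": (2.95, 2.51), "GE": (2.77, 3.50)},
    "decenter":  {"FI": (0.32, 0.27), "MY": (0.29, 0.32), "SS": (0.31, 0.53), "GE": (0.22, 0.42)},
    "height_diff": {"FI": (260., 59.), "MY": (251., 87.), "SS": (224., 65.), "GE": (224., 51.)},
    "rd_t":      {"FI": (0.11, 0.07), "MY": (0.08, 0.05), "SS": (0.06, 0.06), "GE": (0.06, 0.06)},
    "rd_ts":     {"FI": (0.14, 0.05), "MY": (0.13, 0.07), "SS": (0.09, 0.05), "GE": (0.08, 0.06)},
    "rd_ns":     {"FI": (0.12, 0.06), "MY": (0.13, 0.06), "SS": (0.09, 0.05), "GE": (0.09, 0.07)},
    "rd_n":      {"FI": (0.11, 0.06), "MY": (0.11, 0.06), "SS": (0.10, 0.07), "GE": (0.07, 0.08)},
    "rd_ni":     {"FI": (0.08, 0.05), "MY": (0.09, 0.06), "SS": (0.09, 0.08), "GE": (0.06, 0.07)},
    "rd_ti":     {"FI": (0.08, 0.06), "MY": (0.08, 0.07), "SS": (0.07, 0.08), "GE": (0.06, 0.06)},
}

# Within-type factor loadings. A single "cupping severity" latent drives
# the C/D ratios, cup depths and (negatively) the sector R/D profile within
# each type; a shared per-eye rim factor correlates the six sectors. The
# loadings keep the *marginal* SDs at the published values while
# reproducing the published discriminability (the reported partial
# F-to-enter values of 6.5-24 greatly exceed the marginal four-group ANOVA
# F of the same parameters, which is only possible with exactly this kind
# of within-type correlation).
_SEV_CD = 0.95        # severity loading of the C/D area ratio
_SEV_DEPTH = 0.94     # severity loading of the average cup depth
_SEV_CDVH = 0.88      # severity loading of the linear C/D ratios
_SEV_RD = -0.60       # severity loading of the sector R/D averages
_RD_EYE = 0.75        # shared per-eye rim-factor loading of the sectors
_RATIO_SD = 0.095      # SD of the max/avg depth ratio (type means above)
_DEC_COUPLING = 2.0   # decentering response to the (TS - TI) contrast


def sample_disc_parameters(disc_type: str, rng: np.random.Generator) -> DiscParameters:
    """One structurally consistent DiscParameters draw for a disc type.

    A per-eye cupping-severity latent moves the C/D ratios and cup depths
    up and the sector R/D averages down together; the maximum cup depth is
    the average times a type-typical shape ratio; the disc area, tilt
    (log-normal) and height difference are independent. Derived identities
    hold exactly: cup = disc x C/D, rim = disc - cup, R/D = 1 - C/D.
    Marginal means and SDs match the published per-type statistics up to
    clipping effects.
    """
    if disc_type not in DISC_TYPES:
        raise ValidationError(f"unknown disc type {disc_type!r}")

    def ms(name: str) -> tuple[float, float]:
        return _T6[name][disc_type]

    u = rng.normal()  # cupping severity within the type

    def load(name: str, loading: float) -> float:
        m, sd = ms(name)
        resid = math.sqrt(max(1.0 - loading ** 2, 0.0))
        return m + sd * (loading * u + resid * rng.normal())

    cd = float(np.clip(load("cd_area", _SEV_CD), 0.20, 0.97))
    disc = float(np.clip(rng.normal(*ms("disc_area")), 1.2, 4.5))
    cup = disc * cd
    rim = disc - cup

    avg = float(np.clip(load("avg_cup", _SEV_DEPTH), 60.0, 900.0))
    ratio = float(np.clip(rng.normal(ms("max_over_avg")[0], _RATIO_SD), 1.05, 2.6))
    max_depth = avg * ratio

    def lognormal_from(mean: float, sd: float) -> float:
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return float(np.exp(rng.normal(mu, math.sqrt(sigma2))))

    angle = lognormal_from(*ms("angle"))

    eye_rim = rng.normal()
    rd = {}
    rd_resid = math.sqrt(max(1.0 - _SEV_RD ** 2 - _RD_EYE ** 2, 0.0))
    for sec in ("t", "ts", "ns", "n", "ni", "ti"):
        m, sd = ms(f"rd_{sec}")
        rd[sec] = float(np.clip(
            m + sd * (_SEV_RD * u + _RD_EYE * eye_rim + rd_resid * rng.normal()),
            0.0, 1.0))

    m, sd = ms("decenter")
    dec = float(np.clip(
        m + _DEC_COUPLING * ((rd["ts"] - ms("rd_ts")[0]) - (rd["ti"] - ms("rd_ti")[0]))
        + rng.normal(0.0, 0.40 * sd), -1.0, 1.0))

    cd_v = float(np.clip(load("cd_v", _SEV_CDVH), 0.05, 1.0))
    cd_h = float(np.clip(load("cd_h", _SEV_CDVH), 0.05, 1.0))

    return DiscParameters(
        disc_area_mm2=disc,
        cup_area_mm2=cup,
        rim_area_mm2=rim,
        disc_dia_v_mm=float(np.clip(rng.normal(*ms("dia_v")), 0.3, 2.0)),
        disc_dia_h_mm=float(np.clip(rng.normal(*ms("dia_h")), 0.3, 2.0)),
        cd_ratio_v=cd_v,
        cd_ratio_h=cd_h,
        cd_ratio_area=cd,
        rd_ratio_area=1.0 - cd,
        max_cup_depth_um=max_depth,
        avg_cup_depth_um=avg,
        rd_avg_t=rd["t"],
        rd_avg_ts=rd["ts"],
        rd_avg_ns=rd["ns"],
        rd_avg_n=rd["n"],
        rd_avg_ni=rd["ni"],
        rd_avg_ti=rd["ti"],
        rim_decentering_ratio=dec,
        disc_angle_h_deg=angle,
        disc_height_difference_um=float(np.clip(rng.normal(*ms("height_diff")),
                                                0.0, 600.0)),
        rp_height_um=120.0,
        flags=(),
    ).validate()


def make_classification_cohort(n_per_type: int, seed: int = 0,
                               prefix: str = "C") -> list[EyeRecord]:
    """Labelled feature-level cohort at the published per-type statistics."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    records = []
    for disc_type in DISC_TYPES:
        for j in range(n_per_type):
            params = sample_disc_parameters(disc_type, rng)
            records.append(EyeRecord(
                eye_id=f"{prefix}-{disc_type}{j:03d}",
                disc_type=disc_type,
                params=params,
            ))
    return records


def make_stepwise_problem(
    n_per_type: int = 18,
    n_noise: int = 14,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str], list[str]]:
    """Controlled feature-selection experiment: 6 signal + ``n_noise`` null.

    Six informative features carry orthogonal-contrast class-mean patterns
    with non-centralities calibrated to the strong partial-F range reported
    for the leading discriminators (F-to-enter ≈ 6.5–24 at n = 18/type);
    noise features are i.i.d. standard normal in every class. Returns
    (X, y, informative_names, noise_names).
    """
    f_targets = [24.0, 17.92, 12.0, 10.0, 8.51, 6.50]
    contrasts = np.array([
        [1, 1, -1, -1],
        [1, -1, 1, -1],
        [1, -1, -1, 1],
        [1, 1, -1, -1],
        [1, -1, 1, -1],
        [1, -1, -1, 1],
    ], dtype=float) / 2.0  # unit-norm class contrasts
    g = 4
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = np.repeat(np.array(DISC_TYPES, dtype=object), n_per_type)
    n = len(y)
    cls_idx = np.repeat(np.arange(g), n_per_type)
    cols = {}
    informative = []
    for i, (F, contrast) in enumerate(zip(f_targets, contrasts)):
        scale = math.sqrt((F - 1.0) * (g - 1.0) / n_per_type)
        means = scale * contrast
        name = f"signal_{i+1}"
        informative.append(name)
        cols[name] = means[cls_idx] + rng.normal(0.0, 1.0, size=n)
    noise = []
    for i in range(n_noise):
        name = f"noise_{i+1}"
        noise.append(name)
        cols[name] = rng.normal(0.0, 1.0, size=n)
    return pd.DataFrame(cols), y, informative, noise
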