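"""Shared fixtures: analytic phantoms with closed-form expectations."""

from __future__ import annotations

import numpy as np
import pytest

from onhmorph import BMOPointSet, ILMSurface, SegmentationInput


def circle_bmo(radius: float = 0.9, z_um=None, n: int = 24) -> BMOPointSet:
    """BMO ring of n points on a circle (flat unless z_um is given)."""
    psi = np.arange(n) * (360.0 / n)
    x = radius * np.cos(np.radians(psi))
    y = radius * np.sin(np.radians(psi))
    z = np.zeros(n) if z_um is None else np.asarray(z_um, dtype=float)
    side = np.where((psi > 90) & (psi <= 270), "nasal-half", "temporal-half")
    return BMOPointSet(scan_index=np.arange(n) % 12, side=side,
                       x_mm=x, y_mm=y, z_um=z)


def ilm_from_function(fn, shape=(256, 512), extent=(6.0, 6.0)) -> ILMSurface:
    """ILM grid sampled from a height function h(x, y) in µm."""
    ye, xe = extent[1], extent[0]
    x = np.linspace(-xe / 2, xe / 2, shape[1])
    y = np.linspace(ye / 2, -ye / 2, shape[0])
    xg, yg = np.meshgrid(x, y)
    return ILMSurface(heights=fn(xg, yg), x_extent_mm=xe, y_extent_mm=ye)


@pytest.fixture(scope="session")
def paraboloid_seg() -> SegmentationInput:
    """The analytic reference phantom: BMO circle R = 0.9 mm on z = 0 with
    ILM h(r) = 600 (r/0.9)^2 − 400 µm on the full 512 × 256 device raster.

    At a 120 µm reference plane the closed forms are: cup radius
    0.9·sqrt(520/600) = 0.83785 mm, disc area 2.5447 mm², cup area
    2.2050 mm², C/D area 0.8667, max depth 520 µm, mean depth 260 µm,
    sector r/d 0.06906 everywhere, zero decentering/angle/height diff.
    """
    ilm = ilm_from_function(
        lambda x, y: 600.0 * (np.hypot(x, y) / 0.9) ** 2 - 400.0
    )
    return SegmentationInput(bmo=circle_bmo(), ilm=ilm, eye_id="paraboloid")


PARABOLOID_EXPECTED = {
    "disc_area_mm2": np.pi * 0.81,
    "cup_area_mm2": np.pi * 0.81 * 520.0 / 600.0,
    "rim_area_mm2": np.pi * 0.81 * 80.0 / 600.0,
    "disc_dia_v_mm": 1.8,
    "disc_dia_h_mm": 1.8,
    "cd_ratio_v": np.sqrt(520.0 / 600.0),
    "cd_ratio_h": np.sqrt(520.0 / 600.0),
    "cd_ratio_area": 520.0 / 600.0,
    "rd_ratio_area": 80.0 / 600.0,
    "max_cup_depth_um": 520.0,
    "avg_cup_depth_um": 260.0,
    "rd_avg_t": 1.0 - np.sqrt(520.0 / 600.0),
    "rd_avg_ts": 1.0 - np.sqrt(520.0 / 600.0),
    "rd_avg_ns": 1.0 - np.sqrt(520.0 / 600.0),
    "rd_avg_n": 1.0 - np.sqrt(520.0 / 600.0),
    "rd_avg_ni": 1.0 - np.sqrt(520.0 / 600.0),
    "rd_avg_ti": 1.0 - np.sqrt(520.0 / 600.0),
    "rim_decentering_ratio": 0.0,
    "disc_angle_h_deg": 0.0,
    "disc_height_difference_um": 0.0,
}
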