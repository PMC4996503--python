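"""Domain types for BMO-referenced optic nerve head morphometry.

Coordinate convention (after right-eye normalization):

* ``x`` — horizontal, millimetres, temporal positive;
* ``y`` — vertical, millimetres, superior positive;
* ``z`` — axial, micrometres, increasing anteriorly (toward the vitreous),
  so "the reference plane sits *above* the base plane" is a positive
  z-offset.

Left-eye (OS) inputs are mirrored about the vertical axis into OD
orientation on ingest, so every downstream angle and sector label can be
interpreted in a single orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as _dc_fields
from typing import Optional

import numpy as np

__all__ = [
    "DISC_TYPES",
    "SIDE_TEMPORAL",
    "SIDE_NASAL",
    "PARAMETER_NAMES",
    "ValidationError",
    "BMOPointSet",
    "ILMSurface",
    "SegmentationInput",
    "DiscParameters",
    "EyeRecord",
]

#: Fixed label order; also the deterministic tie-break order for classifiers.
DISC_TYPES = ("FI", "GE", "MY", "SS")

SIDE_TEMPORAL = "temporal-half"
SIDE_NASAL = "nasal-half"


class ValidationError(ValueError):
    """An input failed a domain-type invariant."""


@dataclass
class BMOPointSet:
    """Marked Bruch's membrane opening edge points from 12 radial B-scans.

    Parameters
    ----------
    scan_index
        Radial B-scan index, 0–11. Scan ``k`` is oriented at ``k * 15``
        degrees from horizontal; scan 0 is the horizontal scan.
    side
        ``"temporal-half"`` or ``"nasal-half"`` — which half of the radial
        scan the mark came from.
    x_mm, y_mm
        En-face position (mm), disc-centred.
    z_um
        Axial position (µm, anterior positive).
    laterality
        ``"OD"`` or ``"OS"``. Geometric code assumes OD orientation; use
        :func:`onhmorph.io.mirror_to_od` for OS inputs.
    """

    scan_index: np.ndarray
    side: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    z_um: np.ndarray
    laterality: str = "OD"
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.scan_index = np.asarray(self.scan_index, dtype=int)
        self.side = np.asarray(self.side, dtype=object)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        n = self.x_mm.size
        if n < 3:
            raise ValidationError(f"need >=3 BMO points, got {n}")
        for name in ("scan_index", "side", "y_mm", "z_um"):
            if getattr(self, name).size != n:
                raise ValidationError("BMO point columns have unequal length")
        if not (np.isfinite(self.x_mm).all() and np.isfinite(self.y_mm).all()
                and np.isfinite(self.z_um).all()):
            raise ValidationError("BMO coordinates must be finite")
        if self.laterality not in ("OD", "OS"):
            raise ValidationError(f"laterality must be OD or OS, got {self.laterality!r}")
        bad = set(self.side) - {SIDE_TEMPORAL, SIDE_NASAL}
        if bad:
            raise ValidationError(f"unknown BMO side labels: {sorted(bad)}")
        if np.any(self.scan_index < 0) or np.any(self.scan_index > 11):
            raise ValidationError("scan_index must be in 0..11")

    def __len__(self) -> int:
        return int(self.x_mm.size)

    def points_mm(self) -> np.ndarray:
        """All points as an (n, 3) array with *z converted to mm*."""
        return np.column_stack([self.x_mm, self.y_mm, self.z_um / 1000.0])


@dataclass
class ILMSurface:
    """Segmented inner limiting membrane height map on a regular grid.

    ``heights`` is row-major with row 0 at the superior edge; columns run
    nasal→temporal... strictly: column 0 at x = -x_extent/2. Heights are in
    µm, larger = more anterior. Grid is pixel-node sampled: node (r, c) sits
    at ``y = y_extent/2 - r*dy``, ``x = -x_extent/2 + c*dx``.
    """

    heights: np.ndarray
    x_extent_mm: float = 6.0
    y_extent_mm: float = 6.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValidationError("ILM heights must be a 2-D grid")
        if min(self.heights.shape) < 16:
            raise ValidationError("ILM grid must be at least 16x16")
        if not np.isfinite(self.heights).all():
            raise ValidationError("ILM heights must all be finite")
        if not (self.x_extent_mm > 0 and self.y_extent_mm > 0):
            raise ValidationError("ILM extents must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def x_coords(self) -> np.ndarray:
        n = self.heights.shape[1]
        return np.linspace(-self.x_extent_mm / 2.0, self.x_extent_mm / 2.0, n)

    def y_coords(self) -> np.ndarray:
        """Row-aligned y coordinates (descending: row 0 is superior)."""
        n = self.heights.shape[0]
        return np.linspace(self.y_extent_mm / 2.0, -self.y_extent_mm / 2.0, n)

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((np.abs(x) <= self.x_extent_mm / 2.0 + 1e-12)
                & (np.abs(y) <= self.y_extent_mm / 2.0 + 1e-12))

    def interpolator(self):
        """Bilinear interpolator h(x, y) in µm over the grid extent."""
        from scipy.interpolate import RegularGridInterpolator

        y = self.y_coords()[::-1]  # ascending for the interpolator
        h = self.heights[::-1, :]
        return RegularGridInterpolator(
            (y, self.x_coords()), h, method="linear", bounds_error=True
        )


@dataclass
class SegmentationInput:
    """Everything needed to quantify one eye: BMO marks + ILM surface."""

    bmo: BMOPointSet
    ilm: ILMSurface
    eye_id: str = ""

    def __post_init__(self) -> None:
        inside = self.ilm.contains_xy(self.bmo.x_mm, self.bmo.y_mm)
        if not inside.all():
            bad = np.flatnonzero(~inside).tolist()
            raise ValidationError(
                f"BMO points at indices {bad} fall outside the ILM grid extent"
            )


#: The 20 quantified morphometric parameters, in canonical report order.
PARAMETER_NAMES = (
    "disc_area_mm2",
    "cup_area_mm2",
    "rim_area_mm2",
    "disc_dia_v_mm",
    "disc_dia_h_mm",
    "cd_ratio_v",
    "cd_ratio_h",
    "cd_ratio_area",
    "rd_ratio_area",
    "max_cup_depth_um",
    "avg_cup_depth_um",
    "rd_avg_t",
    "rd_avg_ts",
    "rd_avg_ns",
    "rd_avg_n",
    "rd_avg_ni",
    "rd_avg_ti",
    "rim_decentering_ratio",
    "disc_angle_h_deg",
    "disc_height_difference_um",
)


@dataclass
class DiscParameters:
    """The 20 morphometric disc parameters quantified for one eye.

    Areas in mm², diameters in mm, depths and heights in µm, the horizontal
    disc angle in degrees; all ratios are dimensionless. ``rp_height_um``
    records the reference-plane height the cup-dependent values were
    computed at (provenance, not a 21st parameter). ``flags`` carries
    warnings for degenerate geometry (``"empty_cup"``, ``"degenerate_rim"``).
    """

    disc_area_mm2: float
    cup_area_mm2: float
    rim_area_mm2: float
    disc_dia_v_mm: float
    disc_dia_h_mm: float
    cd_ratio_v: float
    cd_ratio_h: float
    cd_ratio_area: float
    rd_ratio_area: float
    max_cup_depth_um: float
    avg_cup_depth_um: float
    rd_avg_t: float
    rd_avg_ts: float
    rd_avg_ns: float
    rd_avg_n: float
    rd_avg_ni: float
    rd_avg_ti: float
    rim_decentering_ratio: float
    disc_angle_h_deg: float
    disc_height_difference_um: float
    rp_height_um: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAMETER_NAMES], dtype=float)

    def validate(self) -> "DiscParameters":
        d = self
        if not all(np.isfinite(v) for v in d.as_dict().values()):
            raise ValidationError("non-finite disc parameter")
        if min(d.disc_area_mm2, d.cup_area_mm2, d.rim_area_mm2) < 0:
            raise ValidationError("areas must be non-negative")
        if d.disc_area_mm2 > 0:
            resid = abs(d.rim_area_mm2 - (d.disc_area_mm2 - d.cup_area_mm2))
            if resid > 0.005 * d.disc_area_mm2:
                raise ValidationError(
                    f"rim+cup vs disc area mismatch: {resid:.3g} mm2"
                )
        for name in ("cd_ratio_v", "cd_ratio_h", "cd_ratio_area", "rd_ratio_area"):
            v = getattr(d, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if abs(d.rd_ratio_area - (1.0 - d.cd_ratio_area)) > 1e-6:
            raise ValidationError("rd_ratio_area must equal 1 - cd_ratio_area")
        if d.max_cup_depth_um < 0 or d.avg_cup_depth_um < 0:
            raise ValidationError("cup depths must be non-negative")
        if not -1.0 - 1e-12 <= d.rim_decentering_ratio <= 1.0 + 1e-12:
            raise ValidationError("rim_decentering_ratio outside [-1, 1]")
        for name in ("rd_avg_t", "rd_avg_ts", "rd_avg_ns", "rd_avg_n",
                     "rd_avg_ni", "rd_avg_ti"):
            if getattr(d, name) < -1e-12:
                raise ValidationError(f"{name} must be non-negative")
        if d.rp_height_um <= 0:
            raise ValidationError("rp_height_um must be positive")
        return d


@dataclass
class EyeRecord:
    """One cohort row: disc parameters joined with clinical covariates.

    Optional fields are ``None`` when absent (never silently zero).
    """

    eye_id: str
    laterality: Optional[str] = None
    disc_type: Optional[str] = None
    cprnflt_um: Optional[float] = None
    md_db: Optional[float] = None
    se_d: Optional[float] = None
    iop_mmhg: Optional[float] = None
    age_y: Optional[float] = None
    params: Optional[DiscParameters] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.disc_type is not None and self.disc_type not in DISC_TYPES:
            raise ValidationError(
                f"eye {self.eye_id!r}: unknown disc type {self.disc_type!r}"
            )
        if self.cprnflt_um is not None and not self.cprnflt_um > 0:
            raise ValidationError(
                f"eye {self.eye_id!r}: cpRNFLT must be positive when present"
            )

    def feature(self, name: str) -> float:
        """Look up a disc parameter or covariate by column name."""
        if self.params is not None and name in PARAMETER_NAMES:
            return float(getattr(self.params, name))
        if hasattr(self, name) and getattr(self, name) is not None:
            return float(getattr(self, name))
        raise KeyError(f"eye {self.eye_id!r} has no feature {name!r}")
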