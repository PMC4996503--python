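"""Reference-plane-height selection.

The cup — and therefore the rim area — depends on how high above the BMO
base plane the reference plane (RP) is set. The selection procedure sweeps
candidate heights (60–180 µm in 30 µm steps), correlates rim area with
cpRNFLT (and MD) per height overall and per disc type, and tests per height
whether rim area is influenced by disc type once cpRNFLT is accounted for.
The chosen height maximises the overall structural correlation among
heights where the disc-type effect is non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .synthetic import CohortEye
from .types import DISC_TYPES, EyeRecord, ValidationError

__all__ = [
    "CorrelationResult",
    "SweepResult",
    "RegressionResult",
    "pearson",
    "quantify_cohort",
    "rp_sweep",
    "type_influence_regression",
    "select_height",
    "DEFAULT_HEIGHTS",
]

DEFAULT_HEIGHTS = (60.0, 90.0, 120.0, 150.0, 180.0)

#: strata evaluated in the sweep: pooled plus the four phenotypes
STRATA = ("all",) + DISC_TYPES


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError("correlation outside [-1, 1]")
        if self.n < 3:
            raise ValidationError("correlation needs n >= 3")


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson needs two equal-length vectors")
    if x.size < 3:
        raise ValidationError("pearson needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=int(x.size))


@dataclass
class SweepResult:
    """Correlation grid: height × stratum × response → CorrelationResult."""

    heights: tuple[float, ...]
    cells: dict[tuple[float, str, str], Optional[CorrelationResult]]
    responses: tuple[str, ...] = ("cprnflt_um", "md_db")

    def r(self, height: float, stratum: str = "all",
          response: str = "cprnflt_um") -> Optional[float]:
        cell = self.cells.get((height, stratum, response))
        return None if cell is None else cell.r

    def best_height(self, stratum: str = "all",
                    response: str = "cprnflt_um") -> tuple[Optional[float], bool]:
        """(argmax height, tie flag) for one stratum/response; None if empty."""
        rs = [(h, self.r(h, stratum, response)) for h in self.heights]
        rs = [(h, r) for h, r in rs if r is not None]
        if not rs:
            return None, False
        rmax = max(r for _, r in rs)
        winners = [h for h, r in rs if abs(r - rmax) <= 1e-12]
        return winners[0], len(winners) > 1

    def to_frame(self, response: str = "cprnflt_um") -> pd.DataFrame:
        rows = []
        for h in self.heights:
            row: dict = {"rp_height_um": h}
            for stratum in STRATA:
                cell = self.cells.get((h, stratum, response))
                row[f"r_{stratum}"] = np.nan if cell is None else cell.r
                row[f"p_{stratum}"] = np.nan if cell is None else cell.p_value
            rows.append(row)
        return pd.DataFrame(rows)


def quantify_cohort(eyes: Iterable[CohortEye],
                    heights: Sequence[float] = DEFAULT_HEIGHTS,
                    step_deg: float = 1.0) -> dict[float, list[EyeRecord]]:
    """Quantify every eye at every height (shared plane fit per eye).

    Returns ``{height: [EyeRecord with measured params], ...}`` with the
    covariates copied from the cohort rows.
    """
    out: dict[float, list[EyeRecord]] = {float(h): [] for h in heights}
    for eye in eyes:
        by_height = geometry.quantify_disc_multi(eye.seg, list(out), step_deg=step_deg)
        for h, params in by_height.items():
            rec = EyeRecord(
                eye_id=eye.record.eye_id,
                laterality=eye.record.laterality,
                disc_type=eye.record.disc_type,
                cprnflt_um=eye.record.cprnflt_um,
                md_db=eye.record.md_db,
                se_d=eye.record.se_d,
                iop_mmhg=eye.record.iop_mmhg,
                age_y=eye.record.age_y,
                params=params,
            )
            out[h].append(rec)
    return out


def rp_sweep(quantified: dict[float, list[EyeRecord]],
             heights: Optional[Sequence[float]] = None,
             responses: Sequence[str] = ("cprnflt_um", "md_db")) -> SweepResult:
    """Correlation grid of rim area vs each response, per height and stratum.

    Strata with fewer than 3 usable eyes (or a constant vector) are flagged
    not-computed (``None`` cells).
    """
    if heights is None:
        heights = sorted(quantified)
    heights = tuple(float(h) for h in heights)
    if not heights:
        raise ValidationError("empty sweep: no heights")
    cells: dict[tuple[float, str, str], Optional[CorrelationResult]] = {}
    for h in heights:
        records = quantified.get(h)
        if records is None:
            raise ValidationError(f"no quantifications at height {h}")
        for stratum in STRATA:
            sub = [r for r in records
                   if stratum == "all" or r.disc_type == stratum]
            for response in responses:
                pairs = [(r.params.rim_area_mm2, getattr(r, response))
                         for r in sub
                         if r.params is not None and getattr(r, response) is not None]
                key = (h, stratum, response)
                if len(pairs) < 3:
                    cells[key] = None
                    continue
                rim, resp = map(np.asarray, zip(*pairs))
                try:
                    cells[key] = pearson(rim, resp)
                except ValidationError:
                    cells[key] = None
    return SweepResult(heights=heights, cells=cells,
                       responses=tuple(responses))


@dataclass
class RegressionResult:
    """OLS of rim area on cpRNFLT + disc type (3-df factor block).

    ``terms`` maps predictor → (F, p); ``cv_pct`` is the residual
    coefficient of variation, 100·RMSE/mean(rim area).
    """

    terms: dict[str, tuple[float, float]]
    r_squared: float
    cv_pct: float
    n: int
    height_um: Optional[float] = None
    field_names: tuple[str, ...] = field(default=("cprnflt_um", "disc_type"))

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError("R^2 outside [0, 1]")
        for name, (f, _) in self.terms.items():
            if f < 0:
                raise ValidationError(f"negative F for {name}")

    @property
    def type_p_value(self) -> float:
        return self.terms["disc_type"][1]


def type_influence_regression(records: Sequence[EyeRecord],
                              height_um: Optional[float] = None) -> RegressionResult:
    """Partial-F test of cpRNFLT and the disc-type factor on rim area.

    Fits ``rim_area ~ cpRNFLT + C(disc_type)`` by OLS (FI is the reference
    level; the factor is tested as a single 3-df block) and reports partial
    F and p per term, the model R², and the residual CV.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = [
        {"rim": r.params.rim_area_mm2, "cprnflt": r.cprnflt_um, "dtype": r.disc_type}
        for r in records
        if r.params is not None and r.cprnflt_um is not None and r.disc_type is not None
    ]
    df = pd.DataFrame(rows)
    types_present = sorted(df["dtype"].unique()) if len(df) else []
    if len(types_present) < 2:
        raise ValidationError("regression needs >= 2 disc types present")
    k = 1 + (len(types_present) - 1)
    if len(df) <= k + 2:
        raise ValidationError("too few records for the regression")
    if np.ptp(df["rim"].to_numpy()) == 0:
        raise ValidationError("degenerate response: rim area is constant")
    if np.ptp(df["cprnflt"].to_numpy()) == 0:
        raise ValidationError("rank-deficient design: cpRNFLT is constant")

    model = smf.ols("rim ~ cprnflt + C(dtype)", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValidationError("rank-deficient design matrix (aliased columns)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    f_type = float(table.loc["C(dtype)", "F"])
    p_type = float(table.loc["C(dtype)", "PR(>F)"])
    f_cp = float(table.loc["cprnflt", "F"])
    p_cp = float(table.loc["cprnflt", "PR(>F)"])
    rmse = float(np.sqrt(model.mse_resid))
    cv = 100.0 * rmse / float(df["rim"].mean())
    return RegressionResult(
        terms={"cprnflt_um": (f_cp, p_cp), "disc_type": (f_type, p_type)},
        r_squared=float(model.rsquared),
        cv_pct=cv,
        n=len(df),
        height_um=height_um,
    )


def select_height(sweep: SweepResult,
                  regressions: dict[float, RegressionResult],
                  alpha: float = 0.05) -> tuple[float, bool]:
    """Pick the RP height: max overall correlation among type-independent heights.

    Among heights whose disc-type block p-value is >= ``alpha`` (type does
    not significantly influence rim area), return the one maximising the
    overall rim–cpRNFLT correlation; ties go to the smallest height. If no
    height qualifies, return the global argmax with a warning flag.
    Returns ``(height, fallback_used)``.
    """
    heights = [h for h in sweep.heights if h in regressions]
    if not heights:
        raise ValidationError("empty sweep or no regressions supplied")
    usable = [(h, sweep.r(h, "all", "cprnflt_um")) for h in heights]
    usable = [(h, r) for h, r in usable if r is not None]
    if not usable:
        raise ValidationError("no computable overall correlations")
    qualifying = [(h, r) for h, r in usable
                  if regressions[h].type_p_value >= alpha]
    if qualifying:
        rmax = max(r for _, r in qualifying)
        winners = sorted(h for h, r in qualifying if abs(r - rmax) <= 1e-12)
        return winners[0], False
    warnings.warn("no height free of disc-type influence; "
                  "falling back to the global correlation argmax")
    rmax = max(r for _, r in usable)
    winners = sorted(h for h, r in usable if abs(r - rmax) <= 1e-12)
    return winners[0], True
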