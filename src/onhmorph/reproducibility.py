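"""Measurement reliability via intraclass correlation coefficients.

Two testers independently marking the BMO and ILM for the same eyes (or
one tester twice) yield paired quantifications per parameter; agreement is
summarised by ANOVA-based single-measure ICCs:

* inter-rater — ICC(2,1), two-way random effects, absolute agreement
  (a systematic offset between raters counts against agreement);
* intra-rater — ICC(3,1), two-way mixed effects, consistency (a constant
  per-session offset is ignored).

Single-measure forms are used throughout because a clinical reading is a
single measurement, not a rater average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DiscParameters, PARAMETER_NAMES, ValidationError

__all__ = ["IccResult", "icc", "reproducibility_report", "ICC_FORMS"]

ICC_FORMS = ("two-way-random-absolute", "two-way-mixed-consistency")
_FORM_ALIASES = {
    "two-way-random-absolute": "two-way-random-absolute",
    "icc2": "two-way-random-absolute",
    "inter": "two-way-random-absolute",
    "two-way-mixed-consistency": "two-way-mixed-consistency",
    "icc3": "two-way-mixed-consistency",
    "intra": "two-way-mixed-consistency",
}


@dataclass(frozen=True)
class IccResult:
    icc: float
    var_subject: float
    var_rater: float
    var_error: float
    form: str
    n_subjects: int
    n_raters: int

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValidationError("ICC cannot exceed 1")


def icc(table: np.ndarray, form: str = "two-way-random-absolute") -> IccResult:
    """Single-measure ICC from a subjects × raters (or repeats) table.

    Two-way ANOVA mean squares: with n subjects and k columns,
    ``MSR`` between subjects, ``MSC`` between columns, ``MSE`` residual,

    * ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    * ICC(3,1) = (MSR − MSE) / (MSR + (k−1)·MSE)

    Variance components are the ANOVA estimators σ²ₛ = (MSR − MSE)/k,
    σ²ᵣ = (MSC − MSE)/n, σ²ₑ = MSE (reported unclipped).
    """
    if form not in _FORM_ALIASES:
        raise ValidationError(f"unknown ICC form {form!r}")
    form = _FORM_ALIASES[form]
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings table must be 2-D (subjects x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 raters/repeats")
    if not np.isfinite(x).all():
        raise ValidationError("ratings table contains missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_rows <= 0 or np.ptp(x) == 0:
        raise ValidationError("ICC undefined: no between-subject variance")

    if form == "two-way-random-absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom <= 0:
        raise ValidationError("ICC undefined: non-positive denominator")
    value = (msr - mse) / denom
    return IccResult(
        icc=float(value),
        var_subject=float((msr - mse) / k),
        var_rater=float((msc - mse) / n),
        var_error=float(mse),
        form=form,
        n_subjects=n,
        n_raters=k,
    )


def reproducibility_report(
    ratings_a: Mapping[str, DiscParameters],
    ratings_b: Mapping[str, DiscParameters],
    mode: str = "inter",
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-parameter ICC table from paired quantifications of the same eyes.

    ``mode`` is ``"inter"`` (two raters, ICC(2,1)) or ``"intra"`` (two
    repeats of one rater, ICC(3,1)). Rows flag parameters whose ICC falls
    below ``threshold``. The two mappings must cover the same eyes at the
    same reference-plane height.
    """
    if mode not in ("inter", "intra"):
        raise ValidationError("mode must be 'inter' or 'intra'")
    only_a = sorted(set(ratings_a) - set(ratings_b))
    only_b = sorted(set(ratings_b) - set(ratings_a))
    if only_a or only_b:
        raise ValidationError(
            f"mismatched eye sets: missing from B {only_a}, missing from A {only_b}"
        )
    eyes = sorted(ratings_a)
    if len(eyes) < 2:
        raise ValidationError("need >= 2 eyes")
    rp = {round(ratings_a[e].rp_height_um, 6) for e in eyes} | {
        round(ratings_b[e].rp_height_um, 6) for e in eyes}
    if len(rp) != 1:
        raise ValidationError("all quantifications must share one RP height")

    form = "icc2" if mode == "inter" else "icc3"
    rows = []
    for name in PARAMETER_NAMES:
        col_a = np.array([getattr(ratings_a[e], name) for e in eyes])
        col_b = np.array([getattr(ratings_b[e], name) for e in eyes])
        try:
            res = icc(np.column_stack([col_a, col_b]), form=form)
            value = res.icc
            note = ""
        except ValidationError as exc:
            value, note = np.nan, str(exc)
        rows.append({
            "parameter": name,
            "icc": value,
            "form": _FORM_ALIASES[form],
            "n_subjects": len(eyes),
            "below_threshold": bool(np.isfinite(value) and value < threshold),
            "note": note,
        })
    return pd.DataFrame(rows)
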