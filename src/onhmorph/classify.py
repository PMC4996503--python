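"""Objective disc-type classification.

Feature selection is the classic Wilks'-lambda stepwise discriminant
procedure: at each step the candidate with the largest partial F
(lambda-ratio statistic) enters if its p-value clears ``alpha_enter``, then
any included feature whose partial F falls above ``alpha_remove`` is
removed; iterate to a fixed point. The classifier is 4-class linear
discriminant analysis with a pooled within-class covariance: posterior
probability of each type via normalised Gaussian likelihood × prior, and
the highest posterior decides the type.

Note the published procedure calls the selection a "stepwise regression";
because the outcome is the categorical disc type it is implemented here as
stepwise *discriminant* analysis (partial-F thresholds exposed, since the
original thresholds were not reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DISC_TYPES, EyeRecord, PARAMETER_NAMES, ValidationError

__all__ = [
    "StepwiseResult",
    "DiscTypeModel",
    "Evaluation",
    "stepwise_select",
    "fit_lda",
    "classify_eyes",
    "cohen_kappa",
    "auc_one_vs_rest",
    "evaluate",
    "feature_frame",
]


def feature_frame(records: Sequence[EyeRecord],
                  features: Sequence[str] = PARAMETER_NAMES) -> tuple[pd.DataFrame, np.ndarray]:
    """(X, y) from cohort records; y entries are None where unlabelled."""
    rows, labels = [], []
    for r in records:
        if r.params is None:
            raise ValidationError(f"eye {r.eye_id!r} has no parameters")
        rows.append({f: r.feature(f) for f in features})
        labels.append(r.disc_type)
    return pd.DataFrame(rows, index=[r.eye_id for r in records]), np.array(labels, dtype=object)


# ---------------------------------------------------------------------------
# Stepwise discriminant selection
# ---------------------------------------------------------------------------


@dataclass
class StepwiseStep:
    action: str          # "enter" | "remove"
    feature: str
    f_value: float
    p_value: float
    wilks_lambda: float  # lambda of the selected set after the action


@dataclass
class StepwiseResult:
    selected: list[str]
    history: list[StepwiseStep]
    entry_stats: dict[str, tuple[float, float]]  # feature -> (F, p) at entry

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValidationError("a feature was selected twice")


def _scatter(X: np.ndarray, y_codes: np.ndarray, g: int) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    Xc = X - mean
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for k in range(g):
        Xk = X[y_codes == k]
        Xkc = Xk - Xk.mean(axis=0)
        W += Xkc.T @ Xkc
    return W, T


def _wilks(X: np.ndarray, y_codes: np.ndarray, g: int) -> float:
    W, T = _scatter(X, y_codes, g)
    sw, ldw = np.linalg.slogdet(W)
    st, ldt = np.linalg.slogdet(T)
    if sw <= 0 or st <= 0:
        raise ValidationError("singular within- or total scatter matrix")
    return float(np.exp(ldw - ldt))


def stepwise_select(X: pd.DataFrame, y: Sequence[str],
                    alpha_enter: float = 0.05,
                    alpha_remove: float = 0.10,
                    max_steps: int = 200) -> StepwiseResult:
    """Wilks'-lambda stepwise selection of discriminating features.

    Deterministic given the column order: exact partial-F ties are broken
    toward the earlier column. Constant features are excluded up front with
    a warning step in the history.
    """
    if alpha_enter > alpha_remove:
        raise ValidationError("alpha_enter must be <= alpha_remove")
    y = np.asarray(y, dtype=object)
    classes = [c for c in DISC_TYPES if c in set(y)]
    extra = sorted(set(y) - set(DISC_TYPES))
    classes += extra
    if len(classes) < 2:
        raise ValidationError("stepwise selection needs >= 2 classes")
    codes = np.array([classes.index(v) for v in y])
    g = len(classes)
    n = len(y)

    usable = []
    history: list[StepwiseStep] = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            history.append(StepwiseStep("exclude_constant", name, 0.0, 1.0, 1.0))
        else:
            usable.append(name)

    selected: list[str] = []
    entry_stats: dict[str, tuple[float, float]] = {}
    lam_sel = 1.0

    def lam_of(names: list[str]) -> float:
        if not names:
            return 1.0
        return _wilks(X[names].to_numpy(dtype=float), codes, g)

    for _ in range(max_steps):
        changed = False
        # --- entry ---
        p_s = len(selected)
        df2 = n - g - p_s
        best: Optional[tuple[float, float, str, float]] = None
        if df2 >= 1:
            for name in usable:
                if name in selected:
                    continue
                try:
                    lam_new = lam_of(selected + [name])
                except ValidationError:
                    # candidate (near-)collinear with the entered set:
                    # zero tolerance, never enters
                    continue
                ratio = lam_sel / lam_new if lam_new > 0 else np.inf
                F = (df2 / (g - 1.0)) * (ratio - 1.0)
                if best is None or F > best[0] + 1e-12:
                    p_val = float(stats.f.sf(F, g - 1, df2)) if np.isfinite(F) else 0.0
                    best = (F, p_val, name, lam_new)
        if best is not None and best[1] < alpha_enter:
            F, p_val, name, lam_new = best
            selected.append(name)
            lam_sel = lam_new
            entry_stats[name] = (F, p_val)
            history.append(StepwiseStep("enter", name, F, p_val, lam_sel))
            changed = True

        # --- removal ---
        while len(selected) > 1:
            p_s = len(selected)
            df2r = n - g - p_s + 1
            worst: Optional[tuple[float, float, str, float]] = None
            for name in selected:
                others = [m for m in selected if m != name]
                try:
                    lam_wo = lam_of(others)
                except ValidationError:  # numerically degenerate subset
                    continue
                ratio = lam_wo / lam_sel if lam_sel > 0 else np.inf
                F = (df2r / (g - 1.0)) * (ratio - 1.0)
                p_val = float(stats.f.sf(F, g - 1, df2r)) if np.isfinite(F) else 0.0
                if worst is None or p_val > worst[1] + 1e-15:
                    worst = (F, p_val, name, lam_wo)
            if worst is not None and worst[1] > alpha_remove:
                F, p_val, name, lam_wo = worst
                selected.remove(name)
                lam_sel = lam_wo
                history.append(StepwiseStep("remove", name, F, p_val, lam_sel))
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseResult(selected=selected, history=history,
                          entry_stats=entry_stats)


# ---------------------------------------------------------------------------
# Linear discriminant model
# ---------------------------------------------------------------------------


@dataclass
class DiscTypeModel:
    """Gaussian LDA over the selected morphometric features.

    ``covariance`` is the pooled within-class covariance, ridge-stabilised
    before inversion by inflating each diagonal element by a relative
    1e-8 (features span µm² and pure-ratio scales, so an absolute ridge
    would distort the small-variance coordinates); priors default to equal
    across the four types, matching a balanced training design.
    """

    features: list[str]
    classes: list[str]
    means: dict[str, np.ndarray]
    covariance: np.ndarray
    priors: dict[str, float]
    rp_height_um: Optional[float] = None
    precision: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValidationError("model needs >= 2 classes")
        psum = sum(self.priors.values())
        if abs(psum - 1.0) > 1e-9:
            raise ValidationError(f"priors sum to {psum}, not 1")
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise ValidationError("covariance must be positive-definite")
        if self.precision is None:
            self.precision = np.linalg.inv(cov)

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) posterior probabilities; rows sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        logp = np.empty((X.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            d = X - self.means[c]
            maha = np.einsum("ij,jk,ik->i", d, self.precision, d)
            logp[:, j] = -0.5 * maha + np.log(self.priors[c])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def fit_lda(X: pd.DataFrame, y: Sequence[str],
            priors: Optional[dict[str, float]] = None,
            rp_height_um: Optional[float] = None,
            ridge: float = 1e-8) -> DiscTypeModel:
    """Fit the pooled-covariance linear discriminant model."""
    y = np.asarray(y, dtype=object)
    classes = [c for c in DISC_TYPES if c in set(y)]
    classes += sorted(set(y) - set(DISC_TYPES))
    if len(classes) < 2:
        raise ValidationError("LDA needs >= 2 classes")
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    means, W = {}, np.zeros((p, p))
    for c in classes:
        Xc = Xv[y == c]
        if Xc.shape[0] < 2:
            raise ValidationError(f"class {c!r} needs n >= 2")
        means[c] = Xc.mean(axis=0)
        d = Xc - means[c]
        W += d.T @ d
    cov = W / (n - len(classes))
    # relative ridge: the parameters span um^2 to pure ratios, so an
    # absolute diagonal term sized by the trace would distort the
    # small-variance features; scale the stabiliser per coordinate instead
    cov = cov + np.diag(ridge * np.clip(np.diag(cov), np.trace(cov) / p * 1e-6, None))
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValidationError("pooled covariance singular even after ridge")
    if priors is None:
        priors = {c: 1.0 / len(classes) for c in classes}
    return DiscTypeModel(
        features=list(X.columns), classes=classes, means=means,
        covariance=cov, priors=dict(priors), rp_height_um=rp_height_um,
    )


def classify_eyes(model: DiscTypeModel,
                  records: Sequence[EyeRecord]) -> pd.DataFrame:
    """Predicted type + posteriors per record.

    Exact posterior ties are broken by the fixed label order FI < GE < MY
    < SS and flagged. Records missing a selected feature get a per-row
    error message; the rest are still classified.
    """
    rows = []
    for r in records:
        row: dict = {"eye_id": r.eye_id, "specialist_type": r.disc_type,
                     "predicted_type": None, "tie": False, "error": ""}
        try:
            x = np.array([r.feature(f) for f in model.features], dtype=float)
        except KeyError as exc:
            row["error"] = str(exc)
            for c in model.classes:
                row[f"p_{c}"] = np.nan
            rows.append(row)
            continue
        post = model.posteriors(x)[0]
        best = post.max()
        winners = [j for j, v in enumerate(post) if abs(v - best) <= 1e-12]
        order = sorted(winners, key=lambda j: DISC_TYPES.index(model.classes[j])
                       if model.classes[j] in DISC_TYPES else 99)
        row["predicted_type"] = model.classes[order[0]]
        row["tie"] = len(winners) > 1
        for c, v in zip(model.classes, post):
            row[f"p_{c}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Agreement and discrimination metrics
# ---------------------------------------------------------------------------


def cohen_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Unweighted multi-class Cohen's kappa, (po − pe)/(1 − pe)."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("kappa needs two equal-length label vectors")
    labels = sorted(set(a) | set(b))
    n = a.size
    po = float(np.mean(a == b))
    pe = sum((np.mean(a == lab)) * (np.mean(b == lab)) for lab in labels)
    if abs(1.0 - pe) < 1e-15:
        raise ValidationError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def auc_one_vs_rest(scores: Sequence[float], is_positive: Sequence[bool]) -> float:
    """ROC AUC by the Mann–Whitney rank statistic (ties counted 1/2)."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(is_positive, dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both positives and negatives")
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class Evaluation:
    """Validation of predictions against the specialist labels."""

    classes: list[str]
    confusion: pd.DataFrame              # rows specialist, cols predicted
    identification_rate: float           # overall, diagonal / n
    per_type_rate: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    auc: dict[str, float]
    kappa: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12:
            raise ValidationError("kappa outside [-1, 1]")
        for d in (self.per_type_rate, self.sensitivity, self.specificity):
            for v in d.values():
                if not -1e-12 <= v <= 1 + 1e-12:
                    raise ValidationError("rate outside [0, 1]")


def evaluate(model: DiscTypeModel, records: Sequence[EyeRecord]) -> Evaluation:
    """Confusion matrix, per-type rates, AUCs and kappa on labelled records."""
    labelled = [r for r in records if r.disc_type is not None]
    if len({r.disc_type for r in labelled}) < 2:
        raise ValidationError("evaluation needs >= 2 classes present")
    preds = classify_eyes(model, labelled)
    if (preds["error"] != "").any():
        bad = preds.loc[preds["error"] != "", "eye_id"].tolist()
        raise ValidationError(f"records missing features: {bad}")
    truth = np.array([r.disc_type for r in labelled], dtype=object)
    pred = preds["predicted_type"].to_numpy(dtype=object)
    classes = [c for c in model.classes]

    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        conf.loc[t, p] += 1
    n = len(truth)
    diag = sum(conf.loc[c, c] for c in classes)
    per_type, sens, spec, auc = {}, {}, {}, {}
    for c in classes:
        row_n = int(conf.loc[c].sum())
        per_type[c] = conf.loc[c, c] / row_n if row_n else np.nan
        tp = int(conf.loc[c, c])
        fn = row_n - tp
        fp = int(conf[c].sum()) - tp
        tn = n - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) else np.nan
        spec[c] = tn / (tn + fp) if (tn + fp) else np.nan
        if (truth == c).any() and (truth != c).any():
            auc[c] = auc_one_vs_rest(preds[f"p_{c}"].to_numpy(), truth == c)
        else:
            auc[c] = np.nan
    return Evaluation(
        classes=classes,
        confusion=conf,
        identification_rate=diag / n,
        per_type_rate=per_type,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        kappa=cohen_kappa(truth, pred),
    )
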