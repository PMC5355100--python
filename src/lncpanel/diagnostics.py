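"""ROC evaluation of single markers and a combined logistic panel.

AUC is the Mann-Whitney probability that a random positive outscores a
random negative (ties count half), identical to the trapezoidal area
under the empirical ROC curve. Its standard error uses the
Hanley-McNeil moments Q1 = A/(2-A), Q2 = 2A^2/(1+A). Operating points
maximize Youden's J = sensitivity + specificity - 1 over observed
cut-points with the rule score >= threshold => positive; J ties break
toward the higher-specificity (higher) threshold.

Markers are combined with ridge-stabilized binary logistic regression
(penalty 1e-6, enough to keep separable data finite without visibly
biasing coefficients); the panel score is the linear predictor, whose
ROC equals that of the fitted probability.

``binormal_auc`` gives the closed-form AUC of two normal score
distributions, Phi(dmu / sqrt(sd0^2 + sd1^2)) — the bridge between
published group means/SDs and an achievable AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import ConvergenceError, InputError

logger = logging.getLogger(__name__)

#: ridge penalty applied to the panel logistic fit
PANEL_RIDGE = 1e-6


@dataclass(frozen=True)
class RocSummary:
    """AUC with SE and the Youden-optimal operating point."""

    auc: float
    se: float
    threshold: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class PanelModel:
    """Fitted logistic combination of markers; score = linear predictor."""

    markers: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float

    def score(self, markers: pd.DataFrame) -> np.ndarray:
        missing = [m for m in self.markers if m not in markers.columns]
        if missing:
            raise InputError(f"marker(s) missing from input: {missing}")
        x = markers.loc[:, list(self.markers)].to_numpy(dtype=float)
        return x @ self.coefficients + self.intercept


def _check_scores(pos_scores, neg_scores):
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score classes must be non-empty")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise InputError("scores must be finite")
    return pos, neg


def auc_mann_whitney(pos_scores, neg_scores) -> float:
    """Empirical AUC with midrank tie handling."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    u = rank_sum - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_se_hanley(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    if not 0.0 <= auc <= 1.0:
        raise InputError("auc must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise InputError("class counts must be >= 1")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1.0) * (q1 - a * a)
        + (n_neg - 1.0) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def youden_threshold(pos_scores, neg_scores) -> tuple[float, float, float]:
    """Operating point maximizing J over observed cut-points.

    Classification rule: score >= threshold => positive. Returns
    (threshold, sensitivity, specificity); among J-ties the higher
    threshold (higher specificity) wins.
    """
    pos, neg = _check_scores(pos_scores, neg_scores)
    best = None
    for threshold in np.unique(np.concatenate([pos, neg])):
        sens = float((pos >= threshold).mean())
        spec = float((neg < threshold).mean())
        j = sens + spec - 1.0
        key = (j, threshold)  # ties toward the higher threshold
        if best is None or key > best[0]:
            best = (key, (float(threshold), sens, spec))
    return best[1]


def roc_summary(pos_scores, neg_scores) -> RocSummary:
    """Bundle AUC, Hanley-McNeil SE and the Youden operating point."""
    pos, neg = _check_scores(pos_scores, neg_scores)
    auc = auc_mann_whitney(pos, neg)
    threshold, sens, spec = youden_threshold(pos, neg)
    return RocSummary(
        auc=auc, se=auc_se_hanley(auc, pos.size, neg.size),
        threshold=threshold, sensitivity=sens, specificity=spec,
        n_pos=int(pos.size), n_neg=int(neg.size),
    )


def binormal_auc(
    mu_neg: float, sd_neg: float, mu_pos: float, sd_pos: float
) -> float:
    """Closed-form AUC of two normal score distributions.

    Phi((mu_pos - mu_neg) / sqrt(sd_neg^2 + sd_pos^2)). Degenerate SDs
    collapse to a point mass: equal means is undefined (error), unequal
    means give 0 or 1.
    """
    if sd_neg < 0 or sd_pos < 0:
        raise InputError("standard deviations must be non-negative")
    spread = float(np.hypot(sd_neg, sd_pos))
    delta = mu_pos - mu_neg
    if spread == 0.0:
        if delta == 0.0:
            raise InputError("binormal AUC undefined: two identical point masses")
        return 1.0 if delta > 0 else 0.0
    return float(stats.norm.cdf(delta / spread))


def fit_panel(
    markers: pd.DataFrame,
    labels,
    ridge: float = PANEL_RIDGE,
    max_iter: int = 10_000,
) -> PanelModel:
    """Fit the logistic marker panel (labels: 1 = tumor, 0 = normal).

    Constant markers carry no information and are dropped with a
    warning; non-convergence raises with the solver diagnostics.
    """
    y = np.asarray(labels, dtype=int)
    if markers.shape[0] != y.size:
        raise InputError("markers and labels disagree on sample count")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise InputError("need at least 2 samples per class")
    keep = [c for c in markers.columns if markers[c].nunique() > 1]
    dropped = [c for c in markers.columns if c not in keep]
    if dropped:
        logger.warning("dropping constant marker(s): %s", dropped)
    if not keep:
        raise InputError("no informative (non-constant) markers")
    x = markers.loc[:, keep].to_numpy(dtype=float)
    model = LogisticRegression(  # default l2 penalty, C = 1/ridge
        C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-10,
    )
    model.fit(x, y)
    n_iter = int(np.max(model.n_iter_))
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"panel logistic fit did not converge in {max_iter} iterations "
            f"(markers={keep}, n={y.size})"
        )
    return PanelModel(
        markers=tuple(keep),
        coefficients=model.coef_.ravel().copy(),
        intercept=float(model.intercept_[0]),
    )


def _cohort_rows(cohort: str, markers: pd.DataFrame, y: np.ndarray, panel: PanelModel):
    rows = []
    for marker in markers.columns:
        values = markers[marker].to_numpy(dtype=float)
        pos, neg = values[y == 1], values[y == 0]
        summary = roc_summary(pos, neg)
        p = float(stats.ttest_ind(pos, neg, equal_var=True).pvalue)
        rows.append(_row(cohort, marker, pos, neg, p, summary))
    score = panel.score(markers)
    pos, neg = score[y == 1], score[y == 0]
    summary = roc_summary(pos, neg)
    p = float(stats.ttest_ind(pos, neg, equal_var=True).pvalue)
    rows.append(_row(cohort, "panel", pos, neg, p, summary))
    return rows


def _row(cohort, marker, pos, neg, p, s: RocSummary):
    return {
        "cohort": cohort, "marker": marker,
        "mean_normal": float(np.mean(neg)), "sd_normal": float(np.std(neg, ddof=1)),
        "mean_tumor": float(np.mean(pos)), "sd_tumor": float(np.std(pos, ddof=1)),
        "p_value": p, "auc": s.auc, "se": s.se, "threshold": s.threshold,
        "sensitivity": s.sensitivity, "specificity": s.specificity,
        "n_tumor": s.n_pos, "n_normal": s.n_neg,
    }


def evaluate_cohorts(
    train_markers: pd.DataFrame,
    train_labels,
    validation_markers: pd.DataFrame | None = None,
    validation_labels=None,
    ridge: float = PANEL_RIDGE,
) -> tuple[pd.DataFrame, PanelModel]:
    """Per-marker and panel ROC report for training (and validation).

    The panel is fit on the training cohort only; the validation cohort
    is scored with the frozen coefficients. Returns the report — one row
    per (cohort, marker) plus a 'panel' row per cohort, with group
    means/SDs, t-test p, AUC (SE) and the Youden operating point — and
    the fitted panel.
    """
    y_train = np.asarray(train_labels, dtype=int)
    panel = fit_panel(train_markers, y_train, ridge=ridge)
    rows = _cohort_rows("training", train_markers, y_train, panel)
    if validation_markers is not None:
        if validation_labels is None:
            raise InputError("validation labels required with validation markers")
        missing = [m for m in panel.markers if m not in validation_markers.columns]
        if missing:
            raise InputError(f"validation cohort lacks panel marker(s): {missing}")
        y_val = np.asarray(validation_labels, dtype=int)
        rows += _cohort_rows("validation", validation_markers, y_val, panel)
    return pd.DataFrame(rows), panel
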