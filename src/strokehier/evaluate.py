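"""Performance evaluation: Youden-index cutoff selection by stratified
10-fold cross-validation, the confusion-matrix metric suite, ROC AUC, and the
univariate cohort-description engine (two-sample t, chi-square, Fisher).

The Youden index gamma = sensitivity + specificity - 1 balances the two error
rates; the operating cutoff is the pooled out-of-fold score threshold that
maximises it on the training cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic import CONTINUOUS_COLUMNS, LEVEL2_COLUMNS

__all__ = [
    "MetricsReport",
    "CutoffConfig",
    "UnivariateResult",
    "youden",
    "best_cutoff",
    "select_cutoff_cv",
    "confusion_metrics",
    "roc_auc",
    "table_one",
    "chi2_df2_p",
    "reconstruct_confusion",
]


def youden(sensitivity: float, specificity: float) -> float:
    """gamma = sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass
class MetricsReport:
    youden: float
    accuracy: float
    recall: float
    specificity: float
    f1: float
    auc: float
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("youden", "accuracy", "recall", "specificity", "f1", "auc",
                 "cutoff", "tp", "fp", "tn", "fn")}


def confusion_metrics(labels, scores, cutoff: float) -> MetricsReport:
    """Metric suite at one operating point; a score >= cutoff predicts
    positive (boundary inclusive)."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty input")
    pred = s >= cutoff
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    recall = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    auc = roc_auc(y, s) if (y.any() and not y.all()) else float("nan")
    return MetricsReport(youden=youden(recall, spec),
                         accuracy=(tp + tn) / y.size, recall=recall,
                         specificity=spec, f1=f1, auc=auc, cutoff=float(cutoff),
                         tp=tp, fp=fp, tn=tn, fn=fn)


def roc_auc(labels, scores) -> float:
    """Trapezoidal AUC, equal to the positive–negative concordance
    probability with ties counted one half."""
    return float(roc_auc_score(np.asarray(labels, dtype=int), np.asarray(scores)))


def best_cutoff(labels, scores) -> tuple[float, float]:
    """Exhaustive Youden maximisation over the unique observed scores.

    Returns (cutoff, gamma); the smallest optimal threshold wins ties.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=np.float64)
    candidates = np.unique(s)
    best_c, best_g = None, -np.inf
    for c in candidates:  # ascending, so first strict improvement keeps smallest
        pred = s >= c
        tp = np.sum(pred & y)
        fn = np.sum(~pred & y)
        tn = np.sum(~pred & ~y)
        fp = np.sum(pred & ~y)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        g = sens + spec - 1.0
        if g > best_g:
            best_g, best_c = g, float(c)
    return best_c, float(best_g)


@dataclass
class CutoffConfig:
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def select_cutoff_cv(fit_score, X, labels, config: CutoffConfig | None = None) -> float:
    """Choose the operating cutoff by stratified cross-validation.

    ``fit_score(X_train, y_train, X_valid) -> scores`` refits the model per
    fold; out-of-fold scores are pooled and the cutoff maximising the pooled
    empirical Youden index is returned (smallest threshold on ties).
    """
    config = config or CutoffConfig()
    y = np.asarray(labels, dtype=bool)
    if min(int(y.sum()), int((~y).sum())) < config.n_folds:
        raise ValueError("need at least n_folds patients of each class for stratified CV")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    oof = np.full(y.size, np.nan)
    idx_all = np.arange(y.size)
    for tr, va in skf.split(idx_all, y.astype(int)):
        Xtr = X.iloc[tr] if hasattr(X, "iloc") else X[tr]
        Xva = X.iloc[va] if hasattr(X, "iloc") else X[va]
        oof[va] = np.asarray(fit_score(Xtr, y[tr], Xva), dtype=np.float64)
    cutoff, _ = best_cutoff(y, oof)
    return cutoff


# ---------------------------------------------------------------------------
# Univariate cohort description
# ---------------------------------------------------------------------------

@dataclass
class UnivariateResult:
    variable: str
    test: str
    statistic: float
    p: float


def chi2_df2_p(statistic: float) -> float:
    """Exact chi-square upper tail at 2 degrees of freedom: p = exp(-x/2)."""
    if statistic < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    return float(np.exp(-statistic / 2.0))


def _categorical_test(table: np.ndarray) -> tuple[str, float, float]:
    """Route a 2 x L contingency table to the cohort-description test.

    2x2 tables use Pearson chi-square with Yates continuity correction, or
    Fisher's exact test when any expected count is below 5; wider tables use
    the plain Pearson chi-square (df = L-1, evaluated in closed form for
    df = 2).
    """
    table = np.asarray(table, dtype=np.float64)
    if table.shape[1] == 2:
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            stat, p = stats.fisher_exact(table.astype(int))
            return "fisher-exact", float(stat), float(p)
        stat, p, _, _ = stats.chi2_contingency(table, correction=True)
        return "chi-square-yates-2x2", float(stat), float(p)
    stat, _, dof, _ = stats.chi2_contingency(table, correction=False)
    if dof == 2:
        return "chi-square-df2-with-unknown", float(stat), chi2_df2_p(float(stat))
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return f"chi-square-df{dof}", float(stat), float(p)


def table_one(cohort: pd.DataFrame, columns: list[str] | None = None,
              label_col: str = "lvo") -> pd.DataFrame:
    """Univariate LVO-association screen over the cohort table.

    Continuous variables: two-sample pooled-variance (Student) t-test on
    observed values. Categorical variables: contingency test on the
    class-by-level table with missing cells counted as a real ``Unknown``
    level (the routing of :func:`_categorical_test`). Returns one row per
    variable with the test name, statistic and p-value.
    """
    y = cohort[label_col].astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes required")
    columns = columns or [c for c in LEVEL2_COLUMNS if c in cohort.columns]
    rows = []
    for col in columns:
        if col in CONTINUOUS_COLUMNS or np.issubdtype(
                np.asarray(cohort[col].dropna()).dtype, np.number):
            x = pd.to_numeric(cohort[col], errors="coerce")
            a, b = x[y].dropna(), x[~y].dropna()
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(UnivariateResult(col, "student-t", float(stat), float(p)))
        else:
            vals = cohort[col].astype(object).where(cohort[col].notna(), "Unknown")
            levels = sorted(vals.unique())
            table = np.array([[(vals[y] == lv).sum() for lv in levels],
                              [(vals[~y] == lv).sum() for lv in levels]], dtype=float)
            test, stat, p = _categorical_test(table)
            rows.append(UnivariateResult(col, test, stat, p))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Printed-performance identities
# ---------------------------------------------------------------------------

def reconstruct_confusion(recall: float, specificity: float, accuracy: float,
                          n: int = 100, digits: int = 3) -> tuple[int, int, int, int]:
    """Recover the unique integer confusion matrix (tp, fp, tn, fn) on ``n``
    subjects whose recall/specificity/accuracy round to the given values at
    ``digits`` decimals. Raises if no matrix or more than one matches."""
    tol = 0.5 * 10.0 ** (-digits) + 1e-12
    matches: set[tuple[int, int, int, int]] = set()
    for pos in range(1, n):
        neg = n - pos
        for tp in range(pos + 1):
            if abs(tp / pos - recall) > tol:
                continue
            for tn in range(neg + 1):
                if abs(tn / neg - specificity) > tol:
                    continue
                if abs((tp + tn) / n - accuracy) > tol:
                    continue
                matches.add((tp, neg - tn, tn, pos - tp))
    if not matches:
        raise ValueError("no confusion matrix consistent with the printed metrics")
    if len(matches) > 1:
        raise ValueError(f"printed metrics are ambiguous: {sorted(matches)}")
    return matches.pop()
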