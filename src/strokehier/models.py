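"""The four tabular learner families with the study's missing-data policies.

Missing categorical cells become a literal ``Unknown`` level (a real category,
since unascertained status is itself informative in registry data); missing
continuous cells are filled by KNN-median imputation anchored to training-set
state. Gradient boosting is the exception: it consumes the raw table and
routes missing values through learned default split directions.

Families: bidirectional stepwise logistic regression (Wald entry p<0.05,
removal p>0.10), random forest (500 trees, sqrt-p splits), an RBF-kernel SVM
restricted to features the boosting model found useful (positive total gain),
and XGBoost (300 rounds, depth 4, learning rate 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ImputeConfig",
    "KNNImputer",
    "TrainedLevelModel",
    "encode_unknown",
    "knn_impute",
    "fit_stepwise_logistic",
    "fit_random_forest",
    "fit_svm",
    "fit_gradient_boosting",
    "importance_report",
    "TabularPipeline",
]

FAMILIES = ("lr", "rf", "svm", "xgb")


# ---------------------------------------------------------------------------
# Missing-data handling
# ---------------------------------------------------------------------------

def encode_unknown(table: pd.DataFrame) -> pd.DataFrame:
    """Assign the literal level ``"Unknown"`` to every missing categorical
    (object-dtype) cell; non-missing cells and continuous columns untouched."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].where(out[col].notna(), "Unknown")
    return out


@dataclass
class ImputeConfig:
    k_neighbors: int = 5

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


class KNNImputer:
    """KNN-median imputation of continuous columns, deployable to unseen rows.

    Distances are Euclidean over jointly observed continuous features, each
    standardised by the training mean/SD, rescaled by sqrt(p / p_observed) so
    rows with different missingness patterns are comparable. A missing cell is
    filled with the median of that column's non-missing values among the k
    nearest training rows; when no neighbour has the column observed (or the
    query shares no observed feature with training), the training-column
    median is used and a warning is issued.
    """

    def __init__(self, config: ImputeConfig | None = None):
        self.config = config or ImputeConfig()
        self._fitted = False

    def fit(self, train: pd.DataFrame) -> "KNNImputer":
        num = train.select_dtypes(include=[np.number])
        self.columns_ = list(num.columns)
        X = num.to_numpy(dtype=np.float64)
        self.train_ = X
        self.mean_ = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        self.median_ = np.nanmedian(X, axis=0)
        self.z_train_ = (X - self.mean_) / self.sd_
        self._fitted = True
        return self

    def _impute_vector(self, row: np.ndarray) -> np.ndarray:
        z = (row - self.mean_) / self.sd_
        out = row.copy()
        miss = np.isnan(row)
        if not miss.any():
            return out
        obs = ~miss
        if not obs.any():
            warnings.warn("row has no observed continuous features; using training medians",
                          stacklevel=2)
            out[miss] = self.median_[miss]
            return out
        diff = self.z_train_[:, obs] - z[obs]
        joint = ~np.isnan(diff)
        n_joint = joint.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d2 = np.nansum(diff * diff, axis=1) * (obs.sum() / np.maximum(n_joint, 1))
        d2[n_joint == 0] = np.inf
        order = np.argsort(d2, kind="stable")
        k = min(self.config.k_neighbors, int(np.isfinite(d2).sum()))
        nbrs = order[:k]
        for j in np.flatnonzero(miss):
            vals = self.train_[nbrs, j]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                warnings.warn("no neighbour observed the target column; using training median",
                              stacklevel=2)
                out[j] = self.median_[j]
            else:
                out[j] = float(np.median(vals))
        return out

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self._fitted:
            raise RuntimeError("fit before transform")
        out = table.copy()
        X = out[self.columns_].to_numpy(dtype=np.float64)
        for i in range(X.shape[0]):
            if np.isnan(X[i]).any():
                X[i] = self._impute_vector(X[i])
        out[self.columns_] = X
        return out


def knn_impute(train_table: pd.DataFrame, query_row: pd.Series,
               config: ImputeConfig | None = None) -> pd.Series:
    """Impute one row's missing continuous cells from training-set state."""
    imp = KNNImputer(config).fit(train_table)
    out = imp.transform(query_row.to_frame().T)
    return out.iloc[0]


# ---------------------------------------------------------------------------
# Design-matrix encoding
# ---------------------------------------------------------------------------

class DummyEncoder:
    """One-hot encoding of object columns with category levels frozen at fit
    time; unseen levels at transform map to all-zero indicator blocks."""

    def fit(self, table: pd.DataFrame) -> "DummyEncoder":
        self.cat_cols_ = [c for c in table.columns if table[c].dtype == object]
        self.levels_ = {c: sorted(table[c].dropna().astype(str).unique()) for c in self.cat_cols_}
        self.num_cols_ = [c for c in table.columns if c not in self.cat_cols_]
        self.columns_ = list(self.num_cols_)
        for c in self.cat_cols_:
            self.columns_ += [f"{c}={lv}" for lv in self.levels_[c]]
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=table.index)
        for c in self.num_cols_:
            out[c] = pd.to_numeric(table[c], errors="coerce")
        for c in self.cat_cols_:
            col = table[c].astype(str)
            for lv in self.levels_[c]:
                out[f"{c}={lv}"] = (col == lv).astype(float)
            # keep genuine NaN propagating for the raw-data (boosting) path
            out.loc[table[c].isna(), [f"{c}={lv}" for lv in self.levels_[c]]] = np.nan
        return out[self.columns_]


# ---------------------------------------------------------------------------
# Learner families
# ---------------------------------------------------------------------------

@dataclass
class TrainedLevelModel:
    """A fitted learner bound to its feature list and scoring machinery."""

    family: str
    feature_list: list[str]
    predictor: object
    level: int | None = None
    cutoff: float | None = None
    importance: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.predictor(X[self.feature_list])


def _wald_pvalues(result) -> pd.Series:
    return result.pvalues.drop("const", errors="ignore")


def fit_stepwise_logistic(
    table: pd.DataFrame,
    labels: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> TrainedLevelModel:
    """Bidirectional stepwise logistic regression on an imputed numeric table.

    Forward step adds the candidate with the smallest Wald p below
    ``p_enter``; backward step drops the included term with the largest p
    above ``p_remove``. A term removed in a sweep may not re-enter in that
    same sweep, which prevents cycling. Perfect separation (or a failed fit)
    falls back to an L2-penalised logistic model on the current selection with
    a warning.
    """
    y = np.asarray(labels, dtype=float)
    X = table.astype(float)
    candidates = list(X.columns)
    selected: list[str] = []

    def try_fit(cols: list[str]):
        design = sm.add_constant(X[cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, design).fit(disp=0, maxiter=100)
            except Exception:
                return None
        if not np.all(np.isfinite(res.params)):
            return None
        return res

    changed = True
    while changed:
        changed = False
        banned: set[str] = set()
        # backward
        while selected:
            res = try_fit(selected)
            if res is None:
                break
            pv = _wald_pvalues(res)
            worst = pv.idxmax()
            if pv[worst] > p_remove:
                selected.remove(worst)
                banned.add(worst)
                changed = True
            else:
                break
        # forward
        best_p, best_col = None, None
        for col in candidates:
            if col in selected or col in banned:
                continue
            res = try_fit(selected + [col])
            if res is None:
                continue
            p = _wald_pvalues(res).get(col, 1.0)
            if best_p is None or p < best_p:
                best_p, best_col = p, col
        if best_col is not None and best_p < p_enter:
            selected.append(best_col)
            changed = True

    selected = sorted(selected, key=list(X.columns).index)
    final = try_fit(selected) if selected else try_fit([])
    if final is not None:
        cols = list(selected)

        def predict(Xq: pd.DataFrame) -> np.ndarray:
            design = sm.add_constant(Xq[cols].astype(float), has_constant="add")
            return np.asarray(final.predict(design))

        coefs = final.params
    else:
        warnings.warn("logistic fit failed (separation?); falling back to penalised model",
                      stacklevel=2)
        cols = selected if selected else list(X.columns)
        lr = LogisticRegression(max_iter=2000, C=1.0)
        lr.fit(X[cols].to_numpy(), y)

        def predict(Xq: pd.DataFrame) -> np.ndarray:
            return lr.predict_proba(Xq[cols].astype(float).to_numpy())[:, 1]

        coefs = pd.Series(lr.coef_[0], index=cols)

    return TrainedLevelModel(family="lr", feature_list=list(X.columns),
                             predictor=lambda Xq: predict(Xq),
                             extras={"selected": list(cols), "coefficients": coefs})


def fit_random_forest(table: pd.DataFrame, labels: np.ndarray, seed: int = 0,
                      n_estimators: int = 500) -> TrainedLevelModel:
    """Random forest: bootstrap trees over sqrt-p feature subsets; the score
    is the mean of per-tree class frequencies."""
    rf = RandomForestClassifier(n_estimators=n_estimators, max_features="sqrt",
                                random_state=seed, n_jobs=1)
    rf.fit(table.to_numpy(dtype=float), np.asarray(labels, dtype=int))
    imp = pd.Series(rf.feature_importances_, index=table.columns)
    return TrainedLevelModel(family="rf", feature_list=list(table.columns),
                             predictor=lambda Xq: rf.predict_proba(
                                 Xq.to_numpy(dtype=float))[:, 1],
                             importance=imp)


def fit_svm(table: pd.DataFrame, labels: np.ndarray, feature_list: list[str],
            seed: int = 0) -> TrainedLevelModel:
    """RBF-kernel SVM on externally selected features (the boosting model's
    positive-gain set), with cost/gamma chosen by an internal cross-validated
    grid and Platt-calibrated probabilities."""
    if feature_list is None:
        raise ValueError("SVM requires an externally provided feature list")
    if len(feature_list) == 0:
        raise ValueError("SVM feature list is empty")
    X = table[feature_list].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    inner = min(5, n_min)
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svc", SVC(kernel="rbf", random_state=seed))])
    grid = {"svc__C": [0.1, 1.0, 10.0], "svc__gamma": ["scale", 0.01, 0.1]}
    if inner >= 2:
        cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(X, y)
        best = search.best_estimator_
        model = CalibratedClassifierCV(best, method="sigmoid", cv=cv, ensemble=False)
        model.fit(X, y)
    else:
        # too few subjects to calibrate; fall back to a logistic squash of the
        # margin fitted on the training data itself
        model = CalibratedClassifierCV(pipe, method="sigmoid", cv=2, ensemble=False)
        model.fit(X, y)
    return TrainedLevelModel(family="svm", feature_list=list(feature_list),
                             predictor=lambda Xq: model.predict_proba(
                                 Xq.to_numpy(dtype=float))[:, 1])


def fit_gradient_boosting(table: pd.DataFrame, labels: np.ndarray, seed: int = 0,
                          n_estimators: int = 300, max_depth: int = 4,
                          learning_rate: float = 0.1) -> TrainedLevelModel:
    """XGBoost on the raw (non-imputed) table; missing cells route through
    learned default split directions at both fit and predict time. Per-feature
    total gain is exposed for importance reporting and SVM feature hand-off."""
    xgb = XGBClassifier(n_estimators=n_estimators, max_depth=max_depth,
                        learning_rate=learning_rate, random_state=seed,
                        eval_metric="logloss", n_jobs=1, verbosity=0)
    X = table.to_numpy(dtype=float)
    xgb.fit(X, np.asarray(labels, dtype=int))
    booster = xgb.get_booster()
    raw_gain = booster.get_score(importance_type="total_gain")
    gains = pd.Series(0.0, index=table.columns)
    for key, val in raw_gain.items():
        gains.iloc[int(key[1:])] = val
    return TrainedLevelModel(family="xgb", feature_list=list(table.columns),
                             predictor=lambda Xq: xgb.predict_proba(
                                 Xq.to_numpy(dtype=float))[:, 1],
                             importance=gains)


def importance_report(model: TrainedLevelModel, drop_below: float = 0.01) -> pd.Series:
    """Scaled importances: the top feature's score becomes exactly 1.0, the
    rest scale proportionally, sorted descending, entries below ``drop_below``
    omitted."""
    if model.importance is None:
        raise ValueError(f"family {model.family!r} exposes no importances")
    imp = model.importance
    top = imp.max()
    if top <= 0:
        return pd.Series(dtype=float)
    scaled = (imp / top).sort_values(ascending=False, kind="stable")
    return scaled[scaled >= drop_below]


# ---------------------------------------------------------------------------
# End-to-end per-family pipeline
# ---------------------------------------------------------------------------

class TabularPipeline:
    """Missing-data policy + encoding + one learner family, fit on training
    rows only and deployable to unseen rows.

    ``raw`` policy (gradient boosting): Unknown-encode categoricals, one-hot
    encode, keep continuous NaNs. ``imputed`` policy (the other families):
    additionally KNN-median impute continuous cells from training state.
    """

    def __init__(self, family: str, seed: int = 0,
                 impute_config: ImputeConfig | None = None,
                 svm_features: list[str] | None = None):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.seed = seed
        self.impute_config = impute_config or ImputeConfig()
        self.svm_features = svm_features
        self.policy = "raw" if family == "xgb" else "imputed"

    def _design(self, table: pd.DataFrame, fitting: bool) -> pd.DataFrame:
        t = encode_unknown(table)
        if fitting:
            self.encoder_ = DummyEncoder().fit(t)
        X = self.encoder_.transform(t)
        if self.policy == "imputed":
            if fitting:
                self.imputer_ = KNNImputer(self.impute_config).fit(X)
            X = self.imputer_.transform(X)
        return X

    def fit(self, table: pd.DataFrame, labels: np.ndarray) -> "TabularPipeline":
        X = self._design(table, fitting=True)
        y = np.asarray(labels, dtype=bool)
        if self.family == "lr":
            self.model_ = fit_stepwise_logistic(X, y)
        elif self.family == "rf":
            self.model_ = fit_random_forest(X, y, seed=self.seed)
        elif self.family == "xgb":
            self.model_ = fit_gradient_boosting(X, y, seed=self.seed)
        else:
            feats = self.svm_features
            if feats is None:
                gb = fit_gradient_boosting(X, y, seed=self.seed)
                feats = list(gb.importance[gb.importance > 0].index)
                self.svm_features_used_ = feats
            self.model_ = fit_svm(X, y, feats, seed=self.seed)
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = self._design(table, fitting=False)
        return self.model_.predict_proba(X)
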