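"""End-to-end driver: simulate (or load) a cohort, split it stratified into
training and test groups, fit every requested (level, family) cell, choose
each cell's operating cutoff by cross-validated Youden maximisation on the
training group only, and evaluate once on the held-out test group.

The design enforces a hard train/test firewall: deep-feature screening,
Unknown encoding levels, imputation state, stepwise selection, SVM feature
hand-off and the cutoff are all functions of the training split alone, so
permuting test labels cannot change any trained artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import synthetic
from .evaluate import CutoffConfig, confusion_metrics, select_cutoff_cv
from .features import SelectConfig, assemble_level, ttest_screen
from .models import FAMILIES, TabularPipeline, importance_report
from .synthetic import CohortConfig, simulate_deep_features

__all__ = ["RunConfig", "PreparedData", "FittedCell", "run_pipeline",
           "prepare_data", "fit_all", "evaluate_all"]


@dataclass
class RunConfig:
    """Study-scale defaults: 300 simulated patients split 200/100."""

    n_train: int = 200
    n_test: int = 100
    seed: int = 0
    levels: tuple[int, ...] = (1, 2, 3)
    families: tuple[str, ...] = FAMILIES
    n_folds: int = 10
    top_k: int = 10
    deep_channels: int = 64
    deep_informative: int = 8
    deep_effect: float = 1.5
    select_cutoff: bool = True
    cohort_config: CohortConfig | None = None

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
        for lv in self.levels:
            if lv not in (1, 2, 3):
                raise ValueError(f"unknown level {lv}")


@dataclass
class PreparedData:
    cohort: pd.DataFrame
    deep_features: pd.DataFrame
    train_ids: np.ndarray
    test_ids: np.ndarray

    def labels(self, ids: np.ndarray) -> np.ndarray:
        return self.cohort.set_index("id").loc[ids, "lvo"].to_numpy(dtype=bool)


@dataclass
class FittedCell:
    level: int
    family: str
    policy: str
    pipeline: TabularPipeline
    columns: list[str]
    cutoff: float
    selected_channels: list[str] = field(default_factory=list)


def prepare_data(config: RunConfig) -> PreparedData:
    """Simulate the cohort and its deep-feature block; stratified split."""
    cohort_config = config.cohort_config or CohortConfig(
        n_patients=config.n_train + config.n_test, seed=config.seed)
    cohort = synthetic.generate_cohort(cohort_config)
    deep, _ = simulate_deep_features(cohort, n_channels=config.deep_channels,
                                     n_informative=config.deep_informative,
                                     effect=config.deep_effect, seed=config.seed)
    ids = cohort["id"].to_numpy()
    y = cohort["lvo"].to_numpy(dtype=bool)
    train_ids, test_ids = train_test_split(
        ids, train_size=config.n_train, test_size=config.n_test,
        stratify=y, random_state=config.seed)
    return PreparedData(cohort=cohort, deep_features=deep,
                        train_ids=np.sort(train_ids), test_ids=np.sort(test_ids))


def _level_table(level: int, data: PreparedData, ids: np.ndarray,
                 selected_channels: list[str] | None) -> pd.DataFrame:
    cohort = data.cohort[data.cohort["id"].isin(ids)]
    deep = None
    if level == 3:
        deep = data.deep_features[selected_channels]
    return assemble_level(level, cohort, deep).loc[ids]


def fit_all(data: PreparedData, config: RunConfig) -> dict[tuple[int, str], FittedCell]:
    """Fit every requested (level, family) cell on the training split only."""
    y_train = data.labels(data.train_ids)
    cells: dict[tuple[int, str], FittedCell] = {}

    # deep-feature screen: training patients only, indices frozen
    screen_idx, _ = ttest_screen(
        data.deep_features.loc[data.train_ids].to_numpy(), y_train,
        SelectConfig(top_k=config.top_k))
    selected_channels = [data.deep_features.columns[i] for i in sorted(screen_idx)]

    for level in config.levels:
        X_train = _level_table(level, data, data.train_ids,
                               selected_channels if level == 3 else None)
        # SVM consumes the boosting model's positive-gain features; fit the
        # reference boosting model once per level on the training split
        svm_features = None
        if "svm" in config.families:
            ref = TabularPipeline("xgb", seed=config.seed).fit(X_train, y_train)
            gains = ref.model_.importance
            svm_features = list(gains[gains > 0].index)
            if not svm_features:
                svm_features = list(gains.index)
        for family in config.families:
            pipe = TabularPipeline(family, seed=config.seed,
                                   svm_features=svm_features if family == "svm" else None)
            pipe.fit(X_train, y_train)
            if config.select_cutoff:
                def fit_score(Xtr, ytr, Xva, _family=family, _svm=svm_features):
                    fold = TabularPipeline(_family, seed=config.seed,
                                           svm_features=_svm if _family == "svm" else None)
                    fold.fit(Xtr, ytr)
                    return fold.predict_proba(Xva)

                cutoff = select_cutoff_cv(fit_score, X_train, y_train,
                                          CutoffConfig(n_folds=config.n_folds,
                                                       seed=config.seed))
            else:
                cutoff = 0.5
            cells[(level, family)] = FittedCell(
                level=level, family=family, policy=pipe.policy, pipeline=pipe,
                columns=list(X_train.columns), cutoff=float(cutoff),
                selected_channels=selected_channels if level == 3 else [])
    return cells


def evaluate_all(cells: dict[tuple[int, str], FittedCell], data: PreparedData,
                 config: RunConfig) -> pd.DataFrame:
    """Score every fitted cell once on the held-out test split."""
    y_test = data.labels(data.test_ids)
    rows = []
    for (level, family), cell in cells.items():
        X_test = _level_table(level, data, data.test_ids,
                              cell.selected_channels if level == 3 else None)
        scores = cell.pipeline.predict_proba(X_test)
        report = confusion_metrics(y_test, scores, cell.cutoff)
        rows.append({"level": level, "family": family, "policy": cell.policy,
                     **report.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Full run. Returns the per-cell metric grid, the fitted cells (for
    importance reports and audits), and the prepared data."""
    config = config or RunConfig()
    data = prepare_data(config)
    cells = fit_all(data, config)
    report = evaluate_all(cells, data, config)
    importances = {}
    for key, cell in cells.items():
        model = cell.pipeline.model_
        if model.importance is not None:
            importances[key] = importance_report(model)
    return {"report": report, "cells": cells, "data": data,
            "importances": importances, "config": config}
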