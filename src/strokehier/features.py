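"""Level assembly and deep-feature screening.

The imaging block enters the tabular models through a brief univariate
filter: each pooled network channel is split by LVO label and tested with a
two-sample t-test; the ``top_k`` channels with the smallest p-values (default
10) are kept. Screening is fit on training patients only and the frozen
indices are applied to held-out patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import LEVEL1_COLUMNS, LEVEL2_COLUMNS

__all__ = ["SelectConfig", "ttest_screen", "assemble_level"]


@dataclass
class SelectConfig:
    top_k: int = 10
    welch: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def ttest_screen(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    config: SelectConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank feature channels by two-sample t-test p-value.

    Returns ``(selected_indices, pvalues)`` where ``selected_indices`` holds
    the ``top_k`` column indices with the smallest p, ascending (ties broken
    by column index), and ``pvalues`` has one entry per column. Channels with
    no variance in either group get p = 1. Pooled-variance (Student) t by
    default; Welch behind the ``welch`` flag.
    """
    config = config or SelectConfig()
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to screen features")
    if min(int(y.sum()), int((~y).sum())) < 2:
        raise ValueError("need at least 2 patients per class")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(X[y], X[~y], axis=0, equal_var=not config.welch)
    p = np.where(np.isnan(p), 1.0, p)
    # stable argsort on (p, index) — ties go to the lower channel index
    order = np.lexsort((np.arange(X.shape[1]), p))
    k = min(config.top_k, X.shape[1])
    return order[:k], p


LEVEL_COLUMNS = {1: LEVEL1_COLUMNS, 2: LEVEL2_COLUMNS}


def assemble_level(
    level: int,
    cohort: pd.DataFrame,
    deep_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Model-ready feature table for one evaluation level, indexed by patient.

    Level-1: demographics and observable deficits; Level-2: Level-1 plus
    clinical history, vitals and comorbidities; Level-3: Level-2 plus the
    (already screened) deep-feature columns. Column order is deterministic.
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    base = cohort.set_index("id")[LEVEL_COLUMNS[min(level, 2)]].copy()
    if level < 3:
        return base
    if deep_features is None:
        raise ValueError("Level-3 assembly requires deep features")
    missing = base.index.difference(deep_features.index)
    if len(missing):
        raise ValueError(f"deep features missing for {len(missing)} patients")
    joined = base.join(deep_features.loc[base.index], how="left")
    return joined
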