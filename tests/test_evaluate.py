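"""Metric suite, cutoff selection and the univariate cohort-description
engine, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from strokehier import evaluate
from strokehier.evaluate import (CutoffConfig, best_cutoff, chi2_df2_p, confusion_metrics,
                                 reconstruct_confusion, roc_auc, select_cutoff_cv,
                                 table_one, youden)


class TestYouden:
    def test_printed_operating_point(self):
        g = youden(41 / 43, 39 / 57)
        assert round(g, 3) == 0.638

    @pytest.mark.parametrize("sens,spec,expected", [(1, 1, 1), (0.5, 0.5, 0.0)])
    def test_arithmetic(self, sens, spec, expected):
        assert youden(sens, spec) == pytest.approx(expected)

    def test_identity_holds_in_report(self):
        rng = np.random.default_rng(0)
        y = rng.random(50) < 0.4
        s = rng.random(50)
        rep = confusion_metrics(y, s, 0.5)
        sens = rep.tp / (rep.tp + rep.fn)
        spec = rep.tn / (rep.tn + rep.fp)
        assert rep.youden == pytest.approx(sens + spec - 1, abs=1e-15)
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / 50)


class TestConfusionMetrics:
    def test_hand_counted_eight_rows(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        s = np.array([0.9, 0.8, 0.4, 0.2, 0.7, 0.3, 0.2, 0.1])
        rep = confusion_metrics(y, s, 0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 1, 3, 2)
        assert rep.recall == pytest.approx(0.5)
        assert rep.specificity == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(2 * (2 / 3) * 0.5 / (2 / 3 + 0.5))

    def test_all_correct(self):
        y = np.array([True, False, True])
        rep = confusion_metrics(y, y.astype(float), 0.5)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0 and rep.youden == 1.0

    def test_boundary_score_counts_positive(self):
        rep = confusion_metrics([True], [0.5], 0.5)
        assert rep.tp == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [], 0.5)


class TestROCAUC:
    def test_perfect_and_reversed(self):
        y = np.array([True, True, False, False])
        assert roc_auc(y, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert roc_auc(y, [0.1, 0.2, 0.8, 0.9]) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random(30) < 0.5
        if y.all() or not y.any():
            return
        s = np.round(rng.random(30), 2)  # coarse grid to exercise ties
        conc = 0.0
        pairs = 0
        for i in np.flatnonzero(y):
            for j in np.flatnonzero(~y):
                pairs += 1
                if s[i] > s[j]:
                    conc += 1.0
                elif s[i] == s[j]:
                    conc += 0.5
        assert roc_auc(y, s) == pytest.approx(conc / pairs, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random(25) < 0.5
        if y.all() or not y.any():
            return
        s = rng.random(25)
        assert roc_auc(y, s) == pytest.approx(roc_auc(y, np.exp(3 * s)), abs=1e-12)


def _oracle_best_cutoff(y, s):
    """Independent exhaustive scan."""
    best = (None, -np.inf)
    for c in sorted(set(s)):
        pred = np.asarray(s) >= c
        y = np.asarray(y, dtype=bool)
        sens = (pred & y).sum() / max(y.sum(), 1)
        spec = (~pred & ~y).sum() / max((~y).sum(), 1)
        g = sens + spec - 1
        if g > best[1]:
            best = (c, g)
    return best


class TestCutoffSelection:
    def test_scores_equal_labels(self):
        y = np.array([True, False, True, False])
        c, g = best_cutoff(y, y.astype(float))
        assert g == 1.0
        # candidates are the unique observed scores {0, 1}; 1.0 is the
        # smallest candidate attaining gamma = 1
        assert c == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            return
        s = np.round(rng.random(n), 2)
        c, g = best_cutoff(y, s)
        oc, og = _oracle_best_cutoff(y, s)
        assert g == pytest.approx(og, abs=1e-12)
        assert c == oc

    def test_cv_cutoff_deterministic_and_sane(self):
        rng = np.random.default_rng(5)
        n = 200
        y = rng.random(n) < 0.45
        X = pd.DataFrame({"x": y + rng.normal(0, 0.6, n)})

        def fit_score(Xtr, ytr, Xva):
            mu1 = Xtr.loc[ytr, "x"].mean()
            mu0 = Xtr.loc[~ytr, "x"].mean()
            d = (Xva["x"] - mu0) / (mu1 - mu0)
            return np.clip(d, 0, 1).to_numpy()

        c1 = select_cutoff_cv(fit_score, X, y, CutoffConfig(n_folds=10, seed=0))
        c2 = select_cutoff_cv(fit_score, X, y, CutoffConfig(n_folds=10, seed=0))
        assert c1 == c2
        assert 0.0 <= c1 <= 1.0

    def test_label_permutation_chance_band(self):
        """Under permuted labels the selected operating point's out-of-sample
        Youden stays near zero."""
        rng = np.random.default_rng(7)
        n = 200
        X = pd.DataFrame({"x": rng.normal(0, 1, n)})
        y = rng.permutation(np.repeat([True, False], n // 2))

        def fit_score(Xtr, ytr, Xva):
            return np.clip(Xva["x"].to_numpy() * 0.1 + 0.5, 0, 1)

        gammas = []
        for seed in range(6):
            yp = np.random.default_rng(seed).permutation(y)
            c = select_cutoff_cv(fit_score, X, yp, CutoffConfig(n_folds=10, seed=seed))
            rep = confusion_metrics(yp, fit_score(X, yp, X), c)
            gammas.append(rep.youden)
        assert np.median(gammas) <= 0.25

    def test_too_few_per_class_rejected(self):
        y = np.array([True] * 3 + [False] * 20)
        X = pd.DataFrame({"x": np.arange(23.0)})
        with pytest.raises(ValueError, match="n_folds"):
            select_cutoff_cv(lambda a, b, c: np.zeros(len(c)), X, y,
                             CutoffConfig(n_folds=10))


class TestChi2Df2:
    def test_zero_statistic(self):
        assert chi2_df2_p(0.0) == 1.0

    @pytest.mark.parametrize("stat", [0.5, 2.0, 11.878, 22.90])
    def test_matches_generic_survival_function(self, stat):
        assert chi2_df2_p(stat) == pytest.approx(stats.chi2.sf(stat, df=2), abs=1e-12)


def _counts_cohort(spec: dict) -> pd.DataFrame:
    """Deterministic cohort whose contingency tables equal given counts.

    spec: {column: ({level: count_lvo}, {level: count_nolvo})}
    """
    n_pos, n_neg = 130, 170
    data = {"lvo": np.repeat([True, False], [n_pos, n_neg])}
    for col, (pos_counts, neg_counts) in spec.items():
        vals = []
        for counts, n in ((pos_counts, n_pos), (neg_counts, n_neg)):
            assert sum(counts.values()) == n
            for lv, k in counts.items():
                vals += [lv] * k
        data[col] = np.array(vals, dtype=object)
    df = pd.DataFrame(data)
    df["id"] = [f"P{i}" for i in range(len(df))]
    for col in spec:
        df.loc[df[col] == "NA", col] = np.nan
    return df


class TestTableOne:
    def test_atrial_fibrillation_printed_p(self):
        df = _counts_cohort({"atrial_fibrillation": ({"yes": 48, "NA": 82},
                                                     {"yes": 32, "NA": 138})})
        out = table_one(df, columns=["atrial_fibrillation"])
        assert out.iloc[0]["test"] == "chi-square-yates-2x2"
        assert out.iloc[0]["p"] == pytest.approx(7.22e-4, rel=5e-3)

    def test_facial_weakness_printed_p(self):
        df = _counts_cohort({"facial_weakness": ({"yes": 41, "no": 11, "NA": 78},
                                                 {"yes": 44, "no": 53, "NA": 73})})
        out = table_one(df, columns=["facial_weakness"])
        assert out.iloc[0]["test"] == "chi-square-df2-with-unknown"
        assert out.iloc[0]["p"] == pytest.approx(1.06e-5, rel=5e-3)

    def test_balanced_2x2_p_one(self):
        df = _counts_cohort({"v": ({"yes": 65, "no": 65}, {"yes": 85, "no": 85})})
        out = table_one(df, columns=["v"])
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_sparse_table_routes_to_fisher(self):
        df = _counts_cohort({"v": ({"yes": 2, "no": 128}, {"yes": 3, "no": 167})})
        out = table_one(df, columns=["v"])
        assert out.iloc[0]["test"] == "fisher-exact"

    def test_continuous_uses_student_t(self, cohort300):
        out = table_one(cohort300, columns=["age"])
        assert out.iloc[0]["test"] == "student-t"
        y = cohort300["lvo"]
        ref = stats.ttest_ind(cohort300.loc[y, "age"], cohort300.loc[~y, "age"],
                              equal_var=True)
        assert out.iloc[0]["p"] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_class_rejected(self, cohort300):
        df = cohort300[cohort300["lvo"]]
        with pytest.raises(ValueError):
            table_one(df)


class TestReconstructConfusion:
    def test_level3_xgb_matrix_unique(self):
        assert reconstruct_confusion(0.953, 0.684, 0.800) == (41, 18, 39, 2)

    def test_no_match_raises(self):
        with pytest.raises(ValueError, match="no confusion matrix"):
            reconstruct_confusion(0.999, 0.999, 0.5)
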