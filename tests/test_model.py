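import numpy as np
import pandas as pd
import pytest

from abruptcut._errors import ParameterError
from abruptcut.features import FeatureTable
from abruptcut.model import (
    ClassifierConfig,
    channel_scores,
    elimination_curve,
    evaluate,
    metrics,
    svm_rfe_rank,
)


def table_from(X, y, columns=None, normalized=True):
    frame = pd.DataFrame(np.asarray(X, dtype=float), columns=columns)
    labels = pd.Series(np.where(np.asarray(y) == 1, "malignant", "benign"),
                       index=frame.index)
    return FeatureTable(frame, labels, normalized=normalized)


def separable_table(n=20, p=5, seed=0):
    """f1 alone separates the classes; the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 1, (n, p))
    X[:, 0] = np.where(y == 1, 1.0, -1.0)
    cols = [f"f{i + 1}" for i in range(p)]
    return table_from(X, y, columns=cols), y


class TestMetrics:
    def test_perfect_confusion_at_paper_class_sizes(self):
        rep = metrics(TP=31, TN=69, FP=0, FN=0)
        assert rep.precision == rep.recall == rep.f_measure == 1.0
        assert rep.accuracy == 1.0
        assert rep.TP + rep.TN + rep.FP + rep.FN == 100

    def test_f_closed_form(self):
        # precision 0.5, recall 1.0 -> F = 2/3
        rep = metrics(TP=10, TN=0, FP=10, FN=0)
        assert rep.precision == pytest.approx(0.5)
        assert rep.recall == 1.0
        assert rep.f_measure == pytest.approx(2 / 3)

    def test_zero_tp_gives_zero_f(self):
        rep = metrics(TP=0, TN=5, FP=0, FN=5)
        assert rep.f_measure == 0.0
        assert rep.recall == 0.0

    def test_sensitivity_equals_recall_specificity(self):
        rep = metrics(TP=8, TN=12, FP=3, FN=2)
        assert rep.sensitivity == rep.recall
        assert rep.specificity == pytest.approx(12 / 15)
        for v in (rep.accuracy, rep.precision, rep.recall, rep.f_measure,
                  rep.specificity):
            assert 0.0 <= v <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            metrics(-1, 0, 0, 0)


class TestSvmRfeRank:
    def test_separating_feature_ranked_last_removed(self):
        t, _ = separable_table()
        ranks = svm_rfe_rank(t)
        assert ranks["f1"] == len(t.feature_columns)

    def test_ranks_are_permutation(self):
        t, _ = separable_table(p=7, seed=3)
        ranks = svm_rfe_rank(t)
        assert sorted(ranks.values()) == list(range(1, 8))

    def test_single_feature(self):
        t, _ = separable_table(p=1)
        assert svm_rfe_rank(t) == {"f1": 1}

    def test_duplicate_columns_adjacent_ranks_column_order_tie(self):
        rng = np.random.default_rng(0)
        n = 24
        y = np.array([0] * 12 + [1] * 12)
        sig = y + rng.normal(0, 0.3, n)
        dup = y + rng.normal(0, 0.5, n)
        t = table_from(
            np.column_stack([sig, dup, dup, rng.normal(0, 1, n),
                             rng.normal(0, 1, n)]),
            y, columns=["s", "d1", "d2", "n1", "n2"],
        )
        ranks = svm_rfe_rank(t)
        assert abs(ranks["d1"] - ranks["d2"]) == 1
        assert ranks["d1"] < ranks["d2"]  # first column dropped first

    def test_non_finite_rejected(self):
        t, _ = separable_table()
        t.frame.iloc[0, 0] = np.nan
        with pytest.raises(ParameterError):
            svm_rfe_rank(t)

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"f": [1.0, 2.0]})
        labels = pd.Series(["benign", "benign"], index=frame.index)
        with pytest.raises(ParameterError):
            svm_rfe_rank(FeatureTable(frame, labels, normalized=True))


class TestChannelScores:
    def test_top_block_sum(self):
        # one channel holding ranks 217..240 scores the arithmetic-series sum
        names, ranks = [], {}
        rank = 1
        for ch in ("Gra", "Red", "Gre", "Y", "Cb", "Cr", "Hue", "Sat", "V"):
            for r in (5, 7, 10, 15):
                for stat in ("AH", "MH", "AM", "MM", "AS", "MS"):
                    ranks[f"{ch}-{r}-{stat}"] = rank
                    rank += 1
        for r in (5, 7, 10, 15):
            for stat in ("AH", "MH", "AM", "MM", "AS", "MS"):
                ranks[f"Blu-{r}-{stat}"] = rank
                rank += 1
        scores = channel_scores(ranks)
        assert scores["Blu"] == sum(range(217, 241)) == 5484
        assert list(scores)[0] == "Blu"

    def test_scores_sum_to_rank_total(self):
        rng = np.random.default_rng(1)
        perm = rng.permutation(48) + 1
        names = [f"{ch}-{r}-A{s}" for ch in ("Blu", "Cr") for r in (5, 7, 10, 15)
                 for s in "HMS"] + \
                [f"{ch}-{r}-M{s}" for ch in ("Blu", "Cr") for r in (5, 7, 10, 15)
                 for s in "HMS"]
        scores = channel_scores(dict(zip(names, perm)))
        assert sum(scores.values()) == 48 * 49 // 2 == 1176

    def test_incomplete_ranking_rejected(self):
        with pytest.raises(ParameterError):
            channel_scores({"Blu-5-AH": 1, "Blu-5-MH": 3})


class TestEvaluate:
    def test_model_scheme_on_separable(self):
        t, _ = separable_table()
        rep = evaluate(t, ClassifierConfig(kernel="linear"), "model")
        assert rep.accuracy == 1.0

    def test_loo_on_xor_linear_fails(self):
        t = table_from([[0, 0], [0, 1], [1, 0], [1, 1]], [0, 1, 1, 0],
                       columns=["f1", "f2"])
        rep = evaluate(t, ClassifierConfig(kernel="linear"), "loo")
        assert rep.accuracy <= 0.5

    def test_cv10_reproducible(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (30, 4))
        y = np.array([0, 1] * 15)
        X[:, 0] += y * 1.5
        t = table_from(X, y, columns=list("abcd"))
        cfg = ClassifierConfig(seed=42)
        r1 = evaluate(t, cfg, "cv10")
        r2 = evaluate(t, cfg, "cv10")
        assert r1 == r2

    def test_cv10_needs_ten_rows(self):
        t, _ = separable_table(n=8)
        with pytest.raises(ParameterError):
            evaluate(t, scheme="cv10")

    def test_unknown_scheme_rejected(self):
        t, _ = separable_table()
        with pytest.raises(ParameterError):
            evaluate(t, scheme="5CV")

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"f": [1.0, 2.0]})
        labels = pd.Series(["benign", "benign"], index=frame.index)
        with pytest.raises(ParameterError):
            evaluate(FeatureTable(frame, labels, normalized=True))

    def test_unnormalized_table_fold_scaling(self):
        # raw-scale features still classify: normalization is fit per fold
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 3)) * 1000 + 5000
        y = np.array([0, 1] * 10)
        X[:, 0] += y * 4000
        t = table_from(X, y, columns=list("abc"), normalized=False)
        rep = evaluate(t, ClassifierConfig(kernel="linear"), "loo")
        assert rep.accuracy >= 0.9

    def test_model_at_least_loo_on_average(self):
        deltas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 15 + [1] * 15)
            X = rng.normal(0, 1, (30, 6)) + y[:, None] * 0.8
            t = table_from(X, y, columns=[f"c{i}" for i in range(6)])
            deltas.append(evaluate(t, scheme="model").accuracy
                          - evaluate(t, scheme="loo").accuracy)
        assert np.mean(deltas) >= 0.0


class TestEliminationCurve:
    def test_curve_shape_and_consistency(self):
        t, _ = separable_table(p=5)
        cfg = ClassifierConfig(kernel="linear")
        curve = elimination_curve(t, cfg, schemes=("model",))
        assert len(curve) == 5
        assert curve[0]["n_features"] == 5
        assert curve[-1]["n_features"] == 1
        full = evaluate(t, cfg, "model")
        assert curve[0]["accuracy_model"] == pytest.approx(full.accuracy)

    def test_separable_stays_perfect(self):
        t, _ = separable_table(p=4)
        cfg = ClassifierConfig(kernel="linear")
        ranks = svm_rfe_rank(t, cfg)
        curve = elimination_curve(t, cfg, schemes=("model",), ranks=ranks)
        # f1 is ranked best, so every prefix contains it
        assert all(e["accuracy_model"] == 1.0 for e in curve)


class TestClassifierConfig:
    def test_invalid_kernel(self):
        with pytest.raises(ParameterError):
            ClassifierConfig(kernel="sigmoid")

    def test_invalid_type(self):
        with pytest.raises(ParameterError):
            ClassifierConfig(svm_type="epsilon")

    def test_nu_svm_builds(self):
        clf = ClassifierConfig(svm_type="nu", kernel="polynomial").build()
        assert clf.kernel == "poly"

    def test_force_linear_for_rfe(self):
        clf = ClassifierConfig(kernel="rbf").build(force_linear=True)
        assert clf.kernel == "linear"
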