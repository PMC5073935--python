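"""SVM-RFE feature ranking, per-channel scores, and classifier assessment.

Ranking: a linear SVM is refit repeatedly, each round discarding the
feature with the smallest squared weight; the first feature discarded gets
rank 1 and the last survivor rank p (higher rank = more significant). The
per-channel total score is the sum of that channel's feature ranks.

Assessment schemes: ``model`` (train and test on everything), ``loo``
(leave-one-out) and ``cv10`` (stratified, seeded 10-fold). Min/max
normalization to [-1, 1] is fit on each training portion and applied to
the held-out portion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.svm import SVC, NuSVC

from ._errors import ParameterError
from .features import FeatureTable, normalize_like

SCHEMES = ("model", "loo", "cv10")


@dataclass(frozen=True)
class ClassifierConfig:
    svm_type: str = "C"  # 'C' or 'nu'
    kernel: str = "rbf"  # linear | polynomial | rbf
    C: float = 1.0
    nu: float = 0.5
    gamma: float | str = "auto"  # 'auto' = 1/p
    degree: int = 3
    coef0: float = 0.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.svm_type not in ("C", "nu"):
            raise ParameterError(f"svm_type must be 'C' or 'nu', got {self.svm_type}")
        if self.kernel not in ("linear", "polynomial", "rbf"):
            raise ParameterError(f"unsupported kernel {self.kernel!r}")

    def build(self, *, force_linear: bool = False):
        kernel = "linear" if force_linear else self.kernel
        if kernel == "polynomial":
            kernel = "poly"
        kwargs = dict(
            kernel=kernel, gamma=self.gamma, degree=self.degree,
            coef0=self.coef0, random_state=self.seed,
        )
        if self.svm_type == "C":
            return SVC(C=self.C, **kwargs)
        return NuSVC(nu=self.nu, **kwargs)


@dataclass(frozen=True)
class EvalReport:
    scheme: str
    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


def metrics(TP: int, TN: int, FP: int, FN: int, scheme: str = "model") -> EvalReport:
    """Confusion counts -> metric report; zero denominators yield 0."""
    if min(TP, TN, FP, FN) < 0:
        raise ParameterError("confusion counts must be nonnegative")
    n = TP + TN + FP + FN

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else 0.0

    accuracy = _ratio(TP + TN, n)
    recall = _ratio(TP, TP + FN)
    precision = _ratio(TP, TP + FP)
    f = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    specificity = _ratio(TN, TN + FP)
    return EvalReport(
        scheme=scheme, TP=TP, TN=TN, FP=FP, FN=FN,
        accuracy=accuracy, precision=precision, recall=recall,
        f_measure=f, sensitivity=recall, specificity=specificity,
    )


def svm_rfe_rank(t: FeatureTable, cfg: ClassifierConfig | None = None) -> Dict[str, int]:
    """Backward elimination with a linear SVM, one feature per round.

    Returns rendered-name -> rank in 1..p (higher = kept longer = more
    significant). Ties in squared weight are broken by column order.
    """
    cfg = cfg or ClassifierConfig()
    X = t.X()
    y = t.y()
    if np.unique(y).size < 2:
        raise ParameterError("ranking needs both classes present")
    if not np.isfinite(X).all():
        raise ParameterError("feature table contains non-finite values")
    names = list(t.feature_columns)
    p = len(names)
    remaining = list(range(p))
    ranks: Dict[str, int] = {}
    next_rank = 1
    while len(remaining) > 1:
        clf = cfg.build(force_linear=True)
        clf.fit(X[:, remaining], y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        drop_pos = int(np.argmin(w2))  # argmin keeps first on ties
        ranks[names[remaining[drop_pos]]] = next_rank
        next_rank += 1
        del remaining[drop_pos]
    ranks[names[remaining[0]]] = next_rank
    return ranks


def channel_scores(ranks: Dict[str, int]) -> Dict[str, int]:
    """Total score per channel: sum of its feature ranks, sorted descending."""
    p = len(ranks)
    if sorted(ranks.values()) != list(range(1, p + 1)):
        raise ParameterError("ranks must be a permutation of 1..p")
    totals: Dict[str, int] = {}
    for name, r in ranks.items():
        chan = name.split("-")[0]
        totals[chan] = totals.get(chan, 0) + r
    return dict(sorted(totals.items(), key=lambda kv: -kv[1]))


def _fit_predict(
    train: pd.DataFrame, test: pd.DataFrame, y_train: np.ndarray,
    cfg: ClassifierConfig, prenormalized: bool,
) -> np.ndarray:
    if prenormalized:
        Xtr, Xte = train.to_numpy(float), test.to_numpy(float)
    else:
        Xtr = normalize_like(train, train).to_numpy(float)
        Xte = normalize_like(test, train).to_numpy(float)
    clf = cfg.build()
    clf.fit(Xtr, y_train)
    return clf.predict(Xte)


def evaluate(
    t: FeatureTable,
    cfg: ClassifierConfig | None = None,
    scheme: str = "model",
    *,
    features: Sequence[str] | None = None,
) -> EvalReport:
    """Run one assessment scheme and pool held-out confusion counts."""
    cfg = cfg or ClassifierConfig()
    if scheme not in SCHEMES:
        raise ParameterError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    frame = t.frame if features is None else t.frame[list(features)]
    y = t.y()
    if np.unique(y).size < 2:
        raise ParameterError("evaluation needs both classes present")

    if scheme == "model":
        pred = _fit_predict(frame, frame, y, cfg, t.normalized)
        truth = y
    else:
        if scheme == "cv10":
            if len(y) < 10:
                raise ParameterError("cv10 needs at least 10 rows")
            splitter = StratifiedKFold(
                n_splits=10, shuffle=True, random_state=cfg.seed
            )
        else:
            splitter = LeaveOneOut()
        preds = np.empty_like(y)
        for tr_idx, te_idx in splitter.split(frame, y):
            preds[te_idx] = _fit_predict(
                frame.iloc[tr_idx], frame.iloc[te_idx], y[tr_idx], cfg, t.normalized
            )
        pred, truth = preds, y

    TP = int(np.sum((pred == 1) & (truth == 1)))
    TN = int(np.sum((pred == 0) & (truth == 0)))
    FP = int(np.sum((pred == 1) & (truth == 0)))
    FN = int(np.sum((pred == 0) & (truth == 1)))
    return metrics(TP, TN, FP, FN, scheme=scheme)


def elimination_curve(
    t: FeatureTable,
    cfg: ClassifierConfig | None = None,
    schemes: Iterable[str] = ("model",),
    ranks: Dict[str, int] | None = None,
) -> List[Dict[str, float]]:
    """Accuracy as features are discarded worst-first down to a single one.

    Uses one fixed initial ranking; each entry holds ``n_features`` and one
    accuracy per requested scheme.
    """
    cfg = cfg or ClassifierConfig()
    schemes = list(schemes)
    if ranks is None:
        ranks = svm_rfe_rank(t, cfg)
    ordered = sorted(t.feature_columns, key=lambda n: -ranks[n])  # best first
    curve = []
    for n in range(len(ordered), 0, -1):
        entry: Dict[str, float] = {"n_features": n}
        for scheme in schemes:
            rep = evaluate(t, cfg, scheme, features=ordered[:n])
            entry[f"accuracy_{scheme}"] = rep.accuracy
        curve.append(entry)
    return curve
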