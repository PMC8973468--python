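"""Exhaustive wrapper feature selection for difficulty classification.

Every non-empty subset of the seven pupil features (2^7 - 1 = 127) is
evaluated with every classifier family — SVM with linear, RBF and sigmoid
kernels, a squared-hinge linear SVC, LDA, a decision tree and a random
forest — under stratified 5-fold cross-validation. Per-class precision and
recall come from the confusion matrix pooled over the folds' test
predictions; macro precision/recall are unweighted means over the three
classes, and the headline F1 is the harmonic mean of macro precision and
macro recall (a per-class macro F1 is reported alongside). Configurations
are ranked by F1, ties broken toward smaller subsets.

Margin-based families (SVMs, LDA) see features standardised with
training-fold statistics; tree families see raw features. The RBF kernel
scale is set by the median heuristic on the (standardised) training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

CLASSIFIER_FAMILIES = (
    "svm_linear",
    "svm_rbf",
    "svm_sigmoid",
    "linear_svc",
    "lda",
    "decision_tree",
    "random_forest",
)

_SCALED_FAMILIES = {"svm_linear", "svm_rbf", "svm_sigmoid", "linear_svc", "lda"}

LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")


@dataclass
class ModelReport:
    """One classifier x feature-subset evaluation (one ranking-table row)."""

    family: str
    feature_subset: tuple
    per_class_precision: dict
    per_class_recall: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float  # harmonic mean of macro precision and macro recall
    macro_f1_classwise: float  # unweighted mean of per-class F1 scores
    fold_mean_f1: float  # mean over folds of the per-fold harmonic-mean F1


def enumerate_feature_subsets(feature_names) -> list[tuple]:
    """All 2^b - 1 non-empty subsets, ordered by size then position."""
    names = list(feature_names)
    if not names:
        raise ValueError("feature list must be non-empty")
    if len(names) > 20:
        raise ValueError("refusing to enumerate subsets of more than 20 features")
    out: list[tuple] = []
    for size in range(1, len(names) + 1):
        out.extend(combinations(names, size))
    return out


def make_folds(y, k: int, seed: int, groups=None) -> list[tuple[np.ndarray, np.ndarray]]:
    """k train/test index pairs; stratified by label, optionally grouped.

    With ``groups=None`` the folds are stratified by difficulty; passing
    per-row subject ids keeps every subject's trials in a single fold
    (the leakage-safe variant).
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(y):
        raise ValueError(f"cannot make {k} folds from {len(y)} rows")
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y)
    else:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(y)), y, groups=np.asarray(groups))
    return [(tr, te) for tr, te in split]


def _median_heuristic_gamma(X: np.ndarray, max_rows: int = 256, seed: int = 0) -> float:
    """1 / median squared pairwise distance, on a subsample for large folds."""
    if len(X) > max_rows:
        idx = np.random.default_rng(seed).choice(len(X), max_rows, replace=False)
        X = X[idx]
    d2 = pdist(X, "sqeuclidean")
    med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def _build_estimator(spec: ClassifierSpec, X_train: np.ndarray):
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "svm_linear":
        return SVC(kernel="linear", **hp)
    if fam == "svm_rbf":
        hp.setdefault("gamma", _median_heuristic_gamma(X_train, seed=spec.seed))
        return SVC(kernel="rbf", **hp)
    if fam == "svm_sigmoid":
        return SVC(kernel="sigmoid", **hp)
    if fam == "linear_svc":
        return LinearSVC(**hp)
    if fam == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if fam == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if fam == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    raise AssertionError(fam)


def _precision_recall(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred_tot = cm.sum(axis=0)
    true_tot = cm.sum(axis=1)
    tp = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
    return prec, rec


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def evaluate_model(
    features: pd.DataFrame,
    spec: ClassifierSpec,
    subset,
    k: int = 5,
    seed: int = 0,
    groups_col: str | None = None,
    folds=None,
) -> ModelReport:
    """Cross-validate one classifier on one feature subset.

    Per-fold test predictions are pooled into a single confusion matrix
    from which all metrics derive. ``folds`` may carry precomputed index
    pairs so a wrapper search holds the partition fixed across its 889
    configurations.
    """
    subset = tuple(subset)
    unknown = [f for f in subset if f not in features.columns]
    if unknown:
        raise ValueError(f"features not in table: {unknown}")
    X = features.loc[:, list(subset)].to_numpy(float)
    y = features["difficulty"].to_numpy()
    if folds is None:
        groups = features[groups_col].to_numpy() if groups_col else None
        folds = make_folds(y, k=k, seed=seed, groups=groups)
    labels = [lev for lev in LEVELS if lev in set(y)]
    pooled = np.zeros((len(labels), len(labels)), dtype=int)
    fold_f1 = []
    for tr, te in folds:
        if len(set(y[tr])) < len(labels):
            raise ValueError("a class is absent from a training fold")
        X_tr, X_te = X[tr], X[te]
        if spec.family in _SCALED_FAMILIES:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        est = _build_estimator(spec, X_tr)
        est.fit(X_tr, y[tr])
        pred = est.predict(X_te)
        cm = confusion_matrix(y[te], pred, labels=labels)
        pooled += cm
        fp, fr = _precision_recall(cm)
        fold_f1.append(_harmonic(float(fp.mean()), float(fr.mean())))
    prec, rec = _precision_recall(pooled)
    macro_p, macro_r = float(prec.mean()), float(rec.mean())
    classwise_f1 = float(np.mean([_harmonic(p, r) for p, r in zip(prec, rec)]))
    return ModelReport(
        family=spec.family,
        feature_subset=subset,
        per_class_precision={lab: float(p) for lab, p in zip(labels, prec)},
        per_class_recall={lab: float(r) for lab, r in zip(labels, rec)},
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=_harmonic(macro_p, macro_r),
        macro_f1_classwise=classwise_f1,
        fold_mean_f1=float(np.mean(fold_f1)),
    )


def wrapper_search(
    features: pd.DataFrame,
    families=CLASSIFIER_FAMILIES,
    k: int = 5,
    seed: int = 0,
    feature_names=FEATURE_NAMES,
    groups_col: str | None = None,
) -> list[ModelReport]:
    """Evaluate every family x subset pair; rank by macro F1 descending.

    Ties prefer fewer features, then earlier subsets in enumeration order,
    then family order — making the ranking fully deterministic.
    """
    if features["difficulty"].nunique() < 2:
        raise ValueError("need at least 2 classes")
    y = features["difficulty"].to_numpy()
    groups = features[groups_col].to_numpy() if groups_col else None
    folds = make_folds(y, k=k, seed=seed, groups=groups)
    subsets = enumerate_feature_subsets(feature_names)
    subset_order = {s: i for i, s in enumerate(subsets)}
    family_order = {f: i for i, f in enumerate(families)}
    reports: list[ModelReport] = []
    for family in families:
        spec = ClassifierSpec(family=family, seed=seed)
        for subset in subsets:
            reports.append(evaluate_model(features, spec, subset, folds=folds))
    reports.sort(
        key=lambda r: (
            -r.macro_f1,
            len(r.feature_subset),
            subset_order[r.feature_subset],
            family_order[r.family],
        )
    )
    return reports


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Ranking table: one row per configuration, best first."""
    rows = []
    for rank, r in enumerate(reports, start=1):
        rows.append(
            {
                "rank": rank,
                "classifier": r.family,
                "subset": "+".join(r.feature_subset),
                "n_features": len(r.feature_subset),
                "prec_low": r.per_class_precision.get("low", np.nan),
                "prec_med": r.per_class_precision.get("medium", np.nan),
                "prec_high": r.per_class_precision.get("high", np.nan),
                "avg_prec": r.macro_precision,
                "avg_recall": r.macro_recall,
                "f1": r.macro_f1,
                "f1_classwise": r.macro_f1_classwise,
                "f1_fold_mean": r.fold_mean_f1,
            }
        )
    return pd.DataFrame(rows)
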