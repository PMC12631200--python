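"""Splitting, random-forest training, CV, confusion-matrix metrics, MDA.

The classifier is scikit-learn's RandomForestClassifier behind a thin
contract; accuracy bookkeeping (overall accuracy OA, Cohen's Kappa,
producer's accuracy PA = row-wise recall, user's accuracy UA =
column-wise precision) is computed here from the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from defoliascan.damage import STAGE_ORDER
from defoliascan.errors import InvalidInputError


@dataclass
class RFConfig:
    """Random-forest settings: 500 trees, sqrt feature subsampling, fixed seed."""

    n_estimators: int = 500
    random_state: int = 42
    max_features: str = "sqrt"

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state,
            n_jobs=1,
        )


@dataclass
class SplitPlan:
    """Stratified train/test index sets; per-class train counts are the
    nearest integer to ratio x class size, test is the complement."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    ratio: float
    seed: int


def stratified_split(labels, ratio: float = 0.6, seed: int = 0) -> SplitPlan:
    """Per-class nearest-integer stratified split, shuffled by seed."""
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise InvalidInputError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise InvalidInputError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = int(np.floor(ratio * len(idx) + 0.5))  # round half up
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return SplitPlan(
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)),
        ratio=ratio,
        seed=seed,
    )


def fit_predict_rf(X_train, y_train, X_test, rf_cfg: RFConfig | None = None):
    """Fit the forest and predict the test rows; returns (y_pred, model)."""
    rf_cfg = rf_cfg or RFConfig()
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise InvalidInputError("training data must contain >= 2 classes")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if np.any(~np.isfinite(X_train)) or np.any(~np.isfinite(X_test)):
        raise InvalidInputError("features contain missing values")
    model = rf_cfg.build()
    model.fit(X_train, y_train)
    return model.predict(X_test), model


@dataclass
class ClassificationReport:
    """Confusion matrix plus the accuracy metrics derived from it.

    OA and PA/UA are percentages; Kappa is unitless. Rounding happens
    only at presentation (``summary``), never in the stored values.
    """

    confusion: np.ndarray
    class_order: tuple
    oa: float
    kappa: float
    pa: dict
    ua: dict
    mean_pa: float
    mean_ua: float
    importances: dict | None = None
    cv_accuracy: float | None = None

    def summary(self, decimals: int = 2) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "oa_pct": round(self.oa, decimals),
            "kappa": round(self.kappa, decimals + 2),
            "pa_pct": {str(k): round(v, decimals) for k, v in self.pa.items()},
            "ua_pct": {str(k): round(v, decimals) for k, v in self.ua.items()},
            "mean_pa_pct": round(self.mean_pa, decimals),
            "mean_ua_pct": round(self.mean_ua, decimals),
        }


def report_from_confusion(matrix, class_order=STAGE_ORDER) -> ClassificationReport:
    """Derive OA / Kappa / PA / UA from a counts matrix (rows = truth)."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise InvalidInputError("confusion matrix must be square")
    if np.any(mat < 0):
        raise InvalidInputError("confusion matrix counts must be >= 0")
    total = mat.sum()
    if total == 0:
        raise InvalidInputError("empty confusion matrix")
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    diag = np.diag(mat)
    p_o = diag.sum() / total
    p_e = float(np.dot(row, col)) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(row > 0, 100.0 * diag / row, np.nan)
        ua = np.where(col > 0, 100.0 * diag / col, np.nan)
    classes = tuple(class_order[: mat.shape[0]])
    return ClassificationReport(
        confusion=np.asarray(matrix),
        class_order=classes,
        oa=100.0 * p_o,
        kappa=float(kappa),
        pa=dict(zip(classes, pa)),
        ua=dict(zip(classes, ua)),
        mean_pa=float(np.nanmean(pa)),
        mean_ua=float(np.nanmean(ua)),
    )


def confusion_and_report(y_true, y_pred, class_order=None) -> ClassificationReport:
    """Build the confusion matrix from label vectors and score it."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise InvalidInputError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise InvalidInputError("label vectors must have equal length")
    if class_order is None:
        class_order = tuple(np.unique(np.concatenate([y_true, y_pred])).tolist())
    mat = _sk_confusion(y_true, y_pred, labels=list(class_order))
    return report_from_confusion(mat, class_order=class_order)


def cross_val_accuracy(X, y, folds: int = 10, rf_cfg: RFConfig | None = None,
                       seed: int = 0) -> float:
    """Mean accuracy over stratified k-fold CV of the configured forest."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise InvalidInputError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise InvalidInputError(
            f"smallest class ({counts.min()}) cannot be stratified into {folds} folds"
        )
    rf_cfg = rf_cfg or RFConfig()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = rf_cfg.build()
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def mda_importance(model, X_eval, y_eval, n_repeats: int = 10, seed: int = 0):
    """Mean-decrease-accuracy permutation importance on a held-out set.

    Each feature is shuffled ``n_repeats`` times and the drop in
    accuracy relative to the unpermuted evaluation is averaged. Returns
    (importance mean, importance sd) arrays over features.
    """
    X_eval = np.asarray(X_eval, dtype=float)
    if X_eval.shape[1] < 2:
        raise InvalidInputError("need >= 2 features for importance ranking")
    result = permutation_importance(
        model, X_eval, np.asarray(y_eval), n_repeats=n_repeats,
        random_state=seed, scoring="accuracy",
    )
    return result.importances_mean, result.importances_std
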