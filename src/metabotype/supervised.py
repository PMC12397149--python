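"""Classifiers, PLS regression, performance metrics and VIP panel selection.

All model kinds sit behind one contract: :func:`fit_model` grid-searches the
hyperparameters by 7-fold cross-validation on the training data only
(maximizing balanced accuracy for classification, minimizing CV RMSEP for
regression), breaking ties toward the simpler model, and refits on the full
training set.

:class:`PLSDAClassifier` is a scikit-learn estimator wrapping PLS regression
on a +/-1 class code; VIP (Variable Importance in Projection) scores are
available for any PLS-family fit and drive panel selection via the
greater-than-one rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .blocks import ClassLabelSet  # noqa: F401  (re-exported convenience)

__all__ = [
    "ModelSpec",
    "ConfusionMatrix",
    "RegressionMetrics",
    "PLSDAClassifier",
    "FittedModel",
    "fit_model",
    "predict_confusion",
    "balanced_accuracy",
    "random_undersample",
    "regression_metrics",
    "vip_scores",
    "select_vip",
]

MODEL_KINDS = ("plsda", "svm_linear", "random_forest", "plsr")


def _default_grid(kind: str) -> dict[str, list]:
    if kind in ("plsda", "plsr"):
        return {"n_components": list(range(1, 16))}
    if kind == "svm_linear":
        return {"C": [0.01, 0.1, 1.0, 10.0, 100.0]}
    if kind == "random_forest":
        return {"n_estimators": [500], "max_features": ["sqrt", "quarter", "half"]}
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class ModelSpec:
    """Which model to fit and how to tune it.

    ``grid`` maps hyperparameter name to candidate values; ``cv_folds``
    cross-validation folds used for tuning (default 7).
    """

    kind: str
    grid: dict[str, list] | None = None
    cv_folds: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.grid is None:
            self.grid = _default_grid(self.kind)
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def is_regression(self) -> bool:
        return self.kind == "plsr"


@dataclass
class ConfusionMatrix:
    """2x2 counts, rows = predicted, columns = actual.

    With positive class first: [[TP, FP], [FN, TN]].
    """

    counts: np.ndarray
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a 2x2 non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_percent(self) -> np.ndarray:
        return 100.0 * self.counts / self.counts.sum()


@dataclass
class RegressionMetrics:
    """RMSEP (response units) and Q2 of blind test predictions.

    Q2 is None when the true response is constant on the test set (its
    denominator vanishes); RMSEP is always defined.
    """

    rmsep: float
    q2: float | None


# ---------------------------------------------------------------------------
# PLS-DA estimator
# ---------------------------------------------------------------------------


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis for two classes.

    The class labels are coded -1/+1 (positive = ``classes_[1]``), a PLS
    regression is fitted on the code, and samples are assigned to the class
    whose code is nearest to the predicted response (threshold 0).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"degenerate labels: PLS-DA needs exactly 2 classes, got {len(self.classes_)}"
            )
        code = np.where(y == self.classes_[1], 1.0, -1.0)
        ncomp = min(self.n_components, X.shape[1], X.shape[0] - 1)
        self.pls_ = PLSRegression(n_components=ncomp, scale=False).fit(X, code)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "pls_")
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0])


def _build_estimator(kind: str, params: dict, seed: int, n_features: int):
    params = dict(params)
    if kind == "plsda":
        return PLSDAClassifier(n_components=int(params["n_components"]))
    if kind == "plsr":
        return PLSRegression(n_components=int(params["n_components"]), scale=False)
    if kind == "svm_linear":
        return SVC(kernel="linear", C=float(params["C"]), random_state=seed)
    if kind == "random_forest":
        mf = params.get("max_features", "sqrt")
        if mf == "quarter":
            mf = max(1, n_features // 4)
        elif mf == "half":
            mf = max(1, n_features // 2)
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 500)),
            max_features=mf,
            random_state=seed,
        )
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class FittedModel:
    """A tuned, refitted estimator plus its provenance."""

    estimator: object
    spec: ModelSpec
    chosen_params: dict
    cv_score: float
    classes: tuple[str, str] | None = None
    feature_names: list[str] | None = field(default=None)

    @property
    def kind(self) -> str:
        return self.spec.kind


def _candidate_list(spec: ModelSpec, n_train: int, p: int) -> list[dict]:
    """Expand the grid simplest-first and cap PLS components at
    min(p, n_train - fold size)."""
    grid = {k: list(v) for k, v in spec.grid.items()}
    if spec.kind in ("plsda", "plsr"):
        fold = int(np.ceil(n_train / spec.cv_folds))
        cap = max(1, min(p, n_train - fold - 1))
        comps = sorted(c for c in grid.get("n_components", [1]) if c <= cap)
        grid["n_components"] = comps or [1]
    elif spec.kind == "svm_linear":
        grid["C"] = sorted(grid["C"])  # small C = stronger regularization first
    elif spec.kind == "random_forest":
        order = {"sqrt": 0, "quarter": 1, "half": 2}
        if "max_features" in grid:
            grid["max_features"] = sorted(
                grid["max_features"], key=lambda m: order.get(m, 99)
            )
        if "n_estimators" in grid:
            grid["n_estimators"] = sorted(grid["n_estimators"])
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _cv_score(spec: ModelSpec, params: dict, X, y, classification: bool) -> float:
    seed = int(spec.seed) & 0x7FFFFFFF
    if classification:
        splitter = StratifiedKFold(spec.cv_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        splitter = KFold(spec.cv_folds, shuffle=True, random_state=seed)
        split = splitter.split(X)
    scores = []
    for tr, te in split:
        if classification and len(np.unique(y[tr])) < 2:
            continue
        est = _build_estimator(spec.kind, params, seed, X.shape[1])
        est.fit(X[tr], y[tr])
        if classification:
            pred = est.predict(X[te])
            classes = np.unique(y)
            cm = _tally(pred, y[te], (classes[0], classes[1]))
            try:
                scores.append(balanced_accuracy(cm))
            except ValueError:
                continue
        else:
            pred = np.asarray(est.predict(X[te])).ravel()
            scores.append(float(np.sqrt(np.mean((y[te] - pred) ** 2))))
    if not scores:
        raise ValueError("no valid cross-validation fold")
    return float(np.mean(scores))


def fit_model(X, y, spec: ModelSpec, feature_names: list[str] | None = None) -> FittedModel:
    """Tune by k-fold CV on the training data only, then refit.

    Classification kinds maximize CV balanced accuracy, plsr minimizes CV
    RMSEP; ties go to the earlier (simpler) candidate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classification = not spec.is_regression
    if classification and len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: need two classes to fit a classifier")
    if X.shape[0] < spec.cv_folds:
        raise ValueError(
            f"n_train={X.shape[0]} is smaller than cv_folds={spec.cv_folds}"
        )
    candidates = _candidate_list(spec, X.shape[0], X.shape[1])
    if len(candidates) == 1:  # nothing to tune
        est = _build_estimator(
            spec.kind, candidates[0], int(spec.seed) & 0x7FFFFFFF, X.shape[1]
        )
        est.fit(X, y)
        classes = None
        if classification:
            u = np.unique(y)
            classes = (str(u[0]), str(u[1]))
        return FittedModel(est, spec, candidates[0], float("nan"), classes, feature_names)
    best_params, best_score = None, None
    for params in candidates:
        score = _cv_score(spec, params, X, y, classification)
        if best_score is None:
            best_params, best_score = params, score
        elif classification and score > best_score + 1e-12:
            best_params, best_score = params, score
        elif not classification and score < best_score - 1e-12:
            best_params, best_score = params, score
    est = _build_estimator(spec.kind, best_params, int(spec.seed) & 0x7FFFFFFF, X.shape[1])
    est.fit(X, y)
    classes = None
    if classification:
        u = np.unique(y)
        classes = (str(u[0]), str(u[1]))
    return FittedModel(est, spec, best_params, best_score, classes, feature_names)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _tally(pred, actual, class_names: tuple[str, str]) -> ConfusionMatrix:
    pos, neg = class_names[0], class_names[1]
    pred = np.asarray(pred)
    actual = np.asarray(actual)
    counts = np.array(
        [
            [(pred == pos)[actual == pos].sum(), (pred == pos)[actual == neg].sum()],
            [(pred == neg)[actual == pos].sum(), (pred == neg)[actual == neg].sum()],
        ],
        dtype=int,
    )
    return ConfusionMatrix(counts, class_names)


def predict_confusion(model: FittedModel, X_test, y_test, class_names=None) -> ConfusionMatrix:
    """Confusion matrix of a fitted classifier: predicted in rows, actual in columns."""
    X_test = np.asarray(X_test, dtype=float)
    if X_test.shape[0] == 0:
        raise ValueError("test set is empty")
    pred = model.estimator.predict(X_test)
    if class_names is None:
        class_names = model.classes
    return _tally(pred, np.asarray(y_test), tuple(class_names))


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of the two per-class recalls, (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    tp, fp = cm.counts[0]
    fn, tn = cm.counts[1]
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("an actual class is absent from the test set")
    return float((tp / (tp + fn) + tn / (tn + fp)) / 2.0)


def random_undersample(labels, seed: int) -> np.ndarray:
    """Indices keeping all minority samples and an equal-size random majority subset."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("random_undersample needs two classes")
    if len(classes) != 2:
        raise ValueError("random_undersample supports binary labels only")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    keep = []
    for cls in classes:
        idx = np.where(labels == cls)[0]
        if cls != minority and len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """RMSEP = sqrt(mean squared prediction error); Q2 = 1 - PRESS/TSS.

    The reference mean in Q2 is the test-set mean of the true response.  A
    constant true response leaves Q2 undefined (None).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    press = float(np.sum((y_true - y_pred) ** 2))
    rmsep = float(np.sqrt(press / y_true.size))
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    q2 = None if tss == 0.0 else 1.0 - press / tss
    return RegressionMetrics(rmsep=rmsep, q2=q2)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------


@dataclass
class VIPScore:
    feature_name: str
    vip: float
    selected: bool


def _get_pls(model) -> PLSRegression:
    if isinstance(model, FittedModel):
        model = model.estimator
    if isinstance(model, PLSDAClassifier):
        model = model.pls_
    if not isinstance(model, PLSRegression):
        raise ValueError("VIP scores require a PLS-family model (plsda or plsr)")
    check_is_fitted(model, "x_weights_")
    return model


def vip_scores(model, feature_names: list[str] | None = None, threshold: float = 1.0) -> list[VIPScore]:
    """Variable Importance in Projection scores of a fitted PLS model.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ), where
    SS_a is the response sum of squares explained by component a.  The mean
    square of the VIPs is 1 by construction; ``selected`` applies the
    strict greater-than-``threshold`` rule.
    """
    names = None
    if isinstance(model, FittedModel):
        names = model.feature_names
    pls = _get_pls(model)
    W = pls.x_weights_  # p x A
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # 1 x A for a univariate response
    p, A = W.shape
    ss = (Q.ravel() ** 2) * np.einsum("ij,ij->j", T, T)  # explained response SS per comp
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ss) / ss.sum())
    if feature_names is None:
        feature_names = names or [f"x{j}" for j in range(p)]
    return [
        VIPScore(str(f), float(v), bool(v > threshold))
        for f, v in zip(feature_names, vip)
    ]


def select_vip(vips: list[VIPScore], threshold: float = 1.0) -> list[str]:
    """Feature names with VIP strictly greater than ``threshold``."""
    if not vips:
        raise ValueError("empty VIP list")
    return [v.feature_name for v in vips if v.vip > threshold]
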