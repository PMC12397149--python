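"""Bootstrap + permutation-NULL model validation and learning curves.

Each bootstrap iteration resamples n subjects with replacement as the
training set and uses the out-of-bag subjects as the test set (expected
63.2% / 36.8% split).  An observed model (7-fold CV-tuned) and a NULL model
(same training set, labels permuted) are fitted on identically scaled data
and evaluated on the same test set; the empirical p-value is the fraction of
iterations in which the NULL model beats the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from threadpoolctl import threadpool_limits

from .preprocess import Autoscaler, BlockScaler
from .supervised import (
    ConfusionMatrix,
    FittedModel,
    ModelSpec,
    balanced_accuracy,
    fit_model,
    predict_confusion,
    random_undersample,
    regression_metrics,
)

__all__ = [
    "BootstrapIteration",
    "ValidationSummary",
    "LearningCurve",
    "bootstrap_validate",
    "empirical_pvalue",
    "learning_curve",
]


@dataclass
class BootstrapIteration:
    train_indices: np.ndarray  # multiset, size n
    test_indices: np.ndarray  # out-of-bag
    train_fit_indices: np.ndarray  # training multiset actually fitted (post-RUS)
    observed_metric: float
    null_metric: float
    chosen_hyperparameters: dict
    observed_confusion: ConfusionMatrix | None = None
    null_confusion: ConfusionMatrix | None = None
    observed_rmsep: float | None = None
    null_rmsep: float | None = None


@dataclass
class ValidationSummary:
    iterations: list[BootstrapIteration]
    metric_name: str
    mean_metric: float
    metric_sd: float
    empirical_p: float
    class_names: tuple[str, str] | None = None
    averaged_confusion: np.ndarray | None = None  # mean of per-iteration percentages
    median_q2: float | None = None
    median_rmsep: float | None = None
    n_redraws: int = 0
    mean_train_fraction: float = field(default=float("nan"))
    mean_test_fraction: float = field(default=float("nan"))

    @property
    def B(self) -> int:
        return len(self.iterations)

    @property
    def p_label(self) -> str:
        """Human-readable empirical p; a zero count is reported as < 1/B."""
        if self.empirical_p == 0.0:
            return f"< {1.0 / self.B:g}"
        return f"{self.empirical_p:g}"

    def to_dict(self) -> dict:
        out = {
            "metric": self.metric_name,
            "B": self.B,
            "mean_metric": self.mean_metric,
            "metric_sd": self.metric_sd,
            "empirical_p": self.empirical_p,
            "empirical_p_label": self.p_label,
            "n_redraws": self.n_redraws,
            "mean_train_fraction": self.mean_train_fraction,
            "mean_test_fraction": self.mean_test_fraction,
        }
        if self.averaged_confusion is not None:
            out["averaged_confusion_percent"] = self.averaged_confusion.tolist()
            out["class_names"] = list(self.class_names)
        if self.median_q2 is not None:
            out["median_q2"] = self.median_q2
            out["median_rmsep"] = self.median_rmsep
        return out


@dataclass
class LearningCurve:
    train_fractions: np.ndarray
    mean_metric: np.ndarray
    sd_metric: np.ndarray
    repeats: int
    metric_name: str


def empirical_pvalue(observed, null, better: str = "higher", smoothed: bool = False) -> float:
    """Fraction of paired iterations where the NULL metric is strictly better.

    ``better`` is the direction in which the metric improves ("higher" for
    balanced accuracy and Q2, "lower" for RMSEP).  Ties never count as
    better.  With ``smoothed`` the (x+1)/(B+1) estimator is returned.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.shape != null.shape or observed.ndim != 1 or observed.size == 0:
        raise ValueError("observed and null must be equal-length 1-D arrays")
    if better == "higher":
        count = int(np.sum(null > observed))
    elif better == "lower":
        count = int(np.sum(null < observed))
    else:
        raise ValueError("better must be 'higher' or 'lower'")
    B = observed.size
    if smoothed:
        return (count + 1.0) / (B + 1.0)
    return count / B


def _make_scaler(block_sizes):
    if block_sizes is None:
        return Autoscaler()
    return BlockScaler(block_sizes=block_sizes)


def _evaluate_classifier(model: FittedModel, Xte, yte, class_names):
    cm = predict_confusion(model, Xte, yte, class_names)
    return balanced_accuracy(cm), cm


def bootstrap_validate(
    X,
    y,
    spec: ModelSpec,
    B: int = 1000,
    balance: bool = False,
    seed: int = 0,
    class_names: tuple[str, str] | None = None,
    block_sizes=None,
    global_scaling: bool = False,
    max_redraws: int = 100,
    smoothed: bool = False,
) -> ValidationSummary:
    """Bootstrap + permutation-NULL validation of one model on one data set.

    Per iteration: draw a bootstrap training multiset and its out-of-bag
    test set (redrawn, with logging in ``n_redraws``, if the test set lacks
    a class); optionally balance the training classes by random
    under-sampling; autoscale (or block-scale, when ``block_sizes`` is
    given) on the training samples only — or once globally with
    ``global_scaling``; tune and fit the observed model; fit the NULL model
    on the same training set with permuted labels; evaluate both on the same
    test set.  Deterministic: iteration i uses seed ``seed + i``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if B < 1:
        raise ValueError("B must be >= 1")
    classification = not spec.is_regression
    if classification:
        if class_names is None:
            u = np.unique(y)
            if len(u) != 2:
                raise ValueError("classification labels must have exactly 2 classes")
            class_names = (str(u[0]), str(u[1]))
        metric_name = "balanced_accuracy"
        better = "higher"
    else:
        y = y.astype(float)
        metric_name = "q2"
        better = "higher"

    if global_scaling:
        X = _make_scaler(block_sizes).fit(X).transform(X)

    iterations: list[BootstrapIteration] = []
    n_redraws = 0
    with threadpool_limits(limits=1):
        for i in range(B):
            it_seed = (int(seed) + i) % (2**31 - 1)
            rng = np.random.default_rng(it_seed)
            for _ in range(max_redraws + 1):
                train = rng.integers(0, n, size=n)
                test = np.setdiff1d(np.arange(n), np.unique(train))
                if test.size == 0:
                    n_redraws += 1
                    continue
                if classification and (
                    len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2
                ):
                    n_redraws += 1
                    continue
                break
            else:
                raise RuntimeError("exceeded redraw cap for out-of-bag test sets")

            train_fit = train
            if balance and classification:
                keep = random_undersample(y[train], it_seed)
                train_fit = train[keep]

            Xtr, ytr = X[train_fit], y[train_fit]
            Xte, yte = X[test], y[test]
            if not global_scaling:
                scaler = _make_scaler(block_sizes).fit(Xtr)
                Xtr = scaler.transform(Xtr)
                Xte = scaler.transform(Xte)

            it_spec = ModelSpec(spec.kind, {k: list(v) for k, v in spec.grid.items()},
                                spec.cv_folds, it_seed)
            observed = fit_model(Xtr, ytr, it_spec)
            y_null = rng.permutation(ytr)
            if classification and len(np.unique(y_null)) < 2:  # pragma: no cover
                y_null = rng.permutation(ytr)
            null = fit_model(Xtr, y_null, it_spec)

            if classification:
                obs_metric, obs_cm = _evaluate_classifier(observed, Xte, yte, class_names)
                null_metric, null_cm = _evaluate_classifier(null, Xte, yte, class_names)
                iterations.append(
                    BootstrapIteration(
                        train, test, train_fit, obs_metric, null_metric,
                        observed.chosen_params, obs_cm, null_cm,
                    )
                )
            else:
                obs = regression_metrics(yte, observed.estimator.predict(Xte))
                nul = regression_metrics(yte, null.estimator.predict(Xte))
                obs_q2 = obs.q2 if obs.q2 is not None else float("nan")
                nul_q2 = nul.q2 if nul.q2 is not None else float("nan")
                iterations.append(
                    BootstrapIteration(
                        train, test, train_fit, obs_q2, nul_q2,
                        observed.chosen_params,
                        observed_rmsep=obs.rmsep, null_rmsep=nul.rmsep,
                    )
                )

    obs_arr = np.array([it.observed_metric for it in iterations])
    null_arr = np.array([it.null_metric for it in iterations])
    p = empirical_pvalue(obs_arr, null_arr, better=better, smoothed=smoothed)
    summary = ValidationSummary(
        iterations=iterations,
        metric_name=metric_name,
        mean_metric=float(np.mean(obs_arr)),
        metric_sd=float(np.std(obs_arr, ddof=1)) if len(iterations) > 1 else 0.0,
        empirical_p=p,
        class_names=class_names if classification else None,
        n_redraws=n_redraws,
        mean_train_fraction=float(
            np.mean([np.unique(it.train_indices).size / n for it in iterations])
        ),
        mean_test_fraction=float(
            np.mean([it.test_indices.size / n for it in iterations])
        ),
    )
    if classification:
        summary.averaged_confusion = np.mean(
            [it.observed_confusion.as_percent() for it in iterations], axis=0
        )
    else:
        summary.median_q2 = float(np.median(obs_arr))
        summary.median_rmsep = float(
            np.median([it.observed_rmsep for it in iterations])
        )
    return summary


def learning_curve(
    X,
    y,
    spec: ModelSpec,
    fractions=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    repeats: int = 100,
    balance: bool = False,
    seed: int = 0,
    class_names: tuple[str, str] | None = None,
    block_sizes=None,
) -> LearningCurve:
    """Performance vs training-set size.

    At each training fraction, ``repeats`` random splits (stratified by
    class for classification) are fitted and evaluated with the same
    scale-on-train / tune / test contract as :func:`bootstrap_validate`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classification = not spec.is_regression
    if classification and class_names is None:
        u = np.unique(y)
        class_names = (str(u[0]), str(u[1]))
    means, sds = [], []
    with threadpool_limits(limits=1):
        for f_i, frac in enumerate(fractions):
            vals = []
            for r in range(repeats):
                it_seed = (int(seed) + 1009 * f_i + r) % (2**31 - 1)
                rng = np.random.default_rng(it_seed)
                if classification:
                    train_idx = []
                    for cls in np.unique(y):
                        idx = rng.permutation(np.where(y == cls)[0])
                        k = int(round(frac * idx.size))
                        k = min(max(k, 1), idx.size - 1)
                        train_idx.append(idx[:k])
                    train = np.sort(np.concatenate(train_idx))
                else:
                    idx = rng.permutation(n)
                    k = min(max(int(round(frac * n)), 2), n - 2)
                    train = np.sort(idx[:k])
                test = np.setdiff1d(np.arange(n), train)
                if train.size < spec.cv_folds:
                    raise ValueError(
                        f"fraction {frac} leaves fewer training samples than cv_folds"
                    )
                train_fit = train
                if balance and classification:
                    train_fit = train[random_undersample(y[train], it_seed)]
                scaler = _make_scaler(block_sizes).fit(X[train_fit])
                Xtr = scaler.transform(X[train_fit])
                Xte = scaler.transform(X[test])
                it_spec = ModelSpec(
                    spec.kind, {k: list(v) for k, v in spec.grid.items()},
                    spec.cv_folds, it_seed,
                )
                model = fit_model(Xtr, y[train_fit], it_spec)
                if classification:
                    metric, _ = _evaluate_classifier(model, Xte, y[test], class_names)
                else:
                    m = regression_metrics(y[test], model.estimator.predict(Xte))
                    metric = m.q2 if m.q2 is not None else float("nan")
                vals.append(metric)
            means.append(float(np.mean(vals)))
            sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    return LearningCurve(
        train_fractions=np.asarray(fractions, dtype=float),
        mean_metric=np.asarray(means),
        sd_metric=np.asarray(sds),
        repeats=repeats,
        metric_name="balanced_accuracy" if classification else "q2",
    )
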