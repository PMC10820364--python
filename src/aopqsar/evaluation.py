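"""Splitting, cross-validation, grid search, metrics and explainability.

Conventions used throughout:

- test-set size is ``round(N * test_fraction)`` with round-half-away-from-
  zero, and per-class test counts are the nearest integers to the
  class-proportional shares that sum to the test size (largest-remainder
  apportionment);
- the six-metric report (balanced accuracy, precision, sensitivity,
  specificity, MCC, F1) is derived from stored confusion counts; any
  zero-denominator metric is reported as 0;
- every fold-local statistic (feature preprocessing, oversampling) is
  fitted inside that fold's training indices only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from .assay_labeling import EndpointDataset
from .imbalance import OversampleConfig, oversample

METRIC_ORDER = [
    "balanced_accuracy", "precision", "sensitivity", "specificity", "mcc", "f1",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SplitPlan:
    test_fraction: float
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0 < self.test_fraction < 0.5:
            raise ValueError("0 < test_fraction < 0.5")


def stratified_split(
    ds: EndpointDataset, plan: SplitPlan
) -> tuple[EndpointDataset, EndpointDataset]:
    """Stratified train/test split preserving the class ratio.

    The test size is ``round(N * fraction)`` (half away from zero); class
    shares are apportioned by largest remainder. A class that would get no
    test compound is forced one (with a warning).
    """
    labels = ds.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    n = len(ds)
    n_test = _round_half_away(n * plan.test_fraction)
    shares = counts * n_test / n
    base = np.floor(shares).astype(int)
    remainder = n_test - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    for i in range(remainder):
        base[order[i]] += 1
    for c in range(len(classes)):
        if base[c] == 0:
            import warnings

            warnings.warn(
                f"class {classes[c]} would receive 0 test compounds; forcing 1"
            )
            base[c] = 1
            base[np.argmax(base)] -= 1
    rng = np.random.default_rng(plan.seed)
    test_idx: list[int] = []
    for cls, n_cls in zip(classes, base):
        cls_idx = np.flatnonzero(labels == cls)
        test_idx.extend(rng.permutation(cls_idx)[:n_cls].tolist())
    test_idx = np.sort(np.array(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return ds.subset(train_idx, "train"), ds.subset(test_idx, "test")


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    balanced_accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    mcc: float
    f1: float

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_ORDER}

    def as_row(self) -> dict:
        d = self.as_dict()
        d.update(tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn)
        return d


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Six-metric report from binary truth/prediction vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return MetricsReport(
        tp, fp, tn, fn,
        balanced_accuracy=(sensitivity + specificity) / 2.0,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        mcc=mcc,
        f1=f1,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    summary: pd.DataFrame  # mean/sd per metric
    redraws: int = 0

    @property
    def mean(self) -> dict:
        return self.summary["mean"].to_dict()


def _summarize(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    frame = pd.DataFrame([r.as_dict() for r in reports])
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})


def repeated_kfold_cv(
    model_factory: Callable,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    iterations: int = 10,
    oversample_cfg: OversampleConfig | None = None,
    preprocess: bool = False,
    seed: int = 0,
) -> CVResult:
    """``iterations`` repeats of stratified k-fold CV.

    ``model_factory(fold_seed)`` must return an object with
    ``fit(X, y)`` and ``predict_proba(X) -> P(active)``. Oversampling and
    (optional) feature preprocessing are fitted inside each training fold
    only. Folds containing a single truth class are re-drawn with a new
    seed (counted in ``redraws``).
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k >= 2")
    if min(np.bincount(y)) < k:
        raise ValueError("each class needs at least k members")
    reports: list[MetricsReport] = []
    redraws = 0
    for it in range(iterations):
        fold_seed = seed + 1000 * it
        attempts = 0
        while True:
            splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                       random_state=fold_seed + attempts)
            folds = list(splitter.split(X, y))
            if all(len(np.unique(y[te])) == 2 for _, te in folds):
                redraws += attempts
                break
            attempts += 1
        for f, (tr, te) in enumerate(folds):
            X_tr, y_tr = X[tr], y[tr]
            X_te = X[te]
            if preprocess:
                from .encoders.preprocess import FeaturePreprocessor
                from .encoders.tabular import FeatureBundle

                names = [f"f{j}" for j in range(X_tr.shape[1])]
                prep = FeaturePreprocessor().fit(
                    FeatureBundle("cv", X_tr, names)
                )
                X_tr = prep.transform(FeatureBundle("cv", X_tr, names)).matrix
                X_te = prep.transform(FeatureBundle("cv", X_te, names)).matrix
            if oversample_cfg is not None:
                X_tr, y_tr = oversample(X_tr, y_tr, oversample_cfg)
            model = model_factory(fold_seed + f)
            model.fit(X_tr, y_tr)
            proba = model.predict_proba(X_te)
            reports.append(compute_metrics(y[te], (proba >= 0.5).astype(int)))
    return CVResult(reports, _summarize(reports), redraws)


@dataclass
class GridSearchResult:
    best_params: dict
    best_mean_f1: float
    table: pd.DataFrame


def grid_search(
    model_factory: Callable,  # (params, seed) -> model
    grid: dict,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    oversample_cfg: OversampleConfig | None = None,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive grid evaluation by k-fold CV mean F1.

    Ties broken by higher mean balanced accuracy, then first-in-grid order.
    """
    points = list(ParameterGrid(grid))
    if not points:
        raise ValueError("empty grid")
    rows = []
    best = None
    for order_idx, params in enumerate(points):
        cv = repeated_kfold_cv(
            lambda s, p=params: model_factory(p, s),
            X, y, k=k, iterations=1, oversample_cfg=oversample_cfg, seed=seed,
        )
        f1, ba = cv.mean["f1"], cv.mean["balanced_accuracy"]
        rows.append({**params, "mean_f1": f1, "mean_balanced_accuracy": ba})
        key = (f1, ba, -order_idx)
        if best is None or key > best[0]:
            best = (key, params, f1)
    return GridSearchResult(best[1], best[2], pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# explainability


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    metric: str = "f1",
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +/- sd drop in ``metric`` when one feature column is shuffled."""
    if repeats < 1:
        raise ValueError("repeats >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)

    def score(mat) -> float:
        proba = model.predict_proba(mat)
        return compute_metrics(y, (proba >= 0.5).astype(int)).as_dict()[metric]

    baseline = score(X)
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for j in range(X.shape[1]):
        drops = []
        for _ in range(repeats):
            Xp = X.copy()
            col = Xp[:, j]
            if np.all(col == col[0]):
                drops.append(0.0)  # shuffling a constant is a no-op
                continue
            Xp[:, j] = rng.permutation(col)
            drops.append(baseline - score(Xp))
        means.append(float(np.mean(drops)))
        sds.append(float(np.std(drops, ddof=1)) if repeats > 1 else 0.0)
    return pd.DataFrame(
        {"feature": np.arange(X.shape[1]), "importance_mean": means,
         "importance_sd": sds}
    ).sort_values("importance_mean", ascending=False, ignore_index=True)


def _linear_readout(model):
    est = getattr(model, "estimator", model)
    coef = getattr(est, "coef_", None)
    intercept = getattr(est, "intercept_", None)
    if coef is not None and intercept is not None and np.ndim(coef) <= 2:
        return np.ravel(coef), float(np.ravel(intercept)[0])
    return None


def shap_summary(
    model,
    X_background: np.ndarray,
    X_explain: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-compound, per-feature Shapley attributions plus the base value.

    Linear models get the exact closed form ``phi_j = w_j (x_j - mean
    background x_j)``; other models with ``predict_proba`` get a seeded
    permutation-sampling estimate of interventional Shapley values. In
    both cases ``base + sum(phi) ~= model output``.
    """
    X_background = np.asarray(X_background, dtype=float)
    X_explain = np.asarray(X_explain, dtype=float)
    linear = _linear_readout(model)
    if linear is not None:
        w, b = linear
        base = float(X_background.mean(axis=0) @ w + b)
        phi = (X_explain - X_background.mean(axis=0)) * w
        return phi, base

    if not hasattr(model, "predict_proba"):
        raise TypeError(
            "model exposes no probability output; use permutation_importance instead"
        )

    def f(mat) -> np.ndarray:
        return np.asarray(model.predict_proba(mat), dtype=float)

    rng = np.random.default_rng(seed)
    n, p = X_explain.shape
    base = float(f(X_background).mean())
    phi = np.zeros((n, p))
    for s in range(n_samples):
        order = rng.permutation(p)
        bg = X_background[rng.integers(len(X_background))]
        for i in range(n):
            current = bg.copy()
            prev = f(current[None, :])[0]
            for j in order:
                current[j] = X_explain[i, j]
                new = f(current[None, :])[0]
                phi[i, j] += new - prev
                prev = new
    return phi / n_samples, base


# ---------------------------------------------------------------------------
# reporting


def reports_to_frame(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Rows = models, columns in the canonical six-metric order."""
    return pd.DataFrame(
        {name: r.as_dict() for name, r in reports.items()}
    ).T[METRIC_ORDER]
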