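"""Event-risk classification stage.

Implements the machine-learning pipeline applied to the cohort table:
one-hot encoding of categorical covariates, a stratified 70-30 train/test
split, two class-imbalance corrections (SMOTE oversampling of the minority
class and random undersampling of the majority class), a gradient-boosted
tree classifier written from first principles (log loss, Friedman-MSE split
quality, shrinkage), stratified k-fold cross-validation and a confusion-
matrix-based metric suite.

The boosting model is the stagewise additive expansion

    F_M(x) = F_0 + sum_{m=1..M} v * h_m(x),

with F_0 the log-odds of the training prevalence (the log-loss minimising
constant), pseudo-residuals r_i = y_i - sigmoid(F_{m-1}(x_i)), depth-limited
regression trees h_m fit to the residuals, and leaf values refined by one
Newton step (sum r / sum p(1-p)) — the same construction as reference
gradient-boosting implementations, against which it is cross-checked in the
test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synth_data import (
    ALL_FEATURES,
    BINARY_FEATURES,
    ECRF_FEATURES,
    IMAGING_FEATURES,
    SIMULATION_FEATURES,
    CohortTable,
    substream,
)

__all__ = [
    "ColumnMeta",
    "FeatureMatrix",
    "GBTModel",
    "EvaluationReport",
    "encode_features",
    "stratified_split",
    "stratified_folds",
    "smote_oversample",
    "random_undersample",
    "gbt_fit",
    "gbt_predict",
    "cross_validate",
    "evaluate",
    "report_from_confusion",
    "mean_report",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# feature matrix & encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnMeta:
    name: str
    group: str  # imaging | simulation | ecrf | other
    binary: bool


@dataclass
class FeatureMatrix:
    """Numeric design matrix with column metadata and binary labels."""

    X: np.ndarray
    columns: list[ColumnMeta]
    y: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X shape does not match column metadata")
        if np.isnan(self.X).any():
            raise ValueError("missing values after encoding")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if len(self.y) != len(self.X):
                raise ValueError("row count must equal label count")
            if not np.isin(self.y, [0, 1]).all():
                raise ValueError("labels must be binary")
        for j, c in enumerate(self.columns):
            if c.binary and not np.isin(self.X[:, j], [0.0, 1.0]).all():
                raise ValueError(f"binary-flagged column {c.name} has non-binary values")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def binary_mask(self) -> np.ndarray:
        return np.array([c.binary for c in self.columns])

    def take(self, idx: np.ndarray) -> "FeatureMatrix":
        y = None if self.y is None else self.y[idx]
        return FeatureMatrix(self.X[idx], self.columns, y)


def _column_group(name: str) -> str:
    base = name.split("=")[0]
    if base in IMAGING_FEATURES:
        return "imaging"
    if base in SIMULATION_FEATURES:
        return "simulation"
    if base in ECRF_FEATURES:
        return "ecrf"
    return "other"


def encode_features(cohort: CohortTable | pd.DataFrame) -> FeatureMatrix:
    """One-hot encode categorical columns; pass numeric columns through.

    Categorical (non-numeric) columns expand to one indicator column per
    level, named ``col=level`` (full encoding, no dropped reference level).
    The ``event`` column, when present, becomes the label vector.  Non-numeric
    columns outside the cohort schema raise an error.
    """
    df = cohort.frame if isinstance(cohort, CohortTable) else cohort.copy()
    y = df["event"].to_numpy(dtype=int) if "event" in df.columns else None
    df = df.drop(columns=["event"], errors="ignore")

    cols: list[ColumnMeta] = []
    mats: list[np.ndarray] = []
    for name in df.columns:
        series = df[name]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.to_numpy(dtype=float)
            binary = bool(np.isin(vals, [0.0, 1.0]).all()) and name in BINARY_FEATURES
            cols.append(ColumnMeta(name, _column_group(name), binary))
            mats.append(vals[:, None])
        else:
            if name not in ALL_FEATURES:
                raise ValueError(f"unknown categorical column {name!r}")
            levels = sorted(series.astype(str).unique())
            for lev in levels:
                cols.append(ColumnMeta(f"{name}={lev}", _column_group(name), True))
                mats.append((series.astype(str) == lev).to_numpy(dtype=float)[:, None])
    return FeatureMatrix(np.hstack(mats), cols, y)


# ---------------------------------------------------------------------------
# splitting & imbalance correction
# ---------------------------------------------------------------------------


def stratified_split(
    fm: FeatureMatrix, test_fraction: float = 0.3, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Per-class stratified split; fractional remainders go to the test set.

    With 115/19 rows at 70-30 this yields a (80, 13) train and (35, 6) test
    partition: train receives floor(n_c * (1 - test_fraction)) per class.
    """
    if fm.y is None:
        raise ValueError("labels required for a stratified split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = substream(seed, "split")
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in (0, 1):
        idx = np.flatnonzero(fm.y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * (1 - test_fraction)))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return fm.take(np.sort(np.concatenate(train_idx))), fm.take(
        np.sort(np.concatenate(test_idx))
    )


def stratified_folds(y: np.ndarray, n_folds: int, seed: int = 0) -> list[np.ndarray]:
    """Stratified fold index sets; fold sizes differ by at most one."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = substream(seed, "folds")
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def smote_oversample(
    train: FeatureMatrix,
    k_neighbors: int = 5,
    seed: int = 0,
    binary_columns: np.ndarray | None = None,
) -> FeatureMatrix:
    """SMOTE: synthesize minority rows by interpolating nearest neighbours.

    Each synthetic point is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbours of x_i.  Binary columns are
    rounded half-up and clipped to {0, 1} afterwards.  Majority rows are left
    untouched; the output has equal class counts.
    """
    if train.y is None:
        raise ValueError("labels required")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    counts = np.bincount(train.y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if n_min < k_neighbors + 1:
        warnings.warn(
            f"minority count {n_min} < k_neighbors+1; reducing k to {n_min - 1}",
            stacklevel=2,
        )
        k_neighbors = n_min - 1
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return train

    if binary_columns is None:
        binary_columns = train.binary_mask
    rng = substream(seed, "smote")
    Xm = train.X[train.y == minority]
    # brute-force k-NN among minority points (cohort-scale data)
    d2 = ((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1)[:, :k_neighbors]

    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    u = rng.random(n_new)
    Xs = Xm[base] + u[:, None] * (Xm[nn[base, pick]] - Xm[base])
    Xs[:, binary_columns] = np.clip(np.floor(Xs[:, binary_columns] + 0.5), 0.0, 1.0)
    X_out = np.vstack([train.X, Xs])
    y_out = np.concatenate([train.y, np.full(n_new, minority, dtype=int)])
    return FeatureMatrix(X_out, train.columns, y_out)


def random_undersample(train: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Subsample the majority class without replacement to the minority count."""
    if train.y is None:
        raise ValueError("labels required")
    counts = np.bincount(train.y, minlength=2)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    if counts[majority] < counts[minority]:
        raise ValueError("majority class smaller than minority class")
    rng = substream(seed, "undersample")
    maj_idx = np.flatnonzero(train.y == majority)
    keep_maj = np.sort(rng.choice(maj_idx, size=counts[minority], replace=False))
    keep = np.sort(np.concatenate([keep_maj, np.flatnonzero(train.y == minority)]))
    return train.take(keep)


# ---------------------------------------------------------------------------
# gradient-boosted trees from first principles
# ---------------------------------------------------------------------------


def _fit_tree(
    X: np.ndarray,
    residuals: np.ndarray,
    max_depth: int,
    min_samples_leaf: int = 1,
) -> dict:
    """Depth-limited regression tree on the pseudo-residuals.

    Splits maximise the Friedman improvement score
    n_L * n_R / (n_L + n_R) * (mean_L - mean_R)^2 over all feature/threshold
    candidates; thresholds are midpoints between adjacent distinct values.
    """

    def build(idx: np.ndarray, depth: int) -> dict:
        r = residuals[idx]
        node = {"n": int(len(idx)), "mean": float(r.mean()), "idx": idx}
        if depth >= max_depth or len(idx) < 2 * min_samples_leaf or np.ptp(r) == 0:
            return node
        best = None
        for j in range(X.shape[1]):
            x = X[idx, j]
            order = np.argsort(x, kind="mergesort")
            xs, rs = x[order], r[order]
            cum = np.cumsum(rs)
            n = len(idx)
            nl = np.arange(1, n)
            valid = xs[1:] != xs[:-1]
            if min_samples_leaf > 1:
                valid &= (nl >= min_samples_leaf) & (n - nl >= min_samples_leaf)
            if not valid.any():
                continue
            sl = cum[:-1]
            sr = cum[-1] - sl
            ml = sl / nl
            mr = sr / (n - nl)
            imp = nl * (n - nl) / n * (ml - mr) ** 2
            imp[~valid] = -np.inf
            k = int(np.argmax(imp))
            if best is None or imp[k] > best[0]:
                thr = 0.5 * (xs[k] + xs[k + 1])
                best = (float(imp[k]), j, thr, order, k)
        if best is None or best[0] <= 0:
            return node
        _, j, thr, order, k = best
        left_idx = idx[order[: k + 1]]
        right_idx = idx[order[k + 1 :]]
        node.update(
            feature=j,
            threshold=float(thr),
            left=build(left_idx, depth + 1),
            right=build(right_idx, depth + 1),
        )
        return node

    return build(np.arange(len(X)), 0)


def _leaves(node: dict):
    if "feature" in node:
        yield from _leaves(node["left"])
        yield from _leaves(node["right"])
    else:
        yield node


def _tree_predict(node: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if len(idx) == 0:
            continue
        if "feature" in nd:
            mask = X[idx, nd["feature"]] <= nd["threshold"]
            stack.append((nd["left"], idx[mask]))
            stack.append((nd["right"], idx[~mask]))
        else:
            out[idx] = nd["value"]
    return out


def _strip_idx(node: dict) -> dict:
    clean = {k: v for k, v in node.items() if k not in ("idx", "left", "right")}
    if "feature" in node:
        clean["left"] = _strip_idx(node["left"])
        clean["right"] = _strip_idx(node["right"])
    return clean


@dataclass
class GBTModel:
    """Additive model: base log-odds plus shrunken regression trees."""

    base_score: float
    trees: list[dict]
    learning_rate: float
    feature_names: list[str]
    loss: str = "log_loss"
    max_depth: int = 3
    train_log_loss: list[float] = field(default_factory=list)

    @property
    def n_estimators(self) -> int:
        return len(self.trees)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        F = np.full(len(X), self.base_score)
        for tree in self.trees:
            F += self.learning_rate * _tree_predict(tree, X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "base_score": self.base_score,
                    "learning_rate": self.learning_rate,
                    "feature_names": self.feature_names,
                    "loss": self.loss,
                    "max_depth": self.max_depth,
                    "trees": self.trees,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GBTModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["base_score"], d["trees"], d["learning_rate"], d["feature_names"],
            d["loss"], d["max_depth"],
        )


def gbt_fit(
    train: FeatureMatrix,
    n_estimators: int = 100,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    seed: int = 0,
    leaf_newton: bool = True,
) -> GBTModel:
    """Fit the boosting model with log loss.

    F_0 is the log-odds of the training prevalence; each stage fits a tree to
    the pseudo-residuals y - sigmoid(F) and (by default) replaces leaf values
    with the one-step Newton estimate sum(r) / sum(p(1-p)); set
    ``leaf_newton=False`` for the literal least-squares leaf means.
    The procedure is deterministic; ``seed`` is accepted for interface
    symmetry with the samplers.
    """
    if train.y is None:
        raise ValueError("labels required")
    y = train.y.astype(float)
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    X = train.X
    p0 = y.mean()
    F0 = float(np.log(p0 / (1 - p0)))
    F = np.full(len(y), F0)
    trees: list[dict] = []
    losses: list[float] = []
    for _ in range(n_estimators):
        p = _sigmoid(F)
        r = y - p
        tree = _fit_tree(X, r, max_depth)
        for leaf in _leaves(tree):
            idx = leaf.pop("idx", None)
            if leaf_newton and idx is not None:
                denom = (p[idx] * (1 - p[idx])).sum()
                leaf["value"] = float(r[idx].sum() / max(denom, 1e-150))
            else:
                leaf["value"] = leaf["mean"]
        tree = _strip_idx(tree)
        F = F + learning_rate * _tree_predict(tree, X)
        trees.append(tree)
        p = _sigmoid(F)
        eps = 1e-15
        losses.append(float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))))
    return GBTModel(F0, trees, learning_rate, train.names, "log_loss", max_depth, losses)


def gbt_predict(
    model: GBTModel, fm: FeatureMatrix | np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Event risk score (probability) and thresholded class labels."""
    if isinstance(fm, FeatureMatrix):
        if fm.names != model.feature_names:
            raise ValueError("feature columns do not match the training metadata")
        X = fm.X
    else:
        X = np.asarray(fm, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature count does not match the training metadata")
    proba = model.predict_proba(X)
    return proba, (proba >= threshold).astype(int)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Confusion-matrix metric suite at a fixed decision threshold.

    Zero-denominator rates are ``None`` (undefined), never coerced to 0.
    ``accuracy``/``weighted_recall``/``weighted_f1`` follow the support-
    weighted convention under which the published aggregate table is
    reproducible from its confusion matrices; ``balanced_accuracy`` is the
    macro (sensitivity+specificity)/2 variant.
    """

    tn: int
    fp: int
    fn: int
    tp: int
    threshold: float = 0.5
    auc: float | None = None

    @staticmethod
    def _rate(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def balanced_accuracy(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def accuracy(self) -> float | None:
        return self._rate(self.tn + self.tp, self.n)

    @property
    def f1(self) -> float | None:
        if self.ppv is None or self.sensitivity is None or self.ppv + self.sensitivity == 0:
            return None
        return 2 * self.ppv * self.sensitivity / (self.ppv + self.sensitivity)

    def _per_class(self, cls: int) -> tuple[float | None, float | None, float | None]:
        """(precision, recall, f1) treating ``cls`` as the positive label."""
        if cls == 1:
            prec, rec = self.ppv, self.sensitivity
        else:
            prec, rec = self.npv, self.specificity
        if prec is None or rec is None or prec + rec == 0:
            return prec, rec, None
        return prec, rec, 2 * prec * rec / (prec + rec)

    def _weighted(self, metric_idx: int) -> float | None:
        n0, n1 = self.tn + self.fp, self.tp + self.fn
        vals = [self._per_class(0)[metric_idx], self._per_class(1)[metric_idx]]
        if any(v is None for v in vals) or self.n == 0:
            return None
        return (n0 * vals[0] + n1 * vals[1]) / self.n

    @property
    def weighted_precision(self) -> float | None:
        return self._weighted(0)

    @property
    def weighted_recall(self) -> float | None:
        return self._weighted(1)

    @property
    def weighted_f1(self) -> float | None:
        return self._weighted(2)

    def validate(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion-matrix entries must be non-negative")
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp,
            "threshold": self.threshold,
            "balanced_accuracy": self.balanced_accuracy,
            "npv": self.npv, "ppv": self.ppv, "auc": self.auc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "f1": self.f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
        }


def report_from_confusion(
    tn: int, fp: int, fn: int, tp: int, auc: float | None = None
) -> EvaluationReport:
    rep = EvaluationReport(tn, fp, fn, tp, auc=auc)
    rep.validate()
    return rep


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal ROC area (rank/Mann-Whitney form; ties averaged)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined: test scores contain a single class")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def evaluate(model: GBTModel, test: FeatureMatrix, threshold: float = 0.5) -> EvaluationReport:
    """Confusion matrix, rate metrics and ROC AUC on a held-out set."""
    if test.y is None or len(test.y) == 0:
        raise ValueError("test set must be non-empty and labelled")
    proba, pred = gbt_predict(model, test, threshold)
    y = test.y
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    rep = EvaluationReport(tn, fp, fn, tp, threshold, auc=roc_auc(y, proba))
    rep.validate()
    return rep


_MEAN_METRICS = [
    "balanced_accuracy", "npv", "ppv", "auc", "sensitivity", "specificity",
    "accuracy", "f1", "weighted_recall", "weighted_f1",
]


def mean_report(reports: list[EvaluationReport]) -> dict[str, float | None]:
    """Arithmetic mean of each metric across folds (the summary-row rule)."""
    out: dict[str, float | None] = {}
    for m in _MEAN_METRICS:
        vals = [getattr(r, m) for r in reports]
        out[m] = None if any(v is None for v in vals) else float(np.mean(vals))
    return out


def _apply_imbalance(train: FeatureMatrix, method: str, seed: int) -> FeatureMatrix:
    if method == "smote":
        return smote_oversample(train, seed=seed)
    if method == "undersample":
        return random_undersample(train, seed=seed)
    if method == "none":
        return train
    raise ValueError(f"unknown imbalance method {method!r}")


def cross_validate(
    train: FeatureMatrix,
    n_folds: int = 5,
    imbalance_method: str = "smote",
    seed: int = 0,
    threshold: float = 0.5,
    **gbt_kwargs,
) -> tuple[list[EvaluationReport], dict[str, float | None]]:
    """Stratified k-fold CV; imbalance correction inside training folds only.

    The validation fold is never resampled.  Returns the per-fold reports and
    the mean summary row.
    """
    if train.y is None:
        raise ValueError("labels required")
    folds = stratified_folds(train.y, n_folds, seed)
    reports: list[EvaluationReport] = []
    for k, val_idx in enumerate(folds):
        if len(np.unique(train.y[val_idx])) < 2:
            raise ValueError(f"fold {k} does not contain both classes")
        tr_idx = np.sort(np.concatenate([f for i, f in enumerate(folds) if i != k]))
        fold_train = _apply_imbalance(train.take(tr_idx), imbalance_method, seed + k)
        model = gbt_fit(fold_train, seed=seed, **gbt_kwargs)
        reports.append(evaluate(model, train.take(val_idx), threshold))
    return reports, mean_report(reports)


def reports_to_frame(reports: list[EvaluationReport], mean_row: dict | None = None) -> pd.DataFrame:
    """Fold-by-fold metric table with an optional trailing Mean row."""
    rows = []
    for i, r in enumerate(reports):
        d = {"fold": str(i)}
        d.update({m: getattr(r, m) for m in _MEAN_METRICS})
        rows.append(d)
    if mean_row is not None:
        rows.append({"fold": "mean", **{m: mean_row.get(m) for m in _MEAN_METRICS}})
    return pd.DataFrame(rows)
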