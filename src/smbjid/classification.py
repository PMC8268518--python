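"""Gradient-boosted histogram classification and the tandem architecture.

The primary model is an XGBoost multiclass classifier (cross-entropy
objective) over trimmed conductance-histogram probability vectors, with
a deliberately shallow configuration (200 trees of depth 2 by default).

The tandem architecture routes a designated hard pair of classes —
typically two strands differing by a single base mismatch — through a
dedicated binary stage: whenever the multiclass stage predicts a member
of the routed pair, an RBF-kernel SVM trained only on that pair makes
the final call.  Predictions outside the pair are never touched.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .histogramming import (
    DesignMatrix,
    HistogramConfig,
    LabelingScheme,
    sample_histogram_set,
    split_traces,
)
from .preprocess import ConductanceTrace

__all__ = [
    "ClassifierConfig",
    "TandemConfig",
    "EvaluationResult",
    "BoostedHistogramClassifier",
    "TandemModel",
    "train",
    "grid_search",
    "evaluate",
    "repeat_protocol",
    "train_tandem",
    "tandem_predict",
    "pair_accuracy",
    "tandem_protocol",
]

# default exhaustive grids used when none are supplied
DEFAULT_DEPTH_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 16, 18, 20)
DEFAULT_N_EST_GRID = (10, 50, 100, 150, 200, 250, 300, 350, 400, 500, 600, 700)


@dataclass(frozen=True)
class ClassifierConfig:
    """Boosted-tree hyperparameters (shallow trees, default shrinkage)."""

    n_est: int = 200
    d_est: int = 2
    learning_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_est < 1 or self.d_est < 1:
            raise ValueError("n_est and d_est must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass(frozen=True)
class TandemConfig:
    """Routing configuration of the two-stage classifier."""

    routed_pair: tuple[int, int]
    stage2_c: float = 1.0

    def __post_init__(self) -> None:
        if len(set(self.routed_pair)) != 2:
            raise ValueError("routed_pair must contain exactly two distinct labels")


@dataclass
class EvaluationResult:
    """Confusion matrix and accuracies, optionally averaged over repeats.

    ``confusion`` rows are true classes; when ``n_repeats > 1`` the
    confusion counts are summed over repeats while the accuracies are
    means of per-repeat accuracies.
    """

    confusion: np.ndarray
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    classes: np.ndarray
    n_repeats: int = 1
    mean_predict_time: float = 0.0  # seconds per sample; informational only


class BoostedHistogramClassifier:
    """XGBoost wrapper handling arbitrary integer class labels.

    Single-threaded and seeded for bit-reproducible training; `predict`
    returns labels in the caller's original label space.
    """

    def __init__(self, cfg: ClassifierConfig):
        self.cfg = cfg
        self.classes_: np.ndarray | None = None
        self._model: XGBClassifier | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BoostedHistogramClassifier":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes, encoded = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("training design must contain at least 2 classes")
        self.classes_ = classes
        # objective left to the wrapper: softmax cross-entropy for k > 2,
        # logistic cross-entropy for the binary case
        self._model = XGBClassifier(
            n_estimators=self.cfg.n_est,
            max_depth=self.cfg.d_est,
            learning_rate=self.cfg.learning_rate,
            tree_method="hist",
            n_jobs=1,
            random_state=self.cfg.seed,
            verbosity=0,
        )
        self._model.fit(X, encoded)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        encoded = self._model.predict(np.asarray(X, dtype=np.float32))
        return self.classes_[encoded]


def train(design: DesignMatrix, cfg: ClassifierConfig | None = None) -> BoostedHistogramClassifier:
    """Fit the boosted-tree model on a design matrix."""
    cfg = cfg or ClassifierConfig()
    return BoostedHistogramClassifier(cfg).fit(design.features, design.labels)


def grid_search(
    design: DesignMatrix,
    depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
    n_est_grid: Sequence[int] = DEFAULT_N_EST_GRID,
    validation_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[int, int]:
    """Exhaustive (n_est, d_est) search on a held-out validation split.

    Returns the pair with the highest validation accuracy; ties break
    toward smaller ``n_est``, then smaller ``d_est``.
    """
    if not depth_grid or not n_est_grid:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    n = design.n_samples
    n_val = int(round(validation_fraction * n))
    if n_val == 0 or n_val == n:
        raise ValueError("validation split is empty")
    order = rng.permutation(n)
    val_idx, fit_idx = order[:n_val], order[n_val:]
    X, y = design.features, design.labels
    best: tuple[float, int, int] | None = None
    for n_est, d_est in product(sorted(n_est_grid), sorted(depth_grid)):
        cfg = ClassifierConfig(n_est=n_est, d_est=d_est, seed=seed)
        model = BoostedHistogramClassifier(cfg).fit(X[fit_idx], y[fit_idx])
        acc = float(np.mean(model.predict(X[val_idx]) == y[val_idx]))
        if best is None or acc > best[0]:
            best = (acc, n_est, d_est)
    return best[1], best[2]


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def evaluate(model, test: DesignMatrix) -> EvaluationResult:
    """Confusion matrix and accuracies of a fitted model on a test design."""
    if test.features.shape[1] != _feature_length(model):
        raise ValueError(
            f"feature length mismatch: model expects {_feature_length(model)}, "
            f"test design has {test.features.shape[1]}"
        )
    classes = np.asarray(model.classes_)
    t0 = time.perf_counter()
    preds = model.predict(test.features)
    dt = time.perf_counter() - t0
    cm = _confusion(test.labels, preds, classes)
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row_sums > 0, np.diag(cm) / np.maximum(row_sums, 1), np.nan)
    overall = float(np.trace(cm)) / float(cm.sum())
    return EvaluationResult(
        confusion=cm,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        classes=classes,
        n_repeats=1,
        mean_predict_time=dt / max(len(preds), 1),
    )


def _feature_length(model) -> int:
    inner = getattr(model, "_model", None)
    if inner is not None:
        return int(inner.n_features_in_)
    return int(model.n_features_in_)


def repeat_protocol(
    pool: Mapping[str, Sequence[ConductanceTrace]],
    scheme: LabelingScheme,
    hist_cfg: HistogramConfig,
    clf_cfg: ClassifierConfig,
    n_repeats: int,
    base_seed: int,
    n_hist_train: int = 700,
    n_hist_test: int = 300,
    train_fraction: float = 0.7,
) -> EvaluationResult:
    """Repeated random-split training and evaluation.

    Each repeat r performs a fresh per-class trace split (seed
    ``base_seed + r``), builds fresh train/test histogram sets, trains,
    and evaluates.  Confusion counts are summed over repeats;
    per-class and overall accuracies are means of per-repeat values.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    cm_sum = None
    per_class_accs = []
    overall_accs = []
    times = []
    classes = None
    for r in range(n_repeats):
        seed = base_seed + r
        train_pool, test_pool = split_traces(pool, train_fraction, seed)
        train_design = sample_histogram_set(train_pool, hist_cfg, n_hist_train, seed * 2 + 1, scheme)
        test_design = sample_histogram_set(test_pool, hist_cfg, n_hist_test, seed * 2 + 2, scheme)
        model = train(train_design, clf_cfg)
        res = evaluate(model, test_design)
        cm_sum = res.confusion if cm_sum is None else cm_sum + res.confusion
        per_class_accs.append(res.per_class_accuracy)
        overall_accs.append(res.overall_accuracy)
        times.append(res.mean_predict_time)
        classes = res.classes
    return EvaluationResult(
        confusion=cm_sum,
        per_class_accuracy=np.mean(per_class_accs, axis=0),
        overall_accuracy=float(np.mean(overall_accs)),
        classes=classes,
        n_repeats=n_repeats,
        mean_predict_time=float(np.mean(times)),
    )


# --------------------------------------------------------------------------
# tandem (multiclass -> binary) architecture


@dataclass
class TandemModel:
    stage1: BoostedHistogramClassifier
    stage2: Pipeline
    cfg: TandemConfig

    @property
    def classes_(self) -> np.ndarray:
        return self.stage1.classes_


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF kernel scale from the median pairwise distance of (a subsample of) X."""
    n = X.shape[0]
    if n > 400:
        X = X[rng.choice(n, size=400, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    if med <= 0:
        return 1.0
    return 1.0 / (2.0 * med)


def train_tandem(
    design: DesignMatrix,
    clf_cfg: ClassifierConfig,
    tandem_cfg: TandemConfig,
) -> TandemModel:
    """Train the multiclass stage on all classes and the binary stage on the pair.

    Stage 2 reuses the stage-1 histogram features, standardized per bin
    on its own training rows, with the RBF kernel scale set by the
    median heuristic.
    """
    pair = set(tandem_cfg.routed_pair)
    if not pair <= set(np.unique(design.labels).tolist()):
        raise ValueError(f"routed pair {sorted(pair)} not a subset of design classes")
    stage1 = train(design, clf_cfg)
    mask = np.isin(design.labels, list(pair))
    X2, y2 = design.features[mask], design.labels[mask]
    rng = np.random.default_rng(clf_cfg.seed)
    scaler = StandardScaler().fit(X2)
    gamma = _median_heuristic_gamma(scaler.transform(X2), rng)
    stage2 = Pipeline(
        [
            ("scale", scaler),
            ("svm", SVC(kernel="rbf", C=tandem_cfg.stage2_c, gamma=gamma)),
        ]
    )
    stage2.fit(X2, y2)
    return TandemModel(stage1=stage1, stage2=stage2, cfg=tandem_cfg)


def tandem_predict(model: TandemModel, X: np.ndarray) -> np.ndarray:
    """Stage-1 predictions, with routed-pair predictions re-decided by stage 2.

    Samples whose stage-1 prediction falls outside the routed pair are
    returned untouched.
    """
    X = np.atleast_2d(np.asarray(X))
    preds = model.stage1.predict(X)
    mask = np.isin(preds, list(model.cfg.routed_pair))
    if mask.any():
        if model.stage2 is None:
            raise RuntimeError("routing triggered but no stage-2 model is available")
        preds = preds.copy()
        preds[mask] = model.stage2.predict(X[mask])
    return preds


def pair_accuracy(y_true: np.ndarray, y_pred: np.ndarray, pair: Sequence[int]) -> float:
    """Mean of the two per-class accuracies of the routed pair."""
    accs = []
    for c in pair:
        sel = y_true == c
        if not sel.any():
            raise ValueError(f"class {c} absent from y_true")
        accs.append(float(np.mean(y_pred[sel] == c)))
    return float(np.mean(accs))


def tandem_protocol(
    pool: Mapping[str, Sequence[ConductanceTrace]],
    scheme: LabelingScheme,
    hist_cfg: HistogramConfig,
    clf_cfg: ClassifierConfig,
    tandem_cfg: TandemConfig,
    n_repeats: int,
    base_seed: int,
    n_hist_train: int = 700,
    n_hist_test: int = 300,
    train_fraction: float = 0.7,
) -> tuple[float, float]:
    """Paired comparison of stage-1-only vs tandem accuracy on the routed pair.

    Both architectures see identical splits, histogram draws and
    stage-1 models in every repeat, so the comparison is paired.
    Returns ``(stage1_pair_accuracy, tandem_pair_accuracy)`` as means
    over repeats.
    """
    s1_accs, tandem_accs = [], []
    for r in range(n_repeats):
        seed = base_seed + r
        train_pool, test_pool = split_traces(pool, train_fraction, seed)
        train_design = sample_histogram_set(train_pool, hist_cfg, n_hist_train, seed * 2 + 1, scheme)
        test_design = sample_histogram_set(test_pool, hist_cfg, n_hist_test, seed * 2 + 2, scheme)
        clf_cfg_r = ClassifierConfig(
            n_est=clf_cfg.n_est, d_est=clf_cfg.d_est,
            learning_rate=clf_cfg.learning_rate, seed=seed,
        )
        model = train_tandem(train_design, clf_cfg_r, tandem_cfg)
        preds1 = model.stage1.predict(test_design.features)
        preds_t = tandem_predict(model, test_design.features)
        s1_accs.append(pair_accuracy(test_design.labels, preds1, tandem_cfg.routed_pair))
        tandem_accs.append(pair_accuracy(test_design.labels, preds_t, tandem_cfg.routed_pair))
    return float(np.mean(s1_accs)), float(np.mean(tandem_accs))
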