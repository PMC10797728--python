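"""Tile-level histology classification under stratified eightfold CV.

Four classifiers (1NN, linear SVM, RBF SVM, RUSBoost ensemble trees) are
trained on the retained texture features; feature standardization is fit on
the training folds only and that is asserted by instrumentation on every CV
run.  Each tested tile yields a per-class probability profile whose argmax
(ties to the lower class id) is the predicted histology class; predicted
classes are then placed back on the tile grid to form the patient's
histology classification map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import BACKGROUND, HistologyMap, TileRecord
from .rusboost import RUSBoostClassifier

CLASSIFIER_KINDS = ("1NN", "linSVM", "rbfSVM", "ensembleTree")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "1NN": {"n_neighbors": 1},
    "linSVM": {"C": 1.0},
    "rbfSVM": {"C": 10.0, "gamma": "scale"},
    "ensembleTree": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
}


@dataclass
class FoldAssignment:
    folds: np.ndarray  # per-tile fold index
    k: int
    seed: int


@dataclass
class TileClassifier:
    kind: str
    classes: np.ndarray
    scaler: StandardScaler
    estimator: object
    train_index: np.ndarray | None = None


@dataclass
class MulticlassReport:
    classes: np.ndarray
    confusion: np.ndarray  # rows true, cols predicted
    accuracy: float
    per_class: dict[str, np.ndarray]  # accuracy/recall/precision/specificity/f1/auc
    missing_classes: list[int] = field(default_factory=list)


def stratified_folds(labels, k: int = 8, seed: int = 0) -> FoldAssignment:
    """Seeded per-class shuffle + round-robin: per-class fold counts differ
    by at most one.  Classes with fewer than k members get a warning and a
    best-effort assignment."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    folds = np.full(labels.shape[0], -1, dtype=int)
    offset = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            warnings.warn(
                f"class {c!r} has {idx.size} < k={k} members; folds will be uneven",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size % k  # rotate start so small classes spread out
    return FoldAssignment(folds=folds, k=k, seed=seed)


def _make_estimator(kind: str, hyper: dict | None, seed: int | None = None):
    h = dict(DEFAULT_HYPERPARAMS.get(kind, {}))
    if hyper:
        h.update(hyper)
    if kind == "1NN":
        return KNeighborsClassifier(**h)
    if kind == "linSVM":
        return SVC(kernel="linear", probability=True, random_state=seed, **h)
    if kind == "rbfSVM":
        return SVC(kernel="rbf", probability=True, random_state=seed, **h)
    if kind == "ensembleTree":
        return RUSBoostClassifier(random_state=seed, **h)
    raise ValueError(f"unknown classifier kind {kind!r}")


def fit_tile_classifier(
    X, y, kind: str = "rbfSVM", hyper: dict | None = None, seed: int | None = 0
) -> TileClassifier:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("NA values in the feature matrix")
    scaler = StandardScaler().fit(X)
    est = _make_estimator(kind, hyper, seed)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates SVC(probability=True); Platt scaling there
        # is still the calibration we want
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(scaler.transform(X), y)
    return TileClassifier(kind=kind, classes=np.unique(y), scaler=scaler, estimator=est)


def predict_profiles(model: TileClassifier, X) -> np.ndarray:
    """Per-class probability profiles (rows sum to 1); class order is the
    sorted class list of the training data."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError("feature-dimension mismatch")
    proba = model.estimator.predict_proba(model.scaler.transform(X))
    # sklearn orders columns by estimator.classes_, already sorted
    return proba


def predicted_classes(model: TileClassifier, profiles: np.ndarray) -> np.ndarray:
    """Argmax class per profile; ties break to the lower class id."""
    return model.classes[np.argmax(profiles, axis=1)]


def cross_validate_tiles(
    X,
    y,
    kind: str = "rbfSVM",
    k: int = 8,
    seed: int = 0,
    hyper: dict | None = None,
) -> dict:
    """Stratified k-fold CV; returns per-fold accuracies, pooled predictions
    and profiles, and the pooled multiclass report."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fa = stratified_folds(y, k=k, seed=seed)
    classes = np.unique(y)
    y_pred = np.empty_like(y)
    profiles = np.zeros((y.size, classes.size))
    fold_acc = []
    for f in range(k):
        test = fa.folds == f
        train = ~test
        if not test.any():
            continue
        model = fit_tile_classifier(X[train], y[train], kind, hyper, seed=seed + f)
        # leakage instrumentation: standardization must reflect training folds only
        assert np.allclose(model.scaler.mean_, X[train].mean(axis=0)), (
            "standardization leaked outside the training folds"
        )
        prof = predict_profiles(model, X[test])
        pred = predicted_classes(model, prof)
        y_pred[test] = pred
        cols = np.searchsorted(classes, model.classes)
        profiles[np.ix_(test, cols)] = prof
        fold_acc.append(float(np.mean(pred == y[test])))
    report = multiclass_metrics(y, y_pred, profiles, classes)
    return {
        "fold_accuracies": fold_acc,
        "mean_accuracy": float(np.mean(fold_acc)),
        "y_pred": y_pred,
        "profiles": profiles,
        "report": report,
        "folds": fa,
    }


def assemble_map(
    tile_records: list[TileRecord],
    predicted: np.ndarray | list[int],
    patient_id: str = "",
) -> HistologyMap:
    """Scatter predicted tile classes onto the grid bounding box; cells with
    no tile hold the background sentinel."""
    if not tile_records:
        raise ValueError("no tiles to assemble")
    coords = [(t.grid_row, t.grid_col) for t in tile_records]
    if len(set(coords)) != len(coords):
        raise ValueError("duplicate grid coordinates")
    rows = [r for r, _ in coords]
    cols = [c for _, c in coords]
    r0, c0 = min(rows), min(cols)
    grid = np.full((max(rows) - r0 + 1, max(cols) - c0 + 1), BACKGROUND, dtype=np.int64)
    for (r, c), p in zip(coords, predicted):
        grid[r - r0, c - c0] = int(p)
    pid = patient_id or tile_records[0].patient_id
    return HistologyMap(grid=grid, patient_id=pid)


def multiclass_metrics(y_true, y_pred, profiles=None, classes=None) -> MulticlassReport:
    """One-vs-rest per-class metrics from the confusion matrix; AUC from
    probability profiles by the rank statistic."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    K = classes.size
    conf = np.zeros((K, K), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        conf[pos[t], pos[p]] += 1
    total = conf.sum()
    acc = float(np.trace(conf)) / total
    per = {m: np.full(K, np.nan) for m in
           ("accuracy", "recall", "precision", "specificity", "f1", "auc")}
    missing = []
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        per["accuracy"][i] = (tp + tn) / total
        if tp + fn == 0:
            missing.append(int(c) if np.issubdtype(classes.dtype, np.integer) else c)
        else:
            per["recall"][i] = tp / (tp + fn)
        if tp + fp > 0:
            per["precision"][i] = tp / (tp + fp)
        if tn + fp > 0:
            per["specificity"][i] = tn / (tn + fp)
        pr, rc = per["precision"][i], per["recall"][i]
        if np.isfinite(pr) and np.isfinite(rc) and (pr + rc) > 0:
            per["f1"][i] = 2 * pr * rc / (pr + rc)
        if profiles is not None and (tp + fn) > 0 and (tp + fn) < total:
            from .patient_model import rank_auc

            per["auc"][i] = rank_auc(profiles[:, i], (y_true == c).astype(int))
    return MulticlassReport(
        classes=classes, confusion=conf, accuracy=acc, per_class=per,
        missing_classes=missing,
    )
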