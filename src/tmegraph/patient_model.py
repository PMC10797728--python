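"""Patient-level chemo-response (pCR vs RD) prediction under LOO-CV.

Each patient is a vector of spatial pair features; for every patient a
model trained on all the others predicts two class probabilities and the
larger one is the call (exact 0.5 ties go to RD, so a pCR call needs a
strict majority).  pCR is the positive class throughout.  Feature selection
runs in two modes: ``nested`` re-runs ReliefF inside every training fold
(no selection leakage, the default), ``global`` selects once on the full
cohort, matching a select-then-validate ordering.  Confidence intervals are
seeded patient-level bootstrap percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import BACKGROUND, HistologyMap
from .relieff import rank_and_select, relieff_weights
from .tile_model import fit_tile_classifier, predict_profiles

POSITIVE = "pCR"
NEGATIVE = "RD"


@dataclass
class BinaryConfusion:
    """Counts with pCR as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class BinaryMetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)


def binary_metrics(conf: BinaryConfusion) -> BinaryMetricsReport:
    """Point metrics from confusion counts; undefined ratios become NaN and
    are listed in ``undefined``."""
    if conf.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, tn, fn = conf.tp, conf.fp, conf.tn, conf.fn
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = (tp + tn) / conf.total
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        undefined.append("f1")
        f1 = float("nan")
    return BinaryMetricsReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec, f1=f1,
        undefined=undefined,
    )


def rank_auc(scores, labels) -> float:
    """AUC as the all-pairs rank statistic, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_auc(scores, labels):
    """ROC curve points plus the rank-statistic AUC.

    Returns (fpr, tpr, thresholds, auc); the trapezoidal area under the
    returned curve equals the rank AUC.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("one-class input")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, thr, rank_auc(scores, labels)


def confusion_from_calls(y_true, calls) -> BinaryConfusion:
    y_true = np.asarray(y_true)
    calls = np.asarray(calls)
    return BinaryConfusion(
        tp=int(np.sum((y_true == POSITIVE) & (calls == POSITIVE))),
        fp=int(np.sum((y_true == NEGATIVE) & (calls == POSITIVE))),
        tn=int(np.sum((y_true == NEGATIVE) & (calls == NEGATIVE))),
        fn=int(np.sum((y_true == POSITIVE) & (calls == NEGATIVE))),
    )


@dataclass
class LoocvResult:
    p_pcr: np.ndarray
    calls: np.ndarray
    confusion: BinaryConfusion
    metrics: BinaryMetricsReport
    auc: float
    selected_global: list[int] | None
    selected_per_fold: list[list[int]] | None
    patient_ids: list[str]


def loocv_evaluate(
    X: pd.DataFrame | np.ndarray,
    y,
    classifier_kind: str = "rbfSVM",
    selection_mode: str = "nested",
    n_top: int = 8,
    relieff_k: int = 10,
    seed: int = 0,
    hyper: dict | None = None,
) -> LoocvResult:
    """Leave-one-out evaluation of pCR/RD prediction with ReliefF selection."""
    if selection_mode not in ("nested", "global"):
        raise ValueError("selection_mode must be 'nested' or 'global'")
    if isinstance(X, pd.DataFrame):
        ids = [str(i) for i in X.index]
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        ids = [f"P{i:03d}" for i in range(Xa.shape[0])]
        names = [f"f{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y)
    min_per_class = 3 if selection_mode == "nested" else 2
    for cls in (POSITIVE, NEGATIVE):
        if int(np.sum(y == cls)) < min_per_class:
            # nested mode needs 2 per class inside every training fold
            raise ValueError(
                f"need >= {min_per_class} patients with outcome {cls}"
            )
    n = Xa.shape[0]
    y01 = (y == POSITIVE).astype(int)
    selected_global = None
    if selection_mode == "global":
        wv = relieff_weights(Xa, y01, k_neighbors=relieff_k, feature_names=names)
        selected_global = rank_and_select(wv, n_top)
    p_pcr = np.empty(n)
    per_fold: list[list[int]] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        assert not train[i], "held-out patient leaked into the training fold"
        if selection_mode == "nested":
            wv = relieff_weights(
                Xa[train], y01[train], k_neighbors=relieff_k, feature_names=names
            )
            sel = rank_and_select(wv, n_top)
        else:
            sel = selected_global
        per_fold.append(list(sel))
        model = fit_tile_classifier(
            Xa[np.ix_(train, sel)], y[train], kind=classifier_kind, hyper=hyper,
            seed=seed + i,
        )
        prof = predict_profiles(model, Xa[i, sel].reshape(1, -1))[0]
        p_pcr[i] = prof[list(model.classes).index(POSITIVE)]
    calls = np.where(p_pcr > 0.5, POSITIVE, NEGATIVE)  # ties -> RD
    conf = confusion_from_calls(y, calls)
    metrics = binary_metrics(conf)
    metrics.auc = rank_auc(p_pcr, y01)
    return LoocvResult(
        p_pcr=p_pcr,
        calls=calls,
        confusion=conf,
        metrics=metrics,
        auc=metrics.auc,
        selected_global=selected_global,
        selected_per_fold=per_fold if selection_mode == "nested" else None,
        patient_ids=ids,
    )


def bootstrap_cis(
    y_true, p_pcr, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Patient-level bootstrap percentile intervals for the point metrics."""
    y_true = np.asarray(y_true)
    p_pcr = np.asarray(p_pcr, dtype=float)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    n = y_true.size
    stats: dict[str, list[float]] = {
        m: [] for m in ("accuracy", "sensitivity", "specificity", "precision",
                        "f1", "auc")
    }
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y_true[idx]
        pb = p_pcr[idx]
        if np.unique(yb).size < 2:
            continue
        calls = np.where(pb > 0.5, POSITIVE, NEGATIVE)
        rep = binary_metrics(confusion_from_calls(yb, calls))
        stats["accuracy"].append(rep.accuracy)
        stats["sensitivity"].append(rep.sensitivity)
        stats["specificity"].append(rep.specificity)
        stats["precision"].append(rep.precision)
        stats["f1"].append(rep.f1)
        stats["auc"].append(rank_auc(pb, (yb == POSITIVE).astype(int)))
    alpha = (1 - level) / 2
    out = {}
    for m, vals in stats.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size:
            out[m] = (float(np.quantile(v, alpha)), float(np.quantile(v, 1 - alpha)))
    return out


# ---------------------------------------------------------------------------
# Attention maps


def attention_map(
    hmap: HistologyMap, selected_pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Boolean overlay of cells whose clusters are nodes of any selected
    pair's graph (i.e. cells of the selected pairs' classes)."""
    overlay = np.zeros(hmap.shape, dtype=bool)
    classes = {c for pair in selected_pairs for c in pair}
    classes.discard(BACKGROUND)
    for c in classes:
        overlay |= hmap.class_mask(int(c))
    return overlay


def selected_pairs_from_names(feature_names: list[str]) -> list[tuple[int, int]]:
    """Parse ``pair<a>-<b>|<feature>`` column names into class pairs."""
    pairs = []
    for name in feature_names:
        head = name.split("|")[0]
        if head.startswith("pair") and "-" in head:
            a, b = head[4:].split("-")
            pair = (int(a), int(b))
            if pair not in pairs:
                pairs.append(pair)
    return pairs
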