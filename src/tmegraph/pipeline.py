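"""End-to-end orchestration of the two-step pipeline.

``run_end_to_end`` executes: synthetic cohort generation (or loading of a
real-mode tile/annotation/outcome trio) -> tile-level classifier CV ->
per-patient histology classification maps -> pair-graph features ->
ReliefF selection -> patient-level LOO evaluation -> reports and attention
overlays.  Every stage logs counts in/out and its content hash; re-running
with the same config and seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import PipelineConfig, validate_config
from .core import BACKGROUND, HistologyMap
from .graphs import pair_feature_matrix
from .patient_model import (
    attention_map,
    bootstrap_cis,
    loocv_evaluate,
    selected_pairs_from_names,
)
from .relieff import rank_and_select, relieff_weights, weight_table
from .synthetic import CohortConfig, generate_cohort
from .tile_model import cross_validate_tiles, predicted_classes


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, name: str, t0: float, payload, **counts) -> None:
        self.stages[name] = {
            "seconds": round(time.time() - t0, 3),
            "hash": _content_hash(payload),
            **counts,
        }

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "seed": self.seed,
                           "stages": self.stages}, indent=1, default=str)


def _content_hash(payload) -> str:
    h = hashlib.sha256()
    if isinstance(payload, np.ndarray):
        h.update(np.ascontiguousarray(payload).tobytes())
    elif isinstance(payload, pd.DataFrame):
        h.update(payload.to_csv().encode())
    else:
        h.update(json.dumps(payload, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def run_end_to_end(
    config: PipelineConfig | dict | None = None,
    mode: str = "synthetic",
    out_dir: str | Path | None = None,
    real_inputs: dict | None = None,
) -> dict:
    """Run the full pipeline; returns the manifest plus all reports."""
    cfg = validate_config(config)
    if mode not in ("synthetic", "real"):
        raise ValueError("mode must be 'synthetic' or 'real'")
    manifest = RunManifest(config=cfg.echo(), seed=cfg.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort -----------------------------------------------------
    t0 = time.time()
    if mode == "synthetic":
        sc = cfg.synthetic
        cohort_cfg = CohortConfig(
            n_patients=sc.n_patients,
            prevalence_pCR=sc.prevalence_pCR,
            map_shape=sc.map_shape,
            effect_size=sc.effect_size,
            planted_pair=sc.planted_pair,
            smoothness=sc.smoothness,
            background_fraction=sc.background_fraction,
            seed=cfg.seed,
        )
        patients = generate_cohort(cohort_cfg)
        outcomes = {p.patient_id: p.outcome for p in patients}
        class_ids = sorted({int(k) for k in cohort_cfg.class_mixing})
    else:
        if not real_inputs or "outcomes_csv" not in real_inputs:
            raise StageError("cohort", "real mode requires an outcome CSV")
        raise StageError("cohort", "real-mode ingestion requires tile inputs; "
                         "use the preprocess module directly")
    manifest.record(
        "cohort", t0,
        np.concatenate([p.label_map.grid.ravel() for p in patients])
        if patients else [],
        n_patients=len(patients),
        n_pcr=sum(1 for p in patients if p.outcome == "pCR"),
    )

    # --- stage: tile-level classification ---------------------------------
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    Xt, yt = _sample_tile_training_set(patients, cfg, rng)
    tile_cv = cross_validate_tiles(
        Xt, yt, kind=cfg.tile_classifier, k=cfg.k_folds, seed=cfg.seed
    )
    manifest.record(
        "tiles", t0, tile_cv["y_pred"],
        n_tiles=int(len(yt)), mean_accuracy=tile_cv["mean_accuracy"],
    )

    # --- stage: histology maps (predicted) ---------------------------------
    t0 = time.time()
    from .tile_model import fit_tile_classifier, predict_profiles

    model = fit_tile_classifier(Xt, yt, kind=cfg.tile_classifier, seed=cfg.seed)
    pred_patients = []
    for p in patients:
        R, C, F = p.tile_features.shape
        flat = p.tile_features.reshape(-1, F)
        tissue = p.label_map.grid.ravel() != BACKGROUND
        pred = np.full(R * C, BACKGROUND, dtype=np.int64)
        if tissue.any():
            prof = predict_profiles(model, flat[tissue])
            pred[tissue] = predicted_classes(model, prof)
        pmap = HistologyMap(grid=pred.reshape(R, C), patient_id=p.patient_id)
        pred_patients.append(replace(p, label_map=pmap))
    manifest.record(
        "maps", t0,
        np.concatenate([p.label_map.grid.ravel() for p in pred_patients]),
        n_maps=len(pred_patients),
    )

    # --- stage: pair-graph features ----------------------------------------
    t0 = time.time()
    pair_df = pair_feature_matrix(
        pred_patients, class_ids, radius=cfg.graph_radius,
        connectivity=cfg.graph_connectivity,
        cross_class_only=cfg.cross_class_edges_only,
    )
    manifest.record("graphs", t0, pair_df, n_pairs=len(class_ids) * (len(class_ids) - 1) // 2,
                    n_features=pair_df.shape[1])

    # --- stage: selection ---------------------------------------------------
    t0 = time.time()
    y = np.array([outcomes[pid] for pid in pair_df.index])
    wv = relieff_weights(
        pair_df.to_numpy(), (y == "pCR").astype(int),
        k_neighbors=cfg.relieff_k, feature_names=list(pair_df.columns),
    )
    selected = rank_and_select(wv, cfg.n_top)
    wt = weight_table(wv)
    manifest.record("select", t0, wv.weights, n_selected=len(selected))

    # --- stage: LOO evaluation ----------------------------------------------
    t0 = time.time()
    loo = loocv_evaluate(
        pair_df, y, classifier_kind=cfg.patient_classifier,
        selection_mode=cfg.selection_mode, n_top=cfg.n_top,
        relieff_k=cfg.relieff_k, seed=cfg.seed,
    )
    cis = bootstrap_cis(y, loo.p_pcr, n_boot=500, seed=cfg.seed)
    loo.metrics.ci = cis
    manifest.record("predict", t0, loo.p_pcr,
                    accuracy=loo.metrics.accuracy, auc=loo.auc)

    # --- stage: attention maps ----------------------------------------------
    t0 = time.time()
    sel_names = [pair_df.columns[i] for i in selected]
    sel_pairs = selected_pairs_from_names(sel_names)
    overlays = {
        p.patient_id: attention_map(p.label_map, sel_pairs) for p in pred_patients
    }
    manifest.record(
        "attention", t0,
        np.concatenate([o.ravel() for o in overlays.values()]) if overlays else [],
        n_pairs_highlighted=len(sel_pairs),
    )

    results = {
        "manifest": manifest,
        "patients": patients,
        "pred_patients": pred_patients,
        "tile_cv": tile_cv,
        "pair_features": pair_df,
        "weights": wv,
        "weight_table": wt,
        "selected": selected,
        "selected_names": sel_names,
        "loo": loo,
        "overlays": overlays,
        "outcomes": y,
    }
    if out is not None:
        _write_reports(results, out)
    return results


def _sample_tile_training_set(patients, cfg: PipelineConfig, rng):
    """Balanced per-class tile feature sample drawn from the cohort cells."""
    cells_by_class: dict[int, list[np.ndarray]] = {}
    for p in patients:
        g = p.label_map.grid
        for cid in np.unique(g):
            if cid == BACKGROUND:
                continue
            mask = g == cid
            cells_by_class.setdefault(int(cid), []).append(p.tile_features[mask])
    X_parts, y_parts = [], []
    n_per = cfg.synthetic.tiles_per_class
    for cid, chunks in sorted(cells_by_class.items()):
        allc = np.concatenate(chunks, axis=0)
        take = min(n_per, allc.shape[0])
        idx = rng.choice(allc.shape[0], size=take, replace=False)
        X_parts.append(allc[idx])
        y_parts.append(np.full(take, cid))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    X = np.nan_to_num(X, nan=0.0)
    return X, y


def _write_reports(results, out: Path) -> None:
    loo = results["loo"]
    metrics = {
        "accuracy": loo.metrics.accuracy,
        "sensitivity": loo.metrics.sensitivity,
        "specificity": loo.metrics.specificity,
        "precision": loo.metrics.precision,
        "f1": loo.metrics.f1,
        "auc": loo.auc,
        "ci": loo.metrics.ci,
        "confusion": {"tp": loo.confusion.tp, "fp": loo.confusion.fp,
                      "tn": loo.confusion.tn, "fn": loo.confusion.fn},
        "tile_cv_mean_accuracy": results["tile_cv"]["mean_accuracy"],
        "selected_features": results["selected_names"],
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    preds = pd.DataFrame(
        {"patient_id": loo.patient_ids, "p_pCR": loo.p_pcr, "call": loo.calls,
         "outcome": results["outcomes"]}
    )
    preds.to_csv(out / "predictions.csv", index=False)
    results["weight_table"].to_csv(out / "relieff_weights.csv", index=False)
    from .patient_model import roc_auc

    fpr, tpr, thr, _ = roc_auc(loo.p_pcr, (results["outcomes"] == "pCR").astype(int))
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
        out / "roc_points.csv", index=False
    )
    (out / "manifest.json").write_text(results["manifest"].to_json())
    for pid, overlay in results["overlays"].items():
        tio.write_attention_png(overlay, out / f"{pid}_attention.png")
    for p in results["pred_patients"]:
        tio.write_map_png(p.label_map, out / f"{p.patient_id}_map.png")
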