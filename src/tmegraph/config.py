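"""Pipeline configuration: every fixed setting of the method is a named,
validated default here — 224-px tiles, the 90 % overlap retention rule,
stratified eightfold tile CV, the 8-tile graph radius, top-8 ReliefF
selection — so stage logic never hard-codes them."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .core import HISTOLOGY_CLASSES
from .tile_model import CLASSIFIER_KINDS


class ConfigError(ValueError):
    """Aggregated validation failure naming every offending key."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config: " + "; ".join(errors))


@dataclass
class SyntheticConfig:
    n_patients: int = 60
    prevalence_pCR: float = 0.6
    map_shape: tuple[int, int] = (48, 48)
    effect_size: float = 2.0
    planted_pair: tuple[int, int] = (1, 2)
    smoothness: float = 3.0
    background_fraction: float = 0.05
    tiles_per_class: int = 60
    tile_render_size: int = 64


@dataclass
class PipelineConfig:
    tile_size: int = 224
    min_overlap: float = 0.90
    k_folds: int = 8
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    tile_classifier: str = "rbfSVM"
    patient_classifier: str = "rbfSVM"
    graph_radius: float = 8.0
    graph_connectivity: int = 4
    cross_class_edges_only: bool = False
    n_top: int = 8
    relieff_k: int = 10
    selection_mode: str = "nested"
    seed: int = 0
    class_catalog: tuple[str, ...] = HISTOLOGY_CLASSES
    include_background_class: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def validate_config(doc: dict | PipelineConfig | None = None) -> PipelineConfig:
    """Fill defaults and check all cross-field constraints; raises
    :class:`ConfigError` listing every offending key."""
    if doc is None:
        doc = {}
    if isinstance(doc, PipelineConfig):
        cfg = doc
    else:
        doc = dict(doc)
        synth = doc.pop("synthetic", {})
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = [k for k in doc if k not in known]
        if unknown:
            raise ConfigError([f"unknown key {k!r}" for k in unknown])
        cfg = PipelineConfig(**doc)
        if synth:
            cfg.synthetic = SyntheticConfig(**synth)
    errors = []
    if cfg.tile_size < 1:
        errors.append("tile_size must be >= 1")
    if not 0 < cfg.min_overlap <= 1:
        errors.append("min_overlap must be in (0, 1]")
    if cfg.k_folds < 2:
        errors.append("k_folds must be >= 2")
    if cfg.graph_radius <= 0:
        errors.append("graph_radius must be > 0")
    if cfg.graph_connectivity not in (4, 8):
        errors.append("graph_connectivity must be 4 or 8")
    if cfg.n_top < 1:
        errors.append("n_top must be >= 1")
    if cfg.relieff_k < 1:
        errors.append("relieff_k must be >= 1")
    if cfg.selection_mode not in ("nested", "global"):
        errors.append("selection_mode must be 'nested' or 'global'")
    if not cfg.class_catalog:
        errors.append("class_catalog must be non-empty")
    for kind in tuple(cfg.classifiers) + (cfg.tile_classifier, cfg.patient_classifier):
        if kind not in CLASSIFIER_KINDS:
            errors.append(f"unknown classifier kind {kind!r}")
    if cfg.synthetic.n_patients < 0:
        errors.append("synthetic.n_patients must be >= 0")
    if not 0 <= cfg.synthetic.prevalence_pCR <= 1:
        errors.append("synthetic.prevalence_pCR must be in [0, 1]")
    if cfg.synthetic.effect_size < 0:
        errors.append("synthetic.effect_size must be >= 0")
    if cfg.synthetic.planted_pair[0] == cfg.synthetic.planted_pair[1]:
        errors.append("synthetic.planted_pair classes must be distinct")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(doc)
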