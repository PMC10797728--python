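"""Tile extraction, stain normalization and color deconvolution.

Annotated H&E regions are cut into a non-overlapping 224x224 grid anchored
at the slide origin; a tile is kept only when at least 90 % of its area lies
inside annotated tissue.  Color handling works in optical-density (OD)
space, where stain contributions mix linearly: a 3x2 matrix of unit H and E
OD vectors is estimated per image (SVD over tissue pixels, extreme-angle
percentiles), concentrations are unmixed by least squares, and tiles are
re-rendered against a common reference stain model.  The hematoxylin
concentration image is the substrate for all downstream texture features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box, shape
from shapely.ops import unary_union

from .core import BACKGROUND, HISTOLOGY_CLASSES, TileRecord

#: Standard published H&E OD direction vectors (columns: H, E), unit-norm.
_H_VEC = np.array([0.650, 0.704, 0.286])
_E_VEC = np.array([0.072, 0.990, 0.105])

OD_EPS = 1e-6
BACKGROUND_OD_THRESHOLD = 0.10


class InsufficientTissueError(ValueError):
    """Raised when too few pixels exceed the tissue OD threshold."""


@dataclass
class AnnotatedRegion:
    """A pathologist-drawn closed contour with its histology class."""

    polygon: Polygon
    class_label: int

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid:
            raise ValueError("region polygon is invalid (self-intersecting?)")


@dataclass
class StainModel:
    """Unit H/E OD vectors plus robust per-stain maximum concentrations."""

    stain_matrix: np.ndarray  # (3, 2), columns H then E
    max_concentrations: np.ndarray = field(
        default_factory=lambda: np.array([1.9705, 1.0308])
    )

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be nonzero")
        self.stain_matrix = self.stain_matrix / norms


def reference_stain_model() -> StainModel:
    """The fallback/deconvolution default: standard published H&E vectors."""
    return StainModel(np.column_stack([_H_VEC, _E_VEC]))


# ---------------------------------------------------------------------------
# Tiling


def tile_partition(
    regions: list[AnnotatedRegion],
    image_extent: tuple[float, float],
    tile_size: int = 224,
    min_overlap: float = 0.90,
    patient_id: str = "",
) -> list[TileRecord]:
    """Grid-aligned tiles overlapping annotated tissue by >= ``min_overlap``.

    The grid is anchored at (0, 0) with stride = ``tile_size`` (x rightward,
    y downward).  A tile is retained iff its intersection area with the
    union of the regions reaches ``min_overlap * tile_size**2``; its class
    is the label of the region with the largest overlap, ties broken by the
    lower class id.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    if not regions:
        raise ValueError("empty region list")
    width, height = image_extent
    union = unary_union([r.polygon for r in regions])
    need = min_overlap * tile_size * tile_size
    n_cols = int(np.ceil(width / tile_size))
    n_rows = int(np.ceil(height / tile_size))
    minx, miny, maxx, maxy = union.bounds
    c0 = max(int(np.floor(minx / tile_size)), 0)
    r0 = max(int(np.floor(miny / tile_size)), 0)
    c1 = min(int(np.ceil(maxx / tile_size)), n_cols)
    r1 = min(int(np.ceil(maxy / tile_size)), n_rows)
    out: list[TileRecord] = []
    for r in range(r0, r1):
        for c in range(c0, c1):
            x0, y0 = c * tile_size, r * tile_size
            square = box(x0, y0, x0 + tile_size, y0 + tile_size)
            if square.intersection(union).area + 1e-9 < need:
                continue
            best_area, best_label = -1.0, BACKGROUND
            for reg in regions:
                a = square.intersection(reg.polygon).area
                if a > best_area + 1e-9 or (
                    abs(a - best_area) <= 1e-9 and reg.class_label < best_label
                ):
                    best_area, best_label = a, reg.class_label
            out.append(
                TileRecord(
                    patient_id=patient_id,
                    grid_row=r,
                    grid_col=c,
                    origin=(float(x0), float(y0)),
                    true_class=best_label,
                )
            )
    return out


def read_geojson_regions(
    path: str, class_catalog: tuple[str, ...] = HISTOLOGY_CLASSES
) -> list[AnnotatedRegion]:
    """Read QuPath-dialect GeoJSON: polygon features with the class name
    under ``properties.classification.name``."""
    with open(path) as fh:
        doc = json.load(fh)
    name_to_id = {n: i for i, n in enumerate(class_catalog)}
    regions = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        name = feat.get("properties", {}).get("classification", {}).get("name")
        if name is None:
            raise ValueError("feature lacks properties.classification.name")
        if name not in name_to_id:
            raise ValueError(f"unknown histology class {name!r}")
        if geom.geom_type == "MultiPolygon":
            for g in geom.geoms:
                regions.append(AnnotatedRegion(g, name_to_id[name]))
        else:
            regions.append(AnnotatedRegion(geom, name_to_id[name]))
    return regions


# ---------------------------------------------------------------------------
# Optical density and stain estimation


def rgb_to_od(tile: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """OD = -log10((I + eps) / I0) elementwise, eps = 1e-6."""
    I = np.asarray(tile, dtype=float)
    return -np.log10((I + OD_EPS) / background_intensity)


def od_to_rgb(od: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    rgb = background_intensity * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(rgb, 0, 255).astype(np.uint8)


def estimate_stain_vectors(
    od: np.ndarray,
    alpha_percentile: float = 1.0,
    beta_od: float = 0.15,
    min_tissue_pixels: int = 50,
) -> StainModel:
    """SVD/extreme-angle (Macenko-style) stain-vector estimation.

    Tissue pixels (OD norm > ``beta_od``) are projected onto their top two
    singular directions; the H and E directions are the alpha and
    100-alpha percentile angles in that plane.  The vector with the larger
    red-channel OD is labeled hematoxylin.
    """
    pixels = np.asarray(od, dtype=float).reshape(-1, 3)
    tissue = pixels[np.linalg.norm(pixels, axis=1) > beta_od]
    if tissue.shape[0] < min_tissue_pixels:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {beta_od}"
        )
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2].T  # (3, 2)
    # orient basis vectors consistently
    for k in range(2):
        if basis[:, k].sum() < 0:
            basis[:, k] = -basis[:, k]
    proj = tissue @ basis
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha_percentile, 100 - alpha_percentile])
    v1 = basis @ np.array([np.cos(lo), np.sin(lo)])
    v2 = basis @ np.array([np.cos(hi), np.sin(hi)])
    for v in (v1, v2):
        if v.sum() < 0:
            v *= -1
    v1 = v1 / np.linalg.norm(v1)
    v2 = v2 / np.linalg.norm(v2)
    # hematoxylin has the larger red-channel OD
    if v1[0] >= v2[0]:
        M = np.column_stack([v1, v2])
    else:
        M = np.column_stack([v2, v1])
    model = StainModel(np.clip(M, 0, None))
    model.max_concentrations = _robust_max_concentrations(pixels, model)
    return model


def _robust_max_concentrations(od_pixels: np.ndarray, model: StainModel) -> np.ndarray:
    C = stain_concentrations(od_pixels.reshape(-1, 3), model)
    return np.percentile(C, 99, axis=0)


def stain_concentrations(od: np.ndarray, model: StainModel) -> np.ndarray:
    """Least-squares unmixing of OD pixels into (H, E) concentrations."""
    flat = np.asarray(od, dtype=float).reshape(-1, 3)
    M = model.stain_matrix
    if np.linalg.matrix_rank(M) < 2:
        raise np.linalg.LinAlgError("singular stain matrix")
    C, *_ = np.linalg.lstsq(M, flat.T, rcond=None)
    return C.T  # (n_pixels, 2)


def estimate_stain_model(tile: np.ndarray, **kwargs) -> StainModel:
    """Estimate a full StainModel (vectors + robust maxima) from an RGB tile."""
    return estimate_stain_vectors(rgb_to_od(tile), **kwargs)


def normalize_stains(
    tile: np.ndarray, source: StainModel, reference: StainModel
) -> np.ndarray:
    """Re-render a tile under the reference stain model.

    Concentrations are unmixed against ``source``, rescaled so the source's
    robust maxima map onto the reference's, and remixed with the reference
    stain matrix.  Output is clipped to [0, 255] uint8.
    """
    od = rgb_to_od(tile)
    flat = od.reshape(-1, 3)
    C = stain_concentrations(od, source)
    # off-span OD (noise, quantization) is carried through unchanged so
    # that normalizing against the source model itself is the identity
    residual = flat - (source.stain_matrix @ C.T).T
    scale = reference.max_concentrations / np.where(
        source.max_concentrations > 0, source.max_concentrations, 1.0
    )
    C = np.clip(C, 0, None) * scale
    od_new = (reference.stain_matrix @ C.T).T + residual
    return od_to_rgb(od_new.reshape(np.asarray(tile).shape))


def hematoxylin_channel(tile: np.ndarray, model: StainModel | None = None) -> np.ndarray:
    """Per-pixel hematoxylin concentration (OD units), clamped >= 0."""
    if model is None:
        model = reference_stain_model()
    arr = np.asarray(tile)
    C = stain_concentrations(rgb_to_od(arr), model)
    H = C[:, 0].reshape(arr.shape[:2])
    return np.clip(H, 0, None)


def is_background_tile(tile: np.ndarray, threshold: float = BACKGROUND_OD_THRESHOLD) -> bool:
    """Mean OD below threshold means (near-)empty glass: background tile."""
    return float(rgb_to_od(tile).mean()) < threshold
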