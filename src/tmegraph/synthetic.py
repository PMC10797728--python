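"""Synthetic histology substrate: class-conditional tiles, coherent label
maps, and outcome-linked cohorts.

Tiles are rendered as two-stain optical-density mixtures: per-class
hematoxylin/eosin concentration fields are Gaussian random fields (spectral
smoothing of white noise at a class-specific correlation length) plus
anti-aliased nucleus disks, mixed through the standard H&E stain vectors and
exponentiated to RGB.  Label maps are argmax compositions of smoothed
per-class noise fields, giving spatially coherent multi-class patches with a
background rim.  Cohorts plant an outcome-linked spatial interaction: pCR
patients' maps are edited at class boundaries until the planted class pair's
interface density exceeds their baseline by ``effect_size`` cohort standard
deviations, so recovery of the signal by ReliefF and the patient-level
classifiers is quantifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import features as feat
from .core import BACKGROUND, HistologyMap, interface_density
from .preprocess import reference_stain_model


@dataclass(frozen=True)
class ClassTextureParams:
    """Stain-and-texture recipe for one synthetic histology class."""

    class_id: int
    correlation_length: float = 4.0  # px, GRF smoothing scale
    anisotropy_angle: float = 0.0  # rad
    nucleus_density: float = 80.0  # expected nuclei per 224x224 tile
    nucleus_radius: tuple[float, float] = (3.0, 0.6)  # px (mean, sd)
    hematoxylin_level: float = 0.6  # OD
    eosin_level: float = 0.5  # OD

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.hematoxylin_level < 0 or self.eosin_level < 0:
            raise ValueError("OD levels must be >= 0")


#: Default class recipes for synthetic cohorts: the six TME components the
#: development data's strongest class pairs involve.
SYNTH_CLASS_NAMES = ("stroma", "tumor", "tumor_TIL", "stroma_TIL", "PGCC", "microvessel")

DEFAULT_CLASS_PARAMS: dict[int, ClassTextureParams] = {
    0: ClassTextureParams(0, correlation_length=9.0, nucleus_density=15,
                          hematoxylin_level=0.25, eosin_level=0.85),
    1: ClassTextureParams(1, correlation_length=4.0, nucleus_density=130,
                          hematoxylin_level=0.85, eosin_level=0.40),
    2: ClassTextureParams(2, correlation_length=2.0, nucleus_density=220,
                          nucleus_radius=(2.0, 0.4), hematoxylin_level=1.15,
                          eosin_level=0.20),
    3: ClassTextureParams(3, correlation_length=3.0, nucleus_density=160,
                          nucleus_radius=(2.2, 0.5), hematoxylin_level=0.95,
                          eosin_level=0.55),
    4: ClassTextureParams(4, correlation_length=6.0, nucleus_density=35,
                          nucleus_radius=(8.0, 1.5), hematoxylin_level=1.05,
                          eosin_level=0.50),
    5: ClassTextureParams(5, correlation_length=5.0, nucleus_density=55,
                          anisotropy_angle=np.pi / 4, hematoxylin_level=0.45,
                          eosin_level=1.00),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic patient cohort."""

    n_patients: int = 60
    prevalence_pCR: float = 0.6  # development-cohort pCR fraction (51/85)
    map_shape: tuple[int, int] = (48, 48)
    class_mixing: dict[int, float] = field(
        default_factory=lambda: {0: 1.5, 1: 1.2, 2: 0.8, 3: 0.8, 4: 0.5, 5: 0.6}
    )
    planted_pair: tuple[int, int] = (1, 2)  # tumor - tumor_TIL
    effect_size: float = 2.0
    smoothness: float = 3.0  # cells, label-map coherence scale
    background_fraction: float = 0.05
    tile_feature_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_pCR <= 1:
            raise ValueError("prevalence_pCR must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.planted_pair[0] == self.planted_pair[1]:
            raise ValueError("planted_pair classes must be distinct")


@dataclass
class SyntheticPatient:
    patient_id: str
    outcome: str  # "pCR" or "RD"
    label_map: HistologyMap
    tile_features: np.ndarray  # (rows, cols, 80); NaN-free, zeros on background


# ---------------------------------------------------------------------------
# Tile rendering


def _gaussian_random_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    correlation_length: float,
    anisotropy_angle: float = 0.0,
    anisotropy_ratio: float = 2.0,
) -> np.ndarray:
    """Unit-variance GRF via anisotropic Gaussian smoothing of white noise."""
    noise = rng.standard_normal(shape)
    s_major = correlation_length
    s_minor = correlation_length / anisotropy_ratio
    if abs(anisotropy_angle) < 1e-12:
        f = ndimage.gaussian_filter(noise, sigma=(s_minor, s_major), mode="wrap")
    else:
        pad = shape[0] // 4
        big = rng.standard_normal((shape[0] + 2 * pad, shape[1] + 2 * pad))
        f = ndimage.gaussian_filter(big, sigma=(s_minor, s_major), mode="wrap")
        f = ndimage.rotate(f, np.rad2deg(anisotropy_angle), reshape=False, order=1)
        f = f[pad : pad + shape[0], pad : pad + shape[1]]
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _nucleus_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    radius: tuple[float, float],
    tile_scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of anti-aliased disks and the boolean disk mask."""
    field_ = np.zeros(shape)
    n = rng.poisson(density * tile_scale)
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(n):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        r = max(rng.normal(radius[0], radius[1]), 0.8)
        d = np.hypot(yy - cy, xx - cx)
        field_ += np.clip(r + 0.5 - d, 0, 1)  # 1 inside, linear AA edge
    return field_, field_ > 0.5


def generate_class_tile(
    params: ClassTextureParams,
    seed: int,
    size: int = 224,
    return_fields: bool = False,
):
    """Render one RGB tile for a histology class; deterministic in (params, seed).

    The hematoxylin concentration is the class GRF modulated around
    ``hematoxylin_level`` plus 0.8-OD nucleus disks; eosin is an independent
    GRF around ``eosin_level``.  OD = M @ (cH, cE) with the standard H&E
    stain matrix, exponentiated to RGB.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, params.class_id])
    )
    shape = (size, size)
    tile_scale = (size / 224.0) ** 2
    gH = _gaussian_random_field(rng, shape, params.correlation_length,
                                params.anisotropy_angle)
    gE = _gaussian_random_field(rng, shape, params.correlation_length,
                                params.anisotropy_angle)
    nuc, nuc_mask = _nucleus_field(rng, shape, params.nucleus_density,
                                   params.nucleus_radius, tile_scale)
    cH = np.clip(params.hematoxylin_level * (1.0 + 0.35 * gH), 0, None) + 0.8 * nuc
    cE = np.clip(params.eosin_level * (1.0 + 0.35 * gE), 0, None)
    M = reference_stain_model().stain_matrix
    od = np.stack([cH, cE], axis=-1) @ M.T  # (H, W, 3)
    rgb = np.clip(255.0 * np.power(10.0, -od), 0, 255).astype(np.uint8)
    if return_fields:
        return rgb, {"cH": cH, "cE": cE, "nucleus_mask": nuc_mask}
    return rgb


# ---------------------------------------------------------------------------
# Label maps


def generate_label_map(
    class_mixing: dict[int, float],
    map_shape: tuple[int, int],
    smoothness: float,
    seed: int,
    background_fraction: float = 0.0,
    patient_id: str = "",
) -> HistologyMap:
    """Argmax of weighted, smoothed per-class noise fields.

    Each class gets an exp-transformed smoothed Gaussian field scaled by its
    mixing weight; each cell takes the argmax class, yielding coherent
    patches whose prevalence grows with the weight.  Optionally the lowest
    ``background_fraction`` quantile of a smoothed tissue field becomes
    background.
    """
    if min(map_shape) < 1:
        raise ValueError("map_shape dimensions must be >= 1")
    weights = {int(k): float(v) for k, v in class_mixing.items()}
    if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
        raise ValueError("class weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    ids = sorted(weights)
    fields = np.empty((len(ids),) + tuple(map_shape))
    for i, cid in enumerate(ids):
        g = ndimage.gaussian_filter(rng.standard_normal(map_shape), smoothness,
                                    mode="wrap")
        sd = g.std()
        g = g / (sd if sd > 0 else 1.0)
        fields[i] = weights[cid] * np.exp(g)
    grid = np.array(ids, dtype=np.int64)[np.argmax(fields, axis=0)]
    if background_fraction > 0:
        t = ndimage.gaussian_filter(rng.standard_normal(map_shape),
                                    max(smoothness * 2, 1.0), mode="wrap")
        thresh = np.quantile(t, background_fraction)
        grid[t < thresh] = BACKGROUND
    return HistologyMap(grid=grid, patient_id=patient_id)


# ---------------------------------------------------------------------------
# Class-conditional tile feature statistics (cached)

_CLASS_STAT_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def class_feature_statistics(
    params: ClassTextureParams, n_reference_tiles: int = 6, render_size: int = 96
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sd of the 80-feature vector over rendered reference tiles.

    Cohort per-cell features are drawn from these class-conditional
    statistics rather than rendering one tile per grid cell, which keeps
    cohort generation tractable while tying the feature distributions to
    the actual tile renderer.  NaN features (undefined statistics) map to 0
    with sd 0 so downstream matrices stay NaN-free.
    """
    key = (params, n_reference_tiles, render_size)
    if key in _CLASS_STAT_CACHE:
        return _CLASS_STAT_CACHE[key]
    vecs = []
    for i in range(n_reference_tiles):
        tile = generate_class_tile(params, seed=1_000_003 + i, size=render_size)
        gray = feat._as_gray_u8(
            np.clip(hema_proxy(tile), 0, 2.0)
        )
        vecs.append(feat.extract_all(gray))
    V = np.array(vecs)
    mean = np.nanmean(V, axis=0)
    sd = np.nanstd(V, axis=0)
    bad = ~np.isfinite(mean)
    mean[bad] = 0.0
    sd[bad | ~np.isfinite(sd)] = 0.0
    _CLASS_STAT_CACHE[key] = (mean, sd)
    return mean, sd


def hema_proxy(tile: np.ndarray) -> np.ndarray:
    """Hematoxylin concentration of a rendered tile via deconvolution."""
    from .preprocess import hematoxylin_channel

    return hematoxylin_channel(tile)


# ---------------------------------------------------------------------------
# Cohorts


def _neighbor_count(g: np.ndarray, r: int, c: int, cls: int) -> int:
    n = 0
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < g.shape[0] and 0 <= cc < g.shape[1] and g[rr, cc] == cls:
            n += 1
    return n


def _plant_interface(
    grid: np.ndarray,
    pair: tuple[int, int],
    target: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow existing B clusters toward A until the A-B interface density
    reaches ``target``.

    Each step converts the free cell adjacent to B that is closest to an A
    cell (ties broken at random), so existing B clusters extend along a
    corridor to the nearest A region and then hug its boundary -- an
    infiltration-like, pair-specific edit that leaves B's cluster count and
    the rest of the map essentially unchanged.
    """
    a, b = pair
    g = grid.copy()
    current = interface_density(HistologyMap(g), a, b)
    if current >= target:
        return g
    # phase 1: micro-infiltration.  Convert isolated interior A cells to B
    # (each adds 4 A-B adjacencies and a B node at an A cluster's core) and
    # retire an equally small far-from-A B cluster so B's cluster count is
    # conserved: the pair's spatial coupling rises with little change to
    # the other class pairs.
    labeled_b, n_b = ndimage.label(g == b, structure=_FOUR_CONN_STRUCT)
    dist_a = ndimage.distance_transform_edt(g != a)
    removable = sorted(
        (k for k in range(1, n_b + 1) if np.sum(labeled_b == k) <= 6),
        key=lambda k: -float(dist_a[labeled_b == k].min()),
    )
    interior = ndimage.binary_erosion(g == a, structure=_FOUR_CONN_STRUCT)
    labeled_a, n_a = ndimage.label(g == a, structure=_FOUR_CONN_STRUCT)
    # visit A clusters round-robin so every tumor region is infiltrated
    per_cluster = []
    for k in range(1, n_a + 1):
        cells_k = np.argwhere(interior & (labeled_a == k))
        rng.shuffle(cells_k)
        per_cluster.append(list(cells_k))
    cand = []
    while any(per_cluster):
        for lst in per_cluster:
            if lst:
                cand.append(lst.pop())
    taken = np.zeros_like(g, dtype=bool)
    for r, c in cand:
        if current >= target:
            break
        if taken[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2].any():
            continue  # keep infiltrates isolated so each gains 4 adjacencies
        g[r, c] = b
        taken[r, c] = True
        current += 4 / g.size
        if removable:
            k = removable.pop(0)
            cells = np.argwhere(labeled_b == k)
            lost = sum(_neighbor_count(g, r2, c2, a) for r2, c2 in cells)
            fill = _majority_neighbor_class(g, cells, exclude=(a, b, BACKGROUND))
            g[cells[:, 0], cells[:, 1]] = fill
            labeled_b[cells[:, 0], cells[:, 1]] = 0
            current -= lost / g.size
    # phase 2: thicken existing A-B contact zones cell by cell
    free = (g != a) & (g != b) & (g != BACKGROUND)
    for _ in range(g.size):
        if current >= target:
            break
        near_b = ndimage.binary_dilation(g == b) & free
        near_a = ndimage.binary_dilation(g == a)
        cand = np.argwhere(near_b & near_a)
        if cand.size == 0:
            cand = np.argwhere(near_b)
            if cand.size == 0:
                break
            dist_a = ndimage.distance_transform_edt(g != a)
            d = dist_a[cand[:, 0], cand[:, 1]]
            cand = cand[d == d.min()]
        r, c = cand[rng.integers(cand.shape[0])]
        g[r, c] = b
        free[r, c] = False
        current += _neighbor_count(g, r, c, a) / g.size
    return g


_FOUR_CONN_STRUCT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _majority_neighbor_class(g, cells, exclude):
    """Most common class on the cluster's outer boundary, for backfilling."""
    votes: dict[int, int] = {}
    cellset = {(int(r), int(c)) for r, c in cells}
    for r, c in cells:
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            rr, cc = int(r + dr), int(c + dc)
            if (rr, cc) in cellset:
                continue
            if 0 <= rr < g.shape[0] and 0 <= cc < g.shape[1]:
                v = int(g[rr, cc])
                if v not in exclude:
                    votes[v] = votes.get(v, 0) + 1
    if not votes:
        return 0
    return max(sorted(votes), key=lambda k: votes[k])


def generate_cohort(
    config: CohortConfig, with_features: bool = True
) -> list[SyntheticPatient]:
    """Generate an outcome-linked synthetic cohort.

    Outcomes are drawn i.i.d. at ``prevalence_pCR``; baseline maps are
    generated per patient, the cohort SD of the planted pair's interface
    density is measured, and each pCR patient's map is edited until their
    statistic exceeds baseline by ``effect_size`` SDs.  Per-cell 80-feature
    vectors are sampled from class-conditional renderer statistics.
    """
    if config.n_patients == 0:
        return []
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    outcomes = np.where(
        rng.uniform(size=config.n_patients) < config.prevalence_pCR, "pCR", "RD"
    )
    if config.effect_size > 0:
        for grp in ("pCR", "RD"):
            if int(np.sum(outcomes == grp)) < 2:
                raise ValueError(
                    "need >= 2 patients per outcome group when effect_size > 0"
                )
    maps = []
    for i in range(config.n_patients):
        maps.append(
            generate_label_map(
                config.class_mixing,
                config.map_shape,
                config.smoothness,
                seed=int(rng.integers(2**31 - 1)),
                background_fraction=config.background_fraction,
                patient_id=f"P{i:03d}",
            )
        )
    stats = np.array(
        [interface_density(m, *config.planted_pair) for m in maps]
    )
    sigma = float(np.std(stats, ddof=1)) if len(stats) > 1 else 0.0
    if sigma == 0:
        sigma = 1.0 / maps[0].grid.size
    if config.effect_size > 0:
        for i, m in enumerate(maps):
            if outcomes[i] == "pCR":
                target = stats[i] + config.effect_size * sigma
                m.grid = _plant_interface(
                    m.grid, config.planted_pair, target, rng
                )
    # class-conditional feature sampling
    if with_features:
        class_stats = {
            cid: class_feature_statistics(
                DEFAULT_CLASS_PARAMS.get(cid, ClassTextureParams(cid))
            )
            for cid in sorted({int(k) for k in config.class_mixing})
        }
    patients = []
    for i, m in enumerate(maps):
        R, C = m.shape
        tf = np.zeros((R, C, 80))
        if with_features:
            for cid, (mean, sd) in class_stats.items():
                mask = m.grid == cid
                n = int(mask.sum())
                if n == 0:
                    continue
                tf[mask] = mean + config.tile_feature_noise * sd * rng.standard_normal(
                    (n, 80)
                )
        patients.append(
            SyntheticPatient(
                patient_id=f"P{i:03d}",
                outcome=str(outcomes[i]),
                label_map=m,
                tile_features=tf,
            )
        )
    return patients


def sample_tile_features(
    class_ids: np.ndarray,
    seed: int,
    noise: float = 1.0,
    params: dict[int, ClassTextureParams] | None = None,
) -> np.ndarray:
    """Sample 80-feature vectors for a label vector of class ids."""
    params = params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    class_ids = np.asarray(class_ids)
    X = np.zeros((class_ids.size, 80))
    for cid in np.unique(class_ids):
        mean, sd = class_feature_statistics(
            params.get(int(cid), ClassTextureParams(int(cid)))
        )
        mask = class_ids == cid
        X[mask] = mean + noise * sd * rng.standard_normal((int(mask.sum()), 80))
    return X
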