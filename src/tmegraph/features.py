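"""Tile-level texture features: the 80-dimensional six-family descriptor.

Each 224x224 tile is summarised by 80 engineered texture features computed
on a single grayscale channel (by default the hematoxylin concentration
image, rescaled to 8-bit):

========  ==  ==========================================================
family     n  contents
========  ==  ==========================================================
GLCM      20  contrast, correlation, energy, homogeneity, entropy at
              4 offsets (0/45/90/135 deg, distance 1, 32 gray levels)
Gabor     32  response-magnitude mean and sd for 4 frequencies x 4
              orientations
LBP       18  normalized uniform local-binary-pattern histogram
              (P=16, R=2: P+2 bins)
Tamura     3  coarseness, contrast, directionality
HistLow    4  mean, variance, median, mode
HistHigh   3  skewness, kurtosis, histogram entropy
========  ==  ==========================================================

Undefined statistics (GLCM correlation on a flat tile, skewness at zero
variance) are reported as NaN and removed downstream by the exclusion rule
implemented in :func:`exclude_features`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage.filters import gabor_kernel

GLCM_STATS = ("contrast", "correlation", "energy", "homogeneity", "entropy")
GLCM_ANGLES_DEG = (0, 45, 90, 135)
GLCM_LEVELS = 32
GLCM_DISTANCE = 1

GABOR_FREQUENCIES = (0.10, 0.15, 0.25, 0.40)
GABOR_ORIENTS_DEG = (0, 45, 90, 135)

LBP_P = 16
LBP_R = 2.0

TAMURA_NAMES = ("coarseness", "contrast", "directionality")
HIST_LOW_NAMES = ("mean", "variance", "median", "mode")
HIST_HIGH_NAMES = ("skewness", "kurtosis", "entropy")


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature names with family tags; total cardinality 80."""

    names: tuple[str, ...]
    families: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.families):
            raise ValueError("names and families must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam in self.families:
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_catalog() -> FeatureCatalog:
    names: list[str] = []
    families: list[str] = []
    for stat in GLCM_STATS:
        for ang in GLCM_ANGLES_DEG:
            names.append(f"glcm_{stat}_a{ang}")
            families.append("GLCM")
    for f in GABOR_FREQUENCIES:
        for ang in GABOR_ORIENTS_DEG:
            for stat in ("mean", "sd"):
                names.append(f"gabor_f{f:g}_o{ang}_{stat}")
                families.append("Gabor")
    for b in range(LBP_P + 1):
        names.append(f"lbp_u{b}")
        families.append("LBP")
    names.append("lbp_nonuniform")
    families.append("LBP")
    for nm in TAMURA_NAMES:
        names.append(f"tamura_{nm}")
        families.append("Tamura")
    for nm in HIST_LOW_NAMES:
        names.append(f"hist_{nm}")
        families.append("HistLow")
    for nm in HIST_HIGH_NAMES:
        names.append(f"hist_{nm}")
        families.append("HistHigh")
    return FeatureCatalog(tuple(names), tuple(families))


DEFAULT_CATALOG = default_catalog()
assert len(DEFAULT_CATALOG) == 80


def _as_gray_u8(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if gray.dtype == np.uint8:
        return gray
    # float input is treated as a stain concentration map in OD units;
    # a fixed [0, 2] OD window keeps absolute stain level informative.
    return np.clip(gray / 2.0 * 255.0, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# GLCM


def glcm_features(
    gray: np.ndarray,
    levels: int = GLCM_LEVELS,
    distance: int = GLCM_DISTANCE,
    angles_deg: tuple[int, ...] = GLCM_ANGLES_DEG,
) -> np.ndarray:
    """Five Haralick-style statistics per co-occurrence angle.

    Matrices are symmetric and normalized; ``correlation`` is NaN when a
    marginal variance is zero (e.g. a constant tile).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    gray = _as_gray_u8(gray)
    if min(gray.shape) <= distance:
        raise ValueError("tile smaller than the co-occurrence offset")
    q = (gray.astype(np.intp) * levels) // 256
    out = np.empty(len(GLCM_STATS) * len(angles_deg))
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    for ai, ang in enumerate(angles_deg):
        p = _cooccurrence(q, levels, distance, ang)
        for si, stat in enumerate(GLCM_STATS):
            out[si * len(angles_deg) + ai] = _glcm_stat(p, stat, ii, jj)
    return out


#: Row/col steps per angle (image convention: row down, col right); the
#: diagonal offsets keep both components equal to the distance, so distance
#: 2 at 45 deg pairs cells (r, c) and (r+2, c+2).
_GLCM_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def _cooccurrence(q: np.ndarray, levels: int, distance: int, angle_deg: int) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix."""
    dr, dc = (distance * s for s in _GLCM_OFFSETS[angle_deg])
    H, W = q.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    src = q[r0:r1, c0:c1].ravel()
    dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(src * levels + dst, minlength=levels * levels)
    P = counts.reshape(levels, levels).astype(float)
    P = P + P.T  # symmetric: count both pair orders
    return P / P.sum()


def _glcm_stat(p: np.ndarray, stat: str, ii: np.ndarray, jj: np.ndarray) -> float:
    if stat == "contrast":
        return float(np.sum(p * (ii - jj) ** 2))
    if stat == "energy":
        return float(np.sum(p * p))
    if stat == "homogeneity":
        return float(np.sum(p / (1.0 + np.abs(ii - jj))))
    if stat == "entropy":
        nz = p[p > 0]
        return float(-np.sum(nz * np.log2(nz)))
    if stat == "correlation":
        pi = p.sum(axis=1)
        mu_i = float(np.sum(np.arange(p.shape[0]) * pi))
        var_i = float(np.sum((np.arange(p.shape[0]) - mu_i) ** 2 * pi))
        pj = p.sum(axis=0)
        mu_j = float(np.sum(np.arange(p.shape[1]) * pj))
        var_j = float(np.sum((np.arange(p.shape[1]) - mu_j) ** 2 * pj))
        if var_i <= 0 or var_j <= 0:
            return float("nan")
        cov = float(np.sum(p * (ii - mu_i) * (jj - mu_j)))
        return cov / np.sqrt(var_i * var_j)
    raise ValueError(f"unknown GLCM statistic {stat!r}")


# ---------------------------------------------------------------------------
# Gabor

_GABOR_KERNELS: dict[tuple[float, int], np.ndarray] = {}


def _gabor_bank() -> list[tuple[float, int, np.ndarray]]:
    bank = []
    for f in GABOR_FREQUENCIES:
        for ang in GABOR_ORIENTS_DEG:
            key = (f, ang)
            if key not in _GABOR_KERNELS:
                _GABOR_KERNELS[key] = gabor_kernel(f, theta=np.deg2rad(ang))
            bank.append((f, ang, _GABOR_KERNELS[key]))
    return bank


def gabor_features(gray: np.ndarray) -> np.ndarray:
    """Mean and sd of the response magnitude of a 4x4 Gabor filter bank."""
    img = _as_gray_u8(gray).astype(float)
    out = np.empty(2 * len(GABOR_FREQUENCIES) * len(GABOR_ORIENTS_DEG))
    k = 0
    for _f, _ang, kernel in _gabor_bank():
        resp = signal.fftconvolve(img, kernel, mode="same")
        mag = np.abs(resp)
        out[k] = mag.mean()
        out[k + 1] = mag.std()
        k += 2
    return out


# ---------------------------------------------------------------------------
# LBP

_LBP_OFFSETS = [
    (-LBP_R * np.sin(2 * np.pi * k / LBP_P), LBP_R * np.cos(2 * np.pi * k / LBP_P))
    for k in range(LBP_P)
]


def _bilinear_sample(img: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    r0 = np.floor(rr).astype(int)
    c0 = np.floor(cc).astype(int)
    dr = rr - r0
    dc = cc - c0
    # at exact-integer coordinates the +1 neighbor has zero weight; clamp it
    r1 = np.minimum(r0 + 1, img.shape[0] - 1)
    c1 = np.minimum(c0 + 1, img.shape[1] - 1)
    return (
        img[r0, c0] * (1 - dr) * (1 - dc)
        + img[r0, c1] * (1 - dr) * dc
        + img[r1, c0] * dr * (1 - dc)
        + img[r1, c1] * dr * dc
    )


def lbp_uniform_bins(gray: np.ndarray, P: int = LBP_P, R: float = LBP_R) -> np.ndarray:
    """Per-pixel uniform-LBP bin (0..P for uniform codes, P+1 otherwise).

    Neighbors on the radius-R circle are bilinearly interpolated; a neighbor
    counts as 1 when its value is >= the center value.  Only pixels whose
    full neighborhood lies inside the image are coded.
    """
    img = np.asarray(gray, dtype=float)
    Rc = int(np.ceil(R))
    if min(img.shape) <= 2 * Rc:
        raise ValueError("tile too small for the LBP radius")
    rows = np.arange(Rc, img.shape[0] - Rc)
    cols = np.arange(Rc, img.shape[1] - Rc)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    center = img[rr, cc]
    bits = np.empty((P,) + rr.shape, dtype=bool)
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        vals = _bilinear_sample(img, rr + dr, cc + dc)
        # tie tolerance: interpolating four equal corners must not fall
        # below the center through rounding
        bits[k] = vals >= center - 1e-6
    ones = bits.sum(axis=0)
    transitions = np.zeros(rr.shape, dtype=int)
    for k in range(P):
        transitions += bits[k] != bits[(k + 1) % P]
    bins = np.where(transitions <= 2, ones, P + 1)
    return bins


def lbp_features(gray: np.ndarray, P: int = LBP_P, R: float = LBP_R) -> np.ndarray:
    bins = lbp_uniform_bins(_as_gray_u8(gray).astype(float), P, R)
    hist = np.bincount(bins.ravel(), minlength=P + 2).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Tamura


def tamura_coarseness(img: np.ndarray, max_k: int = 5) -> float:
    """Mean best-scale window size (Tamura's S_best averaging).

    For each pixel, window averages at sizes 2^k are differenced across the
    window in both axes; the pixel's best size is the one maximizing the
    difference, and coarseness is the mean best size over the interior
    (borders are excluded because the largest window overruns them).
    """
    img = np.asarray(img, dtype=float)
    H, W = img.shape
    max_k = min(max_k, int(np.floor(np.log2(max(min(H, W) // 4, 1)))))
    if max_k < 1:
        return 0.0
    best_E = np.full((H, W), -np.inf)
    best_size = np.full((H, W), 2.0)
    for k in range(1, max_k + 1):
        size = 2**k
        half = size // 2
        A = ndimage.uniform_filter(img, size=size, mode="nearest")
        Eh = np.abs(np.roll(A, -half, axis=1) - np.roll(A, half, axis=1))
        Ev = np.abs(np.roll(A, -half, axis=0) - np.roll(A, half, axis=0))
        E = np.maximum(Eh, Ev)
        improved = E > best_E
        best_size[improved] = float(size)
        best_E[improved] = E[improved]
    m = 2 ** max_k
    interior = best_size[m : H - m or None, m : W - m or None]
    if interior.size == 0:
        interior = best_size
    return float(interior.mean())


def tamura_contrast(img: np.ndarray) -> float:
    img = np.asarray(img, dtype=float)
    sigma = img.std()
    if sigma == 0:
        return 0.0
    mu4 = np.mean((img - img.mean()) ** 4)
    kurt = mu4 / sigma**4
    return float(sigma / kurt**0.25)


def tamura_directionality(img: np.ndarray, eps: float = 1e-9) -> float:
    """Orientation concentration of the gradient field in [0, 1].

    Computed as the magnitude-weighted resultant length of doubled gradient
    angles (axial data); 1 means a single dominant orientation, 0 an
    isotropic field.  A gradient-free image returns 0 by convention.
    """
    img = np.asarray(img, dtype=float)
    gx = ndimage.prewitt(img, axis=1, mode="nearest")
    gy = ndimage.prewitt(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    total = mag.sum()
    if total < eps:
        return 0.0
    theta = np.arctan2(gy, gx)
    z = np.sum(mag * np.exp(2j * theta)) / total
    return float(np.abs(z))


def tamura_features(gray: np.ndarray) -> np.ndarray:
    img = _as_gray_u8(gray).astype(float)
    return np.array(
        [tamura_coarseness(img), tamura_contrast(img), tamura_directionality(img)]
    )


# ---------------------------------------------------------------------------
# Histogram


def histogram_features(gray: np.ndarray) -> np.ndarray:
    """Lower-order (mean, variance, median, mode) and higher-order
    (skewness, kurtosis, entropy) intensity-histogram statistics.

    Skewness and kurtosis are NaN on a zero-variance tile; kurtosis is the
    non-excess (Pearson) definition.  Entropy is over the 256-bin intensity
    histogram, in bits.
    """
    vals = _as_gray_u8(gray).astype(float).ravel()
    mean = vals.mean()
    var = vals.var()
    median = float(np.median(vals))
    counts = np.bincount(vals.astype(int), minlength=256)
    mode = float(np.argmax(counts))
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((vals - mean) ** 3) / sd**3)
        kurt = float(np.mean((vals - mean) ** 4) / var**2)
    else:
        skew = float("nan")
        kurt = float("nan")
    p = counts[counts > 0] / vals.size
    entropy = float(-np.sum(p * np.log2(p)))
    return np.array([mean, var, median, mode, skew, kurt, entropy])


# ---------------------------------------------------------------------------
# Full vector and exclusion rule


def extract_all(gray: np.ndarray, catalog: FeatureCatalog = DEFAULT_CATALOG) -> np.ndarray:
    """The full 80-feature vector, in catalog order."""
    vec = np.concatenate(
        [
            glcm_features(gray),
            gabor_features(gray),
            lbp_features(gray),
            tamura_features(gray),
            histogram_features(gray),
        ]
    )
    if vec.shape[0] != len(catalog):
        raise RuntimeError("feature vector does not match catalog cardinality")
    return vec


@dataclass
class RetentionMask:
    """Outcome of the zero/NA/duplicate exclusion rule.

    ``retained`` indexes into the catalog; ``reasons`` maps every dropped
    index to one of ``all-zero``, ``NA`` or ``duplicate-of:<index>``.
    """

    retained: list[int]
    reasons: dict[int, str]
    n_features: int

    def __post_init__(self) -> None:
        if sorted(self.retained + list(self.reasons)) != list(range(self.n_features)):
            raise ValueError("retained and dropped must partition the catalog")


def exclude_features(matrix: np.ndarray) -> RetentionMask:
    """Drop all-zero, NA-containing, and exactly duplicated feature columns.

    Duplicates are resolved keep-first: a column identical to an
    earlier-indexed *retained* column is dropped with reason
    ``duplicate-of:<that index>``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    retained: list[int] = []
    reasons: dict[int, str] = {}
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.isnan(col).any():
            reasons[j] = "NA"
            continue
        if np.all(col == 0):
            reasons[j] = "all-zero"
            continue
        dup = next((r for r in retained if np.array_equal(X[:, r], col)), None)
        if dup is not None:
            reasons[j] = f"duplicate-of:{dup}"
            continue
        retained.append(j)
    return RetentionMask(retained=retained, reasons=reasons, n_features=X.shape[1])
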