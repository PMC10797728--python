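"""Texture-feature extractor tests: brute-force oracles and edge cases."""

import numpy as np
import pytest

from tmegraph import features as F


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix_oracle(img, levels, distance, angle_deg):
    """Nested-loop co-occurrence counting, independent of the implementation."""
    q = (img.astype(int) * levels) // 256
    offs = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}
    dr, dc = (distance * s for s in offs[angle_deg])
    P = np.zeros((levels, levels))
    H, W = q.shape
    for r in range(H):
        for c in range(W):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W:
                P[q[r, c], q[rr, cc]] += 1
                P[q[rr, cc], q[r, c]] += 1
    return P / P.sum()


def glcm_stats_oracle(P):
    levels = P.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = np.sum(P * (ii - jj) ** 2)
    energy = np.sum(P * P)
    homog = np.sum(P / (1 + np.abs(ii - jj)))
    nz = P[P > 0]
    entropy = -np.sum(nz * np.log2(nz))
    pi, pj = P.sum(1), P.sum(0)
    mu_i, mu_j = np.sum(i * pi), np.sum(i * pj)
    var_i = np.sum((i - mu_i) ** 2 * pi)
    var_j = np.sum((i - mu_j) ** 2 * pj)
    if var_i <= 0 or var_j <= 0:
        corr = np.nan
    else:
        corr = np.sum(P * (ii - mu_i) * (jj - mu_j)) / np.sqrt(var_i * var_j)
    return {"contrast": contrast, "correlation": corr, "energy": energy,
            "homogeneity": homog, "entropy": entropy}


@pytest.mark.parametrize("distance", [1, 2])
def test_glcm_matches_counting_oracle_on_random_images(distance):
    rng = np.random.default_rng(42)
    for _ in range(100):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        got = F.glcm_features(img, levels=8, distance=distance)
        for ai, ang in enumerate(F.GLCM_ANGLES_DEG):
            exp = glcm_stats_oracle(glcm_matrix_oracle(img, 8, distance, ang))
            for si, stat in enumerate(F.GLCM_STATS):
                g = got[si * 4 + ai]
                e = exp[stat]
                if np.isnan(e):
                    assert np.isnan(g)
                else:
                    assert abs(g - e) <= 1e-10


def test_glcm_two_by_two_contrast_is_one():
    img = (np.array([[0, 1], [2, 3]]) * 64).astype(np.uint8)
    v = F.glcm_features(img, levels=4, distance=1)
    assert v[0] == pytest.approx(1.0)  # contrast at 0 degrees


def test_glcm_constant_tile_degenerates():
    v = F.glcm_features(np.full((16, 16), 80, dtype=np.uint8))
    contrast, corr, energy, homog = v[0:4], v[4:8], v[8:12], v[12:16]
    assert np.all(contrast == 0)
    assert np.all(np.isnan(corr))
    assert np.all(energy == 1)
    assert np.all(homog == 1)


def test_glcm_rejects_too_few_levels():
    with pytest.raises(ValueError):
        F.glcm_features(np.zeros((8, 8), dtype=np.uint8), levels=1)


# ---------------------------------------------------------------------------
# Gabor


def test_gabor_zero_image_gives_zero_features():
    v = F.gabor_features(np.zeros((32, 32), dtype=np.uint8))
    assert np.allclose(v, 0)


def test_gabor_sinusoid_peaks_at_matching_filter():
    x = np.arange(64)
    img = (127 + 100 * np.sin(2 * np.pi * 0.25 * x))[None, :] * np.ones((64, 1))
    v = F.gabor_features(img.astype(np.uint8))
    means = v[0::2].reshape(len(F.GABOR_FREQUENCIES), len(F.GABOR_ORIENTS_DEG))
    fi, oi = np.unravel_index(np.argmax(means), means.shape)
    assert F.GABOR_FREQUENCIES[fi] == 0.25
    assert F.GABOR_ORIENTS_DEG[oi] == 0  # variation along x: theta = 0 filter


def test_gabor_rotation_permutes_orientations():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
    v = F.gabor_features(img)
    v_rot = F.gabor_features(np.rot90(img))
    means = v[0::2].reshape(4, 4)
    means_rot = v_rot[0::2].reshape(4, 4)
    # rotating the image by 90 deg maps the orientation-0 response onto the
    # orientation-90 filter (within boundary tolerance)
    assert np.allclose(means_rot[:, 2], means[:, 0], rtol=0.05)
    assert np.allclose(means_rot[:, 0], means[:, 2], rtol=0.05)


# ---------------------------------------------------------------------------
# LBP


def lbp_oracle(img, P, R):
    """Per-pixel neighbor-threshold enumeration with explicit bilinear math."""
    img = img.astype(float)
    Rc = int(np.ceil(R))
    hist = np.zeros(P + 2)
    for r in range(Rc, img.shape[0] - Rc):
        for c in range(Rc, img.shape[1] - Rc):
            bits = []
            for k in range(P):
                dr = -R * np.sin(2 * np.pi * k / P)
                dc = R * np.cos(2 * np.pi * k / P)
                rr, cc = r + dr, c + dc
                r0, c0 = int(np.floor(rr)), int(np.floor(cc))
                fr, fc = rr - r0, cc - c0
                r1 = min(r0 + 1, img.shape[0] - 1)
                c1 = min(c0 + 1, img.shape[1] - 1)
                val = (img[r0, c0] * (1 - fr) * (1 - fc)
                       + img[r0, c1] * (1 - fr) * fc
                       + img[r1, c0] * fr * (1 - fc)
                       + img[r1, c1] * fr * fc)
                bits.append(val >= img[r, c] - 1e-6)  # same tie tolerance
            trans = sum(bits[k] != bits[(k + 1) % P] for k in range(P))
            hist[sum(bits) if trans <= 2 else P + 1] += 1
    return hist / hist.sum()


def test_lbp_bright_center_matches_enumeration_oracle():
    img = np.full((7, 7), 10, dtype=np.uint8)
    img[3, 3] = 200
    got = F.lbp_features(img)
    exp = lbp_oracle(img.astype(float), F.LBP_P, F.LBP_R)
    assert np.allclose(got, exp, atol=1e-12)


def test_lbp_random_image_matches_oracle():
    rng = np.random.default_rng(9)
    img = rng.integers(0, 256, (9, 9)).astype(np.uint8)
    assert np.allclose(F.lbp_features(img), lbp_oracle(img.astype(float), 16, 2.0))


def test_lbp_histogram_normalized_and_constant_image_single_bin():
    hist = F.lbp_features(np.full((16, 16), 50, dtype=np.uint8))
    assert hist.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(hist >= 0)
    # >= comparison: all neighbors tie with the center -> all-ones pattern
    assert hist[F.LBP_P] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Tamura


def _checker(block, n=64):
    t = (np.indices((n, n)).sum(0) // block) % 2
    return (t * 255).astype(float)


def test_tamura_constant_image_conventions():
    v = F.tamura_features(np.full((32, 32), 77, dtype=np.uint8))
    assert v[1] == 0  # contrast convention at zero variance
    assert v[2] == 0  # directionality convention with no gradient


def test_tamura_coarseness_grows_with_block_size():
    assert F.tamura_coarseness(_checker(16)) > F.tamura_coarseness(_checker(2))


def test_tamura_directionality_stripes_exceed_noise():
    stripes = (np.tile(np.arange(64) % 8 < 4, (64, 1)) * 255).astype(float)
    noise = np.random.default_rng(0).uniform(0, 255, (64, 64))
    assert F.tamura_directionality(stripes) > F.tamura_directionality(noise) + 0.5


# ---------------------------------------------------------------------------
# Histogram


def test_histogram_constant_tile():
    v = F.histogram_features(np.full((8, 8), 42, dtype=np.uint8))
    mean, var, median, mode, skew, kurt, _ = v
    assert (mean, var, median, mode) == (42, 0, 42, 42)
    assert np.isnan(skew) and np.isnan(kurt)


def test_histogram_mean_of_mixed_values():
    img = np.array([[0, 0], [0, 255]], dtype=np.uint8)
    assert F.histogram_features(img)[0] == pytest.approx(63.75)


def test_histogram_symmetric_distribution_has_zero_skewness():
    vals = np.concatenate([np.arange(0, 128), np.arange(128, 0, -1)])
    img = np.tile(vals, 2).reshape(16, 32).astype(np.uint8)
    assert F.histogram_features(img)[4] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Full vector + exclusion


def test_extract_all_is_80_long_deterministic_and_family_aligned(rng):
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    v1 = F.extract_all(img)
    v2 = F.extract_all(img)
    assert len(v1) == 80
    assert np.array_equal(v1, v2, equal_nan=True)
    counts = F.DEFAULT_CATALOG.family_counts()
    assert counts == {"GLCM": 20, "Gabor": 32, "LBP": 18, "Tamura": 3,
                      "HistLow": 4, "HistHigh": 3}


def test_exclude_features_reasons_and_keep_first():
    X = np.array([[1.0, 0.0, 1.0, np.nan, 2.0],
                  [2.0, 0.0, 2.0, 1.0, 3.0]])
    mask = F.exclude_features(X)
    assert mask.retained == [0, 4]
    assert mask.reasons[1] == "all-zero"
    assert mask.reasons[2] == "duplicate-of:0"
    assert mask.reasons[3] == "NA"


def test_exclude_features_full_rank_matrix_keeps_all(rng):
    X = rng.normal(size=(20, 80))
    mask = F.exclude_features(X)
    assert mask.retained == list(range(80))
    # pairwise distinctness confirmed directly
    for j in range(80):
        for k in range(j + 1, 80):
            assert not np.array_equal(X[:, j], X[:, k])


def test_exclude_features_is_idempotent(rng):
    X = rng.normal(size=(10, 12))
    X[:, 3] = 0
    X[:, 7] = X[:, 1]
    first = F.exclude_features(X)
    second = F.exclude_features(X[:, first.retained])
    assert second.retained == list(range(len(first.retained)))
    assert not second.reasons
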