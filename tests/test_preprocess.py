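"""Tiling, optical density, stain estimation and deconvolution tests."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from tmegraph.preprocess import (
    AnnotatedRegion,
    InsufficientTissueError,
    StainModel,
    estimate_stain_vectors,
    hematoxylin_channel,
    normalize_stains,
    od_to_rgb,
    reference_stain_model,
    rgb_to_od,
    stain_concentrations,
    tile_partition,
)


def square(x0, y0, side):
    return Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])


def angular_error_deg(u, v):
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


# ---------------------------------------------------------------------------
# Tiling


def test_partition_square_region_yields_expected_grid_tiles():
    regions = [AnnotatedRegion(square(0, 0, 448), 1)]
    tiles = tile_partition(regions, (896, 896))
    assert sorted((t.grid_row, t.grid_col) for t in tiles) == [
        (0, 0), (0, 1), (1, 0), (1, 1)
    ]
    assert all(t.true_class == 1 for t in tiles)
    assert tiles[0].origin == (0.0, 0.0)


def test_partition_small_region_retains_nothing():
    regions = [AnnotatedRegion(square(10, 10, 100), 2)]
    assert tile_partition(regions, (448, 448)) == []


def test_partition_full_extent_retains_every_tile():
    regions = [AnnotatedRegion(square(0, 0, 896), 0)]
    assert len(tile_partition(regions, (896, 896))) == 16


def test_partition_invariant_to_vertex_order_and_tile_size_translation():
    poly = [(30, 40), (500, 40), (500, 470), (30, 470)]
    base = tile_partition([AnnotatedRegion(Polygon(poly), 3)], (1120, 1120))
    reversed_ = tile_partition(
        [AnnotatedRegion(Polygon(poly[::-1]), 3)], (1120, 1120)
    )
    assert [(t.grid_row, t.grid_col) for t in base] == [
        (t.grid_row, t.grid_col) for t in reversed_
    ]
    shifted = tile_partition(
        [AnnotatedRegion(Polygon([(x + 224, y + 224) for x, y in poly]), 3)],
        (1344, 1344),
    )
    assert [(t.grid_row + 1, t.grid_col + 1) for t in base] == [
        (t.grid_row, t.grid_col) for t in shifted
    ]


def test_partition_matches_rasterized_mask_oracle():
    """Retention thresholded on exact polygon area agrees with a pixel-mask
    count within one tile on random polygons."""
    rng = np.random.default_rng(5)
    T = 28  # small tiles keep rasterization cheap
    for _ in range(5):
        cx, cy = rng.uniform(40, 120, 2)
        pts = []
        for a in np.linspace(0, 2 * np.pi, 9)[:-1]:
            rad = rng.uniform(25, 60)
            pts.append((cx + rad * np.cos(a), cy + rad * np.sin(a)))
        poly = Polygon(pts).buffer(0)
        regions = [AnnotatedRegion(poly, 1)]
        tiles = tile_partition(regions, (196, 196), tile_size=T, min_overlap=0.9)
        got = {(t.grid_row, t.grid_col) for t in tiles}
        # independent oracle: rasterize the polygon at 1-px resolution and
        # count covered pixels per tile
        from PIL import Image, ImageDraw

        im = Image.new("1", (196, 196), 0)
        ImageDraw.Draw(im).polygon(
            [(x, y) for x, y in poly.exterior.coords], fill=1
        )
        mask = np.asarray(im)
        exp = set()
        borderline = set()
        for r in range(196 // T):
            for c in range(196 // T):
                frac = mask[r * T : (r + 1) * T, c * T : (c + 1) * T].mean()
                if frac >= 0.9:
                    exp.add((r, c))
                if abs(frac - 0.9) < 0.02:  # rasterization is +-boundary px
                    borderline.add((r, c))
        assert got.symmetric_difference(exp) <= borderline


def test_partition_validates_inputs():
    with pytest.raises(ValueError):
        tile_partition([], (896, 896))
    bowtie = [(0, 0), (100, 100), (100, 0), (0, 100)]
    with pytest.raises(ValueError):
        AnnotatedRegion(Polygon(bowtie), 1)


def test_partition_class_tie_breaks_to_lower_id():
    a = AnnotatedRegion(Polygon([(0, 0), (224, 0), (224, 224), (0, 224)]), 5)
    b = AnnotatedRegion(Polygon([(0, 0), (224, 0), (224, 224), (0, 224)]), 2)
    tiles = tile_partition([a, b], (224, 224))
    assert tiles[0].true_class == 2


# ---------------------------------------------------------------------------
# Optical density


def test_od_examples_and_monotonicity():
    assert rgb_to_od(np.array(255.0)) == pytest.approx(0.0, abs=1e-6)
    assert rgb_to_od(np.array(25.5)) == pytest.approx(1.0, abs=1e-6)
    vals = rgb_to_od(np.arange(0, 256, dtype=float))
    assert np.all(np.diff(vals) < 0)


# ---------------------------------------------------------------------------
# Stain estimation and deconvolution


def test_planted_stain_vectors_recovered_within_5_degrees():
    rng = np.random.default_rng(1)
    M = reference_stain_model().stain_matrix
    C = rng.uniform(0, 1.5, size=(64 * 64, 2))
    tile = od_to_rgb((M @ C.T).T.reshape(64, 64, 3))
    model = estimate_stain_vectors(rgb_to_od(tile))
    assert angular_error_deg(model.stain_matrix[:, 0], M[:, 0]) < 5
    assert angular_error_deg(model.stain_matrix[:, 1], M[:, 1]) < 5


def test_single_pure_stain_recovered_within_2_degrees():
    rng = np.random.default_rng(2)
    M = reference_stain_model().stain_matrix
    C = np.zeros((64 * 64, 2))
    C[:2000, 0] = rng.uniform(0.3, 1.2, 2000)
    tile = od_to_rgb((M @ C.T).T.reshape(64, 64, 3))
    model = estimate_stain_vectors(rgb_to_od(tile))
    assert angular_error_deg(model.stain_matrix[:, 0], M[:, 0]) < 2


def test_near_white_tile_raises_insufficient_tissue():
    tile = np.full((32, 32, 3), 250, dtype=np.uint8)
    with pytest.raises(InsufficientTissueError):
        estimate_stain_vectors(rgb_to_od(tile))


def test_normalization_identity_and_output_range():
    rng = np.random.default_rng(1)
    ref = reference_stain_model()
    C = rng.uniform(0, 1.2, size=(64 * 64, 2))
    tile = od_to_rgb((ref.stain_matrix @ C.T).T.reshape(64, 64, 3))
    out = normalize_stains(tile, ref, ref)
    assert np.abs(out.astype(int) - tile.astype(int)).max() <= 1
    assert out.dtype == np.uint8 and out.min() >= 0 and out.max() <= 255


def test_normalization_aligns_two_stain_renderings_tenfold():
    rng = np.random.default_rng(4)
    ref = reference_stain_model()
    M1 = ref.stain_matrix
    M2 = np.clip(M1 + rng.normal(0, 0.08, (3, 2)), 0.01, None)
    M2 /= np.linalg.norm(M2, axis=0)
    C = rng.uniform(0, 1.2, size=(64 * 64, 2))
    t1 = od_to_rgb((M1 @ C.T).T.reshape(64, 64, 3))
    t2 = od_to_rgb((M2 @ C.T).T.reshape(64, 64, 3))
    before = np.abs(
        t1.astype(float).mean((0, 1)) - t2.astype(float).mean((0, 1))
    ).mean()
    n1 = normalize_stains(t1, StainModel(M1), ref)
    n2 = normalize_stains(t2, StainModel(M2), ref)
    after = np.abs(
        n1.astype(float).mean((0, 1)) - n2.astype(float).mean((0, 1))
    ).mean()
    assert before >= 10 * after


def test_deconvolution_linear_round_trip_is_exact():
    rng = np.random.default_rng(6)
    model = reference_stain_model()
    C = rng.uniform(0, 2.0, size=(500, 2))
    od = (model.stain_matrix @ C.T).T
    C_back = stain_concentrations(od, model)
    assert np.abs(C_back - C).max() < 1e-6


def test_pure_eosin_tile_has_no_hematoxylin():
    model = reference_stain_model()
    C = np.zeros((32 * 32, 2))
    C[:, 1] = 0.8
    tile = od_to_rgb((model.stain_matrix @ C.T).T.reshape(32, 32, 3))
    H = hematoxylin_channel(tile, model)
    assert H.mean() < 0.01


def test_hematoxylin_higher_inside_nucleus_disks():
    from tmegraph.synthetic import ClassTextureParams, generate_class_tile

    params = ClassTextureParams(class_id=1, nucleus_density=120,
                                hematoxylin_level=0.3, eosin_level=0.4)
    tile, fields = generate_class_tile(params, seed=3, size=96, return_fields=True)
    H = hematoxylin_channel(tile)
    mask = fields["nucleus_mask"]
    assert mask.any() and (~mask).any()
    assert H[mask].mean() > H[~mask].mean()


def test_geojson_regions_read_qupath_dialect(tmp_path):
    import json

    from tmegraph.preprocess import read_geojson_regions

    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[0, 0], [448, 0], [448, 448], [0, 448],
                                     [0, 0]]],
                },
                "properties": {"classification": {"name": "tumor"}},
            },
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[500, 0], [900, 0], [900, 400], [500, 400],
                                     [500, 0]]],
                },
                "properties": {"classification": {"name": "stroma"}},
            },
        ],
    }
    path = tmp_path / "annot.geojson"
    path.write_text(json.dumps(doc))
    regions = read_geojson_regions(str(path))
    assert [r.class_label for r in regions] == [1, 0]  # tumor=1, stroma=0
    tiles = tile_partition(regions, (1120, 448))
    assert {t.true_class for t in tiles} == {0, 1}

    doc["features"][0]["properties"] = {}
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError):
        read_geojson_regions(str(path))
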