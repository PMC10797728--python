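"""Artifact readers/writers: paletted map PNGs, CSV manifests, JSON legends."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .core import BACKGROUND, HistologyMap

_PNG_BACKGROUND_INDEX = 255


def write_map_png(hmap: HistologyMap, path: str | Path) -> None:
    """Paletted PNG: pixel value = class id, background at index 255."""
    grid = hmap.grid.astype(np.int64)
    img = np.where(grid == BACKGROUND, _PNG_BACKGROUND_INDEX, grid).astype(np.uint8)
    im = Image.fromarray(img, mode="P")
    palette = [0] * (256 * 3)
    for cid, rgb in hmap.colors.items():
        idx = _PNG_BACKGROUND_INDEX if cid == BACKGROUND else cid
        palette[idx * 3 : idx * 3 + 3] = list(rgb)
    im.putpalette(palette)
    im.save(path)


def read_map_png(path: str | Path, patient_id: str = "") -> HistologyMap:
    img = np.asarray(Image.open(path))
    grid = img.astype(np.int64)
    grid[grid == _PNG_BACKGROUND_INDEX] = BACKGROUND
    return HistologyMap(grid=grid, patient_id=patient_id)


def write_map_legend(hmap: HistologyMap, class_names: dict[int, str], path) -> None:
    legend = {
        str(cid): {"name": class_names.get(cid, f"class_{cid}"),
                   "rgb": list(hmap.colors.get(cid, (0, 0, 0)))}
        for cid in sorted(set(hmap.classes_present()) | set(class_names))
    }
    Path(path).write_text(json.dumps(legend, indent=1))


def write_tile_manifest(tiles, path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in tiles],
            "grid_row": [t.grid_row for t in tiles],
            "grid_col": [t.grid_col for t in tiles],
            "origin_x": [t.origin[0] for t in tiles],
            "origin_y": [t.origin[1] for t in tiles],
            "class": [t.true_class for t in tiles],
        }
    )
    df.to_csv(path, index=False)


def write_cohort(patients, out_dir, config_echo: dict | None = None) -> None:
    """Per-patient paletted map PNG + tile-feature CSV + cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": [], "config": config_echo or {}}
    for p in patients:
        write_map_png(p.label_map, out / f"{p.patient_id}_map.png")
        R, C, F = p.tile_features.shape
        rows, cols = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        df = pd.DataFrame(p.tile_features.reshape(-1, F))
        df.insert(0, "grid_row", rows.ravel())
        df.insert(1, "grid_col", cols.ravel())
        df.insert(2, "class", p.label_map.grid.ravel())
        df.to_csv(out / f"{p.patient_id}_tiles.csv", index=False)
        manifest["patients"].append(
            {"patient_id": p.patient_id, "outcome": p.outcome,
             "map": f"{p.patient_id}_map.png", "tiles": f"{p.patient_id}_tiles.csv"}
        )
    (out / "cohort.json").write_text(json.dumps(manifest, indent=1))


def write_attention_png(overlay: np.ndarray, path, color=(255, 215, 0)) -> None:
    """RGBA overlay aligned to the map grid: highlighted cells opaque gold."""
    H, W = overlay.shape
    rgba = np.zeros((H, W, 4), dtype=np.uint8)
    rgba[overlay] = list(color) + [200]
    Image.fromarray(rgba, mode="RGBA").save(path)
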