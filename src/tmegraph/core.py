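"""Shared domain types for the tile-to-graph histology pipeline.

The pipeline works on a regular, non-overlapping grid of 224x224 tiles cut
from an H&E slide.  A patient's spatial substrate is a :class:`HistologyMap`:
a 2-D grid whose cells hold histology class ids (tumor, stroma, TIL
subtypes, ...), with ``BACKGROUND`` marking non-tissue or unobserved cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel class id for non-tissue / unobserved grid cells.
BACKGROUND: int = -1

#: The 16 annotated histology classes, in their conventional id order
#: (ids 0..15; background is kept out of this catalog).
HISTOLOGY_CLASSES: tuple[str, ...] = (
    "stroma",
    "tumor",
    "tertiary_TIL",
    "stroma_TIL",
    "normal_tissue",
    "PGCC",
    "blood_vessel",
    "necrosis",
    "microvessel",
    "benign_tumor",
    "tumor_TIL",
    "in_situ_carcinoma",
    "hemorrhage",
    "adipocytes",
    "apocrine_change",
    "mucinous_change",
)

#: Display colors (RGB, 0-255) for map rendering; background renders white.
CLASS_COLORS: dict[int, tuple[int, int, int]] = {
    0: (86, 170, 76),
    1: (200, 46, 38),
    2: (142, 85, 171),
    3: (186, 135, 211),
    4: (160, 200, 160),
    5: (240, 140, 30),
    6: (200, 30, 90),
    7: (90, 70, 50),
    8: (235, 90, 140),
    9: (60, 110, 200),
    10: (120, 40, 150),
    11: (40, 170, 180),
    12: (150, 20, 20),
    13: (240, 220, 120),
    14: (180, 160, 90),
    15: (130, 190, 230),
    BACKGROUND: (255, 255, 255),
}


@dataclass
class TileRecord:
    """One grid-aligned tile cut from a slide.

    ``origin`` is the level-0 pixel coordinate of the tile's top-left
    corner and always equals ``(grid_col * tile_size, grid_row * tile_size)``.
    """

    patient_id: str
    grid_row: int
    grid_col: int
    origin: tuple[float, float]
    true_class: int = BACKGROUND
    pixels: np.ndarray | None = None


@dataclass
class HistologyMap:
    """2-D grid of histology class ids for one patient.

    ``grid[r, c]`` holds a class id or :data:`BACKGROUND`.  The grid covers
    the bounding box of the patient's tile grid; cells with no tile carry
    the background sentinel.
    """

    grid: np.ndarray
    patient_id: str = ""
    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(CLASS_COLORS)
    )

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        if self.grid.ndim != 2:
            raise ValueError("HistologyMap grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def diagonal(self) -> float:
        """Map diagonal in tile units; normalizer for MST total length."""
        r, c = self.grid.shape
        return float(np.hypot(r, c))

    def classes_present(self) -> list[int]:
        present = np.unique(self.grid)
        return [int(c) for c in present if c != BACKGROUND]

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.grid == class_id


def interface_density(hmap: HistologyMap, class_a: int, class_b: int) -> float:
    """Density of 4-adjacent cell pairs with one cell of each class.

    The count of unordered adjacent {a, b} pairs is normalized by the map
    area (number of grid cells), making the statistic comparable across map
    sizes.  This is the spatial-interaction statistic the synthetic cohort
    generator plants between outcome groups.
    """
    if class_a == class_b:
        raise ValueError("interface_density needs two distinct classes")
    g = hmap.grid
    a = g == class_a
    b = g == class_b
    count = 0
    # horizontal and vertical neighbor pairs
    count += int(np.sum(a[:, :-1] & b[:, 1:]) + np.sum(b[:, :-1] & a[:, 1:]))
    count += int(np.sum(a[:-1, :] & b[1:, :]) + np.sum(b[:-1, :] & a[1:, :]))
    return count / g.size
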