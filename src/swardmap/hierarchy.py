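"""Hierarchical label scheme for grass-clover canopy images.

Every pixel carries two labels: a top-level class (soil / clover / grass /
weed) used by the first cascade stage, and a sub-class that refines clover
into species and plant parts, names individual weed species, and keeps an
``unknown_clover_leaf`` slot for clover pixels without a species annotation.
The second cascade stage discriminates only red vs. white clover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# -- top-level classes (stage-1 prospect classes) -------------------------
SOIL = 0
CLOVER = 1
GRASS = 2
WEED = 3

TOP_NAMES = ("soil", "clover", "grass", "weed")

# -- sub-classes ----------------------------------------------------------
SUB_SOIL = 0
WHITE_CLOVER_LEAF = 1
WHITE_CLOVER_FLOWER = 2
RED_CLOVER_LEAF = 3
RED_CLOVER_FLOWER = 4
UNKNOWN_CLOVER_LEAF = 5
SUB_GRASS = 6
WEED_DANDELION = 7
WEED_SHEPHERDS_PURSE = 8
WEED_THISTLE = 9

SUB_NAMES = (
    "soil",
    "white_clover_leaf",
    "white_clover_flower",
    "red_clover_leaf",
    "red_clover_flower",
    "unknown_clover_leaf",
    "grass",
    "weed_dandelion",
    "weed_shepherds_purse",
    "weed_thistle",
)

#: map sub-class index -> top-class index (total on SUB_NAMES)
PARENT = {
    SUB_SOIL: SOIL,
    WHITE_CLOVER_LEAF: CLOVER,
    WHITE_CLOVER_FLOWER: CLOVER,
    RED_CLOVER_LEAF: CLOVER,
    RED_CLOVER_FLOWER: CLOVER,
    UNKNOWN_CLOVER_LEAF: CLOVER,
    SUB_GRASS: GRASS,
    WEED_DANDELION: WEED,
    WEED_SHEPHERDS_PURSE: WEED,
    WEED_THISTLE: WEED,
}

# -- stage-2 prospect classes ---------------------------------------------
STAGE2_RED = 0
STAGE2_WHITE = 1
STAGE2_NAMES = ("red_clover", "white_clover")

# -- fine (cascaded) classes ----------------------------------------------
FINE_SOIL = 0
FINE_GRASS = 1
FINE_WEED = 2
FINE_RED_CLOVER = 3
FINE_WHITE_CLOVER = 4
FINE_NAMES = ("soil", "grass", "weed", "red_clover", "white_clover")

#: collapse a fine label back to its top-level class
FINE_TO_TOP = {
    FINE_SOIL: SOIL,
    FINE_GRASS: GRASS,
    FINE_WEED: WEED,
    FINE_RED_CLOVER: CLOVER,
    FINE_WHITE_CLOVER: CLOVER,
}

# indexed-PNG display palettes (RGB per class index)
TOP_PALETTE = {
    "soil": (96, 64, 32),
    "clover": (200, 40, 40),
    "grass": (60, 180, 60),
    "weed": (240, 150, 20),
}
SUB_PALETTE = {
    "soil": (96, 64, 32),
    "white_clover_leaf": (250, 240, 80),
    "white_clover_flower": (255, 255, 210),
    "red_clover_leaf": (160, 40, 180),
    "red_clover_flower": (230, 60, 120),
    "unknown_clover_leaf": (200, 40, 40),
    "grass": (60, 180, 60),
    "weed_dandelion": (240, 150, 20),
    "weed_shepherds_purse": (200, 120, 10),
    "weed_thistle": (160, 95, 10),
}


@dataclass(frozen=True)
class LabelHierarchy:
    """Ordered class lists of both cascade stages and the sub->top map."""

    top_classes: tuple = TOP_NAMES
    sub_classes: tuple = SUB_NAMES
    parent: dict = field(default_factory=lambda: dict(PARENT))

    @property
    def stage1_classes(self) -> tuple:
        return self.top_classes

    @property
    def stage2_classes(self) -> tuple:
        return STAGE2_NAMES

    def collapse(self, label_sub: np.ndarray) -> np.ndarray:
        """Map a sub-class raster to its top-class raster through ``parent``."""
        lut = np.zeros(len(self.sub_classes), dtype=np.uint8)
        for sub, top in self.parent.items():
            lut[sub] = top
        return lut[label_sub]


def collapse_sub_to_top(label_sub: np.ndarray) -> np.ndarray:
    return LabelHierarchy().collapse(label_sub)


def collapse_fine_to_top(fine: np.ndarray) -> np.ndarray:
    """Collapse cascaded fine labels (species-resolved) to stage-1 classes."""
    lut = np.zeros(len(FINE_NAMES), dtype=np.uint8)
    for f, t in FINE_TO_TOP.items():
        lut[f] = t
    return lut[fine]
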