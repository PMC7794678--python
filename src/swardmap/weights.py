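"""Frequency-based class weighting for cascade training.

Pixel classes in sward imagery are highly imbalanced (soil and grass
dominate; weeds and clover flowers are rare).  To keep the cross-entropy
loss from ignoring rare classes, each class c gets a weight

    w_c = w_ce * ln(N_sum / N_c)

where N_c is the class pixel count, N_sum the total pixel count and w_ce a
hyper-parameter controlling the emphasis (default 2.1).  The weight is zero
for a class occupying every pixel and grows as the class gets rarer.

Two refinements mirror how clovers and weeds are handled during training:
clover-species leaf weights are derived from the *combined* clover count and
then scaled by the species' within-clover rarity (so the weight of the
clover canopy as a whole stays controlled even though species splits vary),
and all weed species share one weight derived from the combined weed
coverage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hierarchy as hi

DEFAULT_W_CE = 2.1

#: stage-agnostic weight vector as used for CNN training, keyed by class
#: name, ingested from the published configuration.
PUBLISHED_TRAINING_WEIGHTS = {
    "soil": 3.97,
    "clover": 1.46,
    "grass": 2.86,
    "weeds": 6.07,
    "white_clover": 1.46,
    "red_clover": 6.68,
    "dandelion": 6.07,
    "shepherds_purse": 6.07,
    "thistle": 6.07,
    "white_clover_flower": 8.58,
    "white_clover_leaf": 2.41,
    "red_clover_flower": 13.28,
    "red_clover_leaf": 0.88,
    "unknown_clover_leaf": 1.46,
}


@dataclass
class ClassWeightTable:
    """Per-class pixel counts and loss weights."""

    counts: dict[str, int]
    n_sum: int
    w_ce: float = DEFAULT_W_CE
    weights: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": c, "N_c": n, "w_c": self.weights.get(c, np.nan)}
                for c, n in self.counts.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def count_pixels(scenes, level: str = "top") -> ClassWeightTable:
    """Exact per-class pixel counts over a list of labelled scenes."""
    if not scenes:
        raise ValueError("scenes list is empty")
    if level not in ("top", "sub"):
        raise ValueError("level must be 'top' or 'sub'")
    names = hi.TOP_NAMES if level == "top" else hi.SUB_NAMES
    totals = np.zeros(len(names), dtype=np.int64)
    n_sum = 0
    for sc in scenes:
        labels = sc.label_top if level == "top" else sc.label_sub
        totals += np.bincount(np.asarray(labels).ravel(), minlength=len(names))
        n_sum += np.asarray(labels).size
    return ClassWeightTable({n: int(c) for n, c in zip(names, totals)}, n_sum)


def class_weight(n_c: int, n_sum: int, w_ce: float = DEFAULT_W_CE,
                 cap: float | None = None) -> float:
    """Frequency weight w_c = w_ce * ln(N_sum / N_c).

    A zero count leaves the weight undefined; the configured ``cap`` is
    returned with a warning (defaults to the weight of a single pixel).
    """
    if w_ce <= 0:
        raise ValueError("w_ce must be positive")
    if n_c > n_sum:
        raise ValueError("N_c cannot exceed N_sum")
    if n_c == 0:
        if cap is None:
            cap = w_ce * math.log(n_sum) if n_sum > 1 else w_ce
        warnings.warn("zero-count class: weight undefined, returning cap")
        return float(cap)
    return w_ce * math.log(n_sum / n_c)


def compute_weights(table: ClassWeightTable, w_ce: float = DEFAULT_W_CE) -> ClassWeightTable:
    """Fill plain per-class weights for every counted class."""
    table.w_ce = w_ce
    max_w = 0.0
    for c, n in table.counts.items():
        if n > 0:
            max_w = max(max_w, w_ce * math.log(table.n_sum / n))
    for c, n in table.counts.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table.weights[c] = class_weight(n, table.n_sum, w_ce, cap=max_w or w_ce)
        if n == 0:
            warnings.warn(f"class {c!r} absent: capped weight {table.weights[c]:.3g}")
    return table


def regularized_clover_weights(table: ClassWeightTable,
                               w_ce: float = DEFAULT_W_CE) -> ClassWeightTable:
    """Sub-class weights with clover regularization and a shared weed weight.

    Expects a ``sub``-level count table.  Red- and white-clover leaf weights
    start from the frequency weight of the *combined* clover count and are
    scaled by each species' within-clover rarity (combined clover-species
    count / (2 x species count)); balanced species therefore both get the
    combined-clover weight.  All named weed species share the weight derived
    from the combined weed coverage.  Absent sub-classes get the capped
    weight with a warning.
    """
    needed = {"white_clover_leaf", "red_clover_leaf"}
    if not needed <= set(table.counts):
        raise ValueError("sub-level counts with clover species are required")
    compute_weights(table, w_ce)

    n_clover = sum(table.counts[c] for c in
                   ("white_clover_leaf", "white_clover_flower",
                    "red_clover_leaf", "red_clover_flower",
                    "unknown_clover_leaf") if c in table.counts)
    weed_names = [c for c in table.counts if c.startswith("weed_")]
    n_weed = sum(table.counts[c] for c in weed_names)
    cap = max(table.weights.values()) if table.weights else w_ce

    if n_clover > 0:
        w_clover = class_weight(n_clover, table.n_sum, w_ce)
        n_w = table.counts["white_clover_leaf"]
        n_r = table.counts["red_clover_leaf"]
        n_species = n_w + n_r
        for name, n_s in (("white_clover_leaf", n_w), ("red_clover_leaf", n_r)):
            if n_s == 0:
                warnings.warn(f"{name} absent within clover: capped weight")
                table.weights[name] = cap
            else:
                table.weights[name] = w_clover * (n_species / (2.0 * n_s))
    if weed_names:
        if n_weed > 0:
            shared = class_weight(n_weed, table.n_sum, w_ce)
        else:
            warnings.warn("no weed pixels: capped shared weed weight")
            shared = cap
        for c in weed_names:
            table.weights[c] = shared
    return table


def load_published_weights() -> pd.DataFrame:
    """The stage-agnostic training weight vector, one named class per row."""
    return pd.DataFrame(
        [{"class": k, "w_c": v} for k, v in PUBLISHED_TRAINING_WEIGHTS.items()]
    )


def to_prospect_labels(scene, stage: int):
    """Translate hierarchical labels into one cascade stage's classes.

    Returns ``(labels, loss_mask)``.  Stage 1: the top-level classes with an
    all-on mask.  Stage 2: red(0)/white(1) clover labels, with the loss mask
    on only where the pixel is clover of known species; everything else
    (including unknown-species clover) contributes no loss.
    """
    if stage == 1:
        return scene.label_top.copy(), np.ones_like(scene.label_top, bool)
    if stage != 2:
        raise ValueError("stage must be 1 or 2")
    sub = scene.label_sub
    red = np.isin(sub, (hi.RED_CLOVER_LEAF, hi.RED_CLOVER_FLOWER))
    white = np.isin(sub, (hi.WHITE_CLOVER_LEAF, hi.WHITE_CLOVER_FLOWER))
    labels = np.full(sub.shape, hi.STAGE2_RED, np.uint8)
    labels[white] = hi.STAGE2_WHITE
    mask = (red | white) & (scene.label_top == hi.CLOVER)
    return labels, mask
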