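"""Synthetic grass-clover canopy scenes with pixel-accurate hierarchical labels.

Real pixel-labelled training data for sward segmentation is prohibitively
expensive to annotate, so training scenes are composited: procedurally drawn
plant sprites (thin curved blades for grass, trifoliate rounded leaflets for
the two clover species, a lobed rosette for weeds) are placed one by one on
a speckled soil background, in painter's order, until a target fraction of
the scene is covered by vegetation.  Because every sprite carries its own
species identity, the emitted image comes with exact per-pixel labels at two
levels: the stage-1 classes (soil/clover/grass/weed) and the sub-classes
(clover species x plant part, named weed species).

White clover sprites carry a pale chevron-like leaf marking and red clover a
darker one, so a learner has a visual cue to separate the species - the same
role the natural leaf markings play in real imagery.

The stopping rule targets *projected visible coverage* (fraction of non-soil
pixels), which the labels can certify exactly; the cumulative placed sprite
area is also tracked so a leaf-area-index-like statistic (placed area /
scene area) is reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import disk, ellipse
from skimage.transform import rotate as _sk_rotate

from . import hierarchy as hi
from .metrics import CanopyMetrics, canopy_metrics

SPECIES = ("grass", "white_clover", "red_clover", "weed")

#: hard cap on placements per scene -- termination guarantee at extreme targets
MAX_PLACEMENTS = 10_000

_WEED_KINDS = (hi.WEED_DANDELION, hi.WEED_SHEPHERDS_PURSE, hi.WEED_THISTLE)


@dataclass
class PlantSprite:
    """A cut-out plant: binary mask + RGB appearance, sprite-local frame."""

    species: str
    subpart: str  # leaf | flower | none
    mask: np.ndarray
    appearance: np.ndarray
    sprite_id: str
    weed_kind: int | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if not self.mask.any():
            raise ValueError("sprite mask is empty")
        if self.appearance.shape[:2] != self.mask.shape:
            raise ValueError("appearance and mask dimensions differ")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def sub_label(self) -> int:
        if self.species == "grass":
            return hi.SUB_GRASS
        if self.species == "weed":
            return self.weed_kind if self.weed_kind is not None else hi.WEED_DANDELION
        if self.species == "white_clover":
            return hi.WHITE_CLOVER_FLOWER if self.subpart == "flower" else hi.WHITE_CLOVER_LEAF
        return hi.RED_CLOVER_FLOWER if self.subpart == "flower" else hi.RED_CLOVER_LEAF

    @property
    def top_label(self) -> int:
        return hi.PARENT[self.sub_label]


@dataclass
class SceneSpec:
    """Configuration of one synthetic scene."""

    width_px: int = 256
    height_px: int = 256
    gsd_px_per_mm: float = 6.0
    target_coverage: float = 0.8
    species_mix: tuple = (0.4, 0.3, 0.2, 0.1)  # grass, white, red, weed
    flower_rate: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        mix = np.asarray(self.species_mix, dtype=float)
        if mix.shape != (4,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("species_mix must be 4 non-negative probabilities summing to 1")
        if not 0.0 <= self.target_coverage <= 0.995:
            raise ValueError("target_coverage must be in [0, 0.995]")


@dataclass
class Placement:
    order: int
    sprite_id: str
    row: float  # sprite centre, scene coordinates (row-major, origin top-left)
    col: float
    angle_deg: float


@dataclass
class LabeledScene:
    image: np.ndarray
    label_top: np.ndarray
    label_sub: np.ndarray
    truth: CanopyMetrics
    placement_log: list = field(default_factory=list)
    spec: SceneSpec | None = None
    achieved_coverage: float = 0.0
    placed_area_index: float = 0.0  # cumulative placed sprite area / scene area


# ---------------------------------------------------------------------------
# procedural sprite drawing
# ---------------------------------------------------------------------------

def _blank(h, w):
    return np.zeros((h, w), bool), np.zeros((h, w, 3), np.float64)


def _jitter_color(rng, base, sd=12.0):
    return np.clip(np.asarray(base, float) + rng.normal(0, sd, 3), 0, 255)


def _draw_grass(rng, size):
    length = int(size * rng.uniform(1.4, 2.4))
    width0 = max(2, int(size * rng.uniform(0.08, 0.14)))
    amp = size * rng.uniform(0.1, 0.4)
    w = int(2 * amp + width0 + 4)
    mask, app = _blank(length, w)
    color = _jitter_color(rng, (110, 170, 55))
    bend = rng.uniform(0.5, 1.5)
    for y in range(length):
        t = y / max(length - 1, 1)
        cx = w / 2 + amp * np.sin(np.pi * t * bend)
        half = max(0.5, width0 * (1 - 0.8 * t) / 2)
        c0, c1 = int(round(cx - half)), int(round(cx + half))
        c0, c1 = max(c0, 0), min(c1, w - 1)
        mask[y, c0:c1 + 1] = True
        shade = 0.75 + 0.25 * t  # tip brighter than base
        app[y, c0:c1 + 1] = color * shade
    return mask, app


def _draw_clover_leaf(rng, size, species):
    r = max(4, int(size * rng.uniform(0.35, 0.55)))  # leaflet radius
    half = int(2.6 * r)
    h = w = 2 * half + 1
    mask, app = _blank(h, w)
    if species == "white_clover":
        leaf = _jitter_color(rng, (55, 135, 60))
        marking = _jitter_color(rng, (195, 220, 190), 8)
    else:
        leaf = _jitter_color(rng, (35, 105, 50))
        marking = _jitter_color(rng, (18, 55, 30), 6)
    base_angle = rng.uniform(0, 2 * np.pi)
    for k in range(3):
        ang = base_angle + k * 2 * np.pi / 3
        cy = half + 1.15 * r * np.sin(ang)
        cx = half + 1.15 * r * np.cos(ang)
        rr, cc = ellipse(cy, cx, r, 0.8 * r, shape=mask.shape, rotation=-ang)
        mask[rr, cc] = True
        app[rr, cc] = leaf * rng.uniform(0.92, 1.08)
        # crescent-like marking: smaller ellipse offset toward the leaf base
        rr, cc = ellipse(cy - 0.3 * r * np.sin(ang), cx - 0.3 * r * np.cos(ang),
                         0.45 * r, 0.3 * r, shape=mask.shape, rotation=-ang)
        keep = mask[rr, cc]
        app[rr[keep], cc[keep]] = marking
    # short stem
    rr, cc = ellipse(h - 0.6 * r, half, 0.6 * r, 0.12 * r, shape=mask.shape)
    mask[rr, cc] = True
    app[rr, cc] = leaf * 0.8
    return mask, app


def _draw_clover_flower(rng, size, species):
    r = max(3, int(size * rng.uniform(0.3, 0.45)))
    h = w = 2 * r + 3
    mask, app = _blank(h, w)
    color = (238, 238, 215) if species == "white_clover" else (210, 90, 145)
    color = _jitter_color(rng, color, 8)
    rr, cc = disk((h // 2, w // 2), r, shape=mask.shape)
    mask[rr, cc] = True
    app[rr, cc] = color
    # petal speckle texture
    speck = rng.normal(0, 14, (h, w, 1))
    app = np.clip(app + speck * mask[..., None], 0, 255)
    return mask, app


def _draw_weed(rng, size):
    n_lobes = rng.integers(5, 8)
    reach = int(size * rng.uniform(0.8, 1.2))
    h = w = 2 * reach + 5
    mask, app = _blank(h, w)
    color = _jitter_color(rng, (70, 140, 130))  # teal-green rosette
    for k in range(n_lobes):
        ang = k * 2 * np.pi / n_lobes + rng.uniform(-0.2, 0.2)
        for t, frac in ((0.35, 0.3), (0.65, 0.24), (0.92, 0.16)):  # lobed outline
            cy = h / 2 + t * reach * np.sin(ang)
            cx = w / 2 + t * reach * np.cos(ang)
            rr, cc = disk((cy, cx), max(2, frac * reach), shape=mask.shape)
            mask[rr, cc] = True
            app[rr, cc] = color * (1.05 - 0.3 * t)
    return mask, app


def make_sprite_bank(n_per_species: int, rng_seed: int, size_px: int = 22,
                     flower_share: float = 0.2) -> list[PlantSprite]:
    """Draw ``4 * n_per_species`` sprites with within-species variation.

    For the clover species, roughly ``flower_share`` of the sprites are
    flower heads (at least one when ``n_per_species`` > 2); weeds cycle
    through the named weed kinds.  Deterministic for a fixed seed.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    rng = np.random.default_rng(rng_seed)
    bank: list[PlantSprite] = []
    for species in SPECIES:
        n_flowers = 0
        if species in ("white_clover", "red_clover") and n_per_species > 2:
            n_flowers = max(1, int(round(flower_share * n_per_species)))
        for i in range(n_per_species):
            sid = f"{species}_{i:03d}"
            if species == "grass":
                mask, app = _draw_grass(rng, size_px)
                subpart, kind = "leaf", None
            elif species == "weed":
                mask, app = _draw_weed(rng, size_px)
                subpart, kind = "leaf", _WEED_KINDS[i % len(_WEED_KINDS)]
            elif i < n_flowers:
                mask, app = _draw_clover_flower(rng, size_px, species)
                subpart, kind = "flower", None
            else:
                mask, app = _draw_clover_leaf(rng, size_px, species)
                subpart, kind = "leaf", None
            bank.append(PlantSprite(species, subpart, mask,
                                    app.astype(np.uint8), sid, kind))
    return bank


# ---------------------------------------------------------------------------
# scene composition
# ---------------------------------------------------------------------------

def rotated_sprite(sprite: PlantSprite, angle_deg: float):
    """Deterministic nearest-neighbour rotation of mask + appearance."""
    m = _sk_rotate(sprite.mask.astype(float), angle_deg, resize=True, order=0,
                   preserve_range=True) > 0.5
    a = _sk_rotate(sprite.appearance.astype(float), angle_deg, resize=True,
                   order=0, preserve_range=True)
    return m, np.clip(a, 0, 255).astype(np.uint8)


def _soil_background(rng, h, w):
    base = np.array((105.0, 75.0, 45.0))
    img = base + rng.normal(0, 10, (h, w, 3))
    # gentle low-frequency mottling
    yy = np.linspace(0, 2 * np.pi, h)[:, None]
    xx = np.linspace(0, 2 * np.pi, w)[None, :]
    phase = rng.uniform(0, 2 * np.pi, 2)
    img += 8 * (np.sin(yy + phase[0]) * np.cos(xx + phase[1]))[..., None]
    return np.clip(img, 0, 255).astype(np.uint8)


def _paint(image, label_top, label_sub, mask, app, top, sub, r_c, c_c):
    """Paint one rotated sprite centred at (r_c, c_c); returns newly-vegetated px."""
    h, w = mask.shape
    H, W = label_top.shape
    r0 = int(round(r_c - h / 2))
    c0 = int(round(c_c - w / 2))
    sr0, sc0 = max(0, -r0), max(0, -c0)
    dr0, dc0 = max(0, r0), max(0, c0)
    dr1, dc1 = min(H, r0 + h), min(W, c0 + w)
    if dr1 <= dr0 or dc1 <= dc0:
        return 0, 0
    m = mask[sr0:sr0 + (dr1 - dr0), sc0:sc0 + (dc1 - dc0)]
    a = app[sr0:sr0 + (dr1 - dr0), sc0:sc0 + (dc1 - dc0)]
    tgt_top = label_top[dr0:dr1, dc0:dc1]
    newly_veg = int((m & (tgt_top == hi.SOIL)).sum())
    image[dr0:dr1, dc0:dc1][m] = a[m]
    tgt_top[m] = top
    label_sub[dr0:dr1, dc0:dc1][m] = sub
    return newly_veg, int(m.sum())


def compose_scene(spec: SceneSpec, bank: list[PlantSprite]) -> LabeledScene:
    """Composite sprites onto soil until the coverage target is reached.

    Sprites are drawn in placement order; later sprites occlude earlier ones
    in both the image and the labels, so labels describe the visible canopy
    only.  A hard cap of ``MAX_PLACEMENTS`` guarantees termination; if the
    target is unreachable a warning is issued and the achieved coverage is
    recorded.
    """
    mix = np.asarray(spec.species_mix, float)
    by_species: dict[str, list[int]] = {s: [] for s in SPECIES}
    for idx, sp in enumerate(bank):
        by_species[sp.species].append(idx)
    for s, p in zip(SPECIES, mix):
        if p > 0 and not by_species[s]:
            raise ValueError(f"species_mix gives {s} nonzero probability but bank has none")

    rng = np.random.default_rng(spec.rng_seed)
    H, W = spec.height_px, spec.width_px
    image = _soil_background(rng, H, W)
    label_top = np.full((H, W), hi.SOIL, np.uint8)
    label_sub = np.full((H, W), hi.SUB_SOIL, np.uint8)

    n_veg = 0
    placed_area = 0
    log: list[Placement] = []
    target_veg = spec.target_coverage * H * W
    for order in range(MAX_PLACEMENTS):
        if n_veg >= target_veg:
            break
        species = SPECIES[rng.choice(4, p=mix)]
        cands = by_species[species]
        if species in ("white_clover", "red_clover"):
            want_flower = rng.random() < spec.flower_rate
            sub = [i for i in cands if (bank[i].subpart == "flower") == want_flower]
            cands = sub or cands
        idx = cands[rng.integers(len(cands))]
        sprite = bank[idx]
        angle = float(rng.uniform(0, 360))
        r_c = float(rng.uniform(0, H))
        c_c = float(rng.uniform(0, W))
        m, a = rotated_sprite(sprite, angle)
        new_veg, in_scene = _paint(image, label_top, label_sub, m, a,
                                   sprite.top_label, sprite.sub_label, r_c, c_c)
        n_veg += new_veg
        placed_area += in_scene
        log.append(Placement(order, sprite.sprite_id, r_c, c_c, angle))
    else:
        if n_veg < target_veg:
            warnings.warn(
                f"coverage target {spec.target_coverage:.3f} unreachable within "
                f"{MAX_PLACEMENTS} placements; achieved {n_veg / (H * W):.3f}")

    truth = canopy_metrics(label_top, label_sub)
    return LabeledScene(image, label_top, label_sub, truth, log, spec,
                        achieved_coverage=n_veg / (H * W),
                        placed_area_index=placed_area / (H * W))


def render_labels_from_log(spec: SceneSpec, bank: list[PlantSprite],
                           log: list[Placement]):
    """Replay a placement log in painter's order; returns (label_top, label_sub)."""
    by_id = {sp.sprite_id: sp for sp in bank}
    H, W = spec.height_px, spec.width_px
    label_top = np.full((H, W), hi.SOIL, np.uint8)
    label_sub = np.full((H, W), hi.SUB_SOIL, np.uint8)
    image = np.zeros((H, W, 3), np.uint8)
    for p in sorted(log, key=lambda p: p.order):
        sp = by_id[p.sprite_id]
        m, a = rotated_sprite(sp, p.angle_deg)
        _paint(image, label_top, label_sub, m, a, sp.top_label, sp.sub_label,
               p.row, p.col)
    return label_top, label_sub


# ---------------------------------------------------------------------------
# scene bundle I/O
# ---------------------------------------------------------------------------

def _save_indexed(path: Path, labels: np.ndarray, palette: dict):
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = []
    for rgb in palette.values():
        flat.extend(rgb)
    flat.extend([0] * (768 - len(flat)))
    im.putpalette(flat)
    im.save(path)


def write_scene(scene: LabeledScene, directory) -> dict:
    """Write a scene bundle; returns the manifest (also saved as JSON).

    Bundle: image.png (8-bit RGB), label_top.png / label_sub.png (indexed PNG
    with the shared palette), palette.json, truth.json, placement_log.csv,
    manifest.json (records the SceneSpec incl. rng_seed for exact regeneration).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scene.image, "RGB").save(directory / "image.png")
    _save_indexed(directory / "label_top.png", scene.label_top, hi.TOP_PALETTE)
    _save_indexed(directory / "label_sub.png", scene.label_sub, hi.SUB_PALETTE)
    palette = {
        "top": {name: {"index": i, "rgb": list(hi.TOP_PALETTE[name])}
                for i, name in enumerate(hi.TOP_NAMES)},
        "sub": {name: {"index": i, "rgb": list(hi.SUB_PALETTE[name])}
                for i, name in enumerate(hi.SUB_NAMES)},
    }
    (directory / "palette.json").write_text(json.dumps(palette, indent=2))
    truth = {
        "metrics": scene.truth.as_dict(),
        "achieved_coverage": scene.achieved_coverage,
        "placed_area_index": scene.placed_area_index,
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=2))
    pd.DataFrame([asdict(p) for p in scene.placement_log],
                 columns=["order", "sprite_id", "row", "col", "angle_deg"]).to_csv(
        directory / "placement_log.csv", index=False)
    manifest = {
        "files": ["image.png", "label_top.png", "label_sub.png",
                  "palette.json", "truth.json", "placement_log.csv"],
        "spec": asdict(scene.spec) if scene.spec else None,
        "rng_seed": scene.spec.rng_seed if scene.spec else None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_scene(directory) -> LabeledScene:
    """Read back a scene bundle written by :func:`write_scene`."""
    directory = Path(directory)
    image = np.asarray(Image.open(directory / "image.png").convert("RGB"))
    label_top = np.asarray(Image.open(directory / "label_top.png"))
    label_sub = np.asarray(Image.open(directory / "label_sub.png"))
    manifest = json.loads((directory / "manifest.json").read_text())
    spec = SceneSpec(**{k: tuple(v) if isinstance(v, list) else v
                        for k, v in manifest["spec"].items()}) if manifest["spec"] else None
    truth_doc = json.loads((directory / "truth.json").read_text())
    truth = CanopyMetrics(**truth_doc["metrics"])
    log_df = pd.read_csv(directory / "placement_log.csv")
    log = [Placement(int(r.order), r.sprite_id, float(r.row), float(r.col),
                     float(r.angle_deg)) for r in log_df.itertuples()] if len(log_df) else []
    return LabeledScene(image, label_top, label_sub, truth, log, spec,
                        truth_doc["achieved_coverage"], truth_doc["placed_area_index"])
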