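"""Seeded generator of plot-like maize scenes with known tassel annotations.

Scenes emulate small UAV plot crops: brownish textured soil, dark shadow
patches, two rows of green elliptical foliage canopies, and yellowish
branched tassel glyphs at recorded centers. Every scene carries a per-pixel
class map and a marker image (a copy of the scene with a subsample of each
class overpainted in the four pure marker colors), so the filtering,
sampling, counting and evaluation machinery is all testable without any
real imagery.

The default palette is chosen so the two-step filter behaves as designed:

* rescaled ExG — soil 127.5 and shadow ≈126 fall below threshold 131,
  foliage 175.0 and tassel 147.5 above it;
* rescaled tassel index — foliage ≈45.96, tassel ≈143.5, so thresholds in
  :data:`SEPARATION_BAND` eliminate foliage while sparing tassels.

Foliage canopies are flat-colored (no jitter) so the foliage→tassel
separation band has exact edges; soil and shadow carry per-pixel texture
jitter and each tassel glyph a per-glyph color jitter. The jitter sizes are
small enough that the separation contract holds for every seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .core_io import BoxAnnotation, PointAnnotation, RgbImage, write_annotations, write_image
from .errors import ConfigurationError, ValidationError
from .indices import rescaled_index
from .pixel_sampling import MARKER_COLORS

__all__ = [
    "CLASS_NAMES",
    "SEPARATION_BAND",
    "OPTIMAL_TASSEL_THRESHOLD",
    "SceneConfig",
    "SyntheticScene",
    "default_palette",
    "generate_scene",
    "generate_scenes",
    "generate_dataset",
]

CLASS_NAMES = ("soil", "shadow", "foliage", "tassel")

#: Step-2 (tassel-index) threshold band, on the rescaled 0–255 scale, inside
#: which the default palette guarantees >=95% foliage elimination and <=20%
#: tassel elimination. The field-data working band 90–110 lies inside it.
SEPARATION_BAND: tuple[int, int] = (46, 135)

#: Documented optimal step-2 threshold for the default palette.
OPTIMAL_TASSEL_THRESHOLD: int = 95


def default_palette() -> dict[str, tuple[tuple[int, int, int], int]]:
    """Class → (mean RGB, per-channel jitter) for the default scenes."""
    return {
        "soil": ((120, 90, 60), 3),
        "shadow": ((40, 40, 45), 3),
        "foliage": ((50, 140, 40), 0),
        "tassel": ((200, 180, 80), 3),
    }


@dataclasses.dataclass
class SceneConfig:
    """Parameters of one synthetic plot scene."""

    height: int = 128
    width: int = 256
    n_tassels: int = 12
    palette: dict[str, tuple[tuple[int, int, int], int]] = dataclasses.field(
        default_factory=default_palette
    )
    tassel_shape: tuple[int, int, int] = (5, 7, 2)  # (n_branches, branch_length, thickness)
    shadow_fraction: float = 0.08
    seed: int = 0
    min_separation: int = 20  # minimum distance between tassel centers (pixels)
    marker_pixels_per_class: int = 250

    def __post_init__(self) -> None:
        if self.n_tassels < 0:
            raise ValidationError("n_tassels must be >= 0")
        if self.height < 48 or self.width < 48:
            raise ValidationError("scene must be at least 48×48")
        missing = [c for c in CLASS_NAMES if c not in self.palette]
        if missing:
            raise ConfigurationError(f"palette missing classes: {missing}")


@dataclasses.dataclass
class SyntheticScene:
    """A generated scene with full ground truth."""

    image: RgbImage
    points: PointAnnotation
    boxes: BoxAnnotation
    class_map: np.ndarray  # H×W uint8, indices into CLASS_NAMES
    marker_image: RgbImage


def _jitter_fill(
    rng: np.random.Generator, shape: tuple[int, ...], mean: tuple[int, int, int], j: int
) -> np.ndarray:
    base = np.broadcast_to(np.array(mean, dtype=np.int16), (*shape, 3)).copy()
    if j > 0:
        base += rng.integers(-j, j + 1, size=(*shape, 3), dtype=np.int16)
    return np.clip(base, 0, 255).astype(np.uint8)


def _draw_tassel(
    img: np.ndarray,
    cmap: np.ndarray,
    r: int,
    c: int,
    color: np.ndarray,
    shape: tuple[int, int, int],
) -> tuple[int, int, int, int]:
    """Draw a branched glyph; returns its bounding box (row_min, col_min, h, w)."""
    n_branches, length, thickness = shape
    h, w = cmap.shape
    rows_all, cols_all = [], []
    angles = np.linspace(-1.15, 1.15, n_branches)  # fan of ~±66° around vertical
    segments = [(r, c, r + 2, c)]  # short stem below the center
    for a in angles:
        r1 = int(round(r - length * np.cos(a)))
        c1 = int(round(c + length * np.sin(a)))
        segments.append((r, c, r1, c1))
    for r0, c0, r1, c1 in segments:
        rr, cc = draw_line(r0, c0, r1, c1)
        for dc in range(thickness):
            rows_all.append(rr)
            cols_all.append(np.clip(cc + dc, 0, w - 1))
    rr = np.concatenate(rows_all)
    cc = np.concatenate(cols_all)
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[ok], cc[ok]
    img[rr, cc] = color
    cmap[rr, cc] = CLASS_NAMES.index("tassel")
    return (
        int(rr.min()),
        int(cc.min()),
        int(rr.max() - rr.min() + 1),
        int(cc.max() - cc.min() + 1),
    )


def _check_separation(scene: SyntheticScene) -> None:
    """Verify the palette's separation contract on the drawn scene."""
    cmap = scene.class_map
    exg = rescaled_index(scene.image, "exg").values
    tas = rescaled_index(scene.image, "tassel").values
    lo, hi = SEPARATION_BAND

    def frac(mask: np.ndarray, cond: np.ndarray) -> float:
        return float(cond[mask].mean()) if mask.any() else 1.0

    checks = [
        ("soil below ExG 131", frac(cmap == 0, exg < 131.0), 0.99),
        ("shadow below ExG 131", frac(cmap == 1, exg < 131.0), 0.99),
        ("foliage above ExG 131", frac(cmap == 2, exg >= 131.0), 0.95),
        ("tassel above ExG 131", frac(cmap == 3, exg >= 131.0), 0.95),
        (f"foliage eliminated at band start {lo}", frac(cmap == 2, tas < lo), 0.95),
        (f"tassel surviving at band end {hi}", frac(cmap == 3, tas >= hi), 0.80),
    ]
    for name, value, minimum in checks:
        if value < minimum:
            raise ConfigurationError(
                f"palette separation contract violated: {name} = {value:.3f} < {minimum}"
            )


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Render one scene deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    pal = cfg.palette

    img = _jitter_fill(rng, (h, w), *pal["soil"])
    cmap = np.zeros((h, w), dtype=np.uint8)

    # shadow patches: random ellipses covering roughly shadow_fraction
    mean_area = np.pi * 8 * 12
    n_shadows = max(1, int(round(cfg.shadow_fraction * h * w / mean_area)))
    for _ in range(n_shadows):
        rc = rng.integers(0, h)
        cc = rng.integers(0, w)
        rr_ax = rng.integers(5, 12)
        cc_ax = rng.integers(8, 17)
        rows, cols = draw_ellipse(rc, cc, rr_ax, cc_ax, shape=(h, w))
        img[rows, cols] = _jitter_fill(rng, (len(rows),), *pal["shadow"])
        cmap[rows, cols] = 1

    # foliage canopies along two plant rows (flat-colored; see module docstring)
    fol_color = np.array(pal["foliage"][0], dtype=np.uint8)
    for row_center in (int(h * 0.32), int(h * 0.68)):
        col = rng.integers(4, 16)
        while col < w - 4:
            rc = row_center + rng.integers(-6, 7)
            rows, cols = draw_ellipse(
                rc,
                col,
                rng.integers(8, 15),
                rng.integers(10, 17),
                shape=(h, w),
            )
            img[rows, cols] = fol_color
            cmap[rows, cols] = 2
            col += rng.integers(14, 24)

    # tassel glyphs at rejection-sampled centers with a minimum separation
    n_br, length, _ = cfg.tassel_shape
    margin = length + 3
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < cfg.n_tassels:
        tries += 1
        if tries > 5000:
            raise ValidationError(
                "could not place tassels with the requested separation; "
                "reduce n_tassels or min_separation"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all(
            (r - r0) ** 2 + (c - c0) ** 2 >= cfg.min_separation**2 for r0, c0 in centers
        ):
            centers.append((r, c))

    mean, j = pal["tassel"]
    boxes = []
    for r, c in centers:
        color = np.clip(
            np.array(mean, dtype=np.int16) + rng.integers(-j, j + 1, size=3), 0, 255
        ).astype(np.uint8)
        boxes.append(_draw_tassel(img, cmap, r, c, color, cfg.tassel_shape))

    image = RgbImage(img, image_id=f"scene_{cfg.seed}")
    points = PointAnnotation(image.image_id, [(float(r), float(c)) for r, c in centers])
    box_ann = BoxAnnotation(image.image_id, [tuple(map(float, b)) for b in boxes])

    # marker image: subsample of each class overpainted with the pure colors
    marker = img.copy()
    for ci, cname in enumerate(CLASS_NAMES):
        rows, cols = np.nonzero(cmap == ci)
        if len(rows) == 0:
            continue
        k = min(cfg.marker_pixels_per_class, len(rows))
        pick = rng.choice(len(rows), size=k, replace=False)
        marker[rows[pick], cols[pick]] = MARKER_COLORS[cname]
    marker_image = RgbImage(marker, image_id=image.image_id)

    scene = SyntheticScene(image, points, box_ann, cmap, marker_image)
    _check_separation(scene)
    return scene


def generate_scenes(
    n_scenes: int,
    seed: int,
    template: SceneConfig | None = None,
    tassel_range: tuple[int, int] = (5, 25),
) -> list[SyntheticScene]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from ``seed``
    and per-scene tassel counts drawn uniformly from ``tassel_range``."""
    if n_scenes < 1:
        raise ValidationError("n_scenes must be >= 1")
    template = template or SceneConfig()
    rng = np.random.default_rng([seed, 0x5CE2E])
    scenes = []
    for _ in range(n_scenes):
        n_t = int(rng.integers(tassel_range[0], tassel_range[1] + 1))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(template, n_tassels=n_t, seed=scene_seed)
        scenes.append(generate_scene(cfg))
    # per-scene seeds collide with vanishing probability, but ids must be unique
    for i, s in enumerate(scenes):
        new_id = f"scene_{i:04d}"
        s.image.image_id = new_id
        s.points.image_id = new_id
        s.boxes.image_id = new_id
        s.marker_image.image_id = new_id
    return scenes


def generate_dataset(
    n_scenes: int,
    out_dir: str | Path,
    seed: int,
    template: SceneConfig | None = None,
    tassel_range: tuple[int, int] = (5, 25),
    train_fraction: float = 0.8,
    force: bool = False,
) -> dict:
    """Write a full synthetic dataset: images, marker images, class maps,
    point/box CSVs, a train/test split and a manifest.

    The split holds out ``1 − train_fraction`` of the scenes for testing
    (default 80/20). Refuses to write into an existing non-empty directory
    unless ``force`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output directory {out} is not empty (use force=True)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "markers").mkdir(exist_ok=True)
    (out / "class_maps").mkdir(exist_ok=True)

    scenes = generate_scenes(n_scenes, seed, template, tassel_range)
    for s in scenes:
        write_image(s.image, out / "images" / f"{s.image.image_id}.png")
        write_image(s.marker_image, out / "markers" / f"{s.image.image_id}.png")
        np.savetxt(
            out / "class_maps" / f"{s.image.image_id}.txt",
            s.class_map,
            fmt="%d",
        )
    write_annotations([s.points for s in scenes], out / "points.csv")
    write_annotations([s.boxes for s in scenes], out / "boxes.csv")

    ids = [s.image.image_id for s in scenes]
    split_rng = np.random.default_rng([seed, 0x511])
    order = split_rng.permutation(n_scenes)
    n_train = int(round(train_fraction * n_scenes))
    train_ids = sorted(ids[i] for i in order[:n_train])
    test_ids = sorted(ids[i] for i in order[n_train:])

    manifest = {
        "n_scenes": n_scenes,
        "seed": seed,
        "tassel_range": list(tassel_range),
        "scene_ids": ids,
        "n_tassels": {s.image.image_id: len(s.points) for s in scenes},
        "train_ids": train_ids,
        "test_ids": test_ids,
        "separation_band": list(SEPARATION_BAND),
        "optimal_tassel_threshold": OPTIMAL_TASSEL_THRESHOLD,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "splits.json").write_text(
        json.dumps({"train": train_ids, "test": test_ids}, indent=1)
    )
    return manifest
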