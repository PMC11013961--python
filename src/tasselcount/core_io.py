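"""Domain types, image and annotation I/O, and coordinate conventions.

Conventions used throughout the package:

* pixel addressing is ``(row, col)``, 0-based, row 0 at the top;
* boxes are ``(row_min, col_min, height, width)`` with half-open extent;
* PNG is the canonical (lossless) image format, JPEG is accepted on read;
* annotations are CSV, metric reports and curves are JSON.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "RgbImage",
    "NormalizedChannels",
    "PointAnnotation",
    "BoxAnnotation",
    "CountRecord",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "boxes_to_points",
]


@dataclasses.dataclass
class RgbImage:
    """An 8-bit H×W×3 raster, the unit of all processing.

    Parameters
    ----------
    pixels
        Integer array of shape ``(H, W, 3)`` with values in [0, 255].
    image_id
        Identifier used to join the image with its annotations.
    """

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected an H×W×3 raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must be at least 1×1")
        if px.min() < 0 or px.max() > 255:
            raise ValidationError("channel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the raster."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclasses.dataclass
class NormalizedChannels:
    """Per-channel rasters R*, G*, B* = channel / 255, each in [0, 1]."""

    r_star: np.ndarray
    g_star: np.ndarray
    b_star: np.ndarray


@dataclasses.dataclass
class PointAnnotation:
    """Point-referenced tassel locations for one image."""

    image_id: str
    points: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.points)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for r, c in self.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError(
                    f"point ({r}, {c}) outside image bounds {h}×{w}"
                )


@dataclasses.dataclass
class BoxAnnotation:
    """Bounding-box tassel annotations, boxes as (row_min, col_min, height, width)."""

    image_id: str
    boxes: list[tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        for rm, cm, h, w in self.boxes:
            if h < 1 or w < 1:
                raise ValidationError(
                    f"box ({rm}, {cm}, {h}, {w}) must have height, width >= 1"
                )

    def __len__(self) -> int:
        return len(self.boxes)


@dataclasses.dataclass
class CountRecord:
    """Observed vs. predicted tassel count for one test image."""

    image_id: str
    observed: int
    predicted: float

    def __post_init__(self) -> None:
        if self.observed < 0:
            raise ValidationError("observed count must be >= 0")
        if self.predicted < 0:
            raise ValidationError("predicted count must be >= 0")


def read_image(path: str | Path, image_id: str | None = None) -> RgbImage:
    """Read a PNG/JPEG file into an :class:`RgbImage`.

    An alpha channel is dropped; single-channel (grayscale) input is rejected
    because the color-index filters are undefined without distinct R, G, B.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    px = iio.imread(path)
    if px.ndim == 2 or (px.ndim == 3 and px.shape[2] == 1):
        raise FormatError(f"{path}: single-channel input; RGB required")
    if px.ndim != 3:
        raise FormatError(f"{path}: unsupported raster shape {px.shape}")
    if px.shape[2] == 4:
        px = px[:, :, :3]
    elif px.shape[2] != 3:
        raise FormatError(f"{path}: expected 3 or 4 channels, got {px.shape[2]}")
    return RgbImage(px, image_id=image_id if image_id is not None else path.stem)


def write_image(img: RgbImage, path: str | Path) -> None:
    """Write an image as PNG (lossless; read→write→read is bit-exact)."""
    iio.imwrite(Path(path), img.pixels, extension=".png")


_POINT_COLS = ["image_id", "row", "col"]
_BOX_COLS = ["image_id", "row_min", "col_min", "height", "width"]


def read_annotations(
    path: str | Path, kind: str
) -> dict[str, PointAnnotation] | dict[str, BoxAnnotation]:
    """Read a point or box annotation CSV, grouped per ``image_id``.

    Schemas: ``image_id,row,col`` for points and
    ``image_id,row_min,col_min,height,width`` for boxes.
    """
    if kind not in ("points", "boxes"):
        raise ValueError(f"kind must be 'points' or 'boxes', got {kind!r}")
    df = pd.read_csv(path, dtype={"image_id": str})
    cols = _POINT_COLS if kind == "points" else _BOX_COLS
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out: dict = {}
    if kind == "points":
        for image_id, grp in df.groupby("image_id", sort=False):
            out[image_id] = PointAnnotation(
                image_id, list(zip(grp["row"].astype(float), grp["col"].astype(float)))
            )
    else:
        for image_id, grp in df.groupby("image_id", sort=False):
            out[image_id] = BoxAnnotation(
                image_id,
                list(
                    zip(
                        grp["row_min"].astype(float),
                        grp["col_min"].astype(float),
                        grp["height"].astype(float),
                        grp["width"].astype(float),
                    )
                ),
            )
    return out


def write_annotations(
    annotations: Iterable[PointAnnotation] | Iterable[BoxAnnotation],
    path: str | Path,
) -> None:
    """Write annotations back to CSV, preserving record order within an image."""
    rows: list[dict] = []
    kind = None
    for ann in annotations:
        if isinstance(ann, PointAnnotation):
            kind = "points"
            for r, c in ann.points:
                rows.append({"image_id": ann.image_id, "row": r, "col": c})
        else:
            kind = "boxes"
            for rm, cm, h, w in ann.boxes:
                rows.append(
                    {
                        "image_id": ann.image_id,
                        "row_min": rm,
                        "col_min": cm,
                        "height": h,
                        "width": w,
                    }
                )
    cols = _POINT_COLS if kind != "boxes" else _BOX_COLS
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def boxes_to_points(a: BoxAnnotation) -> PointAnnotation:
    """Convert boxes to their center points, (row_min + h/2, col_min + w/2)."""
    pts = [(rm + h / 2.0, cm + w / 2.0) for rm, cm, h, w in a.boxes]
    return PointAnnotation(a.image_id, pts)


def spawn_rng(seed: int, *keys: int) -> np.random.Generator:
    """Derive a child generator from a master seed and integer stream keys.

    All randomness in the package flows through this helper so one master
    seed makes an entire run reproducible.
    """
    return np.random.default_rng([seed, *keys])
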