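"""Pixel-sampling evaluation of the color-index filters.

To judge how well an index separates tassels from everything else, sample
pixels of known class (soil, shadow, foliage, tassel) are marked on copies
of the images with four pure marker colors, the index is evaluated on the
corresponding pixels of the unmarked originals, and the fraction of each
class eliminated is tabulated at every integer threshold from 0 to 256.
A good tassel filter shows a threshold band where soil, shadow and foliage
elimination is near 1 while tassel elimination stays low.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core_io import RgbImage
from .errors import ValidationError
from .indices import rescaled_index

__all__ = [
    "MARKER_COLORS",
    "PixelClassSample",
    "EliminationCurve",
    "extract_samples",
    "elimination_curve",
    "elimination_at",
]

#: Pure marker colors → class labels (the marking convention for sample images).
MARKER_COLORS: dict[str, tuple[int, int, int]] = {
    "soil": (0, 0, 255),
    "shadow": (0, 255, 0),
    "foliage": (255, 0, 0),
    "tassel": (255, 255, 0),
}

CLASS_LABELS = tuple(MARKER_COLORS)


@dataclasses.dataclass
class PixelClassSample:
    """Sampled pixel coordinates of one class in one image."""

    image_id: str
    class_label: str
    coords: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.coords)


@dataclasses.dataclass
class EliminationCurve:
    """Per-class elimination fractions at integer thresholds 0…256.

    ``per_class[label][t]`` is the fraction of that class's sampled pixels
    whose rescaled index score is strictly below ``t``; every curve is
    non-decreasing, 0 at threshold 0 and 1 at threshold 256.
    """

    index_name: str
    per_class: dict[str, np.ndarray]
    sample_sizes: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "index_name": self.index_name,
            "thresholds": list(range(257)),
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
            "sample_sizes": self.sample_sizes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EliminationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            d["index_name"],
            {k: np.asarray(v, dtype=float) for k, v in d["per_class"].items()},
            {k: int(v) for k, v in d["sample_sizes"].items()},
        )


def extract_samples(
    marked: RgbImage, original: RgbImage, tolerance: int = 0
) -> list[PixelClassSample]:
    """Find marker-colored pixels in ``marked`` and return their coordinates.

    Matching is exact by default; ``tolerance`` allows a per-channel slack
    for hand-marked data. Pixels matching no marker color are ignored.
    Classes must be disjoint: with a non-zero tolerance, a pixel matching
    two marker colors is an annotation error.
    """
    if marked.shape != original.shape:
        raise ValidationError(
            f"marked image shape {marked.shape} != original shape {original.shape}"
        )
    px = marked.pixels.astype(np.int16)
    claimed = np.zeros(marked.shape, dtype=bool)
    samples = []
    for label, color in MARKER_COLORS.items():
        match = (np.abs(px - np.array(color, dtype=np.int16)) <= tolerance).all(axis=2)
        if (match & claimed).any():
            raise ValidationError(
                "overlapping marker classes at a coordinate (increase separation "
                "or reduce tolerance)"
            )
        claimed |= match
        rows, cols = np.nonzero(match)
        samples.append(
            PixelClassSample(
                original.image_id, label, list(zip(rows.tolist(), cols.tolist()))
            )
        )
    return samples


def elimination_curve(
    samples: list[PixelClassSample], original: RgbImage, index_name: str
) -> EliminationCurve:
    """Tabulate elimination fractions at all 257 integer thresholds 0…256.

    A class's fraction at threshold ``t`` is the share of its sampled pixels
    whose rescaled index value is < t (those the filter would eliminate).
    Classes with zero sampled pixels are absent from the result.
    """
    ridx = rescaled_index(original, index_name)
    h, w = original.shape
    per_class: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    thresholds = np.arange(257, dtype=float)
    for s in samples:
        if len(s) == 0:
            continue
        rows = np.array([rc[0] for rc in s.coords])
        cols = np.array([rc[1] for rc in s.coords])
        if rows.min() < 0 or rows.max() >= h or cols.min() < 0 or cols.max() >= w:
            raise ValidationError(f"sample coordinates outside {h}×{w} image")
        vals = ridx.values[rows, cols]
        # fraction of values strictly below each integer threshold
        per_class[s.class_label] = (
            vals[None, :] < thresholds[:, None]
        ).mean(axis=1)
        sizes[s.class_label] = len(s)
    return EliminationCurve(index_name, per_class, sizes)


def elimination_at(curve: EliminationCurve, threshold: int) -> dict[str, float]:
    """Per-class elimination fraction at one threshold (the single-threshold
    summary used to justify a filter setting)."""
    if not 0 <= threshold <= 256:
        raise ValidationError(f"threshold {threshold} outside [0, 256]")
    return {k: float(v[threshold]) for k, v in curve.per_class.items()}
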