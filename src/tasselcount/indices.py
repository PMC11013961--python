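"""Vegetation color indices and the two-step tassel filter.

The filter isolates maize tassel pixels in plot-level RGB imagery in two
thresholding passes on channel-normalized values (R*, G*, B* = R/255 …):

1. the Excess Green index ``ExG = 2G* − R* − B*`` removes non-foliage
   elements (soil, shadow), which score low on greenness;
2. a tassel index ``(2(G* + R*))² − B*`` removes foliage, scoring high for
   yellowish pixels (high red and green, low blue) typical of tassels.

Each index is linearly rescaled from its fixed theoretical range onto
[0, 255] so that a single integer threshold is meaningful across an entire
image set; a pixel is eliminated whenever its rescaled score falls below
the threshold, and eliminated pixels are blacked out.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import NormalizedChannels, RgbImage
from .errors import ConfigurationError, ValidationError

__all__ = [
    "INDEX_RANGES",
    "IndexMap",
    "RescaledIndexMap",
    "BinaryMask",
    "FilterResult",
    "normalize",
    "excess_green",
    "excess_red",
    "tassel_index",
    "compute_index",
    "rescale",
    "rescaled_index",
    "threshold_mask",
    "two_step_filter",
]

#: Theoretical (min, max) of each raw index over the 8-bit RGB cube. The
#: rescaling maps these endpoints to 0 and 255 exactly, independent of the
#: image, so thresholds transfer across images.
INDEX_RANGES: dict[str, tuple[float, float]] = {
    "exg": (-2.0, 2.0),
    "exr": (-1.0, 1.4),
    "tassel": (-1.0, 16.0),
    # Alternative reading of the tassel formula, (2G* + R*)² − B*.
    "tassel_compact": (-1.0, 9.0),
}


@dataclasses.dataclass
class IndexMap:
    """Raw per-pixel index scores plus the name of the index that produced them."""

    values: np.ndarray
    index_name: str


@dataclasses.dataclass
class RescaledIndexMap:
    """Index scores linearly mapped onto [0, 255]; kept floating-point."""

    values: np.ndarray
    index_name: str


@dataclasses.dataclass
class BinaryMask:
    """Per-pixel survival flags (True = pixel survives the filter)."""

    keep: np.ndarray


@dataclasses.dataclass
class FilterResult:
    """Output of :func:`two_step_filter`, with both masks kept for audit."""

    filtered: RgbImage
    step1_mask: BinaryMask
    step2_mask: BinaryMask
    thresholds: tuple[float, float]


def normalize(img: RgbImage) -> NormalizedChannels:
    """Split an 8-bit image into channel-normalized rasters R*, G*, B* in [0, 1]."""
    px = img.pixels.astype(np.float64) / 255.0
    return NormalizedChannels(px[:, :, 0], px[:, :, 1], px[:, :, 2])


def excess_green(nc: NormalizedChannels) -> IndexMap:
    """Excess Green index, ``2G* − R* − B*``; high for green vegetation."""
    return IndexMap(2.0 * nc.g_star - nc.r_star - nc.b_star, "exg")


def excess_red(nc: NormalizedChannels) -> IndexMap:
    """Excess Red index, ``1.4R* − G*``; sensitive to reddish/yellowish pixels."""
    return IndexMap(1.4 * nc.r_star - nc.g_star, "exr")


def tassel_index(nc: NormalizedChannels, variant: str = "prose") -> IndexMap:
    """Tassel index, high for yellowish pixels (high R and G, low B).

    ``variant="prose"`` (default) computes ``(2(G* + R*))² − B*``: the red
    and green values are combined, doubled, and the result squared.
    ``variant="compact"`` computes the alternative reading
    ``(2G* + R*)² − B*``; both are exposed so they can be compared.
    """
    if variant == "prose":
        return IndexMap((2.0 * (nc.g_star + nc.r_star)) ** 2 - nc.b_star, "tassel")
    if variant == "compact":
        return IndexMap(
            (2.0 * nc.g_star + nc.r_star) ** 2 - nc.b_star, "tassel_compact"
        )
    raise ConfigurationError(f"unknown tassel-index variant {variant!r}")


def compute_index(nc: NormalizedChannels, index_name: str) -> IndexMap:
    """Compute a registered index by name ({exg, exr, tassel, tassel_compact})."""
    if index_name == "exg":
        return excess_green(nc)
    if index_name == "exr":
        return excess_red(nc)
    if index_name == "tassel":
        return tassel_index(nc, "prose")
    if index_name == "tassel_compact":
        return tassel_index(nc, "compact")
    raise ConfigurationError(f"unknown index name {index_name!r}")


def rescale(idx: IndexMap) -> RescaledIndexMap:
    """Map an index's fixed theoretical range linearly onto [0, 255].

    The mapping is image-independent (see :data:`INDEX_RANGES`), strictly
    monotone, and maps the range endpoints to 0 and 255 exactly.
    """
    if idx.index_name not in INDEX_RANGES:
        raise ConfigurationError(
            f"no registered theoretical range for index {idx.index_name!r}"
        )
    lo, hi = INDEX_RANGES[idx.index_name]
    return RescaledIndexMap((idx.values - lo) / (hi - lo) * 255.0, idx.index_name)


def rescaled_index(img: RgbImage, index_name: str) -> RescaledIndexMap:
    """Convenience: normalize → index → rescale in one call."""
    return rescale(compute_index(normalize(img), index_name))


def threshold_mask(ridx: RescaledIndexMap, threshold: float) -> BinaryMask:
    """Survival mask at a threshold: a pixel is eliminated iff its rescaled
    score is strictly less than the threshold (score >= threshold survives)."""
    if not 0.0 <= threshold <= 256.0:
        raise ValidationError(f"threshold {threshold} outside [0, 256]")
    return BinaryMask(ridx.values >= threshold)


def two_step_filter(
    img: RgbImage,
    exg_threshold: float = 131.0,
    tassel_threshold: float = 90.0,
    variant: str = "prose",
) -> FilterResult:
    """Apply the two-part tassel filter and black out eliminated pixels.

    Step 1 thresholds the rescaled ExG (default 131, the value found to
    best remove soil and shadow while sparing foliage and tassels); step 2
    thresholds the rescaled tassel index. Step-2 scores are computed from
    the original pixel colors, so the two masks are independent and the
    surviving set is exactly their intersection.
    """
    nc = normalize(img)
    step1 = threshold_mask(rescale(excess_green(nc)), exg_threshold)
    step2 = threshold_mask(rescale(tassel_index(nc, variant)), tassel_threshold)
    keep = step1.keep & step2.keep
    out = img.pixels.copy()
    out[~keep] = 0
    return FilterResult(
        RgbImage(out, image_id=img.image_id),
        step1,
        step2,
        (float(exg_threshold), float(tassel_threshold)),
    )
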