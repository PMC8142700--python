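"""Per-object color summaries: mean, White Point, most saturated/frequent, difference maps."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .colorspace import ColorImage, RegionMask, ciede2000

__all__ = [
    "SummaryColor",
    "DiffMap",
    "mean_lab_color",
    "white_point",
    "most_saturated",
    "most_frequent",
    "ciede_map",
]


@dataclass(frozen=True)
class SummaryColor:
    lab: np.ndarray
    statistic: str
    n_pixels_used: int

    def __post_init__(self):
        object.__setattr__(self, "lab", np.asarray(self.lab, dtype=float))
        if self.n_pixels_used < 1:
            raise ValueError("a summary color must use at least one pixel")


@dataclass(frozen=True)
class DiffMap:
    """Companion image: original color within threshold, dimmed gray otherwise."""

    data: np.ndarray
    threshold: float
    reference: np.ndarray
    colored: np.ndarray  # boolean mask of pixels that kept their color


def _lab_pixels(img: ColorImage, mask: RegionMask) -> np.ndarray:
    if img.space != "LAB":
        raise ValueError(f"expected a LAB image, got {img.space}")
    mask.require_nonempty()
    return img.pixels(mask)


def _top_k(n: int, fraction: float) -> int:
    """Selection size for fraction-based picks: ceil(fraction * n), minimum 1."""
    return max(1, math.ceil(fraction * n))


def mean_lab_color(img: ColorImage, mask: RegionMask) -> SummaryColor:
    """Component-wise mean of LAB values over the mask.

    This is deliberately the mean IN LAB space, not the colorimetric mean
    of linear values converted afterwards.
    """
    px = _lab_pixels(img, mask)
    return SummaryColor(px.mean(axis=0), "mean", px.shape[0])


def white_point(
    img: ColorImage,
    mask: RegionMask,
    highlights: RegionMask | None = None,
    top_fraction: float = 0.05,
) -> SummaryColor:
    """Mean LAB of the brightest ``top_fraction`` of pixels, highlights excluded.

    Brightness is ranked by L*.
    """
    region = mask if highlights is None else mask.minus(highlights)
    px = _lab_pixels(img, region)
    k = _top_k(px.shape[0], top_fraction)
    order = np.argsort(px[:, 0], kind="stable")
    chosen = px[order[-k:]]
    return SummaryColor(chosen.mean(axis=0), "white_point", k)


def most_saturated(
    img: ColorImage,
    mask: RegionMask,
    highlights: RegionMask | None = None,
    L_min: float = 1.0,
    L_max: float = 85.0,
    top_fraction: float = 0.05,
) -> SummaryColor:
    """Mean LAB of the most saturated pixels.

    Saturation score: chroma distance from the achromatic axis divided by
    lightness, ``sqrt(a*^2 + b*^2) / L*``. Pixels with ``L* < L_min``
    (dark, division blow-up) or ``L* > L_max`` (excessively bright, e.g.
    highlight spill) are excluded, as are highlight-mask pixels.
    """
    region = mask if highlights is None else mask.minus(highlights)
    px = _lab_pixels(img, region)
    in_window = (px[:, 0] >= L_min) & (px[:, 0] <= L_max)
    survivors = px[in_window]
    if survivors.shape[0] == 0:
        n_dark = int((px[:, 0] < L_min).sum())
        n_bright = int((px[:, 0] > L_max).sum())
        raise ValueError(
            "no pixels survive the filters: "
            f"{n_dark} below L*={L_min}, {n_bright} above L*={L_max}, "
            f"{px.shape[0]} in region after highlight exclusion"
        )
    score = np.hypot(survivors[:, 1], survivors[:, 2]) / survivors[:, 0]
    k = _top_k(survivors.shape[0], top_fraction)
    order = np.argsort(score, kind="stable")
    chosen = survivors[order[-k:]]
    return SummaryColor(chosen.mean(axis=0), "most_saturated", k)


def most_frequent(
    img: ColorImage,
    mask: RegionMask,
    highlights: RegionMask | None = None,
    box_size: float = 1.0,
) -> SummaryColor:
    """Center of the most populated cube of a box partition of the LAB cloud.

    The axis-aligned bounding box of the cloud is partitioned into cubes of
    side ``box_size`` anchored at the minimum corner (a final partial cube
    covers any remainder). Ties break to the lexicographically lowest cube
    origin.
    """
    if box_size <= 0:
        raise ValueError("box_size must be positive")
    region = mask if highlights is None else mask.minus(highlights)
    px = _lab_pixels(img, region)
    lo = px.min(axis=0)
    idx = np.floor((px - lo) / box_size).astype(np.int64)
    # points exactly on the upper face of the last full cube belong to it
    n_boxes = np.maximum(1, np.ceil((px.max(axis=0) - lo) / box_size).astype(np.int64))
    idx = np.minimum(idx, n_boxes - 1)

    keys, counts = np.unique(idx, axis=0, return_counts=True)
    # np.unique sorts keys lexicographically; argmax takes the first maximum,
    # which is the lowest cube origin among ties.
    winner = keys[np.argmax(counts)]
    center = lo + (winner + 0.5) * box_size
    return SummaryColor(center, "most_frequent", int(counts.max()))


def ciede_map(
    rgb_img: ColorImage,
    lab_img: ColorImage,
    mask: RegionMask,
    reference: np.ndarray,
    threshold: float = 15.0,
    dim: float = 1.5,
) -> DiffMap:
    """Companion image showing which pixels are close to a reference color.

    Starts all black. Masked pixels within ``threshold`` CIEDE2000 units of
    ``reference`` keep their original RGB value; the remaining masked
    pixels become a dimmed grayscale,
    ``(0.299 R + 0.587 G + 0.114 B) / dim`` replicated across channels.
    """
    if rgb_img.space != "linearRGB":
        raise ValueError(f"expected a linearRGB image, got {rgb_img.space}")
    if lab_img.space != "LAB":
        raise ValueError(f"expected a LAB companion image, got {lab_img.space}")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    reference = np.asarray(reference, dtype=float)
    m = mask.data
    if m.shape != rgb_img.shape:
        raise ValueError("mask shape does not match image")

    out = np.zeros_like(rgb_img.data)
    dist = ciede2000(lab_img.data[m], reference)
    passed = np.asarray(dist) <= threshold

    masked_rgb = rgb_img.data[m]
    gray = (
        0.299 * masked_rgb[:, 0] + 0.587 * masked_rgb[:, 1] + 0.114 * masked_rgb[:, 2]
    ) / dim
    vals = np.where(passed[:, None], masked_rgb, np.repeat(gray[:, None], 3, axis=1))
    out[m] = vals

    colored = np.zeros(m.shape, dtype=bool)
    colored[m] = passed
    return DiffMap(data=out, threshold=float(threshold), reference=reference, colored=colored)
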