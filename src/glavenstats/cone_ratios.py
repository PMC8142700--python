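"""Region-ratio statistics: RMC, RSD, and the robust ratio estimator.

The statistics compare the cone-excitation distribution of a filtered
region (pixels seen through a transparent object) to that of the
unfiltered remainder of the scene, per cone class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import ColorImage, MonitorCalibration, RegionMask

__all__ = [
    "ConeRatioTriplet",
    "RobustRatioEstimate",
    "rmc",
    "rsd",
    "estimate_illuminant",
    "robust_ratio",
    "dark_pixel_mask",
    "find_best_matching_filter",
]

_CHANNELS = ("L", "M", "S")


@dataclass(frozen=True)
class ConeRatioTriplet:
    """Per-cone-class ratio of a filtered-region statistic to the unfiltered one."""

    ratio_L: float
    ratio_M: float
    ratio_S: float
    statistic: str  # "RMC" | "RSD"

    def as_array(self) -> np.ndarray:
        return np.array([self.ratio_L, self.ratio_M, self.ratio_S])


@dataclass(frozen=True)
class RobustRatioEstimate:
    """Three-component filter color code tau with its intermediate quantities."""

    tau: np.ndarray
    u: float
    v: float
    delta: float
    msd_channel: int
    illuminant_estimate: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.asarray(self.tau)


def _region_pixels(img: ColorImage, mask: RegionMask) -> np.ndarray:
    if img.space != "LMS":
        raise ValueError(f"cone-ratio statistics need an LMS image, got {img.space}")
    mask.require_nonempty()
    if mask.data.shape != img.shape:
        raise ValueError("mask shape does not match image")
    return img.pixels(mask)


def _std(x: np.ndarray, ddof: int) -> np.ndarray:
    return np.std(x, axis=0, ddof=ddof)


def rmc(
    img: ColorImage,
    filtered: RegionMask,
    unfiltered: RegionMask,
) -> ConeRatioTriplet:
    """Ratio of mean cone excitations, filtered region in the numerator."""
    P = _region_pixels(img, filtered)
    A = _region_pixels(img, unfiltered)
    mean_A = A.mean(axis=0)
    for i, ch in enumerate(_CHANNELS):
        if mean_A[i] == 0:
            raise ZeroDivisionError(f"unfiltered mean is zero in cone class {ch}")
    r = P.mean(axis=0) / mean_A
    return ConeRatioTriplet(*map(float, r), statistic="RMC")


def rsd(
    img: ColorImage,
    filtered: RegionMask,
    unfiltered: RegionMask,
    ddof: int = 0,
) -> ConeRatioTriplet:
    """Ratio of standard deviations of cone excitations (values > 1 are legal).

    ``ddof=0`` is the population form (the pinned default); pass ``ddof=1``
    for the sample form.
    """
    P = _region_pixels(img, filtered)
    A = _region_pixels(img, unfiltered)
    std_A = _std(A, ddof)
    for i, ch in enumerate(_CHANNELS):
        if std_A[i] == 0:
            raise ZeroDivisionError(
                f"unfiltered standard deviation is zero in cone class {ch}"
            )
    r = _std(P, ddof) / std_A
    return ConeRatioTriplet(*map(float, r), statistic="RSD")


def estimate_illuminant(img: ColorImage, unfiltered: RegionMask) -> np.ndarray:
    """Illuminant estimate: mean LMS of the unfiltered background pixels."""
    return _region_pixels(img, unfiltered).mean(axis=0)


def robust_ratio(
    img: ColorImage,
    filtered: RegionMask,
    unfiltered: RegionMask,
    illuminant="estimate",
    ddof: int = 0,
) -> RobustRatioEstimate:
    """Robust three-component filter color code tau.

    In the cone class with the largest background standard deviation (MSD):

    * ``tau_MSD = std(P_MSD) / std(A_MSD)``
    * ``u = mean(P_MSD) - tau_MSD * mean(A_MSD)``
    * ``v = (tau_MSD + u) * I_MSD`` and ``delta = u / v``

    then for every cone class

    * ``tau_i = (mean(P_i) - u * delta * I_i) / (mean(A_i) + delta * I_i)``

    which reproduces ``tau_MSD`` exactly in the MSD channel. ``illuminant``
    is the LMS triplet ``I``; the default ``"estimate"`` uses the mean of
    the unfiltered background.
    """
    P = _region_pixels(img, filtered)
    A = _region_pixels(img, unfiltered)
    if isinstance(illuminant, str):
        if illuminant != "estimate":
            raise ValueError("illuminant must be an LMS triplet or 'estimate'")
        I = A.mean(axis=0)
    else:
        I = np.asarray(illuminant, dtype=float)

    std_A = _std(A, ddof)
    msd = int(np.argmax(std_A))
    if std_A[msd] == 0:
        raise ZeroDivisionError("background is constant in every cone class")

    tau_msd = float(_std(P, ddof)[msd] / std_A[msd])
    u = float(P[:, msd].mean() - tau_msd * A[:, msd].mean())
    v = float((tau_msd + u) * I[msd])
    if v == 0:
        raise ZeroDivisionError("degenerate estimate: v = (tau_MSD + u) * I_MSD is zero")
    delta = u / v

    mean_P = P.mean(axis=0)
    mean_A = A.mean(axis=0)
    tau = (mean_P - u * delta * I) / (mean_A + delta * I)
    return RobustRatioEstimate(
        tau=tau,
        u=u,
        v=v,
        delta=delta,
        msd_channel=msd,
        illuminant_estimate=I,
    )


def _luminance(img: ColorImage, cal: MonitorCalibration | None) -> np.ndarray:
    """Per-pixel luminance-like channel used for dark-pixel thresholds."""
    if img.space == "linearRGB":
        if cal is None:
            raise ValueError("linearRGB luminance needs a monitor calibration")
        ymat = cal.rgb_to_xyz_matrix()[1]  # Y row
        return img.data @ ymat
    if img.space == "XYZ":
        return img.data[..., 1]
    if img.space == "LMS":
        return img.data.sum(axis=-1)
    if img.space == "LAB":
        return img.data[..., 0]
    if img.space == "MBDKL":
        return img.data[..., 2]
    raise ValueError(f"no luminance channel defined for space {img.space}")


def dark_pixel_mask(
    img: ColorImage,
    object_mask: RegionMask,
    highlights: RegionMask | None = None,
    fraction: float = 0.05,
    cal: MonitorCalibration | None = None,
) -> RegionMask:
    """Mask of object pixels to EXCLUDE as too dark.

    A pixel is excluded when its luminance is below ``fraction`` times the
    maximum luminance over the object, where that maximum is computed with
    specular highlights removed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    object_mask.require_nonempty()
    lum = _luminance(img, cal)
    ref_region = object_mask.data
    if highlights is not None:
        ref_region = ref_region & ~highlights.data
    if not ref_region.any():
        raise ValueError("object region is entirely inside the highlight mask")
    threshold = fraction * lum[ref_region].max()
    dark = object_mask.data & (lum < threshold)
    return RegionMask(dark, label="dark")


def find_best_matching_filter(
    target,
    render_element,
    thickness_grid,
    nmx_grid,
    nmy_grid,
    statistic_fn,
):
    """Exhaustive search of the flat-filter gamut for the closest statistic.

    ``render_element(thickness, nmx, nmy)`` must render the matching
    element and ``statistic_fn(rendered)`` must return a length-3 vector of
    the statistic for it. Returns ``(params, achieved, distance)`` where
    ``params`` is the (Thickness, NMX, NMY) triple minimizing Euclidean
    distance to ``target``; ties break to the first triple in lexicographic
    grid order.
    """
    target = np.asarray(
        target.as_array() if hasattr(target, "as_array") else target, dtype=float
    )
    thickness_grid = list(thickness_grid)
    nmx_grid = list(nmx_grid)
    nmy_grid = list(nmy_grid)
    if not thickness_grid or not nmx_grid or not nmy_grid:
        raise ValueError("search grid must be non-empty on every axis")

    best = None
    for th in thickness_grid:
        for nx in nmx_grid:
            for ny in nmy_grid:
                try:
                    stat = np.asarray(statistic_fn(render_element(th, nx, ny)), float)
                except Exception as exc:  # pragma: no cover - propagated with context
                    raise RuntimeError(
                        f"flat-filter generator failed at "
                        f"(Thickness={th}, NMX={nx}, NMY={ny})"
                    ) from exc
                dist = float(np.linalg.norm(stat - target))
                if best is None or dist < best[2]:
                    best = ((th, nx, ny), stat, dist)
    return best
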