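"""Synthetic filtered-scene generation with ground truth.

Emulates the statistical structure of rendered glass-object stimuli
without a physically based renderer: variegated Voronoi backgrounds built
from spectral reflectances, a blob-shaped "object" region whose colors are
either an exact affine transform of the background or a spectral
transmission filter perturbed by specular highlights, caustics, shadows
and refraction-like displacement. Every generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import colorspace as cs
from .colorspace import ColorImage, RegionMask, Spectrum

__all__ = [
    "EffectSettings",
    "SceneSpec",
    "SyntheticScene",
    "FilterParams",
    "default_grid",
    "munsell_standin_bases",
    "flat_filter_bases",
    "flat_illuminant",
    "voronoi_background",
    "mix_transmission",
    "filter_transmission",
    "mix_illuminants",
    "blob_mask",
    "simulate_affine_scene",
    "simulate_glass_scene",
    "render_flat_filter",
]

#: Default spectral sampling: 47 equally spaced bands over 360-830 nm.
N_BANDS = 47
GRID_LO, GRID_HI = 360.0, 830.0


def default_grid() -> np.ndarray:
    return np.linspace(GRID_LO, GRID_HI, N_BANDS)


def _bump(grid: np.ndarray, mu: float, sigma: float, amp: float = 0.85, base: float = 0.04):
    return np.clip(base + amp * np.exp(-0.5 * ((grid - mu) / sigma) ** 2), 0.0, 1.0)


def munsell_standin_bases(grid: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Smooth stand-in reflectance/transmission bumps peaking in R/G/B/Y.

    These substitute for external measured chip databases; users may
    supply measured chips as Spectrum CSVs anywhere a base is accepted.
    """
    if grid is None:
        grid = default_grid()
    return {
        "red": Spectrum(grid, _bump(grid, 620.0, 45.0)),
        "green": Spectrum(grid, _bump(grid, 530.0, 40.0)),
        "blue": Spectrum(grid, _bump(grid, 460.0, 35.0)),
        "yellow": Spectrum(grid, _bump(grid, 575.0, 50.0)),
    }


def flat_filter_bases(grid: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Transmission-axis endpoint bases, normalized so each maximum is 1."""
    bases = munsell_standin_bases(grid)
    return {
        name: Spectrum(s.wavelengths_nm, s.values / s.values.max())
        for name, s in bases.items()
    }


def flat_illuminant(value: float = 1.0, grid: np.ndarray | None = None) -> Spectrum:
    if grid is None:
        grid = default_grid()
    return Spectrum(grid, np.full(grid.shape, float(value)))


# ---------------------------------------------------------------------------
# Spec / result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSettings:
    """Nonlinear perturbations applied by the glass simulator."""

    specular_fraction: float = 0.01
    specular_tint: float = 0.5
    specular_gain: float = 0.3
    caustic_gain: float = 0.5
    shadow_gain: float = 0.6
    refraction_magnitude: float = 2.0
    passes: int = 2
    body_variation: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.specular_fraction <= 0.05:
            raise ValueError("specular_fraction must be in [0, 0.05]")
        if not 0.0 <= self.specular_tint <= 1.0:
            raise ValueError("specular_tint must be in [0, 1]")
        for name in ("specular_gain", "caustic_gain", "shadow_gain",
                     "refraction_magnitude", "body_variation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")

    @classmethod
    def none(cls, passes: int = 1) -> "EffectSettings":
        """All effects switched off (perfectly clean filtering)."""
        return cls(
            specular_fraction=0.0,
            specular_tint=0.0,
            specular_gain=0.0,
            caustic_gain=0.0,
            shadow_gain=1.0,
            refraction_magnitude=0.0,
            passes=passes,
            body_variation=0.0,
        )


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to regenerate a synthetic scene bit-identically."""

    size: tuple[int, int] = (96, 96)
    background: str = "voronoi"  # voronoi | achromatic_voronoi | grating | uniform
    palette: str = "none"  # red | green | blue | yellow | none
    n_sites: int = 40
    seed: int = 0
    illuminant: Spectrum | None = None
    transmission: Spectrum | None = None
    effects: EffectSettings = field(default_factory=EffectSettings)

    def __post_init__(self):
        h, w = self.size
        if h < 16 or w < 16:
            raise ValueError("scene size must be at least 16 x 16")
        if self.background not in ("voronoi", "achromatic_voronoi", "grating", "uniform"):
            raise ValueError(f"unknown background kind {self.background!r}")
        if self.palette not in ("red", "green", "blue", "yellow", "none"):
            raise ValueError(f"unknown palette bias {self.palette!r}")

    def with_effects(self, **kwargs) -> "SceneSpec":
        return replace(self, effects=replace(self.effects, **kwargs))


@dataclass
class SyntheticScene:
    unfiltered: ColorImage
    filtered: ColorImage
    masks: dict[str, RegionMask]
    truth: dict


@dataclass(frozen=True)
class FilterParams:
    """Flat-filter matching-element parameters.

    NMX = NMY = 0 is the top-left of the notional screen, 1 the bottom-right.
    """

    thickness: float
    nmx: float
    nmy: float

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("Thickness must be > 0")
        if not (0.0 <= self.nmx <= 1.0 and 0.0 <= self.nmy <= 1.0):
            raise ValueError("NMX and NMY must be in [0, 1]")


# ---------------------------------------------------------------------------
# Spectral mixing
# ---------------------------------------------------------------------------


def _common_grid(spectra) -> np.ndarray:
    grids = [s.wavelengths_nm for s in spectra]
    g0 = grids[0]
    for g in grids[1:]:
        if g.shape != g0.shape or not np.allclose(g, g0):
            raise ValueError("spectra must share a common wavelength grid")
    return g0


def mix_transmission(
    alpha_rg: float,
    alpha_by: float,
    ld_scale: float,
    bases: dict[str, Spectrum] | None = None,
) -> tuple[Spectrum, float]:
    """Two-axis linear combination of R/G/B/Y transmission bases.

    ``0.5 * ld_scale * ((a_RG * D_red + (1 - a_RG) * D_green)
    + (a_BY * D_blue + (1 - a_BY) * D_yellow))``, clipped to [0, 1].
    Returns ``(spectrum, clip_fraction)``.
    """
    if bases is None:
        bases = munsell_standin_bases()
    grid = _common_grid(list(bases.values()))
    raw = 0.5 * ld_scale * (
        (alpha_rg * bases["red"].values + (1 - alpha_rg) * bases["green"].values)
        + (alpha_by * bases["blue"].values + (1 - alpha_by) * bases["yellow"].values)
    )
    clipped = np.clip(raw, 0.0, 1.0)
    clip_fraction = float(np.mean(clipped != raw))
    return Spectrum(grid, clipped), clip_fraction


def filter_transmission(
    params: FilterParams,
    bases: dict[str, Spectrum] | None = None,
) -> tuple[Spectrum, float]:
    """Observer-controlled flat-filter transmission.

    ``Thickness * ((NMX * RF + (1 - NMX) * GF) + (NMY * BF + (1 - NMY) * YF))``
    with max-normalized bases, clipped to [0, 1]. The Thickness factor
    multiplies the sum of both axis mixtures (the reading under which
    circular parameter paths traverse all hues). Returns
    ``(spectrum, clip_fraction)``.
    """
    if bases is None:
        bases = flat_filter_bases()
    grid = _common_grid(list(bases.values()))
    raw = params.thickness * (
        (params.nmx * bases["red"].values + (1 - params.nmx) * bases["green"].values)
        + (params.nmy * bases["blue"].values + (1 - params.nmy) * bases["yellow"].values)
    )
    clipped = np.clip(raw, 0.0, 1.0)
    clip_fraction = float(np.mean(clipped != raw))
    return Spectrum(grid, clipped), clip_fraction


def mix_illuminants(
    spd_a: Spectrum,
    spd_b: Spectrum,
    w: float = 0.7,
    prescale: float = 0.5,
) -> Spectrum:
    """Desaturating illuminant mix: prescale both, then ``w a + (1 - w) b``."""
    grid = _common_grid([spd_a, spd_b])
    vals = prescale * (w * spd_a.values + (1 - w) * spd_b.values)
    return Spectrum(grid, vals)


# ---------------------------------------------------------------------------
# Backgrounds
# ---------------------------------------------------------------------------


def _voronoi_cells(size, n_sites, rng) -> np.ndarray:
    """Nearest-site tessellation cell indices (H x W of site ids)."""
    h, w = size
    sites = np.column_stack([rng.uniform(0, h, n_sites), rng.uniform(0, w, n_sites)])
    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    d2 = ((pts[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(h, w)


_PALETTE_BIAS = {
    "red": np.array([1.0, 0.35, 0.35]),
    "green": np.array([0.35, 1.0, 0.35]),
    "blue": np.array([0.35, 0.45, 1.0]),
    "yellow": np.array([1.0, 0.95, 0.35]),
    "none": np.array([1.0, 1.0, 1.0]),
}


def voronoi_background(
    size,
    n_sites: int,
    palette: str = "none",
    achromatic: bool = False,
    seed: int = 0,
) -> ColorImage:
    """Seeded nearest-site tessellation with per-cell random colors.

    ``achromatic=True`` emits R = G = B per cell (shades of gray).
    Deterministic given the seed.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 Voronoi sites")
    rng = np.random.default_rng(seed)
    cells = _voronoi_cells(size, n_sites, rng)
    if achromatic:
        grays = rng.uniform(0.15, 0.9, n_sites)
        colors = np.repeat(grays[:, None], 3, axis=1)
    else:
        bias = _PALETTE_BIAS[palette]
        colors = rng.uniform(0.1, 0.95, (n_sites, 3)) * bias
        colors = np.clip(colors, 0.0, 1.0)
    return ColorImage(colors[cells], "linearRGB")


def _cell_reflectances(background: str, palette: str, n_sites: int, rng,
                       grid: np.ndarray) -> np.ndarray:
    """Per-cell reflectance spectra (n_sites x n_bands) in [0, 1]."""
    bases = munsell_standin_bases(grid)
    basis = np.stack([bases[k].values for k in ("red", "green", "blue", "yellow")])
    if background == "uniform":
        gray = rng.uniform(0.4, 0.7)
        return np.full((n_sites, grid.size), gray)
    if background in ("achromatic_voronoi", "grating"):
        grays = rng.uniform(0.15, 0.9, n_sites)
        if background == "grating":
            # alternating light/dark stripes rather than random cell grays
            grays = np.where(np.arange(n_sites) % 2 == 0, 0.75, 0.25)
        return np.repeat(grays[:, None], grid.size, axis=1)
    weights = rng.uniform(0.0, 1.0, (n_sites, 4))
    if palette != "none":
        k = ("red", "green", "blue", "yellow").index(palette)
        weights[:, k] += 1.0
    weights /= weights.sum(axis=1, keepdims=True)
    gray_floor = rng.uniform(0.05, 0.25, n_sites)
    refl = gray_floor[:, None] + 0.9 * weights @ basis
    return np.clip(refl, 0.0, 1.0)


def blob_mask(size, rng=None, scale: float = 0.62, wobble: float = 0.18,
              seed: int | None = None) -> RegionMask:
    """Seeded superellipse blob with perturbed boundary (object silhouette)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = size
    cy, cx = h / 2.0, w / 2.0
    ry, rx = scale * h / 2.0, scale * w / 2.0
    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    theta = np.arctan2(yy - cy, xx - cx)
    # low-order Fourier boundary perturbation
    amps = rng.uniform(-wobble, wobble, 3)
    phases = rng.uniform(0, 2 * np.pi, 3)
    pert = 1.0 + sum(a * np.cos((k + 2) * theta + p)
                     for k, (a, p) in enumerate(zip(amps, phases)))
    r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    return RegionMask(r <= pert, label="object")


def _smooth_field(size, rng, n_modes: int = 3) -> np.ndarray:
    """Smooth seeded random field in roughly [-1, 1] (sum of low-freq sinusoids)."""
    h, w = size
    yy, xx = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    out = np.zeros((h, w))
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.5, 3.0, 2)
        py, px = rng.uniform(0, 2 * np.pi, 2)
        out += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * fy * yy + py) * np.sin(
            2 * np.pi * fx * xx + px
        )
    m = np.max(np.abs(out))
    return out / m if m > 0 else out


# ---------------------------------------------------------------------------
# Scene simulators
# ---------------------------------------------------------------------------


def simulate_affine_scene(
    background: ColorImage,
    object_mask: RegionMask,
    M: np.ndarray | None = None,
    beta: float | None = None,
    t: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Oracle scene: the filtered region is an exact affine map of the background."""
    d = background.data.shape[2]
    if t is None:
        t = np.zeros(d)
    t = np.asarray(t, dtype=float)
    rng = np.random.default_rng(seed)
    filtered = background.data.copy()
    px = background.data[object_mask.data]
    if M is not None:
        M = np.asarray(M, dtype=float)
        out = px @ M.T + t
    elif beta is not None:
        out = beta * px + t
    else:
        M = np.eye(d)
        out = px + t
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, out.shape)
    filtered[object_mask.data] = out
    h, w = background.shape
    empty = RegionMask(np.zeros((h, w), bool))
    return SyntheticScene(
        unfiltered=background,
        filtered=ColorImage(filtered, background.space),
        masks={
            "object": object_mask,
            "highlight": RegionMask(empty.data.copy(), "highlight"),
            "caustic": RegionMask(empty.data.copy(), "caustic"),
            "shadow": RegionMask(empty.data.copy(), "shadow"),
        },
        truth={"M": M, "beta": beta, "t": t, "noise_sigma": noise_sigma, "seed": seed},
    )


def _lms_matrix_and_inverse():
    cal = cs.default_calibration()
    m = cal.rgb_to_lms_matrix()
    return cal, m, np.linalg.inv(m)


def simulate_glass_scene(spec: SceneSpec, sensors=None) -> SyntheticScene:
    """Spectrally filtered scene with optional nonlinear glass effects.

    The background is a Voronoi tessellation of reflectance spectra under
    the spec's illuminant. Inside the object mask, the light reaching the
    eye is filtered by ``transmission ** (passes * e(x, y))`` where ``e``
    is a smooth seeded path-length exponent field (body-color variation),
    sampled through a smooth displacement field (refraction emulation).
    Specular highlight, caustic and shadow pixels are perturbed as recorded
    in the masks. Images are returned in linear RGB of the default
    calibration; ground truth carries the generating parameters.
    """
    if sensors is None:
        sensors = cs.cone_fundamentals()
    eff = spec.effects
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    grid = default_grid()
    dlam = float(np.mean(np.diff(grid)))

    illum = (spec.illuminant or flat_illuminant(1.0)).resample(grid)
    trans = (spec.transmission or mix_transmission(0.8, 0.3, 1.0)[0]).resample(grid)
    sensor_mat = np.stack([s.resample(grid).values for s in sensors], axis=1)  # bands x 3

    if spec.background == "grating":
        # vertical sinusoid-period stripes indexed like cells
        _, w_ = spec.size
        period = max(2, w_ // max(spec.n_sites, 2))
        col_band = (np.arange(w_) // period) % spec.n_sites
        cells = np.tile(col_band, (spec.size[0], 1))
    else:
        cells = _voronoi_cells(spec.size, spec.n_sites, rng)
    refl = _cell_reflectances(spec.background, spec.palette, spec.n_sites, rng, grid)

    # unfiltered image: per-cell spectral integration
    cell_lms = (refl * illum.values) @ sensor_mat * dlam  # n_sites x 3
    unfiltered_lms = cell_lms[cells]

    object_mask = blob_mask(spec.size, rng=rng)
    obj = object_mask.data

    # refraction-like displacement of the background seen through the glass
    if eff.refraction_magnitude > 0:
        dy = eff.refraction_magnitude * _smooth_field(spec.size, rng)
        dx = eff.refraction_magnitude * _smooth_field(spec.size, rng)
    else:
        dy = dx = np.zeros(spec.size)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    src_y = np.clip(np.rint(yy + dy).astype(int), 0, h - 1)
    src_x = np.clip(np.rint(xx + dx).astype(int), 0, w - 1)
    src_cells = cells[src_y, src_x]

    # per-pixel optical path-length exponent
    if eff.body_variation > 0:
        exponent = eff.passes * (1.0 + eff.body_variation * _smooth_field(spec.size, rng))
    else:
        exponent = np.full(spec.size, float(eff.passes))

    filtered_lms = unfiltered_lms.copy()
    obj_idx = np.nonzero(obj)
    refl_src = refl[src_cells[obj_idx]]  # n_obj x bands
    t_pow = np.power(trans.values[None, :], exponent[obj_idx][:, None])
    filtered_lms[obj_idx] = (refl_src * illum.values * t_pow) @ sensor_mat * dlam

    # masks for the nonlinear effects
    empty = np.zeros(spec.size, dtype=bool)
    highlight = empty.copy()
    caustic = empty.copy()
    shadow = empty.copy()

    illum_lms = spectrum_lms(illum, sensor_mat, dlam)
    tint_lms = spectrum_lms(
        Spectrum(grid, trans.values * illum.values), sensor_mat, dlam
    )
    tint_dir = tint_lms / max(tint_lms.max(), 1e-12)

    if eff.specular_fraction > 0 and obj.any():
        area = obj.sum()
        r_hl = max(1.0, np.sqrt(eff.specular_fraction * area / np.pi))
        ys, xs = np.nonzero(obj)
        # top-right quadrant of the object
        cy = np.quantile(ys, 0.25)
        cx = np.quantile(xs, 0.75)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_hl**2
        highlight = disk & obj
        if highlight.any():
            spec_color = (
                1 - eff.specular_tint
            ) * illum_lms + eff.specular_tint * tint_lms
            filtered_lms[highlight] += eff.specular_gain * spec_color

    if eff.caustic_gain > 0 and obj.any():
        ys, xs = np.nonzero(obj)
        cy = min(h - 1, np.quantile(ys, 0.95) + 0.06 * h)
        cx = np.median(xs)
        ell = ((yy - cy) / (0.08 * h)) ** 2 + ((xx - cx) / (0.2 * w)) ** 2 <= 1.0
        caustic = ell & ~obj
        filtered_lms[caustic] *= (1.0 + eff.caustic_gain * tint_dir)[None, :]

    if eff.shadow_gain != 1.0 and obj.any():
        ys, xs = np.nonzero(obj)
        cy = min(h - 1, np.quantile(ys, 0.9) + 0.1 * h)
        cx = np.clip(np.median(xs) - 0.15 * w, 0, w - 1)
        ell = ((yy - cy) / (0.12 * h)) ** 2 + ((xx - cx) / (0.25 * w)) ** 2 <= 1.0
        shadow = ell & ~obj & ~caustic
        filtered_lms[shadow] *= eff.shadow_gain

    cal, lms_mat, lms_inv = _lms_matrix_and_inverse()
    unfiltered = ColorImage(unfiltered_lms @ lms_inv.T, "linearRGB")
    filtered = ColorImage(filtered_lms @ lms_inv.T, "linearRGB")

    return SyntheticScene(
        unfiltered=unfiltered,
        filtered=filtered,
        masks={
            "object": object_mask,
            "highlight": RegionMask(highlight, "highlight"),
            "caustic": RegionMask(caustic, "caustic"),
            "shadow": RegionMask(shadow, "shadow"),
        },
        truth={
            "spec": spec,
            "transmission": trans,
            "illuminant": illum,
            "displacement_max": float(np.max(np.hypot(dy, dx))),
            "exponent_range": (float(exponent.min()), float(exponent.max())),
            "unfiltered_lms": unfiltered_lms,
            "filtered_lms": filtered_lms,
        },
    )


def spectrum_lms(spd: Spectrum, sensor_mat: np.ndarray, dlam: float) -> np.ndarray:
    return spd.values @ sensor_mat * dlam


def render_flat_filter(
    background: ColorImage,
    transmission: Spectrum,
    illuminant: Spectrum | None = None,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
    passes: int = 2,
    sensors=None,
    out_space: str = "LMS",
) -> tuple[ColorImage, RegionMask]:
    """Flat transparent filter over an achromatic background (simplified model).

    Inside a centered disk each pixel's gray reflectance is filtered by
    ``transmission ** passes`` under the illuminant; outside it is lit
    directly. This is a declared simplification of the full published
    flat-filter formula. Returns the image (LMS or linearRGB) and the disk
    mask.
    """
    if background.space != "linearRGB":
        raise ValueError("flat-filter background must be linearRGB")
    data = background.data
    if not np.allclose(data[..., 0], data[..., 1]) or not np.allclose(
        data[..., 1], data[..., 2]
    ):
        raise ValueError("flat-filter background must be achromatic (R = G = B)")
    if sensors is None:
        sensors = cs.cone_fundamentals()
    h, w = background.shape
    if center is None:
        center = (h / 2.0, w / 2.0)
    if radius is None:
        radius = 0.3 * min(h, w)
    cy, cx = center
    if not (0 <= cy < h and 0 <= cx < w) or radius <= 0:
        raise ValueError("disk must lie within the image")

    grid = default_grid()
    dlam = float(np.mean(np.diff(grid)))
    illum = (illuminant or flat_illuminant(1.0)).resample(grid)
    trans = transmission.resample(grid)
    sensor_mat = np.stack([s.resample(grid).values for s in sensors], axis=1)

    k_open = spectrum_lms(illum, sensor_mat, dlam)
    k_filt = spectrum_lms(
        Spectrum(grid, illum.values * trans.values**passes), sensor_mat, dlam
    )

    yy, xx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    gray = data[..., 0]
    lms = gray[..., None] * np.where(disk[..., None], k_filt, k_open)

    if out_space == "LMS":
        img = ColorImage(lms, "LMS")
    elif out_space == "linearRGB":
        _, _, lms_inv = _lms_matrix_and_inverse()
        img = ColorImage(lms @ lms_inv.T, "linearRGB")
    else:
        raise ValueError("out_space must be 'LMS' or 'linearRGB'")
    return img, RegionMask(disk, label="filter")
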