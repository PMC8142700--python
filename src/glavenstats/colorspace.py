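"""Calibrated color-space conversions.

Conversions among linear RGB, CIE XYZ, CIELAB, LMS cone excitations, and a
differential opponent (MB-DKL style) representation, plus the CIEDE2000
color difference and spectral integration against sensor curves.

All image-level conversions are pixel-wise and vectorized; the common
currency is :class:`ColorImage`, an ``H x W x 3`` float array tagged with
its color space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "SPACES",
    "Spectrum",
    "MonitorCalibration",
    "ColorImage",
    "RegionMask",
    "calibration_to_matrix",
    "rgb_to_xyz",
    "xyz_to_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "ciede2000",
    "rgb_to_lms",
    "lms_to_mbdkl",
    "project_isoluminant",
    "spectrum_to_tristimulus",
    "cone_fundamentals",
    "cie1931_cmfs",
    "default_calibration",
]

SPACES = ("linearRGB", "XYZ", "LMS", "MBDKL", "LAB")

#: CIELAB branch point delta = 6/29.
_LAB_DELTA = 6.0 / 29.0


class CalibrationError(ValueError):
    """Invalid or degenerate monitor calibration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """Non-negative values on an explicit, strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be equal-length 1-D vectors")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def resample(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto ``grid``, zero outside the support."""
        grid = np.asarray(grid, dtype=float)
        vals = np.interp(grid, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        return Spectrum(grid, vals)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.values * factor)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        """Read a two-column (wavelength_nm, value) CSV; header optional."""
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.replace(";", ",").split(",")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue  # header line
        arr = np.array(rows)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("wavelength_nm,value\n")
            for w, v in zip(self.wavelengths_nm, self.values):
                fh.write(f"{w:.6g},{v:.10g}\n")


@dataclass
class MonitorCalibration:
    """Monitor primaries: xyY chromaticity/luminance and/or emission spectra.

    The reference white is the sum of the three primaries at maximum drive.
    ``gamma`` is the decoding gamma applied to 8/16-bit integer images.
    """

    primaries_xyY: np.ndarray | None = None  # 3 x (x, y, Y)
    primary_spectra: tuple[Spectrum, Spectrum, Spectrum] | None = None
    gamma: float = 2.2
    lms_matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.primaries_xyY is None and self.primary_spectra is None:
            raise CalibrationError("need primaries_xyY or primary_spectra")
        if self.primaries_xyY is not None:
            p = np.asarray(self.primaries_xyY, dtype=float)
            if p.shape != (3, 3):
                raise CalibrationError("primaries_xyY must be 3x3 rows of (x, y, Y)")
            if np.any(p[:, 1] <= 0):
                raise CalibrationError("primary chromaticity y must be > 0")
            self.primaries_xyY = p

    # -- derived matrices ---------------------------------------------------

    def rgb_to_xyz_matrix(self) -> np.ndarray:
        return calibration_to_matrix(self)

    def white_xyz(self) -> np.ndarray:
        return self.rgb_to_xyz_matrix() @ np.ones(3)

    def rgb_to_lms_matrix(self, fundamentals=None, normalize: bool = True) -> np.ndarray:
        """3x3 matrix whose column i is the LMS excitation of primary i at max.

        Requires primary emission spectra or a precomputed ``lms_matrix``.
        ``fundamentals`` defaults to the bundled cone curves; ``normalize``
        rescales them so an equal-energy unit-intensity stimulus maps to
        (1, 1, 1).
        """
        if self.lms_matrix is not None:
            return np.asarray(self.lms_matrix, dtype=float)
        if self.primary_spectra is None:
            raise CalibrationError(
                "LMS conversion needs primary emission spectra or an lms_matrix"
            )
        if fundamentals is None:
            fundamentals = cone_fundamentals(normalize=normalize)
        cols = [
            spectrum_to_tristimulus(spd, fundamentals)
            for spd in self.primary_spectra
        ]
        return np.column_stack(cols)

    @classmethod
    def from_json(cls, path) -> "MonitorCalibration":
        """Load ``{primaries: [{x,y,Y} x3], gamma}`` or ``{primary_spectra: paths, gamma}``."""
        blob = json.loads(Path(path).read_text())
        gamma = float(blob.get("gamma", 2.2))
        if "primaries" in blob:
            prim = np.array([[p["x"], p["y"], p["Y"]] for p in blob["primaries"]])
            spectra = None
        else:
            prim = None
            spectra = None
        if "primary_spectra" in blob:
            base = Path(path).parent
            spectra = tuple(
                Spectrum.from_csv(base / p) for p in blob["primary_spectra"]
            )
        return cls(primaries_xyY=prim, primary_spectra=spectra, gamma=gamma)


@dataclass
class ColorImage:
    """``H x W x 3`` real image tagged with its color space."""

    data: np.ndarray
    space: str

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] != 3 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("ColorImage data must be H x W x 3 with H, W >= 1")
        if not np.all(np.isfinite(data)):
            raise ValueError("ColorImage entries must be finite")
        if self.space not in SPACES:
            raise ValueError(f"unknown color space {self.space!r}; expected one of {SPACES}")
        self.data = data

    @property
    def shape(self):
        return self.data.shape[:2]

    @property
    def is_hdr(self) -> bool:
        """True when a nominally-[0, 1] linearRGB image carries values > 1."""
        return self.space == "linearRGB" and bool(np.any(self.data > 1.0))

    def pixels(self, mask: "RegionMask | np.ndarray | None" = None) -> np.ndarray:
        """Masked pixels as an N x 3 array (all pixels when mask is None)."""
        if mask is None:
            return self.data.reshape(-1, 3)
        m = mask.data if isinstance(mask, RegionMask) else np.asarray(mask, bool)
        return self.data[m]


@dataclass
class RegionMask:
    """Boolean ``H x W`` pixel selector."""

    data: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("RegionMask data must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self):
        if not self.data.any():
            raise ValueError(f"mask {self.label!r} selects no pixels")
        return self

    def __and__(self, other):
        return RegionMask(self.data & _mask_data(other), self.label)

    def __or__(self, other):
        return RegionMask(self.data | _mask_data(other), self.label)

    def minus(self, other) -> "RegionMask":
        return RegionMask(self.data & ~_mask_data(other), self.label)

    def complement(self, border: int = 0) -> "RegionMask":
        """Everything outside this mask, optionally shrunk by a border margin."""
        out = ~self.data
        if border > 0:
            out = out.copy()
            out[:border, :] = False
            out[-border:, :] = False
            out[:, :border] = False
            out[:, -border:] = False
        return RegionMask(out, label=f"not-{self.label}")


def _mask_data(m) -> np.ndarray:
    return m.data if isinstance(m, RegionMask) else np.asarray(m, bool)


# ---------------------------------------------------------------------------
# Bundled sensor curves
# ---------------------------------------------------------------------------


def _load_table(name: str) -> np.ndarray:
    with resources.files("glavenstats.data").joinpath(name).open() as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


def cie1931_cmfs() -> tuple[Spectrum, Spectrum, Spectrum]:
    """Bundled CIE 1931 2-degree color matching functions (x̄, ȳ, z̄)."""
    tab = _load_table("cmf_cie1931_2deg.csv")
    return tuple(Spectrum(tab[:, 0], tab[:, i]) for i in (1, 2, 3))


def cone_fundamentals(normalize: bool = True) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Bundled L/M/S sensitivity curves.

    With ``normalize=True`` (the default analysis convention) each curve is
    rescaled so that an equal-energy stimulus of unit intensity produces a
    response of exactly 1, i.e. ``sum(curve) * dlambda == 1``. Raw curves
    are available with ``normalize=False``.
    """
    tab = _load_table("cone_fundamentals_2deg.csv")
    wl = tab[:, 0]
    out = []
    for i in (1, 2, 3):
        vals = tab[:, i]
        if normalize:
            dlam = np.mean(np.diff(wl))
            vals = vals / (vals.sum() * dlam)
        out.append(Spectrum(wl, vals))
    return tuple(out)


#: Eizo ColorEdge CG245W phosphor xyY values (measurement-grade reference
#: primaries used as the package default calibration).
EIZO_PRIMARIES_XYY = np.array(
    [
        [0.6733, 0.3088, 37.223],
        [0.2103, 0.6869, 86.659],
        [0.1564, 0.0554, 7.9206],
    ]
)


def default_calibration() -> MonitorCalibration:
    """Default calibration: Eizo xyY primaries plus stand-in emission spectra.

    The emission spectra are smooth single-peak curves scaled so each
    primary's Y matches the measured phosphor luminance; they stand in for
    unpublished measured spectra so that LMS conversion is possible
    out of the box. Users with measured spectra should load their own
    calibration JSON instead.
    """
    grid = np.arange(380.0, 741.0, 5.0)
    peaks = (610.0, 545.0, 465.0)
    widths = (28.0, 35.0, 22.0)
    _, ybar, _ = cie1931_cmfs()
    spectra = []
    for (x, y, Y), mu, sig in zip(EIZO_PRIMARIES_XYY, peaks, widths):
        vals = np.exp(-0.5 * ((grid - mu) / sig) ** 2)
        spd = Spectrum(grid, vals)
        # scale so the spectrum's photometric Y equals the measured phosphor Y
        got_Y = spectrum_to_tristimulus(spd, (ybar, ybar, ybar))[0]
        spectra.append(spd.scaled(Y / got_Y))
    return MonitorCalibration(
        primaries_xyY=EIZO_PRIMARIES_XYY.copy(),
        primary_spectra=tuple(spectra),
        gamma=2.2,
    )


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------


def calibration_to_matrix(cal: MonitorCalibration) -> np.ndarray:
    """3x3 linear RGB -> XYZ matrix from the calibration.

    Column i is the XYZ of primary i at maximum drive: ``X = x Y / y``,
    ``Y = Y``, ``Z = (1 - x - y) Y / y``; hence ``matrix @ (1, 1, 1)`` is
    the reference white.
    """
    if cal.primaries_xyY is None:
        # derive from primary emission spectra and the CMFs
        cmfs = cie1931_cmfs()
        cols = [spectrum_to_tristimulus(spd, cmfs) for spd in cal.primary_spectra]
        mat = np.column_stack(cols)
    else:
        p = cal.primaries_xyY
        if np.any(p[:, 1] <= 0):
            raise CalibrationError("primary chromaticity y must be > 0")
        x, y, Y = p[:, 0], p[:, 1], p[:, 2]
        mat = np.column_stack([np.array([xi * Yi / yi, Yi, (1 - xi - yi) * Yi / yi])
                               for xi, yi, Yi in zip(x, y, Y)])
    if abs(np.linalg.det(mat)) < 1e-12:
        raise CalibrationError("degenerate primaries: RGB->XYZ matrix is singular")
    return mat


def _apply_matrix(img: np.ndarray, mat: np.ndarray) -> np.ndarray:
    return img @ mat.T


def rgb_to_xyz(img: ColorImage, cal: MonitorCalibration) -> ColorImage:
    if img.space != "linearRGB":
        raise ValueError(f"expected linearRGB input, got {img.space}")
    return ColorImage(_apply_matrix(img.data, calibration_to_matrix(cal)), "XYZ")


def xyz_to_rgb(img: ColorImage, cal: MonitorCalibration) -> ColorImage:
    if img.space != "XYZ":
        raise ValueError(f"expected XYZ input, got {img.space}")
    inv = np.linalg.inv(calibration_to_matrix(cal))
    return ColorImage(_apply_matrix(img.data, inv), "linearRGB")


def _lab_f(t: np.ndarray) -> np.ndarray:
    d = _LAB_DELTA
    t = np.asarray(t, dtype=float)
    return np.where(t > d**3, np.cbrt(t), t / (3 * d**2) + 4.0 / 29.0)


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    d = _LAB_DELTA
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > d, ft**3, 3 * d**2 * (ft - 4.0 / 29.0))


def xyz_to_lab(img: ColorImage, white: np.ndarray) -> ColorImage:
    """CIELAB from XYZ relative to the reference white ``(Xn, Yn, Zn)``."""
    if img.space != "XYZ":
        raise ValueError(f"expected XYZ input, got {img.space}")
    white = np.asarray(white, dtype=float)
    if white.shape != (3,) or np.any(white <= 0):
        raise ValueError("reference white must be a strictly positive XYZ triplet")
    fx = _lab_f(img.data[..., 0] / white[0])
    fy = _lab_f(img.data[..., 1] / white[1])
    fz = _lab_f(img.data[..., 2] / white[2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return ColorImage(np.stack([L, a, b], axis=-1), "LAB")


def lab_to_xyz(img: ColorImage, white: np.ndarray) -> ColorImage:
    if img.space != "LAB":
        raise ValueError(f"expected LAB input, got {img.space}")
    white = np.asarray(white, dtype=float)
    L, a, b = img.data[..., 0], img.data[..., 1], img.data[..., 2]
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    xyz = np.stack(
        [white[0] * _lab_f_inv(fx), white[1] * _lab_f_inv(fy), white[2] * _lab_f_inv(fz)],
        axis=-1,
    )
    return ColorImage(xyz, "XYZ")


def rgb_to_lab(img: ColorImage, cal: MonitorCalibration) -> ColorImage:
    """Linear RGB -> CIELAB with the monitor's maximum white as reference."""
    return xyz_to_lab(rgb_to_xyz(img, cal), cal.white_xyz())


def rgb_to_lms(
    img: ColorImage,
    cal: MonitorCalibration,
    fundamentals=None,
    normalize: bool = True,
) -> ColorImage:
    """LMS excitations as RGB-weighted sums of per-primary maximum excitations.

    For an RGB triplet (r, g, b) the excitation is
    ``L = r*L_R + g*L_G + b*L_B`` and analogously for M and S, where e.g.
    ``L_R`` is the L excitation of the red primary at maximum drive.
    """
    if img.space != "linearRGB":
        raise ValueError(f"expected linearRGB input, got {img.space}")
    mat = cal.rgb_to_lms_matrix(fundamentals=fundamentals, normalize=normalize)
    return ColorImage(_apply_matrix(img.data, mat), "LMS")


#: Opponent-axis matrix acting on (dL, dM, dS): rows are L-M, S-(L+M), L+M+S.
MBDKL_AXES = np.array(
    [
        [1.0, -1.0, 0.0],
        [-1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
    ]
)


def lms_to_mbdkl(
    img: ColorImage,
    background: np.ndarray,
    scale: str = "none",
) -> ColorImage:
    """Differential opponent coordinates relative to a background LMS.

    Axes: (dL - dM, dS - (dL + dM), dL + dM + dS) with d* = LMS - background.
    ``scale='none'`` leaves the axes un-rescaled (mechanism-null directions
    only); ``scale='unit_contrast'`` divides each cone difference by the
    background excitation (cone contrast) before forming the axes.
    """
    if img.space != "LMS":
        raise ValueError(f"expected LMS input, got {img.space}")
    background = np.asarray(background, dtype=float)
    if background.shape != (3,) or np.any(background <= 0):
        raise ValueError("background LMS must be a strictly positive triplet")
    diff = img.data - background
    if scale == "unit_contrast":
        diff = diff / background
    elif scale != "none":
        raise ValueError("scale must be 'none' or 'unit_contrast'")
    return ColorImage(_apply_matrix(diff, MBDKL_AXES), "MBDKL")


def project_isoluminant(img: ColorImage) -> np.ndarray:
    """Drop the light-dark component: MBDKL axis 3 or LAB L*.

    Returns an ``H x W x 2`` array of the retained chromatic components.
    """
    if img.space == "MBDKL":
        return img.data[..., :2].copy()
    if img.space == "LAB":
        return img.data[..., 1:].copy()
    raise ValueError(f"isoluminant projection needs MBDKL or LAB, got {img.space}")


def spectrum_to_tristimulus(spd: Spectrum, sensors, grid: np.ndarray | None = None) -> np.ndarray:
    """Integrate ``spd`` against three sensor curves: sum(spd * sensor) * dlambda.

    All spectra are resampled onto the common grid (linear interpolation,
    zero outside support). The default grid is the sensor grid of the first
    sensor restricted to... the union handled by zero-fill.
    """
    if grid is None:
        grid = sensors[0].wavelengths_nm
    grid = np.asarray(grid, dtype=float)
    lo = max(spd.wavelengths_nm[0], min(s.wavelengths_nm[0] for s in sensors))
    hi = min(spd.wavelengths_nm[-1], max(s.wavelengths_nm[-1] for s in sensors))
    if lo >= hi:
        raise ValueError("spectrum and sensors have no overlapping support")
    dlam = np.mean(np.diff(grid))
    spd_v = spd.resample(grid).values
    out = np.empty(3)
    for i, s in enumerate(sensors):
        out[i] = float(np.sum(spd_v * s.resample(grid).values) * dlam)
    return out


# ---------------------------------------------------------------------------
# CIEDE2000
# ---------------------------------------------------------------------------


def ciede2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 color difference (CIE 2001 recommendation, JND units).

    Accepts single LAB triplets or broadcastable ``... x 3`` arrays and is
    symmetric, non-negative, and zero exactly on identical inputs.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = np.moveaxis(lab1, -1, 0)
    L2, a2, b2 = np.moveaxis(lab2, -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where((C1p * C2p) == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        (C1p * C2p) == 0,
        hsum,
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / (kL * SL)) ** 2
        + (dCp / (kC * SC)) ** 2
        + (dHp / (kH * SH)) ** 2
        + RT * (dCp / (kC * SC)) * (dHp / (kH * SH))
    )
    if dE.ndim == 0:
        return float(dE)
    return dE
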