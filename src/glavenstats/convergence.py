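"""Affine convergence-model fitting scored by RRPE.

Fits the 12-parameter general affine map ``b = M a + t``, the 4-parameter
uniform-scaling map ``b = beta a + t``, and the constrained "over" operator
``b = a_coef * a + (1 - a_coef) * c_conv`` to unfiltered -> filtered color
pairs, and scores each fit by the relative reduction in prediction error
against the identity baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import colorspace as cs
from .colorspace import ColorImage, MonitorCalibration, RegionMask

__all__ = [
    "ColorPairSet",
    "AffineFit",
    "DegenerateBaselineError",
    "build_pairs",
    "fit_affine12",
    "fit_affine4",
    "fit_over",
    "rrpe",
    "converge_report",
]


class DegenerateBaselineError(ZeroDivisionError):
    """Identity-baseline RMSE is zero; RRPE is undefined."""


@dataclass
class ColorPairSet:
    """Paired unfiltered (a) and filtered (b) colors in a common space."""

    a: np.ndarray
    b: np.ndarray
    space: str

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 2 or b.shape != a.shape:
            raise ValueError("a and b must be equal-shape N x D arrays")
        if a.shape[1] not in (2, 3):
            raise ValueError("color dimension must be 2 or 3")
        if a.shape[0] < a.shape[1] + 1:
            raise ValueError("need at least D + 1 color pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("color pairs must be finite")
        self.a, self.b = a, b

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def dims(self) -> int:
        return self.a.shape[1]


@dataclass
class AffineFit:
    """A fitted convergence map with its error scores."""

    family: str  # "affine12" | "affine4" | "over"
    t: np.ndarray
    rmse_model: float
    rmse_identity: float
    rrpe: float
    space: str
    dims: int
    M: np.ndarray | None = None  # affine12
    beta: float | None = None  # affine4 / over
    c_conv: np.ndarray | None = None  # over
    representable: bool = True
    solver: str = "closed_form"
    extras: dict = field(default_factory=dict)

    def predict(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        if self.family == "affine12":
            return a @ self.M.T + self.t
        return self.beta * a + self.t


def _rmse(pred: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared Euclidean color error over pixels."""
    return float(np.sqrt(np.mean(np.sum((pred - b) ** 2, axis=1))))


def rrpe(rmse_model: float, rmse_identity: float) -> float:
    """Relative reduction in prediction error."""
    if rmse_identity <= 0:
        raise DegenerateBaselineError(
            "identity RMSE is zero (filtered == unfiltered); RRPE is undefined"
        )
    return (rmse_identity - rmse_model) / rmse_identity


def build_pairs(
    unfiltered: ColorImage,
    filtered: ColorImage,
    mask: RegionMask,
    space: str = "LMS",
    cal: MonitorCalibration | None = None,
    isoluminant: bool = False,
    exclude: list[RegionMask] | None = None,
    mbdkl_background: np.ndarray | None = None,
) -> ColorPairSet:
    """Extract pixel-paired colors from an image pair under one mask.

    Both images are converted to ``space`` (from linearRGB via the
    calibration when needed), optionally projected onto the isoluminant
    plane (D = 2), and excluded-region pixels are dropped. Pairs are in
    row-major scan order of the mask.
    """
    if unfiltered.shape != filtered.shape:
        raise ValueError("unfiltered and filtered images differ in size")
    eff = mask.data.copy()
    for ex in exclude or []:
        eff &= ~ex.data
    if not eff.any():
        raise ValueError("mask is empty after exclusions")

    def convert(img: ColorImage) -> ColorImage:
        if img.space == space:
            return img
        if img.space != "linearRGB":
            raise ValueError(
                f"cannot convert {img.space} -> {space}; provide linearRGB input"
            )
        if cal is None:
            raise ValueError("conversion from linearRGB requires a calibration")
        if space == "LMS":
            return cs.rgb_to_lms(img, cal)
        if space == "LAB":
            return cs.rgb_to_lab(img, cal)
        if space == "XYZ":
            return cs.rgb_to_xyz(img, cal)
        if space == "MBDKL":
            lms = cs.rgb_to_lms(img, cal)
            bg = mbdkl_background
            if bg is None:
                # mid-gray of the monitor as the adapting background
                bg = cs.rgb_to_lms(
                    ColorImage(np.full((1, 1, 3), 0.5), "linearRGB"), cal
                ).data[0, 0]
            return cs.lms_to_mbdkl(lms, bg)
        raise ValueError(f"unsupported space {space!r}")

    ua = convert(unfiltered)
    fb = convert(filtered)
    if isoluminant:
        a = cs.project_isoluminant(ua)[eff]
        b = cs.project_isoluminant(fb)[eff]
    else:
        a = ua.data[eff]
        b = fb.data[eff]
    return ColorPairSet(a=a, b=b, space=space)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def _closed_form_affine12(a: np.ndarray, b: np.ndarray):
    n, d = a.shape
    X = np.column_stack([a, np.ones(n)])
    centered = a - a.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < d:
        warnings.warn(
            "color matrix is rank-deficient after centering; "
            "returning the minimum-norm least-squares affine map",
            stacklevel=3,
        )
    coef, *_ = np.linalg.lstsq(X, b, rcond=None)
    M = coef[:d].T
    t = coef[d]
    return M, t


def _closed_form_affine4(a: np.ndarray, b: np.ndarray):
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = float(np.sum(ac * ac))
    if denom == 0:
        warnings.warn("constant unfiltered colors; scaling is unidentified", stacklevel=3)
        beta = 0.0
    else:
        beta = float(np.sum(ac * bc) / denom)
    t = b.mean(axis=0) - beta * a.mean(axis=0)
    return beta, t


def _simplex_affine(a, b, family: str, seed, restarts: int = 5, tol: float = 1e-9,
                    maxiter: int = 20000):
    """Seeded Nelder-Mead search mirroring the iterative-simplex procedure."""
    rng = np.random.default_rng(seed)
    n, d = a.shape

    if family == "affine12":
        def unpack(x):
            return x[: d * d].reshape(d, d), x[d * d:]

        def start():
            return np.concatenate(
                [(np.eye(d) + rng.uniform(-1, 1, (d, d))).ravel(), rng.uniform(-1, 1, d)]
            )
    else:
        def unpack(x):
            return float(x[0]), x[1:]

        def start():
            return np.concatenate([[1.0 + rng.uniform(-1, 1)], rng.uniform(-1, 1, d)])

    def objective(x):
        m, t = unpack(x)
        pred = a @ np.asarray(m).T + t if family == "affine12" else m * a + t
        return _rmse(pred, b)

    best = None
    for _ in range(restarts):
        res = minimize(
            objective,
            start(),
            method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x), float(best.fun)


def _finish(family, a, b, M, beta, t, space, solver, seed=None) -> AffineFit:
    pred = a @ M.T + t if family == "affine12" else beta * a + t
    rmse_model = _rmse(pred, b)
    rmse_identity = _rmse(a, b)
    score = rrpe(rmse_model, rmse_identity)
    return AffineFit(
        family=family,
        M=M,
        beta=beta,
        t=np.asarray(t, float),
        rmse_model=rmse_model,
        rmse_identity=rmse_identity,
        rrpe=score,
        space=space,
        dims=a.shape[1],
        solver=solver,
        extras={} if seed is None else {"seed": seed},
    )


def fit_affine12(pairs: ColorPairSet, solver: str = "closed_form", seed=None,
                 restarts: int = 5, maxiter: int = 20000) -> AffineFit:
    """Least-RMSE general affine map ``b = M a + t``.

    ``closed_form`` solves the least-squares problem exactly (global
    optimum); ``simplex`` reproduces the iterative simplex search from a
    seeded random start (5 restarts).
    """
    a, b = pairs.a, pairs.b
    if solver == "closed_form":
        M, t = _closed_form_affine12(a, b)
        return _finish("affine12", a, b, M, None, t, pairs.space, solver)
    if solver == "simplex":
        (M, t), _ = _simplex_affine(a, b, "affine12", seed, restarts=restarts,
                                    maxiter=maxiter)
        return _finish("affine12", a, b, np.asarray(M), None, t, pairs.space, solver, seed)
    raise ValueError("solver must be 'closed_form' or 'simplex'")


def fit_affine4(pairs: ColorPairSet, solver: str = "closed_form", seed=None,
                restarts: int = 5, maxiter: int = 20000) -> AffineFit:
    """Least-RMSE uniform-scaling map ``b = beta a + t`` (beta scalar)."""
    a, b = pairs.a, pairs.b
    if solver == "closed_form":
        beta, t = _closed_form_affine4(a, b)
        return _finish("affine4", a, b, None, beta, t, pairs.space, solver)
    if solver == "simplex":
        (beta, t), _ = _simplex_affine(a, b, "affine4", seed, restarts=restarts,
                                       maxiter=maxiter)
        return _finish("affine4", a, b, None, float(beta), t, pairs.space, solver, seed)
    raise ValueError("solver must be 'closed_form' or 'simplex'")


def fit_over(pairs: ColorPairSet, tolerance: float = 1e-9) -> AffineFit:
    """Constrained convex-mixture ("over") fit toward a convergence color.

    Solves the 4-parameter problem and reparameterizes:
    ``beta = a_coef`` and ``c_conv = t / (1 - beta)``. When
    ``|1 - beta| < tolerance`` the map is translation-only and has no
    finite convergence color; the fit is flagged non-representable.
    """
    base = fit_affine4(pairs)
    beta = base.beta
    representable = abs(1.0 - beta) >= tolerance
    c_conv = base.t / (1.0 - beta) if representable else None
    return AffineFit(
        family="over",
        beta=beta,
        t=base.t,
        c_conv=c_conv,
        rmse_model=base.rmse_model,
        rmse_identity=base.rmse_identity,
        rrpe=base.rrpe,
        space=base.space,
        dims=base.dims,
        representable=representable,
    )


# ---------------------------------------------------------------------------
# Full factorial report
# ---------------------------------------------------------------------------

_REPORT_SPACES = ("LMS", "MBDKL", "LAB")
_REPORT_FAMILIES = ("affine12", "affine4")


def converge_report(
    unfiltered: ColorImage,
    filtered: ColorImage,
    masks: dict,
    cal: MonitorCalibration,
    dark_fraction: float = 0.05,
    solver: str = "closed_form",
    seed=None,
) -> pd.DataFrame:
    """Fit the full factorial of convergence-model conditions.

    Cells: {LMS, MBDKL, LAB} x {affine12, affine4} x mask variant
    {full, no_highlight, no_specular} x {full-D, isoluminant} x dark-pixel
    exclusion {False, True}. Isoluminant cells are produced only for MBDKL
    and LAB. ``masks`` must contain ``object`` and may contain
    ``highlight`` and ``specular`` RegionMasks. Per-cell failures are
    recorded, not raised.
    """
    from .cone_ratios import dark_pixel_mask

    object_mask: RegionMask = masks["object"]
    variants = {"full": []}
    if "highlight" in masks and masks["highlight"] is not None:
        variants["no_highlight"] = [masks["highlight"]]
    if "specular" in masks and masks["specular"] is not None:
        variants["no_specular"] = [masks["specular"]]

    rows = []
    for space in _REPORT_SPACES:
        for mask_name, excl in variants.items():
            for exclude_dark in (False, True):
                exclusions = list(excl)
                if exclude_dark:
                    hl = masks.get("highlight")
                    # the luminance threshold lives on the filtered image
                    dark = dark_pixel_mask(
                        filtered,
                        object_mask,
                        highlights=hl,
                        fraction=dark_fraction,
                        cal=cal,
                    )
                    exclusions.append(dark)
                iso_options = (False,) if space == "LMS" else (False, True)
                for isoluminant in iso_options:
                    for family in _REPORT_FAMILIES:
                        row = {
                            "space": space,
                            "family": family,
                            "mask": mask_name,
                            "isoluminant": isoluminant,
                            "exclude_dark": exclude_dark,
                        }
                        try:
                            pairs = build_pairs(
                                unfiltered,
                                filtered,
                                object_mask,
                                space=space,
                                cal=cal,
                                isoluminant=isoluminant,
                                exclude=exclusions,
                            )
                            fit = (
                                fit_affine12(pairs, solver=solver, seed=seed)
                                if family == "affine12"
                                else fit_affine4(pairs, solver=solver, seed=seed)
                            )
                            row.update(
                                rrpe=fit.rrpe,
                                rmse_model=fit.rmse_model,
                                rmse_identity=fit.rmse_identity,
                                n_pairs=pairs.n,
                                failed=False,
                                error="",
                            )
                        except Exception as exc:
                            row.update(
                                rrpe=np.nan,
                                rmse_model=np.nan,
                                rmse_identity=np.nan,
                                n_pairs=0,
                                failed=True,
                                error=str(exc),
                            )
                        rows.append(row)
    return pd.DataFrame(rows)
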