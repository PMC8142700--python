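"""Color vector fields: grid interpolation, streamline tracing, convergence points.

The field connects each unfiltered pixel color (vector tail) to its
filtered counterpart (vector tip). For analysis the scattered one-to-many
samples are box-averaged onto a regular grid, 2-D projections of which can
be traced with fourth-order streamline integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import colorspace as cs
from .colorspace import ColorImage, MonitorCalibration, RegionMask

__all__ = [
    "VectorFieldSamples",
    "GridField",
    "Streamline",
    "build_field",
    "interpolate_field",
    "trace_streamlines",
    "affine_fixed_point",
    "field_convergence_point",
    "default_seeds",
]


@dataclass
class VectorFieldSamples:
    """Scattered (tail, tip) color pairs; tails index the pre-filter color."""

    tails: np.ndarray
    tips: np.ndarray
    space: str

    def __post_init__(self):
        tails = np.asarray(self.tails, dtype=float)
        tips = np.asarray(self.tips, dtype=float)
        if tails.ndim != 2 or tips.shape != tails.shape or tails.shape[1] not in (2, 3):
            raise ValueError("tails and tips must be equal-shape N x D arrays, D in {2, 3}")
        if not (np.all(np.isfinite(tails)) and np.all(np.isfinite(tips))):
            raise ValueError("field samples must be finite")
        self.tails, self.tips = tails, tips

    @property
    def vectors(self) -> np.ndarray:
        return self.tips - self.tails

    @property
    def dims(self) -> int:
        return self.tails.shape[1]

    def project(self, axes: tuple[int, int]) -> "VectorFieldSamples":
        """Project onto two coordinate axes (e.g. (0, 1) for the chromatic plane)."""
        i, j = axes
        return VectorFieldSamples(
            self.tails[:, [i, j]], self.tips[:, [i, j]], self.space
        )


@dataclass
class GridField:
    """Regular grid of box-averaged vectors; zero vector where a box is empty."""

    box_min: np.ndarray
    box_max: np.ndarray
    n_per_axis: int
    vectors: np.ndarray  # shape (n,)*D + (D,)
    counts: np.ndarray  # shape (n,)*D

    @property
    def dims(self) -> int:
        return self.box_min.shape[0]

    @property
    def step(self) -> np.ndarray:
        return (self.box_max - self.box_min) / (self.n_per_axis - 1)

    def grid_axes(self) -> list[np.ndarray]:
        return [
            np.linspace(self.box_min[d], self.box_max[d], self.n_per_axis)
            for d in range(self.dims)
        ]

    def project(self, axes: tuple[int, int]) -> "GridField":
        """Collapse to a 2-D field by averaging occupied cells along the other axes."""
        if self.dims == 2:
            if axes != (0, 1):
                raise ValueError("2-D field only supports axes (0, 1)")
            return self
        (i, j) = axes
        k = ({0, 1, 2} - {i, j}).pop()
        # move axes so (i, j) lead; weight by occupancy when collapsing axis k
        vec = np.moveaxis(self.vectors, (i, j, k), (0, 1, 2))[..., [i, j]]
        cnt = np.moveaxis(self.counts, (i, j, k), (0, 1, 2))
        w = cnt.astype(float)
        total = w.sum(axis=2)
        with np.errstate(invalid="ignore"):
            avg = np.where(
                total[..., None] > 0,
                (vec * w[..., None]).sum(axis=2) / np.where(total, total, 1)[..., None],
                0.0,
            )
        return GridField(
            box_min=self.box_min[[i, j]],
            box_max=self.box_max[[i, j]],
            n_per_axis=self.n_per_axis,
            vectors=avg,
            counts=total.astype(int),
        )


@dataclass
class Streamline:
    points: np.ndarray  # ordered list of 2-D points
    termination: str  # left_box | stagnation | max_steps


def build_field(
    unfiltered: ColorImage,
    filtered: ColorImage,
    mask: RegionMask,
    space: str = "MBDKL",
    cal: MonitorCalibration | None = None,
    mbdkl_background: np.ndarray | None = None,
) -> VectorFieldSamples:
    """One (tail, tip) sample per masked pixel, in the requested space.

    One-to-many structure is preserved: many pixels may share a tail color.
    """
    from .convergence import build_pairs

    pairs = build_pairs(
        unfiltered,
        filtered,
        mask,
        space=space,
        cal=cal,
        mbdkl_background=mbdkl_background,
    )
    return VectorFieldSamples(tails=pairs.a, tips=pairs.b, space=space)


def interpolate_field(
    samples: VectorFieldSamples,
    n_per_axis: int = 100,
    bin_by: str = "tail",
) -> GridField:
    """Box-average scattered vectors onto a regular grid.

    The bounding box spans the union of tails and tips. At each of
    ``n_per_axis`` equally spaced points per axis, vectors whose binning
    key falls inside the averaging box centered there (side length = grid
    step) are averaged component-wise; empty boxes store the zero vector.
    ``bin_by`` selects the key: ``"tail"`` (default), ``"tip"`` or
    ``"midpoint"``.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be at least 2")
    if bin_by == "tail":
        key = samples.tails
    elif bin_by == "tip":
        key = samples.tips
    elif bin_by == "midpoint":
        key = 0.5 * (samples.tails + samples.tips)
    else:
        raise ValueError("bin_by must be 'tail', 'tip' or 'midpoint'")

    cloud = np.vstack([samples.tails, samples.tips])
    box_min = cloud.min(axis=0)
    box_max = cloud.max(axis=0)
    degenerate = box_max - box_min <= 0
    if np.any(degenerate):
        warnings.warn("degenerate bounding box axis; padding by machine epsilon")
        pad = np.where(degenerate, np.maximum(np.abs(box_min) * 1e-9, 1e-12), 0.0)
        box_min = box_min - pad
        box_max = box_max + pad

    d = samples.dims
    step = (box_max - box_min) / (n_per_axis - 1)
    # averaging boxes of side `step` centered on grid points tile the box
    # exactly, so box membership == nearest grid point
    idx = np.rint((key - box_min) / step).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < n_per_axis), axis=1)
    idx = idx[inside]
    vecs = samples.vectors[inside]

    shape = (n_per_axis,) * d
    sums = np.zeros(shape + (d,))
    counts = np.zeros(shape, dtype=np.int64)
    flat = np.ravel_multi_index(tuple(idx.T), shape)
    np.add.at(counts.reshape(-1), flat, 1)
    for c in range(d):
        np.add.at(sums.reshape(-1, d)[:, c], flat, vecs[:, c])
    with np.errstate(invalid="ignore"):
        vectors = np.where(
            counts[..., None] > 0, sums / np.where(counts, counts, 1)[..., None], 0.0
        )
    return GridField(
        box_min=box_min,
        box_max=box_max,
        n_per_axis=n_per_axis,
        vectors=vectors,
        counts=counts,
    )


def _bilinear(field: GridField, p: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a 2-D grid field at points ``p`` (... x 2)."""
    u = (p - field.box_min) / field.step
    i0 = np.clip(np.floor(u).astype(int), 0, field.n_per_axis - 2)
    f = u - i0
    v = field.vectors
    fx, fy = f[..., 0:1], f[..., 1:2]
    return (
        v[i0[..., 0], i0[..., 1]] * (1 - fx) * (1 - fy)
        + v[i0[..., 0] + 1, i0[..., 1]] * fx * (1 - fy)
        + v[i0[..., 0], i0[..., 1] + 1] * (1 - fx) * fy
        + v[i0[..., 0] + 1, i0[..., 1] + 1] * fx * fy
    )


def default_seeds(field: GridField, per_axis: int = 8) -> np.ndarray:
    """Uniform lattice of seed points strictly inside the box."""
    axes = [
        np.linspace(field.box_min[d], field.box_max[d], per_axis + 2)[1:-1]
        for d in range(2)
    ]
    xx, yy = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


def trace_streamlines(
    field: GridField,
    seeds: np.ndarray | None = None,
    step: float | None = None,
    max_steps: int = 1000,
    stagnation_tol: float | None = None,
) -> list[Streamline]:
    """RK4 streamline integration of a 2-D grid field.

    Terminates on leaving the bounding box (``left_box``), when the local
    speed drops below ``stagnation_tol`` (``stagnation``), or after
    ``max_steps`` steps.
    """
    if field.dims != 2:
        raise ValueError("streamlines are traced on 2-D fields; project first")
    if seeds is None:
        seeds = default_seeds(field)
    if step is None:
        step = float(np.min(field.step)) * 0.5
    speeds = np.linalg.norm(field.vectors, axis=-1)
    vmax = float(speeds.max()) if speeds.max() > 0 else 1.0
    if stagnation_tol is None:
        stagnation_tol = 1e-6 * vmax
    # fixed parameter-time step: the fastest cell advances by `step` per
    # iteration and displacements shrink toward sinks, letting trajectories
    # settle instead of orbiting at constant arc length
    dt = step / vmax

    lo, hi = field.box_min, field.box_max
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = seeds.shape[0]

    # integrate all seeds simultaneously; freeze lines as they terminate
    pos = seeds.copy()
    active = np.all((pos >= lo) & (pos <= hi), axis=1)
    termination = np.where(active, "max_steps", "left_box").astype(object)
    trajectories: list[list[np.ndarray]] = [
        [pos[i].copy()] if active[i] else [] for i in range(n)
    ]

    for _ in range(max_steps):
        if not active.any():
            break
        p = pos[active]
        v1 = _bilinear(field, p)
        speed = np.linalg.norm(v1, axis=1)
        stalled = speed < stagnation_tol

        idx = np.flatnonzero(active)
        for i in idx[stalled]:
            termination[i] = "stagnation"
        active[idx[stalled]] = False
        if not np.any(~stalled):
            continue

        live = idx[~stalled]
        p = p[~stalled]
        v1 = v1[~stalled]
        h = dt
        k1 = v1
        k2 = _bilinear(field, p + 0.5 * h * k1)
        k3 = _bilinear(field, p + 0.5 * h * k2)
        k4 = _bilinear(field, p + h * k3)
        p_new = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

        outside = ~np.all((p_new >= lo) & (p_new <= hi), axis=1)
        for j, i in enumerate(live):
            if outside[j]:
                termination[i] = "left_box"
                active[i] = False
            else:
                pos[i] = p_new[j]
                trajectories[i].append(p_new[j].copy())

    return [
        Streamline(
            points=np.array(pts) if pts else np.empty((0, 2)),
            termination=str(termination[i]),
        )
        for i, pts in enumerate(trajectories)
    ]


def affine_fixed_point(fit) -> np.ndarray | None:
    """Closed-form convergence point of a fitted affine map, or None.

    affine12: solves ``(I - M) p = t``; affine4/over: ``p = t / (1 - beta)``.
    Returns None when the system is singular or the map is non-contracting
    (spectral radius >= 1).
    """
    if fit.family == "affine12":
        M = fit.M
        eye = np.eye(fit.dims)
        if np.max(np.abs(np.linalg.eigvals(M))) >= 1.0:
            return None
        try:
            return np.linalg.solve(eye - M, fit.t)
        except np.linalg.LinAlgError:
            return None
    if fit.family in ("affine4", "over"):
        beta = fit.beta
        if abs(beta) >= 1.0 or beta == 1.0:
            return None
        return fit.t / (1.0 - beta)
    raise ValueError(f"no fixed point defined for family {fit.family!r}")


def field_convergence_point(samples: VectorFieldSamples, min_speed: float = 0.0):
    """Model-free convergence point: least-squares intersection of vector lines.

    Minimizes the summed squared perpendicular distance from a point to the
    line through each tail along its vector direction. Returns
    ``(point, mean_residual)``.
    """
    vecs = samples.vectors
    norms = np.linalg.norm(vecs, axis=1)
    keep = norms > max(min_speed, 0.0)
    if keep.sum() < 2:
        raise ValueError("need at least two non-zero vectors")
    d = vecs[keep] / norms[keep, None]
    a = samples.tails[keep]
    dim = samples.dims

    # sum over lines of (I - d d^T)
    eye = np.eye(dim)
    proj = eye[None] - d[:, :, None] * d[:, None, :]
    A = proj.sum(axis=0)
    rhs = np.einsum("nij,nj->i", proj, a)
    if np.linalg.matrix_rank(A) < dim:
        raise np.linalg.LinAlgError("all vectors are parallel; intersection is undetermined")
    p = np.linalg.solve(A, rhs)

    resid = np.einsum("nij,nj->ni", proj, p - a)
    mean_residual = float(np.mean(np.linalg.norm(resid, axis=1)))
    return p, mean_residual
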