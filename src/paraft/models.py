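"""Sparse forward models mapping an image grid to sinogram samples.

Two discretizations of the 2-D circular-integration forward operator are
provided:

* ``dimmi`` - sample points uniformly in angle along each integration circle
  and distribute each point's arc element onto the four surrounding pixel
  centers by bilinear interpolation (piecewise-linear discretization; the
  dense angular sampling acts as an anti-aliasing filter at low resolution).
* ``cdmmi`` - treat each pixel as a constant-valued square cell and compute
  the exact arc length of the integration circle inside every cell it
  crosses, by solving for all crossings with the grid lines.

The assembled model is ``M = (1 / (2 pi v_s)) * D_t @ W`` where ``W`` holds
the (non-negative) arc weights and ``D_t`` is a per-detector temporal
central-difference stencil (one-sided at the record ends). Rows are indexed
detector-major, then time; images are flattened row-major (y, x).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .coords import CoordinateSystem, ScalarAxis, image_grid_vectors
from .datamodel import DetectorGeometry, ImageFrame

__all__ = [
    "ForwardModelMatrix",
    "SolverOptions",
    "build_arc_weights_dimmi",
    "build_arc_weights_cdmmi",
    "assemble_model",
    "apply",
    "apply_adjoint",
]


@dataclass(frozen=True)
class SolverOptions:
    max_iterations: int = 50
    tolerance: float = 1e-6
    regularization: float = 0.0
    regularizer: str = "none"

    def __post_init__(self):
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.regularization < 0:
            raise ValueError("regularization weight must be >= 0")
        if self.regularizer not in ("none", "tikhonov"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")
        if self.regularizer == "none" and self.regularization > 0:
            object.__setattr__(self, "regularizer", "tikhonov")


@dataclass(frozen=True)
class ForwardModelMatrix:
    matrix: sp.csr_matrix
    image_coords: CoordinateSystem
    geometry: DetectorGeometry
    time_axis: ScalarAxis
    kind: str
    params: dict = field(default_factory=dict)

    @property
    def image_shape(self):
        return self.image_coords.shape

    @property
    def data_shape(self):
        return (self.geometry.n_detectors, len(self.time_axis))

    @property
    def shape(self):
        return self.matrix.shape


def _grid_params(image_coords: CoordinateSystem):
    yc, xc = image_grid_vectors(image_coords)
    if len(xc) != len(yc):
        raise ValueError("only square grids are supported")
    n = len(xc)
    h = xc[1] - xc[0]
    half = n * h / 2.0
    return n, h, half, xc, yc


def build_arc_weights_dimmi(
    image_coords: CoordinateSystem,
    geometry: DetectorGeometry,
    time_axis: ScalarAxis,
    n_curve_samples: Optional[int] = None,
) -> sp.csr_matrix:
    """Curve-sampling arc weights with bilinear pixel interpolation.

    For each (detector, time) row the integration circle of radius v_s * t is
    clipped to the field of view, ``n_curve_samples`` points are spread
    uniformly in angle along the clipped arc, and each point contributes
    (in-FOV arc length / n_curve_samples) via bilinear weights of the four
    surrounding pixel centers (coordinates clamped to the pixel-center hull
    at the FOV edge, so total row weight equals the in-FOV arc length).
    Default n_curve_samples is 2 * max(Nx, Ny).
    """
    n, h, half, xc, yc = _grid_params(image_coords)
    if n_curve_samples is None:
        n_curve_samples = 2 * n
    if n_curve_samples < 8:
        raise ValueError("n_curve_samples must be >= 8")
    vs = geometry.speed_of_sound
    t = time_axis.values
    n_t = t.size
    npix = n * n
    c0 = xc[0]
    cmax = xc[-1]
    frac = (np.arange(n_curve_samples) + 0.5) / n_curve_samples

    blocks = []
    for d in range(geometry.n_detectors):
        xd, yd = geometry.positions[d]
        rows_out, cols_out, vals_out = [], [], []
        for k in range(n_t):
            rho = vs * t[k]
            if rho <= 0:
                continue
            theta = _fov_arc_angles(xd, yd, rho, half)
            if theta is None:
                continue
            starts, lengths = theta
            total = lengths.sum()
            if total <= 0:
                continue
            # uniform positions along the clipped arc, mapped into intervals
            s = frac * total
            cum = np.concatenate([[0.0], np.cumsum(lengths)])
            seg = np.searchsorted(cum, s, side="right") - 1
            ang = starts[seg] + (s - cum[seg])
            x = np.clip(xd + rho * np.cos(ang), c0, cmax)
            y = np.clip(yd + rho * np.sin(ang), c0, cmax)
            w = rho * total / n_curve_samples
            gx = (x - c0) / h
            gy = (y - c0) / h
            ix0 = np.minimum(gx.astype(np.int64), n - 2)
            iy0 = np.minimum(gy.astype(np.int64), n - 2)
            fx = gx - ix0
            fy = gy - iy0
            rows_out.append(np.full(4 * n_curve_samples, k, dtype=np.int64))
            cols_out.append(
                np.concatenate(
                    [
                        iy0 * n + ix0,
                        iy0 * n + ix0 + 1,
                        (iy0 + 1) * n + ix0,
                        (iy0 + 1) * n + ix0 + 1,
                    ]
                )
            )
            vals_out.append(
                w
                * np.concatenate(
                    [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
                )
            )
        if rows_out:
            block = sp.coo_matrix(
                (
                    np.concatenate(vals_out),
                    (np.concatenate(rows_out), np.concatenate(cols_out)),
                ),
                shape=(n_t, npix),
            ).tocsr()
            block.sum_duplicates()
        else:
            block = sp.csr_matrix((n_t, npix))
        blocks.append(block)
    return sp.vstack(blocks, format="csr")


def _fov_arc_angles(xd: float, yd: float, rho: float, half: float):
    """Angular intervals (starts, lengths) of the circle of radius rho about
    (xd, yd) that lie inside the square [-half, half]^2; None if empty."""
    th = []
    for e in (-half, half):
        u = (e - xd) / rho
        if abs(u) < 1.0:
            a = np.arccos(u)
            th.extend((a, -a))
        v = (e - yd) / rho
        if abs(v) < 1.0:
            b = np.arcsin(v)
            th.extend((b, np.pi - b))
    if not th:
        # no border crossings: circle entirely inside or outside the square
        if abs(xd + rho) < half and abs(xd) < half and abs(yd) < half:
            return np.array([-np.pi]), np.array([2.0 * np.pi])
        return None
    th = np.sort(np.mod(np.array(th) + np.pi, 2.0 * np.pi) - np.pi)
    th = np.append(th, th[0] + 2.0 * np.pi)
    dth = np.diff(th)
    mid = th[:-1] + dth / 2.0
    px = xd + rho * np.cos(mid)
    py = yd + rho * np.sin(mid)
    inside = (np.abs(px) < half) & (np.abs(py) < half) & (dth > 0)
    if not np.any(inside):
        return None
    return th[:-1][inside], dth[inside]


def build_arc_weights_cdmmi(
    image_coords: CoordinateSystem,
    geometry: DetectorGeometry,
    time_axis: ScalarAxis,
) -> sp.csr_matrix:
    """Exact circle/cell arc-length weights.

    For each (detector, time) row, all crossings of the integration circle
    with the grid lines (including the FOV border) are solved analytically;
    each angular interval between consecutive crossings lies in exactly one
    cell and contributes rho * dtheta to that cell. Row sums therefore equal
    the in-FOV arc length exactly.
    """
    n, h, half, xc, yc = _grid_params(image_coords)
    vs = geometry.speed_of_sound
    t = time_axis.values
    n_t = t.size
    npix = n * n
    edges = -half + h * np.arange(n + 1)

    rows_out, cols_out, vals_out = [], [], []
    for d in range(geometry.n_detectors):
        xd, yd = geometry.positions[d]
        base_row = d * n_t
        ex = edges - xd
        ey = edges - yd
        for k in range(n_t):
            rho = vs * t[k]
            if rho <= 0:
                continue
            # quick reject: circle entirely outside the FOV bounding annulus
            dxo = max(abs(xd) - half, 0.0)
            dyo = max(abs(yd) - half, 0.0)
            dmin = np.hypot(dxo, dyo)
            dmax = np.hypot(abs(xd) + half, abs(yd) + half)
            if rho < dmin or rho > dmax:
                continue
            ux = ex / rho
            mx = np.abs(ux) < 1.0
            uy = ey / rho
            my = np.abs(uy) < 1.0
            th_x = np.arccos(ux[mx])
            t1 = np.arcsin(uy[my])
            thetas = np.concatenate([th_x, -th_x, t1, np.pi - t1])
            thetas = np.mod(thetas + np.pi, 2.0 * np.pi) - np.pi
            if thetas.size == 0:
                # no grid-line crossings: circle is inside one cell or outside
                px, py = xd + rho, yd
                if abs(px) < half and abs(py) < half:
                    ix = int((px + half) / h)
                    iy = int((py + half) / h)
                    rows_out.append(np.array([base_row + k]))
                    cols_out.append(np.array([iy * n + ix]))
                    vals_out.append(np.array([2.0 * np.pi * rho]))
                continue
            thetas = np.sort(thetas)
            thetas = np.append(thetas, thetas[0] + 2.0 * np.pi)
            dtheta = np.diff(thetas)
            mid = thetas[:-1] + dtheta / 2.0
            px = xd + rho * np.cos(mid)
            py = yd + rho * np.sin(mid)
            ix = np.floor((px + half) / h).astype(np.int64)
            iy = np.floor((py + half) / h).astype(np.int64)
            ok = (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n) & (dtheta > 0)
            if not np.any(ok):
                continue
            rows_out.append(np.full(int(ok.sum()), base_row + k))
            cols_out.append(iy[ok] * n + ix[ok])
            vals_out.append(rho * dtheta[ok])

    if rows_out:
        rows = np.concatenate(rows_out)
        cols = np.concatenate(cols_out)
        vals = np.concatenate(vals_out)
    else:  # pragma: no cover - degenerate geometry
        rows = cols = vals = np.array([])
    W = sp.coo_matrix(
        (vals, (rows, cols)), shape=(geometry.n_detectors * n_t, npix)
    ).tocsr()
    W.sum_duplicates()
    return W


def temporal_derivative(n_detectors: int, time_axis: ScalarAxis) -> sp.csr_matrix:
    """Block-diagonal temporal derivative: central differences in the interior,
    one-sided at the record ends."""
    n_t = len(time_axis)
    dt = time_axis.spacing
    D = sp.lil_matrix((n_t, n_t))
    for k in range(1, n_t - 1):
        D[k, k - 1] = -0.5 / dt
        D[k, k + 1] = 0.5 / dt
    D[0, 0] = -1.0 / dt
    D[0, 1] = 1.0 / dt
    D[n_t - 1, n_t - 2] = -1.0 / dt
    D[n_t - 1, n_t - 1] = 1.0 / dt
    return sp.kron(sp.eye(n_detectors), D.tocsr(), format="csr")


def assemble_model(
    kind: str,
    image_coords: CoordinateSystem,
    geometry: DetectorGeometry,
    time_axis: ScalarAxis,
    params: Optional[dict] = None,
    cache_dir=None,
) -> ForwardModelMatrix:
    """Build M = (1/(2 pi v_s)) D_t W for the requested discretization.

    ``params`` may carry ``n_curve_samples`` (dimmi only). When ``cache_dir``
    is given, the sparse matrix is cached on disk keyed by a content hash of
    (grid, geometry, time axis, kind, params).
    """
    params = dict(params or {})
    if kind not in ("dimmi", "cdmmi"):
        raise ValueError(f"unknown model kind {kind!r}")
    n, h, half, xc, yc = _grid_params(image_coords)
    if kind == "dimmi":
        params.setdefault("n_curve_samples", 2 * n)
    params["derivative_stencil"] = "central_1st_order_ends"
    params["speed_of_sound"] = geometry.speed_of_sound

    cache_path = None
    if cache_dir is not None:
        key = hashlib.sha256()
        key.update(np.ascontiguousarray(geometry.positions).tobytes())
        key.update(np.ascontiguousarray(time_axis.values).tobytes())
        key.update(np.ascontiguousarray(xc).tobytes())
        key.update(repr(sorted(params.items())).encode())
        key.update(kind.encode())
        cache_path = os.path.join(os.fspath(cache_dir), f"model_{key.hexdigest()[:24]}.npz")
        if os.path.exists(cache_path):
            M = sp.load_npz(cache_path)
            return ForwardModelMatrix(M, image_coords, geometry, time_axis, kind, params)

    if kind == "dimmi":
        W = build_arc_weights_dimmi(
            image_coords, geometry, time_axis, params["n_curve_samples"]
        )
    else:
        W = build_arc_weights_cdmmi(image_coords, geometry, time_axis)
    D = temporal_derivative(geometry.n_detectors, time_axis)
    M = (D @ W).tocsr() * (1.0 / (2.0 * np.pi * geometry.speed_of_sound))
    M.sum_duplicates()
    if cache_path is not None:
        os.makedirs(os.fspath(cache_dir), exist_ok=True)
        sp.save_npz(cache_path, M)
    return ForwardModelMatrix(M, image_coords, geometry, time_axis, kind, params)


def _flatten_image(model: ForwardModelMatrix, image) -> np.ndarray:
    if isinstance(image, ImageFrame):
        image = image.pixels
    image = np.asarray(image, dtype=float)
    npix = model.matrix.shape[1]
    if image.ndim == 2:
        if image.shape != model.image_shape:
            raise ValueError(f"image shape {image.shape} != model {model.image_shape}")
        return image.ravel()
    if image.ndim == 1 and image.size == npix:
        return image
    raise ValueError("image does not conform to the model's input coordinates")


def apply(model: ForwardModelMatrix, image) -> np.ndarray:
    """Forward-project an image; returns a (n_detectors, n_times) sinogram."""
    sino = model.matrix @ _flatten_image(model, image)
    return sino.reshape(model.data_shape)


def apply_adjoint(model: ForwardModelMatrix, sinogram) -> np.ndarray:
    """Adjoint (transpose) projection; returns an image array (Ny, Nx)."""
    sino = np.asarray(sinogram, dtype=float)
    if sino.ndim == 2:
        if sino.shape != model.data_shape:
            raise ValueError(f"sinogram shape {sino.shape} != model {model.data_shape}")
        sino = sino.ravel()
    elif sino.ndim != 1 or sino.size != model.matrix.shape[0]:
        raise ValueError("sinogram does not conform to the model's output coordinates")
    img = model.matrix.T @ sino
    return img.reshape(model.image_shape)
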