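"""Per-frame image reconstruction: LSQR, non-negative accelerated projected
gradient, and direct universal backprojection (2-D adaptation).

All solvers minimize ||M I - d||_2 (optionally with Tikhonov damping); the
non-negative solver additionally projects onto I >= 0 at every iterate, so
its output never contains a negative pixel. Early stopping doubles as
regularization for the ill-conditioned tomographic systems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from joblib import Parallel, delayed

from .coords import CoordinateSystem, image_grid_vectors
from .datamodel import AcousticFrame, DetectorGeometry, ImageFrame
from .models import ForwardModelMatrix, SolverOptions

logger = logging.getLogger(__name__)

__all__ = [
    "ReconResult",
    "ReconDatasetResult",
    "lsqr_solve",
    "nnapcg_solve",
    "backproject",
    "reconstruct_dataset",
]


@dataclass(frozen=True)
class ReconResult:
    image: ImageFrame
    iterations: int
    residuals: tuple  # relative residual trace, one entry per iteration
    converged: bool


def _model_fov(model: ForwardModelMatrix):
    yc, xc = image_grid_vectors(model.image_coords)
    hx = xc[1] - xc[0]
    hy = yc[1] - yc[0]
    return (hx * len(xc), hy * len(yc))


def _as_data_vector(model: ForwardModelMatrix, sinogram) -> np.ndarray:
    if isinstance(sinogram, AcousticFrame):
        sinogram = sinogram.samples
    d = np.asarray(sinogram, dtype=float).ravel()
    if d.size != model.matrix.shape[0]:
        raise ValueError("data vector does not conform to the model output")
    return d


def lsqr_solve(
    model: ForwardModelMatrix, sinogram, opts: Optional[SolverOptions] = None
) -> ReconResult:
    """Standard LSQR (Golub-Kahan bidiagonalization) on min ||M I - d||.

    With a Tikhonov weight lambda > 0, the damped problem
    min ||M I - d||^2 + lambda ||I||^2 is solved through the usual damping
    rotations. The relative residual ||M I - d|| / ||d|| is tracked per
    iteration and is non-increasing.
    """
    opts = opts or SolverOptions()
    M = model.matrix
    d = _as_data_vector(model, sinogram)
    ny, nx = model.image_shape
    fov = _model_fov(model)
    norm_d = np.linalg.norm(d)
    if norm_d == 0.0:
        return ReconResult(
            ImageFrame(np.zeros((ny, nx)), fov), 0, (0.0,), True
        )
    if opts.max_iterations == 0:
        return ReconResult(ImageFrame(np.zeros((ny, nx)), fov), 0, (1.0,), False)

    damp = np.sqrt(opts.regularization) if opts.regularization > 0 else 0.0
    x = np.zeros(M.shape[1])
    u = d.copy()
    beta = np.linalg.norm(u)
    u /= beta
    v = M.T @ u
    alpha = np.linalg.norm(v)
    if alpha == 0.0:
        return ReconResult(ImageFrame(np.zeros((ny, nx)), fov), 0, (1.0,), False)
    v /= alpha
    w = v.copy()
    phibar = beta
    rhobar = alpha
    residuals = []
    converged = False
    it = 0
    for it in range(1, opts.max_iterations + 1):
        u = M @ v - alpha * u
        beta = np.linalg.norm(u)
        if beta > 0:
            u /= beta
        v = M.T @ u - beta * v
        alpha = np.linalg.norm(v)
        if alpha > 0:
            v /= alpha
        if damp > 0:
            rhobar1 = np.hypot(rhobar, damp)
            c1 = rhobar / rhobar1
            phibar = c1 * phibar
        else:
            rhobar1 = rhobar
        rho = np.hypot(rhobar1, beta)
        c = rhobar1 / rho
        s = beta / rho
        theta = s * alpha
        rhobar = -c * alpha
        phi = c * phibar
        phibar = s * phibar
        x = x + (phi / rho) * w
        w = v - (theta / rho) * w
        if damp > 0:
            r_rel = np.linalg.norm(M @ x - d) / norm_d
        else:
            r_rel = abs(phibar) / norm_d
        residuals.append(float(r_rel))
        if r_rel <= opts.tolerance:
            converged = True
            break
    return ReconResult(
        ImageFrame(x.reshape(ny, nx), fov), it, tuple(residuals), converged
    )


def _power_iteration_norm(M, n_iter: int = 30, reg: float = 0.0) -> float:
    """Largest eigenvalue of M^T M (+ reg), deterministic start vector."""
    n = M.shape[1]
    v = np.ones(n) / np.sqrt(n)
    lam = 1.0
    for _ in range(n_iter):
        w = M.T @ (M @ v) + reg * v
        lam = np.linalg.norm(w)
        if lam == 0.0:
            return 1.0
        v = w / lam
    return float(lam)


def nnapcg_solve(
    model: ForwardModelMatrix, sinogram, opts: Optional[SolverOptions] = None
) -> ReconResult:
    """Non-negative constrained least squares by accelerated projected gradient.

    Nesterov/FISTA momentum with a fixed 1/L step (L estimated by power
    iteration on M^T M) and a function-value restart: whenever an accelerated
    step would increase the objective, the momentum is reset and a plain
    projected-gradient step is taken from the previous iterate, which cannot
    increase the objective. Every iterate is projected onto the non-negative
    orthant, so the output never contains a negative pixel.
    """
    opts = opts or SolverOptions(max_iterations=200, tolerance=1e-8)
    M = model.matrix
    d = _as_data_vector(model, sinogram)
    ny, nx = model.image_shape
    fov = _model_fov(model)
    norm_d = np.linalg.norm(d)
    if norm_d == 0.0:
        return ReconResult(ImageFrame(np.zeros((ny, nx)), fov), 0, (0.0,), True)
    lam = opts.regularization
    L = _power_iteration_norm(M, reg=lam)
    L = max(L, 1e-300) * 1.01  # small safety factor on the Lipschitz estimate

    def objective(z, Mz):
        r = Mz - d
        val = 0.5 * float(r @ r)
        if lam > 0:
            val += 0.5 * lam * float(z @ z)
        return val

    x = np.zeros(M.shape[1])
    Mx = M @ x
    f_x = objective(x, Mx)
    y = x.copy()
    My = Mx.copy()
    tk = 1.0
    residuals = []
    converged = False
    it = 0
    for it in range(1, opts.max_iterations + 1):
        grad = M.T @ (My - d)
        if lam > 0:
            grad += lam * y
        x_new = np.maximum(y - grad / L, 0.0)
        Mx_new = M @ x_new
        f_new = objective(x_new, Mx_new)
        if f_new > f_x:
            # restart: plain projected-gradient step from the previous iterate
            grad = M.T @ (Mx - d)
            if lam > 0:
                grad += lam * x
            x_new = np.maximum(x - grad / L, 0.0)
            Mx_new = M @ x_new
            f_new = objective(x_new, Mx_new)
            tk = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        y = x_new + ((tk - 1.0) / t_new) * (x_new - x)
        My = M @ y
        dx = np.linalg.norm(x_new - x)
        x, Mx, f_x, tk = x_new, Mx_new, f_new, t_new
        r_rel = np.linalg.norm(Mx - d) / norm_d
        residuals.append(float(r_rel))
        if r_rel <= opts.tolerance or dx <= opts.tolerance * max(np.linalg.norm(x), 1e-300):
            converged = True
            break
    return ReconResult(
        ImageFrame(x.reshape(ny, nx), fov), it, tuple(residuals), converged
    )


def backproject(
    sinogram: AcousticFrame,
    geometry: DetectorGeometry,
    image_coords: CoordinateSystem,
) -> ImageFrame:
    """Universal backprojection adapted to 2-D circular geometry.

    b(r) = sum_d w_d [2 p_d(t) - 2 t dp_d/dt] at t = |r - r_d| / v_s, with the
    backprojection term linearly interpolated in time; w_d = weights /
    n_detectors. Pixels whose time of flight falls outside the recorded window
    contribute zero (a warning count is logged). Absolute scale is arbitrary.
    """
    if not sinogram.time_axis.is_uniform():
        raise ValueError("time axis must be uniform")
    t = sinogram.time_axis.values
    dt = sinogram.time_axis.spacing
    p = sinogram.samples
    dp = np.gradient(p, dt, axis=1)
    term = 2.0 * p - 2.0 * t[None, :] * dp

    yc, xc = image_grid_vectors(image_coords)
    X, Y = np.meshgrid(xc, yc)
    vs = geometry.speed_of_sound
    img = np.zeros_like(X)
    w = geometry.weights / geometry.n_detectors
    n_out = 0
    t0, t1 = t[0], t[-1]
    for d in range(geometry.n_detectors):
        xd, yd = geometry.positions[d]
        tof = np.hypot(X - xd, Y - yd) / vs
        g = (tof - t0) / dt
        valid = (tof >= t0) & (tof <= t1)
        n_out += int((~valid).sum())
        gi = np.clip(g, 0, t.size - 1 - 1e-9)
        i0 = gi.astype(np.int64)
        frac = gi - i0
        vals = (1 - frac) * term[d, i0] + frac * term[d, np.minimum(i0 + 1, t.size - 1)]
        img += w[d] * np.where(valid, vals, 0.0)
    if n_out:
        logger.warning("backprojection: %d pixel/detector pairs beyond recorded radii", n_out)
    fov = (float(xc[-1] - xc[0] + (xc[1] - xc[0])), float(yc[-1] - yc[0] + (yc[1] - yc[0])))
    return ImageFrame(img, fov, wavelength=sinogram.wavelength, timestamp=sinogram.timestamp)


@dataclass(frozen=True)
class ReconDatasetResult:
    frames: tuple  # ImageFrame per successfully reconstructed input frame
    failed: tuple  # indices of frames whose reconstruction raised
    iterations: tuple
    residuals: tuple  # final relative residual per frame (nan for bp/failure)

    @property
    def complete(self) -> bool:
        return len(self.failed) == 0


def _recon_one(method, model, image_coords, geometry, samples, time_axis, wavelength, timestamp, opts):
    frame = AcousticFrame(
        samples=samples, time_axis=time_axis, wavelength=wavelength, timestamp=timestamp
    )
    if method == "bp":
        img = backproject(frame, geometry, image_coords)
        return img, 0, np.nan
    solver = lsqr_solve if method == "lsqr" else nnapcg_solve
    res = solver(model, frame.samples, opts)
    img = ImageFrame(
        res.image.pixels, res.image.fov, wavelength=wavelength, timestamp=timestamp
    )
    final = res.residuals[-1] if res.residuals else np.nan
    return img, res.iterations, final


def reconstruct_dataset(
    store,
    method: str,
    model: Optional[ForwardModelMatrix] = None,
    image_coords: Optional[CoordinateSystem] = None,
    opts: Optional[SolverOptions] = None,
    n_workers: int = 1,
) -> ReconDatasetResult:
    """Reconstruct every frame of a store; output is independent of n_workers.

    Frames are distributed over process workers in a static, order-preserving
    map, so results for n_workers = k are bit-identical to n_workers = 1.
    Frames whose reconstruction raises are recorded in ``failed`` and the
    result is marked incomplete.
    """
    if method not in ("bp", "lsqr", "nnapcg"):
        raise ValueError(f"unknown reconstruction method {method!r}")
    if method in ("lsqr", "nnapcg") and model is None:
        raise ValueError(f"method {method!r} requires a forward model")
    if method == "bp" and image_coords is None:
        raise ValueError("backprojection requires image coordinates")
    geometry = store.geometry
    time_axis = store.time_axis
    coords = image_coords if image_coords is not None else (model.image_coords if model else None)

    def job(k, frame):
        try:
            return k, _recon_one(
                method, model, coords, geometry, frame.samples, time_axis,
                frame.wavelength, frame.timestamp, opts,
            ), None
        except Exception as exc:  # pragma: no cover - defensive
            return k, None, repr(exc)

    if store.n_frames == 0:
        return ReconDatasetResult((), (), (), ())
    results = Parallel(n_jobs=max(1, n_workers), backend="loky")(
        delayed(job)(k, store.get_frame(k)) for k in range(store.n_frames)
    )
    frames, failed, iters, resids = [], [], [], []
    for k, payload, err in results:
        if err is not None:
            failed.append(k)
            logger.error("frame %d failed: %s", k, err)
            continue
        img, n_it, r = payload
        frames.append(img)
        iters.append(n_it)
        resids.append(r)
    return ReconDatasetResult(tuple(frames), tuple(failed), tuple(iters), tuple(resids))
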