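"""Reconstruction-quality metrics and downstream statistical analyses.

Image-error metrics compare a known source image against a reconstruction:
with e = known - recon and N = Nx * Ny pixels,

    bias  = sum(e) / N
    l1    = sum(|e|) / N
    l2    = sqrt(sum(e^2)) / N        (note the 1/N, not 1/sqrt(N))

plus the structural similarity index (uniform 7x7 windows) and the count of
negative pixels. The statistical suite covers the dynamic-imaging analyses:
negative-pixel indicator maps, binned Bland-Altman comparison, per-pixel
Welch t-scores, relative Cohen's d maps, centered correlation against a
reference waveform, Fisher-Z comparison of correlations, and a 7-parameter
piecewise mono-exponential fit of gas-challenge time courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, optimize, stats

from .datamodel import ImageFrame
from .models import ForwardModelMatrix

__all__ = [
    "ReconQuality",
    "BlandAltmanResult",
    "GasFitResult",
    "SIGNIFICANCE",
    "STRONG_SIGNIFICANCE",
    "error_metrics",
    "ssim",
    "relative_residual",
    "negative_indicator_map",
    "bland_altman_binned",
    "tscore_map",
    "relative_cohens_d",
    "correlation_map",
    "fisher_z_compare",
    "fit_gas_model",
    "gas_model",
]

SIGNIFICANCE = 0.01
STRONG_SIGNIFICANCE = 0.0001


@dataclass(frozen=True)
class ReconQuality:
    bias: float
    l1: float
    l2: float
    n_negative_pixels: int
    ssim: Optional[float] = None
    relative_residual: Optional[float] = None


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, ImageFrame) else np.asarray(img, dtype=float)


def error_metrics(known, recon) -> ReconQuality:
    """Pixel-count-normalized bias, L1, and L2 error plus negative-pixel count."""
    x = _pixels(known)
    y = _pixels(recon)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    e = x - y
    n = e.size
    return ReconQuality(
        bias=float(e.sum() / n),
        l1=float(np.abs(e).sum() / n),
        l2=float(np.sqrt((e**2).sum()) / n),
        n_negative_pixels=int((y < 0).sum()),
    )


def ssim(
    x,
    y,
    C1: Optional[float] = None,
    C2: Optional[float] = None,
    win_size: int = 7,
    data_range: Optional[float] = None,
) -> float:
    """Mean structural similarity over uniform local windows.

    Local means, variances (sample-normalized), and covariance are computed
    with a uniform win_size x win_size filter; the map is averaged over the
    interior where the window fits entirely. C1 and C2 default to the
    standard stabilizers (0.01 L)^2 and (0.03 L)^2 with L the dynamic range.
    """
    a = _pixels(x)
    b = _pixels(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        both = np.concatenate([a.ravel(), b.ravel()])
        data_range = float(both.max() - both.min())
        if data_range == 0.0:
            data_range = 1.0
    if C1 is None:
        C1 = (0.01 * data_range) ** 2
    if C2 is None:
        C2 = (0.03 * data_range) ** 2
    np_win = win_size * win_size
    cov_norm = np_win / (np_win - 1)
    filt = lambda z: ndimage.uniform_filter(z, size=win_size)
    ux = filt(a)
    uy = filt(b)
    uxx = filt(a * a)
    uyy = filt(b * b)
    uxy = filt(a * b)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    smap = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
        (ux**2 + uy**2 + C1) * (vx + vy + C2)
    )
    pad = (win_size - 1) // 2
    return float(smap[pad:-pad, pad:-pad].mean())


def relative_residual(model: ForwardModelMatrix, image, data) -> float:
    """||M I - d|| / ||d||; defined as 0 for d = 0 with M I = 0, inf otherwise."""
    from .models import apply as model_apply

    d = np.asarray(data, dtype=float).ravel()
    r = model_apply(model, image).ravel() - d
    norm_d = np.linalg.norm(d)
    if norm_d == 0.0:
        return 0.0 if np.linalg.norm(r) == 0.0 else np.inf
    return float(np.linalg.norm(r) / norm_d)


def negative_indicator_map(image_series) -> np.ndarray:
    """Per-pixel count of frames in which the value is negative."""
    stack = np.stack([_pixels(f) for f in image_series])
    return (stack < 0).sum(axis=0).astype(np.int64)


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_edges: np.ndarray
    diff_edges: np.ndarray
    counts: np.ndarray
    mean_difference: float
    loa_low: float
    loa_high: float
    n_sampled: int


def bland_altman_binned(
    a, b, n_bins: int = 100, sample_frac: float = 0.1, seed: int = 0
) -> BlandAltmanResult:
    """Binned Bland-Altman density of (mean, difference) over a random pixel sample.

    floor(sample_frac * N) points are drawn without replacement (seeded), and
    a 2-D histogram with n_bins x n_bins bins spanning the sampled ranges is
    returned together with the mean difference and 1.96-SD limits of agreement.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have the same shape")
    if not 0 < sample_frac <= 1:
        raise ValueError("sample_frac must be in (0, 1]")
    n = int(np.floor(sample_frac * a.size))
    if n == 0:
        raise ValueError("sample is empty; increase sample_frac or input size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(a.size, size=n, replace=False)
    mean = (a[idx] + b[idx]) / 2.0
    diff = a[idx] - b[idx]
    counts, me, de = np.histogram2d(mean, diff, bins=n_bins)
    md = float(diff.mean())
    sd = float(diff.std(ddof=1)) if n > 1 else 0.0
    return BlandAltmanResult(
        mean_edges=me,
        diff_edges=de,
        counts=counts,
        mean_difference=md,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        n_sampled=n,
    )


def tscore_map(before, after) -> np.ndarray:
    """Per-pixel Welch two-sample t statistic (after minus before)."""
    x = np.stack([_pixels(f) for f in before]).astype(float)
    y = np.stack([_pixels(f) for f in after]).astype(float)
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("each stack needs at least 2 frames for a t-test")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    vx = x.var(axis=0, ddof=1) / x.shape[0]
    vy = y.var(axis=0, ddof=1) / y.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (my - mx) / np.sqrt(vx + vy)
    return t


def _cohens_d(before: np.ndarray, after: np.ndarray) -> np.ndarray:
    n1, n2 = before.shape[0], after.shape[0]
    m1, m2 = before.mean(axis=0), after.mean(axis=0)
    s1 = before.var(axis=0, ddof=1)
    s2 = after.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m2 - m1) / pooled


def relative_cohens_d(
    drug_before, drug_after, gas_before, gas_after, eps: float = 1e-12
) -> np.ndarray:
    """Per-pixel Cohen's d of the drug response scaled by the gas-transition d.

    NaN wherever the gas-transition effect size is below eps (undefined ratio).
    """
    d_drug = _cohens_d(
        np.stack([_pixels(f) for f in drug_before]),
        np.stack([_pixels(f) for f in drug_after]),
    )
    d_gas = _cohens_d(
        np.stack([_pixels(f) for f in gas_before]),
        np.stack([_pixels(f) for f in gas_after]),
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(d_gas) >= eps, d_drug / d_gas, np.nan)
    return out


def correlation_map(series, reference_waveform) -> np.ndarray:
    """Per-pixel centered Pearson correlation against a reference waveform.

    Pixels with zero temporal variance are NaN.
    """
    stack = np.stack([_pixels(f) for f in series]).astype(float)
    w = np.asarray(reference_waveform, dtype=float)
    if stack.shape[0] != w.size:
        raise ValueError("series length does not match the reference waveform")
    xc = stack - stack.mean(axis=0)
    wc = w - w.mean()
    num = np.tensordot(wc, xc, axes=(0, 0))
    den = np.sqrt((xc**2).sum(axis=0)) * np.linalg.norm(wc)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def fisher_z_compare(rho1: float, n1: int, rho2: float, n2: int):
    """Two-population Z-test on Fisher-transformed correlation coefficients.

    Returns (z, p) with z = (atanh(rho1) - atanh(rho2)) /
    sqrt(1/(n1-3) + 1/(n2-3)) and a two-sided normal p-value.
    """
    for rho in (rho1, rho2):
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Gas-challenge exponential response model
# ---------------------------------------------------------------------------


def gas_model(t, b, a1, k1, tau1, a2, k2, tau2):
    """Piecewise mono-exponential response: baseline b, a rise of amplitude a1
    and rate k1 starting at switching time tau1, and a fall of amplitude a2
    and rate k2 starting at tau2."""
    t = np.asarray(t, dtype=float)
    y = np.full_like(t, float(b))
    m = t >= tau1
    y[m] += a1 * (1.0 - np.exp(-k1 * (t[m] - tau1)))
    m = t >= tau2
    y[m] -= a2 * (1.0 - np.exp(-k2 * (t[m] - tau2)))
    return y


@dataclass(frozen=True)
class GasFitResult:
    baseline: float
    rise_amplitude: float
    rise_rate: float
    rise_time: float
    fall_amplitude: float
    fall_rate: float
    fall_time: float
    residual_norm: float
    converged: bool
    degenerate: bool = False
    noncausal: bool = False

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [
                self.baseline,
                self.rise_amplitude,
                self.rise_rate,
                self.rise_time,
                self.fall_amplitude,
                self.fall_rate,
                self.fall_time,
            ]
        )


def fit_gas_model(
    timecourse, times, stimulus_onsets: Optional[tuple] = None
) -> GasFitResult:
    """Least-squares fit of the 7-parameter exponential gas-response model.

    Switching times are bounded to the record; a constant series yields a
    degenerate fit (amplitudes 0, baseline = mean). If ``stimulus_onsets``
    (rise, fall) are supplied, the fit is flagged noncausal when a fitted
    switching time precedes the corresponding known stimulus onset.
    Non-convergence is reported via the ``converged`` flag, never raised.
    """
    y = np.asarray(timecourse, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValueError("timecourse and times must be matching vectors")
    if y.size < 50:
        raise ValueError("gas-model fit requires at least 50 samples")
    scale = max(float(np.abs(y).max()), 1e-30)
    if float(y.std()) < 1e-12 * scale:
        b = float(y.mean())
        return GasFitResult(b, 0.0, 0.0, t[0], 0.0, 0.0, t[-1], 0.0, True, degenerate=True)

    span = t[-1] - t[0]
    # smoothed derivative locates candidate switching times
    k_s = max(3, y.size // 20)
    ys = np.convolve(y, np.ones(k_s) / k_s, mode="same")
    dy = np.gradient(ys, t)
    i1 = int(np.argmax(dy))
    after = dy.copy()
    after[: i1 + 1] = np.inf
    i2 = int(np.argmin(after))
    tau1_0 = float(t[i1])
    tau2_0 = float(t[i2]) if t[i2] > tau1_0 else min(tau1_0 + 0.25 * span, t[-1])
    b0 = float(y[t < tau1_0].mean()) if np.any(t < tau1_0) else float(y[0])
    a1_0 = max(float(ys.max() - b0), 1e-12 * scale)
    a2_0 = max(float(ys.max() - ys[-1]), 1e-12 * scale)
    k0 = 5.0 / span

    lb = [-np.inf, 0.0, 1e-9 / span, t[0], 0.0, 1e-9 / span, t[0]]
    ub = [np.inf, np.inf, np.inf, t[-1], np.inf, np.inf, t[-1]]

    def residual(p):
        return gas_model(t, *p) - y

    best = None
    for tau1_i, tau2_i in (
        (tau1_0, tau2_0),
        (t[0] + 0.3 * span, t[0] + 0.6 * span),
        (t[0] + 0.2 * span, t[0] + 0.8 * span),
    ):
        p0 = [b0, a1_0, k0, tau1_i, a2_0, k0, tau2_i]
        try:
            sol = optimize.least_squares(
                residual, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return GasFitResult(
            float(y.mean()), 0.0, 0.0, t[0], 0.0, 0.0, t[-1],
            float(np.linalg.norm(y - y.mean())), False,
        )
    b, a1, k1, tau1, a2, k2, tau2 = best.x
    rnorm = float(np.linalg.norm(best.fun))
    noncausal = False
    if stimulus_onsets is not None:
        tol = 1e-9 * span
        noncausal = bool(tau1 < stimulus_onsets[0] - tol or tau2 < stimulus_onsets[1] - tol)
    degenerate = bool(a1 < 1e-9 * scale and a2 < 1e-9 * scale)
    return GasFitResult(
        float(b), float(a1), float(k1), float(tau1), float(a2), float(k2), float(tau2),
        rnorm, bool(best.success), degenerate=degenerate, noncausal=noncausal,
    )
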