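"""Multispectral state estimation and linear spectral unmixing.

A wavelength-cycled acquisition yields one single-wavelength image at a time;
the filters here turn that stream into a full-spectrum estimate at every
frame time:

* sliding window - hold the most recent image of each wavelength;
* Kalata fixed-gain tracking filters - an alpha filter (static-level model,
  strong noise suppression, lagged response to change) or an alpha-beta
  filter (level + trend model, tracks ramps with zero steady-state lag).
  Gains derive from the tracking index L (ratio of process to measurement
  noise scales): for the alpha-beta filter r = (4 + L - sqrt(8 L + L^2))/4,
  alpha = 1 - r^2, beta = 2 (2 - alpha) - 4 sqrt(1 - alpha); for the alpha
  filter the first-order steady-state relation L^2 = alpha^2 / (1 - alpha)
  gives alpha = (-L^2 + sqrt(L^4 + 4 L^2)) / 2.

Unmixing inverts the mixing model I = E C per pixel, either by pseudoinverse
or by non-negative least squares (the same accelerated projected-gradient
iteration used for image reconstruction, vectorized across pixels), and the
oxygen saturation map is SO2 = HbO2 / (HbO2 + Hb), undefined (NaN) where the
denominator is zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Optional

import numpy as np

from .datamodel import ImageFrame, MultispectralFrame, UnmixedFrame

__all__ = [
    "EndmemberSpectra",
    "KalataGains",
    "builtin_hemoglobin_spectra",
    "load_spectra_csv",
    "kalata_gains",
    "sliding_window_assemble",
    "kalata_filter",
    "unmix",
    "compute_so2",
]


@dataclass(frozen=True)
class EndmemberSpectra:
    """Mixing matrix E [N_lambda x N_c] of molar absorption coefficients."""

    wavelengths: np.ndarray
    matrix: np.ndarray
    names: tuple = ("HbO2", "Hb")

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        E = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "matrix", E)
        object.__setattr__(self, "names", tuple(self.names))
        if E.ndim != 2 or E.shape != (wl.size, len(self.names)):
            raise ValueError("matrix must be (N_lambda, N_c) matching names")
        if np.any(E < 0):
            raise ValueError("absorption coefficients must be non-negative")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def interpolate(self, wavelengths) -> "EndmemberSpectra":
        wl = np.asarray(wavelengths, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError("requested wavelength outside the tabulated range")
        E = np.column_stack(
            [np.interp(wl, self.wavelengths, self.matrix[:, j]) for j in range(self.matrix.shape[1])]
        )
        return EndmemberSpectra(wl, E, self.names)


def load_spectra_csv(path_or_file) -> EndmemberSpectra:
    """Load endmember spectra from CSV: wavelength_nm, then one column per endmember."""
    if hasattr(path_or_file, "read"):
        rows = list(csv.reader(line for line in path_or_file if not line.startswith("#")))
    else:
        with open(path_or_file) as fh:
            rows = list(csv.reader(line for line in fh if not line.startswith("#")))
    header = rows[0]
    if header[0] != "wavelength_nm":
        raise ValueError("first CSV column must be wavelength_nm")
    names = tuple(header[1:])
    data = np.array([[float(v) for v in r] for r in rows[1:]])
    return EndmemberSpectra(data[:, 0], data[:, 1:], names)


def builtin_hemoglobin_spectra() -> EndmemberSpectra:
    """Shipped HbO2/Hb molar absorption table, 700-900 nm."""
    ref = resources.files("paraft").joinpath("data/hemoglobin_spectra.csv")
    with ref.open() as fh:
        return load_spectra_csv(fh)


# ---------------------------------------------------------------------------
# Tracking filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KalataGains:
    alpha: float
    beta: float = 0.0


def kalata_gains(order: str, tracking_index: float) -> KalataGains:
    if tracking_index <= 0:
        raise ValueError("tracking_index must be positive")
    L = float(tracking_index)
    if order == "alpha":
        a = (-(L**2) + np.sqrt(L**4 + 4 * L**2)) / 2.0
        return KalataGains(alpha=float(a))
    if order == "alphabeta":
        r = (4.0 + L - np.sqrt(8.0 * L + L**2)) / 4.0
        a = 1.0 - r**2
        b = 2.0 * (2.0 - a) - 4.0 * np.sqrt(1.0 - a)
        return KalataGains(alpha=float(a), beta=float(b))
    raise ValueError(f"unknown filter order {order!r}")


def _check_stream_frame(frame: ImageFrame, wavelengths: np.ndarray):
    if frame.wavelength is None or frame.wavelength not in wavelengths:
        raise ValueError(
            f"frame wavelength {frame.wavelength!r} not in the configured set"
        )


def sliding_window_assemble(
    stream: Iterable[ImageFrame], wavelengths
) -> Iterator[MultispectralFrame]:
    """Emit, at each incoming frame, the most recent image of every wavelength.

    Nothing is emitted until each wavelength has been seen once (warm-up).
    """
    wl = np.sort(np.asarray(wavelengths, dtype=float))
    latest = {}
    for frame in stream:
        _check_stream_frame(frame, wl)
        latest[float(frame.wavelength)] = frame.pixels
        if len(latest) == wl.size:
            yield MultispectralFrame(
                stack=np.stack([latest[w] for w in wl]),
                wavelengths=wl,
                timestamp=frame.timestamp,
            )


def kalata_filter(
    stream: Iterable[ImageFrame],
    wavelengths,
    order: str = "alphabeta",
    tracking_index: float = 0.1,
) -> Iterator[MultispectralFrame]:
    """Fixed-gain tracking filter over a wavelength-cycled image stream.

    Every incoming frame advances all channels in time (identity for the
    alpha filter; x += v dt for alpha-beta), then applies a measurement
    update with gain alpha (and beta/dt on the trend) to the channel of the
    incoming frame's wavelength. A full-stack estimate is emitted at every
    frame once all channels have been initialized.
    """
    gains = kalata_gains(order, tracking_index)
    wl = np.sort(np.asarray(wavelengths, dtype=float))
    level = {}
    trend = {}
    last_meas_time = {}
    last_frame_time = None
    for frame in stream:
        _check_stream_frame(frame, wl)
        t = frame.timestamp
        if last_frame_time is not None:
            if t < last_frame_time:
                raise ValueError("frame timestamps must be non-decreasing")
            dt_frame = t - last_frame_time
            if order == "alphabeta":
                for w in level:
                    level[w] = level[w] + trend[w] * dt_frame
        last_frame_time = t
        w = float(frame.wavelength)
        if w not in level:
            level[w] = frame.pixels.astype(float).copy()
            trend[w] = np.zeros_like(level[w])
            last_meas_time[w] = t
        else:
            residual = frame.pixels - level[w]
            level[w] = level[w] + gains.alpha * residual
            if order == "alphabeta":
                dt_meas = t - last_meas_time[w]
                if dt_meas > 0:
                    trend[w] = trend[w] + (gains.beta / dt_meas) * residual
            last_meas_time[w] = t
        if len(level) == wl.size:
            yield MultispectralFrame(
                stack=np.stack([level[v] for v in wl]), wavelengths=wl, timestamp=t
            )


# ---------------------------------------------------------------------------
# Unmixing
# ---------------------------------------------------------------------------


def _nnls_fista(E: np.ndarray, I: np.ndarray, max_iter: int = 500, tol: float = 1e-12):
    """Non-negative least squares min ||E C - I||^2, C >= 0, vectorized over
    pixel columns of I; accelerated projected gradient with function restart."""
    EtE = E.T @ E
    EtI = E.T @ I
    L = float(np.linalg.eigvalsh(EtE)[-1]) * 1.01
    C = np.zeros_like(EtI)
    Y = C.copy()
    tk = 1.0

    def obj(Z):
        R = E @ Z - I
        return 0.5 * np.sum(R * R)

    f_prev = obj(C)
    for _ in range(max_iter):
        G = EtE @ Y - EtI
        C_new = np.maximum(Y - G / L, 0.0)
        f_new = obj(C_new)
        if f_new > f_prev:
            G = EtE @ C - EtI
            C_new = np.maximum(C - G / L, 0.0)
            f_new = obj(C_new)
            tk = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        Y = C_new + ((tk - 1.0) / t_new) * (C_new - C)
        delta = np.abs(C_new - C).max()
        C, f_prev, tk = C_new, f_new, t_new
        if delta <= tol * max(1.0, np.abs(C).max()):
            break
    return C


def unmix(ms: MultispectralFrame, spectra: EndmemberSpectra, method: str = "pinv") -> UnmixedFrame:
    """Invert I = E C per pixel by pseudoinverse or non-negative least squares."""
    if not np.array_equal(ms.wavelengths, spectra.wavelengths):
        raise ValueError("frame wavelengths do not match the spectra wavelengths")
    E = spectra.matrix
    if np.linalg.matrix_rank(E) < E.shape[1]:
        raise ValueError("mixing matrix is rank-deficient; endmembers not separable")
    n_l, ny, nx = ms.stack.shape
    I = ms.stack.reshape(n_l, ny * nx)
    if method == "pinv":
        C = np.linalg.pinv(E) @ I
    elif method == "nonneg":
        C = _nnls_fista(E, I)
    else:
        raise ValueError(f"unknown unmixing method {method!r}")
    conc = C.reshape(E.shape[1], ny, nx)
    out = UnmixedFrame(
        concentrations=conc, endmember_names=spectra.names, timestamp=ms.timestamp
    )
    if {"HbO2", "Hb"} <= set(spectra.names):
        out = UnmixedFrame(
            concentrations=conc,
            endmember_names=spectra.names,
            so2=compute_so2(out),
            timestamp=ms.timestamp,
        )
    return out


def compute_so2(unmixed: UnmixedFrame) -> np.ndarray:
    """SO2 = HbO2 / (HbO2 + Hb); NaN where total hemoglobin is exactly zero.

    With non-negative inputs the result lies in [0, 1]; unconstrained inputs
    may fall outside that range (they are returned as-is, to be flagged by
    downstream analyses).
    """
    names = unmixed.endmember_names
    if "HbO2" not in names or "Hb" not in names:
        raise ValueError("SO2 requires HbO2 and Hb endmembers")
    hbo2 = unmixed.concentrations[names.index("HbO2")]
    hb = unmixed.concentrations[names.index("Hb")]
    denom = hbo2 + hb
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(denom != 0.0, hbo2 / denom, np.nan)
    return so2
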