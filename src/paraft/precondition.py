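"""Per-frame signal conditioning applied before reconstruction.

The composite chain runs in a fixed order: laser-energy calibration, per-
transducer mean subtraction, Wiener deconvolution of the transducer impulse
response, zero-phase band-pass filtering, Beer's-law water-absorption
compensation, and finally temporal regridding onto the solver's time axis.
Deconvolution precedes band-pass filtering deliberately: Wiener deconvolution
assumes white noise, which band-passing would violate. Every stage is linear
and individually disableable; the order itself is not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .coords import ScalarAxis
from .datamodel import AcousticFrame

__all__ = [
    "ImpulseResponse",
    "WaterAbsorptionTable",
    "PreconditionSettings",
    "energy_calibrate",
    "subtract_mean",
    "wiener_deconvolve",
    "bandpass",
    "water_correction",
    "regrid_time",
    "precondition_frame",
    "default_water_table",
]


@dataclass(frozen=True)
class ImpulseResponse:
    kernel: np.ndarray
    reference: str = "unit impulse (identity)"

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", k)
        if k.ndim != 1 or k.size == 0:
            raise ValueError("impulse-response kernel must be a non-empty vector")
        if not np.all(np.isfinite(k)):
            raise ValueError("impulse-response kernel must be finite")


@dataclass(frozen=True)
class WaterAbsorptionTable:
    """Wavelength (nm) -> water absorption coefficient (1/cm)."""

    wavelengths_nm: np.ndarray
    mu_per_cm: np.ndarray
    source: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mu = np.asarray(self.mu_per_cm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mu_per_cm", mu)
        if wl.shape != mu.shape or wl.ndim != 1:
            raise ValueError("wavelengths and coefficients must be matching vectors")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(mu < 0):
            raise ValueError("absorption coefficients must be non-negative")

    def mu(self, wavelength_nm: float) -> float:
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside table range [{wl[0]}, {wl[-1]}]"
            )
        return float(np.interp(wavelength_nm, wl, self.mu_per_cm))


# Pure-water absorption coefficients (1/cm), linearly interpolated between
# tabulated points; approximate values from standard published compilations
# of near-infrared water absorption (Hale & Querry-type data).
_WATER_NM = np.array([700, 725, 750, 775, 800, 825, 850, 875, 900], dtype=float)
_WATER_MU = np.array(
    [0.0060, 0.0152, 0.0262, 0.0240, 0.0204, 0.0280, 0.0430, 0.0550, 0.0679]
)


def default_water_table() -> WaterAbsorptionTable:
    return WaterAbsorptionTable(
        _WATER_NM, _WATER_MU, source="published NIR pure-water absorption compilation"
    )


def energy_calibrate(frame: AcousticFrame, energy_ref: float = 1.0) -> AcousticFrame:
    """Scale samples by energy_ref / laser_energy to remove shot-to-shot drift."""
    if energy_ref <= 0:
        raise ValueError("energy_ref must be positive")
    if frame.laser_energy <= 0:
        raise ValueError("frame laser_energy must be positive")
    return frame.with_samples(frame.samples * (energy_ref / frame.laser_energy))


def subtract_mean(frame: AcousticFrame) -> AcousticFrame:
    """Remove each transducer row's temporal mean (DC offset)."""
    return frame.with_samples(frame.samples - frame.samples.mean(axis=1, keepdims=True))


def wiener_deconvolve(
    frame: AcousticFrame, ir: ImpulseResponse, nsr: float = 0.1
) -> AcousticFrame:
    """Frequency-domain Wiener deconvolution of the transducer impulse response.

    X = Y conj(H) / (|H|^2 + nsr) per transducer row, with H the DFT of the
    kernel zero-padded to the record length (circular convolution model).
    """
    if nsr < 0:
        raise ValueError("nsr must be >= 0")
    n = frame.samples.shape[1]
    kernel = ir.kernel
    if np.all(kernel == 0.0):
        raise ValueError("impulse-response kernel is identically zero")
    if kernel.size > n:
        raise ValueError("kernel longer than the data record")
    H = np.fft.rfft(kernel, n=n)
    Y = np.fft.rfft(frame.samples, axis=1)
    denom = np.abs(H) ** 2 + nsr
    if nsr == 0 and np.any(denom == 0.0):
        raise ValueError("kernel spectrum has zeros; nsr = 0 would divide by zero")
    X = Y * np.conj(H)[None, :] / denom[None, :]
    return frame.with_samples(np.fft.irfft(X, n=n, axis=1))


def bandpass(frame: AcousticFrame, f_lo: float, f_hi: float) -> AcousticFrame:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward)."""
    fs = 1.0 / frame.dt
    nyq = fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(
            f"invalid band [{f_lo}, {f_hi}] Hz for Nyquist {nyq:.3g} Hz"
        )
    sos = sps.butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return frame.with_samples(sps.sosfiltfilt(sos, frame.samples, axis=1))


def water_correction(
    frame: AcousticFrame,
    table: Optional[WaterAbsorptionTable] = None,
    path_length_cm: float = 3.0,
) -> AcousticFrame:
    """Compensate Beer's-law water attenuation: multiply by exp(+mu_w * L)."""
    if path_length_cm < 0:
        raise ValueError("path length must be >= 0")
    if frame.wavelength is None:
        raise ValueError("frame carries no wavelength; cannot water-correct")
    table = table or default_water_table()
    factor = float(np.exp(table.mu(frame.wavelength) * path_length_cm))
    return frame.with_samples(frame.samples * factor)


def regrid_time(frame: AcousticFrame, target_time_axis: ScalarAxis) -> AcousticFrame:
    """Linear per-row interpolation onto a new time axis (no extrapolation)."""
    src = frame.time_axis.values
    tgt = target_time_axis.values
    if tgt[0] < src[0] - 1e-15 or tgt[-1] > src[-1] + 1e-15:
        raise ValueError("target time axis extends beyond the source span")
    if tgt.size == src.size and np.array_equal(tgt, src):
        return AcousticFrame(
            samples=frame.samples.copy(),
            time_axis=target_time_axis,
            wavelength=frame.wavelength,
            laser_energy=frame.laser_energy,
            timestamp=frame.timestamp,
            frame_index=frame.frame_index,
        )
    out = np.empty((frame.samples.shape[0], tgt.size))
    for i in range(frame.samples.shape[0]):
        out[i] = np.interp(tgt, src, frame.samples[i])
    return AcousticFrame(
        samples=out,
        time_axis=target_time_axis,
        wavelength=frame.wavelength,
        laser_energy=frame.laser_energy,
        timestamp=frame.timestamp,
        frame_index=frame.frame_index,
    )


_STAGE_ORDER = ("energy", "mean", "wiener", "bandpass", "water", "regrid")


@dataclass(frozen=True)
class PreconditionSettings:
    energy: bool = True
    energy_ref: float = 1.0
    mean: bool = True
    wiener: bool = True
    wiener_nsr: float = 0.1
    impulse_response: Optional[ImpulseResponse] = None  # None -> unit impulse
    bandpass_enabled: bool = True
    f_lo_hz: float = 5e4
    f_hi_hz: float = 7e6
    water: bool = True
    water_path_cm: float = 3.0
    water_table: Optional[WaterAbsorptionTable] = None
    regrid: Optional[ScalarAxis] = None
    order: Optional[tuple] = None  # must match the canonical order if given

    def __post_init__(self):
        if self.order is not None and tuple(self.order) != _STAGE_ORDER:
            raise ValueError(
                f"stage order is fixed to {_STAGE_ORDER}; stages can only be toggled"
            )


def precondition_frame(frame: AcousticFrame, settings: PreconditionSettings) -> AcousticFrame:
    """Apply the enabled stages in the canonical order."""
    out = frame
    if settings.energy:
        out = energy_calibrate(out, settings.energy_ref)
    if settings.mean:
        out = subtract_mean(out)
    if settings.wiener and settings.impulse_response is not None:
        # with no instrument kernel supplied the stage is an exact no-op
        out = wiener_deconvolve(out, settings.impulse_response, settings.wiener_nsr)
    if settings.bandpass_enabled:
        out = bandpass(out, settings.f_lo_hz, settings.f_hi_hz)
    if settings.water and out.wavelength is not None:
        out = water_correction(out, settings.water_table, settings.water_path_cm)
    if settings.regrid is not None:
        out = regrid_time(out, settings.regrid)
    return out
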