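"""Analytical phantoms: paraboloid absorbers with closed-form acoustic signals.

A paraboloid source is an absorbed-energy profile
``p0(r) = A * (1 - |r - c|^2 / R^2)`` on the disc of radius R about center c,
zero outside. For an ideal point detector in 2-D, the pressure trace is the
time derivative of the line integral of p0 over the circle of radius
``v_s * t`` centered on the detector, scaled by ``1 / (2 pi v_s)``. That line
integral has a closed form for a paraboloid, and so does its radial
derivative, so the expected signal can be evaluated exactly - this is the
ground truth against which discretized forward models are validated.

The dynamic simulator composes paraboloid absorbers with hemoglobin spectra
and a gas-challenge oxygenation schedule to emulate a multispectral in vivo
acquisition: wavelength cycling with oversampling, exponential transitions of
oxygen saturation following a rectangular breathing-gas waveform, and
additive Gaussian detector noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .coords import CoordinateSystem, ScalarAxis, image_grid_vectors
from .datamodel import AcousticFrame, DetectorGeometry, ImageFrame, write_dataset

__all__ = [
    "ParaboloidSource",
    "PhantomSpec",
    "DynamicSpectralSpec",
    "sample_phantom",
    "rasterize",
    "arc_integral",
    "analytical_signal",
    "simulate_dynamic_dataset",
]


@dataclass(frozen=True)
class ParaboloidSource:
    center: tuple
    radius: float
    amplitude: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))


@dataclass(frozen=True)
class PhantomSpec:
    sources: tuple
    fov: float
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "sources", tuple(self.sources))
        half = self.fov / 2.0
        for s in self.sources:
            if abs(s.center[0]) + s.radius > half or abs(s.center[1]) + s.radius > half:
                raise ValueError("source disc must lie wholly inside the field of view")
        for i, a in enumerate(self.sources):
            for b in self.sources[i + 1 :]:
                d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d <= a.radius + b.radius:
                    raise ValueError("sources must be pairwise non-overlapping")


def sample_phantom(
    n_sources_range=(1, 8),
    radius_range=None,
    amplitude_range=(0.5, 2.0),
    fov: float = 0.025,
    seed: int = 0,
    max_tries: int = 10_000,
) -> PhantomSpec:
    """Draw a random non-overlapping paraboloid phantom (uniform distributions).

    Defaults: 1-8 sources, radii 2-15% of the FOV, amplitudes 0.5-2.
    Placement is rejection-sampled until all discs lie inside the FOV and are
    pairwise disjoint.
    """
    if radius_range is None:
        radius_range = (0.02 * fov, 0.15 * fov)
    if min(n_sources_range) < 1 or min(radius_range) <= 0 or min(amplitude_range) <= 0:
        raise ValueError("ranges must be positive")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_sources_range[0], n_sources_range[1] + 1))
    half = fov / 2.0
    sources: list[ParaboloidSource] = []
    tries = 0
    while len(sources) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} non-overlapping sources in {max_tries} tries"
            )
        R = float(rng.uniform(*radius_range))
        if R >= half:
            continue
        cx = float(rng.uniform(-half + R, half - R))
        cy = float(rng.uniform(-half + R, half - R))
        A = float(rng.uniform(*amplitude_range))
        cand = ParaboloidSource(center=(cx, cy), radius=R, amplitude=A)
        if all(
            np.hypot(cx - s.center[0], cy - s.center[1]) > R + s.radius for s in sources
        ):
            sources.append(cand)
    return PhantomSpec(sources=tuple(sources), fov=fov, seed=seed)


def rasterize(spec: PhantomSpec, coords: CoordinateSystem) -> ImageFrame:
    """Evaluate the summed paraboloid profile at every pixel center."""
    yc, xc = image_grid_vectors(coords)
    X, Y = np.meshgrid(xc, yc)
    img = np.zeros_like(X)
    for s in spec.sources:
        rho2 = (X - s.center[0]) ** 2 + (Y - s.center[1]) ** 2
        img += s.amplitude * np.clip(1.0 - rho2 / s.radius**2, 0.0, None)
    return ImageFrame(pixels=img, fov=(spec.fov, spec.fov))


# ---------------------------------------------------------------------------
# Closed-form circle integrals
# ---------------------------------------------------------------------------


def _arc_integral_scalar(A: float, R: float, D: float, rho: float) -> float:
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho == 0.0:
        return 0.0
    if D == 0.0:
        if rho >= R:
            return 0.0
        return 2.0 * np.pi * rho * A * (1.0 - rho**2 / R**2)
    u = (D**2 + rho**2 - R**2) / (2.0 * D * rho)
    if u >= 1.0:
        return 0.0
    if u <= -1.0:
        # integration circle entirely inside the source disc
        return 2.0 * np.pi * A * rho * (1.0 - (D**2 + rho**2) / R**2)
    phi = np.arccos(u)
    return A * rho * (
        2.0 * phi * (1.0 - (D**2 + rho**2) / R**2)
        + (4.0 * D * rho / R**2) * np.sin(phi)
    )


def arc_integral(source: ParaboloidSource, detector_pos, rho) -> float | np.ndarray:
    """Line integral of the paraboloid profile over the circle of radius rho
    centered at the detector (closed form)."""
    D = float(np.hypot(source.center[0] - detector_pos[0], source.center[1] - detector_pos[1]))
    A, R = source.amplitude, source.radius
    if np.ndim(rho) == 0:
        return _arc_integral_scalar(A, R, D, float(rho))
    return np.array([_arc_integral_scalar(A, R, D, float(r)) for r in np.ravel(rho)]).reshape(
        np.shape(rho)
    )


def _arc_integral_vec(A, R, D, rho):
    """Vectorized closed-form arc integral for a single source (D scalar)."""
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    if D == 0.0:
        m = (rho > 0) & (rho < R)
        out[m] = 2.0 * np.pi * rho[m] * A * (1.0 - rho[m] ** 2 / R**2)
        return out
    pos = rho > 0
    u = np.full_like(rho, np.inf)
    u[pos] = (D**2 + rho[pos] ** 2 - R**2) / (2.0 * D * rho[pos])
    inside = u <= -1.0
    partial = (u > -1.0) & (u < 1.0)
    out[inside] = 2.0 * np.pi * A * rho[inside] * (1.0 - (D**2 + rho[inside] ** 2) / R**2)
    r = rho[partial]
    phi = np.arccos(u[partial])
    out[partial] = A * r * (
        2.0 * phi * (1.0 - (D**2 + r**2) / R**2) + (4.0 * D * r / R**2) * np.sin(phi)
    )
    return out


def _arc_integral_derivative_vec(A, R, D, rho):
    """d/drho of the arc integral, closed form (kinks at tangency radii)."""
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    if D == 0.0:
        m = rho < R
        out[m] = 2.0 * np.pi * A * (1.0 - 3.0 * rho[m] ** 2 / R**2)
        return out
    pos = rho > 0
    u = np.full_like(rho, np.inf)
    u[pos] = (D**2 + rho[pos] ** 2 - R**2) / (2.0 * D * rho[pos])
    inside = u <= -1.0
    partial = (u > -1.0) & (u < 1.0)
    out[inside] = 2.0 * np.pi * A * (1.0 - (D**2 + 3.0 * rho[inside] ** 2) / R**2)
    r = rho[partial]
    phi = np.arccos(u[partial])
    g = A * r * (
        2.0 * phi * (1.0 - (D**2 + r**2) / R**2) + (4.0 * D * r / R**2) * np.sin(phi)
    )
    out[partial] = g / r - (2.0 * A * r / R**2) * (2.0 * r * phi - 2.0 * D * np.sin(phi))
    # rho == 0 and D < R: limit of the interior branch
    if D < R:
        z = rho == 0.0
        out[z] = 2.0 * np.pi * A * (1.0 - D**2 / R**2)
    return out


def analytical_signal(
    spec: PhantomSpec, geometry: DetectorGeometry, time_axis: ScalarAxis
) -> AcousticFrame:
    """Exact point-detector pressure traces for a paraboloid phantom.

    s_d(t) = (1 / (2 pi v_s)) d/dt [ sum_sources arc_integral(., r_d, v_s t) ].
    The radial derivative is evaluated in closed form except within one sample
    of the tangency radii |D - R| and D + R, where the closed form has a kink
    and a central difference of the arc integral (step v_s dt / 100) is used
    instead.
    """
    if not time_axis.is_uniform():
        raise ValueError("time axis must be uniform")
    vs = geometry.speed_of_sound
    t = time_axis.values
    rho = vs * t
    drho = vs * time_axis.spacing
    n_det = geometry.n_detectors
    out = np.zeros((n_det, t.size))
    for s in spec.sources:
        A, R = s.amplitude, s.radius
        for d in range(n_det):
            D = float(
                np.hypot(s.center[0] - geometry.positions[d, 0], s.center[1] - geometry.positions[d, 1])
            )
            g1 = _arc_integral_derivative_vec(A, R, D, rho)
            # patch samples within one sample spacing of a tangency radius
            near = np.zeros(rho.shape, dtype=bool)
            for rt in (abs(D - R), D + R):
                near |= np.abs(rho - rt) < drho
            if np.any(near):
                h = drho / 100.0
                rn = rho[near]
                fd = (
                    _arc_integral_vec(A, R, D, rn + h)
                    - _arc_integral_vec(A, R, D, np.maximum(rn - h, 0.0))
                ) / (2.0 * h)
                g1[near] = fd
            out[d] += g1 / (2.0 * np.pi)
    return AcousticFrame(samples=out, time_axis=time_axis)


# ---------------------------------------------------------------------------
# Dynamic multispectral gas-challenge simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DynamicSpectralSpec:
    """Specification of a synthetic gas-challenge acquisition.

    ``total_hemoglobin`` is a phantom of absorbers (relative Hb_tot maps);
    oxygen saturation in every source follows the rectangular breathing-gas
    waveform through first-order (mono-exponential) kinetics between the two
    plateaus. Frames cycle through ``wavelengths`` with ``oversampling``
    repeats per wavelength, one frame every ``frame_period`` seconds, with
    i.i.d. Gaussian noise of standard deviation ``noise_sigma`` added to the
    simulated transducer data.
    """

    total_hemoglobin: PhantomSpec
    wavelengths: tuple = (715.0, 730.0, 760.0, 800.0, 830.0, 850.0)
    oversampling: int = 1
    frame_period: float = 10.0
    n_cycles: int = 6
    so2_baseline: float = 0.60
    so2_hyperoxic: float = 0.90
    transition_rate: float = 1.0 / 6.0  # 1/s; plateau:transition ratio ~20:1
    switch_times: tuple = (120.0, 240.0)  # air->O2, O2->air
    noise_sigma: float = 0.0
    noise_relative: bool = False  # if True, sigma is a fraction of the RMS signal
    seed: int = 0
    spectra: Optional[object] = None  # EndmemberSpectra; defaults to shipped Hb/HbO2


def gas_waveform(times: np.ndarray, switch_times) -> np.ndarray:
    """Rectangular inhaled-pO2 reference: 0 on air, 1 on oxygen."""
    t_up, t_down = switch_times
    times = np.asarray(times, dtype=float)
    return ((times >= t_up) & (times < t_down)).astype(float)


def so2_timecourse(times, baseline, hyperoxic, rate, switch_times):
    """Mono-exponential relaxation of SO2 toward the plateau selected by the
    gas waveform; evaluated exactly segment by segment."""
    times = np.asarray(times, dtype=float)
    t_up, t_down = switch_times
    s = np.empty_like(times)
    # air segment: at baseline
    s[times < t_up] = baseline
    m = (times >= t_up) & (times < t_down)
    s[m] = hyperoxic + (baseline - hyperoxic) * np.exp(-rate * (times[m] - t_up))
    s_at_down = hyperoxic + (baseline - hyperoxic) * np.exp(-rate * (t_down - t_up))
    m = times >= t_down
    s[m] = baseline + (s_at_down - baseline) * np.exp(-rate * (times[m] - t_down))
    return s


def simulate_dynamic_dataset(
    dyn: DynamicSpectralSpec,
    geometry: DetectorGeometry,
    coords: CoordinateSystem,
    path,
    time_axis: Optional[ScalarAxis] = None,
    n_samples: int = 256,
):
    """Simulate a wavelength-cycled acquisition and write it to ``path``.

    Per frame, the absorption image mu_a(r, lambda) = HbO2(r,t) eps_HbO2(lambda)
    + Hb(r,t) eps_Hb(lambda) is rasterized and forward-projected through an
    exact-arc-length (CDMMI) model; Gaussian noise is added; ground-truth
    concentration maps, SO2 maps, and the reference waveform are stored in the
    file's /truth group.
    """
    from .coords import make_image_coords  # noqa: F401  (documentation aid)
    from .models import assemble_model, apply as model_apply
    from .spectral import builtin_hemoglobin_spectra

    spectra = dyn.spectra if dyn.spectra is not None else builtin_hemoglobin_spectra()
    wl = np.asarray(dyn.wavelengths, dtype=float)
    E = spectra.interpolate(wl)  # EndmemberSpectra at the schedule wavelengths
    if E.matrix.shape[1] != 2 or tuple(E.names) != ("HbO2", "Hb"):
        raise ValueError("dynamic simulation expects HbO2/Hb endmember spectra")

    fov = dyn.total_hemoglobin.fov
    if time_axis is None:
        from .datamodel import fov_time_axis

        time_axis = fov_time_axis(geometry, fov, n_samples=n_samples)

    model = assemble_model("cdmmi", coords, geometry, time_axis)
    hbtot = rasterize(dyn.total_hemoglobin, coords).pixels

    n_frames = dyn.n_cycles * len(wl) * dyn.oversampling
    times = dyn.frame_period * np.arange(n_frames)
    schedule = np.tile(np.repeat(wl, dyn.oversampling), dyn.n_cycles)

    rng = np.random.default_rng(dyn.seed)
    so2_truth = np.empty((n_frames,) + hbtot.shape)
    conc_truth = np.empty((n_frames, 2) + hbtot.shape)
    eps = {w: E.matrix[i] for i, w in enumerate(E.wavelengths)}
    sinos = np.empty((n_frames, geometry.n_detectors * len(time_axis)))
    for k in range(n_frames):
        s_k = float(
            so2_timecourse(
                times[k], dyn.so2_baseline, dyn.so2_hyperoxic, dyn.transition_rate, dyn.switch_times
            )
        )
        hbo2 = hbtot * s_k
        hb = hbtot * (1.0 - s_k)
        e_hbo2, e_hb = eps[schedule[k]]
        mu_a = hbo2 * e_hbo2 + hb * e_hb
        sinos[k] = model_apply(model, mu_a).ravel()
        so2_truth[k] = np.where(hbtot > 0, s_k, np.nan)
        conc_truth[k, 0] = hbo2
        conc_truth[k, 1] = hb
    sigma = dyn.noise_sigma
    if dyn.noise_relative and sigma > 0:
        sigma = sigma * float(np.sqrt(np.mean(sinos**2)))
    if sigma > 0:
        sinos = sinos + rng.normal(0.0, sigma, size=sinos.shape)
    frames = [
        AcousticFrame(
            samples=sinos[k].reshape(geometry.n_detectors, len(time_axis)),
            time_axis=time_axis,
            wavelength=float(schedule[k]),
            laser_energy=1.0,
            timestamp=float(times[k]),
            frame_index=k,
        )
        for k in range(n_frames)
    ]

    truth = {
        "so2": so2_truth,
        "concentrations": conc_truth,
        "waveform": gas_waveform(times, dyn.switch_times),
        "times": times,
        "wavelength_schedule": schedule,
        "hbtot": hbtot,
    }
    truth_attrs = {
        "fov_m": fov,
        "endmembers": "HbO2,Hb",
        "so2_baseline": dyn.so2_baseline,
        "so2_hyperoxic": dyn.so2_hyperoxic,
        "transition_rate": dyn.transition_rate,
        "switch_times": np.asarray(dyn.switch_times),
        "noise_sigma": sigma,
    }
    return write_dataset(frames, geometry, path, truth=truth, truth_attrs=truth_attrs)
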