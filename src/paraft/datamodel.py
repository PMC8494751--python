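"""Frame containers, detector geometry, and the chunked on-disk dataset store.

The on-disk layout is a plain HDF5 file:

    /data                   float64 [n_frames, n_transducers, n_samples], chunked per frame
    /geometry/positions     float64 [n_transducers, 2]  (m)
    /geometry/weights       float64 [n_transducers]
    /geometry/speed_of_sound  scalar (m/s)
    /acquisition/wavelength_nm, /acquisition/energy, /acquisition/timestamp_s
    root attrs: dt_s, t0_s, format_version

Frames are read lazily (one chunk per frame), so arbitrarily large stores can
be processed with per-frame memory. All writes disable HDF5 object timestamps
so that a store written twice from the same inputs is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .coords import ScalarAxis, make_time_axis

__all__ = [
    "FormatError",
    "DetectorGeometry",
    "AcousticFrame",
    "ImageFrame",
    "MultispectralFrame",
    "UnmixedFrame",
    "DatasetStore",
    "open_dataset",
    "write_dataset",
    "ring_geometry",
    "fov_time_axis",
]

FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised when an on-disk store is missing a required group or attribute."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Point-detector positions (m), per-detector weights, and speed of sound (m/s)."""

    positions: np.ndarray
    speed_of_sound: float
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", positions)
        if positions.ndim != 2 or positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_detectors, 2)")
        if positions.shape[0] < 3:
            raise ValueError("geometry requires at least 3 detectors")
        # pairwise distinctness
        if len(np.unique(positions.round(12), axis=0)) != positions.shape[0]:
            raise ValueError("detector positions must be distinct")
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")
        w = self.weights
        w = np.ones(positions.shape[0]) if w is None else np.asarray(w, dtype=float)
        if w.shape != (positions.shape[0],) or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per detector")
        object.__setattr__(self, "weights", w)

    @property
    def n_detectors(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class AcousticFrame:
    """One laser shot: transducer x time pressure record with acquisition metadata."""

    samples: np.ndarray
    time_axis: ScalarAxis
    wavelength: Optional[float] = None
    laser_energy: float = 1.0
    timestamp: float = 0.0
    frame_index: int = 0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 2:
            raise ValueError("samples must be (n_transducers, n_times)")
        if samples.shape[1] != len(self.time_axis):
            raise ValueError("samples/time_axis length mismatch")
        if not self.time_axis.is_uniform():
            raise ValueError("time axis must be uniformly spaced")
        if self.time_axis.spacing <= 0:
            raise ValueError("time axis spacing must be positive")
        if self.laser_energy <= 0:
            raise ValueError("laser_energy must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_transducers(self) -> int:
        return self.samples.shape[0]

    @property
    def dt(self) -> float:
        return self.time_axis.spacing

    def with_samples(self, samples: np.ndarray) -> "AcousticFrame":
        return AcousticFrame(
            samples=samples,
            time_axis=self.time_axis,
            wavelength=self.wavelength,
            laser_energy=self.laser_energy,
            timestamp=self.timestamp,
            frame_index=self.frame_index,
        )


@dataclass(frozen=True)
class ImageFrame:
    """Reconstructed (or rasterized) image on a uniform, origin-centered grid."""

    pixels: np.ndarray
    fov: tuple
    wavelength: Optional[float] = None
    timestamp: float = 0.0

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", pixels)
        if pixels.ndim != 2 or min(pixels.shape) < 2:
            raise ValueError("pixels must be a 2-D array with Nx, Ny >= 2")
        fov = (float(self.fov[0]), float(self.fov[1])) if np.ndim(self.fov) else (
            float(self.fov),
            float(self.fov),
        )
        if fov[0] <= 0 or fov[1] <= 0:
            raise ValueError("fov must be positive")
        object.__setattr__(self, "fov", fov)

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def pixel_size(self) -> tuple:
        ny, nx = self.pixels.shape
        return (self.fov[1] / ny, self.fov[0] / nx)


@dataclass(frozen=True)
class MultispectralFrame:
    """Full-spectrum image estimate at one point in time."""

    stack: np.ndarray
    wavelengths: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self):
        stack = np.asarray(self.stack, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "stack", stack)
        object.__setattr__(self, "wavelengths", wl)
        if stack.ndim != 3:
            raise ValueError("stack must be (N_lambda, Ny, Nx)")
        if wl.ndim != 1 or wl.size != stack.shape[0]:
            raise ValueError("wavelengths must match stack leading dimension")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass(frozen=True)
class UnmixedFrame:
    """Per-endmember concentration maps plus an oxygen-saturation map.

    so2 is NaN wherever total hemoglobin is zero (undefined ratio).
    """

    concentrations: np.ndarray
    endmember_names: tuple
    so2: Optional[np.ndarray] = None
    timestamp: float = 0.0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "endmember_names", tuple(self.endmember_names))
        if conc.ndim != 3 or conc.shape[0] != len(self.endmember_names):
            raise ValueError("concentrations must be (N_c, Ny, Nx) matching names")


def ring_geometry(
    n_detectors: int = 128,
    radius: float = 0.04,
    arc_deg: float = 270.0,
    speed_of_sound: float = 1500.0,
) -> DetectorGeometry:
    """Point detectors uniformly spaced on a circular arc centered on the origin.

    Defaults (128 detectors, 270 deg arc, 40 mm radius, 1500 m/s) are package
    defaults for synthetic work, not properties of any particular instrument.
    """
    if arc_deg >= 360.0:
        theta = np.linspace(0, 2 * np.pi, n_detectors, endpoint=False)
    else:
        half = np.deg2rad(arc_deg) / 2.0
        theta = np.linspace(-half, half, n_detectors) + np.pi / 2.0
    pos = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return DetectorGeometry(positions=pos, speed_of_sound=speed_of_sound)


def fov_time_axis(
    geometry: DetectorGeometry, fov: float, n_samples: int = 1024, margin: float = 0.02
) -> ScalarAxis:
    """Uniform time axis covering every detector-to-FOV distance.

    The first sample corresponds to the shortest detector-to-FOV distance and
    the last to the longest, padded by ``margin`` (fraction of the span), so
    integration circles of every sample intersect the field of view.
    """
    half = fov / 2.0
    pos = geometry.positions
    dx = np.maximum(np.abs(pos[:, 0]) - half, 0.0)
    dy = np.maximum(np.abs(pos[:, 1]) - half, 0.0)
    dmin = float(np.min(np.hypot(dx, dy)))
    corners = np.array([[sx * half, sy * half] for sx in (-1, 1) for sy in (-1, 1)])
    dmax = float(np.max(np.linalg.norm(pos[:, None, :] - corners[None], axis=2)))
    span = dmax - dmin
    r0 = max(dmin - margin * span, 0.0)
    r1 = dmax + margin * span
    vs = geometry.speed_of_sound
    dt = (r1 - r0) / (vs * (n_samples - 1))
    return make_time_axis(n_samples, dt, t0=r0 / vs)


# ---------------------------------------------------------------------------
# On-disk store
# ---------------------------------------------------------------------------


def _require(obj, name: str, kind: str):
    if name not in obj:
        raise FormatError(f"store is missing required {kind} {name!r}")
    return obj[name]


class DatasetStore:
    """Lazy, random-access view of an acoustic dataset file.

    ``get_frame(k)`` reads exactly one chunk; repeated reads are bit-identical.
    """

    def __init__(self, path):
        self.path = os.fspath(path)
        self._file = h5py.File(self.path, "r")
        try:
            self._validate()
        except Exception:
            self._file.close()
            raise

    def _validate(self):
        f = self._file
        data = _require(f, "data", "dataset")
        geo = _require(f, "geometry", "group")
        _require(geo, "positions", "dataset")
        _require(geo, "speed_of_sound", "dataset")
        acq = _require(f, "acquisition", "group")
        for k in ("wavelength_nm", "energy", "timestamp_s"):
            _require(acq, k, "dataset")
        for attr in ("dt_s", "t0_s", "format_version"):
            if attr not in f.attrs:
                raise FormatError(f"store is missing required attribute {attr!r}")
        if float(f.attrs["dt_s"]) <= 0:
            raise ValueError("dt_s must be positive")
        if data.ndim != 3:
            raise FormatError("/data must be a 3-D (frames, transducers, samples) dataset")

    # -- basic protocol ----------------------------------------------------
    def close(self):
        self._file.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- accessors ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self._file["data"].shape[0]

    @property
    def dt(self) -> float:
        return float(self._file.attrs["dt_s"])

    @property
    def t0(self) -> float:
        return float(self._file.attrs["t0_s"])

    @property
    def time_axis(self) -> ScalarAxis:
        n = self._file["data"].shape[2]
        return make_time_axis(n, self.dt, t0=self.t0)

    @property
    def geometry(self) -> DetectorGeometry:
        g = self._file["geometry"]
        weights = g["weights"][...] if "weights" in g else None
        return DetectorGeometry(
            positions=g["positions"][...],
            speed_of_sound=float(g["speed_of_sound"][()]),
            weights=weights,
        )

    @property
    def acquisition(self) -> pd.DataFrame:
        acq = self._file["acquisition"]
        return pd.DataFrame(
            {
                "wavelength_nm": acq["wavelength_nm"][...],
                "energy": acq["energy"][...],
                "timestamp_s": acq["timestamp_s"][...],
            }
        )

    def get_frame(self, k: int) -> AcousticFrame:
        n = self.n_frames
        if not 0 <= k < n:
            raise IndexError(f"frame index {k} out of range [0, {n})")
        acq = self._file["acquisition"]
        wl = float(acq["wavelength_nm"][k])
        return AcousticFrame(
            samples=self._file["data"][k],
            time_axis=self.time_axis,
            wavelength=None if np.isnan(wl) else wl,
            laser_energy=float(acq["energy"][k]),
            timestamp=float(acq["timestamp_s"][k]),
            frame_index=k,
        )

    def iter_frames(self):
        for k in range(self.n_frames):
            yield self.get_frame(k)

    # -- optional ground-truth payload (written by the dynamic simulator) ---
    @property
    def has_truth(self) -> bool:
        return "truth" in self._file

    def truth(self) -> dict:
        if not self.has_truth:
            raise FormatError("store carries no /truth group")
        g = self._file["truth"]
        out = {k: g[k][...] for k in g}
        out.update({f"attr:{k}": g.attrs[k] for k in g.attrs})
        return out


def _create_group(f: h5py.File, name: str) -> h5py.Group:
    gcpl = h5py.h5p.create(h5py.h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    gid = h5py.h5g.create(f.id, name.encode(), gcpl=gcpl)
    return h5py.Group(gid)


def write_dataset(
    frames: Sequence[AcousticFrame],
    geometry: DetectorGeometry,
    path,
    truth: Optional[dict] = None,
    truth_attrs: Optional[dict] = None,
):
    """Write frames + geometry to the repo HDF5 layout; round-trips bit-exactly."""
    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an empty frame list")
    n_tr = frames[0].n_transducers
    n_t = len(frames[0].time_axis)
    dt = frames[0].dt
    t0 = float(frames[0].time_axis.values[0])
    for fr in frames:
        if fr.samples.shape != (n_tr, n_t):
            raise ValueError("all frames must share (n_transducers, n_times)")
        if not np.isclose(fr.dt, dt, rtol=1e-12):
            raise ValueError("all frames must share the time axis spacing")
    if n_tr != geometry.n_detectors:
        raise ValueError("frame transducer count does not match geometry")

    path = os.fspath(path)
    with h5py.File(path, "w", libver="earliest") as f:
        f.attrs["dt_s"] = dt
        f.attrs["t0_s"] = t0
        f.attrs["format_version"] = FORMAT_VERSION
        data = np.stack([fr.samples for fr in frames]).astype(float)
        f.create_dataset("data", data=data, chunks=(1, n_tr, n_t), track_times=False)
        geo = _create_group(f, "geometry")
        geo.create_dataset("positions", data=geometry.positions, track_times=False)
        geo.create_dataset("weights", data=geometry.weights, track_times=False)
        geo.create_dataset(
            "speed_of_sound", data=float(geometry.speed_of_sound), track_times=False
        )
        acq = _create_group(f, "acquisition")
        wl = np.array(
            [np.nan if fr.wavelength is None else fr.wavelength for fr in frames]
        )
        acq.create_dataset("wavelength_nm", data=wl, track_times=False)
        acq.create_dataset(
            "energy", data=np.array([fr.laser_energy for fr in frames]), track_times=False
        )
        acq.create_dataset(
            "timestamp_s", data=np.array([fr.timestamp for fr in frames]), track_times=False
        )
        if truth is not None:
            tg = _create_group(f, "truth")
            for k, v in truth.items():
                tg.create_dataset(k, data=np.asarray(v), track_times=False)
            for k, v in (truth_attrs or {}).items():
                tg.attrs[k] = v
    return path


def open_dataset(path) -> DatasetStore:
    """Open a repo-format HDF5 store with lazy per-frame access."""
    return DatasetStore(path)
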