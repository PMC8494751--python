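"""Coordinate systems for image and data spaces.

Images live on a uniform pixel-center grid described by two scalar axes;
acoustic data live on a (transducer, time) grid where the transducer axis is
a vector axis (each index carries an (x, y) position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalarAxis",
    "VectorAxis",
    "CoordinateSystem",
    "make_image_coords",
    "make_time_axis",
]


@dataclass(frozen=True)
class ScalarAxis:
    """A strictly increasing real-valued axis (e.g. x position, time)."""

    name: str
    units: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError(f"axis {self.name!r}: values must be a non-empty 1-D vector")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise ValueError(f"axis {self.name!r}: values must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Uniform spacing; raises if the axis is not uniform."""
        d = np.diff(self.values)
        if d.size == 0:
            raise ValueError(f"axis {self.name!r} has a single sample, no spacing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError(f"axis {self.name!r} is not uniformly spaced")
        return float(d[0])

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.values)
        return d.size > 0 and bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))


@dataclass(frozen=True)
class VectorAxis:
    """An integer-indexed axis whose elements are fixed-length position tuples."""

    name: str
    units: str
    positions: np.ndarray

    def __post_init__(self):
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", positions)
        if positions.ndim != 2 or positions.shape[0] == 0:
            raise ValueError(
                f"axis {self.name!r}: positions must be a non-empty (n, k) array"
            )

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class CoordinateSystem:
    axes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "axes", tuple(self.axes))
        dims = {
            ax.positions.shape[1]
            for ax in self.axes
            if isinstance(ax, VectorAxis)
        }
        if len(dims) > 1:
            raise ValueError("all VectorAxis entries must share one dimensionality")

    @property
    def shape(self) -> tuple:
        return tuple(len(ax) for ax in self.axes)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.axes else 0

    def axis(self, name: str):
        for ax in self.axes:
            if ax.name == name:
                return ax
        raise KeyError(f"no axis named {name!r}")


def make_image_coords(n: int, fov: float) -> CoordinateSystem:
    """Uniform n x n pixel-center grid spanning a square field of view.

    Pixel centers are spaced fov/n apart and the grid is centered on the
    origin, so pixel i sits at -fov/2 + (i + 1/2) * fov/n.
    """
    if n < 2:
        raise ValueError("image grid requires n >= 2")
    if fov <= 0:
        raise ValueError("fov must be positive")
    h = fov / n
    centers = -fov / 2.0 + (np.arange(n) + 0.5) * h
    return CoordinateSystem(
        axes=(
            ScalarAxis("y", "m", centers.copy()),
            ScalarAxis("x", "m", centers.copy()),
        )
    )


def make_time_axis(n_samples: int, dt: float, t0: float = 0.0) -> ScalarAxis:
    if n_samples < 2:
        raise ValueError("time axis requires >= 2 samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return ScalarAxis("t", "s", t0 + dt * np.arange(n_samples))


def image_grid_vectors(coords: CoordinateSystem):
    """(y_centers, x_centers) convenience accessor for an image coordinate system."""
    return coords.axis("y").values, coords.axis("x").values
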