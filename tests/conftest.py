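import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paraft import (
    assemble_model,
    fov_time_axis,
    make_image_coords,
    ring_geometry,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FOV = 0.025


@pytest.fixture(scope="session")
def fov():
    return FOV


@pytest.fixture(scope="session")
def small_geometry():
    """16 point detectors on a full ring; enough for solver-level tests."""
    return ring_geometry(n_detectors=16, arc_deg=360.0)


@pytest.fixture(scope="session")
def small_time_axis(small_geometry):
    return fov_time_axis(small_geometry, FOV, n_samples=128)


@pytest.fixture(scope="session")
def small_coords():
    return make_image_coords(12, FOV)


@pytest.fixture(scope="session")
def small_model(small_coords, small_geometry, small_time_axis):
    return assemble_model("dimmi", small_coords, small_geometry, small_time_axis)


@pytest.fixture(scope="session")
def small_model_cdmmi(small_coords, small_geometry, small_time_axis):
    return assemble_model("cdmmi", small_coords, small_geometry, small_time_axis)


def arc_length_in_square(xd, yd, rho, half):
    """Independent oracle: length of the circle of radius rho about (xd, yd)
    inside the square [-half, half]^2, from border crossings only."""
    if rho <= 0:
        return 0.0
    th = []
    for e in (-half, half):
        u = (e - xd) / rho
        if abs(u) < 1:
            a = np.arccos(u)
            th += [a, -a]
        v = (e - yd) / rho
        if abs(v) < 1:
            b = np.arcsin(v)
            th += [b, np.pi - b]
    th = np.mod(np.array(th) + np.pi, 2 * np.pi) - np.pi
    if th.size == 0:
        inside = abs(xd + rho) < half and abs(xd) < half and abs(yd) < half
        return 2 * np.pi * rho if inside else 0.0
    th = np.sort(th)
    th = np.append(th, th[0] + 2 * np.pi)
    dth = np.diff(th)
    mid = th[:-1] + dth / 2
    px = xd + rho * np.cos(mid)
    py = yd + rho * np.sin(mid)
    keep = (np.abs(px) < half) & (np.abs(py) < half)
    return float(rho * dth[keep].sum())
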