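"""Angle bookkeeping on the periodic domain [-180, 180) degrees."""

from __future__ import annotations

import numpy as np

DEG = 360.0
UNIFORM_DENSITY = 1.0 / DEG  # P0-bar, per degree


def wrap_deg(x):
    """Wrap angle(s) to [-180, 180) degrees."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_bias(x):
    """Wrap a signed difference to (-180, 180] degrees.

    The open end is at -180 so that an exact half-turn is reported as
    +180, keeping e.g. bias(179, -179) = +2 rather than -358.
    """
    w = (-np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    return -w


def wrap_rad(x):
    """Wrap angle(s) to [-pi, pi) radians."""
    return (np.asarray(x, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi


def angle_grid(n: int = 2000) -> np.ndarray:
    """Uniform periodic grid of n angles in degrees, starting at -180.

    n = 2000 gives the 0.18 deg spacing used by the fine simulation
    profile; n must divide 360 exactly into a float-representable step.
    """
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    return -180.0 + (360.0 / n) * np.arange(n)


def grid_spacing(grid: np.ndarray) -> float:
    """Spacing of a uniform periodic degree grid; raises if non-uniform."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("invalid grid: need a 1-d grid with >= 2 points")
    d = np.diff(grid)
    dx = 360.0 / grid.size
    if not np.allclose(d, dx, rtol=0, atol=1e-9 * max(1.0, dx)):
        raise ValueError("invalid grid: spacing is not uniform over 360 deg")
    return dx
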