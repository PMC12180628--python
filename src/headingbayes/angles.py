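"""Angle conventions and wrapping helpers.

Headings are degrees at every public interface and radians internally.
0 is straight ahead, negative angles are leftward, positive rightward,
and every angle lives on the circle [-180, 180) degrees / [-pi, pi) rad.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_rad(theta):
    """Wrap angle(s) in radians to the canonical interval [-pi, pi)."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi, TWO_PI) - np.pi


def wrap_deg(theta):
    """Wrap angle(s) in degrees to the canonical interval [-180, 180)."""
    return np.mod(np.asarray(theta, dtype=float) + 180.0, 360.0) - 180.0


def deg2rad(theta_deg):
    return np.deg2rad(np.asarray(theta_deg, dtype=float))


def rad2deg(theta_rad):
    return np.rad2deg(np.asarray(theta_rad, dtype=float))


def wrapped_diff_rad(a, b):
    """Signed circular difference a - b in radians, in [-pi, pi)."""
    return wrap_rad(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def wrapped_diff_deg(a, b):
    """Signed circular difference a - b in degrees, in [-180, 180)."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circular_grid(resolution: int) -> np.ndarray:
    """Uniform grid of `resolution` points on [-pi, pi), endpoint excluded.

    The excluded endpoint pi is identified with -pi; with this layout the
    plain Riemann sum times the spacing is the exact trapezoidal rule for
    periodic integrands (spectrally accurate for smooth densities).
    """
    if resolution < 8:
        raise ValueError(f"grid resolution must be >= 8, got {resolution}")
    return -np.pi + TWO_PI * np.arange(resolution) / resolution


def circular_integral(values: np.ndarray, grid: np.ndarray) -> float:
    """Integrate tabulated values over the circle (periodic trapezoid)."""
    values = np.asarray(values, dtype=float)
    spacing = TWO_PI / len(grid)
    return float(values.sum() * spacing)


def circular_mean_rad(angles, weights=None):
    """Circular mean direction of angles (radians); weights need not sum to 1."""
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        c = np.cos(angles).mean()
        s = np.sin(angles).mean()
    else:
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        c = float(np.cos(angles) @ weights) / total
        s = float(np.sin(angles) @ weights) / total
    return float(np.arctan2(s, c)), float(np.hypot(c, s))


def circular_sd_from_R(R) -> float:
    """Circular standard deviation sqrt(2 (1 - R)) in radians.

    R is the mean resultant length of the angle distribution.
    """
    return float(np.sqrt(np.maximum(2.0 * (1.0 - R), 0.0)))
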