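"""Heading prior: a two-peak von Mises mixture over direction.

Under efficient coding the prior over heading direction is inversely
proportional to the discrimination threshold, p(theta) ~ 1 / D(theta).
Human heading discrimination is best straight ahead and straight back, so
the prior has characteristic peaks at 0 and 180 degrees; a two-component
von Mises mixture with peaks at those directions is the smooth
approximation used throughout this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .angles import (
    TWO_PI,
    circular_grid,
    circular_integral,
    deg2rad,
    wrap_rad,
)

DEFAULT_RESOLUTION = 1024

__all__ = [
    "PriorModel",
    "build_prior",
    "uniform_prior",
    "prior_from_thresholds",
    "DEFAULT_RESOLUTION",
]


def _vm_density(theta, mu, kappa):
    """von Mises density exp(k cos(theta-mu)) / (2 pi I0(k)), stable in k."""
    # i0e(k) = exp(-k) I0(k) keeps the ratio finite for large concentration
    return np.exp(kappa * (np.cos(theta - mu) - 1.0)) / (TWO_PI * special.i0e(kappa))


def _mixture_density(theta, peaks, concentrations, weights):
    dens = np.zeros_like(np.asarray(theta, dtype=float))
    for mu, kap, w in zip(peaks, concentrations, weights):
        if w > 0:
            dens = dens + w * _vm_density(theta, mu, kap)
    return dens


@dataclass(frozen=True)
class PriorModel:
    """Tabulated heading prior on a uniform circular grid.

    Attributes
    ----------
    grid : ndarray
        Uniform grid over [-pi, pi) in radians, endpoint excluded.
    density : ndarray
        Prior density at each grid point, unit circular integral.
    peak_locations : tuple of float
        Component means in radians (default straight ahead and straight back).
    concentrations, mixture_weights : tuple of float
        von Mises mixture parameters that generated the table (informational
        when the prior came from a threshold fit).
    """

    grid: np.ndarray
    density: np.ndarray
    peak_locations: tuple = (0.0, np.pi)
    concentrations: tuple = (2.0, 2.0)
    mixture_weights: tuple = (0.5, 0.5)
    fit_info: dict = field(default_factory=dict, compare=False)

    @property
    def resolution(self) -> int:
        return len(self.grid)

    def pdf(self, theta_rad):
        """Density at arbitrary angles (periodic linear interpolation)."""
        theta = wrap_rad(theta_rad)
        return np.interp(
            theta,
            np.append(self.grid, np.pi),
            np.append(self.density, self.density[0]),
        )

    def is_normalized(self, tol: float = 1e-8) -> bool:
        return abs(circular_integral(self.density, self.grid) - 1.0) < tol

    def with_resolution(self, resolution: int) -> "PriorModel":
        """Re-tabulate the same mixture on a grid of a different size."""
        if resolution == self.resolution:
            return self
        grid = circular_grid(resolution)
        density = _mixture_density(
            grid, self.peak_locations, self.concentrations, self.mixture_weights
        )
        density = density / circular_integral(density, grid)
        return PriorModel(
            grid=grid,
            density=density,
            peak_locations=self.peak_locations,
            concentrations=self.concentrations,
            mixture_weights=self.mixture_weights,
            fit_info=dict(self.fit_info),
        )


def build_prior(
    peaks_deg=(0.0, 180.0),
    concentrations=(2.0, 2.0),
    weights=(0.5, 0.5),
    resolution: int = DEFAULT_RESOLUTION,
) -> PriorModel:
    """Tabulate a two-peak von Mises mixture prior.

    Parameters are in degrees at this interface; concentrations are ordinary
    von Mises kappas (0 gives a flat component). Weights are renormalized to
    sum to one; all-zero weights are rejected.
    """
    weights = np.asarray(weights, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(weights < 0):
        raise ValueError(f"mixture weights must be nonnegative, got {weights}")
    if weights.sum() <= 0:
        raise ValueError("at least one mixture weight must be positive")
    if np.any(concentrations < 0):
        raise ValueError(f"concentrations must be >= 0, got {concentrations}")
    weights = weights / weights.sum()
    peaks = wrap_rad(deg2rad(peaks_deg))

    grid = circular_grid(resolution)
    density = _mixture_density(grid, peaks, concentrations, weights)
    density = density / circular_integral(density, grid)
    return PriorModel(
        grid=grid,
        density=density,
        peak_locations=tuple(np.atleast_1d(peaks)),
        concentrations=tuple(concentrations),
        mixture_weights=tuple(weights),
    )


def uniform_prior(resolution: int = DEFAULT_RESOLUTION) -> PriorModel:
    """Flat prior 1/(2 pi): the homogeneous-coding control case."""
    return build_prior(concentrations=(0.0, 0.0), resolution=resolution)


def prior_from_thresholds(
    thresholds,
    resolution: int = DEFAULT_RESOLUTION,
    fit_peaks: bool = False,
) -> PriorModel:
    """Fit the two-peak von Mises prior to discrimination thresholds.

    The target density is the normalized reciprocal threshold 1/D(theta)
    (efficient coding: precision follows the prior). A two-component von
    Mises mixture is then fitted by least squares on the density scale,
    peaks fixed at 0 and 180 degrees unless ``fit_peaks`` frees them.

    Parameters
    ----------
    thresholds : DataFrame or array-like
        Columns ``theta_deg`` and ``threshold_deg`` (or a two-column array);
        must sample the circle densely enough to interpolate, all D > 0.
    """
    if isinstance(thresholds, pd.DataFrame):
        theta_deg = thresholds["theta_deg"].to_numpy(dtype=float)
        d_vals = thresholds["threshold_deg"].to_numpy(dtype=float)
    else:
        arr = np.asarray(thresholds, dtype=float)
        theta_deg, d_vals = arr[:, 0], arr[:, 1]

    bad = ~np.isfinite(d_vals) | (d_vals <= 0)
    if np.any(bad):
        offending = theta_deg[bad]
        raise ValueError(
            "discrimination thresholds must be positive and finite; "
            f"offending angles (deg): {offending.tolist()}"
        )

    theta = wrap_rad(deg2rad(theta_deg))
    order = np.argsort(theta)
    theta, d_vals = theta[order], d_vals[order]

    grid = circular_grid(resolution)
    # periodic linear interpolation of the reciprocal threshold
    theta_ext = np.concatenate([theta - TWO_PI, theta, theta + TWO_PI])
    recip_ext = np.tile(1.0 / d_vals, 3)
    target = np.interp(grid, theta_ext, recip_ext)
    target = target / circular_integral(target, grid)

    def residuals(params):
        if fit_peaks:
            k1, k2, w_logit, mu1, mu2 = params
        else:
            k1, k2, w_logit = params
            mu1, mu2 = 0.0, np.pi
        w1 = 1.0 / (1.0 + np.exp(-w_logit))
        dens = _mixture_density(grid, (mu1, mu2), (k1, k2), (w1, 1.0 - w1))
        return dens - target

    x0 = [2.0, 2.0, 0.0] + ([0.0, np.pi] if fit_peaks else [])
    lower = [0.0, 0.0, -10.0] + ([-np.pi, 0.0] if fit_peaks else [])
    upper = [200.0, 200.0, 10.0] + ([np.pi, TWO_PI] if fit_peaks else [])
    sol = optimize.least_squares(residuals, x0, bounds=(lower, upper))

    if fit_peaks:
        k1, k2, w_logit, mu1, mu2 = sol.x
        peaks = (float(wrap_rad(mu1)), float(wrap_rad(mu2)))
    else:
        k1, k2, w_logit = sol.x
        peaks = (0.0, np.pi)
    w1 = 1.0 / (1.0 + np.exp(-w_logit))
    weights = (float(w1), float(1.0 - w1))
    if min(weights) < 1e-3:
        warnings.warn(
            "prior fit is degenerate: one mixture weight collapsed to "
            f"{min(weights):.2e}; the fitted prior is effectively unimodal",
            RuntimeWarning,
            stacklevel=2,
        )

    density = _mixture_density(grid, peaks, (k1, k2), weights)
    density = density / circular_integral(density, grid)
    return PriorModel(
        grid=grid,
        density=density,
        peak_locations=peaks,
        concentrations=(float(k1), float(k2)),
        mixture_weights=weights,
        fit_info={
            "cost": float(sol.cost),
            "success": bool(sol.success),
            "rms_residual": float(np.sqrt(np.mean(sol.fun**2))),
        },
    )
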