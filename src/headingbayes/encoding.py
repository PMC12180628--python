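"""Efficient-coding transform from stimulus space to sensory space.

The cumulative prior F(theta) = int_{-pi}^{theta} p(v) dv maps heading
direction into the space where the observer's Fisher information is
uniform; sensory noise is homogeneous there. F is rescaled from [0, 1]
onto the sensory circle [-pi, pi) so that the von Mises noise model is
well formed and its concentration is an ordinary circular kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import TWO_PI, wrap_rad
from .prior import PriorModel

__all__ = ["SensoryMapping", "encode"]


@dataclass(frozen=True)
class SensoryMapping:
    """Tabulated cumulative-prior mapping with its inverse.

    Attributes
    ----------
    theta_nodes : ndarray
        Stimulus grid nodes in radians, [-pi, ..., pi] inclusive.
    F_values : ndarray
        Cumulative prior at the nodes; F(-pi) = 0, F(pi) = 1.
    sensory_values : ndarray
        F rescaled to the sensory circle: 2 pi F - pi, in [-pi, pi].
    """

    theta_nodes: np.ndarray
    F_values: np.ndarray
    sensory_values: np.ndarray
    prior: PriorModel

    def cdf(self, theta_rad):
        """Cumulative prior F(theta) in [0, 1]."""
        return np.interp(wrap_rad(theta_rad), self.theta_nodes, self.F_values)

    def forward(self, theta_rad):
        """Sensory coordinate F~(theta) = 2 pi F(theta) - pi."""
        return np.interp(wrap_rad(theta_rad), self.theta_nodes, self.sensory_values)

    def inverse(self, sensory_rad):
        """Stimulus angle with the given sensory coordinate.

        Monotone interpolation of the tabulated inverse; well defined
        wherever the prior density is positive (F strictly increasing).
        """
        return np.interp(wrap_rad(sensory_rad), self.sensory_values, self.theta_nodes)


def encode(prior: PriorModel) -> SensoryMapping:
    """Build the cumulative-prior sensory mapping for a normalized prior."""
    if not prior.is_normalized(tol=1e-6):
        raise ValueError("prior density must integrate to 1 over the circle")
    grid = prior.grid
    dens = prior.density
    spacing = TWO_PI / len(grid)
    # trapezoid cumulative over nodes [-pi, ..., pi]; the closing panel uses
    # the periodic image of the first density value
    panel = 0.5 * spacing * (dens + np.roll(dens, -1))
    F = np.concatenate([[0.0], np.cumsum(panel)])
    F = F / F[-1]  # absorb residual quadrature error so F(pi) = 1 exactly
    theta_nodes = np.append(grid, np.pi)
    sensory = TWO_PI * F - np.pi
    return SensoryMapping(
        theta_nodes=theta_nodes,
        F_values=F,
        sensory_values=sensory,
        prior=prior,
    )
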