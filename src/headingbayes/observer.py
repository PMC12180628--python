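"""Efficient Bayesian observer of heading and the response-range mapping.

The generative chain: a heading theta0 is encoded through the cumulative
prior into sensory space, a von Mises measurement m = F~(theta0) + eta is
drawn with concentration kappa, the observer decodes m to the posterior
mean estimate theta_hat(m) (L2 loss, circular mean), and the report is the
linearly scaled estimate theta_r = alpha_i * theta_hat, clipped to the
probe's response interval. alpha_i depends only on the response range of
condition i; the probe geometry (line / arc / circle) is metadata.

All densities here are tabulated on uniform circular grids; the periodic
trapezoid rule is spectrally accurate for these smooth integrands, so a
1024-point grid resolves every quantity far below the reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .angles import (
    TWO_PI,
    circular_grid,
    circular_integral,
    circular_sd_from_R,
    deg2rad,
    rad2deg,
    wrap_rad,
    wrapped_diff_deg,
)
from .encoding import SensoryMapping
from .prior import PriorModel

__all__ = [
    "ObserverParams",
    "ResponseCondition",
    "ResponseMapping",
    "DecoderTable",
    "ResponseDensity",
    "PredictionCurve",
    "likelihood",
    "posterior",
    "estimate",
    "apply_response_mapping",
    "decode_table",
    "response_density",
    "predict_bias_sd",
    "standard_condition",
    "STANDARD_CONDITIONS",
]


@dataclass(frozen=True)
class ObserverParams:
    """Sensory noise level of the observer.

    kappa is the von Mises concentration of the noise in sensory space;
    larger kappa means less noise. The decoding loss is squared error
    (posterior mean); it is recorded for completeness but not configurable.
    """

    kappa: float
    loss: str = "L2"

    def __post_init__(self):
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError(f"kappa must be positive and finite, got {self.kappa}")
        if self.loss != "L2":
            raise ValueError(f"only the L2 (posterior mean) loss is supported, got {self.loss!r}")


@dataclass(frozen=True)
class ResponseCondition:
    """A response probe: its angular range and (metadata-only) geometry."""

    label: str
    range_degrees: float
    geometry: str = "arc"  # line | arc | circle

    def __post_init__(self):
        if not 0 < self.range_degrees <= 360:
            raise ValueError(
                f"range_degrees must be in (0, 360], got {self.range_degrees}"
            )
        if self.geometry not in ("line", "arc", "circle"):
            raise ValueError(f"unknown probe geometry {self.geometry!r}")

    @property
    def is_full_circle(self) -> bool:
        return self.range_degrees >= 360.0

    @property
    def half_range_deg(self) -> float:
        return self.range_degrees / 2.0


STANDARD_CONDITIONS = {
    "line80": ResponseCondition("line80", 80.0, "line"),
    "arc80": ResponseCondition("arc80", 80.0, "arc"),
    "arc160": ResponseCondition("arc160", 160.0, "arc"),
    "arc240": ResponseCondition("arc240", 240.0, "arc"),
    "circle360": ResponseCondition("circle360", 360.0, "circle"),
}


def standard_condition(label: str) -> ResponseCondition:
    try:
        return STANDARD_CONDITIONS[label]
    except KeyError:
        raise KeyError(
            f"unknown condition {label!r}; standard conditions are "
            f"{sorted(STANDARD_CONDITIONS)}"
        ) from None


class ResponseMapping:
    """Per-condition scaling factors alpha_i of the perception-action stage."""

    def __init__(self, alphas: dict[str, float]):
        for label, a in alphas.items():
            if not np.isfinite(a) or a <= 0:
                raise ValueError(f"alpha for condition {label!r} must be > 0, got {a}")
        self._alphas = dict(alphas)

    def alpha_for(self, condition) -> float:
        label = condition.label if isinstance(condition, ResponseCondition) else condition
        try:
            return self._alphas[label]
        except KeyError:
            raise KeyError(
                f"no scaling factor alpha defined for condition {label!r}; "
                f"available: {sorted(self._alphas)}"
            ) from None

    @property
    def alphas(self) -> dict[str, float]:
        return dict(self._alphas)

    def __repr__(self):
        items = ", ".join(f"{k}={v:.3f}" for k, v in sorted(self._alphas.items()))
        return f"ResponseMapping({items})"


def _vm_pdf(x, kappa):
    """von Mises density about 0, numerically stable for large kappa."""
    return np.exp(kappa * (np.cos(x) - 1.0)) / (TWO_PI * special.i0e(kappa))


def likelihood(m: float, mapping: SensoryMapping, params: ObserverParams, theta_grid=None):
    """Likelihood p(m | theta) over the stimulus grid for one measurement m.

    m is a sensory-space coordinate in radians. As a function of m at fixed
    theta this is a von Mises density, so it integrates to one over the
    sensory circle.
    """
    if theta_grid is None:
        theta_grid = mapping.prior.grid
    return _vm_pdf(m - mapping.forward(theta_grid), params.kappa)


def posterior(m: float, mapping: SensoryMapping, prior: PriorModel, params: ObserverParams):
    """Posterior p(theta | m) on the stimulus grid, unit circular integral."""
    # work in log space so large kappa cannot underflow the evidence
    with np.errstate(divide="ignore"):
        log_post = params.kappa * np.cos(m - mapping.forward(prior.grid)) + np.log(
            prior.density
        )
    finite = np.isfinite(log_post)
    if not np.any(finite):
        raise FloatingPointError(
            f"posterior underflow: no grid point has positive mass at "
            f"m={m:.4f}, kappa={params.kappa:.4g}"
        )
    post = np.zeros_like(log_post)
    post[finite] = np.exp(log_post[finite] - log_post[finite].max())
    norm = circular_integral(post, prior.grid)
    if norm <= 0:
        raise FloatingPointError(
            f"posterior normalization failed at m={m:.4f}, kappa={params.kappa:.4g}"
        )
    return post / norm


def estimate(m: float, mapping: SensoryMapping, prior: PriorModel, params: ObserverParams) -> float:
    """L2-optimal heading estimate for measurement m, in degrees.

    The posterior mean of a circular variable is taken as the circular mean
    (direction of the average unit vector); for the concentrated posteriors
    of the forward-heading regime it coincides with the linear mean.
    """
    post = posterior(m, mapping, prior, params)
    grid = prior.grid
    w = post / post.sum()
    c = float(np.cos(grid) @ w)
    s = float(np.sin(grid) @ w)
    R = np.hypot(c, s)
    if R < 1e-12:
        raise FloatingPointError(
            f"posterior mean undefined (resultant length {R:.2e}) at m={m:.4f}"
        )
    return float(rad2deg(np.arctan2(s, c)))


def apply_response_mapping(theta_hat_deg, condition: ResponseCondition, mapping: ResponseMapping):
    """Reported heading: alpha * theta_hat, kept inside the probe's range.

    Scaling is about straight ahead (0 deg). Finite probes clip at
    +/- range/2; the full circle wraps instead of clipping.
    """
    alpha = mapping.alpha_for(condition)
    scaled = alpha * np.asarray(theta_hat_deg, dtype=float)
    if condition.is_full_circle:
        return np.mod(scaled + 180.0, 360.0) - 180.0
    h = condition.half_range_deg
    return np.clip(scaled, -h, h)


class DecoderTable:
    """Tabulated decoder theta_hat(m) for fixed prior and kappa.

    The decoder is a degree-one circular map: as m traverses the sensory
    circle once, theta_hat traverses the stimulus circle once. It is stored
    unwrapped (monotone nondecreasing, theta_hat(m + 2 pi) = theta_hat(m) +
    2 pi) so that change-of-variables densities and interpolation are plain
    one-dimensional operations.
    """

    def __init__(self, mapping: SensoryMapping, prior: PriorModel, params: ObserverParams,
                 n_m: int | None = None):
        self.mapping = mapping
        self.prior = prior
        self.params = params
        grid = prior.grid
        n_m = n_m or len(grid)
        m_grid = circular_grid(n_m)

        ftil = mapping.forward(grid)
        kappa = params.kappa
        # cos(m - F~) via outer products: cheaper than cos of an n_m x n matrix
        cosdiff = np.outer(np.cos(m_grid), np.cos(ftil)) + np.outer(
            np.sin(m_grid), np.sin(ftil)
        )
        post = np.exp(kappa * (cosdiff - 1.0)) * prior.density[None, :]
        c = post @ np.cos(grid)
        s = post @ np.sin(grid)
        norm = post.sum(axis=1)
        R = np.hypot(c, s) / np.maximum(norm, 1e-300)
        if np.any(norm <= 0) or np.any(R < 1e-12):
            raise FloatingPointError(
                "decoder undefined: posterior resultant length vanished for "
                f"some measurement (kappa={kappa:.4g})"
            )
        theta_hat = np.arctan2(s, c)

        unwrapped = np.unwrap(theta_hat)
        # anchor the branch so the value at the m closest to 0 lies in [-pi, pi)
        i0 = int(np.argmin(np.abs(m_grid)))
        unwrapped = unwrapped - TWO_PI * np.round(
            (unwrapped[i0] - wrap_rad(unwrapped[i0])) / TWO_PI
        )
        diffs = np.diff(unwrapped)
        if np.any(diffs < -1e-9):
            worst = float(diffs.min())
            raise FloatingPointError(
                "decoded estimate theta_hat(m) is not monotone in m (worst "
                f"backward step {worst:.3e} rad); increase the grid resolution "
                "or check the prior for near-zero density regions"
            )
        # periodic extension over three turns for seam-free interpolation
        self.m_nodes = np.concatenate([m_grid - TWO_PI, m_grid, m_grid + TWO_PI])
        self.theta_nodes = np.concatenate(
            [unwrapped - TWO_PI, unwrapped, unwrapped + TWO_PI]
        )
        self.m_grid = m_grid
        self.theta_hat = unwrapped

    def decode(self, m):
        """theta_hat(m) in radians, unwrapped (m may lie in [-2 pi, 2 pi])."""
        return np.interp(m, self.m_nodes, self.theta_nodes)

    def decode_deg(self, m):
        """theta_hat(m) wrapped to [-180, 180) degrees."""
        return rad2deg(wrap_rad(self.decode(m)))


def decode_table(mapping: SensoryMapping, prior: PriorModel, params: ObserverParams,
                 n_m: int | None = None) -> DecoderTable:
    """Build the decoder table theta_hat(m); see DecoderTable."""
    return DecoderTable(mapping, prior, params, n_m=n_m)


@dataclass(frozen=True)
class ResponseDensity:
    """Distribution of the reported heading for one true heading.

    The continuous part is tabulated at the (non-uniform) support points
    ``r_deg`` with density ``pdf_deg`` per degree; probability mass pushed
    outside a finite probe is kept as atoms at the interval boundaries.
    ``cdf_vals`` is the CDF at ``r_deg`` including the lower atom.
    """

    theta0_deg: float
    condition: ResponseCondition
    alpha: float
    r_deg: np.ndarray
    pdf_deg: np.ndarray
    cdf_vals: np.ndarray
    atom_lower: float
    atom_upper: float
    clip_deg: tuple | None  # (lo, hi) for finite probes, None for the circle

    def pdf(self, x_deg):
        """Continuous density (per degree) at reported headings x_deg.

        Zero outside the support; boundary atoms are not smeared into the
        density — query them via ``atom_lower`` / ``atom_upper``.
        """
        x = np.asarray(x_deg, dtype=float)
        if self.clip_deg is None:
            # full-circle support is stored folded onto [-180, 180]
            xw = np.mod(x + 180.0, 360.0) - 180.0
            return np.interp(xw, self.r_deg, self.pdf_deg)
        return np.interp(x, self.r_deg, self.pdf_deg, left=0.0, right=0.0)

    def cdf(self, x_deg):
        """CDF of the report at x_deg, boundary atoms included."""
        x = np.asarray(x_deg, dtype=float)
        if self.clip_deg is None:
            # canonical circular CDF with its cut at -180 deg
            xw = np.mod(x + 180.0, 360.0) - 180.0
            return np.interp(xw, self.r_deg, self.cdf_vals)
        lo, hi = self.clip_deg
        out = np.interp(x, self.r_deg, self.cdf_vals, left=0.0, right=1.0 - self.atom_upper)
        out = np.where(x >= hi, 1.0, out)
        out = np.where(x < lo, 0.0, out)
        return out

    def total_mass(self) -> float:
        """Continuous mass plus boundary atoms (== 1 up to quadrature)."""
        cont = float(np.trapezoid(self.pdf_deg, self.r_deg))
        return cont + self.atom_lower + self.atom_upper


def _measurement_grid(mu: float, n_m: int):
    """Uniform nodes mu - pi .. mu + pi (inclusive) centred on the mean."""
    return mu + np.linspace(-np.pi, np.pi, n_m + 1)


def response_density(
    theta0_deg: float,
    condition: ResponseCondition,
    prior: PriorModel,
    mapping: SensoryMapping,
    params: ObserverParams,
    response_mapping: ResponseMapping,
    decoder: DecoderTable | None = None,
    n_m: int | None = None,
) -> ResponseDensity:
    """Push the measurement distribution through decoding and scaling.

    Computes the density of the reported heading theta_r = alpha *
    theta_hat(m) with m ~ vonMises(F~(theta0), kappa), by change of
    variables along the monotone decoder; mass landing outside a finite
    probe is clipped into boundary atoms.
    """
    if decoder is None:
        decoder = DecoderTable(mapping, prior, params, n_m=n_m)
    alpha = response_mapping.alpha_for(condition)
    mu = float(mapping.forward(deg2rad(theta0_deg)))
    n_m = n_m or len(prior.grid)
    # measurement nodes are cheap (no decoder rebuild), so oversample them
    # relative to the decoder grid: the trapezoid mass error on the
    # non-uniform report support falls quadratically with node count
    n_meas = 4 * n_m

    m_nodes = _measurement_grid(mu, n_meas)
    p_m = _vm_pdf(m_nodes - mu, params.kappa)
    theta_hat = decoder.decode(m_nodes)  # unwrapped, monotone
    r = alpha * theta_hat  # radians, monotone in m

    dr_dm = np.gradient(r, m_nodes)
    if np.any(dr_dm <= 0):
        raise FloatingPointError(
            "decoded estimate is not strictly increasing over the measurement "
            f"support at theta0={theta0_deg:.1f} deg; use a finer grid"
        )
    f_r = p_m / dr_dm  # density per radian of the (unclipped) report

    # CDF of m along the nodes (trapezoid), normalized; tail truncation at
    # +/- pi from the mean is below machine precision for kappa >= ~1e-3
    dm = m_nodes[1] - m_nodes[0]
    cdf_m = np.concatenate([[0.0], np.cumsum(0.5 * dm * (p_m[1:] + p_m[:-1]))])
    cdf_m = cdf_m / cdf_m[-1]

    if condition.is_full_circle:
        # fold the (possibly over- or under-covering) branch density onto
        # the canonical circle [-180, 180]; with alpha != 1 periodic images
        # of the branch can overlap, so images at +/- 360 deg are summed
        branch_r = rad2deg(r)
        branch_f = deg2rad(1.0) * f_r  # per-degree density along the branch
        # the fold grid oversamples the branch so re-gridding the density
        # onto the canonical circle costs no visible mass
        x_grid = np.linspace(-180.0, 180.0, 4 * n_meas + 1)
        pdf_fold = np.zeros_like(x_grid)
        for k in (-360.0, 0.0, 360.0):
            pdf_fold += np.interp(
                x_grid + k, branch_r, branch_f, left=0.0, right=0.0
            )
        dx = x_grid[1] - x_grid[0]
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * dx * (pdf_fold[1:] + pdf_fold[:-1]))]
        )
        cdf = cdf / cdf[-1]
        return ResponseDensity(
            theta0_deg=float(theta0_deg),
            condition=condition,
            alpha=alpha,
            r_deg=x_grid,
            pdf_deg=pdf_fold,
            cdf_vals=cdf,
            atom_lower=0.0,
            atom_upper=0.0,
            clip_deg=None,
        )

    lo = -deg2rad(condition.half_range_deg)
    hi = -lo
    atom_lower = float(np.interp(lo, r, cdf_m)) if r[0] < lo else 0.0
    atom_upper = float(1.0 - np.interp(hi, r, cdf_m)) if r[-1] > hi else 0.0
    inside = (r >= lo) & (r <= hi)
    if not np.any(inside):
        # everything clips to one side; degenerate but total
        r_in = np.array([lo, hi])
        f_in = np.zeros(2)
        cdf_in = np.full(2, atom_lower)
    else:
        r_in = r[inside]
        f_in = f_r[inside]
        cdf_in = cdf_m[inside]
        # pin exact nodes at the clip boundaries so the CDF carries the
        # atoms without a one-cell gap
        if atom_lower > 0 and r_in[0] > lo:
            r_in = np.concatenate([[lo], r_in])
            f_in = np.concatenate([[np.interp(lo, r, f_r)], f_in])
            cdf_in = np.concatenate([[atom_lower], cdf_in])
        if atom_upper > 0 and r_in[-1] < hi:
            r_in = np.concatenate([r_in, [hi]])
            f_in = np.concatenate([f_in, [np.interp(hi, r, f_r)]])
            cdf_in = np.concatenate([cdf_in, [1.0 - atom_upper]])
    return ResponseDensity(
        theta0_deg=float(theta0_deg),
        condition=condition,
        alpha=alpha,
        r_deg=rad2deg(r_in),
        pdf_deg=deg2rad(1.0) * f_in,
        cdf_vals=cdf_in,
        atom_lower=atom_lower,
        atom_upper=atom_upper,
        clip_deg=(-condition.half_range_deg, condition.half_range_deg),
    )


@dataclass(frozen=True)
class PredictionCurve:
    """Model-predicted bias and circular SD of reports per true heading."""

    condition: ResponseCondition
    theta0_deg: np.ndarray
    bias_deg: np.ndarray
    sd_deg: np.ndarray
    kappa: float = field(default=np.nan)
    alpha: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition.label,
                "theta0_deg": self.theta0_deg,
                "bias_deg": self.bias_deg,
                "sd_deg": self.sd_deg,
            }
        )


def predict_bias_sd(
    theta0_grid_deg,
    condition: ResponseCondition,
    prior: PriorModel,
    mapping: SensoryMapping,
    params: ObserverParams,
    response_mapping: ResponseMapping,
    decoder: DecoderTable | None = None,
    n_m: int | None = None,
) -> PredictionCurve:
    """Marginalize the reported estimate over the measurement distribution.

    For each true heading theta0: the bias is the circular mean of the
    report minus theta0 (wrapped, in degrees) and the spread is the
    circular SD sqrt(2 (1 - R)) of the report, R being the mean resultant
    length of the report distribution under p(m | theta0).
    """
    if decoder is None:
        decoder = DecoderTable(mapping, prior, params, n_m=n_m)
    alpha = response_mapping.alpha_for(condition)
    theta0_grid_deg = np.atleast_1d(np.asarray(theta0_grid_deg, dtype=float))
    n_m = n_m or len(prior.grid)

    bias = np.empty_like(theta0_grid_deg)
    sd = np.empty_like(theta0_grid_deg)
    for i, theta0 in enumerate(theta0_grid_deg):
        mu = float(mapping.forward(deg2rad(theta0)))
        m_nodes = _measurement_grid(mu, n_m)
        w = _vm_pdf(m_nodes - mu, params.kappa)
        # trapezoid weights over the closed interval (endpoints are the same
        # circle point; half weights avoid double counting)
        w = w.copy()
        w[0] *= 0.5
        w[-1] *= 0.5
        w = w / w.sum()
        r = alpha * decoder.decode(m_nodes)
        if not condition.is_full_circle:
            h = deg2rad(condition.half_range_deg)
            r = np.clip(r, -h, h)
        c = float(np.cos(r) @ w)
        s = float(np.sin(r) @ w)
        mean_dir = np.arctan2(s, c)
        bias[i] = wrapped_diff_deg(rad2deg(mean_dir), theta0)
        sd[i] = rad2deg(circular_sd_from_R(np.hypot(c, s)))
    return PredictionCurve(
        condition=condition,
        theta0_deg=theta0_grid_deg,
        bias_deg=bias,
        sd_deg=sd,
        kappa=params.kappa,
        alpha=alpha,
    )
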