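import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import headingbayes as hb


@pytest.fixture(scope="session")
def default_prior():
    """Two-peak von Mises prior (peaks 0/180 deg, conc 2, equal weights)."""
    return hb.build_prior()


@pytest.fixture(scope="session")
def default_mapping(default_prior):
    return hb.encode(default_prior)


@pytest.fixture(scope="session")
def flat_prior():
    return hb.uniform_prior()


@pytest.fixture(scope="session")
def flat_mapping(flat_prior):
    return hb.encode(flat_prior)


@pytest.fixture(scope="session")
def fit_prior():
    """Coarser prior grid used for fitting-speed-sensitive tests."""
    return hb.build_prior(resolution=512)


@pytest.fixture(scope="session")
def exp3_design():
    return hb.make_design("exp3")


@pytest.fixture(scope="session")
def exp3_alphas():
    return {"arc80": 0.85, "arc160": 1.0, "arc240": 1.15}


@pytest.fixture(scope="session")
def exp3_trials(exp3_design, fit_prior, exp3_alphas):
    """One synthetic participant's exp3 session (540 trials, kappa=4)."""
    return hb.generate_trials(
        exp3_design,
        fit_prior,
        hb.ObserverParams(4.0),
        hb.ResponseMapping(exp3_alphas),
        seed=11,
        n_participants=1,
    )


def right_continuous_ecdf_distance(samples, density):
    """Max |ECDF - model CDF| at support nodes and their left limits.

    Uses the right-continuous empirical CDF so that boundary atoms
    (clipped mass) are compared jump-to-jump, and restricts queries to
    the canonical circle [-180, 180).
    """
    srt = np.sort(np.asarray(samples, dtype=float))
    xs = np.unique(np.concatenate([density.r_deg, srt[:: max(len(srt) // 2000, 1)]]))
    xs = np.concatenate([xs, xs - 1e-9])
    xs = xs[(xs >= -180.0) & (xs < 180.0)]
    emp = np.searchsorted(srt, xs, side="right") / len(srt)
    return float(np.max(np.abs(emp - density.cdf(xs))))


def sample_reports(theta0_deg, condition, prior, mapping, params, response_mapping,
                   n, rng):
    """Monte-Carlo draw of reported headings from the generative chain."""
    from scipy import stats

    decoder = hb.DecoderTable(mapping, prior, params)
    alpha = response_mapping.alpha_for(condition)
    mu = float(mapping.forward(np.deg2rad(theta0_deg)))
    eta = stats.vonmises.rvs(params.kappa, size=n, random_state=rng)
    m = mu + (np.mod(eta + np.pi, 2 * np.pi) - np.pi)
    r = alpha * decoder.decode(m)
    if condition.is_full_circle:
        return np.rad2deg(np.mod(r + np.pi, 2 * np.pi) - np.pi)
    h = np.deg2rad(condition.half_range_deg)
    return np.rad2deg(np.clip(r, -h, h))
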