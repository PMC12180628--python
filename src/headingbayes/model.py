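"""Model / Results front end for the heading observer.

``HeadingObserverModel`` binds a trial table to a heading prior and a set
of response conditions; ``fit()`` runs the joint maximum-likelihood
estimation of (kappa, alpha_1..alpha_C) and returns a
``HeadingObserverResults`` carrying the estimates, likelihood
diagnostics, a ``summary()`` table, and prediction / simulation /
plotting methods — the statsmodels idiom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__ as _version
from .empirical import bias_slopes, summarize_bias_sd
from .encoding import encode
from .inference import FitResult, fit_individual, fit_mle, negative_log_likelihood
from .observer import (
    ObserverParams,
    ResponseCondition,
    ResponseMapping,
    predict_bias_sd,
    standard_condition,
)
from .prior import PriorModel, build_prior
from .synthetic import ExperimentDesign, generate_trials

__all__ = ["HeadingObserverModel", "HeadingObserverResults"]

DEFAULT_FIT_RESOLUTION = 512


class HeadingObserverModel:
    """Efficient Bayesian observer with response-range scaling, bound to data.

    Parameters
    ----------
    trials : DataFrame
        Trial table with columns ``participant_id`` (optional for group
        fits), ``condition_label``, ``true_heading_deg``,
        ``reported_heading_deg``.
    prior : PriorModel, optional
        Heading prior; defaults to the two-peak von Mises mixture peaked
        straight ahead and straight back.
    conditions : dict, optional
        label -> ResponseCondition for nonstandard probes; standard labels
        (line80, arc80, arc160, arc240, circle360) resolve automatically.
    grid_resolution : int
        Circular grid size used during fitting; predictions default to the
        prior's own (finer) grid.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        prior: PriorModel | None = None,
        conditions: dict[str, ResponseCondition] | None = None,
        grid_resolution: int = DEFAULT_FIT_RESOLUTION,
    ):
        if prior is None:
            prior = build_prior()
        self.trials = trials.reset_index(drop=True)
        self.prior = prior
        self.fit_prior = prior.with_resolution(grid_resolution)
        self.grid_resolution = grid_resolution
        self.conditions = {}
        for label in sorted(self.trials["condition_label"].unique()):
            if conditions and label in conditions:
                self.conditions[label] = conditions[label]
            else:
                self.conditions[label] = standard_condition(label)

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame, **kwargs) -> "HeadingObserverModel":
        return cls(trials, **kwargs)

    def loglike(self, kappa: float, alphas: dict[str, float]) -> float:
        """Log-likelihood of the bound trials at the given parameters."""
        nll = negative_log_likelihood(
            self.trials,
            self.fit_prior,
            ObserverParams(kappa),
            ResponseMapping(alphas),
            conditions=self.conditions,
        )
        return -nll

    def fit(
        self,
        seed: int = 0,
        n_restarts: int = 5,
        constrain_circle_alpha: bool = False,
        **kwargs,
    ) -> "HeadingObserverResults":
        """Group-level (pooled) maximum-likelihood fit."""
        res = fit_mle(
            self.trials,
            self.fit_prior,
            conditions=self.conditions,
            seed=seed,
            n_restarts=n_restarts,
            constrain_circle_alpha=constrain_circle_alpha,
            **kwargs,
        )
        return HeadingObserverResults(self, res)

    def fit_individual(
        self, seed: int = 0, n_restarts: int = 5, **kwargs
    ) -> dict[str, "HeadingObserverResults"]:
        """Per-participant fits, keyed by participant id."""
        fits = fit_individual(
            self.trials,
            self.fit_prior,
            conditions=self.conditions,
            seed=seed,
            n_restarts=n_restarts,
            **kwargs,
        )
        return {pid: HeadingObserverResults(self, fr) for pid, fr in fits.items()}


class HeadingObserverResults:
    """Fit outcome: estimates, diagnostics, predictions, simulation."""

    def __init__(self, model: HeadingObserverModel, fitresult: FitResult):
        self.model = model
        self._fr = fitresult

    # -- estimates -------------------------------------------------------
    @property
    def kappa(self) -> float:
        return self._fr.kappa_hat

    @property
    def alphas(self) -> dict[str, float]:
        return dict(self._fr.alpha_hats)

    @property
    def params(self) -> pd.Series:
        vals = {"kappa": self.kappa}
        vals.update({f"alpha_{lb}": a for lb, a in sorted(self.alphas.items())})
        return pd.Series(vals)

    @property
    def nll(self) -> float:
        return self._fr.nll

    @property
    def llf(self) -> float:
        return -self._fr.nll

    @property
    def aic(self) -> float:
        k = 1 + len(self._fr.alpha_hats)
        return 2.0 * k + 2.0 * self._fr.nll

    @property
    def converged(self) -> bool:
        return self._fr.converged

    @property
    def fitresult(self) -> FitResult:
        return self._fr

    # -- model outputs ---------------------------------------------------
    def predict(
        self,
        theta0_deg=None,
        conditions: list[str] | None = None,
        n_m: int | None = None,
    ) -> pd.DataFrame:
        """Predicted bias and circular SD curves at the fitted parameters."""
        if theta0_deg is None:
            theta0_deg = np.array(
                sorted(self.model.trials["true_heading_deg"].unique())
            )
        labels = conditions or sorted(self.alphas)
        prior = self.model.prior
        mapping = encode(prior)
        params = ObserverParams(self.kappa)
        rmap = ResponseMapping(self.alphas)
        frames = []
        for lb in labels:
            cond = self.model.conditions.get(lb) or standard_condition(lb)
            curve = predict_bias_sd(
                theta0_deg, cond, prior, mapping, params, rmap, n_m=n_m
            )
            frames.append(curve.to_frame())
        return pd.concat(frames, ignore_index=True)

    def simulate(
        self, design: ExperimentDesign, seed: int = 0, **kwargs
    ) -> pd.DataFrame:
        """Trial table simulated from the fitted parameters."""
        return generate_trials(
            design,
            self.model.prior,
            ObserverParams(self.kappa),
            ResponseMapping(self.alphas),
            seed=seed,
            **kwargs,
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        fr = self._fr
        lines = [
            "Heading observer model — maximum likelihood fit",
            "=" * 55,
            f"level:           {fr.level}"
            + (f" (participant {fr.participant_id})" if fr.participant_id else ""),
            f"n trials:        {fr.n_trials}",
            f"log-likelihood:  {self.llf:.3f}",
            f"AIC:             {self.aic:.3f}",
            f"converged:       {fr.converged}   "
            f"(restarts: {fr.n_restarts_used}, seed: {fr.seed})",
            f"floored trials:  {fr.n_floored}",
            "-" * 55,
            f"{'parameter':<20}{'estimate':>12}",
            f"{'kappa (sensory)':<20}{fr.kappa_hat:>12.4f}",
        ]
        for lb, a in sorted(fr.alpha_hats.items()):
            lines.append(f"{'alpha ' + lb:<20}{a:>12.4f}")
        lines.append("=" * 55)
        lines.append(f"headingbayes {_version}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: empirical vs predicted bias and SD curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        else:
            axes = ax
        emp = summarize_bias_sd(self.model.trials, level="group")
        pred = self.predict()
        for lb, sub in emp.groupby("condition_label"):
            axes[0].plot(sub["theta0_deg"], sub["bias_deg"], "o", label=f"{lb} data")
            axes[1].plot(sub["theta0_deg"], sub["sd_deg"], "o")
        for lb, sub in pred.groupby("condition"):
            axes[0].plot(sub["theta0_deg"], sub["bias_deg"], "-", label=f"{lb} model")
            axes[1].plot(sub["theta0_deg"], sub["sd_deg"], "-")
        axes[0].set_xlabel("true heading (deg)")
        axes[0].set_ylabel("bias (deg)")
        axes[0].axhline(0.0, color="k", lw=0.5)
        axes[0].legend(fontsize=7)
        axes[1].set_xlabel("true heading (deg)")
        axes[1].set_ylabel("circular SD (deg)")
        return axes

    def empirical_slopes(self) -> pd.DataFrame:
        """OLS bias slopes of the bound data, per condition."""
        curves = summarize_bias_sd(self.model.trials, level="group")
        return bias_slopes(curves)
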