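"""scikit-learn-style estimators wrapping the fitting machinery.

All three estimators follow the sklearn contract: hyperparameters are
constructor arguments stored verbatim, fitting populates
trailing-underscore attributes, and ``get_params`` / ``set_params`` work
with sklearn model-selection utilities.  ``X`` is a trial table
(``pandas.DataFrame`` in the dialect of :mod:`ineqddm.task`); the response
columns (choice, rt_s) live inside the table, so ``y`` is ignored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import wfpt
from .errors import NoDataError
from .inference import gelman_rubin, sample_posterior, waic
from .model import DriftSpec, PriorSpec, drift_rate
from .selection import fit_value_logistic, predict_value_logistic, run_selection
from .task import DEFAULT_SCALE_YEN, features_frame, valid_trials


def _as_trials(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a trial-table DataFrame")
    if len(X) == 0:
        raise NoDataError("empty trial table")
    return X


class WienerDDM(BaseEstimator):
    """Bayesian Wiener drift-diffusion model with a linear drift term.

    Parameters
    ----------
    drift_spec : str
        Drift specification name, e.g. ``"sr+ai+di"`` or ``"constant"``.
    chains, burn_in, draws : int
        MCMC settings (independent per participant; one participant per fit).
    scale_yen : float
        Yen per model unit for the regressors.
    random_state : int
        Seed for the sampler.

    Attributes
    ----------
    draws_ : PosteriorDraws
    params_ : DDMParams posterior-mean point estimate
    waic_ : float, trial-wise WAIC on the deviance scale
    rhat_ : dict, split-chain Gelman-Rubin per parameter
    """

    def __init__(
        self,
        drift_spec: str = "sr+ai+di",
        chains: int = 4,
        burn_in: int = 2000,
        draws: int = 2000,
        scale_yen: float = DEFAULT_SCALE_YEN,
        priors: PriorSpec | None = None,
        random_state: int = 0,
    ):
        self.drift_spec = drift_spec
        self.chains = chains
        self.burn_in = burn_in
        self.draws = draws
        self.scale_yen = scale_yen
        self.priors = priors
        self.random_state = random_state

    def fit(self, X, y=None):
        trials = _as_trials(X)
        spec = DriftSpec.from_name(self.drift_spec)
        self.draws_ = sample_posterior(
            trials,
            spec,
            priors=self.priors,
            chains=self.chains,
            burn_in=self.burn_in,
            draws=self.draws,
            seed=self.random_state,
            scale_yen=self.scale_yen,
        )
        self.spec_ = spec
        self.params_ = self.draws_.posterior_mean
        self.waic_ = waic(self.draws_.per_trial_loglik).waic
        if self.chains >= 2:
            self.rhat_ = gelman_rubin(self.draws_).rhat
        else:
            self.rhat_ = {}
        return self

    def predict_proba(self, X):
        """P(reject) per trial from the posterior-mean parameters."""
        check_is_fitted(self, "params_")
        feats = features_frame(_as_trials(X), self.scale_yen)
        delta = np.asarray(drift_rate(self.spec_, self.params_, feats), dtype=float)
        p = np.asarray(wfpt.prob_upper(self.params_.alpha, self.params_.z, delta))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        """Most probable choice per trial (1 = reject, 0 = accept)."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_rt(self, X):
        """Expected RT per trial: tau + analytic mean decision time."""
        check_is_fitted(self, "params_")
        feats = features_frame(_as_trials(X), self.scale_yen)
        delta = np.asarray(drift_rate(self.spec_, self.params_, feats), dtype=float)
        return self.params_.tau + wfpt.mean_decision_time(
            self.params_.alpha, self.params_.z, delta
        )

    def score(self, X, y=None):
        """Mean per-trial log-likelihood at the posterior mean."""
        from .ddm import loglik_dataset

        check_is_fitted(self, "params_")
        trials = valid_trials(_as_trials(X))
        total, _ = loglik_dataset(self.spec_, self.params_, trials, self.scale_yen)
        return total / len(trials)


class FirthLogisticValue(BaseEstimator):
    """Bias-reduced logistic value model of accept/reject choices."""

    def __init__(self, scale_yen: float = DEFAULT_SCALE_YEN):
        self.scale_yen = scale_yen

    def fit(self, X, y=None):
        trials = _as_trials(X)
        self.params_ = fit_value_logistic(trials, self.scale_yen)
        self.coef_ = self.params_.vector()
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        pred = predict_value_logistic(self.params_, _as_trials(X), self.scale_yen)
        return np.column_stack([1.0 - pred.p_reject, pred.p_reject])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class DriftSpecSelector(BaseEstimator):
    """WAIC selection over the nine drift specifications on a cohort table."""

    def __init__(
        self,
        chains: int = 2,
        burn_in: int = 800,
        draws: int = 800,
        scale_yen: float = DEFAULT_SCALE_YEN,
        priors: PriorSpec | None = None,
        random_state: int = 0,
    ):
        self.chains = chains
        self.burn_in = burn_in
        self.draws = draws
        self.scale_yen = scale_yen
        self.priors = priors
        self.random_state = random_state

    def fit(self, X, y=None):
        trials = _as_trials(X)
        result = run_selection(
            trials,
            priors=self.priors,
            chains=self.chains,
            burn_in=self.burn_in,
            draws=self.draws,
            seed=self.random_state,
            scale_yen=self.scale_yen,
        )
        self.table_ = result.table
        self.per_participant_ = result.per_participant
        self.best_spec_ = result.best_spec
        return self

    def transform(self, X):
        """Pass-through; provided so the selector can sit in a Pipeline."""
        check_is_fitted(self, "best_spec_")
        return X
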