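"""Bayesian posterior sampling for the DDM, convergence checks, and WAIC.

The sampler is a self-contained adaptive Metropolis scheme, run
independently per participant but vectorized across (participant, chain)
pairs so that many 56-trial fits share each likelihood evaluation:

* burn-in, first 60%: component-wise Gaussian random walk with
  Robbins–Monro scale adaptation toward a 0.44 acceptance rate;
* burn-in, last 40%: proposal scales frozen; states collected to estimate a
  per-participant posterior covariance;
* sampling phase: joint Gaussian random-walk proposals with covariance
  (2.38^2 / d) * Cov-hat (the classic optimal-scaling rule), no further
  adaptation, so retained draws form a time-homogeneous Markov chain.

The nondecision time is restricted to (0, 0.99 * min observed RT) during
sampling: the Wiener density is zero for rt <= tau, and without the
restriction chains waste time on a -inf plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import wfpt
from .errors import InsufficientChainsError, NoDataError
from .model import DDMParams, DriftSpec, PriorSpec
from .task import DEFAULT_SCALE_YEN, features_frame, valid_trials

TAU_UPPER_FRACTION = 0.99


@dataclass
class PosteriorDraws:
    """Retained posterior draws of one participant fit."""

    draws: np.ndarray  # (chains, n_draws, n_params)
    param_names: list[str]
    per_trial_loglik: np.ndarray  # (chains, n_draws, n_valid_trials)
    spec: DriftSpec
    seed: int
    burn_in: int
    acceptance_rate: float
    trial_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def posterior_mean(self) -> DDMParams:
        return DDMParams.from_vector(self.spec, self.flat().mean(axis=0))

    def mean_vector(self) -> np.ndarray:
        return self.flat().mean(axis=0)

    def credible_interval(self, prob: float = 0.95) -> pd.DataFrame:
        q = [(1 - prob) / 2, 1 - (1 - prob) / 2]
        lo, hi = np.quantile(self.flat(), q, axis=0)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.param_names)

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        C, N, D = self.draws.shape
        chain = np.repeat(np.arange(C), N * D)
        iteration = np.tile(np.repeat(np.arange(N), D), C)
        parameter = np.tile(self.param_names, C * N)
        return pd.DataFrame(
            {"chain": chain, "iteration": iteration, "parameter": parameter,
             "value": self.draws.reshape(-1)}
        )


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    effective_sample_size: dict[str, float]

    @property
    def flagged(self) -> list[str]:
        return [k for k, v in self.rhat.items() if v > 1.1]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    per_trial: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.per_trial.shape[-1]


# ---------------------------------------------------------------------------
# stacked likelihood


def _stack_datasets(datasets, spec: DriftSpec, scale_yen: float):
    """Pack per-participant trial tables into padded (P, T) arrays."""
    Xs, chs, rts, valids, rows = [], [], [], [], []
    for df in datasets:
        dfv = valid_trials(df)
        if len(dfv) == 0:
            raise NoDataError("participant has no valid (non-timeout) trials")
        feats = features_frame(dfv, scale_yen) if "di" not in dfv.columns else dfv
        Xs.append(spec.design(feats))
        chs.append((dfv["choice"] == "reject").to_numpy())
        rts.append(dfv["rt_s"].to_numpy(float))
        valids.append(np.ones(len(dfv), dtype=bool))
        rows.append(dfv.index.to_numpy())
    T = max(len(r) for r in rts)
    K = Xs[0].shape[1]
    P = len(datasets)
    X = np.zeros((P, T, K))
    choice = np.zeros((P, T), dtype=bool)
    rt = np.ones((P, T))
    valid = np.zeros((P, T), dtype=bool)
    for p in range(P):
        n = len(rts[p])
        X[p, :n] = Xs[p]
        choice[p, :n] = chs[p]
        rt[p, :n] = rts[p]
        valid[p, :n] = valids[p]
    return X, choice, rt, valid, rows


def _per_trial_loglik(theta, X, choice, rt, valid, tol):
    """Per-trial log-likelihood, stacked over (P participants, C chains).

    theta: (P, C, D); X: (P, T, K); choice/rt/valid: (P, T).
    Returns (P, C, T) with zeros at padded trials.
    """
    alpha = theta[..., 0][..., None]  # (P, C, 1)
    z = theta[..., 1][..., None]
    tau = theta[..., 2][..., None]
    betas = theta[..., 3:]  # (P, C, K)
    drift = np.einsum("pck,ptk->pct", betas, X)
    up = choice[:, None, :]
    v = np.where(up, -drift, drift)
    w = np.where(up, 1.0 - z, z)
    tdec = rt[:, None, :] - tau
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        ll = wfpt._log_f1(tdec / alpha**2, w, tol=tol)
        ll = ll - 2.0 * np.log(alpha) - v * alpha * w - v**2 * np.maximum(tdec, 0.0) / 2.0
        ll = np.where(tdec > 0, ll, -np.inf)
    return np.where(valid[:, None, :], ll, 0.0)


def _initial_states(P, C, D, tau_cap, rng):
    theta = np.empty((P, C, D))
    theta[..., 0] = np.abs(rng.normal(0.0, 1.0, (P, C))) + 0.8
    theta[..., 1] = rng.uniform(0.3, 0.7, (P, C))
    theta[..., 2] = rng.uniform(0.1, 0.9, (P, C)) * np.minimum(tau_cap, 1.0)[:, None]
    theta[..., 3:] = rng.uniform(-0.5, 0.5, (P, C, D - 3))
    return theta


def sample_posterior_stacked(
    datasets,
    spec: DriftSpec,
    priors: PriorSpec | None = None,
    chains: int = 4,
    burn_in: int = 2000,
    draws: int = 2000,
    seed: int = 0,
    scale_yen: float = DEFAULT_SCALE_YEN,
    tol: float = 1e-7,
    prior_only: bool = False,
) -> list[PosteriorDraws]:
    """Fit every dataset independently but in one vectorized MCMC run.

    Returns one :class:`PosteriorDraws` per input dataset.  ``prior_only``
    drops the likelihood term (used to check that the sampler reproduces the
    prior).
    """
    if chains < 1 or burn_in < 10 or draws < 10:
        raise ValueError("need chains >= 1, burn_in >= 10, draws >= 10")
    priors = priors or PriorSpec()
    X, choice, rt, valid, rows = _stack_datasets(datasets, spec, scale_yen)
    P, T, K = X.shape
    D = 3 + K
    C = chains
    rng = np.random.default_rng(seed)

    min_rt = np.where(valid, rt, np.inf).min(axis=1)
    tau_max = np.full(P, np.inf) if prior_only else TAU_UPPER_FRACTION * min_rt

    def logpost(theta):
        lp = priors.log_density(spec, theta, tau_max=tau_max[:, None])
        if prior_only:
            return lp, np.zeros((P, C, T))
        ll_trials = _per_trial_loglik(theta, X, choice, rt, valid, tol)
        return lp + ll_trials.sum(axis=2), ll_trials

    # initialization with re-draws where the posterior is -inf
    theta = _initial_states(P, C, D, np.minimum(tau_max, 10.0), rng)
    lp, ll_trials = logpost(theta)
    for _ in range(200):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        fresh = _initial_states(P, C, D, np.minimum(tau_max, 10.0), rng)
        theta[bad] = fresh[bad]
        lp, ll_trials = logpost(theta)
    else:
        raise NoDataError("could not find a finite-likelihood initial state")

    scales = np.empty((P, C, D))
    scales[..., 0] = 0.3
    scales[..., 1] = 0.08
    scales[..., 2] = 0.08
    scales[..., 3:] = 0.3

    n_adapt = int(0.6 * burn_in)
    n_collect = burn_in - n_adapt
    collected = np.empty((P, C, n_collect, D))

    for it in range(burn_in):
        gamma = (it + 1) ** -0.6
        for j in range(D):
            prop = theta.copy()
            prop[..., j] += scales[..., j] * rng.standard_normal((P, C))
            lp_prop, ll_prop = logpost(prop)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random((P, C))) < (lp_prop - lp)
            theta[accept] = prop[accept]
            lp = np.where(accept, lp_prop, lp)
            ll_trials = np.where(accept[..., None], ll_prop, ll_trials)
            if it < n_adapt:
                scales[..., j] *= np.exp(gamma * (accept.astype(float) - 0.44))
        if it >= n_adapt:
            collected[:, :, it - n_adapt] = theta

    # per-participant covariance pooled over chains (more stable at small n)
    pooled = collected.reshape(P, C * n_collect, D)
    chol = np.empty((P, D, D))
    for p in range(P):
        cov = np.cov(pooled[p].T) + 1e-8 * np.eye(D)
        try:
            chol[p] = np.linalg.cholesky((2.38**2 / D) * cov)
        except np.linalg.LinAlgError:
            chol[p] = np.diag(scales[p].mean(axis=0) * 0.5)

    out_draws = np.empty((P, C, draws, D))
    out_ll = np.empty((P, C, draws, T))
    n_accept = 0
    for it in range(draws):
        eps = np.einsum("pde,pce->pcd", chol, rng.standard_normal((P, C, D)))
        prop = theta + eps
        lp_prop, ll_prop = logpost(prop)
        with np.errstate(invalid="ignore"):
            accept = np.log(rng.random((P, C))) < (lp_prop - lp)
        theta[accept] = prop[accept]
        lp = np.where(accept, lp_prop, lp)
        ll_trials = np.where(accept[..., None], ll_prop, ll_trials)
        n_accept += int(accept.sum())
        out_draws[:, :, it] = theta
        out_ll[:, :, it] = ll_trials

    acc_rate = n_accept / (P * C * draws)
    results = []
    for p in range(P):
        n_valid = int(valid[p].sum())
        results.append(
            PosteriorDraws(
                draws=out_draws[p],
                param_names=spec.param_names,
                per_trial_loglik=out_ll[p, :, :, :n_valid],
                spec=spec,
                seed=seed,
                burn_in=burn_in,
                acceptance_rate=acc_rate,
                trial_rows=rows[p],
            )
        )
    return results


def sample_posterior(
    trials: pd.DataFrame,
    spec: DriftSpec,
    priors: PriorSpec | None = None,
    chains: int = 4,
    burn_in: int = 2000,
    draws: int = 2000,
    seed: int = 0,
    scale_yen: float = DEFAULT_SCALE_YEN,
    tol: float = 1e-7,
) -> PosteriorDraws:
    """Posterior over (alpha, z, tau, betas) for one participant's trials."""
    dfv = valid_trials(trials)
    if len(dfv) == 0:
        raise NoDataError("no valid (non-timeout) trials to fit")
    return sample_posterior_stacked(
        [trials], spec, priors, chains, burn_in, draws, seed, scale_yen, tol
    )[0]


# ---------------------------------------------------------------------------
# diagnostics


def gelman_rubin(draws: PosteriorDraws | np.ndarray, param_names=None) -> ConvergenceReport:
    """Split-chain potential scale reduction factor per parameter.

    Each chain is split in half, so C chains of length N become 2C chains of
    length N // 2; R-hat is sqrt(((n-1)/n * W + B/n) / W).  Degenerate
    all-constant chains report 1.0.
    """
    if isinstance(draws, PosteriorDraws):
        arr = draws.draws
        param_names = draws.param_names
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 2:
            arr = arr[..., None]
        if param_names is None:
            param_names = [f"p{i}" for i in range(arr.shape[-1])]
    C, N, D = arr.shape
    if C < 2:
        raise InsufficientChainsError("Gelman-Rubin needs at least 2 chains")
    if N < 10:
        raise ValueError("need at least 10 retained iterations per chain")
    n = N // 2
    split = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)  # (2C, n, D)

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for d, name in enumerate(param_names):
        x = split[:, :, d]
        W = x.var(axis=1, ddof=1).mean()
        B_over_n = x.mean(axis=1).var(ddof=1)
        if W == 0.0:
            rhat[name] = 1.0 if B_over_n == 0.0 else np.inf
            ess[name] = float(x.size) if B_over_n == 0.0 else 0.0
            continue
        var_hat = (n - 1) / n * W + B_over_n
        rhat[name] = float(np.sqrt(var_hat / W))
        ess[name] = _ess_single(split[:, :, d])
    return ConvergenceReport(rhat=rhat, effective_sample_size=ess)


def _ess_single(x: np.ndarray) -> float:
    """Crude effective sample size from pooled chain autocorrelations."""
    m, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    max_lag = min(n - 1, 200)
    denom = (xc**2).sum()
    if denom == 0:
        return float(x.size)
    rho_sum = 0.0
    for lag in range(1, max_lag):
        rho = (xc[:, :-lag] * xc[:, lag:]).sum() / denom
        if rho < 0.05:
            break
        rho_sum += rho
    return float(x.size / (1.0 + 2.0 * rho_sum))


def waic(per_trial_loglik: np.ndarray) -> WAICResult:
    """Trial-wise WAIC on the deviance scale.

    ``per_trial_loglik`` is (chains, draws, trials) or (samples, trials);
    lppd uses log-sum-exp stabilization and the penalty is the variance-form
    p_waic; waic = -2 * (lppd - p_waic).
    """
    ll = np.asarray(per_trial_loglik, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2:
        raise ValueError("per_trial_loglik must be 2-D or 3-D")
    S = ll.shape[0]
    all_bad = np.all(~np.isfinite(ll), axis=0)
    if all_bad.any():
        raise NoDataError(f"WAIC undefined: trial(s) {np.flatnonzero(all_bad).tolist()} "
                          "have no finite log-likelihood draws")
    lppd_t = logsumexp(ll, axis=0) - np.log(S)
    if S > 1:
        finite = np.where(np.isfinite(ll), ll, np.nan)
        p_t = np.nanvar(finite, axis=0, ddof=1)
    else:
        p_t = np.zeros(ll.shape[1])
    per_trial = -2.0 * (lppd_t - p_t)
    lppd = float(lppd_t.sum())
    p_waic = float(p_t.sum())
    return WAICResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic), per_trial=per_trial)
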