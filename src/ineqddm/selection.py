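"""Model selection across drift specifications and the logistic value model.

The nine candidate drift terms are ranked by total trial-wise WAIC summed
over all trials of all participants.  The competing choice-only account is a
value-difference logistic model

    v(t) = gamma0 * (g_reject - g_accept) + gamma_AI * AI_t + gamma_DI * DI_t
    P(reject) = 1 / (1 + exp(-v(t)))

with g_reject = 0 and g_accept = SR_t, fitted by Firth's bias-reduced
(Jeffreys-penalized) likelihood so that estimates stay finite under complete
separation — the typical situation for responders who accept everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wfpt
from .errors import AlignmentError, InsufficientDataError, NoDataError
from .inference import PosteriorDraws, sample_posterior_stacked, waic
from .model import DriftSpec, PriorSpec, enumerate_drift_specs
from .task import DEFAULT_SCALE_YEN, features_frame, valid_trials


@dataclass
class ModelTable:
    """WAIC ranking of drift specifications."""

    table: pd.DataFrame  # rows: spec, total_waic, n_failed
    per_participant: pd.DataFrame  # index participant, columns spec names
    best_spec: DriftSpec

    def __post_init__(self):
        self.table = self.table.sort_values("total_waic").reset_index(drop=True)


@dataclass(frozen=True)
class ValueModelParams:
    gamma0: float
    gamma_ai: float
    gamma_di: float

    def vector(self) -> np.ndarray:
        return np.array([self.gamma0, self.gamma_ai, self.gamma_di])


@dataclass
class ValueModelPrediction:
    v: np.ndarray
    p_reject: np.ndarray


def _group_by_participant(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {pid: df for pid, df in trials.groupby("participant_id", sort=True)}


def run_selection(
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    specs: list[DriftSpec] | None = None,
    chains: int = 2,
    burn_in: int = 800,
    draws: int = 800,
    seed: int = 0,
    scale_yen: float = DEFAULT_SCALE_YEN,
) -> ModelTable:
    """Fit every drift spec to every participant and rank by total WAIC.

    Fits are seeded per spec index so reruns reproduce bit-identical tables.
    A fit whose WAIC is non-finite marks that (participant, spec) cell failed
    (NaN) instead of aborting the run.
    """
    specs = list(specs) if specs is not None else enumerate_drift_specs()
    groups = _group_by_participant(trials)
    pids = list(groups)
    datasets = [groups[p] for p in pids]
    per_part = pd.DataFrame(index=pids, columns=[s.name for s in specs], dtype=float)

    for j, spec in enumerate(specs):
        try:
            fits = sample_posterior_stacked(
                datasets, spec, priors, chains, burn_in, draws,
                seed=int(np.random.SeedSequence([seed, j]).generate_state(1)[0] % (2**31)),
                scale_yen=scale_yen,
            )
        except NoDataError:
            warnings.warn(f"spec {spec.name}: fit failed for the whole cohort")
            continue
        for pid, fit in zip(pids, fits):
            try:
                w = waic(fit.per_trial_loglik).waic
            except NoDataError:
                w = np.nan
            per_part.loc[pid, spec.name] = w if np.isfinite(w) else np.nan

    totals = per_part.sum(axis=0, skipna=False)
    n_failed = per_part.isna().sum(axis=0)
    table = pd.DataFrame(
        {"spec": totals.index, "total_waic": totals.to_numpy(), "n_failed": n_failed.to_numpy()}
    )
    finite = table.dropna(subset=["total_waic"])
    if finite.empty:
        raise NoDataError("every drift spec failed to fit")
    best = DriftSpec.from_name(finite.loc[finite["total_waic"].idxmin(), "spec"])
    return ModelTable(table=table, per_participant=per_part, best_spec=best)


# ---------------------------------------------------------------------------
# Firth bias-reduced logistic value model


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalized logistic regression (no intercept column added).

    Maximizes loglik + 0.5 * log det(X' W X); Newton iterations on the
    modified score U*(b) = X'(y - p + h (1/2 - p)) with h the hat-matrix
    diagonal.  Estimates are finite even under complete separation.
    Returns (beta, penalized_loglik, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = _sigmoid(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        # step-halving on the penalized likelihood
        f0 = _firth_obj(X, y, beta)
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            if _firth_obj(X, y, cand) >= f0 - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        if np.max(np.abs(lam * step)) < tol:
            return beta, _firth_obj(X, y, beta), True
    return beta, _firth_obj(X, y, beta), False


def _firth_obj(X, y, beta):
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = _sigmoid(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    return ll + 0.5 * (logdet if sign > 0 else -np.inf)


def value_design(trials: pd.DataFrame, scale_yen: float = DEFAULT_SCALE_YEN):
    """(X, y) for the logistic value model: columns (-SR, AI, DI), y = reject."""
    dfv = valid_trials(trials)
    feats = features_frame(dfv, scale_yen) if "di" not in dfv.columns else dfv
    X = np.column_stack(
        [-feats["sr"].to_numpy(float), feats["ai"].to_numpy(float), feats["di"].to_numpy(float)]
    )
    y = (feats["choice"] == "reject").to_numpy(float)
    return X, y


def fit_value_logistic(trials: pd.DataFrame, scale_yen: float = DEFAULT_SCALE_YEN) -> ValueModelParams:
    """Bias-reduced fit of (gamma0, gamma_AI, gamma_DI) for one participant."""
    X, y = value_design(trials, scale_yen)
    if len(y) < 3:
        raise InsufficientDataError("need at least 3 valid trials for the value model")
    beta, _, converged = firth_logistic(X, y)
    if not converged:
        warnings.warn("Firth logistic fit did not fully converge")
    return ValueModelParams(gamma0=float(beta[0]), gamma_ai=float(beta[1]), gamma_di=float(beta[2]))


def predict_value_logistic(
    params: ValueModelParams, trials: pd.DataFrame, scale_yen: float = DEFAULT_SCALE_YEN
) -> ValueModelPrediction:
    X, _ = value_design(trials, scale_yen)
    v = X @ params.vector()
    return ValueModelPrediction(v=v, p_reject=_sigmoid(v))


# ---------------------------------------------------------------------------
# choice-only comparison of the two model families


@dataclass
class ChoiceComparison:
    waic_ddm: float
    waic_logistic: float
    coefficients: pd.DataFrame  # per participant: beta_di, gamma_di, ...


def _logistic_posterior_mh(X, y, rng, prior_sd=10.0, burn_in=500, draws=1000):
    """Small component-wise adaptive MH for the Bayesian logistic model."""
    k = X.shape[1]
    beta, _, _ = firth_logistic(X, y)
    scales = np.full(k, 0.5)

    def logpost(b):
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum()) - float(b @ b) / (2 * prior_sd**2)

    lp = logpost(beta)
    out = np.empty((draws, k))
    for it in range(burn_in + draws):
        for j in range(k):
            cand = beta.copy()
            cand[j] += scales[j] * rng.standard_normal()
            lp_c = logpost(cand)
            accepted = np.log(rng.random()) < lp_c - lp
            if accepted:
                beta, lp = cand, lp_c
            if it < burn_in:
                scales[j] *= np.exp((it + 1) ** -0.6 * (float(accepted) - 0.44))
        if it >= burn_in:
            out[it - burn_in] = beta
    return out


def compare_choice_only(
    trials: pd.DataFrame,
    ddm_fits: dict[str, PosteriorDraws],
    logistic_fits: dict[str, ValueModelParams] | None = None,
    seed: int = 0,
    scale_yen: float = DEFAULT_SCALE_YEN,
    max_draws: int = 500,
) -> ChoiceComparison:
    """Bernoulli-likelihood WAIC of choices for the DDM and logistic families.

    Both families are scored on the identical valid trials: the DDM via its
    analytic rejection probability at each posterior draw, the logistic model
    via MH draws under flat normal(0, 10^2) coefficient priors.
    """
    groups = _group_by_participant(trials)
    if set(groups) != set(ddm_fits):
        raise AlignmentError("participants in trials and ddm_fits differ")
    if logistic_fits is not None and set(logistic_fits) != set(groups):
        raise AlignmentError("participants in trials and logistic_fits differ")

    rng = np.random.default_rng(seed)
    total_ddm = 0.0
    total_log = 0.0
    rows = []
    for pid in sorted(groups):
        df = valid_trials(groups[pid])
        feats = features_frame(df, scale_yen) if "di" not in df.columns else df
        y = (feats["choice"] == "reject").to_numpy(float)

        fit = ddm_fits[pid]
        flat = fit.flat()
        if flat.shape[0] > max_draws:
            idx = np.linspace(0, flat.shape[0] - 1, max_draws).astype(int)
            flat = flat[idx]
        Xd = fit.spec.design(feats)
        drift = flat[:, 3:] @ Xd.T  # (S, T)
        p = wfpt.prob_upper(flat[:, 0][:, None], flat[:, 1][:, None], drift)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll_ddm = y[None, :] * np.log(p) + (1 - y[None, :]) * np.log1p(-p)
        total_ddm += waic(ll_ddm).waic

        Xl, _ = value_design(df, scale_yen)
        bdraws = _logistic_posterior_mh(Xl, y, rng)
        eta = bdraws @ Xl.T
        pl = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
        ll_log = y[None, :] * np.log(pl) + (1 - y[None, :]) * np.log1p(-pl)
        total_log += waic(ll_log).waic

        gam = (
            logistic_fits[pid]
            if logistic_fits is not None
            else fit_value_logistic(df, scale_yen)
        )
        mean_vec = fit.mean_vector()
        names = fit.param_names
        rows.append(
            {
                "participant_id": pid,
                "beta_di": mean_vec[names.index("beta_di")] if "beta_di" in names else np.nan,
                "beta_sr": mean_vec[names.index("beta_sr")] if "beta_sr" in names else np.nan,
                "beta_ai": mean_vec[names.index("beta_ai")] if "beta_ai" in names else np.nan,
                "gamma0": gam.gamma0,
                "gamma_ai": gam.gamma_ai,
                "gamma_di": gam.gamma_di,
            }
        )
    return ChoiceComparison(
        waic_ddm=total_ddm, waic_logistic=total_log, coefficients=pd.DataFrame(rows)
    )
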