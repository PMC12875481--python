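"""Model validation: parameter recovery, RT cross-validation, posterior
predictive simulation.

Parameter recovery simulates known agents, refits them, and summarizes bias
and RMSE of the posterior means; held-out response times are predicted with
the analytic mean first-passage time at the posterior-mean parameters plus
the nondecision time (a simulation-based predictor is available via
``predictor="simulate"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wfpt
from .ddm import simulate_dataset
from .errors import ConfigError, IneqDDMError
from .inference import PosteriorDraws, sample_posterior_stacked
from .model import BEST_SPEC, DDMParams, DriftSpec, PriorSpec, drift_rate
from .task import (
    CONDITIONS,
    DEFAULT_SCALE_YEN,
    features_frame,
    generate_offer_set,
    offers_to_frame,
    valid_trials,
)
from .behavior import pearson_holm, summarize_behavior


@dataclass(frozen=True)
class AgentSpec:
    """A simulated responder: a label, true parameters, and the drift spec."""

    label: str
    params: DDMParams
    spec: DriftSpec

    def __post_init__(self):
        b = self.params.betas
        if self.label == "reward_seeker":
            if not (b.get("sr", 0) < 0 and b.get("di", 0) == 0 and b.get("ai", 0) == 0):
                raise ConfigError("reward_seeker needs beta_sr < 0 and beta_di = beta_ai = 0")
        if self.label == "inequity_avoider" and not b.get("di", 0) > 0:
            raise ConfigError("inequity_avoider needs beta_di > 0")


def reward_seeker() -> AgentSpec:
    return AgentSpec(
        "reward_seeker",
        DDMParams(alpha=2.0, z=0.5, tau=0.5, betas={"sr": -1.5, "di": 0.0, "ai": 0.0}),
        BEST_SPEC,
    )


def inequity_avoider() -> AgentSpec:
    return AgentSpec(
        "inequity_avoider",
        DDMParams(alpha=2.0, z=0.5, tau=0.5, betas={"sr": -0.5, "di": 1.0, "ai": 0.5}),
        BEST_SPEC,
    )


@dataclass
class RecoveryResult:
    truth: DDMParams
    estimates: pd.DataFrame  # one row per successful repeat, parameter columns
    bias: pd.Series
    rmse: pd.Series
    n_repeats: int
    n_failed: int


def _simulate_agent_datasets(agent, n_trials, n_repeats, seed, scale_yen, dt):
    if n_trials % len(CONDITIONS) != 0:
        raise ConfigError("n_trials must be a multiple of 7 to balance conditions")
    datasets = []
    for r in range(n_repeats):
        ss = np.random.SeedSequence([seed, r]).generate_state(2) % (2**31)
        offers = offers_to_frame(generate_offer_set(int(ss[0])))
        if n_trials != len(offers):
            reps = int(np.ceil(n_trials / len(offers)))
            offers = pd.concat([offers] * reps, ignore_index=True).iloc[:n_trials]
        df = simulate_dataset(
            agent.spec, agent.params, offers, seed=int(ss[1]),
            participant_id=f"rep{r:03d}", scale_yen=scale_yen, dt=dt,
        )
        datasets.append(df)
    return datasets


def parameter_recovery(
    agent: AgentSpec,
    n_trials: int = 56,
    n_repeats: int = 20,
    priors: PriorSpec | None = None,
    chains: int = 2,
    burn_in: int = 800,
    draws: int = 800,
    seed: int = 0,
    scale_yen: float = DEFAULT_SCALE_YEN,
    dt: float = 1e-3,
) -> RecoveryResult:
    """Simulate-and-refit recovery of one agent's parameters.

    Each repeat simulates ``n_trials`` fresh jittered offers, refits the
    posterior, and records the posterior means; repeats whose fit fails are
    excluded from the aggregates with the failure count reported.
    """
    if n_repeats < 1:
        raise ConfigError("n_repeats must be >= 1")
    datasets = _simulate_agent_datasets(agent, n_trials, n_repeats, seed, scale_yen, dt)
    keep = [d for d in datasets if valid_trials(d).shape[0] > 0]
    n_failed = len(datasets) - len(keep)
    fits = sample_posterior_stacked(
        keep, agent.spec, priors, chains, burn_in, draws, seed=seed, scale_yen=scale_yen
    )
    names = agent.spec.param_names
    est = []
    for fit in fits:
        vec = fit.mean_vector()
        if np.all(np.isfinite(vec)):
            est.append(vec)
        else:
            n_failed += 1
    estimates = pd.DataFrame(est, columns=names)
    truth_vec = agent.params.vector(agent.spec)
    truth_s = pd.Series(truth_vec, index=names)
    bias = estimates.mean(axis=0) - truth_s
    rmse = np.sqrt(((estimates - truth_s) ** 2).mean(axis=0))
    return RecoveryResult(
        truth=agent.params, estimates=estimates, bias=bias, rmse=rmse,
        n_repeats=len(estimates), n_failed=n_failed,
    )


def recovery_grid(
    base_agent: AgentSpec,
    param: str,
    truths,
    n_repeats: int = 4,
    **recovery_kwargs,
) -> pd.DataFrame:
    """Mean recovered value of ``param`` across a grid of true values.

    All (truth, repeat) fits are run in one stacked MCMC pass.  ``param``
    is a spec parameter name such as ``"beta_di"`` or ``"alpha"``.
    """
    seed = recovery_kwargs.pop("seed", 0)
    n_trials = recovery_kwargs.pop("n_trials", 56)
    scale_yen = recovery_kwargs.pop("scale_yen", DEFAULT_SCALE_YEN)
    dt = recovery_kwargs.pop("dt", 1e-3)
    spec = base_agent.spec
    names = spec.param_names
    j = names.index(param)

    datasets, truth_of = [], []
    for g, tv in enumerate(truths):
        vec = base_agent.params.vector(spec).copy()
        vec[j] = tv
        params = DDMParams.from_vector(spec, vec)
        agent = AgentSpec("custom", params, spec)
        datasets.extend(
            _simulate_agent_datasets(agent, n_trials, n_repeats, seed + 1000 * g, scale_yen, dt)
        )
        truth_of.extend([tv] * n_repeats)
    fits = sample_posterior_stacked(datasets, spec, seed=seed, **recovery_kwargs)
    rec = np.array([fit.mean_vector()[j] for fit in fits])
    df = pd.DataFrame({"truth": truth_of, "recovered": rec})
    return df.groupby("truth", as_index=False).agg(
        mean_recovered=("recovered", "mean"), sd_recovered=("recovered", "std"),
        n=("recovered", "size"),
    )


# ---------------------------------------------------------------------------
# leave-one-out RT cross-validation


@dataclass
class CVReport:
    folds: pd.DataFrame  # condition, fold, actual_rt, predicted_rt
    correlations: pd.DataFrame  # condition, r, p_raw, p_holm, n
    n_folds: int


def predict_rt(params: DDMParams, spec: DriftSpec, features) -> float | np.ndarray:
    """Predicted RT = nondecision time + analytic mean decision time."""
    delta = drift_rate(spec, params, features)
    return params.tau + wfpt.mean_decision_time(params.alpha, params.z, delta)


def loo_cv_rt(
    trials: pd.DataFrame,
    spec: DriftSpec = BEST_SPEC,
    priors: PriorSpec | None = None,
    chains: int = 2,
    burn_in: int = 600,
    draws: int = 600,
    seed: int = 0,
    scale_yen: float = DEFAULT_SCALE_YEN,
    predictor: str = "analytic",
    n_pred_sims: int = 200,
) -> CVReport:
    """Leave-one-trial-out-per-condition RT cross-validation (one participant).

    Fold f holds out the f-th valid trial of every condition; the model is
    refit on the remainder and the held-out RT is predicted from the
    posterior-mean parameters.  The standard design yields 8 folds.  Pearson
    correlations between predicted and actual RTs are reported per condition
    with Holm adjustment across the seven conditions.
    """
    dfv = valid_trials(trials).sort_values("trial_index").reset_index(drop=True)
    counts = dfv.groupby("condition")["trial_index"].count()
    missing = [c for c in CONDITIONS if counts.get(c, 0) < 2]
    if missing:
        raise IneqDDMError(f"condition(s) {missing} have fewer than 2 valid trials")
    n_folds = int(counts.min())
    if (counts != 8).any():
        warnings.warn(f"unbalanced design (trials per condition {dict(counts)}); "
                      f"using {n_folds} folds")

    heldout_idx = []
    for f in range(n_folds):
        idx = [g.index[f] for _, g in dfv.groupby("condition", sort=False)]
        heldout_idx.append(np.array(sorted(idx)))

    train_sets = [dfv.drop(index=idx) for idx in heldout_idx]
    fits = sample_posterior_stacked(
        train_sets, spec, priors, chains, burn_in, draws, seed=seed, scale_yen=scale_yen
    )

    rows = []
    rng = np.random.default_rng(seed)
    for f, (idx, fit) in enumerate(zip(heldout_idx, fits)):
        held = features_frame(dfv.loc[idx], scale_yen)
        pm = fit.posterior_mean
        if predictor == "analytic":
            pred = np.asarray(predict_rt(pm, spec, held), dtype=float)
        elif predictor == "simulate":
            delta = np.asarray(drift_rate(spec, pm, held), dtype=float)
            preds = []
            for d in delta:
                _, rts = wfpt.simulate_paths(
                    pm.alpha, pm.z, pm.tau, np.full(n_pred_sims, d), rng
                )
                preds.append(np.nanmean(rts))
            pred = np.array(preds)
        else:
            raise ValueError("predictor must be 'analytic' or 'simulate'")
        for cond, actual, p in zip(held["condition"], held["rt_s"], pred):
            rows.append({"condition": cond, "fold": f, "actual_rt": float(actual),
                         "predicted_rt": float(p)})
    folds = pd.DataFrame(rows)

    pairs = {}
    for cond, g in folds.groupby("condition"):
        pairs[cond] = (g["predicted_rt"].to_numpy(), g["actual_rt"].to_numpy())
    report = pearson_holm(pairs)
    corr = report.table.rename(columns={"pair": "condition"})
    return CVReport(folds=folds, correlations=corr, n_folds=n_folds)


# ---------------------------------------------------------------------------
# posterior-predictive simulation


@dataclass
class PredictiveSummary:
    group: pd.DataFrame  # condition-level predictive rejection rate / RTs
    per_participant: pd.DataFrame


def posterior_predictive(
    fits: dict[str, DDMParams | PosteriorDraws],
    offers: pd.DataFrame,
    n_sims: int = 10,
    seed: int = 0,
    spec: DriftSpec = BEST_SPEC,
    scale_yen: float = DEFAULT_SCALE_YEN,
) -> PredictiveSummary:
    """Simulate cohort behaviour from fitted parameters.

    For each participant, ``n_sims`` replicate datasets are simulated at the
    posterior-mean parameters over the supplied offers; the result is
    summarized in the same condition-by-choice shape as the observed
    behaviour tables.
    """
    frames = []
    for i, (pid, fit) in enumerate(sorted(fits.items())):
        params = fit.posterior_mean if isinstance(fit, PosteriorDraws) else fit
        for s in range(n_sims):
            sim_seed = int(np.random.SeedSequence([seed, i, s]).generate_state(1)[0] % (2**31))
            df = simulate_dataset(
                spec, params, offers, seed=sim_seed, participant_id=pid, scale_yen=scale_yen
            )
            frames.append(df)
    sims = pd.concat(frames, ignore_index=True)
    summary = summarize_behavior(sims)
    return PredictiveSummary(group=summary.group, per_participant=summary.per_participant)
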