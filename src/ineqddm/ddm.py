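"""Dataset-level DDM machinery: likelihoods and trial simulation.

Acceptance maps to the lower boundary and rejection to the upper boundary;
timeout trials must be excluded upstream (see :func:`ineqddm.task.valid_trials`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import wfpt
from .errors import NoDataError
from .model import DDMParams, DriftSpec, drift_rate
from .task import DEADLINE_S, DEFAULT_SCALE_YEN, features_frame, infer_condition

choice_probability = wfpt.prob_upper  # P(reject) given (alpha, z, drift)
wfpt_logdensity = wfpt.wfpt_logdensity


def loglik_dataset(
    spec: DriftSpec,
    params: DDMParams,
    trials: pd.DataFrame,
    scale_yen: float = DEFAULT_SCALE_YEN,
    tol: float = 1e-7,
) -> tuple[float, np.ndarray]:
    """Total and per-trial Wiener log-likelihood of observed (choice, rt).

    ``trials`` must contain only non-timeout rows with feature columns (added
    if absent).  Trials with rt <= tau contribute -inf and trigger a warning
    naming them.
    """
    if len(trials) == 0:
        raise NoDataError("no trials to evaluate")
    if (trials["choice"] == "timeout").any():
        raise NoDataError("timeout trials must be excluded before likelihood evaluation")
    if "di" not in trials.columns:
        trials = features_frame(trials, scale_yen)
    drift = np.asarray(drift_rate(spec, params, trials), dtype=float)
    upper = (trials["choice"] == "reject").to_numpy()
    rt = trials["rt_s"].to_numpy(float)
    per_trial = wfpt.wfpt_logdensity(rt, upper, params.alpha, params.z, params.tau, drift, tol=tol)
    bad = ~np.isfinite(per_trial)
    if bad.any():
        which = trials.index[bad].tolist()
        warnings.warn(f"rt <= tau on trial row(s) {which}: log-likelihood is -inf")
    return float(per_trial.sum()), per_trial


def simulate_trial(
    spec: DriftSpec,
    params: DDMParams,
    features,
    seed: int,
    deadline_s: float = DEADLINE_S,
    dt: float = 1e-3,
) -> tuple[str, float | None]:
    """Simulate one trial; returns (choice, rt_s) with rt_s None on timeout."""
    rng = np.random.default_rng(seed)
    delta = drift_rate(spec, params, features)
    choice, rt = wfpt.simulate_paths(
        params.alpha, params.z, params.tau, delta, rng, deadline_s=deadline_s, dt=dt
    )
    c = int(np.asarray(choice).ravel()[0])
    r = float(np.asarray(rt).ravel()[0])
    if c < 0:
        return "timeout", None
    return ("reject" if c == 1 else "accept"), r


def simulate_dataset(
    spec: DriftSpec,
    params: DDMParams,
    offers: pd.DataFrame,
    seed: int,
    participant_id: str = "sim",
    scale_yen: float = DEFAULT_SCALE_YEN,
    deadline_s: float = DEADLINE_S,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate one trial per offer row; deterministic given ``seed``.

    ``offers`` needs sr_yen / or_yen (and optionally condition) columns; the
    returned frame is a standard trial table.
    """
    feats = features_frame(offers, scale_yen)
    drift = np.asarray(drift_rate(spec, params, feats), dtype=float)
    rng = np.random.default_rng(seed)
    choice, rt = wfpt.simulate_paths(
        params.alpha, params.z, params.tau, drift, rng, deadline_s=deadline_s, dt=dt
    )
    labels = np.where(choice == 1, "reject", np.where(choice == 0, "accept", "timeout"))
    out = pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": np.arange(len(feats)),
            "condition": feats["condition"].to_numpy()
            if "condition" in feats.columns
            else [
                infer_condition(int(sr), int(orr))
                for sr, orr in zip(feats["sr_yen"], feats["or_yen"])
            ],
            "sr_yen": feats["sr_yen"].to_numpy(int),
            "or_yen": feats["or_yen"].to_numpy(int),
            "choice": labels,
            "rt_s": np.where(choice >= 0, rt, np.nan),
        }
    )
    out["valid"] = out["choice"] != "timeout"
    return out
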