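"""Synthetic cohort generation.

Agents are drawn from a truncated-normal population whose moments default to
the across-participant means and standard deviations of the fitted best
model (boundary 2.16 ± 0.680, bias 0.543 ± 0.0962, nondecision time
0.591 ± 0.266 s, beta_AI 0.254 ± 0.868, beta_DI 0.371 ± 0.481,
beta_SR −0.930 ± 0.504).  Truncation keeps every draw inside the parameter
supports (alpha > 0, z in (0,1), tau > 0, |beta| < 3).

A configurable fraction of "all-accept-like" agents — near-zero inequity
weights and a strongly negative self-reward weight, so they accept virtually
every offer — mirrors the sizeable subgroup of real responders who reject
nothing while still showing variable response times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ddm import simulate_dataset
from .errors import ConfigError
from .model import BEST_SPEC, DDMParams, DriftSpec
from .task import DEFAULT_SCALE_YEN, generate_offer_set, offers_to_frame
from .validation import AgentSpec

#: Population anchors: parameter -> (mean, sd).
DEFAULT_POPULATION = {
    "alpha": (2.16, 0.680),
    "z": (0.543, 0.0962),
    "tau": (0.591, 0.266),
    "beta_sr": (-0.930, 0.504),
    "beta_di": (0.371, 0.481),
    "beta_ai": (0.254, 0.868),
}

#: Hard supports used for truncation.
SUPPORTS = {
    "alpha": (0.05, 8.0),
    "z": (0.02, 0.98),
    "tau": (0.05, 3.0),
    "beta_sr": (-3.0, 3.0),
    "beta_di": (-3.0, 3.0),
    "beta_ai": (-3.0, 3.0),
}


@dataclass
class CohortConfig:
    n_participants: int = 63
    means: dict = field(default_factory=lambda: {k: v[0] for k, v in DEFAULT_POPULATION.items()})
    sds: dict = field(default_factory=lambda: {k: v[1] for k, v in DEFAULT_POPULATION.items()})
    all_accept_fraction: float = 13 / 63
    spec: DriftSpec = field(default_factory=lambda: BEST_SPEC)
    jitter_step_yen: int = 5
    scale_yen: float = DEFAULT_SCALE_YEN
    deadline_s: float = 10.0
    dt: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not (0.0 <= self.all_accept_fraction <= 1.0):
            raise ConfigError("all_accept_fraction must lie in [0, 1]")
        for k, sd in self.sds.items():
            if sd < 0:
                raise ConfigError(f"negative SD for {k}")
        for k, m in self.means.items():
            lo, hi = SUPPORTS[k]
            if (m < lo or m > hi) and self.sds[k] == 0:
                raise ConfigError(f"mean of {k} outside support with zero SD")


def _trunc_draw(rng, mean, sd, lo, hi) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_agent(config: CohortConfig, participant_index: int) -> AgentSpec:
    """Draw one agent's true parameters; deterministic per (seed, index)."""
    rng = np.random.default_rng([config.seed, participant_index])
    all_accept = rng.random() < config.all_accept_fraction

    values = {}
    for name in DEFAULT_POPULATION:
        lo, hi = SUPPORTS[name]
        values[name] = _trunc_draw(rng, config.means[name], config.sds[name], lo, hi)
    label = "population"
    if all_accept:
        # near-zero inequity aversion, strong preference for any self-reward
        values["beta_di"] = float(rng.uniform(0.0, 0.05))
        values["beta_ai"] = float(rng.uniform(-0.1, 0.1))
        values["beta_sr"] = _trunc_draw(rng, -2.0, 0.3, -3.0, -1.0)
        label = "all_accept"

    params = DDMParams(
        alpha=values["alpha"],
        z=values["z"],
        tau=values["tau"],
        betas={"sr": values["beta_sr"], "di": values["beta_di"], "ai": values["beta_ai"]},
    )
    return AgentSpec(label=label, params=params, spec=config.spec)


def make_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate trial tables for the whole cohort plus the truth registry.

    Every participant gets a fresh jittered 56-offer set and one simulated
    dataset from their true parameters.  Returns ``(trials, registry)``
    where registry holds one row of ground-truth parameters per participant.
    """
    frames = []
    registry_rows = []
    for i in range(config.n_participants):
        agent = sample_agent(config, i)
        pid = f"sim{i:03d}"
        offer_seed = int(np.random.SeedSequence([config.seed, i, 1]).generate_state(1)[0] % (2**31))
        sim_seed = int(np.random.SeedSequence([config.seed, i, 2]).generate_state(1)[0] % (2**31))
        offers = offers_to_frame(
            generate_offer_set(offer_seed, jitter_step_yen=config.jitter_step_yen)
        )
        df = simulate_dataset(
            agent.spec,
            agent.params,
            offers,
            seed=sim_seed,
            participant_id=pid,
            scale_yen=config.scale_yen,
            deadline_s=config.deadline_s,
            dt=config.dt,
        )
        frames.append(df)
        registry_rows.append(
            {
                "participant_id": pid,
                "label": agent.label,
                "alpha": agent.params.alpha,
                "z": agent.params.z,
                "tau": agent.params.tau,
                "beta_sr": agent.params.betas["sr"],
                "beta_di": agent.params.betas["di"],
                "beta_ai": agent.params.betas["ai"],
            }
        )
    trials = pd.concat(frames, ignore_index=True)
    registry = pd.DataFrame(registry_rows)
    return trials, registry


def write_registry(registry: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(registry.to_dict(orient="records"), fh, indent=2)


def read_registry(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
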