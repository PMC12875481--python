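"""End-to-end orchestration: cohort -> selection -> fit -> validation -> stats.

A run is fully specified by a :class:`RunConfig` (YAML- or JSON-round-trippable);
all stage seeds derive from the master seed via a counter scheme, so identical
configs give bit-identical CSV outputs.  The manifest records versions, seeds,
stage outputs and their SHA-256 hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import drift_behavior_correlations, summarize_behavior
from .cohort import CohortConfig, make_cohort, write_registry
from .errors import ConfigError
from .inference import gelman_rubin, sample_posterior_stacked
from .model import DriftSpec
from .selection import run_selection
from .task import DEFAULT_SCALE_YEN, read_trials, write_trials
from .validation import inequity_avoider, loo_cv_rt, parameter_recovery, reward_seeker


@dataclass
class RunConfig:
    out_dir: str = "ineqddm_run"
    trial_table: str | None = None  # if None, a synthetic cohort is generated
    n_participants: int = 10
    drift_spec: str = "select"  # a spec name, or "select" to run WAIC selection
    chains: int = 2
    burn_in: int = 800
    draws: int = 800
    scale_yen: float = DEFAULT_SCALE_YEN
    recovery_repeats: int = 5
    run_crossval: bool = True
    run_recovery: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.scale_yen <= 0:
            raise ConfigError("scale_yen must be positive")
        if self.seed is None:
            raise ConfigError("seed must be explicit")

    def stage_seed(self, counter: int) -> int:
        return int(np.random.SeedSequence([self.seed, counter]).generate_state(1)[0] % (2**31))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    stage = "init"
    try:
        # --- cohort / ingest ------------------------------------------------
        stage = "cohort"
        t0 = time.perf_counter()
        if config.trial_table is not None:
            path = Path(config.trial_table)
            if not path.exists():
                raise ConfigError(f"trial table not found: {path}")
            trials = read_trials(path)
            trials_path = path
        else:
            cc = CohortConfig(n_participants=config.n_participants, seed=config.stage_seed(0))
            trials, registry = make_cohort(cc)
            trials_path = out / "cohort_trials.csv"
            write_trials(trials, trials_path)
            write_registry(registry, out / "cohort_registry.json")
            manifest["stages"]["cohort"] = {
                "registry": str(out / "cohort_registry.json"),
            }
        manifest["stages"].setdefault("cohort", {}).update(
            {
                "trials": str(trials_path),
                "sha256": _sha256(Path(trials_path)),
                "n_rows": int(len(trials)),
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )

        # --- model selection ------------------------------------------------
        if config.drift_spec == "select":
            stage = "selection"
            t0 = time.perf_counter()
            table = run_selection(
                trials,
                chains=config.chains,
                burn_in=config.burn_in,
                draws=config.draws,
                seed=config.stage_seed(1),
                scale_yen=config.scale_yen,
            )
            sel_path = out / "model_table.csv"
            table.table.to_csv(sel_path, index=False)
            best = table.best_spec
            manifest["stages"]["selection"] = {
                "table": str(sel_path),
                "sha256": _sha256(sel_path),
                "best_spec": best.name,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        else:
            best = DriftSpec.from_name(config.drift_spec)

        # --- best-model fit -------------------------------------------------
        stage = "fit"
        t0 = time.perf_counter()
        groups = {pid: df for pid, df in trials.groupby("participant_id")}
        pids = sorted(groups)
        fits = sample_posterior_stacked(
            [groups[p] for p in pids],
            best,
            chains=max(config.chains, 2),
            burn_in=config.burn_in,
            draws=config.draws,
            seed=config.stage_seed(2),
            scale_yen=config.scale_yen,
        )
        est_rows = []
        max_rhat = 0.0
        for pid, fit in zip(pids, fits):
            row = {"participant_id": pid}
            row.update(dict(zip(fit.param_names, fit.mean_vector())))
            est_rows.append(row)
            max_rhat = max(max_rhat, gelman_rubin(fit).max_rhat)
        estimates = pd.DataFrame(est_rows)
        est_path = out / "estimates.csv"
        estimates.to_csv(est_path, index=False, float_format="%.6f")
        manifest["stages"]["fit"] = {
            "spec": best.name,
            "estimates": str(est_path),
            "sha256": _sha256(est_path),
            "max_rhat": float(max_rhat),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # --- parameter recovery ----------------------------------------------
        if config.run_recovery:
            stage = "recovery"
            t0 = time.perf_counter()
            rec_rows = []
            for agent in (reward_seeker(), inequity_avoider()):
                rec = parameter_recovery(
                    agent,
                    n_repeats=config.recovery_repeats,
                    chains=config.chains,
                    burn_in=config.burn_in,
                    draws=config.draws,
                    seed=config.stage_seed(3),
                )
                for name in rec.bias.index:
                    rec_rows.append(
                        {
                            "agent": agent.label,
                            "parameter": name,
                            "bias": rec.bias[name],
                            "rmse": rec.rmse[name],
                            "n_repeats": rec.n_repeats,
                        }
                    )
            rec_df = pd.DataFrame(rec_rows)
            rec_path = out / "recovery.csv"
            rec_df.to_csv(rec_path, index=False, float_format="%.6f")
            manifest["stages"]["recovery"] = {
                "report": str(rec_path),
                "sha256": _sha256(rec_path),
                "seconds": round(time.perf_counter() - t0, 3),
            }

        # --- cross-validation (first participant) ----------------------------
        if config.run_crossval:
            stage = "crossval"
            t0 = time.perf_counter()
            cv = loo_cv_rt(
                groups[pids[0]],
                best,
                chains=config.chains,
                burn_in=config.burn_in,
                draws=config.draws,
                seed=config.stage_seed(4),
                scale_yen=config.scale_yen,
            )
            cv_path = out / "crossval.csv"
            cv.correlations.to_csv(cv_path, index=False, float_format="%.6f")
            manifest["stages"]["crossval"] = {
                "report": str(cv_path),
                "sha256": _sha256(cv_path),
                "n_folds": cv.n_folds,
                "seconds": round(time.perf_counter() - t0, 3),
            }

        # --- behavioural statistics ------------------------------------------
        stage = "stats"
        t0 = time.perf_counter()
        summary = summarize_behavior(trials)
        stats_path = out / "behavior_group.csv"
        summary.group.to_csv(stats_path, index=False, float_format="%.6f")
        corr = drift_behavior_correlations(estimates, trials)
        corr_path = out / "correlations.csv"
        corr.table.to_csv(corr_path, index=False, float_format="%.6f")
        manifest["stages"]["stats"] = {
            "behavior": str(stats_path),
            "correlations": str(corr_path),
            "sha256": _sha256(stats_path),
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(manifest: dict | str | Path) -> str:
    """Human-readable summary of a run manifest (pure; idempotent)."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    lines = [f"ineqddm run (version {manifest.get('version')}, seed {manifest.get('seed')})"]
    stages = manifest.get("stages", {})
    expected = ["cohort", "selection", "fit", "recovery", "crossval", "stats"]
    for name in expected:
        if name not in stages:
            lines.append(f"  {name}: SKIPPED")
            continue
        info = stages[name]
        lines.append(f"  {name}:")
        for k, v in info.items():
            lines.append(f"    {k}: {v}")
        if name == "selection" and "table" in info:
            tab_path = Path(info["table"])
            if tab_path.exists():
                tab = pd.read_csv(tab_path)
                for row in tab.itertuples(index=False):
                    lines.append(f"      {row.spec:>10s}  WAIC={row.total_waic:.1f}")
    if "failed_stage" in manifest:
        lines.append(f"  FAILED at stage {manifest['failed_stage']}: {manifest.get('error')}")
    return "\n".join(lines)
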