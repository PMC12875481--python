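"""Descriptive and correlational behavioural layer.

Condition-wise rejection rates and choice-conditional response times,
response-time normalization against the equal-split condition, and the
drift-parameter/behaviour correlation family with Holm–Bonferroni
familywise correction.

Conditions are classified by their *base* label (the seven nominal SR/OR
ratios), never by the jittered ratio.  Cells with no trials of a given
choice are explicit missing values, never zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, IneqDDMError, InsufficientDataError, NormalizationError
from .task import AI_CONDITIONS, CONDITIONS, DI_CONDITIONS, EQUAL_CONDITION, valid_trials


@dataclass
class BehaviorSummary:
    per_participant: pd.DataFrame  # participant x condition rows
    group: pd.DataFrame  # one row per condition, averaged over participants


@dataclass
class CorrelationReport:
    table: pd.DataFrame  # pair, r, p_raw, p_holm, n

    def __getitem__(self, pair: str) -> pd.Series:
        hit = self.table[self.table["pair"] == pair]
        if hit.empty:
            raise KeyError(pair)
        return hit.iloc[0]


def summarize_behavior(trials: pd.DataFrame) -> BehaviorSummary:
    """Condition-wise rejection rates and mean RTs per choice.

    Rejection rate is rejections / valid (non-timeout) trials.  The group
    table averages per-participant values, so every participant counts
    equally regardless of timeouts.
    """
    unknown = set(trials["condition"]) - set(CONDITIONS)
    if unknown:
        raise IneqDDMError(f"unknown condition label(s): {sorted(unknown)}")
    rows = []
    for (pid, cond), g in trials.groupby(["participant_id", "condition"], sort=True):
        gv = valid_trials(g)
        acc = gv[gv["choice"] == "accept"]["rt_s"]
        rej = gv[gv["choice"] == "reject"]["rt_s"]
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "n_trials": len(g),
                "n_valid": len(gv),
                "n_reject": len(rej),
                "n_timeout": len(g) - len(gv),
                "rejection_rate": len(rej) / len(gv) if len(gv) else np.nan,
                "mean_rt_accept": acc.mean() if len(acc) else np.nan,
                "mean_rt_reject": rej.mean() if len(rej) else np.nan,
            }
        )
    per_part = pd.DataFrame(rows)
    group = (
        per_part.groupby("condition", sort=False)
        .agg(
            rejection_rate=("rejection_rate", "mean"),
            mean_rt_accept=("mean_rt_accept", "mean"),
            mean_rt_reject=("mean_rt_reject", "mean"),
            n_valid=("n_valid", "sum"),
            n_reject=("n_reject", "sum"),
            n_timeout=("n_timeout", "sum"),
        )
        .reindex([c for c in CONDITIONS if c in per_part["condition"].unique()])
        .reset_index()
    )
    return BehaviorSummary(per_participant=per_part, group=group)


def normalized_rt(trials: pd.DataFrame) -> pd.Series:
    """RT minus the participant's mean RT in the equal-split (1/1) condition.

    Returned as a Series aligned to the valid rows of ``trials``; raises
    :class:`NormalizationError` for participants without valid 1/1 trials.
    """
    dfv = valid_trials(trials)
    out = pd.Series(np.nan, index=dfv.index, name="normalized_rt")
    for pid, g in dfv.groupby("participant_id"):
        ref = g[g["condition"] == EQUAL_CONDITION]["rt_s"]
        if ref.empty:
            raise NormalizationError(f"participant {pid} has no valid {EQUAL_CONDITION} trials")
        out.loc[g.index] = g["rt_s"] - ref.mean()
    return out


def pearson_holm(pairs: dict[str, tuple[np.ndarray, np.ndarray]]) -> CorrelationReport:
    """Pearson correlations with Holm step-down familywise adjustment.

    ``pairs`` maps a name to an (x, y) pair.  Pairs with n < 3 or zero
    variance are flagged (NaN r) and excluded from the adjustment family
    with a warning.
    """
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = x.size
        if n < 3:
            raise InsufficientDataError(f"pair {name!r}: need n >= 3, got {n}")
        if x.var() == 0.0 or y.var() == 0.0:
            warnings.warn(f"pair {name!r}: zero variance, correlation undefined")
            rows.append({"pair": name, "r": np.nan, "p_raw": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"pair": name, "r": float(r), "p_raw": float(p), "n": n})
    table = pd.DataFrame(rows)
    table["p_holm"] = np.nan
    defined = table["p_raw"].notna()
    if defined.any():
        _, adj, _, _ = multipletests(table.loc[defined, "p_raw"], method="holm")
        table.loc[defined, "p_holm"] = adj
    return CorrelationReport(table=table[["pair", "r", "p_raw", "p_holm", "n"]])


def _participant_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant behavioural quantities used in the correlation family."""
    dfv = valid_trials(trials)
    unfair = tuple(DI_CONDITIONS) + tuple(AI_CONDITIONS)
    rows = []
    for pid, g in dfv.groupby("participant_id"):
        def _rate(conds):
            sel = g[g["condition"].isin(conds)]
            return (sel["choice"] == "reject").mean() if len(sel) else np.nan

        def _rt(conds, choice):
            sel = g[g["condition"].isin(conds) & (g["choice"] == choice)]["rt_s"]
            return sel.mean() if len(sel) else np.nan

        rows.append(
            {
                "participant_id": pid,
                "di_rejection_rate": _rate(DI_CONDITIONS),
                "di_rt_accept": _rt(DI_CONDITIONS, "accept"),
                "di_rt_reject": _rt(DI_CONDITIONS, "reject"),
                "unfair_rejection_rate": _rate(unfair),
                "unfair_rt_accept": _rt(unfair, "accept"),
                "ai_rejection_rate": _rate(AI_CONDITIONS),
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


#: (pair name, estimate column, behaviour column) of the correlation family.
CORRELATION_FAMILY = (
    ("beta_di~di_rejection", "beta_di", "di_rejection_rate"),
    ("beta_di~di_rt_accept", "beta_di", "di_rt_accept"),
    ("beta_di~di_rt_reject", "beta_di", "di_rt_reject"),
    ("beta_sr~unfair_rejection", "beta_sr", "unfair_rejection_rate"),
    ("beta_sr~unfair_rt_accept", "beta_sr", "unfair_rt_accept"),
    ("beta_ai~ai_rejection", "beta_ai", "ai_rejection_rate"),
)


def drift_behavior_correlations(
    estimates: pd.DataFrame, trials: pd.DataFrame
) -> CorrelationReport:
    """Correlations between drift coefficients and behaviour, Holm-corrected.

    ``estimates`` is indexed by participant_id (or has that column) with
    beta_sr / beta_di / beta_ai columns — posterior means from fits, or
    ground-truth values when assessing simulation-only behaviour.
    Participants missing a behavioural cell (e.g. no rejections) are dropped
    pairwise.
    """
    if "participant_id" in estimates.columns:
        estimates = estimates.set_index("participant_id")
    metrics = _participant_metrics(trials)
    common = metrics.index.intersection(estimates.index)
    if len(common) == 0:
        raise AlignmentError("no overlapping participants between estimates and trials")
    if len(common) < len(metrics.index.union(estimates.index)):
        missing = sorted(set(metrics.index) ^ set(estimates.index))
        raise AlignmentError(f"participant sets differ: {missing[:5]} ...")
    est = estimates.loc[common]
    met = metrics.loc[common]
    pairs = {}
    for name, ecol, bcol in CORRELATION_FAMILY:
        pairs[name] = (est[ecol].to_numpy(float), met[bcol].to_numpy(float))
    return pearson_holm(pairs)
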