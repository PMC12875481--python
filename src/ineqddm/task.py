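"""Ultimatum-game task design, trial-table I/O, and model regressors.

The responder sees 56 proposals: seven base splits of ¥500 between the
responder (self-reward, SR) and the proposer (other-reward, OR), eight trials
each, with independent uniform jitter of up to ±¥25 added to each reward so
that no two trials look identical.  A trial ends with accept, reject, or — if
no response arrives within the 10-s deadline — timeout.

From an offer the model regressors are built on a configurable monetary scale
(default ¥100 per model unit):

    SR = sr / scale              DI = max(OR - SR, 0)
    OR = or / scale              AI = max(SR - OR, 0)

DI ("disadvantageous inequity") is the amount by which the responder is
short-changed, AI ("advantageous inequity") the amount by which they are
favoured; at most one of the two is non-zero on any trial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DiagnosticsError, InvalidOfferError, TrialParseError

#: Base (condition label -> (self-reward yen, other-reward yen)), ordered from
#: the most disadvantageous to the most advantageous split.
BASE_OFFERS: dict[str, tuple[int, int]] = {
    "1/9": (50, 450),
    "1/4": (100, 400),
    "3/7": (150, 350),
    "2/3": (200, 300),
    "1/1": (250, 250),
    "3/2": (300, 200),
    "7/3": (350, 150),
}

CONDITIONS: tuple[str, ...] = tuple(BASE_OFFERS)
#: Conditions where the responder gets less than the proposer (SR/OR < 1).
DI_CONDITIONS: tuple[str, ...] = ("1/9", "1/4", "3/7", "2/3")
#: Conditions where the responder gets more than the proposer (SR/OR > 1).
AI_CONDITIONS: tuple[str, ...] = ("3/2", "7/3")
EQUAL_CONDITION = "1/1"

TRIALS_PER_CONDITION = 8
N_TRIALS = TRIALS_PER_CONDITION * len(CONDITIONS)
JITTER_MAX_YEN = 25
DEADLINE_S = 10.0
DEFAULT_SCALE_YEN = 100.0

CHOICES = ("accept", "reject", "timeout")

_TRIAL_COLUMNS = ["participant_id", "trial_index", "sr_yen", "or_yen", "choice", "rt_s"]


@dataclass(frozen=True)
class Offer:
    """One proposed split: integer yen for the responder and the proposer."""

    sr_yen: int
    or_yen: int
    condition_label: str

    def __post_init__(self):
        if self.sr_yen < 0 or self.or_yen < 0:
            raise InvalidOfferError(f"negative reward in offer {self}")
        if self.condition_label not in BASE_OFFERS:
            raise InvalidOfferError(f"unknown condition label {self.condition_label!r}")
        base_sr, base_or = BASE_OFFERS[self.condition_label]
        if abs(self.sr_yen - base_sr) > JITTER_MAX_YEN or abs(self.or_yen - base_or) > JITTER_MAX_YEN:
            raise InvalidOfferError(
                f"offer {self.sr_yen}-{self.or_yen} deviates more than ±{JITTER_MAX_YEN} "
                f"from base {base_sr}-{base_or} ({self.condition_label})"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One trial: the offer, the (possibly censored) choice, and the RT."""

    participant_id: str
    trial_index: int
    offer: Offer
    choice: str
    rt_s: float | None = None

    def __post_init__(self):
        if self.choice not in CHOICES:
            raise TrialParseError(f"unknown choice {self.choice!r}")
        if self.choice == "timeout":
            if self.rt_s is not None:
                raise TrialParseError("timeout trials carry no response time")
        else:
            if self.rt_s is None or not (0.0 < self.rt_s <= DEADLINE_S):
                raise TrialParseError(
                    f"rt_s must lie in (0, {DEADLINE_S}] s, got {self.rt_s!r}"
                )


@dataclass(frozen=True)
class InequityFeatures:
    """Scaled model regressors for one offer."""

    sr: float
    or_: float
    di: float
    ai: float
    scale_yen: float = DEFAULT_SCALE_YEN


@dataclass
class DesignDiagnostics:
    vif: dict[str, float]
    correlation_matrix: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {"vif": self.vif, "correlation_matrix": self.correlation_matrix.to_dict()},
            indent=2,
        )


def infer_condition(sr_yen: int, or_yen: int) -> str:
    """Return the base condition whose pair the (jittered) offer belongs to."""
    for label, (bsr, bor) in BASE_OFFERS.items():
        if abs(sr_yen - bsr) <= JITTER_MAX_YEN and abs(or_yen - bor) <= JITTER_MAX_YEN:
            return label
    raise InvalidOfferError(f"offer {sr_yen}-{or_yen} matches no base condition")


def generate_offer_set(
    seed: int, jitter_step_yen: int = 5, jitter: bool = True
) -> list[Offer]:
    """Generate the 56-trial offer set: 8 jittered trials per base condition.

    Each reward is independently perturbed by a uniform draw from the grid
    {-25, ..., +25} with the given step; with ``jitter=False`` the printed
    base pairs are returned exactly.  Order is randomized by ``seed`` and the
    result is deterministic given ``(seed, jitter_step_yen)``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if jitter_step_yen <= 0 or JITTER_MAX_YEN % jitter_step_yen != 0:
        raise ValueError(f"jitter_step_yen must divide {JITTER_MAX_YEN}")
    rng = np.random.default_rng(seed)
    grid = np.arange(-JITTER_MAX_YEN, JITTER_MAX_YEN + 1, jitter_step_yen)
    offers: list[Offer] = []
    for label, (bsr, bor) in BASE_OFFERS.items():
        for _ in range(TRIALS_PER_CONDITION):
            dsr = int(rng.choice(grid)) if jitter else 0
            dor = int(rng.choice(grid)) if jitter else 0
            offers.append(Offer(bsr + dsr, bor + dor, label))
    order = rng.permutation(len(offers))
    return [offers[i] for i in order]


def offers_to_frame(offers: list[Offer]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [o.condition_label for o in offers],
            "sr_yen": [o.sr_yen for o in offers],
            "or_yen": [o.or_yen for o in offers],
        }
    )


def compute_features(offer: Offer | tuple[int, int], scale_yen: float = DEFAULT_SCALE_YEN) -> InequityFeatures:
    """Scaled SR/OR/DI/AI regressors for one offer.

    DI and AI are computed on integer yen before scaling, so exactly one of
    them is non-zero and ``di - ai == or_ - sr`` holds without rounding.
    """
    if scale_yen <= 0:
        raise ValueError("scale_yen must be positive")
    if isinstance(offer, Offer):
        sr_yen, or_yen = offer.sr_yen, offer.or_yen
    else:
        sr_yen, or_yen = offer
    if sr_yen < 0 or or_yen < 0:
        raise InvalidOfferError(f"negative reward in offer ({sr_yen}, {or_yen})")
    return InequityFeatures(
        sr=sr_yen / scale_yen,
        or_=or_yen / scale_yen,
        di=max(or_yen - sr_yen, 0) / scale_yen,
        ai=max(sr_yen - or_yen, 0) / scale_yen,
        scale_yen=scale_yen,
    )


def features_frame(trials: pd.DataFrame, scale_yen: float = DEFAULT_SCALE_YEN) -> pd.DataFrame:
    """Append sr/or_/di/ai feature columns to a trial or offer table."""
    sr_yen = trials["sr_yen"].to_numpy(float)
    or_yen = trials["or_yen"].to_numpy(float)
    if (sr_yen < 0).any() or (or_yen < 0).any():
        raise InvalidOfferError("negative reward in trial table")
    out = trials.copy()
    out["sr"] = sr_yen / scale_yen
    out["or_"] = or_yen / scale_yen
    out["di"] = np.maximum(or_yen - sr_yen, 0) / scale_yen
    out["ai"] = np.maximum(sr_yen - or_yen, 0) / scale_yen
    return out


# ---------------------------------------------------------------------------
# trial-table I/O


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table CSV; timeout rows get an empty rt_s cell."""
    out = trials.copy()
    cols = [c for c in _TRIAL_COLUMNS + ["condition"] if c in out.columns]
    out = out[cols]
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Returns a DataFrame with columns participant_id, trial_index, sr_yen,
    or_yen, choice, rt_s (NaN for timeouts), condition, and a boolean
    ``valid`` flag (False for timeouts, which are excluded from every
    likelihood downstream).  Malformed rows raise :class:`TrialParseError`
    naming the 1-based data row numbers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise TrialParseError(f"missing column(s): {', '.join(missing)}")

    problems: list[str] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            sr_yen = int(rec["sr_yen"])
            or_yen = int(rec["or_yen"])
        except ValueError:
            problems.append(f"row {i}: non-integer reward")
            continue
        choice = rec["choice"].strip()
        if choice not in CHOICES:
            problems.append(f"row {i}: unknown choice token {choice!r}")
            continue
        rt_text = rec["rt_s"].strip()
        rt = None
        if choice == "timeout":
            if rt_text:
                problems.append(f"row {i}: timeout trial must have empty rt_s")
                continue
        else:
            try:
                rt = float(rt_text)
            except ValueError:
                problems.append(f"row {i}: unreadable rt_s {rt_text!r}")
                continue
            if not (0.0 < rt <= DEADLINE_S):
                problems.append(
                    f"row {i}: rt_s={rt} outside (0, {DEADLINE_S}] "
                    f"(responses must beat the {DEADLINE_S:.0f}-s deadline)"
                )
                continue
        condition = rec.get("condition", "") or ""
        try:
            condition = condition.strip() or infer_condition(sr_yen, or_yen)
            Offer(sr_yen, or_yen, condition)
        except InvalidOfferError as exc:
            problems.append(f"row {i}: {exc}")
            continue
        rows.append(
            {
                "participant_id": rec["participant_id"],
                "trial_index": int(rec["trial_index"]),
                "condition": condition,
                "sr_yen": sr_yen,
                "or_yen": or_yen,
                "choice": choice,
                "rt_s": np.nan if rt is None else rt,
            }
        )
    if problems:
        raise TrialParseError("; ".join(problems), rows=problems)
    df = pd.DataFrame(rows, columns=["participant_id", "trial_index", "condition",
                                     "sr_yen", "or_yen", "choice", "rt_s"])
    df["valid"] = df["choice"] != "timeout"
    return df


def records_from_frame(trials: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in trials.itertuples(index=False):
        rt = None if row.choice == "timeout" else float(row.rt_s)
        records.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                trial_index=int(row.trial_index),
                offer=Offer(int(row.sr_yen), int(row.or_yen), str(row.condition)),
                choice=str(row.choice),
                rt_s=rt,
            )
        )
    return records


def frame_from_records(records: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "trial_index": [r.trial_index for r in records],
            "condition": [r.offer.condition_label for r in records],
            "sr_yen": [r.offer.sr_yen for r in records],
            "or_yen": [r.offer.or_yen for r in records],
            "choice": [r.choice for r in records],
            "rt_s": [np.nan if r.rt_s is None else r.rt_s for r in records],
        }
    )
    df["valid"] = df["choice"] != "timeout"
    return df


# ---------------------------------------------------------------------------
# design diagnostics


def design_diagnostics(
    features: pd.DataFrame, regressors: tuple[str, ...] = ("sr", "di", "ai")
) -> DesignDiagnostics:
    """Variance inflation factors and correlation matrix of the regressors.

    VIF(X) = 1 / (1 - R²) where R² comes from an intercept-included OLS of X
    on the remaining regressors.  An exactly collinear regressor is reported
    with a +inf sentinel.
    """
    if len(features) < 4:
        raise DiagnosticsError("need at least 4 trials for design diagnostics")
    mat = features[list(regressors)].to_numpy(float)
    variances = mat.var(axis=0)
    for name, v in zip(regressors, variances):
        if v == 0.0:
            raise DiagnosticsError(f"regressor {name!r} has zero variance")

    vifs: dict[str, float] = {}
    n = mat.shape[0]
    for j, name in enumerate(regressors):
        y = mat[:, j]
        others = np.delete(mat, j, axis=1)
        X = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)

    corr = pd.DataFrame(np.corrcoef(mat, rowvar=False), index=regressors, columns=regressors)
    return DesignDiagnostics(vif=vifs, correlation_matrix=corr)


def valid_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop timeout trials (censored; excluded from all likelihoods)."""
    if "valid" in trials.columns:
        return trials[trials["valid"]].copy()
    return trials[trials["choice"] != "timeout"].copy()
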