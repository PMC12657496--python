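"""Reinforcement-learning model of reward prediction error for the MID task.

The Monetary Incentive Delay (MID) task presents cued trials of five
types — large/small win, neutral, small/large loss — with cue values
Cu ∈ {+5, +0.2, 0, −0.2, −5} points.  A simple Rescorla–Wagner-style
learner tracks pGain, the participant's subjective probability that the
cued amount is realized, starting at 0.5:

    EV_t  = pGain_t · Cu_t
    RPE_t = R_t − EV_t

Two update rules for pGain are provided.  The default, ``normalized``,
is the standard delta rule on a probability,

    pGain_{t+1} = pGain_t + η · RPE_t / Cu_t        (no update for Cu = 0)

which rewrites as pGain + η·(R/Cu − pGain) and therefore stays in [0, 1]
whenever R/Cu ∈ {0, 1}, as it is under the outcome convention below.
The alternative ``literal`` rule, pGain + η·RPE·Cu, multiplies the error
by the cue instead of dividing; it exits [0, 1] after a single
large-magnitude trial (0.5 → 9.25 for a hit large win) and is clipped to
[0, 1], with clip events counted.  The learning rate η defaults to 0.7.

Outcome convention: win trials pay +|Cu| on a hit and 0 on a miss; loss
trials pay 0 on a hit (loss avoided) and Cu (negative) on a miss;
neutral trials always pay 0.

Positive and negative prediction errors (PPE/NPE) are summarized per cue
condition as the mean RPE over trials with RPE > 0 and RPE < 0
respectively; zero-RPE trials contribute to neither, and empty cells are
reported as missing rather than zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cue values in points, by trial type
CUE_VALUES = {
    "LargeWin": 5.0,
    "SmallWin": 0.2,
    "Neutral": 0.0,
    "SmallLoss": -0.2,
    "LargeLoss": -5.0,
}
CUE_TYPES: Tuple[str, ...] = tuple(CUE_VALUES)

#: condition labels used in RPE summaries (neutral trials have RPE that
#: converges to 0 and are excluded from the reward/loss cells)
CONDITIONS = {
    "LargeWin": "large_reward",
    "SmallWin": "small_reward",
    "LargeLoss": "large_loss",
    "SmallLoss": "small_loss",
}

DEFAULT_ETA = 0.7
INITIAL_PGAIN = 0.5


def outcome_value(cue_type: str, hit: bool) -> float:
    """Realized outcome R in points for a trial of the given type."""
    cu = CUE_VALUES[cue_type]
    if cu > 0:
        return cu if hit else 0.0
    if cu < 0:
        return 0.0 if hit else cu
    return 0.0


@dataclass(frozen=True)
class MIDTrial:
    trial_index: int
    cue_type: str
    hit: bool
    outcome: float

    def __post_init__(self):
        if self.cue_type not in CUE_VALUES:
            raise ValueError(f"unknown cue type {self.cue_type!r}")
        if self.cue_type == "Neutral" and self.outcome != 0.0:
            raise ValueError("neutral trials must have outcome 0")
        if not math.isfinite(self.outcome):
            raise ValueError("non-finite outcome")

    @property
    def cue_value(self) -> float:
        return CUE_VALUES[self.cue_type]


@dataclass(frozen=True)
class RLState:
    p_gain: float = INITIAL_PGAIN
    eta: float = DEFAULT_ETA
    update_mode: str = "normalized"
    n_clipped: int = 0

    def __post_init__(self):
        if self.update_mode not in ("normalized", "literal"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must be in (0, 1]")
        if not math.isfinite(self.p_gain):
            raise ValueError("non-finite pGain")


def step(state: RLState, trial: MIDTrial) -> Tuple[float, float, RLState]:
    """One trial of the learner: returns (EV, RPE, post-update state)."""
    cu = trial.cue_value
    ev = state.p_gain * cu
    rpe = trial.outcome - ev
    if cu == 0.0:
        return ev, rpe, state
    if state.update_mode == "normalized":
        p_new = state.p_gain + state.eta * rpe / cu
        return ev, rpe, replace(state, p_gain=p_new)
    # literal printed form, clipped to keep pGain a probability
    p_new = state.p_gain + state.eta * rpe * cu
    clipped = p_new < 0.0 or p_new > 1.0
    p_new = min(1.0, max(0.0, p_new))
    return ev, rpe, replace(state, p_gain=p_new,
                            n_clipped=state.n_clipped + int(clipped))


def _trials_from_frame(trials: pd.DataFrame) -> List[MIDTrial]:
    if not {"run", "trial_index", "cue_type", "hit", "outcome"} <= set(trials.columns):
        raise ValueError("trial table lacks required columns")
    keys = list(zip(trials["run"], trials["trial_index"]))
    if keys != sorted(keys):
        raise ValueError("trials must be ordered by run then trial_index")
    return [
        MIDTrial(int(r.trial_index), r.cue_type, bool(r.hit), float(r.outcome))
        for r in trials.itertuples()
    ]


def run_model(
    trials,
    state0: Optional[RLState] = None,
    per_cue_state: bool = False,
) -> pd.DataFrame:
    """Fold the learner over an ordered trial sequence.

    ``trials`` is either a sequence of MIDTrial (taken as already
    ordered) or a DataFrame with run/trial_index columns (validated).
    One pGain sequence is shared across all runs and trial types by
    default; ``per_cue_state`` maintains an independent state per cue
    type for sensitivity analysis.

    Returns a trace DataFrame with columns cue_type, outcome, p_gain
    (pre-update), ev, rpe.
    """
    state0 = state0 or RLState()
    if isinstance(trials, pd.DataFrame):
        seq = _trials_from_frame(trials)
    else:
        seq = list(trials)
    states: dict = {}
    rows = []
    for trial in seq:
        key = trial.cue_type if per_cue_state else None
        state = states.get(key, state0)
        p_pre = state.p_gain
        ev, rpe, states[key] = step(state, trial)
        rows.append({
            "trial_index": trial.trial_index,
            "cue_type": trial.cue_type,
            "hit": trial.hit,
            "outcome": trial.outcome,
            "p_gain": p_pre,
            "ev": ev,
            "rpe": rpe,
        })
    n_clipped = sum(s.n_clipped for s in states.values())
    if n_clipped:
        logger.info("literal update clipped pGain on %d of %d trials",
                    n_clipped, len(seq))
    return pd.DataFrame(rows)


def summarize_rpe(trace: pd.DataFrame) -> dict:
    """Per-condition positive/negative prediction-error summary.

    Returns a flat dict with ppe_/npe_ means and n_ppe_/n_npe_ counts per
    condition (large_reward, small_reward, large_loss, small_loss).
    Conditions with no qualifying trials are reported as NaN with count 0.
    """
    out = {}
    for cue_type, cond in CONDITIONS.items():
        rpes = trace.loc[trace["cue_type"] == cue_type, "rpe"]
        pos = rpes[rpes > 0]
        neg = rpes[rpes < 0]
        out[f"ppe_{cond}"] = pos.mean() if len(pos) else float("nan")
        out[f"npe_{cond}"] = neg.mean() if len(neg) else float("nan")
        out[f"n_ppe_{cond}"] = int(len(pos))
        out[f"n_npe_{cond}"] = int(len(neg))
    return out


def compute_rpe_summaries(
    mid_trials: pd.DataFrame,
    eta: float = DEFAULT_ETA,
    update_mode: str = "normalized",
    per_cue_state: bool = False,
) -> pd.DataFrame:
    """Run the learner per participant over mid_trials.csv rows.

    Returns one row per participant with PPE/NPE summary columns.
    """
    rows = []
    for pid, sub in mid_trials.groupby("participant_id", sort=True):
        sub = sub.sort_values(["run", "trial_index"]).reset_index(drop=True)
        trace = run_model(sub, RLState(eta=eta, update_mode=update_mode),
                          per_cue_state=per_cue_state)
        row = {"participant_id": pid}
        row.update(summarize_rpe(trace))
        rows.append(row)
    return pd.DataFrame(rows)
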