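"""Scoring of the ambulatory Go/No-go task.

Each session has four main blocks of 50 trials, 10 no-go trials per block
(20% of trials), preceded by a short training block that is excluded from
scoring.  The response-inhibition outcome is no-go accuracy: the percentage
of no-go trials on which the response was successfully withheld.  Responses
landing after the 1200 ms stimulus window count as no response.  Go accuracy
and mean go RT are computed as descriptives only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .ema_data import EmaPanel, OccasionKey, TrialLog, wide_to_long

logger = logging.getLogger(__name__)

#: Stimulus presentation window; later responses are treated as absent.
RESPONSE_WINDOW_MS = 1200.0

RESPONSE_INHIBITION = "response_inhibition"


@dataclass(frozen=True)
class GoNogoScore:
    occasion: OccasionKey
    nogo_accuracy: float       # percent of no-go trials with response withheld
    go_accuracy: float         # percent of go trials with a response
    n_nogo: int
    n_go: int
    mean_go_rt: float          # ms, over responded go trials (NaN if none)


class UnscorableOccasion(ValueError):
    """Occasion cannot be scored (e.g. no main-block no-go trials)."""


def _effective_response(df: pd.DataFrame) -> pd.Series:
    late = df["rt_ms"].notna() & (df["rt_ms"] > RESPONSE_WINDOW_MS)
    return df["responded"] & ~late


def score_session(log: TrialLog, occasion: OccasionKey) -> GoNogoScore:
    """Score one occasion's session from the trial log."""
    df = log.main_trials()
    df = df[(df["person"] == occasion.person) & (df["day"] == occasion.day)
            & (df["slot"] == occasion.slot)]
    nogo = df[df["stimulus"] == "nogo"]
    go = df[df["stimulus"] == "go"]
    if len(nogo) == 0:
        raise UnscorableOccasion(
            f"no main-block no-go trials for {occasion.person} day {occasion.day} "
            f"{occasion.slot}")
    responded_nogo = _effective_response(nogo)
    responded_go = _effective_response(go)
    withheld = (~responded_nogo).sum()
    go_hits = responded_go.sum()
    go_rts = go.loc[responded_go, "rt_ms"]
    return GoNogoScore(
        occasion=occasion,
        nogo_accuracy=100.0 * withheld / len(nogo),
        go_accuracy=100.0 * go_hits / len(go) if len(go) else float("nan"),
        n_nogo=int(len(nogo)),
        n_go=int(len(go)),
        mean_go_rt=float(go_rts.mean()) if len(go_rts) else float("nan"),
    )


def sessions_to_panel(log: TrialLog) -> EmaPanel:
    """Score every occasion in the log into a panel fragment with one
    ``response_inhibition`` value per scorable occasion.  Occasions with only
    a training block are skipped with a warning."""
    rows = []
    for _, occ in log.occasions().iterrows():
        key = OccasionKey(occ["person"], int(occ["day"]), occ["slot"])
        try:
            score = score_session(log, key)
        except UnscorableOccasion as exc:
            logger.warning("skipping unscorable occasion: %s", exc)
            continue
        rows.append({"person": key.person, "day": key.day, "slot": key.slot,
                     "value": score.nogo_accuracy})
    df = pd.DataFrame(rows, columns=["person", "day", "slot", "value"])
    if len(df):
        long = wide_to_long(df.rename(columns={"value": RESPONSE_INHIBITION}),
                            [RESPONSE_INHIBITION])
    else:
        long = pd.DataFrame(columns=["person", "day", "slot", "variable", "value"])
    return EmaPanel(long, {RESPONSE_INHIBITION: "task-score"})
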