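"""Composite scoring, compliance, descriptives and lag-pair construction.

The estimator downstream uses a person-mean (between/within) decomposition:
each person's mean over all their observed occasions estimates the trait
level, and the morning deviation from that mean is the within-person
predictor.  Lag pairs never cross a day boundary — only same-day AM→PM
transitions are formed, so overnight carryover is never modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ema_data import EmaPanel, wide_to_long


@dataclass(frozen=True)
class CompositeSpec:
    """Scoring rule for an item composite.

    ``reverse`` items are flipped (value -> 100 - value) before averaging.
    ``min_answered`` defaults to requiring every listed item; composites with
    fewer answered items score as missing.
    """

    name: str
    items: tuple[str, ...]
    reverse: tuple[str, ...] = ()
    min_answered: int | None = None

    def __post_init__(self) -> None:
        if not set(self.reverse) <= set(self.items):
            raise ValueError(f"{self.name}: reverse items must be a subset of items")
        n = self.min_answered if self.min_answered is not None else len(self.items)
        if n < 1:
            raise ValueError(f"{self.name}: min_answered must be >= 1")

    @property
    def required(self) -> int:
        return self.min_answered if self.min_answered is not None else len(self.items)


def score_composites(panel: EmaPanel, specs: list[CompositeSpec]) -> EmaPanel:
    """Add one composite value per occasion: the mean of the answered
    (reverse-corrected) items, missing when fewer than ``min_answered``
    items were answered."""
    known = set(panel.variables)
    for spec in specs:
        unknown = set(spec.items) - known
        if unknown:
            raise ValueError(f"composite {spec.name!r} references unknown items {sorted(unknown)}")

    wide = panel.pivot().reset_index()
    # rescoring is idempotent: existing composite rows are replaced
    names = {s.name for s in specs}
    frames = [panel.data[~panel.data["variable"].isin(names)]]
    registry = dict(panel.registry)
    for spec in specs:
        # reindex keeps items whose values are all missing as NaN columns
        vals = wide.reindex(columns=list(spec.items)).copy()
        for item in spec.reverse:
            vals[item] = 100.0 - vals[item]
        answered = vals.notna().sum(axis=1)
        score = vals.mean(axis=1, skipna=True)
        score[answered < spec.required] = np.nan
        block = wide[["person", "day", "slot"]].copy()
        block["variable"] = spec.name
        block["value"] = score.values
        frames.append(block)
        registry[spec.name] = "composite"
    return EmaPanel(pd.concat(frames, ignore_index=True), registry)


@dataclass
class ComplianceReport:
    per_person: pd.Series       # completion rate per person
    rate: float                 # mean across persons, in [0, 1]
    n_expected: int


def compliance(panel: EmaPanel, variables: list[str] | None = None,
               expected_occasions: int = 18) -> ComplianceReport:
    """Completion rate: occasions with at least one observed value among
    ``variables`` (default: any variable), divided by the expected number of
    occasions per person (study default 9 weekdays x 2 slots = 18), averaged
    over persons."""
    if expected_occasions <= 0:
        raise ValueError("expected_occasions must be positive")
    obs = panel.observed()
    if variables is not None:
        obs = obs[obs["variable"].isin(variables)]
    done = obs.groupby("person")[["day", "slot"]].apply(
        lambda g: g.drop_duplicates().shape[0])
    done = done.reindex(panel.persons, fill_value=0)
    rates = done / expected_occasions
    return ComplianceReport(per_person=rates, rate=float(rates.mean()),
                            n_expected=expected_occasions)


def descriptives(panel: EmaPanel, variables: list[str]) -> pd.DataFrame:
    """Mean/SD overall and by slot, with an AM-vs-PM comparison per variable.

    The comparison is a paired t-test on person-level AM means vs PM means
    (persons lacking either slot are dropped from the test)."""
    known = set(panel.variables)
    rows = []
    obs = panel.observed()
    for var in variables:
        if var not in known:
            raise ValueError(f"variable {var!r} not present in panel")
        sub = obs[obs["variable"] == var]
        am = sub[sub["slot"] == "AM"]["value"]
        pm = sub[sub["slot"] == "PM"]["value"]
        pmeans = sub.groupby(["person", "slot"])["value"].mean().unstack("slot")
        pval = np.nan
        if {"AM", "PM"} <= set(pmeans.columns):
            paired = pmeans.dropna()
            if len(paired) >= 2:
                diff = paired["AM"] - paired["PM"]
                if np.allclose(diff, diff.iloc[0]):
                    # zero-variance differences: no evidence of a slot effect
                    pval = 1.0 if np.allclose(diff, 0) else 0.0
                else:
                    pval = stats.ttest_rel(paired["AM"], paired["PM"]).pvalue
        rows.append({
            "variable": var,
            "mean": sub["value"].mean(), "sd": sub["value"].std(ddof=1),
            "am_mean": am.mean(), "am_sd": am.std(ddof=1),
            "pm_mean": pm.mean(), "pm_sd": pm.std(ddof=1),
            "am_pm_p": pval,
        })
    return pd.DataFrame(rows)


def write_descriptives(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.3f")


@dataclass
class LagPairSet:
    """Same-day AM→PM rows for the node-wise lag-1 models.

    ``pairs`` has one row per (person, day) with columns ``y_<var>`` (the PM
    outcome), ``c_<var>`` (the within-person-centered AM predictor) and
    ``m_<var>`` (the person mean).  NaNs mark missing values; each node fit
    drops rows it cannot use.  ``person_means`` is the person-level table of
    means over ALL observed occasions (both slots).
    """

    variables: list[str]
    pairs: pd.DataFrame
    person_means: pd.DataFrame = field(repr=False, default=None)

    def complete_rows(self, outcome: str) -> pd.DataFrame:
        """Rows usable by the fit for ``outcome``: PM outcome observed and all
        centered AM predictors observed."""
        cols = [f"y_{outcome}"] + [f"c_{v}" for v in self.variables]
        return self.pairs.dropna(subset=cols)


def build_lag_pairs(panel: EmaPanel, variables: list[str]) -> LagPairSet:
    """Construct the lag-1 design: one candidate row per (person, day) with
    any AM or PM observation of the model variables.

    Person means use all of that person's observed occasions (both slots), so
    an occasion missing its AM partner still informs the trait estimate.
    PM→next-morning pairs are never formed.
    """
    obs = panel.observed()
    obs = obs[obs["variable"].isin(variables)]
    if obs.empty:
        raise ValueError("panel has no observations of the requested variables")
    empty = set(panel.persons) - set(obs["person"].unique())
    if empty:
        raise ValueError(f"persons with zero observations: {sorted(empty)}")

    means = obs.groupby(["person", "variable"])["value"].mean().unstack("variable")
    means = means.reindex(columns=variables)

    wide = obs.pivot_table(index=["person", "day"], columns=["slot", "variable"],
                           values="value", aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    for v in variables:
        am = wide[("AM", v)] if ("AM", v) in wide.columns else pd.Series(np.nan, index=wide.index)
        pm = wide[("PM", v)] if ("PM", v) in wide.columns else pd.Series(np.nan, index=wide.index)
        m = means[v].reindex(out.index.get_level_values("person")).values
        out[f"y_{v}"] = pm
        out[f"c_{v}"] = am - m
        out[f"m_{v}"] = m
    out = out.reset_index()
    # keep only days that can contribute to some fit: at least one y and all c
    has_y = out[[f"y_{v}" for v in variables]].notna().any(axis=1)
    has_c = out[[f"c_{v}" for v in variables]].notna().all(axis=1)
    out = out[has_y & has_c].reset_index(drop=True)
    return LagPairSet(variables=list(variables), pairs=out,
                      person_means=means)
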