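"""Internal-consistency and split-half reliability statistics.

Two statistics cover the two measurement modalities: Cronbach's alpha for
item composites, and an odd/even-day split-half correlation with the
Spearman-Brown step-up for the task outcome.  The split-half unit is the
person: each person's mean over odd study days is correlated with their mean
over even days across persons, the reading most natural for a trait-level
reliability of a repeated ambulatory measure.  An occasion-level split is
available via ``unit="occasion"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ema_data import EmaPanel


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of an (units x k items) matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the item sum),
    with listwise deletion of rows containing a missing item.
    """
    mat = pd.DataFrame(items).dropna()
    k = mat.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if mat.shape[0] < 3:
        raise ValueError("alpha needs at least 3 complete rows")
    item_var = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def spearman_brown(r: float) -> float:
    """Step-up of a half-test correlation to full length: SB = 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_sb(panel: EmaPanel, variable: str,
                  unit: str = "person") -> tuple[float, float, int]:
    """Odd/even-day split-half reliability of ``variable``.

    Returns ``(r, SB, n_units)``.  With ``unit="person"`` (default), each
    person's odd-day and even-day means are correlated across persons; with
    ``unit="occasion"`` the split is within person-slot cells.
    """
    obs = panel.observed()
    sub = obs[obs["variable"] == variable].copy()
    if sub.empty:
        raise ValueError(f"variable {variable!r} not observed in panel")
    sub["parity"] = np.where(sub["day"] % 2 == 1, "odd", "even")
    group = ["person"] if unit == "person" else ["person", "slot"]
    halves = sub.groupby(group + ["parity"])["value"].mean().unstack("parity")
    halves = halves.dropna(subset=["odd", "even"]) if {"odd", "even"} <= set(halves.columns) \
        else halves.iloc[0:0]
    n = len(halves)
    if n < 3:
        raise ValueError(f"fewer than 3 units with both odd- and even-day "
                         f"observations of {variable!r}")
    r = float(stats.pearsonr(halves["odd"], halves["even"]).statistic)
    if r <= -1:
        raise ValueError("half correlation of -1; Spearman-Brown undefined")
    return r, spearman_brown(r), n


@dataclass
class ReliabilityReport:
    table: pd.DataFrame      # columns: statistic, variable, value, n

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def reliability_report(panel: EmaPanel, composites: dict[str, list[str]],
                       split_half_vars: list[str]) -> ReliabilityReport:
    """Alpha for each composite's items (units = occasions with complete
    items) and odd/even split-half + Spearman-Brown for each listed outcome."""
    rows = []
    wide = panel.pivot()
    for name, item_names in composites.items():
        mat = wide[item_names]
        rows.append({"statistic": "cronbach_alpha", "variable": name,
                     "value": cronbach_alpha(mat), "n": int(mat.dropna().shape[0])})
    for var in split_half_vars:
        r, sb, n = split_half_sb(panel, var)
        rows.append({"statistic": "split_half_r", "variable": var, "value": r, "n": n})
        rows.append({"statistic": "spearman_brown", "variable": var, "value": sb, "n": n})
    return ReliabilityReport(pd.DataFrame(rows))
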