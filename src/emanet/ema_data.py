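"""Canonical data model and I/O for twice-daily EMA studies.

The study design is slot-based: every person is prompted twice per weekday
(AM ~7:00, PM ~16:00), so an observation is keyed by ``(person, day, slot)``
rather than by clock time.  Three containers cover the pipeline:

* :class:`EmaPanel` — long-format self-report / task-score observations on a
  0–100 scale;
* :class:`TrialLog` — trial-level Go/No-go records;
* :class:`NetworkSet` — the three estimated networks (temporal,
  contemporaneous, between) with standard errors and p-values.

All file formats are plain text: CSV for panels and trial logs, JSON for
network sets, TSV for edge lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SLOTS = ("AM", "PM")

PANEL_COLUMNS = ["person", "day", "slot", "variable", "value"]
TRIAL_COLUMNS = ["person", "day", "slot", "block", "trial", "stimulus",
                 "responded", "rt_ms"]

#: Roles a variable may play in the registry.
VARIABLE_ROLES = ("item", "composite", "task-score")


class EmaReadError(ValueError):
    """Raised when an input file violates the panel/trial-log contracts."""


@dataclass(frozen=True)
class OccasionKey:
    """One scheduled measurement occasion: (person, study weekday, slot)."""

    person: str
    day: int
    slot: str

    def __post_init__(self) -> None:
        if self.slot not in SLOTS:
            raise ValueError(f"slot must be one of {SLOTS}, got {self.slot!r}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")


@dataclass
class EmaPanel:
    """Long-format EMA observations.

    ``data`` has columns person, day, slot, variable, value; at most one row
    per (occasion, variable); values in [0, 100] or NaN.  ``registry`` maps
    variable name -> role ("item", "composite" or "task-score"); variables
    absent from the registry are tolerated and treated as role "item".
    """

    data: pd.DataFrame
    registry: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.copy()
        df["person"] = df["person"].astype(str)
        df["day"] = df["day"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        # canonical row order makes panels comparable regardless of input order
        df = df.sort_values(PANEL_COLUMNS[:4], kind="mergesort").reset_index(drop=True)
        # structural validation always; the [0, 100] range check is applied at
        # read time only, because the synthetic generator is deliberately
        # unclipped (see synthgen)
        _validate_panel_frame(df, check_range=False)
        for var, role in self.registry.items():
            if role not in VARIABLE_ROLES:
                raise ValueError(f"unknown role {role!r} for variable {var!r}")
        self.data = df[PANEL_COLUMNS]

    @property
    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    @property
    def persons(self) -> list[str]:
        return sorted(self.data["person"].unique())

    def observed(self) -> pd.DataFrame:
        """Rows with a non-missing value."""
        return self.data[self.data["value"].notna()]

    def pivot(self, slot: str | None = None) -> pd.DataFrame:
        """Wide table indexed by (person, day, slot) with one column per variable."""
        df = self.data if slot is None else self.data[self.data["slot"] == slot]
        return df.pivot_table(index=["person", "day", "slot"], columns="variable",
                              values="value", aggfunc="first")

    def merge(self, other: "EmaPanel") -> "EmaPanel":
        """Union of two panels (e.g. self-report + task scores), same keying."""
        data = pd.concat([self.data, other.data], ignore_index=True)
        registry = {**self.registry, **other.registry}
        return EmaPanel(data, registry)

    def equals(self, other: "EmaPanel") -> bool:
        return self.data.equals(other.data)


def _validate_panel_frame(df: pd.DataFrame, check_range: bool = True) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise EmaReadError(f"panel is missing columns {missing}")
    bad_slot = ~df["slot"].isin(SLOTS)
    if bad_slot.any():
        row = df[bad_slot].iloc[0]
        raise EmaReadError(
            f"malformed slot label {row['slot']!r} "
            f"(person={row['person']}, day={row['day']}, variable={row['variable']})")
    if check_range:
        vals = df["value"]
        out = vals.notna() & ((vals < 0) | (vals > 100))
        if out.any():
            row = df[out].iloc[0]
            raise EmaReadError(
                f"value {row['value']} outside [0, 100] "
                f"(person={row['person']}, day={row['day']}, slot={row['slot']}, "
                f"variable={row['variable']})")
    dup = df.duplicated(subset=["person", "day", "slot", "variable"])
    if dup.any():
        row = df[dup].iloc[0]
        raise EmaReadError(
            f"duplicate record for person={row['person']}, day={row['day']}, "
            f"slot={row['slot']}, variable={row['variable']}")


def read_panel(path: str | Path, registry: Mapping[str, str] | None = None,
               check_range: bool = True) -> EmaPanel:
    """Read a long-format panel CSV (columns person, day, slot, variable, value).

    Empty fields and the string ``NA`` are read as missing.  Values outside
    [0, 100], duplicate records and malformed slot labels raise
    :class:`EmaReadError` naming the offending row.  ``check_range=False``
    skips the range check — needed to round-trip unclipped synthetic panels.
    """
    df = pd.read_csv(path, dtype={"person": str}, na_values=["NA"],
                     keep_default_na=True)
    panel = EmaPanel(df, dict(registry or {}))
    _validate_panel_frame(panel.data, check_range=check_range)
    return panel


def write_panel(panel: EmaPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False, na_rep="")


def wide_to_long(df: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Convenience converter: wide columns ``variables`` -> tidy panel rows."""
    long = df.melt(id_vars=["person", "day", "slot"], value_vars=list(variables),
                   var_name="variable", value_name="value")
    return long[PANEL_COLUMNS]


# ---------------------------------------------------------------------------
# Trial logs


@dataclass
class TrialLog:
    """Trial-level Go/No-go records.

    Main blocks are 1–4 with up to 50 trials each; a training block (block 0)
    is permitted and flagged so scoring can drop it.  ``responded`` is boolean;
    ``rt_ms`` is a positive real or NaN (no response).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        df["person"] = df["person"].astype(str)
        for col in ("day", "block", "trial"):
            df[col] = df[col].astype(int)
        df["responded"] = df["responded"].astype(bool)
        df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
        bad_slot = ~df["slot"].isin(SLOTS)
        if bad_slot.any():
            raise EmaReadError(f"malformed slot label {df[bad_slot].iloc[0]['slot']!r} in trial log")
        bad_stim = ~df["stimulus"].isin(("go", "nogo"))
        if bad_stim.any():
            raise EmaReadError(
                f"unknown stimulus label {df[bad_stim].iloc[0]['stimulus']!r}")
        if (df["trial"] > 50).any():
            row = df[df["trial"] > 50].iloc[0]
            raise EmaReadError(
                f"trial index {row['trial']} > 50 (person={row['person']}, "
                f"day={row['day']}, slot={row['slot']}, block={row['block']})")
        if (df["block"] > 4).any() or (df["block"] < 0).any():
            raise EmaReadError("block index outside 0..4")
        df = df.sort_values(["person", "day", "slot", "block", "trial"],
                            kind="mergesort").reset_index(drop=True)
        self.data = df[TRIAL_COLUMNS]

    @property
    def has_training(self) -> bool:
        return bool((self.data["block"] == 0).any())

    def main_trials(self) -> pd.DataFrame:
        """Trials from the four main blocks (training block 0 dropped)."""
        return self.data[self.data["block"] >= 1]

    def occasions(self) -> pd.DataFrame:
        return self.data[["person", "day", "slot"]].drop_duplicates().reset_index(drop=True)


def read_trials(path: str | Path) -> TrialLog:
    df = pd.read_csv(path, dtype={"person": str}, na_values=["NA"])
    return TrialLog(df)


def write_trials(log: TrialLog, path: str | Path) -> None:
    log.data.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Network sets


@dataclass
class SymmetricNetwork:
    """Partial-correlation network from paired node-wise coefficients.

    ``pcor[j, k]`` is the signed-geometric-mean partial correlation; the two
    directional p-values are kept separately because edge selection applies an
    OR rule across them.  ``sign_conflict`` flags pairs whose two directional
    coefficients disagreed in sign (the partial correlation is then 0).
    """

    pcor: np.ndarray            # V x V, symmetric, NaN diagonal
    p_dir: np.ndarray           # V x V, p_dir[j, k] = p of coefficient k -> j
    adj_p_dir: np.ndarray | None = None
    sign_conflict: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sign_conflict is None:
            self.sign_conflict = np.zeros_like(self.pcor, dtype=bool)
        off = ~np.eye(self.pcor.shape[0], dtype=bool)
        vals = self.pcor[off]
        if np.any(np.abs(vals[np.isfinite(vals)]) > 1 + 1e-9):
            raise ValueError("partial correlations must lie in [-1, 1]")
        if not np.allclose(self.pcor[off], self.pcor.T[off], equal_nan=True):
            raise ValueError("partial-correlation matrix must be symmetric")


@dataclass
class TemporalNetwork:
    """Directed lag-1 network: ``beta[j, k]`` is the effect of node k at AM on
    node j at PM; ``slope_sd`` holds the random-slope SDs (between-person
    spread of each lagged effect)."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    slope_sd: np.ndarray
    adj_p: np.ndarray | None = None


@dataclass
class NetworkSet:
    nodes: list[str]
    temporal: TemporalNetwork
    contemporaneous: SymmetricNetwork
    between: SymmetricNetwork
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _arr(a: np.ndarray | None) -> list | None:
    return None if a is None else np.asarray(a).tolist()


def networks_to_dict(ns: NetworkSet) -> dict:
    return {
        "nodes": ns.nodes,
        "temporal": {
            "beta": _arr(ns.temporal.beta), "se": _arr(ns.temporal.se),
            "p": _arr(ns.temporal.p), "slope_sd": _arr(ns.temporal.slope_sd),
            "adj_p": _arr(ns.temporal.adj_p),
        },
        "contemporaneous": {
            "pcor": _arr(ns.contemporaneous.pcor),
            "p_dir": _arr(ns.contemporaneous.p_dir),
            "adj_p_dir": _arr(ns.contemporaneous.adj_p_dir),
            "sign_conflict": _arr(ns.contemporaneous.sign_conflict),
        },
        "between": {
            "pcor": _arr(ns.between.pcor), "p_dir": _arr(ns.between.p_dir),
            "adj_p_dir": _arr(ns.between.adj_p_dir),
            "sign_conflict": _arr(ns.between.sign_conflict),
        },
        "meta": ns.meta,
    }


def networks_from_dict(d: dict) -> NetworkSet:
    def arr(x):
        return None if x is None else np.array(x, dtype=float)

    t = d["temporal"]
    c = d["contemporaneous"]
    b = d["between"]
    return NetworkSet(
        nodes=list(d["nodes"]),
        temporal=TemporalNetwork(arr(t["beta"]), arr(t["se"]), arr(t["p"]),
                                 arr(t["slope_sd"]), arr(t.get("adj_p"))),
        contemporaneous=SymmetricNetwork(
            arr(c["pcor"]), arr(c["p_dir"]), arr(c.get("adj_p_dir")),
            None if c.get("sign_conflict") is None
            else np.array(c["sign_conflict"], dtype=bool)),
        between=SymmetricNetwork(
            arr(b["pcor"]), arr(b["p_dir"]), arr(b.get("adj_p_dir")),
            None if b.get("sign_conflict") is None
            else np.array(b["sign_conflict"], dtype=bool)),
        meta=dict(d.get("meta", {})),
    )


EDGE_LIST_COLUMNS = ["network", "source", "target", "weight", "raw_p", "adj_p",
                     "significant", "line_style"]


def write_networks(ns: NetworkSet, out_dir: str | Path,
                   decisions: Iterable | None = None) -> dict[str, Path]:
    """Write a NetworkSet as JSON (full matrices + metadata) plus a TSV edge
    list of the significant edges only, mirroring a display in which edges
    below the significance threshold are omitted.

    ``decisions`` are :class:`emanet.edges.EdgeDecision` records; if omitted
    they are computed with default settings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "networks.json"
    with open(json_path, "w") as fh:
        json.dump(networks_to_dict(ns), fh, indent=1)

    if decisions is None:
        from .edges import select_edges
        decisions = select_edges(ns)
    rows = [
        {"network": d.network, "source": d.source, "target": d.target,
         "weight": d.weight, "raw_p": d.raw_p, "adj_p": d.adj_p,
         "significant": d.significant,
         "line_style": "solid" if d.weight >= 0 else "dashed"}
        for d in decisions if d.significant
    ]
    edge_path = out_dir / "edges.tsv"
    pd.DataFrame(rows, columns=EDGE_LIST_COLUMNS).to_csv(edge_path, sep="\t", index=False)
    return {"json": json_path, "edges": edge_path}


def read_networks(json_path: str | Path) -> NetworkSet:
    with open(json_path) as fh:
        return networks_from_dict(json.load(fh))


def to_graphml(ns: NetworkSet, decisions: Iterable, path: str | Path) -> None:
    """Optional GraphML export of the significant edges (one graph per file,
    directed; undirected networks are written with both arcs collapsed)."""
    import networkx as nx

    g = nx.MultiDiGraph()
    g.add_nodes_from(ns.nodes)
    for d in decisions:
        if d.significant:
            g.add_edge(d.source, d.target, network=d.network,
                       weight=float(d.weight), adj_p=float(d.adj_p))
    nx.write_graphml(g, path)
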