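"""False-discovery-rate adjustment and edge selection.

All p-values are Benjamini-Hochberg adjusted before edges are displayed.
Temporal (directed) edges carry a single p-value; the two symmetric networks
carry one p-value per direction of the node-wise fits, and an edge is shown
under the "or" rule when either direction survives adjustment (an "and" rule
is available).  Adjustment pools are per network by default — the V^2
temporal p-values, and the 2*C(V,2) directional p-values of each symmetric
network — with a global pool across all three networks as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ema_data import NetworkSet
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class EdgeDecision:
    network: str               # temporal | contemporaneous | between
    source: str
    target: str
    weight: float
    raw_p: float               # single p (temporal) or min of the pair
    adj_p: float               # adjusted p backing the decision under `rule`
    significant: bool
    rule: str                  # single | or | and
    raw_p_pair: tuple[float, float] | None = None
    adj_p_pair: tuple[float, float] | None = None
    sign_conflict: bool = False


def _upper_pairs(V: int):
    for j in range(V):
        for k in range(j + 1, V):
            yield j, k


def select_edges(ns: NetworkSet, threshold: float = 0.05, rule: str = "or",
                 pooling: str = "per-network") -> list[EdgeDecision]:
    """Adjust all p-values and decide every edge of the three networks.

    Also fills the ``adj_p`` / ``adj_p_dir`` fields of ``ns`` in place so
    the adjusted values can be exported alongside the raw ones.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    if pooling not in ("per-network", "global"):
        raise ValueError("pooling must be 'per-network' or 'global'")

    V = ns.n_nodes
    off = ~np.eye(V, dtype=bool)
    p_t = ns.temporal.p.ravel()
    p_c = ns.contemporaneous.p_dir[off]
    p_b = ns.between.p_dir[off]

    if pooling == "global":
        pooled = np.concatenate([p_t, p_c, p_b])
        adj = bh_adjust(pooled)
        a_t = adj[:p_t.size]
        a_c = adj[p_t.size:p_t.size + p_c.size]
        a_b = adj[p_t.size + p_c.size:]
    else:
        a_t = bh_adjust(p_t)
        a_c = bh_adjust(p_c)
        a_b = bh_adjust(p_b)

    ns.temporal.adj_p = a_t.reshape(V, V)
    adj_c = np.full((V, V), np.nan)
    adj_c[off] = a_c
    ns.contemporaneous.adj_p_dir = adj_c
    adj_b = np.full((V, V), np.nan)
    adj_b[off] = a_b
    ns.between.adj_p_dir = adj_b

    decisions: list[EdgeDecision] = []
    for j in range(V):
        for k in range(V):
            adj = ns.temporal.adj_p[j, k]
            decisions.append(EdgeDecision(
                network="temporal", source=ns.nodes[k], target=ns.nodes[j],
                weight=float(ns.temporal.beta[j, k]),
                raw_p=float(ns.temporal.p[j, k]), adj_p=float(adj),
                significant=bool(adj < threshold), rule="single"))

    for name, net in (("contemporaneous", ns.contemporaneous),
                      ("between", ns.between)):
        for j, k in _upper_pairs(V):
            raw_pair = (float(net.p_dir[j, k]), float(net.p_dir[k, j]))
            adj_pair = (float(net.adj_p_dir[j, k]), float(net.adj_p_dir[k, j]))
            if rule == "or":
                backing = np.nanmin(adj_pair)
            else:
                backing = np.nanmax(adj_pair)
            sig = bool(np.isfinite(backing) and backing < threshold)
            decisions.append(EdgeDecision(
                network=name, source=ns.nodes[j], target=ns.nodes[k],
                weight=float(net.pcor[j, k]),
                raw_p=float(np.nanmin(raw_pair)), adj_p=float(backing),
                significant=sig, rule=rule, raw_p_pair=raw_pair,
                adj_p_pair=adj_pair,
                sign_conflict=bool(net.sign_conflict[j, k])))
    return decisions
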