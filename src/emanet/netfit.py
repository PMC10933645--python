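"""Two-step node-wise multilevel VAR estimator.

Step one fits, for each node j, a linear mixed model on the same-day AM→PM
lag rows::

    y[p,d,j] = nu_j + sum_{k != j} gamma[j,k] * m[p,k]
             + sum_k (beta[j,k] + u[p,j,k]) * c[p,d,k]
             + b[p,j] + eps[p,d,j]

where ``m`` are person means (between-person predictors), ``c`` are
person-mean-centered morning values (within-person predictors), ``b`` is a
random intercept and ``u`` are random slopes, mutually independent by
default.  The fixed lagged coefficients form the directed temporal network;
the person-mean coefficient pairs (gamma[j,k], gamma[k,j]) form the
between-person partial-correlation network via a signed geometric mean.

Step two regresses the conditional residuals of each node on the residuals
of all the other nodes (random intercept per person) and converts the
coefficient pairs to the contemporaneous partial-correlation network by the
same rule.

Estimation is restricted maximum likelihood through statsmodels MixedLM;
fixed-effect p-values are Wald z tests.  Non-convergence triggers a
deterministic fallback ladder: random slopes are dropped smallest-variance
first, then the model falls back to a random intercept only; a node that
fails the whole ladder is marked unestimable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .ema_data import NetworkSet, SymmetricNetwork, TemporalNetwork
from .preprocessing import LagPairSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitOptions:
    """Estimation options for the node-wise models.

    ``random_slopes=False`` keeps only the person random intercept;
    disabling both random terms reduces every fit to ordinary least squares
    (useful for oracle checks and for degenerate data).  ``correlated_slopes``
    swaps the default diagonal random-effects covariance for the full one.
    ``standardize`` rescales every variable by its grand SD before fitting.
    """

    random_intercept: bool = True
    random_slopes: bool = True
    correlated_slopes: bool = False
    standardize: bool = False
    reml: bool = True
    min_rows: int = 10
    min_persons: int = 5
    optimizers: tuple[str, ...] = ("powell", "cg", "lbfgs")


@dataclass
class NodeFit:
    """Result of one node's temporal mixed model."""

    node: str
    variables: list[str]
    intercept: float
    beta: pd.Series
    beta_se: pd.Series
    beta_p: pd.Series
    gamma: pd.Series
    gamma_se: pd.Series
    gamma_p: pd.Series
    slope_sd: pd.Series
    intercept_sd: float
    sigma: float
    resid: pd.Series                 # conditional residuals, index (person, day)
    n_rows: int
    n_persons: int
    converged: bool
    fallbacks: list[str] = field(default_factory=list)
    unestimable: bool = False


class UnestimableNode(RuntimeError):
    """Node model failed the whole convergence fallback ladder."""


def _sanitize(variables: list[str]) -> dict[str, str]:
    return {v: f"v{i}" for i, v in enumerate(variables)}


def _fit_ok(res) -> bool:
    if res is None:
        return False
    if not np.all(np.isfinite(res.fe_params)):
        return False
    bse = np.asarray(res.bse_fe if hasattr(res, "bse_fe") else res.bse)
    return bool(np.all(np.isfinite(bse)) and np.all(bse > 0))


def _try_mixed(formula: str, df: pd.DataFrame, re_formula: str | None,
               vc: dict[str, str] | None, options: FitOptions):
    """Fit with each optimizer in turn; return first acceptable result."""
    for meth in options.optimizers:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(formula, df, groups="person",
                                 re_formula=re_formula,
                                 vc_formula=vc if vc else None)
                res = md.fit(reml=options.reml, method=meth)
            if res.converged and _fit_ok(res):
                return res
        except (np.linalg.LinAlgError, ValueError):
            continue
    return None


def _mixed_regression(df: pd.DataFrame, outcome: str, fixed: list[str],
                      slope_vars: list[str], options: FitOptions):
    """Shared mixed/OLS fitting engine with the fallback ladder.

    Returns (result, kind, slope_sd: dict, intercept_sd, fallbacks).
    ``kind`` is "mixed" or "ols".
    """
    fallbacks: list[str] = []
    if not options.random_intercept and not options.random_slopes:
        X = sm.add_constant(df[fixed], has_constant="add")
        res = sm.OLS(df[outcome], X).fit()
        return res, "ols", {}, 0.0, fallbacks

    formula = f"{outcome} ~ {' + '.join(fixed)}" if fixed else f"{outcome} ~ 1"
    slopes = list(slope_vars) if options.random_slopes else []

    while True:
        if options.correlated_slopes and slopes:
            re_formula = "1 + " + " + ".join(slopes)
            vc = None
        else:
            re_formula = "1" if options.random_intercept else None
            vc = {f"sl_{s}": f"0 + {s}" for s in slopes}
        res = _try_mixed(formula, df, re_formula, vc, options)
        if res is not None:
            slope_sd = _extract_slope_sds(res, slopes, options)
            icpt_sd = _extract_intercept_sd(res, options)
            return res, "mixed", slope_sd, icpt_sd, fallbacks
        if slopes:
            dropped = _pick_slope_to_drop(formula, df, slopes, options)
            fallbacks.append(f"dropped random slope on {dropped}")
            logger.warning("fit fallback: dropping random slope on %s", dropped)
            slopes.remove(dropped)
        elif options.random_intercept:
            # intercept-only already failed: one last OLS attempt is not part
            # of the ladder; the node is unestimable
            raise UnestimableNode(f"node model for {outcome!r} failed the "
                                  "convergence fallback ladder")
        else:
            raise UnestimableNode(f"node model for {outcome!r} failed to fit")


def _pick_slope_to_drop(formula, df, slopes, options) -> str:
    """Deterministic choice: the slope with the smallest fitted variance in a
    quick (possibly unconverged) fit, falling back to the last listed."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, df, groups="person", re_formula="1",
                             vc_formula={f"sl_{s}": f"0 + {s}" for s in slopes})
            res = md.fit(reml=options.reml, method=options.optimizers[0],
                         maxiter=50)
        names = list(res.model.exog_vc.names)
        smallest = names[int(np.argmin(res.vcomp))]
        cand = smallest[len("sl_"):]
        return cand if cand in slopes else slopes[-1]
    except Exception:
        return slopes[-1]


def _extract_slope_sds(res, slopes: list[str], options: FitOptions) -> dict[str, float]:
    out: dict[str, float] = {}
    if not slopes:
        return out
    if options.correlated_slopes:
        names = list(res.cov_re.index)
        for s in slopes:
            out[s] = float(np.sqrt(max(res.cov_re.loc[s, s], 0.0)))
        return out
    names = list(res.model.exog_vc.names)
    for s in slopes:
        i = names.index(f"sl_{s}")
        out[s] = float(np.sqrt(max(res.vcomp[i], 0.0)))
    return out


def _extract_intercept_sd(res, options: FitOptions) -> float:
    if not options.random_intercept and not options.correlated_slopes:
        return 0.0
    try:
        return float(np.sqrt(max(res.cov_re.iloc[0, 0], 0.0)))
    except Exception:
        return 0.0


def _standardized(pairs: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    df = pairs.copy()
    for v in variables:
        sd = df[f"y_{v}"].std(ddof=1)
        mu = df[f"y_{v}"].mean()
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant variable {v!r}")
        df[f"y_{v}"] = (df[f"y_{v}"] - mu) / sd
        df[f"m_{v}"] = (df[f"m_{v}"] - mu) / sd
        df[f"c_{v}"] = df[f"c_{v}"] / sd
    return df


def fit_temporal_node(lags: LagPairSet, node: str,
                      options: FitOptions = FitOptions()) -> NodeFit:
    """Fit the step-one mixed model for one node."""
    if node not in lags.variables:
        raise ValueError(f"unknown node {node!r}")
    variables = lags.variables
    pairs = _standardized(lags.pairs, variables) if options.standardize else lags.pairs
    df = pairs.dropna(subset=[f"y_{node}"] + [f"c_{v}" for v in variables]
                      + [f"m_{v}" for v in variables]).copy()
    n_persons = df["person"].nunique()
    if len(df) < options.min_rows or n_persons < options.min_persons:
        raise ValueError(
            f"node {node!r}: {len(df)} usable lag rows across {n_persons} "
            f"persons; need >= {options.min_rows} rows and "
            f">= {options.min_persons} persons")

    names = _sanitize(variables)
    work = pd.DataFrame({"person": df["person"].values, "y": df[f"y_{node}"].values})
    fixed: list[str] = []
    for v in variables:
        work[f"c_{names[v]}"] = df[f"c_{v}"].values
        fixed.append(f"c_{names[v]}")
    for v in variables:
        if v != node:
            work[f"m_{names[v]}"] = df[f"m_{v}"].values
            fixed.append(f"m_{names[v]}")

    slope_cols = [f"c_{names[v]}" for v in variables]
    res, kind, slope_sd_raw, icpt_sd, fallbacks = _mixed_regression(
        work, "y", fixed, slope_cols, options)

    params = res.fe_params if kind == "mixed" else res.params
    bse = res.bse_fe if kind == "mixed" else res.bse
    pvals = res.pvalues[params.index] if kind == "mixed" else res.pvalues

    beta = pd.Series({v: params[f"c_{names[v]}"] for v in variables})
    beta_se = pd.Series({v: bse[f"c_{names[v]}"] for v in variables})
    beta_p = pd.Series({v: pvals[f"c_{names[v]}"] for v in variables})
    gamma = pd.Series({v: (params[f"m_{names[v]}"] if v != node else np.nan)
                       for v in variables})
    gamma_se = pd.Series({v: (bse[f"m_{names[v]}"] if v != node else np.nan)
                          for v in variables})
    gamma_p = pd.Series({v: (pvals[f"m_{names[v]}"] if v != node else np.nan)
                         for v in variables})
    slope_sd = pd.Series({v: slope_sd_raw.get(f"c_{names[v]}", 0.0)
                          for v in variables})

    if kind == "mixed":
        fitted = np.asarray(res.fittedvalues)   # includes predicted random effects
        sigma = float(np.sqrt(res.scale))
    else:
        fitted = np.asarray(res.fittedvalues)
        sigma = float(np.sqrt(res.mse_resid))
    resid = pd.Series(work["y"].values - fitted,
                      index=pd.MultiIndex.from_arrays(
                          [df["person"].values, df["day"].values],
                          names=["person", "day"]))
    return NodeFit(node=node, variables=list(variables),
                   intercept=float(params.get("Intercept", params.get("const", 0.0))),
                   beta=beta, beta_se=beta_se, beta_p=beta_p,
                   gamma=gamma, gamma_se=gamma_se, gamma_p=gamma_p,
                   slope_sd=slope_sd, intercept_sd=icpt_sd, sigma=sigma,
                   resid=resid, n_rows=len(df), n_persons=int(n_persons),
                   converged=True, fallbacks=fallbacks)


def fit_all_nodes(lags: LagPairSet,
                  options: FitOptions = FitOptions()) -> list[NodeFit]:
    fits = []
    for node in lags.variables:
        try:
            fits.append(fit_temporal_node(lags, node, options))
        except UnestimableNode as exc:
            logger.error("node %s unestimable: %s", node, exc)
            raise
    return fits


# ---------------------------------------------------------------------------
# Network assembly


def _signed_geomean(a: float, b: float) -> tuple[float, bool]:
    """Signed geometric mean of a coefficient pair; (0, conflict) when the
    signs disagree, since a conflicted product has no coherent sign."""
    if not (np.isfinite(a) and np.isfinite(b)):
        return np.nan, False
    if a == 0.0 or b == 0.0:
        return 0.0, False
    if np.sign(a) != np.sign(b):
        return 0.0, True
    return float(np.sign(a) * np.sqrt(a * b)), False


def _pair_matrix(coef: np.ndarray, pvals: np.ndarray) -> SymmetricNetwork:
    V = coef.shape[0]
    pcor = np.full((V, V), np.nan)
    conflict = np.zeros((V, V), dtype=bool)
    for j in range(V):
        for k in range(j + 1, V):
            val, con = _signed_geomean(coef[j, k], coef[k, j])
            val = float(np.clip(val, -1.0, 1.0)) if np.isfinite(val) else val
            pcor[j, k] = pcor[k, j] = val
            conflict[j, k] = conflict[k, j] = con
    return SymmetricNetwork(pcor=pcor, p_dir=pvals, sign_conflict=conflict)


def assemble_temporal_network(fits: list[NodeFit]) -> TemporalNetwork:
    """Stack node fits into the directed matrix: entry [j, k] = effect of
    node k in the morning on node j in the afternoon."""
    nodes = fits[0].variables
    if sorted(f.node for f in fits) != sorted(nodes):
        missing = set(nodes) - {f.node for f in fits}
        raise ValueError(f"missing node fits: {sorted(missing)}")
    by_node = {f.node: f for f in fits}
    V = len(nodes)
    beta = np.zeros((V, V))
    se = np.zeros((V, V))
    p = np.ones((V, V))
    ssd = np.zeros((V, V))
    for j, nj in enumerate(nodes):
        f = by_node[nj]
        for k, nk in enumerate(nodes):
            beta[j, k] = f.beta[nk]
            se[j, k] = f.beta_se[nk]
            p[j, k] = f.beta_p[nk]
            ssd[j, k] = f.slope_sd[nk]
    return TemporalNetwork(beta=beta, se=se, p=p, slope_sd=ssd)


def between_network(fits: list[NodeFit]) -> SymmetricNetwork:
    """Between-person partial correlations from the person-mean coefficient
    pairs (gamma[j,k], gamma[k,j])."""
    nodes = fits[0].variables
    by_node = {f.node: f for f in fits}
    V = len(nodes)
    coef = np.full((V, V), np.nan)
    pv = np.full((V, V), np.nan)
    for j, nj in enumerate(nodes):
        for k, nk in enumerate(nodes):
            if j == k:
                continue
            coef[j, k] = by_node[nj].gamma[nk]
            pv[j, k] = by_node[nj].gamma_p[nk]
    return _pair_matrix(coef, pv)


def contemporaneous_network(fits: list[NodeFit],
                            options: FitOptions = FitOptions()) -> SymmetricNetwork:
    """Step two: node-wise mixed regressions among the step-one residuals.

    Residual vectors are aligned on the intersection of the (person, day)
    rows used by all node fits; each node's residual is regressed on the
    others with a person random intercept (no random slopes), and coefficient
    pairs become partial correlations by the signed geometric mean.
    """
    nodes = fits[0].variables
    by_node = {f.node: f for f in fits}
    res_df = pd.DataFrame({f"r_{n}": by_node[n].resid for n in nodes}).dropna()
    if res_df.empty:
        raise ValueError("residual row sets of the node fits do not intersect")
    res_df = res_df.reset_index()

    names = _sanitize(nodes)
    work = pd.DataFrame({"person": res_df["person"].values})
    for n in nodes:
        work[f"r_{names[n]}"] = res_df[f"r_{n}"].values

    step2 = replace(options, random_slopes=False)
    V = len(nodes)
    coef = np.full((V, V), np.nan)
    pv = np.full((V, V), np.nan)
    for j, nj in enumerate(nodes):
        fixed = [f"r_{names[nk]}" for nk in nodes if nk != nj]
        res, kind, _, _, _ = _mixed_regression(work, f"r_{names[nj]}", fixed,
                                               [], step2)
        params = res.fe_params if kind == "mixed" else res.params
        pvals = res.pvalues[params.index] if kind == "mixed" else res.pvalues
        for k, nk in enumerate(nodes):
            if nk == nj:
                continue
            coef[j, k] = params[f"r_{names[nk]}"]
            pv[j, k] = pvals[f"r_{names[nk]}"]
    return _pair_matrix(coef, pv)


def fit_networks(lags: LagPairSet,
                 options: FitOptions = FitOptions()) -> NetworkSet:
    """Run the full two-step estimator and assemble the three networks."""
    fits = fit_all_nodes(lags, options)
    temporal = assemble_temporal_network(fits)
    between = between_network(fits)
    contemp = contemporaneous_network(fits, options)
    meta = {
        "n_persons": int(lags.pairs["person"].nunique()),
        "n_lag_rows": int(len(lags.pairs)),
        "options": {
            "random_intercept": options.random_intercept,
            "random_slopes": options.random_slopes,
            "correlated_slopes": options.correlated_slopes,
            "standardize": options.standardize,
            "reml": options.reml,
        },
        "fallbacks": {f.node: f.fallbacks for f in fits if f.fallbacks},
    }
    return NetworkSet(nodes=list(lags.variables), temporal=temporal,
                      contemporaneous=contemp, between=between, meta=meta)
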