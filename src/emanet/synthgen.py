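"""Synthetic twice-daily EMA studies with known ground truth.

The generative model mirrors the estimator's assumptions so that parameter
recovery is a fair test of the implementation:

* person means ``m_p ~ MVN(mu, Sigma_B)`` — the between-person structure is
  induced by a target partial-correlation matrix and SD vector;
* person-specific lagged-coefficient matrices ``B_p = B + Delta_p`` with
  independent ``N(0, T[j,k]^2)`` entries (random slopes);
* each day, a fresh morning deviation ``dAM ~ MVN(0, Sigma_AM)`` (no
  overnight carryover, matching the same-day AM→PM design), and an afternoon
  deviation ``dPM = B_p dAM + eps`` with ``eps ~ MVN(0, Sigma_C)``;
* observed value = person mean + deviation, NOT clipped to [0, 100] by
  default (clipping would bias linear-model recovery; an option exists for
  realism demonstrations);
* each occasion is observed with a per-modality compliance probability
  (the whole self-report survey, or the task, is missed as a block).

Item-level composites and trial-level Go/No-go logs are layered on top so
the scoring and reliability code paths can be exercised end to end.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .ema_data import EmaPanel, TrialLog, wide_to_long
from .gonogo import RESPONSE_INHIBITION
from .preprocessing import CompositeSpec

SELF_REPORT = "self_report"
TASK = "task"


def build_covariance(partial_corr: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Covariance matrix whose partial correlations and SDs are as given.

    The precision matrix is assembled as ``K[j,j] = 1``, ``K[j,k] =
    -rho[j,k]`` (zero-diagonal convention for ``rho``), inverted, and
    rescaled to the target SDs.  Raises if ``K`` is not positive definite,
    naming the smallest eigenvalue.
    """
    rho = np.asarray(partial_corr, dtype=float)
    sds = np.asarray(sds, dtype=float)
    off = ~np.eye(rho.shape[0], dtype=bool)
    if np.any(np.abs(rho[off]) >= 1):
        raise ValueError("partial correlations must have magnitude < 1")
    K = np.eye(rho.shape[0]) - np.where(off, rho, 0.0)
    ev = np.linalg.eigvalsh(K)
    if ev.min() <= 0:
        raise ValueError(f"precision matrix not positive definite "
                         f"(smallest eigenvalue {ev.min():.3g})")
    cov = np.linalg.inv(K)
    d = sds / np.sqrt(np.diag(cov))
    return cov * np.outer(d, d)


def partial_corr_from_cov(cov: np.ndarray) -> np.ndarray:
    """Partial correlations of a covariance matrix (zero diagonal)."""
    K = np.linalg.inv(cov)
    d = np.sqrt(np.diag(K))
    rho = -K / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho


@dataclass
class TrueModel:
    """Ground truth of a synthetic study; every quantity the estimator is
    later asked to recover lives here."""

    nodes: list[str]
    mu: np.ndarray                     # grand means, 0-100 scale
    sigma_b: np.ndarray                # between-person covariance of means
    B: np.ndarray                      # temporal matrix, [target j, source k]
    T: np.ndarray                      # random-slope SDs, same layout
    sigma_c: np.ndarray                # PM-innovation covariance
    sigma_am: np.ndarray               # AM-deviation covariance
    compliance: dict[str, float] = field(
        default_factory=lambda: {SELF_REPORT: 1.0, TASK: 1.0})
    n_persons: int = 62
    n_days: int = 9
    modality: dict[str, str] | None = None
    clip: bool = False
    overnight_carryover: float = 0.0   # optional misspecification knob

    def __post_init__(self) -> None:
        V = len(self.nodes)
        for name in ("sigma_b", "sigma_c", "sigma_am"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (V, V):
                raise ValueError(f"{name} must be {V}x{V}")
            if np.linalg.eigvalsh(mat).min() <= 0:
                raise ValueError(f"{name} is not positive definite")
            setattr(self, name, mat)
        self.mu = np.asarray(self.mu, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if np.any(self.T < 0):
            raise ValueError("slope SDs must be non-negative")
        for mod, p in self.compliance.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"compliance[{mod}] must lie in (0, 1]")
        rad = np.abs(np.linalg.eigvals(self.B)).max()
        if rad >= 1:
            import warnings
            warnings.warn(f"temporal matrix spectral radius {rad:.3f} >= 1")
        if self.modality is None:
            self.modality = {n: (TASK if n == RESPONSE_INHIBITION else SELF_REPORT)
                             for n in self.nodes}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_partials(cls, nodes, mu, between_partial, between_sds, B, T,
                      contemporaneous_partial, within_sds, sigma_am=None,
                      **kwargs) -> "TrueModel":
        sigma_b = build_covariance(between_partial, between_sds)
        sigma_c = build_covariance(contemporaneous_partial, within_sds)
        return cls(nodes=list(nodes), mu=np.asarray(mu, dtype=float),
                   sigma_b=sigma_b, B=np.asarray(B, dtype=float),
                   T=np.asarray(T, dtype=float), sigma_c=sigma_c,
                   sigma_am=sigma_c.copy() if sigma_am is None else sigma_am,
                   **kwargs)

    @classmethod
    def study_preset(cls, **overrides) -> "TrueModel":
        """The default study conditions: the published four-node networks as
        ground truth at 62 persons x 9 weekdays x 2 slots."""
        ref = importlib.resources.files("emanet") / "presets" / "study_preset.yaml"
        cfg = yaml.safe_load(ref.read_text())
        sds = np.asarray(cfg["total_sds"], dtype=float)
        tm = cls.from_partials(
            nodes=cfg["nodes"], mu=cfg["grand_means"],
            between_partial=np.asarray(cfg["between_partial"], dtype=float),
            between_sds=cfg["between_sd_fraction"] * sds,
            B=cfg["temporal"], T=cfg["slope_sd"],
            contemporaneous_partial=np.asarray(cfg["contemporaneous_partial"],
                                               dtype=float),
            within_sds=cfg["within_sd_fraction"] * sds,
            compliance=dict(cfg["compliance"]),
            n_persons=int(cfg["n_persons"]), n_days=int(cfg["n_days"]))
        return replace(tm, **overrides) if overrides else tm

    @classmethod
    def null_preset(cls, **overrides) -> "TrueModel":
        """All network structure zeroed: no temporal effects, no random
        slopes, independent innovations and independent person means.  Used
        for type-I-error / false-edge controls at study scale."""
        tm = cls.study_preset()
        V = len(tm.nodes)
        null = replace(
            tm,
            B=np.zeros((V, V)), T=np.zeros((V, V)),
            sigma_b=np.diag(np.diag(tm.sigma_b)),
            sigma_c=np.diag(np.diag(tm.sigma_c)),
            sigma_am=np.diag(np.diag(tm.sigma_am)))
        return replace(null, **overrides) if overrides else null

    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes, "mu": self.mu.tolist(),
            "sigma_b": self.sigma_b.tolist(), "B": self.B.tolist(),
            "T": self.T.tolist(), "sigma_c": self.sigma_c.tolist(),
            "sigma_am": self.sigma_am.tolist(),
            "between_partial": partial_corr_from_cov(self.sigma_b).tolist(),
            "contemporaneous_partial": partial_corr_from_cov(self.sigma_c).tolist(),
            "compliance": self.compliance, "n_persons": self.n_persons,
            "n_days": self.n_days,
        }


def simulate_panel(tm: TrueModel, seed: int | np.random.Generator = 0) -> EmaPanel:
    """Draw one study panel from the ground-truth model.

    Identical seed and model give a bit-identical panel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P, D, V = tm.n_persons, tm.n_days, len(tm.nodes)

    Lb = np.linalg.cholesky(tm.sigma_b)
    Lam = np.linalg.cholesky(tm.sigma_am)
    Lc = np.linalg.cholesky(tm.sigma_c)

    m = tm.mu + rng.standard_normal((P, V)) @ Lb.T
    Bp = tm.B[None, :, :] + rng.standard_normal((P, V, V)) * tm.T[None, :, :]
    d_am = rng.standard_normal((P, D, V)) @ Lam.T
    if tm.overnight_carryover:
        for d in range(1, D):
            d_am[:, d] += tm.overnight_carryover * d_am[:, d - 1]
    eps = rng.standard_normal((P, D, V)) @ Lc.T
    d_pm = np.einsum("pjk,pdk->pdj", Bp, d_am) + eps

    am = m[:, None, :] + d_am
    pm = m[:, None, :] + d_pm
    if tm.clip:
        am = np.clip(am, 0.0, 100.0)
        pm = np.clip(pm, 0.0, 100.0)

    # per-occasion per-modality observation indicators
    obs = {mod: rng.random((P, D, 2)) < p for mod, p in tm.compliance.items()}

    persons = np.array([f"p{i + 1:03d}" for i in range(P)])
    frames = []
    for s, (slot, values) in enumerate((("AM", am), ("PM", pm))):
        for k, node in enumerate(tm.nodes):
            keep = obs[tm.modality[node]][:, :, s]
            pi, di = np.nonzero(keep)
            frames.append(pd.DataFrame({
                "person": persons[pi], "day": di + 1, "slot": slot,
                "variable": node, "value": values[pi, di, k]}))
    data = pd.concat(frames, ignore_index=True)
    registry = {n: ("task-score" if tm.modality[n] == TASK else "composite")
                for n in tm.nodes}
    return EmaPanel(data, registry)


def implied_alpha(k: int, composite_var: float, item_sd: float) -> float:
    """Closed-form Cronbach's alpha of k parallel items built as composite +
    independent N(0, item_sd^2) noise: alpha = k*lam / (1 + (k-1)*lam) with
    lam = var / (var + item_sd^2)."""
    lam = composite_var / (composite_var + item_sd ** 2)
    return k * lam / (1.0 + (k - 1) * lam)


def simulate_items(panel: EmaPanel, specs: list[CompositeSpec],
                   item_sd: float = 10.0,
                   seed: int | np.random.Generator = 0) -> EmaPanel:
    """Expand composite values into noisy parallel items.

    item = composite + N(0, item_sd^2); reverse-coded items are stored
    flipped (100 - value) so that scoring flips them back.
    """
    if item_sd < 0:
        raise ValueError("item noise SD must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = [panel.data]
    registry = dict(panel.registry)
    for spec in specs:
        base = panel.data[panel.data["variable"] == spec.name]
        if base.empty:
            raise ValueError(f"composite {spec.name!r} not present in panel")
        for item in spec.items:
            vals = base["value"].to_numpy(dtype=float) + \
                rng.normal(0.0, item_sd, size=len(base))
            if item in spec.reverse:
                vals = 100.0 - vals
            frames.append(pd.DataFrame({
                "person": base["person"].values, "day": base["day"].values,
                "slot": base["slot"].values, "variable": item, "value": vals}))
            registry[item] = "item"
    return EmaPanel(pd.concat(frames, ignore_index=True), registry)


N_BLOCKS, TRIALS_PER_BLOCK, NOGO_PER_BLOCK = 4, 50, 10


def simulate_trials(panel: EmaPanel, seed: int | np.random.Generator = 0,
                    go_response_prob: float = 0.95) -> TrialLog:
    """Generate trial-level Go/No-go logs from panel response-inhibition
    values: 4 blocks x 50 trials, 10 no-go per block at random positions,
    withhold probability = value / 100, lognormal RTs as nuisance."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = panel.observed()
    sub = sub[sub["variable"] == RESPONSE_INHIBITION]
    if ((sub["value"] < 0) | (sub["value"] > 100)).any():
        raise ValueError("response-inhibition values must lie in [0, 100] "
                         "to define a withhold probability")
    rows = []
    for _, occ in sub.iterrows():
        p_withhold = occ["value"] / 100.0
        for block in range(1, N_BLOCKS + 1):
            nogo_pos = rng.choice(TRIALS_PER_BLOCK, size=NOGO_PER_BLOCK,
                                  replace=False)
            is_nogo = np.zeros(TRIALS_PER_BLOCK, dtype=bool)
            is_nogo[nogo_pos] = True
            responded = np.where(
                is_nogo, rng.random(TRIALS_PER_BLOCK) >= p_withhold,
                rng.random(TRIALS_PER_BLOCK) < go_response_prob)
            rts = np.where(responded,
                           rng.lognormal(np.log(450.0), 0.2, TRIALS_PER_BLOCK),
                           np.nan)
            for t in range(TRIALS_PER_BLOCK):
                rows.append((occ["person"], int(occ["day"]), occ["slot"],
                             block, t + 1, "nogo" if is_nogo[t] else "go",
                             bool(responded[t]),
                             round(rts[t], 1) if responded[t] else np.nan))
    df = pd.DataFrame(rows, columns=["person", "day", "slot", "block", "trial",
                                     "stimulus", "responded", "rt_ms"])
    return TrialLog(df)
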