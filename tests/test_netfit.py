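"""Node-wise multilevel VAR estimator: oracle equivalence and recovery."""

import numpy as np
import pandas as pd
import pytest

from emanet import (FitOptions, TrueModel, assemble_temporal_network,
                    between_network, build_lag_pairs, contemporaneous_network,
                    fit_all_nodes, fit_networks, fit_temporal_node,
                    partial_corr_from_cov, simulate_panel)
from emanet.netfit import NodeFit, _signed_geomean

OLS_OPTIONS = FitOptions(random_intercept=False, random_slopes=False)


def _no_random_model(n_persons=80, n_days=8, seed=0):
    tm = TrueModel.study_preset(
        n_persons=n_persons, n_days=n_days,
        compliance={"self_report": 1.0, "task": 1.0})
    V = len(tm.nodes)
    tm = TrueModel(nodes=tm.nodes, mu=tm.mu, sigma_b=tm.sigma_b, B=tm.B,
                   T=np.zeros((V, V)), sigma_c=tm.sigma_c,
                   sigma_am=tm.sigma_am, compliance=tm.compliance,
                   n_persons=n_persons, n_days=n_days)
    return tm, simulate_panel(tm, seed)


class TestOlsEquivalence:
    def test_fixed_effects_match_least_squares_oracle(self):
        """With random effects disabled and no missingness, node estimates
        must equal closed-form least squares on the same design."""
        tm, panel = _no_random_model()
        lags = build_lag_pairs(panel, tm.nodes)
        for node in tm.nodes:
            fit = fit_temporal_node(lags, node, OLS_OPTIONS)
            df = lags.complete_rows(node)
            cols = ([f"c_{v}" for v in tm.nodes]
                    + [f"m_{v}" for v in tm.nodes if v != node])
            X = np.column_stack([np.ones(len(df))] + [df[c] for c in cols])
            coef, *_ = np.linalg.lstsq(X, df[f"y_{node}"], rcond=None)
            for i, v in enumerate(tm.nodes):
                assert fit.beta[v] == pytest.approx(coef[1 + i], abs=1e-6)

    def test_scale_equivariance_and_pcor_invariance(self):
        """Multiplying one variable by a constant rescales its beta row and
        column as linear-model theory dictates and leaves all partial
        correlations unchanged."""
        tm, panel = _no_random_model(n_persons=60, n_days=6, seed=3)
        scale, var = 2.5, "anger"
        scaled_data = panel.data.copy()
        mask = scaled_data["variable"] == var
        scaled_data.loc[mask, "value"] *= scale
        from emanet import EmaPanel
        panel2 = EmaPanel(scaled_data, panel.registry)

        ns1 = fit_networks(build_lag_pairs(panel, tm.nodes), OLS_OPTIONS)
        ns2 = fit_networks(build_lag_pairs(panel2, tm.nodes), OLS_OPTIONS)
        j = tm.nodes.index(var)
        expect = ns1.temporal.beta.copy()
        expect[j, :] *= scale      # outcome scaled up
        expect[:, j] /= scale      # predictor scaled up
        expect[j, j] = ns1.temporal.beta[j, j]
        np.testing.assert_allclose(ns2.temporal.beta, expect, atol=1e-8)
        np.testing.assert_allclose(ns2.contemporaneous.pcor,
                                   ns1.contemporaneous.pcor,
                                   atol=1e-8, equal_nan=True)
        np.testing.assert_allclose(ns2.between.pcor, ns1.between.pcor,
                                   atol=1e-8, equal_nan=True)


class TestPrecisionOracles:
    def test_contemporaneous_matches_inversion_oracle(self):
        """Residuals drawn from a known covariance: node-wise estimates must
        match the precision-matrix partial correlations."""
        rng = np.random.default_rng(12)
        nodes = ["w", "x", "y", "z"]
        rho = np.zeros((4, 4))
        rho[0, 1] = rho[1, 0] = 0.3
        rho[2, 3] = rho[3, 2] = -0.25
        from emanet import build_covariance
        cov = build_covariance(rho, np.array([1.0, 1.2, 0.9, 1.1]))
        n = 10_000
        data = rng.multivariate_normal(np.zeros(4), cov, size=n)
        idx = pd.MultiIndex.from_arrays(
            [np.repeat([f"p{i}" for i in range(500)], n // 500),
             np.tile(np.arange(n // 500), 500)], names=["person", "day"])
        fits = [
            NodeFit(node=nodes[k], variables=nodes, intercept=0.0,
                    beta=pd.Series(dtype=float), beta_se=pd.Series(dtype=float),
                    beta_p=pd.Series(dtype=float), gamma=pd.Series(dtype=float),
                    gamma_se=pd.Series(dtype=float), gamma_p=pd.Series(dtype=float),
                    slope_sd=pd.Series(dtype=float), intercept_sd=0.0, sigma=1.0,
                    resid=pd.Series(data[:, k], index=idx), n_rows=n,
                    n_persons=500, converged=True)
            for k in range(4)]
        net = contemporaneous_network(fits)
        oracle = partial_corr_from_cov(np.cov(data.T, ddof=1))
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs(net.pcor[off] - oracle[off])) < 0.02

    def test_between_matches_inversion_oracle(self):
        """Person-mean coefficients from many persons must reproduce the
        partial correlations of the sample covariance of person means."""
        tm, panel = _no_random_model(n_persons=1500, n_days=4, seed=8)
        lags = build_lag_pairs(panel, tm.nodes)
        fits = fit_all_nodes(lags, OLS_OPTIONS)
        net = between_network(fits)
        oracle = partial_corr_from_cov(np.cov(lags.person_means.T, ddof=1))
        off = ~np.eye(4, dtype=bool)
        # sign-conflicted near-zero entries are set to 0; compare where defined
        keep = off & ~net.sign_conflict
        assert np.max(np.abs(net.pcor[keep] - oracle[keep])) < 0.05
        # the three true nonzero partials must agree closely
        for j, k, truth in [(0, 2, -0.491), (1, 2, -0.150), (2, 3, 0.291)]:
            assert net.pcor[j, k] == pytest.approx(oracle[j, k], abs=0.02)


class TestSignRule:
    @pytest.mark.parametrize("a,b,expected,conflict", [
        (0.2, 0.3, np.sqrt(0.06), False),
        (-0.2, -0.3, -np.sqrt(0.06), False),
        (0.2, -0.3, 0.0, True),
        (0.0, 0.3, 0.0, False),
    ])
    def test_signed_geometric_mean(self, a, b, expected, conflict):
        val, con = _signed_geomean(a, b)
        assert val == pytest.approx(expected)
        assert con is conflict


class TestMixedModelRecovery:
    def test_single_node_autoregression_recovery(self):
        """One-node model with a true self-loop of 0.5 and a random slope:
        the fixed effect is recovered and the network is the 1x1 matrix."""
        tm = TrueModel(
            nodes=["x"], mu=np.array([50.0]), sigma_b=np.array([[64.0]]),
            B=np.array([[0.5]]), T=np.array([[0.1]]),
            sigma_c=np.array([[36.0]]), sigma_am=np.array([[36.0]]),
            compliance={"self_report": 1.0, "task": 1.0},
            n_persons=300, n_days=20)
        panel = simulate_panel(tm, seed=21)
        lags = build_lag_pairs(panel, ["x"])
        fit = fit_temporal_node(lags, "x")
        assert fit.beta["x"] == pytest.approx(0.5, abs=0.05)
        assert fit.slope_sd["x"] == pytest.approx(0.1, abs=0.06)
        net = assemble_temporal_network([fit])
        assert net.beta.shape == (1, 1)
        assert net.beta[0, 0] == fit.beta["x"]

    def test_conditional_residuals_align_with_rows(self):
        tm, panel = _no_random_model(n_persons=40, n_days=6, seed=5)
        lags = build_lag_pairs(panel, tm.nodes)
        fit = fit_temporal_node(lags, "anger")
        assert len(fit.resid) == fit.n_rows
        assert fit.resid.index.names == ["person", "day"]

    def test_minimum_data_enforced(self):
        tm, panel = _no_random_model(n_persons=3, n_days=2, seed=6)
        lags = build_lag_pairs(panel, tm.nodes)
        with pytest.raises(ValueError, match="persons"):
            fit_temporal_node(lags, "anger")

    def test_missing_node_fit_rejected(self):
        tm, panel = _no_random_model(n_persons=40, n_days=6, seed=5)
        lags = build_lag_pairs(panel, tm.nodes)
        fit = fit_temporal_node(lags, "anger", OLS_OPTIONS)
        with pytest.raises(ValueError, match="missing node fits"):
            assemble_temporal_network([fit])
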