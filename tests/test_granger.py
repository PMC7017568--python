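"""Granger causality: embedding, linear/nonlinear pair tests, conditioning."""

import numpy as np
import pytest

from spikegc import (
    GrangerNetworkIdentifier,
    conditional_gc,
    embed,
    linear_gc_pair,
    nonlinear_gc_pair,
    significance_test,
)
from spikegc.granger import DegenerateChannelError

from conftest import var_chain


class TestEmbed:
    def test_definition_example(self):
        e = embed([1, 2, 3, 4, 5], m=2, tau=0)
        assert e.targets.tolist() == [3, 4, 5]
        assert e.lags.tolist() == [[2, 1], [3, 2], [4, 3]]
        assert e.n_eff == 3

    def test_pure_delay_shifts_targets(self):
        e = embed([1, 2, 3, 4, 5], m=2, tau=1)
        assert e.targets.tolist() == [4, 5]
        assert e.lags.tolist() == [[2, 1], [3, 2]]

    def test_constant_series_gives_identical_rows(self):
        e = embed(np.ones(20), m=3)
        assert np.ptp(e.lags) == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            embed([1, 2, 3], m=3, tau=1)


class TestSignificanceTest:
    def test_no_improvement_gives_p_one(self):
        assert significance_test(10.0, 10.0, 100, 5, 11) == pytest.approx(1.0)

    def test_perfect_fit_warns_and_gives_zero(self):
        with pytest.warns(RuntimeWarning, match="perfect fit"):
            assert significance_test(0.0, 1.0, 100, 5, 11) == 0.0

    def test_large_improvement_is_significant(self):
        assert significance_test(1.0, 10.0, 1000, 5, 11) < 1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            significance_test(-1.0, 1.0, 100, 5, 11)
        with pytest.raises(ValueError):
            significance_test(1.0, 1.0, 10, 5, 11)


class TestLinearPair:
    def test_type_one_error_near_nominal(self):
        # independent white noise: false-detection rate ~ alpha = 0.01
        hits = 0
        n_rep = 500
        for s in range(n_rep):
            x, y = var_chain(2000, coupling=0.0, seed=s)
            ryx, rxy = linear_gc_pair(x, y, m=5, alpha=0.01)
            hits += int(ryx.decision)
        assert hits / n_rep <= 0.02  # >= 98% correct non-detections

    def test_power_on_var_coupling(self):
        det_causal, det_anticausal = 0, 0
        n_rep = 100
        for s in range(n_rep):
            x, y = var_chain(2000, coupling=0.8, seed=1000 + s)
            ryx, rxy = linear_gc_pair(x, y, m=5, alpha=0.01)
            det_causal += int(ryx.decision)
            det_anticausal += int(rxy.decision)
        assert det_causal >= 0.95 * n_rep
        assert det_anticausal <= 0.05 * n_rep

    def test_matches_normal_equations_oracle(self):
        # brute-force VAR fit via explicit normal equations
        x, y = var_chain(1500, coupling=0.5, seed=3)
        m = 4
        ryx, _ = linear_gc_pair(x, y, m=m, standardize=False)
        xs, ys = x, y
        n_eff = len(xs) - m
        tgt = xs[m:]
        lx = np.column_stack([xs[m - 1 - k : len(xs) - 1 - k] for k in range(m)])
        ly = np.column_stack([ys[m - 1 - k : len(ys) - 1 - k] for k in range(m)])
        d_full = np.column_stack([np.ones(n_eff), lx, ly])
        d_red = np.column_stack([np.ones(n_eff), lx])
        rss = []
        for d in (d_full, d_red):
            beta = np.linalg.solve(d.T @ d, d.T @ tgt)
            rss.append(np.sum((tgt - d @ beta) ** 2))
        f_oracle = np.log(rss[1] / rss[0])
        assert ryx.f == pytest.approx(f_oracle, rel=1e-8)

    def test_cross_covariance_reported(self):
        x, y = var_chain(1000, coupling=0.5, seed=4)
        ryx, rxy = linear_gc_pair(x, y)
        assert ryx.cross_cov is not None
        assert ryx.cross_cov == pytest.approx(rxy.cross_cov)

    def test_zero_variance_channel_rejected(self):
        with pytest.raises(DegenerateChannelError):
            linear_gc_pair(np.zeros(100), np.random.default_rng(0).standard_normal(100))


class TestNonlinearPair:
    def test_f_nonnegative_under_shared_basis_nesting(self, rng):
        # structural nesting: reduced model reuses the full model's bases
        for s in range(200):
            x = rng.standard_normal(150)
            y = rng.standard_normal(150)
            ryx, rxy = nonlinear_gc_pair(x, y, m=2, n_centers=4, seed=s)
            assert ryx.f >= 0.0
            assert rxy.f >= 0.0
            assert ryx.sigma_reduced >= ryx.sigma_full - 1e-12

    def test_detects_nonlinear_coupling_with_high_power(self):
        n_rep, det_ngc, det_lin = 60, 0, 0
        rng = np.random.default_rng(9)
        for s in range(n_rep):
            y = rng.standard_normal(1200)
            x = np.empty(1200)
            x[0] = rng.standard_normal()
            x[1:] = np.tanh(2.0 * y[:-1]) + 0.3 * rng.standard_normal(1199)
            r_n, _ = nonlinear_gc_pair(x, y, m=3, n_centers=8, seed=s, alpha=0.01)
            r_l, _ = linear_gc_pair(x, y, m=3, alpha=0.01)
            det_ngc += int(r_n.decision)
            det_lin += int(r_l.decision)
        assert det_ngc >= 0.9 * n_rep
        assert det_ngc >= det_lin - int(0.02 * n_rep)  # paired power comparison

    def test_shifted_copy_detected_directionally(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        y = np.roll(x, 1)  # y_k = x_{k-1}: x drives y
        y[0] = 0.0
        ryx, rxy = nonlinear_gc_pair(x, y, m=3, n_centers=8, seed=0, alpha=0.01)
        assert rxy.decision  # x -> y present
        assert rxy.f > ryx.f

    def test_null_type_one_error_near_nominal(self, rng):
        hits, n_rep = 0, 150
        for s in range(n_rep):
            x = rng.standard_normal(800)
            y = rng.standard_normal(800)
            ryx, _ = nonlinear_gc_pair(x, y, m=2, n_centers=5, seed=s, alpha=0.01)
            hits += int(ryx.decision)
        assert hits / n_rep <= 0.04


def _chain_series(rng, n=900, a=0.9):
    """y -> z -> x chain with lag-1 couplings and no direct y -> x edge."""
    y = rng.standard_normal(n)
    z = np.zeros(n)
    x = np.zeros(n)
    noise_z = rng.standard_normal(n)
    noise_x = rng.standard_normal(n)
    for k in range(1, n):
        z[k] = a * y[k - 1] + 0.5 * noise_z[k]
        x[k] = a * z[k - 1] + 0.5 * noise_x[k]
    return np.column_stack([x, y, z])


class TestConditionalGC:
    def test_chain_indirect_edge_suppressed_by_conditioning(self):
        # pairwise testing sees the mediated y -> x influence; conditioning on
        # z must remove it in the majority of replicates
        n_rep = 60
        pairwise_hits, conditional_hits, direct_hits = 0, 0, 0
        for s in range(n_rep):
            rng = np.random.default_rng(500 + s)
            data = _chain_series(rng)
            cond = conditional_gc(data, source=1, target=0, method="linear", m=3, seed=s)
            pair = conditional_gc(data, source=1, target=0, method="linear", m=3,
                                  seed=s, condition="pairwise")
            direct = conditional_gc(data, source=2, target=0, method="linear", m=3, seed=s)
            conditional_hits += int(cond.decision)
            pairwise_hits += int(pair.decision)
            direct_hits += int(direct.decision)
        assert pairwise_hits > 0.9 * n_rep      # mediated influence visible pairwise
        assert conditional_hits < 0.5 * n_rep   # suppressed under conditioning
        assert direct_hits > 0.9 * n_rep        # true direct edge kept

    def test_two_channels_degrade_to_pairwise(self):
        x, y = var_chain(1500, coupling=0.7, seed=8)
        data = np.column_stack([x, y])
        cond = conditional_gc(data, source=1, target=0, method="linear", m=4)
        pair = conditional_gc(data, source=1, target=0, method="linear", m=4,
                              condition="pairwise")
        assert cond.f == pytest.approx(pair.f)
        assert cond.decision and pair.decision

    def test_strong_direct_edge_power(self):
        hits, n_rep = 0, 40
        for s in range(n_rep):
            rng = np.random.default_rng(900 + s)
            data = _chain_series(rng)
            hits += int(conditional_gc(data, source=2, target=0, method="rbf",
                                       m=3, n_centers=6, seed=s).decision)
        assert hits >= 0.9 * n_rep


class TestIdentifierEstimator:
    def test_decision_invariant_to_offset_and_scale(self, rng):
        data = _chain_series(rng, n=800)
        est1 = GrangerNetworkIdentifier(method="linear", order=3, random_state=0).fit(data)
        shifted = data.copy()
        shifted[:, 1] = 5.0 + 3.0 * shifted[:, 1]
        est2 = GrangerNetworkIdentifier(method="linear", order=3, random_state=0).fit(shifted)
        assert np.array_equal(est1.decisions_, est2.decisions_)
        assert np.allclose(est1.f_matrix_, est2.f_matrix_, equal_nan=True)

    def test_log_and_ratio_indices_order_identically(self, rng):
        data = _chain_series(rng, n=600)
        est = GrangerNetworkIdentifier(method="rbf", order=3, n_centers=5,
                                       random_state=1).fit(data)
        f = est.f_matrix_[~np.isnan(est.f_matrix_)]
        ratio = np.exp(f)
        assert np.array_equal(np.argsort(f), np.argsort(ratio))
        assert np.all((f > 0) == (ratio > 1))

    def test_fit_deterministic_under_seed(self, rng):
        data = _chain_series(rng, n=500)
        a = GrangerNetworkIdentifier(order=3, n_centers=5, random_state=7).fit(data)
        b = GrangerNetworkIdentifier(order=3, n_centers=5, random_state=7).fit(data)
        assert np.array_equal(a.decisions_, b.decisions_)
        assert np.allclose(a.p_values_, b.p_values_)

    def test_permutation_agrees_with_parametric_on_linear_instance(self):
        x, y = var_chain(800, coupling=0.8, seed=2)
        data = np.column_stack([x, y])
        par = GrangerNetworkIdentifier(method="linear", order=3,
                                       significance="f", random_state=0).fit(data)
        perm = GrangerNetworkIdentifier(method="linear", order=3,
                                        significance="permutation",
                                        n_permutations=200, random_state=0).fit(data)
        assert np.array_equal(par.decisions_, perm.decisions_)
        # the detected direction: both rules pin the p-value near zero
        assert abs(par.p_values_[0, 1] - perm.p_values_[0, 1]) <= 0.05
        # the null direction: both rules agree it is not significant
        assert par.p_values_[1, 0] > 0.05 and perm.p_values_[1, 0] > 0.05

    def test_silent_channel_handled_as_absent(self, rng):
        data = _chain_series(rng, n=400)
        data[:, 2] = 0.0
        with pytest.warns(RuntimeWarning, match="zero variance"):
            est = GrangerNetworkIdentifier(method="linear", order=3).fit(data)
        assert est.decisions_[:, 2].sum() == 0
        assert est.decisions_[2, :].sum() == 0

    def test_input_validation(self):
        est = GrangerNetworkIdentifier()
        with pytest.raises(ValueError, match="2 channels"):
            est.fit(np.zeros((100, 1)))
        with pytest.raises(ValueError, match="unknown method"):
            GrangerNetworkIdentifier(method="spectral").fit(np.zeros((100, 2)))
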