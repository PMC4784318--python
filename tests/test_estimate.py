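import math

import numpy as np
import pytest
from scipy.special import ndtr

from sortseqkit.distributions import (
    GateConfig,
    gate_probabilities,
    make_log_gates,
)
from sortseqkit.estimate import (
    QCThresholds,
    kl_divergence_bits,
    mle_fit,
    predicted_fractions,
    qc_filter,
    reference_estimate,
    robust_mle_fit,
    simple_cv,
    simple_mean,
)
from sortseqkit.simulate import OutputCounts


def counts_of(arr, n_drawn=None):
    arr = np.asarray(arr, dtype=int)
    return OutputCounts(counts=arr, n_drawn=int(arr.sum() if n_drawn is None else n_drawn))


@pytest.fixture
def gates6():
    return make_log_gates(6, 1.0, math.exp(4.8))


class TestSimpleEstimators:
    def test_b_factor_closed_form(self, gates6):
        # all mass in gate 3: the estimate is exactly phi_3 = b*sqrt(L3*U3)
        out = counts_of([0, 0, 10, 0, 0, 0])
        b = 0.8 / (math.exp(0.4) - math.exp(-0.4))
        assert b == pytest.approx(0.9738, abs=2e-4)
        phi3 = b * math.sqrt(gates6.lower[2] * gates6.upper[2])
        assert simple_mean(out, gates6) == pytest.approx(phi3, rel=1e-12)

    def test_cv_zero_for_single_gate(self, gates6):
        assert simple_cv(counts_of([0, 5, 0, 0, 0, 0]), gates6) == 0.0

    def test_cv_two_point_formula(self, gates6):
        out = counts_of([1, 0, 0, 1, 0, 0])
        b = 0.8 / (math.exp(0.4) - math.exp(-0.4))
        phi = b * np.sqrt(gates6.lower * gates6.upper)
        expected = abs(phi[0] - phi[3]) / (phi[0] + phi[3])
        assert simple_cv(out, gates6) == pytest.approx(expected, rel=1e-12)

    def test_rejects_semibounded_gates(self):
        g = make_log_gates(4, 1.0, 10.0, semibounded=True)
        with pytest.raises(ValueError):
            simple_mean(counts_of([1, 2, 3, 4]), g)

    def test_rejects_empty_counts(self, gates6):
        with pytest.raises(ValueError):
            simple_mean(counts_of([0] * 6), gates6)

    def test_mean_bounded_by_occupied_gate_values(self, gates6, rng):
        b = 0.8 / (math.exp(0.4) - math.exp(-0.4))
        phi = b * np.sqrt(gates6.lower * gates6.upper)
        for _ in range(50):
            r = rng.integers(0, 20, size=6)
            if r.sum() == 0:
                continue
            occ = r > 0
            est = simple_mean(counts_of(r), gates6)
            assert phi[occ].min() - 1e-12 <= est <= phi[occ].max() + 1e-12


class TestMleFit:
    def test_self_consistency_recovery(self):
        # expected proportions of (mu=0, sigma=0.5) on 8 semibounded gates,
        # scaled to 1e6 cells, must reproduce the generating parameters
        g = make_log_gates(8, math.exp(-2), math.exp(2), semibounded=True)
        p = gate_probabilities(g, 0.0, 0.5)
        rec = mle_fit(counts_of(np.round(p * 1e6)), g)
        assert rec.converged
        assert abs(rec.mu_hat) < 0.005
        assert rec.sigma_hat == pytest.approx(0.5, rel=0.005)

    def test_matches_brute_force_grid_argmax(self):
        g = make_log_gates(8, math.exp(-2), math.exp(2), semibounded=True)
        p = gate_probabilities(g, 0.3, 0.45)
        r = np.round(p * 1e5)
        rec = mle_fit(counts_of(r), g)
        mus = np.linspace(-2, 2, 200)
        sigmas = np.linspace(0.05, 2.0, 200)
        MU, SIG = np.meshgrid(mus, sigmas, indexing="ij")
        ll = np.zeros_like(MU)
        for j in range(g.m):
            U, L = g.upper[j], g.lower[j]
            FU = np.ones_like(MU) if np.isinf(U) else ndtr((np.log(U) - MU) / SIG)
            FL = np.zeros_like(MU) if L == 0 else ndtr((np.log(L) - MU) / SIG)
            ll += r[j] * np.log(np.clip(FU - FL, 1e-300, None))
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert abs(rec.mu_hat - mus[i]) <= mus[1] - mus[0]
        assert abs(rec.sigma_hat - sigmas[j]) <= sigmas[1] - sigmas[0]

    def test_scale_invariance_of_counts(self, gates6):
        r = np.array([3, 10, 30, 25, 8, 1])
        a = mle_fit(counts_of(r), gates6)
        b = mle_fit(counts_of(r * 17), gates6)
        assert a.mu_hat == pytest.approx(b.mu_hat, abs=1e-6)
        assert a.sigma_hat == pytest.approx(b.sigma_hat, abs=1e-6)

    def test_degenerate_single_gate_flagged(self, gates6):
        rec = mle_fit(counts_of([0, 0, 50, 0, 0, 0]), gates6)
        assert not rec.converged


class TestPredictedFractions:
    def test_gamma_limits(self):
        g = make_log_gates(4, 1.0, math.exp(4), semibounded=True)
        T = np.array([0.1, 0.2, 0.3, 0.4])
        np.testing.assert_allclose(
            predicted_fractions(0.5, 0.3, g, T, 0.0), gate_probabilities(g, 0.5, 0.3)
        )
        np.testing.assert_allclose(predicted_fractions(0.5, 0.3, g, T, 1 - 1e-12), T, atol=1e-9)

    def test_point_mass_with_uniform_outliers(self):
        g = make_log_gates(4, 1.0, math.exp(4), semibounded=True)
        T = np.full(4, 0.25)
        lam = predicted_fractions(1.5, 1e-9, g, T, 0.05)  # mass inside gate 2
        np.testing.assert_allclose(lam, [0.0125, 0.9625, 0.0125, 0.0125], atol=1e-9)

    def test_rejects_bad_gamma(self):
        g = make_log_gates(2, 1.0, 4.0)
        with pytest.raises(ValueError):
            predicted_fractions(0.0, 0.5, g, np.array([0.5, 0.5]), 1.5)


class TestRobustMle:
    def test_fixed_point_recovery(self):
        g = make_log_gates(32, math.exp(-2), math.exp(2), semibounded=True)
        T = np.full(32, 1 / 32)
        t = predicted_fractions(0.3, 0.25, g, T, 0.05)
        rec = robust_mle_fit(t, g, T, gamma=0.05)
        assert rec.mu_hat == pytest.approx(0.3, abs=1e-4)
        assert rec.sigma_hat == pytest.approx(0.25, abs=1e-4)

    def test_gamma_zero_reduces_to_plain_mle(self):
        g = make_log_gates(8, math.exp(-2), math.exp(2), semibounded=True)
        p = gate_probabilities(g, -0.2, 0.4)
        T = np.full(8, 1 / 8)
        rec0 = robust_mle_fit(p, g, T, gamma=0.0)
        rec_counts = mle_fit(counts_of(np.round(p * 1e6)), g)
        assert rec0.mu_hat == pytest.approx(rec_counts.mu_hat, abs=1e-3)
        assert rec0.sigma_hat == pytest.approx(rec_counts.sigma_hat, abs=1e-3)

    def test_contamination_resistance(self):
        # 5 % uniform contamination: the robust fit stays near truth,
        # the plain MLE drifts
        g = make_log_gates(16, math.exp(-2), math.exp(2), semibounded=True)
        T = np.full(16, 1 / 16)
        clean = gate_probabilities(g, 0.5, 0.2)
        t = 0.95 * clean + 0.05 * T
        robust = robust_mle_fit(t, g, T, gamma=0.05)
        plain = robust_mle_fit(t, g, T, gamma=0.0)
        err_robust = math.hypot(robust.mu_hat - 0.5, robust.sigma_hat - 0.2)
        err_plain = math.hypot(plain.mu_hat - 0.5, plain.sigma_hat - 0.2)
        assert err_robust < err_plain / 5

    def test_fitted_record_exposes_moments(self):
        g = make_log_gates(8, math.exp(-2), math.exp(2), semibounded=True)
        T = np.full(8, 1 / 8)
        t = predicted_fractions(0.0, 0.5, g, T, 0.05)
        rec = robust_mle_fit(t, g, T)
        assert rec.nu_hat == pytest.approx(
            math.exp(rec.mu_hat + rec.sigma_hat**2 / 2), rel=1e-10
        )


class TestKlDivergence:
    def test_identical_distributions_have_zero_divergence(self):
        t = np.array([0.25, 0.25, 0.5])
        assert kl_divergence_bits(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        val = kl_divergence_bits(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        assert val == pytest.approx(0.5 + 0.5 * math.log2(2 / 3), abs=1e-12)

    def test_nonnegative_over_random_pairs(self, rng):
        for _ in range(200):
            t = rng.dirichlet(np.ones(6))
            lam = rng.dirichlet(np.ones(6))
            assert kl_divergence_bits(t, lam) >= -1e-12

    def test_incompatible_support_raises(self):
        with pytest.raises(ValueError):
            kl_divergence_bits(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


class TestQcFilter:
    @pytest.fixture
    def qc_env(self):
        g = make_log_gates(8, math.exp(-2), math.exp(2), semibounded=True)
        return g, np.full(8, 1 / 8)

    def test_read_threshold(self, qc_env):
        g, T = qc_env
        t = np.full(8, 1 / 8)
        res = qc_filter(t, 299, g, T)
        assert not res.keep and res.reason == "reads"
        assert qc_filter(t, 300, g, T).keep

    def test_single_gate_concentration(self, qc_env):
        g, T = qc_env
        t = np.array([0.0, 0.0, 0.61, 0.13, 0.13, 0.13, 0.0, 0.0])
        res = qc_filter(t, 1000, g, T)
        assert not res.keep and res.reason == "concentration"

    def test_two_gate_concentration_uses_top_two_anywhere(self, qc_env):
        g, T = qc_env
        # 46 % + 45 % in non-adjacent gates exceeds the 90 % two-gate cap
        t = np.array([0.0, 0.46, 0.03, 0.45, 0.03, 0.03, 0.0, 0.0])
        res = qc_filter(t, 1000, g, T)
        assert not res.keep and res.reason == "concentration"

    def test_censor_gate_overflow(self, qc_env):
        g, T = qc_env
        t = np.array([0.41, 0.2, 0.13, 0.1, 0.06, 0.05, 0.05, 0.0])
        res = qc_filter(t, 1000, g, T)
        assert not res.keep and res.reason == "concentration"

    def test_clean_sample_from_fitted_model_kept(self, qc_env, rng):
        g, T = qc_env
        p = predicted_fractions(0.0, 0.5, g, T, 0.05)
        counts = rng.multinomial(10_000, p)
        t = counts / counts.sum()
        rec = robust_mle_fit(t, g, T)
        res = qc_filter(t, int(counts.sum()), g, T, record=rec)
        assert res.keep

    def test_bad_fit_rejected_by_divergence(self, qc_env):
        g, T = qc_env
        # bimodal data that no log-normal fits well
        t = np.array([0.0, 0.35, 0.1, 0.05, 0.05, 0.1, 0.35, 0.0])
        rec = robust_mle_fit(t, g, T)
        res = qc_filter(t, 5000, g, T, record=rec, thresholds=QCThresholds())
        assert not res.keep and res.reason == "fit"


class TestReferenceEstimate:
    def test_constant_sample(self):
        rec = reference_estimate(np.full(10, 7.0))
        assert rec.mu_hat == pytest.approx(math.log(7.0))
        assert rec.sigma_hat == pytest.approx(0.0, abs=1e-12)
        assert rec.c_hat == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_computation(self):
        rec = reference_estimate(np.array([1.0, math.e**2]))
        assert rec.mu_hat == pytest.approx(1.0, rel=1e-12)
        assert rec.sigma_hat == pytest.approx(1.0, rel=1e-12)

    def test_consistency_at_large_n(self, rng):
        x = np.exp(1.0 + 0.3 * rng.standard_normal(100_000))
        rec = reference_estimate(x)
        assert rec.mu_hat == pytest.approx(1.0, abs=0.01)
        assert rec.sigma_hat == pytest.approx(0.3, rel=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            reference_estimate(np.array([]))
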