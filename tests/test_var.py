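"""VAR estimation, information criteria, lag selection, stability."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from statsmodels.tsa.api import VAR as SMVAR

from soilvar.model import VAR, fit_var, information_criteria, select_lag_order
from soilvar.process import VARError, VARProcess, companion_matrix
from soilvar.reference import reference_process


class TestFit:
    def test_estimates_match_statsmodels_oracle(self, var1_process):
        y = var1_process.simulate(800, seed=5)
        res = VAR(y).fit(2)
        ref = SMVAR(y).fit(2, trend="c")
        np.testing.assert_allclose(res.coefs, ref.coefs, atol=1e-12)
        np.testing.assert_allclose(res.intercept, ref.params[0], atol=1e-12)
        # ML covariance: statsmodels reports the df-adjusted one
        np.testing.assert_allclose(
            res.sigma_u, ref.sigma_u * (res.nobs - 2 * 2 - 1) / res.nobs, atol=1e-12
        )

    def test_white_noise_pair_estimates_near_zero(self, rng):
        y = rng.standard_normal((5000, 2))
        res = VAR(y).fit(1)
        assert np.abs(res.coefs).max() < 0.05  # ~3 sigma sampling bound

    def test_parameter_recovery_var1(self):
        proc = VARProcess(np.array([[[0.5, 0.1], [0.0, 0.3]]]), sigma=np.eye(2))
        res = VAR(proc.simulate(5000, seed=42)).fit(1)
        np.testing.assert_allclose(res.coefs, proc.coefs, atol=0.05)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_parameter_recovery_random_stable_var(self, p, rng):
        # random stable coefficient sets, identity innovations, T = 10,000
        while True:
            coefs = rng.uniform(-0.45, 0.45, size=(p, 2, 2)) / p
            proc = VARProcess(coefs, sigma=np.eye(2))
            if proc.stability().max_modulus < 0.9:
                break
        res = VAR(proc.simulate(10_000, seed=p)).fit(p)
        assert np.abs(res.coefs - proc.coefs).max() < 0.05

    def test_residual_mean_zero_with_intercept(self, var1_process):
        res = VAR(var1_process.simulate(1500, seed=3)).fit(2)
        np.testing.assert_allclose(res.resid.mean(axis=0), 0.0, atol=1e-10)

    def test_order_and_collinearity_errors(self, rng):
        y = rng.standard_normal((200, 2))
        with pytest.raises(VARError, match="order"):
            VAR(y).fit(0)
        dup = np.column_stack([y[:, 0], y[:, 0]])
        with pytest.raises(VARError, match="collinear"):
            VAR(dup).fit(1)

    def test_functional_wrapper(self, rng):
        y = rng.standard_normal((300, 2))
        assert fit_var(y, 1).p == 1


class TestLoglik:
    def test_closed_form_matches_density_sum_oracle(self, var1_process):
        """ln L̂ equals the summed Gaussian log-density of the residuals
        evaluated at the ML covariance."""
        res = VAR(var1_process.simulate(400, seed=9)).fit(1)
        direct = multivariate_normal(mean=[0, 0], cov=res.sigma_u).logpdf(res.resid).sum()
        assert res.llf == pytest.approx(direct, rel=1e-10)

    def test_invariant_to_variable_relabeling(self, var1_process):
        y = var1_process.simulate(500, seed=12)
        assert VAR(y).fit(2).llf == pytest.approx(VAR(y[:, ::-1]).fit(2).llf, rel=1e-12)

    def test_single_observation_identity_covariance_value(self):
        # -(n/2)(m ln 2pi + ln det I + m) at n=1, m=2
        expected = -0.5 * (2 * np.log(2 * np.pi) + 0.0 + 2)
        n, m = 1, 2
        assert -(n / 2) * (m * np.log(2 * np.pi) + 0.0 + m) == pytest.approx(expected)


class TestInformationCriteria:
    def test_aic_arithmetic_reference_value(self):
        aic, _ = information_criteria(11500.7, p=1, m=2, n=3888)
        assert aic == pytest.approx(-22989.4, abs=0.05)

    def test_bic_arithmetic_reference_value(self):
        _, bic = information_criteria(-2298.5, p=1, m=2, n=3888)
        assert bic == pytest.approx(4646.6, abs=0.15)

    def test_zero_loglik_arithmetic_identity(self):
        # with ln L = 0, AIC = 2k exactly and BIC = k ln(n); at n = e^2
        # (rounded to an integer sample size) the two nearly coincide
        n = int(round(np.e**2))
        aic, bic = information_criteria(0.0, p=3, m=1, n=n)
        k = 1 * (1 * 3 + 1)
        assert aic == 2 * k
        assert bic == pytest.approx(k * np.log(n))


class TestLagSelection:
    def test_parsimony_rule(self):
        def rows(p_aic, p_bic):
            out = []
            for p in range(1, 9):
                out.append((p, 0.0, 0.0 if p == p_aic else 1.0,
                            0.0 if p == p_bic else 1.0))
            return out

        assert select_lag_order(rows(8, 5)) == 5
        assert select_lag_order(rows(8, 7)) == 7
        assert select_lag_order(rows(4, 4)) == 4

    def test_common_sample_makes_criteria_comparable(self, var1_process):
        y = var1_process.simulate(2000, seed=21)
        table = VAR(y).select_order(4)
        assert all(r[0] == i + 1 for i, r in enumerate(table.rows))
        # every row refits on the same trimmed sample
        assert table.n == 2000 - 4
        for p, llf, aic, bic in table.rows:
            a, b = information_criteria(llf, p, 2, table.n)
            assert aic == pytest.approx(a) and bic == pytest.approx(b)

    def test_order_recovery_simulated_var2(self):
        Phi = np.array([[[0.5, 0.2], [0.1, 0.4]], [[-0.3, 0.05], [0.05, -0.2]]])
        proc = VARProcess(Phi, sigma=np.eye(2))
        hits = sum(
            VAR(proc.simulate(4000, seed=200 + i)).select_order(6).chosen_p == 2
            for i in range(40)
        )
        assert hits >= 0.8 * 40


class TestCompanionAndStability:
    def test_p1_companion_is_phi1(self, var1_process):
        np.testing.assert_array_equal(
            var1_process.companion_matrix(), var1_process.coefs[0]
        )

    def test_block_structure_p5(self):
        proc = reference_process(10)
        F = proc.companion_matrix()
        assert F.shape == (10, 10)
        for s in range(5):
            np.testing.assert_array_equal(F[:2, 2 * s : 2 * s + 2], proc.coefs[s])
        np.testing.assert_array_equal(F[2:, :8], np.eye(8))
        np.testing.assert_array_equal(F[2:, 8:], np.zeros((8, 2)))

    def test_companion_reproduces_one_step_prediction(self, rng):
        proc = VARProcess(rng.uniform(-0.3, 0.3, (3, 2, 2)))
        F = proc.companion_matrix()
        state = rng.standard_normal((3, 2))  # newest last
        # stack newest first for the companion form
        z = np.concatenate([state[-1], state[-2], state[-3]])
        direct = sum(proc.coefs[s - 1] @ state[-s] for s in range(1, 4))
        np.testing.assert_allclose((F @ z)[:2], direct, atol=1e-12)

    def test_diagonal_stability_read_off(self):
        stable = VARProcess(np.array([[[0.5, 0.0], [0.0, 0.5]]])).stability()
        assert stable.stable and np.allclose(stable.moduli, 0.5)
        unstable = VARProcess(np.array([[[1.1, 0.0], [0.0, 0.5]]])).stability()
        assert not unstable.stable and unstable.max_modulus == pytest.approx(1.1)

    @pytest.mark.parametrize("depth", [10, 30, 90])
    def test_reference_calibrations_are_stable(self, depth):
        assert reference_process(depth).stability().max_modulus < 1

    def test_companion_helper_matches_method(self, var1_process):
        np.testing.assert_array_equal(
            companion_matrix(var1_process.coefs), var1_process.companion_matrix()
        )


class TestResultsSurface:
    def test_one_step_prediction_consistency(self, var1_process):
        y = var1_process.simulate(300, seed=2)
        res = VAR(y).fit(2)
        fitted = res.fittedvalues()
        np.testing.assert_allclose(
            res.predict_one_step(y[:2]), fitted[0], atol=1e-12
        )

    def test_model_dump_roundtrips_through_json(self, var1_process):
        import json

        res = VAR(var1_process.simulate(200, seed=1)).fit(1)
        d = json.loads(json.dumps(res.to_dict()))
        np.testing.assert_allclose(np.asarray(d["coeffs"]), res.coefs)
        assert d["n"] == res.nobs

    def test_summary_mentions_stability(self, var1_process):
        s = VAR(var1_process.simulate(200, seed=1)).fit(1).summary()
        assert "stable" in s and "VAR(1)" in s
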