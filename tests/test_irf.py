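"""Impulse responses: MA coefficients, shock schemes, summaries, bands."""

import numpy as np
import pytest

from soilvar.irf import ImpulseResponse, bootstrap_bands, ma_coefficients
from soilvar.model import VAR
from soilvar.process import VARError, VARProcess


def _curve_irf(curve, horizon=None):
    """Wrap a scalar response curve into a 1-variable ImpulseResponse."""
    c = np.asarray(curve, dtype=float)
    H = c.size - 1 if horizon is None else horizon
    return ImpulseResponse(
        scheme="reduced", horizon=H, responses=c.reshape(-1, 1, 1), labels=("y",)
    )


class TestMACoefficients:
    def test_psi0_is_identity(self, var1_process):
        assert np.array_equal(ma_coefficients(var1_process, 5)[0], np.eye(2))

    def test_var1_psi_equals_matrix_powers(self, var1_process):
        psi = ma_coefficients(var1_process, 12)
        for i in range(13):
            np.testing.assert_allclose(
                psi[i], np.linalg.matrix_power(var1_process.coefs[0], i), atol=1e-12
            )

    def test_stable_model_tail_decays_below_1e6(self):
        proc = VARProcess(np.array([[[0.9, 0.05], [0.02, 0.85]]]))
        psi = proc.ma_coefficients(1000)
        assert np.linalg.norm(psi[-1]) < 1e-6


class TestUnitShockSchemes:
    def test_reduced_contemporaneous_cross_response_is_zero(self, var1_process):
        irf = ImpulseResponse.from_process(var1_process, 10, "reduced")
        assert irf.responses[0, 0, 1] == 0.0 and irf.responses[0, 1, 0] == 0.0
        np.testing.assert_array_equal(irf.responses[0], np.eye(2))

    def test_generalized_contemporaneous_closed_form(self, var1_process):
        # response of var1 to a one-unit shock in var2 at horizon 0 is
        # sigma_12 / sigma_22 = 0.3
        irf = ImpulseResponse.from_process(var1_process, 10, "generalized")
        assert irf.responses[0, 0, 1] == pytest.approx(0.3)

    def test_generalized_var1_matrix_power_oracle(self, var1_process):
        irf = ImpulseResponse.from_process(var1_process, 8, "generalized")
        S = var1_process.sigma
        W = S / np.diag(S)[None, :]
        for i in range(9):
            np.testing.assert_allclose(
                irf.responses[i],
                np.linalg.matrix_power(var1_process.coefs[0], i) @ W,
                atol=1e-12,
            )

    def test_generalized_is_order_invariant_cholesky_is_not(self, var1_process):
        swapped = VARProcess(
            var1_process.coefs[:, ::-1, :][:, :, ::-1],
            sigma=var1_process.sigma[::-1, ::-1],
            labels=var1_process.labels[::-1],
        )
        for scheme, invariant in (("generalized", True), ("cholesky", False)):
            a = ImpulseResponse.from_process(var1_process, 10, scheme).responses
            b = ImpulseResponse.from_process(swapped, 10, scheme).responses
            matches = np.allclose(a, b[:, ::-1, :][:, :, ::-1], atol=1e-12)
            assert matches == invariant

    def test_degenerate_sigma_rejected_for_orthogonalized_shocks(self):
        proc = VARProcess(np.array([[[0.5, 0.0], [0.0, 0.5]]]), sigma=np.zeros((2, 2)))
        with pytest.raises(VARError, match="degenerate"):
            ImpulseResponse.from_process(proc, 5, "generalized")

    def test_unstable_model_warns(self):
        proc = VARProcess(np.array([[[1.05, 0.0], [0.0, 0.5]]]))
        with pytest.warns(UserWarning, match="unstable"):
            ImpulseResponse.from_process(proc, 5, "reduced")


class TestSummaries:
    def test_cumulative_geometric_closed_form(self):
        phi = 0.9
        irf = _curve_irf(phi ** np.arange(31))
        for n in (0, 5, 30):
            assert irf.cumulative_response(0, 0, n) == pytest.approx(
                (1 - phi ** (n + 1)) / (1 - phi)
            )

    def test_cumulative_of_zero_curve_is_zero(self):
        assert _curve_irf(np.zeros(20)).cumulative_response(0, 0) == 0.0

    @pytest.mark.parametrize(
    	"peak,trough,expected",
        [(0.0086, -0.0077, 0.0163), (0.0017, -0.0033, 0.0050)],
    )
    def test_intensity_is_zero_clamped_peak_gap(self, peak, trough, expected):
        c = np.concatenate([[trough], np.linspace(trough, peak, 30),
                            np.linspace(peak, 0, 60)])
        assert _curve_irf(c).intensity(0, 0) == pytest.approx(expected)

    def test_intensity_of_one_signed_curve_is_its_peak(self):
        c = 0.2 * 0.8 ** np.arange(40)
        assert _curve_irf(c).intensity(0, 0) == pytest.approx(0.2)

    def test_time_lag_geometric_curve(self):
        # 0.9^i falls below 5% of intensity (=1) first at i = 29
        irf = _curve_irf(0.9 ** np.arange(121))
        assert irf.time_lag(0, 0, epsilon_frac=0.05) == 29
        assert irf.settled(0, 0)

    def test_time_lag_zero_curve_and_unsettled_flag(self):
        assert _curve_irf(np.zeros(10)).time_lag(0, 0) == 0
        slow = _curve_irf(0.999 ** np.arange(11))
        assert slow.time_lag(0, 0) == 11  # horizon + 1: never settles
        assert not slow.settled(0, 0)

    def test_table_shape(self, var1_process):
        df = ImpulseResponse.from_process(var1_process, 12, "generalized").to_frame()
        assert list(df["horizon"]) == list(range(13))
        assert "y1<-y2" in df.columns and "y2<-y1" in df.columns


class TestBootstrapBands:
    @pytest.fixture(scope="class")
    def fitted(self, var1_process):
        return VAR(var1_process.simulate(300, seed=8)).fit(1)

    def test_same_seed_is_bit_identical(self, fitted):
        b1 = bootstrap_bands(fitted, horizon=20, B=100, seed=5)
        b2 = bootstrap_bands(fitted, horizon=20, B=100, seed=5)
        assert np.array_equal(b1.bands.lower, b2.bands.lower)
        assert np.array_equal(b1.bands.upper, b2.bands.upper)

    def test_bands_bracket_point_estimate(self, fitted):
        irf = bootstrap_bands(fitted, horizon=20, B=200, seed=9, level=0.90)
        inside = (irf.bands.lower <= irf.responses) & (irf.responses <= irf.bands.upper)
        assert inside.mean() >= 0.85

    def test_band_width_stable_in_replicate_count(self, fitted):
        w100 = bootstrap_bands(fitted, horizon=20, B=100, seed=5)
        w1000 = bootstrap_bands(fitted, horizon=20, B=1000, seed=5)
        r = (w100.bands.upper - w100.bands.lower).mean() / (
            w1000.bands.upper - w1000.bands.lower
        ).mean()
        assert 0.8 < r < 1.2

    def test_too_few_replicates_rejected(self, fitted):
        with pytest.raises(VARError, match="order"):
            bootstrap_bands(fitted, B=50)


def test_plot_returns_figure(var1_process):
    import matplotlib

    matplotlib.use("Agg")
    fig = ImpulseResponse.from_process(var1_process, 10, "generalized").plot()
    assert fig.axes
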