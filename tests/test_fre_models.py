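"""Unit and property tests of the macroscopic rate models."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from qiffre import fre_models as fm
from qiffre.fre_models import (FREParams, FREState, ForcingSpec, IntegrationError,
                               fi_curve, fi_curve_prime, forcing_theta)


class TestFICurve:
    def test_reference_rate_63_66_hz(self):
        # suprathreshold homogeneous input I=4 with tau_m=10 ms fires at
        # sqrt(4)/(10 pi) per ms = 63.66 Hz
        assert fi_curve(4.0, 0.0, 10.0) * 1000 == pytest.approx(63.66, abs=0.005)

    def test_subthreshold_homogeneous_is_silent(self):
        assert fi_curve(-1.0, 0.0, 10.0) == 0.0
        assert fi_curve(-1e-12, 0.0, 7.3) == 0.0

    def test_heterogeneous_matches_integrated_steady_state(self):
        # oracle: long-time rate of the full mean-field flow with J=0, Theta=0
        p = FREParams(tau_m=10.0, tau_d=5.0, J=0.0, Theta=0.0, Delta=0.3)
        ts = fm.integrate(fm.make_qif_fre_rhs(p), [0.001, 0.0, 0.001], (0, 3000), 0.1)
        assert fi_curve(0.0, 0.3, 10.0) == pytest.approx(ts.channel("r")[-1], rel=1e-6)

    def test_homogeneous_closed_form_exact(self):
        I = np.linspace(-3, 5, 33)
        np.testing.assert_array_equal(
            fi_curve(I, 0.0, 4.0), np.sqrt(np.maximum(I, 0.0)) / (np.pi * 4.0))

    @given(I=st.floats(-10, 10), dI=st.floats(1e-6, 5.0),
           Delta=st.floats(0.0, 2.0), tau_m=st.floats(0.5, 50.0))
    def test_monotone_in_current(self, I, dI, Delta, tau_m):
        assert fi_curve(I + dI, Delta, tau_m) >= fi_curve(I, Delta, tau_m)

    @given(I=st.floats(-5, -0.1), Delta=st.floats(0.01, 2.0), dD=st.floats(1e-6, 1.0))
    def test_heterogeneity_smooths_subthreshold(self, I, Delta, dD):
        # below threshold, widening the current distribution raises the rate
        assert fi_curve(I, Delta + dD, 10.0) > fi_curve(I, Delta, 10.0)

    def test_derivative_matches_finite_difference(self):
        for I, Delta in [(2.0, 0.3), (-1.0, 0.5), (0.0, 0.1), (3.0, 0.0)]:
            h = 1e-6
            fd = (fi_curve(I + h, Delta, 10.0) - fi_curve(I - h, Delta, 10.0)) / (2 * h)
            assert fi_curve_prime(I, Delta, 10.0) == pytest.approx(fd, rel=1e-5)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            fi_curve(1.0, -0.1, 10.0)
        with pytest.raises(ValueError):
            fi_curve(1.0, 0.3, 0.0)


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            FREParams(tau_m=0.0, tau_d=5, J=21, Theta=4, Delta=0.3)
        with pytest.raises(ValueError):
            FREParams(tau_m=10, tau_d=-1, J=21, Theta=4, Delta=0.3)
        with pytest.raises(ValueError):
            FREParams(tau_m=10, tau_d=5, J=21, Theta=4, Delta=-0.3)

    def test_nondimensionalize_reference_values(self, fig3_params):
        dp = fm.nondimensionalize(fig3_params)
        assert dp.j == pytest.approx(10.5)
        assert dp.delta == pytest.approx(0.075)
        assert dp.tau == pytest.approx(1.0)
        dp50 = fm.nondimensionalize(fig3_params.with_tau_d(50.0))
        assert dp50.tau == pytest.approx(10.0)

    @given(tau_m=st.floats(1, 50), tau_d=st.floats(0, 100),
           J=st.floats(0, 40), Theta=st.floats(0.1, 20), Delta=st.floats(0, 3))
    def test_round_trip_identity(self, tau_m, tau_d, J, Theta, Delta):
        p = FREParams(tau_m, tau_d, J, Theta, Delta)
        q = fm.dimensionalize(fm.nondimensionalize(p), tau_m, Theta)
        for f in ("tau_m", "tau_d", "J", "Theta", "Delta"):
            assert getattr(q, f) == pytest.approx(getattr(p, f), rel=1e-12, abs=1e-12)

    def test_nondimensionalize_requires_positive_theta(self):
        with pytest.raises(ValueError):
            fm.nondimensionalize(FREParams(10, 5, 21, -1.0, 0.3))

    def test_intrinsic_scale(self):
        assert fm.intrinsic_period(10, 4) == pytest.approx(15.71, abs=0.005)
        assert fm.intrinsic_frequency_hz(10, 4) == pytest.approx(63.66, abs=0.005)


class TestRHS:
    def test_fixed_point_is_stationary(self, fig3_params):
        p = fig3_params.with_tau_d(50.0)
        fp = fm.fixed_point_state(p)
        np.testing.assert_allclose(fm.qif_fre_rhs(fp.as_array(), p, p.Theta),
                                   0.0, atol=1e-14)
        # energy-free identity v* r* = -Delta/(2 pi tau_m)
        assert fp.v * fp.r == pytest.approx(-p.Delta / (2 * np.pi * p.tau_m), rel=1e-12)

    def test_rate_channel_pinned_at_zero_when_homogeneous(self):
        p = FREParams(tau_m=10, tau_d=5, J=3.0, Theta=-1.0, Delta=0.0)
        d = fm.qif_fre_rhs([0.0, -0.5, 0.0], p, -1.0)
        assert d[0] == 0.0

    def test_instantaneous_synapse_is_planar(self):
        p = FREParams(tau_m=10, tau_d=0.0, J=21, Theta=4, Delta=0.3)
        d = fm.qif_fre_rhs([0.01, 0.2, 0.5], p, 4.0)  # s value is ignored
        d2 = fm.qif_fre_rhs([0.01, 0.2, 0.01], p, 4.0)
        np.testing.assert_allclose(d, d2)
        assert d[2] == d[0]  # s slaved to r

    def test_hfre_steady_state_matches_qif_fre(self, fig3_params):
        p = fig3_params.with_tau_d(50.0)
        R = fm.steady_state_rate(p)
        np.testing.assert_allclose(fm.hfre_rhs([R, R], p, p.Theta), 0.0, atol=1e-15)
        ts = fm.integrate(fm.make_hfre_rhs(p), [0.001, 0.001], (0, 3000), 0.1,
                          ("r", "s"))
        assert ts.channel("r")[-1] == pytest.approx(R, rel=1e-6)

    def test_slow_reduction_fixed_point(self, fig3_params):
        p = fig3_params.with_tau_d(50.0)
        R = fm.steady_state_rate(p)
        assert fm.slow_reduction_rhs(R, p, p.Theta) == pytest.approx(0.0, abs=1e-18)


class TestForcing:
    @pytest.mark.parametrize("frac, expected", [(0.0, 5.0), (0.25, 12.0), (0.75, 4.0)])
    def test_sinusoid_cubed_anchor_points(self, frac, expected):
        spec = ForcingSpec("sinusoid-cubed", base=4.0, period=80.0)
        assert forcing_theta(frac * 80.0, spec) == pytest.approx(expected)

    def test_constant_and_errors(self):
        assert forcing_theta(13.0, ForcingSpec("constant", 4.0)) == 4.0
        with pytest.raises(ValueError):
            ForcingSpec("square-wave", 4.0, 10.0)
        with pytest.raises(ValueError):
            ForcingSpec("sinusoid-cubed", 4.0, None)


class TestIntegrator:
    def test_zero_rhs_constant_series(self):
        ts = fm.integrate(lambda t, y: np.zeros_like(y), [1.0, 2.0], (0, 10), 0.1,
                          ("a", "b"))
        np.testing.assert_array_equal(ts.channel("a"), 1.0)
        np.testing.assert_array_equal(ts.channel("b"), 2.0)

    def test_nonfinite_state_reports_time(self):
        blow_up = lambda t, y: np.full_like(y, np.inf if t > 10 else 0.0)  # noqa: E731
        with pytest.raises(IntegrationError, match="t ="):
            fm.integrate(blow_up, [1.0], (0, 100), 0.5, ("x",))

    def test_gamma_oscillation_stable_under_dt_halving(self, fig3_params, fig3_init):
        from qiffre.protocols import oscillation_frequency

        freqs = []
        for dt in (0.1, 0.05):
            ts = fm.integrate(fm.make_qif_fre_rhs(fig3_params), fig3_init.as_array(),
                              (0, 1000), dt)
            freqs.append(oscillation_frequency(ts, "r", transient=500))
        assert 30 < freqs[0] < 100  # gamma band
        assert freqs[0] == pytest.approx(freqs[1], rel=1e-3)


class TestNondimensionalConsistency:
    @pytest.mark.parametrize("tau_d", [5.0, 50.0])
    def test_reduced_flow_is_exact_image(self, fig3_params, fig3_init, tau_d):
        """Integrating the dimensional system and mapping to reduced variables
        reproduces the reduced-system trajectory pointwise."""
        p = fig3_params.with_tau_d(tau_d)
        dp = fm.nondimensionalize(p)
        span = 300.0
        ts = fm.integrate(fm.make_qif_fre_rhs(p), fig3_init.as_array(), (0, span), 0.02)
        scale = np.sqrt(p.Theta) / p.tau_m
        y0 = fm.state_to_dimless(fig3_init.as_array(), p)
        tsd = fm.integrate(fm.make_dimless_rhs(dp), y0, (0, span * scale), 0.02 * scale)
        mapped = fm.state_to_dimless(
            np.column_stack([ts.channel("r"), ts.channel("v"), ts.channel("s")]), p)
        np.testing.assert_allclose(mapped[-1], [tsd.channel("r")[-1],
                                                tsd.channel("v")[-1],
                                                tsd.channel("s")[-1]],
                                   rtol=2e-5, atol=2e-5)

    def test_steady_state_agreement_three_routes(self, fig3_params):
        """Long-time rate of the exact model, the heuristic model and the
        slow reduction agree in the non-oscillatory regime."""
        p = fig3_params.with_tau_d(50.0)
        R = fm.steady_state_rate(p)
        y0 = np.array([0.002, 0.0, 0.002])
        r_exact = fm.integrate(fm.make_qif_fre_rhs(p), y0, (0, 4000), 0.1).channel("r")[-1]
        r_heur = fm.integrate(fm.make_hfre_rhs(p), y0[[0, 2]], (0, 4000), 0.1,
                              ("r", "s")).channel("r")[-1]
        s_slow = fm.integrate(fm.make_slow_reduction_rhs(p), y0[[2]], (0, 4000), 0.1,
                              ("s",)).channel("s")[-1]
        assert r_exact == pytest.approx(R, rel=1e-5)
        assert r_heur == pytest.approx(R, rel=1e-5)
        assert s_slow == pytest.approx(R, rel=1e-5)


def test_timeseries_roundtrip_and_units(tmp_path):
    ts = fm.TimeSeries(np.arange(5) * 0.5,
                       {"r": np.full(5, 0.01), "v": np.zeros(5)},
                       {"note": "unit check"})
    path = tmp_path / "series.csv"
    ts.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["t_ms", "r_hz", "v"]
    np.testing.assert_allclose(df["r_hz"], 10.0)  # 0.01/ms == 10 Hz
    assert (tmp_path / "series.csv.json").exists()
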