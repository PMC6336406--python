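"""Exponential, stopped-flow and binding fitters against exact inputs."""

import numpy as np
import pytest

from pausekit import (
    ProgressCurve,
    fit_binding,
    fit_double_exponential,
    fit_single_exponential,
    fit_stopped_flow,
    make_binding_curve,
    make_stopped_flow,
    pause_metrics,
)
from pausekit.fitting import BiexpFit, FitError


class TestSingleExponential:
    def test_exact_recovery_of_rise(self):
        t = np.linspace(0.1, 20.0, 30)
        curve = ProgressCurve(t, 1 - np.exp(-0.5 * t), species="C17plus")
        fit = fit_single_exponential(curve, kind="rise")
        assert fit.rate == pytest.approx(0.5, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_exact_recovery_of_decay(self):
        t = np.linspace(0.0, 30.0, 25)
        curve = ProgressCurve(t, 0.8 * np.exp(-0.3 * t))
        fit = fit_single_exponential(curve, kind="decay")
        assert fit.rate == pytest.approx(0.3, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.8, rel=1e-6)

    def test_constant_curve_flagged_unidentifiable(self):
        curve = ProgressCurve(np.linspace(0, 10, 8), np.full(8, 0.4))
        fit = fit_single_exponential(curve)
        assert any("unidentifiable" in f for f in fit.flags)
        assert np.isnan(fit.rate)

    def test_short_span_flagged(self):
        t = np.linspace(0.0, 0.05, 6)  # far less than one half-life of 0.1/s
        curve = ProgressCurve(t, np.exp(-0.1 * t))
        fit = fit_single_exponential(curve)
        assert any("span" in f for f in fit.flags)

    def test_noisy_recovery_within_two_se(self, consensus_dataset):
        """Quench-flow style single-exponential recovery across seeds."""
        hits = 0
        for seed in range(40):
            ds = consensus_dataset(seed=seed)
            curves = ds.species("prepause")
            t = curves[0].times
            y = np.mean([c.fractions for c in curves], axis=0)
            fit = fit_single_exponential(
                ProgressCurve(t, np.clip(y, 0, 1), species="prepause")
            )
            hits += abs(fit.rate - ds.truth["k_arrival"]) <= 2 * fit.se["rate"]
        assert hits >= 32  # ~95% nominal, allow sampling slack


class TestDoubleExponential:
    def test_exact_recovery_from_model_class(self):
        t = np.geomspace(0.05, 500.0, 40)
        y = 0.65 * np.exp(-0.2 * t) + 0.15 * np.exp(-0.01 * t)
        fit = fit_double_exponential(ProgressCurve(t, y), from_maximum=False)
        assert fit.a == pytest.approx(0.65, rel=1e-3)
        assert fit.b == pytest.approx(0.15, rel=1e-3)
        assert fit.k_p_app == pytest.approx(0.2, rel=1e-3)
        assert fit.k_sp_app == pytest.approx(0.01, rel=1e-3)
        assert fit.bypass == pytest.approx(0.20, abs=1e-3)

    def test_single_exponential_input_prefers_one_phase(self):
        t = np.geomspace(0.1, 60.0, 30)
        fit = fit_double_exponential(
            ProgressCurve(t, 0.9 * np.exp(-0.2 * t)), from_maximum=False
        )
        assert fit.n_exponentials_preferred == 1
        # the slow phase is degenerate: tiny amplitude or merged rates
        assert fit.b < 0.05 or fit.k_p_app / fit.k_sp_app < 3

    def test_rate_ordering_convention(self, consensus_dataset):
        for seed in (0, 1, 2, 3, 4):
            fit = fit_double_exponential(
                consensus_dataset(seed=seed).species("pause_rna")
            )
            assert fit.k_p_app >= fit.k_sp_app

    def test_close_rates_flagged(self):
        t = np.geomspace(0.1, 100.0, 40)
        y = 0.5 * np.exp(-0.1 * t) + 0.4 * np.exp(-0.05 * t)
        fit = fit_double_exponential(ProgressCurve(t, y), from_maximum=False)
        assert any("identifiability" in f for f in fit.flags)

    def test_requires_enough_points(self):
        with pytest.raises(FitError):
            fit_double_exponential(
                ProgressCurve(np.linspace(1, 5, 5), np.linspace(0.9, 0.5, 5)),
                from_maximum=False,
            )

    def test_consensus_dataset_recovery(self, consensus_dataset):
        ds = consensus_dataset(seed=11)
        fit = fit_double_exponential(ds.species("pause_rna"))
        lo, hi = fit.ci95("a")
        # total pause fraction consistent with the ~80% phenomenology
        total = fit.a + fit.b
        assert 0.7 < total < 0.9
        assert lo <= ds.truth["a"] <= hi


class TestPauseMetrics:
    def _fit(self, a, b, k1, k2):
        cov = np.diag([1e-4, 1e-6, 1e-4, 1e-8])
        return BiexpFit(a=a, b=b, k_p_app=k1, k_sp_app=k2,
                        se={"a": 1e-2, "k_p_app": 1e-3, "b": 1e-2,
                            "k_sp_app": 1e-4},
                        cov=cov, residuals=np.zeros(6),
                        fit_times=np.arange(6.0),
                        n_exponentials_preferred=2, f_test_p=0.0, dof=10)

    def test_pure_pause(self):
        m = pause_metrics(self._fit(1.0, 0.0, 0.2, 0.01))
        assert m.E == pytest.approx(1.0)
        assert m.tau == pytest.approx(5.0)
        assert m.PS == pytest.approx(5.0)

    def test_halving_rate_doubles_pause_strength(self):
        m1 = pause_metrics(self._fit(0.8, 0.0, 0.2, 0.01))
        m2 = pause_metrics(self._fit(0.8, 0.0, 0.1, 0.01))
        assert m2.PS == pytest.approx(2 * m1.PS)

    def test_component_efficiencies_sum(self):
        m = pause_metrics(self._fit(0.65, 0.15, 0.2, 0.01))
        assert m.E == pytest.approx(m.E_a + m.E_b)
        assert m.E == pytest.approx(0.80)

    def test_captured_convention_renormalizes(self):
        m = pause_metrics(self._fit(0.6, 0.2, 0.2, 0.01), convention="captured")
        assert m.convention == "captured"
        assert m.E_a == pytest.approx(0.6)  # t->0 total is 1 by construction

    def test_zero_rate_rejected(self):
        with pytest.raises(FitError):
            pause_metrics(self._fit(0.8, 0.1, 0.0, 0.01))


class TestStoppedFlow:
    def test_noiseless_exact_recovery(self):
        trace = make_stopped_flow(A=0.7, k1_obs=200.0, B=0.3, k2_obs=20.0,
                                  noise_sd=0.0)
        fit = fit_stopped_flow(trace)
        assert fit.A == pytest.approx(0.7, rel=1e-6)
        assert fit.k1_obs == pytest.approx(200.0, rel=1e-6)
        assert fit.B == pytest.approx(0.3, rel=1e-6)
        assert fit.k2_obs == pytest.approx(20.0, rel=1e-6)
        assert fit.translocation_rate == fit.k1_obs

    def test_single_phase_collapse(self):
        trace = make_stopped_flow(A=1.0, k1_obs=100.0, B=0.0, k2_obs=5.0,
                                  noise_sd=0.0)
        fit = fit_stopped_flow(trace)
        # one phase vanishes (by amplitude or by rate -> 0); the surviving
        # phase carries the true rate and full amplitude
        main_rate = fit.k1_obs if fit.A > fit.B else fit.k2_obs
        main_amp = max(fit.A, fit.B)
        T = trace.times[-1]
        minor = min(fit.A * (1 - np.exp(-fit.k1_obs * T)),
                    fit.B * (1 - np.exp(-fit.k2_obs * T)))
        assert main_rate == pytest.approx(100.0, rel=1e-3)
        assert main_amp == pytest.approx(1.0, rel=1e-3)
        assert minor < 1e-3  # the degenerate phase contributes nothing

    def test_translocation_rate_near_200_with_noise(self):
        trace = make_stopped_flow(noise_sd=0.01, seed=4)
        fit = fit_stopped_flow(trace)
        assert fit.k1_obs == pytest.approx(200.0, rel=0.1)


class TestBinding:
    def test_noiseless_exact_recovery(self):
        fit = fit_binding(make_binding_curve(F_max=1.2, K_d=400.0, noise_sd=0.0))
        assert fit.K_d == pytest.approx(400.0, rel=1e-6)
        assert fit.F_max == pytest.approx(1.2, rel=1e-6)
        assert not fit.no_binding

    def test_zero_signal_gives_no_binding_verdict(self):
        fit = fit_binding(make_binding_curve(F_max=0.0, noise_sd=0.02, seed=9))
        assert fit.no_binding

    def test_unidentifiable_design_flagged(self):
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # all << K_d = 400
        fit = fit_binding(make_binding_curve(K_d=400.0, noise_sd=0.0,
                                             concentrations=c))
        assert fit.no_binding or any("unidentifiable" in f for f in fit.flags)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_binding(make_binding_curve(concentrations=np.array([0, 100, 400])))
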