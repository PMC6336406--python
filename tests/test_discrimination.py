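"""Mechanism discrimination: arrival fitting, global fits, residual tests."""

import numpy as np
import pytest

from pausekit import (
    AssayNoiseModel,
    branched_template,
    compare_mechanisms,
    fit_arrival_rates,
    global_fit,
    make_pause_assay,
    make_tandem_dataset,
    residual_randomness,
    tandem_test,
    unbranched_template,
)
from pausekit.fitting import FitError
from pausekit.presets import unbranched_scheme


class TestArrivalRates:
    def test_noiseless_recovery(self):
        ds = make_pause_assay(noise=AssayNoiseModel(sd=0.0, n_replicates=1))
        out = fit_arrival_rates(ds)
        assert out["k_arrival"] == pytest.approx(ds.truth["k_arrival"], rel=1e-3)

    def test_missing_transient_rejected(self):
        ds = make_pause_assay(noise=AssayNoiseModel(sd=0.0, n_replicates=1))
        # drop the pre-pause species entirely
        ds.curves = [c for c in ds.curves if c.species != "prepause"]
        with pytest.raises(FitError, match="pre-pause"):
            fit_arrival_rates(ds)

    def test_data_starting_at_pause_rejected(self):
        ds = make_pause_assay(noise=AssayNoiseModel(sd=0.0, n_replicates=1))
        for c in ds.curves:
            if c.species == "prepause":
                c.fractions = c.fractions * 0.1  # rise already gone
        with pytest.raises(FitError, match="arrival phase absent"):
            fit_arrival_rates(ds)

    def test_estimate_independent_of_downstream_mechanism(self, consensus_dataset):
        """Arrival is identified upstream of the pause branch point."""
        ds_b = consensus_dataset(seed=3)
        ds_u = make_pause_assay(scheme=unbranched_scheme(),
                                noise=AssayNoiseModel(seed=3),
                                pause_states=("C17_pause", "C17_slow"))
        ka_b = fit_arrival_rates(ds_b)["k_arrival"]
        ka_u = fit_arrival_rates(ds_u)["k_arrival"]
        assert ka_b == pytest.approx(10.0, rel=0.05)
        assert ka_u == pytest.approx(10.0, rel=0.05)


class TestResidualRandomness:
    def test_alternating_residuals_flagged_non_random(self):
        e = 0.5 * (-1.0) ** np.arange(40)
        out = residual_randomness(e, seed=0)
        assert out["lag1"] < 0
        assert out["non_random"]
        assert not out["systematic"]  # alternation is not misfit clustering

    def test_monotone_ramp_flagged_systematic(self):
        out = residual_randomness(np.linspace(-1, 1, 30), seed=0)
        assert out["systematic"]

    def test_iid_gaussian_calibration(self):
        """Both statistics stay within their null bands ~95% of the time."""
        rng = np.random.default_rng(123)
        clean = 0
        for i in range(100):
            out = residual_randomness(rng.normal(size=60), seed=i)
            clean += not out["non_random"]
        assert clean >= 93

    def test_too_few_or_degenerate_residuals_rejected(self):
        with pytest.raises(ValueError):
            residual_randomness(np.ones(4))
        with pytest.raises(ValueError):
            residual_randomness(np.ones(20))


class TestGlobalFit:
    def test_matching_template_reaches_noise_floor(self, consensus_dataset):
        ds = consensus_dataset(seed=5)
        fit = global_fit(ds, branched_template(),
                         {"k_arrival": ds.truth["k_arrival"]}, seed=5)
        dof = fit.n_points - 4
        assert 0.5 * dof < fit.weighted_rss < 1.5 * dof

    def test_zero_noise_residuals_vanish(self):
        ds = make_pause_assay(noise=AssayNoiseModel(sd=0.0, n_replicates=3))
        fit = global_fit(ds, branched_template(),
                         {"k_arrival": ds.truth["k_arrival"]}, seed=1)
        # weights hit the SD floor, so scale residuals back to fractions
        assert np.max(np.abs(fit.mean_residuals)) * 5e-3 < 1e-4

    def test_recovers_generating_rates(self, consensus_dataset):
        ds = consensus_dataset(seed=6)
        fit = global_fit(ds, branched_template(),
                         {"k_arrival": ds.truth["k_arrival"]}, seed=6)
        assert fit.params["capture"] == pytest.approx(0.80, abs=0.05)
        assert fit.params["k_slow_escape"] == pytest.approx(0.01, rel=0.5)


class TestCompareMechanisms:
    def test_branched_data_rejects_unbranched(self, consensus_dataset):
        report = compare_mechanisms(
            consensus_dataset(seed=0), unbranched_template(),
            branched_template(), seed=0,
        )
        assert report.verdict == "reject_unbranched"
        assert report.simple_stats["systematic"]
        assert not report.complex_stats["systematic"]

    def test_unbranched_data_cannot_reject(self):
        ds = make_pause_assay(scheme=unbranched_scheme(),
                              noise=AssayNoiseModel(seed=0),
                              pause_states=("C17_pause", "C17_slow"))
        report = compare_mechanisms(ds, unbranched_template(),
                                    branched_template(), seed=0)
        assert report.verdict == "cannot_reject"

    def test_identical_templates_cannot_reject(self, consensus_dataset):
        report = compare_mechanisms(
            consensus_dataset(seed=2), branched_template(),
            branched_template(), seed=2,
        )
        assert report.verdict == "cannot_reject"

    def test_nested_complex_rss_not_worse(self, consensus_dataset):
        ds = consensus_dataset(seed=4)
        report = compare_mechanisms(ds, unbranched_template(),
                                    branched_template(), seed=4)
        assert (report.complex.weighted_rss
                <= report.simple.weighted_rss * (1 + 1e-6) + 1e-6)

    def test_frozen_arrival_identical_in_both_fits(self, consensus_dataset):
        report = compare_mechanisms(
            consensus_dataset(seed=8), unbranched_template(),
            branched_template(), seed=8,
        )
        assert report.simple.frozen == report.complex.frozen == report.frozen

    def test_decision_deterministic_given_seed(self, consensus_dataset):
        ds = consensus_dataset(seed=9)
        r1 = compare_mechanisms(ds, unbranched_template(), branched_template(),
                                seed=9)
        r2 = compare_mechanisms(ds, unbranched_template(), branched_template(),
                                seed=9)
        assert r1.verdict == r2.verdict
        assert r1.simple.weighted_rss == r2.simple.weighted_rss


class TestTandem:
    def test_dynamic_data_rejects_fixed_subpopulation(self):
        ds = make_tandem_dataset("dynamic_partitioning",
                                 noise=AssayNoiseModel(seed=1))
        assert tandem_test(ds, seed=1).verdict == "reject_fixed_subpopulation"

    def test_fixed_data_rejects_dynamic_partitioning(self):
        ds = make_tandem_dataset("fixed_subpopulation",
                                 noise=AssayNoiseModel(seed=1))
        assert tandem_test(ds, seed=1).verdict == "reject_dynamic_partitioning"

    def test_zero_slow_fraction_cannot_reject(self):
        ds = make_tandem_dataset("dynamic_partitioning",
                                 params={"slow_fraction": 1e-3},
                                 noise=AssayNoiseModel(seed=2))
        assert tandem_test(ds, seed=2).verdict == "cannot_reject"

    def test_single_site_data_rejected(self):
        ds = make_tandem_dataset("dynamic_partitioning",
                                 noise=AssayNoiseModel(seed=3))
        ds.curves = [c for c in ds.curves if c.species != "site2"]
        with pytest.raises(FitError, match="both pause sites"):
            tandem_test(ds, seed=3)
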