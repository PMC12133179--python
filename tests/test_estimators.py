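import numpy as np
import pytest

from isokin.bodywater import BodyWaterCurve
from isokin.datasets import (
    NoiseSpec,
    generate_heterogeneity_dataset,
    generate_optimal_dataset,
)
from isokin.estimators import (
    BayesianHeterogeneityFit,
    OneCompartmentFit,
    PrecursorTargetFit,
    bootstrap_ci,
    coverage,
    fit_bayes,
    fit_ml,
    fit_ml_with_ratio,
    percentage_error,
)
from isokin.params import ExplicitHeterogeneityParams, OneCompartmentParams
from isokin.solvers import solve_one_compartment


@pytest.fixture(scope="module")
def optimal_dataset(pt_ensemble, curve):
    return generate_optimal_dataset(pt_ensemble[0], curve, seed=77)


class TestOneCompartmentFit:
    def test_recovers_own_noiseless_parameters(self, curve, daily_times):
        truth = OneCompartmentParams(p=0.008, d_star=0.03)
        y = solve_one_compartment(truth, curve, daily_times)["E"]
        est = OneCompartmentFit(curve=curve, noise=NoiseSpec(scale=0.005), n_starts=10, seed=1)
        est.fit(daily_times, y)
        assert abs(est.p_ - truth.p) / truth.p < 1e-3
        assert abs(est.d_star_ - truth.d_star) / truth.d_star < 1e-3
        assert est.result_.pointwise_loglik.size == daily_times.size

    def test_homogeneous_mode_ties_rates(self, curve, daily_times):
        truth = OneCompartmentParams(p=0.01, d_star=0.01)
        y = solve_one_compartment(truth, curve, daily_times)["E"]
        est = OneCompartmentFit(
            curve=curve, noise=NoiseSpec(scale=0.005), homogeneous=True, n_starts=5, seed=0
        ).fit(daily_times, y)
        assert est.p_ == est.d_star_
        assert est.p_ == pytest.approx(0.01, rel=1e-3)

    def test_deterministic_under_seed(self, optimal_dataset, curve):
        kw = dict(curve=curve, noise=optimal_dataset.noise, n_starts=5, seed=3)
        a = OneCompartmentFit(**kw).fit(optimal_dataset.times, optimal_dataset.observations)
        b = OneCompartmentFit(**kw).fit(optimal_dataset.times, optimal_dataset.observations)
        assert a.p_ == b.p_ and a.d_star_ == b.d_star_

    def test_sklearn_param_interface(self, curve):
        est = OneCompartmentFit(curve=curve, seed=5)
        params = est.get_params()
        assert params["seed"] == 5
        est.set_params(n_starts=7)
        assert est.n_starts == 7


class TestPrecursorTargetFit:
    def test_nested_capacity_beats_one_compartment(self, optimal_dataset, curve):
        # the richer model must attain at least the one-compartment
        # model's likelihood on data it generated
        pt = fit_ml("precursor_target", optimal_dataset, config={"seed": 1, "n_starts": 10})
        oc = fit_ml("one_compartment", optimal_dataset, config={"seed": 1, "n_starts": 20})
        assert pt.diagnostics["nll"] <= oc.diagnostics["nll"] + 1e-6

    def test_collinearity_is_flagged_not_fatal(self, optimal_dataset):
        pt = fit_ml("precursor_target", optimal_dataset, config={"seed": 1, "n_starts": 6})
        assert pt.estimates  # point estimates retained
        assert "identifiable" in pt.diagnostics

    def test_ratio_frozen_variant(self, optimal_dataset, pt_ensemble):
        res = fit_ml_with_ratio(
            optimal_dataset, pt_ensemble[0].ratio_CE, config={"seed": 1, "n_starts": 6}
        )
        assert res.model_id == "precursor_target_ratio"
        assert res.estimates["ratio_CE"] == pytest.approx(pt_ensemble[0].ratio_CE)

    def test_zero_ratio_degenerates_to_one_compartment(self, curve, daily_times):
        # with C/E = 0 all precursor source terms vanish: the target is a
        # closed compartment with rates (p_E, d_E*)
        truth = OneCompartmentParams(p=0.002, d_star=0.01)
        y = solve_one_compartment(truth, curve, daily_times)["E"]
        est = PrecursorTargetFit(
            curve=curve, noise=NoiseSpec(scale=0.005), ratio_CE=0.0, n_starts=8, seed=2
        ).fit(daily_times, y)
        assert est.p_E_ == pytest.approx(truth.p, rel=5e-3)
        assert est.d_E_star_ == pytest.approx(truth.d_star, rel=5e-3)


class TestBootstrap:
    def test_zero_noise_gives_narrow_reproducible_intervals(self, curve, daily_times):
        truth = OneCompartmentParams(p=0.008, d_star=0.03)
        y = solve_one_compartment(truth, curve, daily_times)["E"]
        est = OneCompartmentFit(curve=curve, noise=NoiseSpec(scale=0.005), n_starts=5, seed=1)
        est.fit(daily_times, y)
        ci_a, fail_a = bootstrap_ci(est, daily_times, y, n_boot=30, seed=9)
        ci_b, _ = bootstrap_ci(est, daily_times, y, n_boot=30, seed=9)
        lo, hi = ci_a["p"]
        assert hi - lo < 1e-4 * truth.p  # noiseless data: CI collapses
        assert ci_a == ci_b  # seed determinism
        assert fail_a == 0

    def test_default_resample_count(self):
        import inspect

        assert inspect.signature(bootstrap_ci).parameters["n_boot"].default == 500

    def test_requires_at_least_two_resamples(self, curve, daily_times):
        est = OneCompartmentFit(curve=curve)
        with pytest.raises(ValueError):
            bootstrap_ci(est, daily_times, np.zeros_like(daily_times), n_boot=1)


class TestBayesianFit:
    def test_posterior_concentrates_on_homogeneous_truth(self, curve, weekly_times):
        truth = ExplicitHeterogeneityParams(p=[0.01], alpha=[1.0])
        ds = generate_heterogeneity_dataset(truth, curve, seed=5)
        est = BayesianHeterogeneityFit(
            model="homogeneous", curve=curve, noise=ds.noise,
            n_explore=300, n_steps=1000, n_burn=400, seed=1,
        ).fit(ds.times, ds.observations)
        lo, hi = est.ci_
        assert lo <= 0.01 <= hi
        assert (hi - lo) / 0.01 < 0.1  # tight at sigma = 0.005
        assert est.result_.converged

    def test_implicit_point_estimate_prior_invariant(self, curve):
        truth = ExplicitHeterogeneityParams(p=[0.036, 0.016], alpha=[0.5, 0.5])
        ds = generate_heterogeneity_dataset(truth, curve, seed=8)
        fits = [
            BayesianHeterogeneityFit(
                model="implicit", curve=curve, noise=ds.noise, prior_upper=up,
                n_explore=300, n_steps=1000, n_burn=400, seed=4,
            ).fit(ds.times, ds.observations)
            for up in (1.0, 10.0)
        ]
        rel_shift = abs(fits[1].mean_proliferation_ - fits[0].mean_proliferation_)
        assert rel_shift / fits[0].mean_proliferation_ < 0.05

    def test_pointwise_loglik_shape_and_dispatch(self, curve):
        truth = ExplicitHeterogeneityParams(p=[0.12, 0.0036], alpha=[0.3, 0.7])
        ds = generate_heterogeneity_dataset(truth, curve, seed=2)
        res = fit_bayes(
            "explicit_2", ds,
            config={"n_explore": 200, "n_steps": 600, "n_burn": 200, "seed": 0},
        )
        assert res.model_id == "explicit_2"
        assert res.loglik_draws.shape[1] == len(ds)
        assert res.pointwise_loglik.size == len(ds)
        assert set(res.estimates) >= {"p1", "p2", "alpha1", "mean_proliferation"}


class TestErrorMetrics:
    def test_percentage_error_values(self):
        assert percentage_error(2.0, 1.0) == 100.0
        assert percentage_error(1.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            percentage_error(1.0, 0.0)

    def test_coverage_extremes(self):
        everything = [(-np.inf, np.inf)] * 5
        prop, n = coverage(everything, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert prop == 1.0 and n == 5
        points = [(0.0, 0.0)] * 3
        prop, n = coverage(points, [1.0, 1.0, 1.0])
        assert prop == 0.0 and n == 3
        with pytest.raises(ValueError):
            coverage([], [])
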