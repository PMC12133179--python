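import numpy as np
import pytest
from scipy import stats

from isokin.bodywater import BodyWaterCurve
from isokin.datasets import (
    GRID_ALPHA1,
    GRID_P1,
    GRID_P2,
    LabellingDataset,
    NoiseSpec,
    SamplingBounds,
    generate_heterogeneity_dataset,
    generate_optimal_dataset,
    generate_realistic_dataset,
    heterogeneity_grid,
    sample_precursor_target_params,
    sample_realistic_target_params,
)
from isokin.solvers import (
    solve_explicit_heterogeneity,
    solve_precursor_target,
    solve_realistic_target,
)


class TestParameterSampling:
    def test_reproducible_and_sized(self):
        a = sample_precursor_target_params(100, seed=7)
        b = sample_precursor_target_params(100, seed=7)
        assert len(a) == 100
        assert all(
            x.p_C == y.p_C and x.d_E_star == y.d_E_star for x, y in zip(a, b)
        )

    def test_draws_respect_transformed_bounds(self):
        bounds = SamplingBounds()
        for p in sample_precursor_target_params(200, seed=3):
            assert 1e-4 <= p.p_C <= 1e-2
            assert 1e-4 <= p.p_E <= 1e-2
            assert 1e-2 * p.p_C <= p.r <= p.p_C
            assert 0.0 <= p.k <= 20.0
            assert p.d_C <= p.d_C_star <= 100.0 * p.d_C + 1e-18
            assert p.p_E <= p.d_E <= bounds.delta + 1e-12
            assert p.p_E <= p.d_E_star <= bounds.delta + 1e-12
            assert p.d_E_star > p.d_E  # rejection rule

    def test_k_zero_mode(self):
        assert all(p.k == 0.0 for p in sample_precursor_target_params(20, k_mode="zero", seed=1))

    def test_transformed_marginals_are_uniform(self):
        # Kolmogorov-Smirnov sanity check on the k marginal (untouched by
        # the rejection step) at large n
        draws = sample_precursor_target_params(400, seed=11)
        ks = np.array([p.k for p in draws]) / 20.0
        assert stats.kstest(ks, "uniform").pvalue > 0.01

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError):
            sample_precursor_target_params(5, bounds=SamplingBounds(k=(5.0, 1.0)))

    def test_realistic_sampler_keeps_equilibrium(self):
        for p in sample_realistic_target_params(50, seed=5):
            assert 0.0 <= p.gamma <= 1.0
            assert p.d1 >= p.p1 and p.d2 >= p.p2
            assert p.r <= p.p_C


class TestOptimalDesign:
    def test_daily_sampling_101_points(self, pt_ensemble, curve):
        ds = generate_optimal_dataset(pt_ensemble[0], curve, seed=1)
        assert len(ds) == 101
        assert ds.times[0] == 0.0 and ds.times[-1] == 100.0

    def test_zero_noise_reproduces_model_curve(self, pt_ensemble, curve):
        ds = generate_optimal_dataset(pt_ensemble[0], curve, seed=1, sigma=0.0)
        truth = solve_precursor_target(pt_ensemble[0], curve, ds.times)["E"]
        np.testing.assert_allclose(ds.observations, truth)

    def test_lognormal_noise_scale(self, pt_ensemble, curve):
        # pooled log-residuals across replicates have sd ~ sigma
        logres = []
        for s in range(30):
            ds = generate_optimal_dataset(pt_ensemble[1], curve, seed=s)
            pos = ds.truth_curve > 0
            logres.append(np.log(ds.observations[pos] / ds.truth_curve[pos]))
        sd = np.std(np.concatenate(logres))
        assert sd == pytest.approx(0.005, rel=0.05)

    def test_fixed_seed_bitwise_reproducible(self, pt_ensemble, curve):
        a = generate_optimal_dataset(pt_ensemble[0], curve, seed=42)
        b = generate_optimal_dataset(pt_ensemble[0], curve, seed=42)
        np.testing.assert_array_equal(a.observations, b.observations)


class TestRealisticDesign:
    @pytest.fixture(scope="class")
    def rt_params(self):
        return sample_realistic_target_params(1, seed=9)[0]

    def test_weekly_sampling_15_points(self, rt_params, curve):
        ds = generate_realistic_dataset(rt_params, curve, seed=1)
        assert len(ds) == 15
        np.testing.assert_array_equal(ds.times, np.arange(0.0, 99.0, 7.0))

    def test_noise_sd_is_tenth_of_max(self, rt_params, curve):
        ds = generate_realistic_dataset(rt_params, curve, seed=1)
        assert ds.noise_sd == pytest.approx(0.1 * ds.truth_curve.max())
        residuals = []
        for s in range(200):
            d = generate_realistic_dataset(rt_params, curve, seed=s)
            residuals.append(d.observations - d.truth_curve)
        sd = np.std(np.concatenate(residuals))
        assert sd == pytest.approx(ds.noise_sd, rel=0.05)

    def test_zero_noise_reproduces_mixture_curve(self, rt_params, curve):
        ds = generate_realistic_dataset(rt_params, curve, seed=1, noise_fraction=0.0)
        truth = solve_realistic_target(rt_params, curve, ds.times)["E"]
        np.testing.assert_allclose(ds.observations, truth)


class TestHeterogeneityGrid:
    def test_grid_has_125_combinations(self):
        grid = heterogeneity_grid()
        assert len(grid) == 125

    def test_fast_rate_always_exceeds_slow_rate(self):
        assert all(p.p[0] > p.p[1] for p in heterogeneity_grid())

    def test_membership_by_enumeration(self):
        combos = {(float(g.p[0]), float(g.p[1]), float(g.alpha[0])) for g in heterogeneity_grid()}
        assert (0.0072, 0.0036, 0.1) in combos
        assert not any(p1 == p2 for p1, p2, _ in combos)
        # enumeration oracle: count pairs directly
        n_pairs = sum(1 for p1 in GRID_P1 for p2 in GRID_P2 if p1 > p2)
        assert len(combos) == n_pairs * len(GRID_ALPHA1)

    def test_dataset_weekly_lognormal(self, curve):
        grid = heterogeneity_grid()
        ds = generate_heterogeneity_dataset(grid[0], curve, seed=4)
        assert len(ds) == 15
        assert ds.noise.family == "lognormal"
        exact = generate_heterogeneity_dataset(grid[0], curve, seed=4, sigma=0.0)
        truth = solve_explicit_heterogeneity(grid[0], curve, ds.times)["E"]
        np.testing.assert_allclose(exact.observations, truth)

    def test_default_amplification_factor(self):
        assert BodyWaterCurve().b_w == 4.18


class TestDatasetIO:
    def test_csv_round_trip_with_sidecar(self, pt_ensemble, curve, tmp_path):
        ds = generate_optimal_dataset(pt_ensemble[0], curve, seed=2)
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        assert (tmp_path / "ds.csv.json").exists()
        back = LabellingDataset.from_csv(path)
        np.testing.assert_allclose(back.observations, ds.observations)
        assert back.noise.family == "lognormal"
        assert back.model_id == "precursor_target"
        assert back.curve == curve

    def test_noise_spec_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec(family="poisson")
        with pytest.raises(ValueError):
            NoiseSpec(family="gaussian", scale=-1.0)
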