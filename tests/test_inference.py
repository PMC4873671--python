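"""Three-stage fitting and MCMC uncertainty quantification."""

import numpy as np
import pandas as pd
import pytest

import endokin as ek
from endokin.exceptions import DomainError
from endokin.inference import (
    GridSearchResult,
    grid_axes,
    grid_search,
    run_mcmc,
    steepest_descent,
)

from conftest import random_rates


def naive_error(K, obs, cfg=None):
    """Independent double-loop accumulation of E over compartments and times."""
    cfg = cfg or ek.ModelConfig()
    avg = obs.averaged()
    total = 0.0
    for comp in sorted(avg["compartment"].unique()):
        sub = avg[avg["compartment"] == comp]
        for _, row in sub.iterrows():
            t = np.array([0.0, row["time_s"]]) if row["time_s"] > 0 else np.array([0.0])
            traj = ek.simulate(K, cfg, t)
            pred = traj.x[-1, comp]
            total += (row["value"] - pred) ** 2
    return total


class TestError:
    def test_zero_at_generating_coefficients(self, k_true, noiseless_obs):
        assert ek.error(k_true, noiseless_obs) == pytest.approx(0.0, abs=1e-20)

    def test_single_offset_contributes_delta_squared(self, k_true):
        single, _ = ek.gen_timecourse(
            ek.GeneratorSpec(seed=0, noise_sd=0.0, n_replicates=1)
        )
        delta = 0.037
        df = single.frame.copy()
        df.loc[5, "value"] += delta
        obs = ek.TimeCourseObservations(df)
        assert ek.error(k_true, obs) == pytest.approx(delta**2, rel=1e-10)

    def test_matches_naive_double_loop(self, noisy_obs):
        rng = np.random.default_rng(21)
        for _ in range(3):
            K = random_rates(rng)
            fast = ek.error(K, noisy_obs)
            slow = naive_error(K, noisy_obs)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_replicate_averaging_before_squaring(self, k_true):
        # two replicates symmetric about the prediction: averaged residual is 0
        t = np.arange(0, 301, 60.0)
        traj = ek.simulate(k_true, None, t)
        rows = []
        for comp in (1, 2, 3):
            for rep, offset in ((0, +0.1), (1, -0.1)):
                rows.append(pd.DataFrame({
                    "compartment": comp, "time_s": t,
                    "value": np.clip(traj.x[:, comp] + offset, 0, None),
                    "replicate": rep,
                }))
        obs = ek.TimeCourseObservations(pd.concat(rows, ignore_index=True))
        # clipping only affects points where prediction < 0.1
        assert ek.error(k_true, obs) < 0.1**2 * len(t) * 3

    def test_interpolation_on_supplied_trajectory(self, k_true, noiseless_obs):
        traj = ek.simulate(k_true, None, np.arange(0, 2701, 30.0))
        assert ek.error(k_true, noiseless_obs, traj=traj) == pytest.approx(0.0, abs=1e-12)

    def test_extrapolation_refused(self, k_true, noiseless_obs):
        short = ek.simulate(k_true, None, np.arange(0, 1201, 60.0))
        with pytest.raises(DomainError):
            ek.error(k_true, noiseless_obs, traj=short)


class TestGridSearch:
    def test_axes_span_four_decades(self, k_true):
        axes = grid_axes(k_true, 10)
        for ax, k in zip(axes, k_true.as_array()):
            assert ax[0] == pytest.approx(k / 100)
            assert ax[-1] == pytest.approx(k * 100)
            assert len(ax) == 10

    def test_singleton_grid_returns_seed(self, k_true, noisy_obs):
        res = grid_search(k_true, noisy_obs, n_values=1)
        np.testing.assert_array_equal(res.K1.as_array(), k_true.as_array())
        assert res.n_evaluated == 1

    def test_point_count_is_nvalues_to_the_sixth(self, k_true, noiseless_obs):
        res = grid_search(k_true, noiseless_obs, n_values=2)
        assert res.n_evaluated + res.n_excluded == 2**6

    def test_on_grid_truth_found_exactly(self, k_true, noiseless_obs):
        # n=3 grid has exponents (-2, 0, 2): the seed itself is on the grid
        res = grid_search(k_true, noiseless_obs, n_values=3)
        np.testing.assert_array_equal(res.K1.as_array(), k_true.as_array())
        assert res.E1 == pytest.approx(0.0, abs=1e-20)

    def test_batch_error_agrees_with_scalar_path(self, noisy_obs):
        rng = np.random.default_rng(22)
        res = grid_search(random_rates(rng), noisy_obs, n_values=2)
        assert res.E1 == pytest.approx(ek.error(res.K1, noisy_obs), rel=1e-9)


class TestSteepestDescent:
    def test_fixed_point_at_minimizer(self, k_true, noiseless_obs):
        res = steepest_descent(k_true, noiseless_obs)
        np.testing.assert_allclose(
            res.K_fit.as_array(), k_true.as_array(), rtol=1e-6
        )

    def test_recovery_from_perturbed_start(self, k_true, noiseless_obs):
        start = ek.RateCoefficientSet.from_array(
            k_true.as_array() * [1.5, 1.5, 1.5, 1.5, 1.0, 1.0]
        )
        res = steepest_descent(start, noiseless_obs)
        rel = np.abs(res.K_fit.as_array()[:4] / k_true.as_array()[:4] - 1)
        assert rel.max() < 0.01

    def test_short_circuits_held_fixed_by_default(self, k_true, noiseless_obs):
        start = ek.RateCoefficientSet.from_array(
            k_true.as_array() * [1.5, 1.5, 1.5, 1.5, 1.0, 1.0]
        )
        res = steepest_descent(start, noiseless_obs)
        assert res.K_fit.k10 == start.k10
        assert res.K_fit.k20 == start.k20

    def test_free_descent_drives_short_circuits_toward_zero(self, k_true):
        # data with no short-circuit flux at all: freeing k10/k20 pushes them
        # to the non-negativity boundary instead of a meaningful value
        K_no_sc = k_true.replace(k10=0.0, k20=0.0)
        obs, _ = ek.gen_timecourse(
            ek.GeneratorSpec(K_true=K_no_sc, seed=31, noise_sd=0.0)
        )
        start = K_no_sc.replace(k10=5e-4, k20=5e-4)
        res = steepest_descent(
            start, obs, free=ek.RateCoefficientSet.ORDER, max_iter=300
        )
        assert res.K_fit.k10 < start.k10
        assert res.K_fit.k20 < start.k20
        assert res.K_fit.k10 >= 0 and res.K_fit.k20 >= 0

    def test_error_never_increases(self, ongrid_k0, noisy_obs):
        res = steepest_descent(ongrid_k0, noisy_obs)
        assert res.E_fit <= ek.error(ongrid_k0, noisy_obs)


class TestFitPipeline:
    def test_stage_monotonicity(self, noisy_fit):
        assert noisy_fit.E_fit <= noisy_fit.E1 <= noisy_fit.E0

    def test_noiseless_recovery_within_one_percent(self, k_true, ongrid_k0, noiseless_obs):
        fit = ek.fit_pipeline(ongrid_k0, noiseless_obs, n_values=6)
        # the grid point holding the truth is selected (equal up to the float
        # round-trip of the grid construction itself)
        np.testing.assert_allclose(
            fit.K1.as_array(), k_true.as_array(), rtol=1e-12
        )
        assert fit.E1 < 1e-20
        rel = np.abs(fit.K_fit.as_array()[:4] / k_true.as_array()[:4] - 1)
        assert rel.max() < 0.01

    def test_deterministic(self, ongrid_k0, noisy_obs, noisy_fit):
        again = ek.fit_pipeline(ongrid_k0, noisy_obs, n_values=6)
        np.testing.assert_array_equal(
            again.K_fit.as_array(), noisy_fit.K_fit.as_array()
        )
        assert again.E_fit == noisy_fit.E_fit


class TestMCMC:
    def test_frozen_chain_with_zero_proposal(self, noisy_fit, noisy_obs):
        ens = run_mcmc(noisy_fit, noisy_obs, n_iter=500, seed=1, proposal_scale=0.0)
        assert np.ptp(ens.samples, axis=0).max() == 0.0
        np.testing.assert_allclose(
            ens.samples[0], noisy_fit.K_fit.as_array()[:4]
        )

    def test_seeded_reproducibility(self, noisy_fit, noisy_obs):
        a = run_mcmc(noisy_fit, noisy_obs, n_iter=2000, seed=42)
        b = run_mcmc(noisy_fit, noisy_obs, n_iter=2000, seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_ci_stable_with_tenfold_longer_chain(self, noisy_fit, noisy_obs):
        short = ek.credible_intervals(run_mcmc(noisy_fit, noisy_obs, n_iter=10000, seed=2))
        long = ek.credible_intervals(run_mcmc(noisy_fit, noisy_obs, n_iter=100000, seed=3))
        for name in short:
            for a, b in zip(short[name], long[name]):
                assert abs(a / b - 1) < 0.10

    def test_samples_nonnegative_and_centred_near_fit(self, noisy_fit, noisy_obs):
        ens = run_mcmc(noisy_fit, noisy_obs, n_iter=5000, seed=4)
        assert ens.samples.min() >= 0
        med = np.median(ens.samples, axis=0)
        np.testing.assert_allclose(med, noisy_fit.K_fit.as_array()[:4], rtol=0.15)


class TestCredibleIntervals:
    def test_constant_samples_zero_width(self, noisy_fit):
        ens = ek.PosteriorEnsemble(
            samples=np.full((200, 4), 0.003), param_names=("k01", "k12", "k23", "k30"),
            K_ref=noisy_fit.K_fit, acceptance_rate=0.0, n_iter=200, burn_in=0,
            sigma2=1.0,
        )
        ci = ek.credible_intervals(ens)
        assert all(lo == hi == 0.003 for lo, hi in ci.values())

    def test_uniform_percentile_oracle(self, noisy_fit):
        rng = np.random.default_rng(23)
        a, b = 0.001, 0.005
        samples = rng.uniform(a, b, size=(200000, 4))
        ens = ek.PosteriorEnsemble(
            samples=samples, param_names=("k01", "k12", "k23", "k30"),
            K_ref=noisy_fit.K_fit, acceptance_rate=1.0, n_iter=200000, burn_in=0,
            sigma2=1.0,
        )
        ci = ek.credible_intervals(ens)
        width = b - a
        for lo, hi in ci.values():
            assert lo == pytest.approx(a + 0.025 * width, abs=0.02 * width)
            assert hi == pytest.approx(b - 0.025 * width, abs=0.02 * width)
        # bounds always inside the sample range
        assert all(
            samples[:, i].min() <= ci[n][0] and ci[n][1] <= samples[:, i].max()
            for i, n in enumerate(ens.param_names)
        )

    def test_too_few_samples_refused(self, noisy_fit):
        ens = ek.PosteriorEnsemble(
            samples=np.full((50, 4), 0.003), param_names=("k01", "k12", "k23", "k30"),
            K_ref=noisy_fit.K_fit, acceptance_rate=0.0, n_iter=50, burn_in=0,
            sigma2=1.0,
        )
        with pytest.raises(DomainError):
            ek.credible_intervals(ens)


class TestPredictiveEnvelope:
    def test_degenerate_ensemble_collapses_to_single_trajectory(self, noisy_fit, noisy_obs):
        ens = run_mcmc(noisy_fit, noisy_obs, n_iter=500, seed=5, proposal_scale=0.0)
        env = ek.predictive_envelope(ens)
        np.testing.assert_allclose(env.lower, env.upper)
        traj = ek.simulate(noisy_fit.K_fit, None, env.times)
        np.testing.assert_allclose(env.lower, traj.x.T, rtol=1e-10)

    def test_contains_posterior_median_trajectory(self, noisy_fit, noisy_obs):
        ens = run_mcmc(noisy_fit, noisy_obs, n_iter=5000, seed=6)
        env = ek.predictive_envelope(ens)
        med = noisy_fit.K_fit.replace(
            **dict(zip(ens.param_names, np.median(ens.samples, axis=0)))
        )
        traj = ek.simulate(med, None, env.times)
        assert np.all(traj.x.T >= env.lower - 1e-9)
        assert np.all(traj.x.T <= env.upper + 1e-9)

    def test_band_shrinks_with_quieter_data(self, k_true):
        start = ek.RateCoefficientSet.from_array(
            k_true.as_array() * [1.2, 0.9, 1.1, 0.8, 1.0, 1.0]
        )
        widths = []
        for sd in (0.05, 0.0125):
            obs, _ = ek.gen_timecourse(ek.GeneratorSpec(seed=77, noise_sd=sd))
            descent = steepest_descent(start, obs)
            E0 = ek.error(start, obs)
            fit = ek.FitResult(
                K0=start, K1=start, K_fit=descent.K_fit,
                E0=E0, E1=E0, E_fit=descent.E_fit,
                grid=GridSearchResult(K1=start, E1=E0, n_values=1,
                                      n_evaluated=1, n_excluded=0),
                descent=descent,
            )
            ens = run_mcmc(fit, obs, n_iter=5000, seed=7)
            env = ek.predictive_envelope(ens)
            widths.append(float(np.mean(env.upper - env.lower)))
        assert widths[1] < widths[0]
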