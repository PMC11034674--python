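"""Grid search, bootstrap, joint fit, and the blocked-design sensitivity bias."""

import numpy as np
import pytest

from adaptlab import (
    GridSpec,
    ModelParams,
    bootstrap_alpha_beta,
    estimate_error_sensitivity_blocked,
    fit_correction_jointly,
    gen_experiment,
    grid_fit,
    make_albert_exp6_schedule,
    run_model,
    series_from_trials,
    simulate_cohort,
    sse_objective,
)
from adaptlab.model_fitting import ParticipantSeries, _grid_sse
from adaptlab.synthetic_data import GeneratorConfig

SMALL_GRID = GridSpec((0.8, 1.0, 0.02), (0.0, 0.2, 0.02), (3.0, 5.0, 0.25))


def make_series(truth, engine, n=6, seed=0, **engine_kwargs):
    """Noise-free clamp-training series from a known generating engine."""
    params = ModelParams(engine=engine, motor_noise_sd=0.0, **engine_kwargs)
    out = []
    for i in range(n):
        sched = make_albert_exp6_schedule("high", seed=seed + i)
        # use the clamp error semantics for fitting: feed the schedule's
        # perturbations as experienced errors via a clamp design
        from adaptlab.simulator import Schedule, Trial

        clamp = Schedule(
            [Trial("training", "clamp", t.perturbation, t.target) for t in sched.trials[40:280]]
        )
        trace = run_model(clamp, params, truth)
        out.append(ParticipantSeries(f"p{i}", clamp.perturbations, trace.y))
    return out


class TestSSEObjective:
    def test_zero_at_generating_point(self, truth):
        """Hybrid-generated noise-free data has SSE 0 at its own parameters."""
        data = make_series(truth, "hybrid", alpha=0.9, beta=0.06, sim_scale=4.0)
        assert sse_objective((0.9, 0.06, 4.0), data, truth) == pytest.approx(0.0, abs=1e-12)

    def test_truth_beats_grid_neighbours(self, truth):
        data = make_series(truth, "hybrid", alpha=0.9, beta=0.06, sim_scale=4.0)
        best = sse_objective((0.9, 0.06, 4.0), data, truth)
        for d_alpha, d_beta, d_k in [(0.02, 0, 0), (0, 0.02, 0), (0, 0, 0.25), (-0.02, 0, 0)]:
            neighbour = (0.9 + d_alpha, 0.06 + d_beta, 4.0 + d_k)
            assert sse_objective(neighbour, data, truth) > best

    def test_participant_order_invariant(self, truth):
        data = make_series(truth, "moe", b0=0.037, alpha=0.95, beta=0.05)
        fwd = sse_objective((0.5, 0.1, 2.0), data, truth)
        rev = sse_objective((0.5, 0.1, 2.0), data[::-1], truth)
        assert fwd == rev

    def test_nan_rows_skipped(self, truth):
        data = make_series(truth, "hybrid", alpha=0.9, beta=0.06, sim_scale=4.0, n=2)
        data[0].y[5] = np.nan
        assert np.isfinite(sse_objective((0.9, 0.06, 4.0), data, truth))


class TestGridFit:
    def test_recovers_hybrid_truth_within_one_step(self, truth):
        data = make_series(truth, "hybrid", alpha=0.9, beta=0.06, sim_scale=4.0, n=4)
        result = grid_fit(data, truth, SMALL_GRID)
        assert abs(result.alpha - 0.9) <= 0.02
        assert abs(result.beta - 0.06) <= 0.02
        assert abs(result.k - 4.0) <= 0.25

    def test_nlmc_truth_yields_zero_beta(self, truth):
        """History-free data needs no sensitivity modulation: beta = 0."""
        data = make_series(truth, "nlmc", sim_scale=4.0, n=4)
        result = grid_fit(data, truth, SMALL_GRID)
        assert result.beta == 0.0

    def test_single_point_grid(self, truth):
        data = make_series(truth, "nlmc", sim_scale=4.0, n=2)
        spec = GridSpec((0.5, 0.5, 1.0), (0.1, 0.1, 1.0), (2.0, 2.0, 1.0))
        result = grid_fit(data, truth, spec)
        assert (result.alpha, result.beta, result.k) == (0.5, 0.1, 2.0)

    def test_exhaustive_matches_brute_force(self, truth):
        """The vectorized grid evaluation equals naive per-point re-evaluation."""
        data = make_series(truth, "moe", n=2, b0=0.037, alpha=0.95, beta=0.05)
        spec = GridSpec((0.0, 1.0, 0.1), (0.0, 0.2, 0.04), (1.0, 5.0, 1.0))
        aa, ba, ka = spec.axes()
        flat, shape = _grid_sse(data, aa, ba, ka, truth, 0.945, 3.0)
        brute = np.empty(shape)
        for i, al in enumerate(aa):
            for j, be in enumerate(ba):
                for m, k in enumerate(ka):
                    brute[i, j, m] = sse_objective((al, be, k), data, truth)
        np.testing.assert_allclose(flat.reshape(shape), brute, rtol=1e-12)

    def test_coarse_fine_agrees_with_exhaustive(self, truth):
        data = make_series(truth, "hybrid", alpha=0.9, beta=0.06, sim_scale=4.0, n=3)
        exact = grid_fit(data, truth, SMALL_GRID, mode="exhaustive")
        two_stage = grid_fit(data, truth, SMALL_GRID, mode="coarse_fine")
        assert (two_stage.alpha, two_stage.beta, two_stage.k) == (
            exact.alpha,
            exact.beta,
            exact.k,
        )

    def test_empty_data_rejected(self, truth):
        with pytest.raises(ValueError):
            grid_fit([], truth)


class TestBootstrap:
    def test_identity_resampling_reproduces_point_fit(self, truth):
        data = make_series(truth, "nlmc", sim_scale=4.0, n=4)
        point = grid_fit(
            data, truth, GridSpec((0.0, 1.0, 0.05), (0.0, 0.2, 0.02), (4.0, 4.0, 1.0))
        )
        boot = bootstrap_alpha_beta(
            data,
            truth,
            k=4.0,
            n_resamples=3,
            seed=0,
            alpha_axis_spec=(0.0, 1.0, 0.05),
            beta_axis_spec=(0.0, 0.2, 0.02),
            identity=True,
        )
        assert np.all(boot.alphas == point.alpha)
        assert np.all(boot.betas == point.beta)

    def test_deterministic_given_seed(self, truth):
        data = make_series(truth, "nlmc", sim_scale=4.0, n=4)
        kwargs = dict(
            k=4.0,
            n_resamples=10,
            alpha_axis_spec=(0.0, 1.0, 0.1),
            beta_axis_spec=(0.0, 0.2, 0.04),
        )
        b1 = bootstrap_alpha_beta(data, truth, seed=5, **kwargs)
        b2 = bootstrap_alpha_beta(data, truth, seed=5, **kwargs)
        np.testing.assert_array_equal(b1.alphas, b2.alphas)
        np.testing.assert_array_equal(b1.betas, b2.betas)

    def test_nlmc_truth_bootstrap_beta_zero(self, truth):
        """History-free cohorts: the modulation rate comes back 0 in (nearly)
        every resample, while alpha is unidentified and spreads."""
        data = make_series(truth, "nlmc", sim_scale=4.0, n=8)
        boot = bootstrap_alpha_beta(
            data,
            truth,
            k=4.0,
            n_resamples=50,
            seed=1,
            alpha_axis_spec=(0.0, 1.0, 0.05),
            beta_axis_spec=(0.0, 0.2, 0.02),
        )
        assert np.mean(boot.betas == 0.0) >= 0.95


class TestJointFit:
    def test_recovers_correction_curve_and_zero_beta(self, truth):
        """End-to-end: noise-free clamp cohorts generated with beta = 0 give
        back the correction curve (10% RMS over 0-45 deg) and beta = 0."""
        from adaptlab.correction_function import motor_correction

        config = GeneratorConfig(
            n_per_condition=2, motor_noise_sd=0.0, invalid_rate=0.0, noncompliant_rate=0.0,
            seed=3,
        )
        frames = []
        for design in ("exp1", "exp2"):
            params = ModelParams(engine="hybrid", beta=0.0, sim_scale=3.0, motor_noise_sd=0.0)
            df, _ = gen_experiment(design, params, config, truth)
            frames.append(df)
        import pandas as pd

        data = series_from_trials(pd.concat(frames, ignore_index=True))
        result = fit_correction_jointly(
            data,
            grid=GridSpec((0.9, 0.9, 1.0), (0.0, 0.1, 0.05), (2.0, 4.0, 0.25)),
            seed=0,
            n_restarts=2,
            maxiter=20,
        )
        assert result.fit.beta == 0.0
        e = np.linspace(0.5, 45, 90)
        m_true = motor_correction(e, truth)
        # the product k*M is what the data constrain; compare on that scale
        m_fit = motor_correction(e, result.correction) * result.fit.k / 3.0
        rms = np.sqrt(np.mean((m_fit - m_true) ** 2)) / np.sqrt(np.mean(m_true**2))
        assert rms < 0.10

    def test_history_is_monotone_nonincreasing(self, truth):
        data = make_series(truth, "nlmc", sim_scale=3.0, n=2)
        result = fit_correction_jointly(
            data,
            grid=GridSpec((0.9, 0.9, 1.0), (0.0, 0.05, 0.05), (2.0, 4.0, 1.0)),
            seed=1,
            n_restarts=2,
            maxiter=15,
        )
        assert all(b <= a + 1e-12 for a, b in zip(result.sse_history, result.sse_history[1:]))


class TestBlockedSensitivityEstimate:
    def test_exact_without_noise(self, truth):
        """Noise-free constant-sensitivity traces recover b exactly."""
        params = ModelParams(engine="moe", beta=0.0, b0=0.05, motor_noise_sd=0.0)
        factory = lambda s: make_albert_exp6_schedule("zero", s)
        _, traces = simulate_cohort(factory, params, None, 3, seed=0)
        est = estimate_error_sensitivity_blocked(traces, a=0.945)
        assert len(est) > 0
        np.testing.assert_allclose(est["b_hat"], 0.05, atol=1e-6)

    def test_zero_variance_condition_inflated_by_noise(self, truth):
        """Identical true sensitivity in both conditions: motor noise inflates
        the naive estimate selectively in the zero-variance condition."""
        params = ModelParams(engine="nlmc", sim_scale=4.0, motor_noise_sd=3.0)
        diffs = []
        for c in range(25):
            out = {}
            for variance in ("zero", "high"):
                factory = lambda s, v=variance: make_albert_exp6_schedule(v, s)
                _, traces = simulate_cohort(factory, params, truth, 10, seed=1000 * c + hash(variance) % 97)
                out[variance] = estimate_error_sensitivity_blocked(traces, a=0.945)
            merged = out["zero"].merge(out["high"], on="bin", suffixes=("_z", "_h"))
            merged = merged[(merged["n_z"] >= 10) & (merged["n_h"] >= 10)]
            diffs.append((merged["b_hat_z"] - merged["b_hat_h"]).mean())
        diffs = np.array(diffs)
        assert diffs.mean() > 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_bias_shrinks_with_noise(self, truth):
        """The inflation vanishes as motor noise goes to zero."""
        bias = {}
        for sd in (0.0, 1.0, 3.0):
            params = ModelParams(engine="nlmc", sim_scale=4.0, motor_noise_sd=sd)
            factory = lambda s: make_albert_exp6_schedule("zero", s)
            _, traces = simulate_cohort(factory, params, truth, 20, seed=3)
            est = estimate_error_sensitivity_blocked(traces, a=0.945)
            est = est[est["n"] >= 40]
            true_b = np.array(
                [
                    4.0
                    * float(
                        __import__("adaptlab").motor_correction(c, truth) / c
                    )
                    for c in est["bin_center"]
                ]
            )
            bias[sd] = float((est["b_hat"] - true_b).abs().mean())
        assert bias[0.0] < 0.01
        assert bias[0.0] < bias[1.0] < bias[3.0]
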