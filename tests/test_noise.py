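"""Probe statistics, CV~mean LOWESS fit and changepoint estimation."""

import numpy as np
import pandas as pd
import pytest

from torpormir import (
    ArrayConfig,
    ExpressionMatrix,
    compute_probe_stats,
    estimate_noise_floor,
    estimate_system_noise,
    fit_cv_mean,
    generate_array,
)
from torpormir.noise import NoLinearRegimeError, plot_cv_mean


def _matrix(values, n_acr=2):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.index = [f"p{i}" for i in range(len(df))]
    n = df.shape[1]
    cols = [f"s{j}" for j in range(n)]
    df.columns = cols
    groups = pd.Series(["ACR"] * n_acr + ["LH"] * (n - n_acr), index=cols)
    return ExpressionMatrix(values=df, groups=groups)


class TestComputeProbeStats:
    def test_constant_probe_has_zero_cv(self):
        stats = compute_probe_stats(_matrix([[5, 5, 5, 5]]))
        assert stats["cv"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        # values (1, 3): mean 2, sd sqrt(2) (n-1), cv sqrt(2)/2
        stats = compute_probe_stats(_matrix([[1, 3, 1, 3]]))
        row = stats.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        # 4 values (1,3,1,3): sd = sqrt(4/3)
        assert row["sd"] == pytest.approx(np.sqrt(4 / 3))
        assert row["cv"] == pytest.approx(np.sqrt(4 / 3) / 2)

    def test_two_sample_hand_case(self):
        m = ExpressionMatrix(
            values=pd.DataFrame({"a": [1.0], "b": [3.0]}, index=["p"]),
            groups=pd.Series(["g", "g"], index=["a", "b"]),
        )
        row = compute_probe_stats(m).iloc[0]
        assert row["sd"] == pytest.approx(np.sqrt(2))
        assert row["cv"] == pytest.approx(np.sqrt(2) / 2)

    def test_zero_mean_flagged_undefined(self):
        stats = compute_probe_stats(_matrix([[0, 0, 0, 0]]))
        assert not stats["cv_defined"].iloc[0]
        assert np.isnan(stats["cv"].iloc[0])

    def test_matches_bruteforce_loop(self, rng):
        vals = rng.uniform(1, 100, size=(40, 6))
        stats = compute_probe_stats(_matrix(vals, n_acr=3))
        for i in range(40):
            assert stats["mean"].iloc[i] == pytest.approx(vals[i].mean())
            assert stats["sd"].iloc[i] == pytest.approx(vals[i].std(ddof=1))
            assert stats["cv"].iloc[i] == pytest.approx(
                vals[i].std(ddof=1) / vals[i].mean()
            )

    def test_sample_permutation_invariant(self, small_array):
        m, _ = small_array
        perm = list(m.sample_ids[::-1])
        m2 = ExpressionMatrix(values=m.values[perm], groups=m.groups[perm])
        pd.testing.assert_frame_equal(
            compute_probe_stats(m), compute_probe_stats(m2)
        )


def _stats_frame(means, cvs):
    means = np.asarray(means, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    return pd.DataFrame(
        {"mean": means, "sd": cvs * means, "cv": cvs,
         "cv_defined": np.ones(len(means), bool)},
        index=[f"p{i}" for i in range(len(means))],
    )


class TestFitCvMean:
    def test_constant_cv_fitted_exactly(self, rng):
        means = rng.uniform(1, 1000, 500)
        grid, fitted = fit_cv_mean(_stats_frame(means, np.full(500, 0.3)))
        assert np.all(np.abs(fitted - 0.3) < 1e-6)

    def test_linear_in_log_mean_recovered(self, rng):
        means = np.exp(rng.uniform(0, 6, 2000))
        cv = 0.8 - 0.1 * np.log(means)
        grid, fitted = fit_cv_mean(_stats_frame(means, cv))
        expected = 0.8 - 0.1 * np.log(grid)
        interior = slice(10, -10)
        assert np.all(
            np.abs(fitted[interior] - expected[interior])
            <= 0.01 * np.abs(expected[interior])
        )

    def test_synthetic_array_shape(self):
        m, truth = generate_array(ArrayConfig(n_probes=3000, seed=4))
        grid, fitted = fit_cv_mean(compute_probe_stats(m))
        nu = truth.noise_floor
        below = fitted[grid < 0.6 * nu]
        above = fitted[grid > 2 * nu]
        # decreasing below the floor, flat above it
        assert below[0] > below[-1] > above.mean()
        assert np.ptp(above) < 0.12

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match=">=50"):
            fit_cv_mean(_stats_frame([1, 2, 3], [0.1, 0.1, 0.1]))

    def test_nonfinite_rejected(self, rng):
        s = _stats_frame(rng.uniform(1, 10, 60), np.full(60, 0.2))
        s.loc["p0", "cv"] = np.inf
        with pytest.raises(ValueError, match="finite"):
            fit_cv_mean(s)


def _suffix_oracle(grid, fitted, tau, min_fraction):
    """Exhaustive search over all terminal runs (independent of the
    implementation's incremental scan)."""
    slopes = np.gradient(fitted, np.log(grid))
    band = tau * np.max(np.abs(slopes))
    n = len(grid)
    candidates = []
    for start in range(n - 1):
        suffix = slopes[start:]
        if np.all(np.abs(suffix - np.median(suffix)) <= band):
            candidates.append(start)
    if not candidates:
        return None
    best = min(candidates)  # longest terminal run
    if n - best < int(np.ceil(min_fraction * n)):
        return None
    return best


class TestEstimateSystemNoise:
    def test_constant_curve_floor_at_grid_min(self):
        grid = np.exp(np.linspace(0, 5, 60))
        model = estimate_system_noise(grid, np.full(60, 0.2))
        assert model.linear_suffix_start == 0
        assert model.noise_floor == pytest.approx(grid[0])

    def test_piecewise_hyperbolic_then_constant(self):
        # analytic curve: cv = 0.15 * (50/mean) below 50, 0.15 above
        grid = np.exp(np.linspace(np.log(5), np.log(5000), 200))
        cv = 0.15 * np.maximum(1.0, 50.0 / grid)
        model = estimate_system_noise(grid, cv)
        assert 50 * 0.8 < model.noise_floor < 50 * 1.25

    def test_matches_exhaustive_oracle_on_small_grids(self, rng):
        for trial in range(30):
            n = int(rng.integers(8, 31))
            grid = np.exp(np.linspace(0.0, 4.0, n))
            # random smooth-ish decreasing curve plus noise
            curve = np.exp(-np.linspace(0, rng.uniform(1, 5), n))
            curve += rng.normal(0, 0.02, n)
            tau = float(rng.uniform(0.05, 0.4))
            oracle = _suffix_oracle(grid, curve, tau, 0.25)
            if oracle is None:
                with pytest.raises(NoLinearRegimeError):
                    estimate_system_noise(grid, curve, slope_tolerance=tau)
            else:
                model = estimate_system_noise(grid, curve, slope_tolerance=tau)
                assert model.linear_suffix_start == oracle

    def test_no_linear_regime_raises_informative_error(self):
        grid = np.exp(np.linspace(0, 4, 50))
        cv = 1.0 / grid  # hyperbola everywhere
        with pytest.raises(NoLinearRegimeError, match="slope_tolerance"):
            estimate_system_noise(grid, cv, slope_tolerance=0.01)

    def test_snap_to_observed_mean(self):
        grid = np.exp(np.linspace(0, 5, 60))
        model = estimate_system_noise(
            grid, np.full(60, 0.2), observed_means=np.array([0.5, 1.7, 9.0])
        )
        # grid min is 1.0; nearest observed mean at or above is 1.7
        assert model.noise_floor == pytest.approx(1.7)
        assert model.noise_floor_grid == pytest.approx(1.0)

    def test_roundtrip_json(self, tmp_path):
        grid = np.exp(np.linspace(0, 5, 60))
        model = estimate_system_noise(grid, np.full(60, 0.2))
        p = tmp_path / "nm.json"
        model.save(p)
        from torpormir import NoiseModel

        loaded = NoiseModel.load(p)
        assert loaded.noise_floor == model.noise_floor
        np.testing.assert_allclose(loaded.fitted_cv, model.fitted_cv)


class TestEndToEndFloor:
    def test_scale_equivariance(self, small_array):
        m, _ = small_array
        nu1 = estimate_noise_floor(m).noise_floor
        nu7 = estimate_noise_floor(m.scaled(7.0)).noise_floor
        assert nu7 == pytest.approx(7.0 * nu1, rel=1e-9)

    def test_floor_recovered_on_planted_array(self):
        ests = [
            estimate_noise_floor(
                generate_array(ArrayConfig(n_probes=2000, noise_floor=50.0,
                                           seed=s))[0]
            ).noise_floor
            for s in range(5)
        ]
        assert 0.75 * 50 < np.median(ests) < 1.25 * 50

    def test_diagnostic_plot_written(self, small_array, tmp_path):
        m, _ = small_array
        model = estimate_noise_floor(m)
        out = plot_cv_mean(compute_probe_stats(m), model, tmp_path / "cv.png")
        assert out.exists() and out.stat().st_size > 0
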