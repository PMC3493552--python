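"""Sigma estimation, normality testing, and Monte-Carlo empirical p-values."""

import math
import subprocess

import numpy as np
import pytest

from acedrift import (CopyingErrorSample, anderson_darling_normality,
                      empirical_p_value, estimate_sigma, expected_variance,
                      final_chain_stats, simulate_ensemble)
from acedrift import SyntheticDesign, generate_experiment


def _sample(ratios, condition="larger"):
    ratios = np.asarray(ratios, dtype=float)
    return CopyingErrorSample(ratios=ratios,
                              conditions=np.full(ratios.size, condition))


class TestEstimateSigma:
    def test_sample_sd_arithmetic(self):
        out = estimate_sigma(_sample([1.02, 1.00, 0.98]))
        assert out["larger"] == pytest.approx(0.02)

    def test_constant_ratios_give_zero(self):
        assert estimate_sigma(_sample([1.0] * 10))["larger"] == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            estimate_sigma(_sample([1.0]))

    def test_pooled_scope_reports_both_candidates(self, null_records):
        from acedrift import compute_copying_errors
        sample = compute_copying_errors(null_records)
        pooled = estimate_sigma(sample, scope="pooled")
        per = estimate_sigma(sample, scope="per_condition")
        assert set(pooled) == {"sd_all_ratios", "mean_of_condition_sds"}
        assert pooled["mean_of_condition_sds"] == pytest.approx(
            (per["larger"] + per["smaller"]) / 2)
        # unbiased generation: both summaries sit near the true sigma
        for value in pooled.values():
            assert value == pytest.approx(0.0343, rel=0.25)


class TestAndersonDarling:
    def test_matches_brute_force_sum_formula(self):
        # independent oracle: plain-python evaluation of the A^2 sum
        from scipy.stats import norm
        x = np.sort(np.random.default_rng(3).normal(size=100))
        n = x.size
        z = (x - x.mean()) / x.std(ddof=1)
        total = 0.0
        for i in range(1, n + 1):
            total += (2 * i - 1) * (math.log(norm.cdf(z[i - 1]))
                                    + math.log(1 - norm.cdf(z[n - i])))
        a2_oracle = -n - total / n
        result = anderson_darling_normality(x)
        assert result.statistic == pytest.approx(a2_oracle, abs=1e-10)

    def test_matches_r_nortest(self, tmp_path):
        # cross-implementation check against R's nortest::ad.test
        x = np.random.default_rng(17).normal(loc=1.0, scale=0.03, size=100)
        data = tmp_path / "x.txt"
        np.savetxt(data, x)
        script = (f'x <- scan("{data}", quiet=TRUE); r <- nortest::ad.test(x); '
                  f'cat(sprintf("%.12f %.12f", r$statistic, r$p.value))')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        a_r, p_r = float(out[0]), float(out[1])
        res = anderson_darling_normality(x)
        assert res.statistic == pytest.approx(a_r, abs=1e-9)
        assert res.p_value == pytest.approx(p_r, abs=1e-9)

    def test_rejects_tiny_or_constant_samples(self):
        with pytest.raises(ValueError):
            anderson_darling_normality(np.ones(7))
        with pytest.raises(ValueError):
            anderson_darling_normality(np.ones(50))

    def test_null_rejection_rate_is_calibrated(self):
        # at n=100, the 5%-level rejection rate over 1000 null samples
        rng = np.random.default_rng(99)
        rejections = sum(
            anderson_darling_normality(rng.normal(size=100)).p_value < 0.05
            for _ in range(1000))
        assert abs(rejections / 1000 - 0.05) <= 0.02

    def test_detects_gross_non_normality(self):
        rng = np.random.default_rng(5)
        res = anderson_darling_normality(rng.exponential(size=100))
        assert res.p_value < 1e-4


class TestFinalChainStats:
    def test_zero_sigma_experiment(self):
        exp = generate_experiment(SyntheticDesign(sigma=0.0, seed=0))
        mean, var = final_chain_stats(exp.records, "larger")
        assert (mean, var) == (10.0, 0.0)

    def test_single_chain_variance_undefined(self):
        exp = generate_experiment(SyntheticDesign(sigma=0.01, seed=0,
                                                  n_chains_per_condition=1))
        with pytest.raises(ValueError):
            final_chain_stats(exp.records, "larger")

    def test_incomplete_chain_is_reported(self, null_records):
        truncated = [r for r in null_records
                     if not (r.chain_id == "l01" and r.generation == 10)]
        with pytest.raises(ValueError, match="l01"):
            final_chain_stats(truncated, "larger")

    def test_ensemble_input(self):
        ens = simulate_ensemble(10.0, 0.05, 100, 10, seed=1)
        mean, var = final_chain_stats(ens)
        assert mean == pytest.approx(ens.sizes[:, -1].mean())
        assert var == pytest.approx(ens.sizes[:, -1].var(ddof=1))

    def test_replicate_average_matches_closed_form(self):
        # the final variance is an unbiased estimator of Var[X_10]
        sigma, reps = 0.05, 400
        stats = [final_chain_stats(
            generate_experiment(SyntheticDesign(sigma=sigma, seed=s)).records,
            "larger")[1] for s in range(reps)]
        stats = np.array(stats)
        se = stats.std(ddof=1) / math.sqrt(reps)
        expect = expected_variance(10.0, sigma, 10)
        assert abs(stats.mean() - expect) < 3 * se


class TestEmpiricalPValue:
    def test_unreachable_observation_has_zero_p(self):
        res = empirical_p_value(100.0, "final_mean", 0.0343, reps=2000, seed=0)
        assert res.p_value < 0.001
        assert res.direction == "above"

    def test_observed_at_prediction_is_central(self):
        expect = expected_variance(10.0, 0.0343, 10)
        res = empirical_p_value(expect, "final_variance", 0.0343, reps=4000,
                                seed=1)
        assert 0.2 < res.p_value < 0.8

    def test_monotone_in_observed(self):
        ps = [empirical_p_value(obs, "final_mean", 0.0343, reps=4000,
                                seed=7).p_value
              for obs in (10.0, 10.2, 10.5, 11.0)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_direction_tracks_sign_of_deviation(self):
        above = empirical_p_value(10.5, "final_mean", 0.0343, reps=500, seed=2)
        below = empirical_p_value(9.5, "final_mean", 0.0343, reps=500, seed=2)
        assert (above.direction, below.direction) == ("above", "below")
        forced = empirical_p_value(9.5, "final_mean", 0.0343, reps=500, seed=2,
                                   direction="above")
        assert forced.direction == "above"
        assert forced.p_value > 0.5

    @pytest.mark.parametrize("kwargs", [
        dict(sigma=0.0), dict(reps=50), dict(statistic="median"),
        dict(direction="sideways"),
    ])
    def test_argument_validation(self, kwargs):
        base = dict(observed=10.0, statistic="final_mean", sigma=0.03,
                    reps=500, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            empirical_p_value(base.pop("observed"), base.pop("statistic"),
                              base.pop("sigma"), **base)
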