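import math

import numpy as np
import pytest

from hfcea.parameters import InputClass, ci_to_se
from hfcea.psa import fit_all, fit_distribution, run_psa, summarize

N_DRAWS = 100_000

# One representative input per distribution family.
FAMILY_CASES = [
    ("beta", 0.3255, ci_to_se(0.2403, 0.4163), InputClass.probability),
    ("lognormal", 0.66, ci_to_se(0.24, 1.82), InputClass.relative_risk),
    ("gamma", 2665.0, ci_to_se(2572.0, 4828.0), InputClass.cost),
    ("normal", 50.0, 5.0, InputClass.continuous),
]


class TestFitDistribution:
    @pytest.mark.parametrize("family, mean, se, cls", FAMILY_CASES)
    def test_moments_matched_analytically(self, family, mean, se, cls):
        dist = fit_distribution("x", mean, se, cls)
        assert dist.family == family
        assert dist.fitted_mean() == pytest.approx(mean, abs=1e-9)
        assert dist.fitted_sd() == pytest.approx(se, abs=1e-9)

    @pytest.mark.parametrize("family, mean, se, cls", FAMILY_CASES)
    def test_sampled_mean_within_monte_carlo_error(self, family, mean, se, cls):
        dist = fit_distribution("x", mean, se, cls)
        rng = np.random.default_rng(1234)
        draws = dist.sample(rng, size=N_DRAWS)
        mc_se = draws.std(ddof=1) / math.sqrt(N_DRAWS)
        assert abs(draws.mean() - mean) < 4 * mc_se

    def test_lognormal_log_mean_recovered(self):
        dist = fit_distribution("rr", 0.66, ci_to_se(0.24, 1.82), "relative_risk")
        rng = np.random.default_rng(99)
        draws = dist.sample(rng, size=N_DRAWS)
        log_mean = np.log(draws).mean()
        mc_se = np.log(draws).std(ddof=1) / math.sqrt(N_DRAWS)
        assert abs(log_mean - dist.params["mu"]) < 3 * mc_se
        assert (draws > 0).all()

    def test_zero_se_is_point_mass(self):
        dist = fit_distribution("c", 2665.0, 0.0, "cost")
        assert dist.family == "point"
        rng = np.random.default_rng(0)
        assert dist.sample(rng) == 2665.0
        assert dist.fitted_sd() == 0.0

    def test_beta_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            fit_distribution("p", 0.5, 0.6, "probability")

    def test_families_respect_support(self, base_inputs):
        rng = np.random.default_rng(7)
        for name, dist in fit_all(base_inputs).items():
            draws = np.atleast_1d(dist.sample(rng, size=1000))
            if dist.family == "beta":
                assert ((draws > 0) & (draws < 1)).all(), name
            elif dist.family in ("gamma", "lognormal"):
                assert (draws > 0).all(), name


class TestRunPsa:
    def test_same_seed_is_bit_identical(self, base_inputs):
        a = run_psa(base_inputs, n=5, seed=42)
        b = run_psa(base_inputs, n=5, seed=42)
        assert a.iterations.equals(b.iterations)
        assert a.draws.equals(b.draws)

    def test_different_seeds_differ(self, base_inputs):
        a = run_psa(base_inputs, n=3, seed=1)
        b = run_psa(base_inputs, n=3, seed=2)
        assert not a.draws.equals(b.draws)

    def test_leading_iterations_unchanged_by_larger_n(self, base_inputs):
        # per-iteration substreams: extending the run must not rewrite history
        small = run_psa(base_inputs, n=3, seed=11)
        large = run_psa(base_inputs, n=6, seed=11)
        assert small.iterations.equals(large.iterations.iloc[:3].reset_index(drop=True))

    def test_zero_variance_reproduces_base_case(self, base_inputs, base_run):
        res = run_psa(base_inputs, n=3, seed=5, se_scale=0.0)
        assert (res.iterations.delta_cost == base_run.cea.delta_cost).all()
        assert (res.iterations.delta_eff == base_run.cea.delta_eff).all()

    def test_quadrant_fractions_partition(self, psa_1000):
        frac = psa_1000.quadrant_fractions()
        assert frac.sum() == pytest.approx(1.0)
        assert (frac >= 0).all()
        assert psa_1000.n == 1000

    def test_fraction_under_wtp_monotone_in_threshold(self, psa_1000):
        fractions = [psa_1000.fraction_under_wtp(w) for w in (0.0, 10737.0, 17830.0, 1e9)]
        assert fractions == sorted(fractions)

    def test_running_sd_stabilizes_by_500_iterations(self, psa_1000):
        sd = psa_1000.running_sd("delta_cost")
        for k in range(499, 900, 100):
            assert abs(sd[k + 100] - sd[k]) / sd[k] < 0.05


class TestSummarize:
    def test_percentile_summary_layout(self, psa_1000):
        summary = summarize(psa_1000)
        per_arm = summary["per_arm"]
        assert len(per_arm) == 4  # 2 arms x (cost, readmissions)
        assert (per_arm.cri_low <= per_arm["median"]).all()
        assert (per_arm["median"] <= per_arm.cri_high).all()
        assert 0.0 <= summary["fraction_under_wtp"] <= 1.0
        # widening the threshold can only admit more iterations
        assert summary["fraction_under_wtp_alternative"] >= summary["fraction_under_wtp"]

    def test_degenerate_results_collapse_credible_interval(self, base_inputs):
        res = run_psa(base_inputs, n=4, seed=3, se_scale=0.0)
        per_arm = summarize(res)["per_arm"]
        assert (per_arm.cri_low == per_arm.cri_high).all()
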