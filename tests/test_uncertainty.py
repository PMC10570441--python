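import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dementia_cea.pipeline import evaluate
from dementia_cea.uncertainty import (
    DsaSpec,
    PsaSpec,
    ceac,
    default_psa_specs,
    fit_distribution,
    one_way_dsa,
    probability_cost_effective,
    run_psa,
)


class TestFitDistribution:
    def test_gamma_moment_recovery(self):
        sampler = fit_distribution(PsaSpec("economics.further_assessment_cost",
                                           "gamma", 961.0, se=240.25))
        rng = np.random.default_rng(7)
        draws = np.array([sampler.sample(rng) for _ in range(100_000)])
        assert abs(draws.mean() - 961.0) < 3 * 240.25 / np.sqrt(len(draws))
        assert draws.std() == pytest.approx(240.25, rel=0.03)

    def test_beta_matches_numeric_moment_solver(self):
        """Closed-form method-of-moments alpha/beta vs an independent
        numeric solve of the two moment equations."""
        mean, se = 0.93, 0.02
        sampler = fit_distribution(PsaSpec("p", "beta", mean, se=se))

        def equations(x):
            a, b = x
            return (a / (a + b) - mean,
                    a * b / ((a + b) ** 2 * (a + b + 1)) - se**2)

        a, b = optimize.fsolve(equations, x0=(10.0, 1.0))
        assert sampler.a == pytest.approx(a, rel=1e-6)
        assert sampler.b == pytest.approx(b, rel=1e-6)

    def test_beta_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            fit_distribution(PsaSpec("p", "beta", 0.5, se=0.6))

    def test_lognormal_from_ci_hits_quantiles(self):
        sampler = fit_distribution(PsaSpec("rr", "lognormal", 1.82, ci=(1.2, 2.76)))
        dist = stats.lognorm(s=sampler.sigma, scale=np.exp(sampler.mu))
        assert dist.ppf(0.025) == pytest.approx(1.2, rel=1e-6)
        assert dist.ppf(0.975) == pytest.approx(2.76, rel=1e-6)

    def test_dirichlet_anchor_sd_follows_25pct_rule(self):
        mean = (0.78, 0.16, 0.06)
        sampler = fit_distribution(PsaSpec("split", "dirichlet", mean))
        rng = np.random.default_rng(11)
        draws = np.array([sampler.sample(rng) for _ in range(50_000)])
        assert draws.mean(axis=0) == pytest.approx(mean, abs=0.005)
        assert draws[:, 0].std() == pytest.approx(0.25 * 0.78, rel=0.03)
        assert np.allclose(draws.sum(axis=1), 1.0)

    def test_fixed_seed_gives_identical_stream(self):
        spec = PsaSpec("c", "gamma", 100.0)
        s1 = [fit_distribution(spec).sample(np.random.default_rng(5)) for _ in range(3)]
        s2 = [fit_distribution(spec).sample(np.random.default_rng(5)) for _ in range(3)]
        assert s1 == s2

    def test_se_defaults_to_quarter_of_mean(self):
        sampler = fit_distribution(PsaSpec("c", "gamma", 961.0))
        assert sampler.se == pytest.approx(0.25 * 961.0)


class TestOneWayDsa:
    def test_never_used_parameter_gives_zero_width_bar(self, primary_params):
        # the cohort starts at 77; the under-70 incidence band never applies
        spec = DsaSpec("transitions.healthy_to_mild_undx_by_ageband.<=69",
                       low=0.0, high=0.5)
        row = one_way_dsa(primary_params, [spec]).iloc[0]
        assert row["range"] == pytest.approx(0.0, abs=1e-9)
        assert row["nmb_low"] == pytest.approx(row["nmb_base"])

    def test_degenerate_bounds_reproduce_base_case(self, primary_params):
        base = 0.259
        spec = DsaSpec("transitions.prog_mild_to_mod.undiagnosed", base, base)
        row = one_way_dsa(primary_params, [spec]).iloc[0]
        assert row["nmb_low"] == row["nmb_base"] == row["nmb_high"]

    def test_table_equals_independent_single_runs(self, primary_params):
        """Exhaustive re-run oracle: each tornado cell equals a fresh
        pipeline evaluation at that bound."""
        specs = [
            DsaSpec("economics.state_costs.dx_mod", 30000.0, 35000.0),
            DsaSpec("ica_profile.sens_dem", 0.85, 0.98),
            DsaSpec("transitions.rr_death_dementia", 1.5, 2.2),
        ]
        table = one_way_dsa(primary_params, specs).set_index("parameter")
        for spec in specs:
            for side, bound in (("nmb_low", spec.low), ("nmb_high", spec.high)):
                cand = primary_params.copy()
                from dementia_cea.parameters import set_by_path
                set_by_path(cand, spec.path, bound)
                assert table.loc[spec.path, side] == pytest.approx(
                    evaluate(cand).incremental.nmb, rel=1e-12)

    def test_rows_sorted_by_swing(self, primary_params):
        specs = [DsaSpec("economics.lab_cost", 6.0, 10.0),
                 DsaSpec("ica_profile.sens_dem", 0.85, 0.98)]
        table = one_way_dsa(primary_params, specs)
        assert table["range"].is_monotonic_decreasing

    def test_unresolvable_path_raises(self, primary_params):
        with pytest.raises(KeyError):
            one_way_dsa(primary_params, [DsaSpec("economics.no_such_thing", 0, 1)])


class TestRunPsa:
    def test_zero_se_collapses_to_base_case(self, primary_params):
        base = evaluate(primary_params).incremental
        specs = [PsaSpec("ica_profile.sens_dem", "beta", 0.93, se=0.0),
                 PsaSpec("economics.state_costs.dx_mod", "gamma", 32418.0, se=0.0)]
        draws = run_psa(primary_params, specs, n_iter=5, seed=1)
        assert np.allclose(draws["delta_cost"], base.delta_cost)
        assert np.allclose(draws["delta_qalys"], base.delta_qalys)

    def test_seed_reproducibility_and_seed_sensitivity(self, primary_params):
        specs = default_psa_specs(primary_params)
        a = run_psa(primary_params, specs, n_iter=20, seed=9)
        b = run_psa(primary_params, specs, n_iter=20, seed=9)
        c = run_psa(primary_params, specs, n_iter=20, seed=10)
        pd.testing.assert_frame_equal(a, b)
        assert not a["nmb"].equals(c["nmb"])

    def test_invalid_iteration_budget_rejected(self, primary_params):
        with pytest.raises(ValueError):
            run_psa(primary_params, [], n_iter=0)


class TestCeac:
    def test_uniform_dominance_probability_one(self):
        draws = pd.DataFrame({"delta_cost": [-100.0] * 4, "delta_qalys": [0.01] * 4})
        curve = ceac(draws, thresholds=[0, 10_000, 50_000])
        assert (curve["probability_cost_effective"] == 1.0).all()

    def test_threshold_zero_counts_cost_saving_fraction(self):
        draws = pd.DataFrame({"delta_cost": [-5.0, 3.0, -1.0, 2.0],
                              "delta_qalys": [0.1, 0.1, -0.2, 0.0]})
        assert probability_cost_effective(draws, 0.0) == 0.5

    def test_hand_enumerated_mixed_signs(self):
        draws = pd.DataFrame({
            "delta_cost": [-100.0, 50.0, 300.0, -20.0],
            "delta_qalys": [0.01, 0.001, 0.02, -0.002],
        })
        # NMB at 20k: 300, -30, 100, -60 -> 2 of 4 positive
        assert probability_cost_effective(draws, 20_000) == 0.5

    def test_monotone_in_threshold_when_qaly_gains_nonnegative(self):
        rng = np.random.default_rng(3)
        draws = pd.DataFrame({"delta_cost": rng.normal(0, 100, 400),
                              "delta_qalys": np.abs(rng.normal(0, 0.01, 400))})
        curve = ceac(draws, thresholds=np.arange(0, 50_001, 5_000))
        assert curve["probability_cost_effective"].is_monotonic_increasing

    def test_empty_output_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame({"delta_cost": [], "delta_qalys": []}))
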