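import math

import numpy as np
import pytest

from helpers import simulate_cohort

from dementia_cea.markov import (
    age_band,
    build_transition_matrix,
    mortality_rate,
    run_cohort,
)
from dementia_cea.states import N_STATES, HealthState
from dementia_cea.synthetic import LifeTableSpec, synth_life_table

H = HealthState


class TestMortality:
    def test_general_population_rate_at_anchor_age(self, primary_params):
        assert mortality_rate(77, H.OTHER_HEALTHY, primary_params) == pytest.approx(0.035)

    def test_dementia_relative_risk_at_anchor_age(self, primary_params):
        # 3.5% x RR 1.82 = 6.37%, the published "6%" after rounding
        for state in (H.DX_MILD, H.UNDX_SEV):
            assert mortality_rate(77, state, primary_params) == pytest.approx(0.035 * 1.82)

    def test_mci_mortality_equals_general_population(self, primary_params):
        for age in range(77, 101):
            assert mortality_rate(age, H.MCI, primary_params) == \
                mortality_rate(age, H.OTHER_HEALTHY, primary_params)

    def test_age_outside_life_table_rejected(self, primary_params):
        with pytest.raises(ValueError, match="life table"):
            mortality_rate(60, H.OTHER_HEALTHY, primary_params)

    def test_undx_override_changes_only_undiagnosed_states(self, primary_params):
        params = primary_params.copy()
        params.transitions.rr_death_dementia_undx = 2.5
        assert mortality_rate(77, H.UNDX_MOD, params) == pytest.approx(0.035 * 2.5)
        assert mortality_rate(77, H.DX_MOD, params) == pytest.approx(0.035 * 1.82)


class TestTransitionMatrix:
    def test_dead_row_is_absorbing(self, primary_params):
        m = build_transition_matrix(80, primary_params)
        expected = np.zeros(N_STATES)
        expected[H.DEAD] = 1.0
        assert np.array_equal(m[H.DEAD], expected)

    @pytest.mark.parametrize("setting_fixture", ["primary_params", "memory_params"])
    def test_row_stochastic_at_every_age(self, setting_fixture, request):
        params = request.getfixturevalue(setting_fixture)
        for age in range(params.cohort_start_age, params.horizon_end_age + 1):
            m = build_transition_matrix(age, params)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= -1e-15).all() and (m <= 1 + 1e-15).all()

    def test_undx_mild_row_event_layering(self, primary_params):
        """Survivors leave to diagnosed states with the annual diagnosis
        probability; the newly diagnosed progress at the diagnosed rate the
        same cycle, the rest at the undiagnosed rate."""
        tr = primary_params.transitions
        age = 77
        d = mortality_rate(age, H.UNDX_MILD, primary_params)
        m = build_transition_matrix(age, primary_params)
        surv = 1 - d
        dx = tr.annual_dx_prob["mild"]
        assert m[H.UNDX_MILD, [H.DX_MILD, H.DX_MOD]].sum() == pytest.approx(surv * dx)
        assert m[H.UNDX_MILD, H.DX_MOD] == pytest.approx(
            surv * dx * tr.prog_mild_to_mod["diagnosed"])
        assert m[H.UNDX_MILD, H.UNDX_MOD] == pytest.approx(
            surv * (1 - dx) * tr.prog_mild_to_mod["undiagnosed"])
        assert m[H.UNDX_MILD, H.DEAD] == pytest.approx(d)

    def test_mci_row_matches_sequential_event_oracle(self, primary_params):
        """Step-by-step application of the four event layers to a pure-MCI
        occupancy vector, scalar arithmetic only."""
        params = primary_params.copy()
        params.cohort_start_age = 65
        ages = range(65, params.horizon_end_age + 1)
        params.life_table = synth_life_table(LifeTableSpec(), ages)
        params.utility_norm_by_age = {a: 0.7 for a in ages}
        params.validate()
        age = 68
        tr = params.transitions
        q = params.life_table[age] * tr.rr_death_mci

        # oracle: death, then (diagnosis, progression: no-ops for MCI), then flows
        surv = 1 - q
        expected = {
            H.DEAD: q,
            H.UNDX_MILD: surv * tr.mci_to_mild_undx,
            H.OTHER_HEALTHY: surv * tr.mci_to_healthy,
            H.MCI: surv * (1 - tr.mci_to_mild_undx - tr.mci_to_healthy),
        }
        row = build_transition_matrix(age, params)[H.MCI]
        for state in H:
            assert row[state] == pytest.approx(expected.get(state, 0.0), abs=1e-15)

    def test_age_band_boundaries(self):
        assert [age_band(a) for a in (69, 70, 74, 75, 79, 80, 84, 85, 99)] == \
            ["<=69", "70-74", "70-74", "75-79", "75-79", "80-84", "80-84", "85+", "85+"]


class TestRunCohort:
    def test_all_dead_start_stays_dead(self, primary_params):
        initial = np.zeros(N_STATES)
        initial[H.DEAD] = 1.0
        trace = run_cohort(initial, primary_params)
        assert np.allclose(trace.occupancy[:, H.DEAD], 1.0)

    def test_identity_dynamics_fixed_point(self, primary_params):
        params = primary_params.copy()
        ages = range(params.cohort_start_age, params.horizon_end_age + 1)
        params.life_table = {a: 0.0 for a in ages}
        tr = params.transitions
        tr.annual_dx_prob = {k: 0.0 for k in tr.annual_dx_prob}
        tr.prog_mild_to_mod = {k: 0.0 for k in tr.prog_mild_to_mod}
        tr.prog_mod_to_sev = {k: 0.0 for k in tr.prog_mod_to_sev}
        tr.mci_to_mild_undx = tr.mci_to_healthy = 0.0
        tr.healthy_to_mild_undx_by_ageband = {k: 0.0 for k in tr.healthy_to_mild_undx_by_ageband}
        tr.healthy_to_mci_by_ageband = {k: 0.0 for k in tr.healthy_to_mci_by_ageband}
        initial = np.full(N_STATES, 1.0 / N_STATES)
        trace = run_cohort(initial, params)
        assert np.allclose(trace.occupancy, initial)

    def test_two_cycles_equal_explicit_matrix_products(self, primary_params):
        initial = np.zeros(N_STATES)
        initial[H.OTHER_HEALTHY], initial[H.UNDX_MOD], initial[H.MCI] = 0.5, 0.3, 0.2
        trace = run_cohort(initial, primary_params)
        m77 = build_transition_matrix(77, primary_params)
        m78 = build_transition_matrix(78, primary_params)
        assert np.allclose(trace.occupancy[1], initial @ m77, atol=1e-14)
        assert np.allclose(trace.occupancy[2], (initial @ m77) @ m78, atol=1e-14)

    def test_conservation_and_dead_monotonicity(self, primary_params, memory_params):
        for params in (primary_params, memory_params):
            initial = np.zeros(N_STATES)
            initial[H.OTHER_HEALTHY], initial[H.UNDX_MILD] = 0.9, 0.1
            trace = run_cohort(initial, params)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = trace.occupancy[:, H.DEAD]
            assert (np.diff(dead) >= -1e-12).all()

    def test_cohort_matches_microsimulation(self, primary_params):
        """Deterministic cohort occupancies vs an individual-level
        simulation of 10^5 persons, within 3 Monte-Carlo standard errors
        at cycles 1, 5 and 10."""
        initial = np.zeros(N_STATES)
        initial[H.OTHER_HEALTHY] = 0.85
        initial[H.MCI] = 0.05
        initial[H.UNDX_MILD] = 0.06
        initial[H.DX_MILD] = 0.04
        trace = run_cohort(initial, primary_params)
        n = 100_000
        sim = simulate_cohort(initial, primary_params, n=n, cycles=10, seed=2024)
        for cycle in (1, 5, 10):
            for s in H:
                p = trace.occupancy[cycle, s]
                se = math.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(sim[cycle, s] - p) < 3 * se + 5e-4, (cycle, s.key)

    def test_diagnosed_start_accumulates_less_severe_disease(self, primary_params):
        """Person-years in moderate+severe states are lower when the cohort
        starts diagnosed (slower progression), the mechanism behind the
        care-cost savings of earlier diagnosis."""
        dx_start = np.zeros(N_STATES)
        dx_start[H.DX_MILD] = 1.0
        undx_start = np.zeros(N_STATES)
        undx_start[H.UNDX_MILD] = 1.0
        severe_cols = [H.UNDX_MOD, H.UNDX_SEV, H.DX_MOD, H.DX_SEV]
        py_dx = run_cohort(dx_start, primary_params).occupancy[:, severe_cols].sum()
        py_undx = run_cohort(undx_start, primary_params).occupancy[:, severe_cols].sum()
        assert py_dx < py_undx

    def test_invalid_initial_vectors_rejected(self, primary_params):
        with pytest.raises(ValueError, match="sum to 1"):
            run_cohort(np.full(N_STATES, 0.2), primary_params)
        with pytest.raises(ValueError, match="length"):
            run_cohort(np.ones(4) / 4, primary_params)
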