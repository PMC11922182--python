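import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hfcea.engine import (
    HFMS,
    SOC,
    STATES,
    DailyProbs,
    Layout,
    apply_ratio,
    build_daily_probs,
    daily_to_period,
    period_to_daily,
    run_cohort,
    step,
)


class TestRateConversion:
    @pytest.mark.parametrize(
        "p, days, expected",
        [
            (0.3255, 90, 0.0043658154),  # 1-(1-p)**(1/90)
            (0.0, 90, 0.0),
            (0.5221, 275, 0.0026813216),
        ],
    )
    def test_closed_form(self, p, days, expected):
        assert period_to_daily(p, days) == pytest.approx(expected, abs=1e-9)

    @given(
        p=st.floats(0, 0.999, allow_nan=False),
        days=st.integers(1, 2000),
    )
    def test_round_trip_recovers_period_probability(self, p, days):
        assert daily_to_period(period_to_daily(p, days), days) == pytest.approx(p, abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            period_to_daily(1.0, 90)


class TestApplyRatio:
    def test_identity_and_null(self):
        assert apply_ratio(0.37, 1.0) == pytest.approx(0.37)
        assert apply_ratio(0.37, 0.0) == 0.0

    def test_hazard_scale_example(self):
        assert apply_ratio(0.0043658154, 0.62) == pytest.approx(0.0027090554, abs=1e-9)

    @given(
        p=st.floats(0.0, 0.99, allow_nan=False),
        r=st.floats(0.0, 5.0, allow_nan=False),
    )
    def test_stays_a_probability_and_monotone_in_ratio(self, p, r):
        q = apply_ratio(p, r)
        assert 0.0 <= q < 1.0
        assert apply_ratio(p, r + 0.5) >= q


class TestBuildDailyProbs:
    def test_early_window_uses_90_day_rates(self, base_inputs):
        probs = build_daily_probs(base_inputs, SOC, 45)
        assert probs.p_hosp == pytest.approx(0.0043658154, abs=1e-9)

    def test_intervention_effect_applied_on_hazard_scale(self, base_inputs):
        soc = build_daily_probs(base_inputs, SOC, 45)
        hfms = build_daily_probs(base_inputs, HFMS, 45)
        assert hfms.p_hosp == pytest.approx(0.0027090554, abs=1e-9)
        assert hfms.p_death == pytest.approx(apply_ratio(soc.p_death, 0.66))
        assert hfms.p_er == soc.p_er  # no published ER effect

    def test_arms_identical_after_effect_window(self, base_inputs):
        assert build_daily_probs(base_inputs, HFMS, 200) == build_daily_probs(
            base_inputs, SOC, 200
        )

    @pytest.mark.parametrize("day", [91, 200, 364])
    @pytest.mark.parametrize("arm", [SOC, HFMS])
    def test_year_one_rates_recycled_annually(self, base_inputs, arm, day):
        assert build_daily_probs(base_inputs, arm, day) == build_daily_probs(
            base_inputs, arm, day + 365
        )

    def test_day_out_of_range_rejected(self, base_inputs):
        with pytest.raises(ValueError):
            build_daily_probs(base_inputs, SOC, 0)
        with pytest.raises(ValueError):
            build_daily_probs(base_inputs, SOC, 9999)


class TestStep:
    def test_dead_state_is_absorbing(self, base_inputs):
        lay = Layout.from_settings(base_inputs.settings)
        occ = np.zeros(lay.size)
        occ[lay.i_dead] = 1.0
        probs = build_daily_probs(base_inputs, SOC, 1)
        new, incident = step(occ, probs, base_inputs.settings)
        assert np.array_equal(new, occ)
        assert all(v == 0.0 for v in incident.values())

    def test_single_competing_risk_reduces_to_plain_probability(self, base_inputs):
        lay = Layout.from_settings(base_inputs.settings)
        occ = lay.initial()
        probs = DailyProbs(p_hosp=0.1, p_er=0.0, p_death=0.0, p_eoc_entry=0.0, p_er_admit=0.0)
        _, incident = step(occ, probs, base_inputs.settings)
        assert incident["readmission"] == pytest.approx(0.1)
        assert incident["er_visit"] == 0.0

    def test_death_applied_before_readmission(self, base_inputs):
        lay = Layout.from_settings(base_inputs.settings)
        probs = build_daily_probs(base_inputs, SOC, 1)
        _, incident = step(lay.initial(), probs, base_inputs.settings)
        expected = (1.0 - probs.p_death) * probs.p_hosp
        assert incident["readmission"] == pytest.approx(expected, rel=1e-12)

    def test_mass_conserved_each_step(self, base_inputs):
        lay = Layout.from_settings(base_inputs.settings)
        rng = np.random.default_rng(0)
        occ = rng.dirichlet(np.ones(lay.size))
        probs = build_daily_probs(base_inputs, SOC, 1)
        new, _ = step(occ, probs, base_inputs.settings)
        assert new.sum() == pytest.approx(1.0, abs=1e-14)


class TestRunCohort:
    def test_occupancy_rows_sum_to_one_over_full_horizon(self, base_run):
        for arm, trace in base_run.traces.items():
            err = np.abs(trace.occupancy.sum(axis=1) - 1.0).max()
            assert err < 1e-12, arm

    def test_initial_state_is_outpatient(self, base_run):
        occ0 = base_run.traces[SOC].occupancy[0]
        assert occ0[STATES.index("outpatient")] == 1.0
        assert occ0.sum() == 1.0

    def test_incident_flows_nonnegative(self, base_run):
        for trace in base_run.traces.values():
            for flow in trace.incident.values():
                assert (flow >= 0).all()

    def test_cumulative_mortality_matches_period_rate_in_window(self, base_inputs):
        # Cohort-wide daily death hazard integrates back to the printed
        # 90-day cumulative mortality exactly.
        trace = run_cohort(base_inputs, SOC, horizon_days=90)
        assert trace.occupancy[90, STATES.index("dead")] == pytest.approx(0.0346, abs=1e-12)

    def test_higher_hazard_ratio_weakly_increases_readmissions(self, base_inputs):
        totals = []
        for hr in (0.62, 0.8, 1.0):
            trace = run_cohort(
                base_inputs.with_mean("effects.hr_hosp", hr), HFMS, horizon_days=200
            )
            totals.append(trace.expected_readmissions())
        assert totals[0] < totals[1] < totals[2]

    def test_higher_mortality_weakly_decreases_readmissions(self, base_inputs):
        base = run_cohort(base_inputs, SOC, horizon_days=200).expected_readmissions()
        lethal = run_cohort(
            base_inputs.with_mean("rates.mort_early", 0.3), SOC, horizon_days=200
        ).expected_readmissions()
        assert lethal < base

    def test_null_effect_traces_identical(self, base_inputs):
        neutral = base_inputs.with_mean("effects.hr_hosp", 1.0).with_mean(
            "effects.rr_mort", 1.0
        )
        soc = run_cohort(neutral, SOC, horizon_days=400)
        hfms = run_cohort(neutral, HFMS, horizon_days=400)
        assert np.array_equal(soc.occupancy, hfms.occupancy)
        for key in soc.incident:
            assert np.array_equal(soc.incident[key], hfms.incident[key])

    def test_multiday_hold_retains_mass_in_hospital(self, base_inputs):
        st_held = base_inputs.settings.model_copy(update={"hospital_hold_days": 6})
        held = run_cohort(
            base_inputs.model_copy(update={"settings": st_held}), SOC, horizon_days=90
        )
        quick = run_cohort(base_inputs, SOC, horizon_days=90)
        i_hosp = STATES.index("hospital_readmission")
        assert held.occupancy[:, i_hosp].sum() > quick.occupancy[:, i_hosp].sum()
        assert held.expected_readmissions() < quick.expected_readmissions()

    def test_trace_export_is_tidy(self, base_run_90):
        frame = base_run_90.traces[SOC].to_frame()
        assert set(frame.columns) == {"day", "kind", "name", "value"}
        occ = frame[frame.kind == "occupancy"]
        assert set(occ.name.unique()) == set(STATES)
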