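import numpy as np
import pytest

from hfcea.costing import COMPONENTS, accrue, device_cost, discount_factor, monthly_cumulative
from hfcea.engine import ARMS, HFMS, SOC, run_cohort
from hfcea.parameters import Settings


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "day, expected",
        [
            (1, 1.0),
            (200, 1.0),
            (365, 1.0),
            (400, 0.970874),
            (1800, 0.888487),
        ],
    )
    def test_annual_step_function(self, day, expected):
        assert discount_factor(day, 0.03) == pytest.approx(expected, abs=5e-7)

    def test_zero_rate_is_flat(self):
        assert all(discount_factor(d, 0.0) == 1.0 for d in (1, 400, 1825))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(10, -0.01)


class TestDeviceCost:
    def test_wear_window_schedule(self):
        st = Settings()
        assert device_cost(15, st, 1300.0) == pytest.approx(1300.0 / 30)
        assert device_cost(60, st, 1300.0) == pytest.approx(1300.0 / 30)
        assert device_cost(61, st, 1300.0) == 0.0

    def test_lifetime_total_is_wear_months_times_monthly_cost(self):
        st = Settings()
        total = sum(device_cost(d, st, 1300.0) for d in range(1, 1826))
        assert total == pytest.approx(2600.0)


class TestAccrue:
    def test_all_zero_costs_give_zero_ledger(self, base_inputs):
        zeroed = base_inputs
        for name in base_inputs.costs:
            zeroed = zeroed.with_mean(f"costs.{name}", 0.0)
        trace = run_cohort(zeroed, HFMS, horizon_days=120)
        ledger = accrue(trace, zeroed, HFMS)
        assert ledger.total() == 0.0
        assert ledger.total(discounted=False) == 0.0

    def test_soc_has_no_device_component(self, base_run):
        assert base_run.ledgers[SOC].component_total("device") == 0.0
        assert base_run.ledgers[HFMS].component_total("device") > 0.0

    def test_discounting_only_bites_after_year_one(self, base_run):
        for ledger in base_run.ledgers.values():
            undisc = ledger.undiscounted
            disc = ledger.discounted
            assert np.array_equal(disc[:366], undisc[:366])
            late = slice(366, None)
            assert (disc[late] <= undisc[late] + 1e-12).all()
            assert disc[late].sum() < undisc[late].sum()

    def test_zero_discount_rate_leaves_costs_unchanged(self, base_inputs):
        st = base_inputs.settings.model_copy(update={"discount_rate_annual": 0.0})
        inputs = base_inputs.model_copy(update={"settings": st})
        trace = run_cohort(inputs, SOC, horizon_days=800)
        ledger = accrue(trace, inputs, SOC)
        assert np.array_equal(ledger.discounted, ledger.undiscounted)

    def test_components_nonnegative_and_total_consistent(self, base_run):
        for ledger in base_run.ledgers.values():
            assert (ledger.undiscounted >= 0).all()
            component_sum = sum(ledger.component_total(c) for c in COMPONENTS)
            assert ledger.total() == pytest.approx(component_sum, rel=1e-12)

    def test_null_effect_arm_difference_is_device_only(self, base_inputs):
        neutral = base_inputs.with_mean("effects.hr_hosp", 1.0).with_mean(
            "effects.rr_mort", 1.0
        )
        ledgers = {
            arm: accrue(run_cohort(neutral, arm, horizon_days=60), neutral, arm)
            for arm in ARMS
        }
        non_device = [c for c in COMPONENTS if c != "device"]
        for comp in non_device:
            assert ledgers[HFMS].component_total(comp) == pytest.approx(
                ledgers[SOC].component_total(comp)
            )
        diff = ledgers[HFMS].total() - ledgers[SOC].total()
        assert diff == pytest.approx(ledgers[HFMS].component_total("device"))
        assert diff >= 0.0

    def test_billed_stay_scales_hospital_component(self, base_inputs):
        trace = run_cohort(base_inputs, SOC, horizon_days=90)
        base_ledger = accrue(trace, base_inputs, SOC)
        st = base_inputs.settings.model_copy(update={"hospital_los_days": 13.74})
        doubled_inputs = base_inputs.model_copy(update={"settings": st})
        trace2 = run_cohort(doubled_inputs, SOC, horizon_days=90)
        doubled = accrue(trace2, doubled_inputs, SOC)
        assert doubled.component_total("hospital") == pytest.approx(
            2 * base_ledger.component_total("hospital"), rel=1e-9
        )

    def test_ledger_export_is_tidy(self, base_run_90):
        frame = base_run_90.ledgers[HFMS].to_frame()
        assert set(frame.columns) == {"day", "component", "undiscounted", "discounted"}
        assert set(frame.component.unique()) == set(COMPONENTS)


class TestMonthlyCumulative:
    def test_cumulative_and_balanced(self, base_run):
        monthly = monthly_cumulative(base_run.traces, base_run.ledgers)
        assert set(monthly.arm.unique()) == set(ARMS)
        for arm in ARMS:
            sub = monthly[monthly.arm == arm]
            assert sub.month.tolist() == list(range(1, 61))
            assert sub.cumulative_cost.is_monotonic_increasing
            assert sub.cumulative_readmissions.is_monotonic_increasing
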