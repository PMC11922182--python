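"""Cost accrual over a cohort trace: per-day state costs, per-event episode
costs, the device schedule, and annual-step discounting.

All costs are 2022 USD per modelled patient, from the payer perspective.
Occupancy-based costs (outpatient care, post-readmission outpatient care)
are charged per day in state; emergency-room visits are charged per visit
on the day they occur; hospital readmissions are billed as length-of-stay x
per-day hospital cost, and escalations of care as length-of-stay x per-day
intensive-care cost, attributed to the admission day. Months are fixed at
30 days so the device subscription integrates exactly to wear-months x
monthly cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import HFMS, CohortTrace
from .parameters import CostUnit, ModelInputs, Settings

__all__ = [
    "COMPONENTS",
    "CostLedger",
    "discount_factor",
    "device_cost",
    "accrue",
    "monthly_cumulative",
]

DAYS_PER_MONTH = 30

COMPONENTS = (
    "outpatient",
    "post_readmission_outpatient",
    "er",
    "hospital",
    "icu_eoc",
    "device",
)


def discount_factor(day: int, rate: float) -> float:
    """Annual-step discount factor for a model day (1-based).

    Costs in the first model year are undiscounted; a day in year ``y + 1``
    is discounted by ``(1 + rate)**-y``.
    """
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    if rate < 0.0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    year_index = (day - 1) // 365
    return float((1.0 + rate) ** -year_index)


def device_cost(day: int, settings: Settings, cost_per_month: float) -> float:
    """Per-day device cost schedule: monthly cost spread over 30-day months
    for the configured wear time, zero afterwards."""
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    if day <= DAYS_PER_MONTH * settings.device_wear_months:
        return cost_per_month / DAYS_PER_MONTH
    return 0.0


def _daily_rate(cost_mean: float, unit: CostUnit) -> float:
    if unit is CostUnit.per_day:
        return cost_mean
    if unit is CostUnit.per_month:
        return cost_mean / DAYS_PER_MONTH
    raise ValueError(f"cannot convert a {unit.value} cost to a daily rate")


@dataclass
class CostLedger:
    """Day-indexed cost accrual for one arm, split by component.

    ``undiscounted[d, c]`` and ``discounted[d, c]`` hold the expected cost
    per patient accrued on day ``d`` for component ``c`` (row 0 is zero).
    """

    arm: str
    undiscounted: np.ndarray = field(repr=False)  # (horizon+1, n_components)
    discounted: np.ndarray = field(repr=False)

    @property
    def horizon_days(self) -> int:
        return self.undiscounted.shape[0] - 1

    def component_total(self, component: str, discounted: bool = True) -> float:
        arr = self.discounted if discounted else self.undiscounted
        return float(arr[:, COMPONENTS.index(component)].sum())

    def total(self, discounted: bool = True, through_day: int | None = None) -> float:
        arr = self.discounted if discounted else self.undiscounted
        end = self.horizon_days if through_day is None else through_day
        return float(arr[: end + 1].sum())

    def daily_total(self, discounted: bool = True) -> np.ndarray:
        arr = self.discounted if discounted else self.undiscounted
        return arr.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: day, component, undiscounted, discounted."""
        days = np.arange(self.undiscounted.shape[0])
        frames = []
        for c, name in enumerate(COMPONENTS):
            frames.append(
                pd.DataFrame(
                    {
                        "day": days,
                        "component": name,
                        "undiscounted": self.undiscounted[:, c],
                        "discounted": self.discounted[:, c],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def accrue(trace: CohortTrace, inputs: ModelInputs, arm: str) -> CostLedger:
    """Accrue all cost components over a cohort trace.

    The hospital component charges the per-day hospital cost for occupied
    hospital days plus the remaining billed length of stay at admission;
    with the default 1-day dynamic hold this equals length of stay x per-day
    cost per admission. Escalations of care are billed analogously at the
    intensive-care rate. The post-readmission outpatient rate applies to the
    discharged-outpatient and post-EoC states, replacing (or, if configured,
    adding to) the baseline outpatient rate. The device is charged to the
    surviving cohort fraction during the wear window, intervention arm only.
    """
    st = inputs.settings
    if trace.settings is not None and trace.settings.horizon_days < trace.horizon_days:
        raise ValueError("trace horizon exceeds settings horizon")
    horizon = trace.horizon_days
    occ = trace.occupancy
    costs = inputs.costs

    c_out = _daily_rate(costs["outpatient_daily"].mean, costs["outpatient_daily"].unit)
    c_post = _daily_rate(
        costs["post_readmission_outpatient"].mean,
        costs["post_readmission_outpatient"].unit,
    )
    if st.post_readmission_additive:
        c_post += c_out
    c_er = costs["er_visit"].mean
    c_hosp = costs["hospital_daily"].mean
    c_icu = costs["icu_daily"].mean

    days = np.arange(horizon + 1)
    disc = np.ones(horizon + 1)
    disc[1:] = (1.0 + st.discount_rate_annual) ** (-((days[1:] - 1) // 365))

    undisc = np.zeros((horizon + 1, len(COMPONENTS)))
    undisc[:, 0] = occ[:, 0] * c_out
    undisc[:, 1] = (occ[:, 3] + occ[:, 7]) * c_post
    undisc[:, 2] = trace.incident["er_visit"] * c_er
    # Occupied hospital/ICU days plus the balance of the billed stay.
    extra_hosp = max(st.hospital_los_days - st.hospital_hold_days, 0.0)
    extra_eoc = max(st.eoc_los_days - st.eoc_hold_days, 0.0)
    undisc[:, 3] = (occ[:, 2] + occ[:, 5]) * c_hosp
    undisc[:, 3] += trace.incident["hosp_admission_billed"] * extra_hosp * c_hosp
    undisc[:, 4] = occ[:, 6] * c_icu
    undisc[:, 4] += trace.incident["eoc_entry"] * extra_eoc * c_icu
    if arm == HFMS:
        alive = 1.0 - occ[:, 8]
        sched = np.array(
            [0.0] + [device_cost(d, st, costs["device_monthly"].mean) for d in range(1, horizon + 1)]
        )
        undisc[:, 5] = sched * alive
    undisc[0] = 0.0
    return CostLedger(arm=arm, undiscounted=undisc, discounted=undisc * disc[:, None])


def monthly_cumulative(
    traces: dict[str, CohortTrace], ledgers: dict[str, CostLedger]
) -> pd.DataFrame:
    """Month-end cumulative cost and readmissions per arm (30-day months).

    One row per (month, arm) with cumulative discounted cost and cumulative
    expected readmissions through the month's last day.
    """
    rows = []
    for arm, ledger in ledgers.items():
        daily = ledger.daily_total(discounted=True)
        cum_cost = daily.cumsum()
        cum_readm = traces[arm].incident["readmission"].cumsum()
        horizon = ledger.horizon_days
        for month in range(1, horizon // DAYS_PER_MONTH + 1):
            d = month * DAYS_PER_MONTH
            rows.append(
                {
                    "month": month,
                    "arm": arm,
                    "cumulative_cost": cum_cost[d],
                    "cumulative_readmissions": cum_readm[d],
                }
            )
    return pd.DataFrame(rows)
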