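"""Daily-cycle Markov cohort engine for the 9-state readmission model.

The cohort enters in outpatient care after an index heart-failure discharge
and each day faces competing risks of death, hospital readmission, and an
emergency-room (ER) visit. A first readmission moves the cohort to a
post-discharge outpatient state from which subsequent readmissions and ER
visits can occur; a fixed fraction of subsequent readmissions escalates to
an intensive-care intervention (escalation of care, EoC), after which the
cohort is removed from the readmission pathway. Death is reachable from
every state.

Rates are supplied as cumulative probabilities over an observation window
and converted to daily probabilities on the complementary-log (constant
hazard) scale; treatment effects act multiplicatively on the hazard. Within
a day, risks compete in a fixed cascade: death first, then readmission,
then ER visit, each applied to the mass that escaped the previous risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ModelInputs, Settings

__all__ = [
    "STATES",
    "SOC",
    "HFMS",
    "ARMS",
    "DailyProbs",
    "CohortTrace",
    "period_to_daily",
    "daily_to_period",
    "apply_ratio",
    "build_daily_probs",
    "step",
    "run_cohort",
]

#: The nine aggregated health states, in reporting order.
STATES = (
    "outpatient",
    "er_visit",
    "hospital_readmission",
    "discharged_outpatient",
    "er_visit_post",
    "hospital_readmission_subsequent",
    "escalation_of_care",
    "post_eoc",
    "dead",
)

SOC = "SOC"
HFMS = "HFMS"
ARMS = (SOC, HFMS)

#: Incident event flows tracked per day (expected events per patient).
EVENTS = ("readmission", "er_visit", "eoc_entry", "death")


def period_to_daily(p_period: float, period_days: int) -> float:
    """Convert a cumulative probability over ``period_days`` to a daily one.

    Assumes a constant hazard within the window:
    ``p_daily = 1 - (1 - p_period)**(1/period_days)``, so that applying the
    daily probability independently on each of ``period_days`` days recovers
    the cumulative probability exactly.
    """
    if not 0.0 <= p_period < 1.0:
        raise ValueError(f"p_period must be in [0, 1), got {p_period}")
    if period_days < 1:
        raise ValueError(f"period_days must be >= 1, got {period_days}")
    return 1.0 - (1.0 - p_period) ** (1.0 / period_days)


def daily_to_period(p_daily: float, period_days: int) -> float:
    """Inverse of :func:`period_to_daily`."""
    return 1.0 - (1.0 - p_daily) ** period_days


def apply_ratio(p_daily: float, ratio: float) -> float:
    """Scale a daily probability by a hazard/risk ratio on the hazard scale.

    ``p' = 1 - (1 - p)**ratio`` — exact for proportional hazards under the
    complementary-log survival form; reduces to identity at ratio 1 and to a
    null hazard at ratio 0.
    """
    if not 0.0 <= p_daily < 1.0:
        raise ValueError(f"p_daily must be in [0, 1), got {p_daily}")
    if ratio < 0.0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    return 1.0 - (1.0 - p_daily) ** ratio


@dataclass(frozen=True)
class DailyProbs:
    """Per-day exit probabilities applicable on a given model day."""

    p_hosp: float
    p_er: float
    p_death: float
    p_eoc_entry: float  # fraction of subsequent readmissions escalating
    p_er_admit: float  # fraction of ER visitors admitted the next day

    def __post_init__(self) -> None:
        for name in ("p_hosp", "p_er", "p_death", "p_eoc_entry", "p_er_admit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]: {v}")


def build_daily_probs(inputs: ModelInputs, arm: str, day: int) -> DailyProbs:
    """Daily transition probabilities for a model day (1-based).

    Day-of-year 1-90 uses the "at 3 months" cumulative rates over a 90-day
    window; later days of each model year use the "after 3 months" rates
    over the configured late window (default days 91-365, i.e. 275 days).
    Years 2-5 recycle the year-1 schedule. The intervention arm's hazard
    ratio (readmission) and risk ratio (mortality) apply only within the
    absolute effect window (days 1-90).
    """
    st = inputs.settings
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if not 1 <= day <= st.horizon_days:
        raise ValueError(f"day {day} outside 1..{st.horizon_days}")
    doy = (day - 1) % 365 + 1
    early = doy <= st.effect_window_days
    suffix = "early" if early else "late"
    rates = inputs.rates
    p_hosp = period_to_daily(rates[f"hosp_{suffix}"].mean, rates[f"hosp_{suffix}"].period_days)
    p_er = period_to_daily(rates[f"er_{suffix}"].mean, rates[f"er_{suffix}"].period_days)
    p_death = period_to_daily(rates[f"mort_{suffix}"].mean, rates[f"mort_{suffix}"].period_days)
    if arm == HFMS and day <= st.effect_window_days:
        p_hosp = apply_ratio(p_hosp, inputs.effects["hr_hosp"].mean)
        p_death = apply_ratio(p_death, inputs.effects["rr_mort"].mean)
    return DailyProbs(
        p_hosp=p_hosp,
        p_er=p_er,
        p_death=p_death,
        p_eoc_entry=st.eoc_fraction,
        p_er_admit=st.er_to_hosp_fraction,
    )


@dataclass(frozen=True)
class Layout:
    """Index layout of the expanded occupancy vector.

    Hospital and EoC states may be tunnels of ``hold`` daily compartments so
    that a multi-day sojourn can be represented; with 1-day holds the
    expanded vector coincides with the nine reporting states.
    """

    hosp_hold: int
    eoc_hold: int

    @classmethod
    def from_settings(cls, settings: Settings) -> "Layout":
        return cls(hosp_hold=settings.hospital_hold_days, eoc_hold=settings.eoc_hold_days)

    @property
    def i_out(self) -> int:
        return 0

    @property
    def i_er(self) -> int:
        return 1

    @property
    def i_hosp(self) -> int:  # first-readmission tunnel start
        return 2

    @property
    def i_disch(self) -> int:
        return 2 + self.hosp_hold

    @property
    def i_er_post(self) -> int:
        return self.i_disch + 1

    @property
    def i_hosp2(self) -> int:  # subsequent-readmission tunnel start
        return self.i_er_post + 1

    @property
    def i_eoc(self) -> int:
        return self.i_hosp2 + self.hosp_hold

    @property
    def i_post_eoc(self) -> int:
        return self.i_eoc + self.eoc_hold

    @property
    def i_dead(self) -> int:
        return self.i_post_eoc + 1

    @property
    def size(self) -> int:
        return self.i_dead + 1

    def initial(self) -> np.ndarray:
        occ = np.zeros(self.size)
        occ[self.i_out] = 1.0
        return occ

    def aggregate(self, occ: np.ndarray) -> np.ndarray:
        """Collapse an expanded vector to the nine reporting states."""
        occ = np.asarray(occ)
        out = np.empty(occ.shape[:-1] + (9,))
        out[..., 0] = occ[..., self.i_out]
        out[..., 1] = occ[..., self.i_er]
        out[..., 2] = occ[..., self.i_hosp : self.i_hosp + self.hosp_hold].sum(-1)
        out[..., 3] = occ[..., self.i_disch]
        out[..., 4] = occ[..., self.i_er_post]
        out[..., 5] = occ[..., self.i_hosp2 : self.i_hosp2 + self.hosp_hold].sum(-1)
        out[..., 6] = occ[..., self.i_eoc : self.i_eoc + self.eoc_hold].sum(-1)
        out[..., 7] = occ[..., self.i_post_eoc]
        out[..., 8] = occ[..., self.i_dead]
        return out


def step(
    occupancy: np.ndarray, probs: DailyProbs, settings: Settings | Layout
) -> tuple[np.ndarray, dict[str, float]]:
    """Advance the expanded occupancy vector by one daily cycle.

    Returns the new occupancy and the incident event flows of the day
    (expected events per patient): all readmissions (first, subsequent, and
    escalations), ER visits, EoC entries, deaths, plus the hospital
    admissions billed at the hospital rate (readmissions net of EoC
    entries, which are billed as intensive care instead).
    """
    lay = settings if isinstance(settings, Layout) else Layout.from_settings(settings)
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (lay.size,):
        raise ValueError(f"occupancy must have shape ({lay.size},)")
    pd_, ph, pe = probs.p_death, probs.p_hosp, probs.p_er
    f_eoc, f_adm = probs.p_eoc_entry, probs.p_er_admit

    new = np.zeros(lay.size)
    # Death first, from every alive state.
    deaths = (occ.sum() - occ[lay.i_dead]) * pd_
    new[lay.i_dead] = occ[lay.i_dead] + deaths
    surv = occ * (1.0 - pd_)

    # Outpatient (never readmitted): readmission, then ER, else stay.
    m = surv[lay.i_out]
    adm_first = m * ph
    er_first = m * (1.0 - ph) * pe
    new[lay.i_hosp] += adm_first
    new[lay.i_er] += er_first
    new[lay.i_out] += m - adm_first - er_first

    # ER visitors (pre-first-readmission): admitted or sent home next day.
    m = surv[lay.i_er]
    er_adm = m * f_adm
    new[lay.i_hosp] += er_adm
    new[lay.i_out] += m - er_adm

    # First-readmission tunnel: advance, release to discharged outpatient.
    for k in range(lay.hosp_hold - 1):
        new[lay.i_hosp + k + 1] += surv[lay.i_hosp + k]
    new[lay.i_disch] += surv[lay.i_hosp + lay.hosp_hold - 1]

    # Discharged outpatient: subsequent readmission (EoC-routed), ER, stay.
    m = surv[lay.i_disch]
    adm_sub = m * ph
    er_sub = m * (1.0 - ph) * pe
    eoc_in = adm_sub * f_eoc
    new[lay.i_eoc] += eoc_in
    new[lay.i_hosp2] += adm_sub - eoc_in
    new[lay.i_er_post] += er_sub
    new[lay.i_disch] += m - adm_sub - er_sub

    # Post-readmission ER visitors: admitted (subsequent) or home next day.
    m = surv[lay.i_er_post]
    er_adm2 = m * f_adm
    eoc_in2 = er_adm2 * f_eoc
    new[lay.i_eoc] += eoc_in2
    new[lay.i_hosp2] += er_adm2 - eoc_in2
    new[lay.i_disch] += m - er_adm2

    # Subsequent-readmission tunnel.
    for k in range(lay.hosp_hold - 1):
        new[lay.i_hosp2 + k + 1] += surv[lay.i_hosp2 + k]
    new[lay.i_disch] += surv[lay.i_hosp2 + lay.hosp_hold - 1]

    # EoC tunnel, then permanent post-EoC state.
    for k in range(lay.eoc_hold - 1):
        new[lay.i_eoc + k + 1] += surv[lay.i_eoc + k]
    new[lay.i_post_eoc] += surv[lay.i_eoc + lay.eoc_hold - 1]
    new[lay.i_post_eoc] += surv[lay.i_post_eoc]

    if new.min() < -1e-12:
        raise RuntimeError("internal consistency error: negative cohort mass")

    eoc_entries = eoc_in + eoc_in2
    readmissions = adm_first + adm_sub + er_adm + er_adm2
    incident = {
        "readmission": readmissions,
        "er_visit": er_first + er_sub,
        "eoc_entry": eoc_entries,
        "death": deaths,
        "hosp_admission_billed": readmissions - eoc_entries,
    }
    return new, incident


@dataclass
class CohortTrace:
    """Day-indexed cohort occupancy and incident event flows for one arm.

    ``occupancy[d]`` is the distribution over the nine reporting states
    during day ``d`` (row 0 is the initial distribution, all mass in
    outpatient care); ``incident[event][d]`` is the expected number of
    events per patient on day ``d``.
    """

    arm: str
    occupancy: np.ndarray  # (horizon+1, 9)
    incident: dict[str, np.ndarray] = field(repr=False)
    settings: Settings = field(repr=False, default=None)

    @property
    def horizon_days(self) -> int:
        return self.occupancy.shape[0] - 1

    def total(self, event: str, through_day: int | None = None) -> float:
        """Cumulative expected events per patient through a given day."""
        end = self.horizon_days if through_day is None else through_day
        return float(self.incident[event][: end + 1].sum())

    def expected_readmissions(self, through_day: int | None = None) -> float:
        return self.total("readmission", through_day)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: day, variable kind, name, value."""
        days = np.arange(self.occupancy.shape[0])
        occ = pd.DataFrame(self.occupancy, columns=list(STATES))
        occ.insert(0, "day", days)
        occ = occ.melt(id_vars="day", var_name="name", value_name="value")
        occ.insert(1, "kind", "occupancy")
        inc = pd.DataFrame({k: v for k, v in self.incident.items() if k in EVENTS})
        inc.insert(0, "day", days)
        inc = inc.melt(id_vars="day", var_name="name", value_name="value")
        inc.insert(1, "kind", "incident")
        return pd.concat([occ, inc], ignore_index=True)


def run_cohort(
    inputs: ModelInputs, arm: str, horizon_days: int | None = None
) -> CohortTrace:
    """Evolve the cohort over the horizon and account incident flows.

    Deterministic given inputs. Occupancy rows are conserved (sum to 1
    including the dead state).
    """
    st = inputs.settings
    horizon = st.horizon_days if horizon_days is None else int(horizon_days)
    if not 1 <= horizon <= st.horizon_days:
        raise ValueError(f"horizon_days must be in 1..{st.horizon_days}")
    lay = Layout.from_settings(st)
    occ = lay.initial()
    occ_hist = np.zeros((horizon + 1, lay.size))
    occ_hist[0] = occ
    flows = {k: np.zeros(horizon + 1) for k in (*EVENTS, "hosp_admission_billed")}
    # Only a handful of distinct daily-probability regimes exist (early/late
    # rates x treated/untreated); cache them rather than rebuilding per day.
    cache: dict[tuple[bool, bool], DailyProbs] = {}
    for day in range(1, horizon + 1):
        doy = (day - 1) % 365 + 1
        key = (doy <= st.effect_window_days, arm == HFMS and day <= st.effect_window_days)
        probs = cache.get(key)
        if probs is None:
            probs = cache[key] = build_daily_probs(inputs, arm, day)
        occ, inc = step(occ, probs, lay)
        occ_hist[day] = occ
        for k, v in inc.items():
            flows[k][day] = v
    return CohortTrace(
        arm=arm, occupancy=lay.aggregate(occ_hist), incident=flows, settings=st
    )
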