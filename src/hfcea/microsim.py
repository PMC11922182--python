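"""Patient-level Monte Carlo twin of the cohort engine.

Each simulated patient walks the same nine-state structure with the same
daily probabilities and within-day risk cascade (death, then readmission,
then ER visit) as the cohort model, so sample means converge to the cohort
expectations — this is the brute-force oracle used to validate the engine,
and the generator of synthetic two-arm trial data.

Every patient draws from a dedicated counter-based RNG stream keyed by
(seed, arm, patient index), so trajectories are reproducible and
independent of the number of patients simulated, chunking, or order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import DAYS_PER_MONTH, device_cost
from .engine import ARMS, HFMS, STATES, build_daily_probs
from .parameters import CostUnit, ModelInputs

__all__ = [
    "MicrosimResult",
    "PatientHistory",
    "simulate_patients",
    "make_synthetic_trial",
]

# State codes (== indices into engine.STATES).
OUT, ER, HOSP, DISCH, ER_POST, HOSP2, EOC, POST_EOC, DEAD = range(9)

TRIAL_WINDOW_DAYS = 90  # summary window of the emulated two-arm trial


@dataclass(frozen=True)
class PatientHistory:
    """One patient's day-indexed state path and dated events."""

    arm: str
    states: np.ndarray = field(repr=False)  # (horizon+1,) int codes
    events: tuple[tuple[int, str], ...]  # (day, event) pairs
    cost_undiscounted: float
    cost_discounted: float

    def state_names(self) -> list[str]:
        return [STATES[s] for s in self.states]


@dataclass
class MicrosimResult:
    """Per-patient outcome arrays for one simulated arm."""

    arm: str
    n: int
    horizon_days: int
    readmissions: np.ndarray = field(repr=False)
    readmissions_90: np.ndarray = field(repr=False)
    er_visits: np.ndarray = field(repr=False)
    er_visits_90: np.ndarray = field(repr=False)
    eoc: np.ndarray = field(repr=False)  # bool, ever escalated
    death_day: np.ndarray = field(repr=False)  # 0 if alive at horizon
    first_readmission_day: np.ndarray = field(repr=False)  # 0 if never
    cost_undiscounted: np.ndarray = field(repr=False)
    cost_discounted: np.ndarray = field(repr=False)
    cost_discounted_90: np.ndarray = field(repr=False)
    histories: list[PatientHistory] | None = field(default=None, repr=False)

    def mean_sem(self, attribute: str) -> tuple[float, float]:
        """Sample mean and its Monte-Carlo standard error."""
        x = np.asarray(getattr(self, attribute), dtype=float)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

    @property
    def died(self) -> np.ndarray:
        return self.death_day > 0

    @property
    def died_by_90(self) -> np.ndarray:
        return (self.death_day > 0) & (self.death_day <= TRIAL_WINDOW_DAYS)


def _daily_prob_arrays(inputs: ModelInputs, arm: str, horizon: int):
    """Vectors of (p_hosp, p_er, p_death) for days 1..horizon."""
    ph = np.empty(horizon + 1)
    pe = np.empty(horizon + 1)
    pm = np.empty(horizon + 1)
    cache = {}
    st = inputs.settings
    for day in range(1, horizon + 1):
        doy = (day - 1) % 365 + 1
        key = (doy <= st.effect_window_days, arm == HFMS and day <= st.effect_window_days)
        if key not in cache:
            cache[key] = build_daily_probs(inputs, arm, day)
        p = cache[key]
        ph[day], pe[day], pm[day] = p.p_hosp, p.p_er, p.p_death
    return ph, pe, pm


def simulate_patients(
    inputs: ModelInputs,
    arm: str,
    n: int,
    seed: int,
    horizon_days: int | None = None,
    record_histories: bool = False,
    chunk_size: int = 8192,
) -> MicrosimResult:
    """Simulate ``n`` patients of one arm by daily categorical draws."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    st = inputs.settings
    horizon = st.horizon_days if horizon_days is None else int(horizon_days)
    ph, pe, pm = _daily_prob_arrays(inputs, arm, horizon)

    costs = inputs.costs
    c_out = costs["outpatient_daily"].mean
    post = costs["post_readmission_outpatient"]
    c_post = post.mean / DAYS_PER_MONTH if post.unit is CostUnit.per_month else post.mean
    if st.post_readmission_additive:
        c_post += c_out
    c_er = costs["er_visit"].mean
    c_hosp = costs["hospital_daily"].mean
    c_icu = costs["icu_daily"].mean
    extra_hosp = max(st.hospital_los_days - st.hospital_hold_days, 0.0) * c_hosp
    extra_eoc = max(st.eoc_los_days - st.eoc_hold_days, 0.0) * c_icu
    dev = np.array(
        [0.0] + [device_cost(d, st, costs["device_monthly"].mean) for d in range(1, horizon + 1)]
    )
    disc = np.ones(horizon + 1)
    days = np.arange(1, horizon + 1)
    disc[1:] = (1.0 + st.discount_rate_annual) ** (-((days - 1) // 365))

    eoc_frac, f_admit = st.eoc_fraction, st.er_to_hosp_fraction
    hosp_hold, eoc_hold = st.hospital_hold_days, st.eoc_hold_days
    arm_code = ARMS.index(arm)
    w90 = min(TRIAL_WINDOW_DAYS, horizon)

    out = {
        k: np.zeros(n, dtype=np.int64)
        for k in (
            "readmissions",
            "readmissions_90",
            "er_visits",
            "er_visits_90",
            "death_day",
            "first_readmission_day",
        )
    }
    out["eoc"] = np.zeros(n, dtype=bool)
    for k in ("cost_undiscounted", "cost_discounted", "cost_discounted_90"):
        out[k] = np.zeros(n, dtype=float)
    histories: list[PatientHistory] | None = [] if record_histories else None

    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        m = stop - start
        uni = np.empty((m, 2, horizon))
        for j, pid in enumerate(range(start, stop)):
            rng = np.random.default_rng(np.random.SeedSequence((seed, arm_code, pid)))
            uni[j] = rng.random((2, horizon))

        state = np.full(m, OUT, dtype=np.int8)
        hold = np.zeros(m, dtype=np.int32)
        if record_histories:
            path = np.zeros((m, horizon + 1), dtype=np.int8)
            ev_log: list[list[tuple[int, str]]] = [[] for _ in range(m)]

        for d in range(1, horizon + 1):
            u = uni[:, 0, d - 1]
            v = uni[:, 1, d - 1]
            p_m, p_h, p_e = pm[d], ph[d], pe[d]
            t1 = p_m + (1.0 - p_m) * p_h
            t2 = t1 + (1.0 - p_m) * (1.0 - p_h) * p_e

            alive = state != DEAD
            die = alive & (u < p_m)
            state[die] = DEAD
            out["death_day"][start:stop][die] = d
            srv = alive & ~die
            snap = state.copy()

            m0 = srv & (snap == OUT)
            adm1 = m0 & (u >= p_m) & (u < t1)
            erv1 = m0 & (u >= t1) & (u < t2)
            state[adm1] = HOSP
            hold[adm1] = hosp_hold
            state[erv1] = ER

            m3 = srv & (snap == DISCH)
            adm2 = m3 & (u >= p_m) & (u < t1)
            erv2 = m3 & (u >= t1) & (u < t2)
            to_eoc = adm2 & (v < eoc_frac)
            state[to_eoc] = EOC
            hold[to_eoc] = eoc_hold
            sub = adm2 & ~to_eoc
            state[sub] = HOSP2
            hold[sub] = hosp_hold
            state[erv2] = ER_POST

            m1 = srv & (snap == ER)
            eradm = m1 & (v < f_admit)
            state[eradm] = HOSP
            hold[eradm] = hosp_hold
            state[m1 & ~eradm] = OUT

            m4 = srv & (snap == ER_POST)
            eradm2 = m4 & (v < f_admit)
            # u, renormalised past the death threshold, is a fresh uniform
            # for the escalation draw of ER-routed admissions.
            w = (u - p_m) / (1.0 - p_m)
            eoc2 = eradm2 & (w < eoc_frac)
            state[eoc2] = EOC
            hold[eoc2] = eoc_hold
            state[eradm2 & ~eoc2] = HOSP2
            state[m4 & ~eradm2] = DISCH

            for code, release in ((HOSP, DISCH), (HOSP2, DISCH), (EOC, POST_EOC)):
                mt = srv & (snap == code)
                hold[mt] -= 1
                done = mt & (hold == 0)
                state[done] = release

            readm = adm1 | adm2 | eradm | eradm2
            eoc_in = to_eoc | eoc2
            er_in = erv1 | erv2
            sl = slice(start, stop)
            out["readmissions"][sl] += readm
            out["er_visits"][sl] += er_in
            out["eoc"][sl] |= eoc_in
            first = out["first_readmission_day"][sl]
            first[readm & (first == 0)] = d
            if d <= w90:
                out["readmissions_90"][sl] += readm
                out["er_visits_90"][sl] += er_in

            cost = np.zeros(m)
            cost[state == OUT] += c_out
            cost[(state == DISCH) | (state == POST_EOC)] += c_post
            cost[(state == HOSP) | (state == HOSP2)] += c_hosp
            cost[state == EOC] += c_icu
            cost[readm & ~eoc_in] += extra_hosp
            cost[eoc_in] += extra_eoc
            cost[er_in] += c_er
            if arm == HFMS and dev[d] > 0:
                cost[state != DEAD] += dev[d]
            out["cost_undiscounted"][sl] += cost
            out["cost_discounted"][sl] += cost * disc[d]
            if d <= w90:
                out["cost_discounted_90"][sl] += cost * disc[d]

            if record_histories:
                path[:, d] = state
                for name, mask in (
                    ("readmission", readm),
                    ("er_visit", er_in),
                    ("eoc_entry", eoc_in),
                    ("death", die),
                ):
                    for j in np.nonzero(mask)[0]:
                        ev_log[j].append((d, name))

        if record_histories:
            for j, pid in enumerate(range(start, stop)):
                histories.append(
                    PatientHistory(
                        arm=arm,
                        states=path[j].copy(),
                        events=tuple(ev_log[j]),
                        cost_undiscounted=float(out["cost_undiscounted"][pid]),
                        cost_discounted=float(out["cost_discounted"][pid]),
                    )
                )

    return MicrosimResult(
        arm=arm, n=n, horizon_days=horizon, histories=histories, **out
    )


def make_synthetic_trial(
    inputs: ModelInputs, n_per_arm: int, seed: int
) -> pd.DataFrame:
    """Synthetic two-arm trial table emulating a 90-day monitoring study.

    One row per patient: arm, time to first readmission in days (censored
    at day 90 or at death, whichever comes first), the event indicator,
    death by day 90, and the 90-day ER visit count.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    horizon = min(TRIAL_WINDOW_DAYS, inputs.settings.horizon_days)
    frames = []
    for arm in ARMS:
        res = simulate_patients(inputs, arm, n_per_arm, seed, horizon_days=horizon)
        first = res.first_readmission_day
        death = res.death_day
        event = first > 0
        time = np.where(
            event, first, np.where(death > 0, death, horizon)
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.arange(n_per_arm) + (0 if arm == "SOC" else n_per_arm),
                    "arm": arm,
                    "time_to_first_readmission": time,
                    "readmitted": event.astype(int),
                    "death_by_90": res.died_by_90.astype(int),
                    "er_visits_90": res.er_visits_90,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
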