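"""Cost-effectiveness metrics: incremental cost and effect, ICER with
dominance classification, and net monetary benefit (NMB).

Effectiveness is counted in hospital readmissions per patient, so a
*negative* incremental effect (fewer readmissions with the intervention)
means better effectiveness. The intervention dominates when it is both
cheaper and more effective; it is dominated in the mirror case. On the
cost-effectiveness plane (x = incremental readmissions, y = incremental
cost) quadrants are labelled in the health-economics convention where the
dominant region is quadrant II.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["CEAResult", "icer", "nmb", "quadrant", "QUADRANT_LABELS"]

DOMINANT = "dominant"
DOMINATED = "dominated"

#: Cost-effectiveness-plane quadrant by (sign of delta_cost, sign of
#: delta_eff): II = cheaper and more effective (dominant), I = costlier and
#: more effective, IV = costlier and less effective (dominated), III =
#: cheaper and less effective.
QUADRANT_LABELS = {
    (1, -1): "I",
    (-1, -1): "II",
    (-1, 1): "III",
    (1, 1): "IV",
}


def quadrant(delta_cost: float, delta_eff: float) -> str:
    """CE-plane quadrant label; axis points resolve toward the
    more-effective half-plane."""
    se = -1 if delta_eff <= 0 else 1
    sc = 1 if delta_cost > 0 else -1
    return QUADRANT_LABELS[(sc, se)]


def nmb(delta_cost: float, delta_eff: float, wtp: float) -> float:
    """Net monetary benefit of the intervention at a WTP threshold.

    ``wtp x readmissions avoided - incremental cost``; non-negative NMB
    means the intervention is cost-effective at that threshold (the CE-plane
    point lies on or below the WTP line).
    """
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * (-delta_eff) - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Per-arm totals and incremental cost-effectiveness summary."""

    cost_soc: float
    cost_hfms: float
    eff_soc: float
    eff_hfms: float
    delta_cost: float
    delta_eff: float
    icer: float | str | None  # USD per readmission avoided, or dominance label
    nmb: float
    under_wtp: bool
    wtp: float

    @property
    def quadrant(self) -> str:
        return quadrant(self.delta_cost, self.delta_eff)

    def table(self) -> pd.DataFrame:
        """Base-case results table (one row per arm)."""
        icer_repr = self.icer if self.icer is not None else "undefined"
        if isinstance(icer_repr, float):
            icer_repr = f"{icer_repr:.0f}"
        return pd.DataFrame(
            {
                "arm": ["SOC", "HFMS"],
                "cost": [self.cost_soc, self.cost_hfms],
                "incremental_cost": [None, self.delta_cost],
                "effectiveness": [self.eff_soc, self.eff_hfms],
                "incremental_effectiveness": [None, self.delta_eff],
                "icer": [None, icer_repr],
            }
        )


def icer(
    cost_hfms: float,
    cost_soc: float,
    eff_hfms: float,
    eff_soc: float,
    wtp: float = 10737.0,
) -> CEAResult:
    """Incremental cost-effectiveness of the intervention vs standard care.

    Deltas are intervention minus comparator. The ICER is reported as the
    label ``dominant`` (cheaper, fewer readmissions) or ``dominated``
    (costlier, more readmissions) when a ratio would be misleading, as a
    finite ratio in the trade-off quadrants, and as ``None`` when the
    incremental effect is zero.
    """
    for v in (cost_hfms, cost_soc, eff_hfms, eff_soc):
        if not math.isfinite(v):
            raise ValueError("per-arm totals must be finite")
    delta_cost = cost_hfms - cost_soc
    delta_eff = eff_hfms - eff_soc
    ratio: float | str | None
    if delta_cost < 0 and delta_eff < 0:
        ratio = DOMINANT
    elif delta_cost > 0 and delta_eff > 0:
        ratio = DOMINATED
    elif delta_eff == 0:
        ratio = None
    else:
        ratio = delta_cost / delta_eff
    benefit = nmb(delta_cost, delta_eff, wtp)
    return CEAResult(
        cost_soc=cost_soc,
        cost_hfms=cost_hfms,
        eff_soc=eff_soc,
        eff_hfms=eff_hfms,
        delta_cost=delta_cost,
        delta_eff=delta_eff,
        icer=ratio,
        nmb=benefit,
        under_wtp=benefit >= 0.0,
        wtp=wtp,
    )
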