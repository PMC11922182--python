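"""One deterministic end-to-end model evaluation: both arms' cohort traces,
cost ledgers, and the incremental cost-effectiveness summary."""

from __future__ import annotations

from dataclasses import dataclass, field

from .costing import CostLedger, accrue
from .engine import ARMS, HFMS, SOC, CohortTrace, run_cohort
from .metrics import CEAResult, icer
from .parameters import ModelInputs

__all__ = ["DeterministicRun", "evaluate"]


@dataclass
class DeterministicRun:
    """Traces, ledgers, and CEA summary of one deterministic evaluation."""

    inputs: ModelInputs = field(repr=False)
    traces: dict[str, CohortTrace] = field(repr=False)
    ledgers: dict[str, CostLedger] = field(repr=False)
    cea: CEAResult

    @property
    def horizon_days(self) -> int:
        return self.traces[SOC].horizon_days


def evaluate(
    inputs: ModelInputs,
    horizon_days: int | None = None,
    wtp: float | None = None,
) -> DeterministicRun:
    """Run both arms over the horizon and compute the CEA summary.

    Effectiveness is total expected readmissions per patient; costs are
    total discounted USD per patient.
    """
    wtp = inputs.settings.wtp_per_readmission_avoided if wtp is None else wtp
    traces = {arm: run_cohort(inputs, arm, horizon_days) for arm in ARMS}
    ledgers = {arm: accrue(traces[arm], inputs, arm) for arm in ARMS}
    cea = icer(
        cost_hfms=ledgers[HFMS].total(),
        cost_soc=ledgers[SOC].total(),
        eff_hfms=traces[HFMS].expected_readmissions(),
        eff_soc=traces[SOC].expected_readmissions(),
        wtp=wtp,
    )
    return DeterministicRun(inputs=inputs, traces=traces, ledgers=ledgers, cea=cea)
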