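"""Model/results interface tying the engine, costing, metrics, and
sensitivity analyses together.

`CostEffectivenessModel` is constructed from a validated input set (or the
packaged base case) and evaluated with `run()`, which returns a
`CEAResults` object carrying per-arm traces, cost ledgers, the incremental
summary, and a printable `summary()`. Probabilistic and one-way sensitivity
analyses and the patient-level simulator hang off the same object.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import owsa as _owsa
from . import psa as _psa
from .costing import monthly_cumulative
from .deterministic import DeterministicRun, evaluate
from .engine import HFMS, SOC
from .microsim import MicrosimResult, make_synthetic_trial, simulate_patients
from .parameters import ModelInputs, load_base_case, load_inputs

__all__ = ["CostEffectivenessModel", "CEAResults"]


class CEAResults(DeterministicRun):
    """Deterministic run results with reporting helpers."""

    def table(self) -> pd.DataFrame:
        """Base-case results per patient (one row per arm)."""
        return self.cea.table()

    def monthly(self) -> pd.DataFrame:
        """Cumulative discounted cost and readmissions by 30-day month."""
        return monthly_cumulative(self.traces, self.ledgers)

    def cost_crossing_month(self) -> int | None:
        """First month in which cumulative intervention cost drops below
        cumulative standard-of-care cost (None if it never does)."""
        monthly = self.monthly().pivot(
            index="month", columns="arm", values="cumulative_cost"
        )
        below = monthly.index[monthly[HFMS] < monthly[SOC]]
        return int(below[0]) if len(below) else None

    def summary(self) -> str:
        cea = self.cea
        icer_line = (
            cea.icer if isinstance(cea.icer, str) else
            ("undefined" if cea.icer is None else f"{cea.icer:,.0f} per readmission avoided")
        )
        lines = [
            "Cost-effectiveness results per patient "
            f"({self.horizon_days}-day horizon, discounted)",
            "=" * 66,
            f"{'':14}{'cost (USD)':>16}{'readmissions':>16}",
            f"{'SOC':14}{cea.cost_soc:>16,.0f}{cea.eff_soc:>16.3f}",
            f"{'HFMS':14}{cea.cost_hfms:>16,.0f}{cea.eff_hfms:>16.3f}",
            f"{'incremental':14}{cea.delta_cost:>16,.0f}{cea.delta_eff:>16.3f}",
            "-" * 66,
            f"ICER: {icer_line}",
            f"NMB at WTP ${cea.wtp:,.0f}/readmission avoided: ${cea.nmb:,.0f}"
            f" ({'cost-effective' if cea.under_wtp else 'not cost-effective'})",
        ]
        return "\n".join(lines)


class CostEffectivenessModel:
    """Markov cohort cost-effectiveness model of wearable heart-failure
    monitoring (HFMS) versus standard of care."""

    def __init__(self, inputs: ModelInputs):
        self.inputs = inputs

    @classmethod
    def from_config(cls, config_path: str | Path) -> "CostEffectivenessModel":
        return cls(load_inputs(config_path))

    @classmethod
    def base_case(cls) -> "CostEffectivenessModel":
        """Model on the packaged base-case inputs."""
        return cls(load_base_case())

    @property
    def settings(self):
        return self.inputs.settings

    def run(self, horizon_days: int | None = None, wtp: float | None = None) -> CEAResults:
        """Deterministic evaluation of both arms."""
        run = evaluate(self.inputs, horizon_days=horizon_days, wtp=wtp)
        return CEAResults(
            inputs=run.inputs, traces=run.traces, ledgers=run.ledgers, cea=run.cea
        )

    def run_psa(
        self, n: int | None = None, seed: int | None = None, se_scale: float = 1.0
    ) -> _psa.PSAResults:
        """Probabilistic sensitivity analysis (see :mod:`hfcea.psa`)."""
        return _psa.run_psa(self.inputs, n=n, seed=seed, se_scale=se_scale)

    def run_owsa(
        self, fraction: float | None = None, wtp: float | None = None
    ) -> pd.DataFrame:
        """One-way sensitivity analysis; returns the sorted tornado table."""
        return _owsa.tornado_frame(_owsa.run_owsa(self.inputs, fraction, wtp))

    def simulate_patients(
        self, arm: str, n: int, seed: int, **kwargs
    ) -> MicrosimResult:
        """Patient-level Monte Carlo simulation of one arm."""
        return simulate_patients(self.inputs, arm, n, seed, **kwargs)

    def make_synthetic_trial(self, n_per_arm: int, seed: int) -> pd.DataFrame:
        """Synthetic 90-day two-arm trial table."""
        return make_synthetic_trial(self.inputs, n_per_arm, seed)
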