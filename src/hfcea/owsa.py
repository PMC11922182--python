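"""One-way (tornado) sensitivity analysis.

Each input is perturbed alone to mean x (1 - f) and mean x (1 + f), all
other inputs held at base, and the full deterministic model rerun. Entries
are ranked by the induced range in the deterministic ICER — computed as the
signed ratio of incremental cost to incremental effect, including in the
dominant quadrant — with the net monetary benefit (NMB) at the WTP
threshold reported alongside. Because per-day costs shared by both arms
largely cancel out of the incremental cost, an NMB ranking understates
inputs that scale the absolute cost of care; the ICER ranking, whose
numerator carries the same cancellation but whose magnitude is normalised
by the (cost-independent) incremental effect, is the outcome the published
tornado orderings in this literature correspond to. ``outcome="nmb"``
switches the ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .deterministic import evaluate
from .metrics import CEAResult
from .parameters import ModelInputs

__all__ = ["TornadoEntry", "run_owsa", "tornado_frame", "sweep_names"]

#: Settings fields swept in addition to the named clinical/cost inputs.
SWEPT_SETTINGS = ("hospital_los_days", "eoc_los_days", "eoc_fraction")


def _icer_ratio(cea: CEAResult) -> float:
    """Signed incremental cost / incremental effect (NaN when undefined)."""
    if cea.delta_eff == 0:
        return math.nan
    return cea.delta_cost / cea.delta_eff


@dataclass(frozen=True)
class TornadoEntry:
    """One input's low/high perturbation and the resulting outcomes."""

    name: str
    value_low: float
    value_high: float
    nmb_low: float
    nmb_high: float
    icer_low: float  # signed ratio; NaN when the incremental effect is 0
    icer_high: float
    outcome: str = "icer"

    @property
    def range(self) -> float:
        if self.outcome == "nmb":
            return abs(self.nmb_high - self.nmb_low)
        return abs(self.icer_high - self.icer_low)


def _perturbed(inputs: ModelInputs, name: str, value: float) -> ModelInputs:
    if name.startswith("settings."):
        field_name = name.split(".", 1)[1]
        new_settings = inputs.settings.model_copy(update={field_name: value})
        return inputs.model_copy(update={"settings": new_settings})
    return inputs.with_mean(name, value)


def _clamped(name: str, value: float, inputs: ModelInputs) -> float:
    """Keep perturbed values inside the input's support."""
    is_prob = name.startswith("rates.") or name.endswith(
        ("eoc_fraction", "er_to_hosp_fraction")
    )
    if is_prob and value >= 1.0:
        warnings.warn(
            f"{name}: perturbed value {value:.4g} exceeds 1; clamped",
            stacklevel=3,
        )
        return 1.0 - 1e-9
    return max(value, 0.0)


def sweep_names(inputs: ModelInputs) -> list[str]:
    """Inputs included in the tornado: all rates, effects, and costs, plus
    the structural settings (length of stay, EoC stay, EoC fraction)."""
    names = [f"rates.{k}" for k in inputs.rates]
    names += [f"effects.{k}" for k in inputs.effects]
    names += [f"costs.{k}" for k in inputs.costs]
    names += [f"settings.{k}" for k in SWEPT_SETTINGS]
    return names


def run_owsa(
    inputs: ModelInputs,
    fraction: float | None = None,
    wtp: float | None = None,
    outcome: str = "icer",
) -> list[TornadoEntry]:
    """Tornado sweep, sorted by descending outcome range.

    Entries whose range is undefined (zero incremental effect under
    ``outcome="icer"``) sort last.
    """
    st = inputs.settings
    fraction = st.owsa_fraction if fraction is None else fraction
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if outcome not in ("icer", "nmb"):
        raise ValueError("outcome must be 'icer' or 'nmb'")
    wtp = st.wtp_per_readmission_avoided if wtp is None else wtp
    entries = []
    for name in sweep_names(inputs):
        if name.startswith("settings."):
            base_value = getattr(st, name.split(".", 1)[1])
        else:
            base_value = inputs.get_param(name).mean
        lo = _clamped(name, base_value * (1.0 - fraction), inputs)
        hi = _clamped(name, base_value * (1.0 + fraction), inputs)
        outcomes = {}
        for tag, value in (("low", lo), ("high", hi)):
            cea = evaluate(_perturbed(inputs, name, value), wtp=wtp).cea
            outcomes[tag] = (cea.nmb, _icer_ratio(cea))
        entries.append(
            TornadoEntry(
                name=name,
                value_low=lo,
                value_high=hi,
                nmb_low=outcomes["low"][0],
                nmb_high=outcomes["high"][0],
                icer_low=outcomes["low"][1],
                icer_high=outcomes["high"][1],
                outcome=outcome,
            )
        )
    entries.sort(
        key=lambda e: e.range if math.isfinite(e.range) else -math.inf, reverse=True
    )
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado entries as a pre-sorted DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "input": [e.name for e in entries],
            "value_low": [e.value_low for e in entries],
            "value_high": [e.value_high for e in entries],
            "range": [e.range for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "nmb_low": [e.nmb_low for e in entries],
            "nmb_high": [e.nmb_high for e in entries],
        }
    )
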