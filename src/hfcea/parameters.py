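"""Model input schema, validation, and uncertainty bookkeeping.

The model consumes a small, fully enumerated parameter set: six cumulative
event probabilities with their observation windows, two treatment effects
(a hazard ratio on readmission and a risk ratio on mortality), six unit
costs in 2022 USD, and a block of run settings. Inputs carry optional 95%
confidence intervals; where an interval is printed it is converted to a
normal-theory standard error, otherwise a standard error is imputed as a
fixed fraction of the mean (10% for clinical inputs, 30% for costs).
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import ClassVar, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "InputClass",
    "CostUnit",
    "RateInput",
    "EffectInput",
    "CostInput",
    "Settings",
    "ModelInputs",
    "ci_to_se",
    "impute_se",
    "load_inputs",
    "save_inputs",
    "base_case_path",
    "load_base_case",
]

#: Half-width of a 95% normal interval, in standard errors.
_Z95_WIDTH = 3.92

#: Default imputed SE as a fraction of the mean, by input class.
SE_FRACTION_CLINICAL = 0.10
SE_FRACTION_COST = 0.30


class InputClass(str, enum.Enum):
    """Input taxonomy that determines the PSA sampling distribution."""

    probability = "probability"
    relative_risk = "relative_risk"
    cost = "cost"
    continuous = "continuous"


class CostUnit(str, enum.Enum):
    per_day = "per_day"
    per_visit = "per_visit"
    per_month = "per_month"


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a 95% confidence interval.

    Uses the normal-theory identity se = (hi - lo) / 3.92.
    """
    if ci_high < ci_low:
        raise ValueError(f"ci_high ({ci_high}) < ci_low ({ci_low})")
    return (ci_high - ci_low) / _Z95_WIDTH


def impute_se(mean: float, input_class: InputClass | str) -> float:
    """Imputed standard error for an input with no published interval.

    Clinical inputs (probabilities, relative risks, other continuous
    clinical quantities) get 10% of the mean; costs get 30%.
    """
    cls = InputClass(input_class)
    if cls in (InputClass.probability, InputClass.relative_risk, InputClass.continuous):
        return mean * SE_FRACTION_CLINICAL
    if cls is InputClass.cost:
        return mean * SE_FRACTION_COST
    raise ValueError(f"unknown input class: {input_class!r}")


class _Uncertain(BaseModel):
    """Shared CI / standard-error behaviour."""

    model_config = ConfigDict(validate_assignment=True)

    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    @model_validator(mode="after")
    def _check_ci(self) -> "_Uncertain":
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("ci_low and ci_high must be given together")
        if self.ci_low is not None:
            if not (self.ci_low <= self.mean <= self.ci_high):
                raise ValueError(
                    f"mean {self.mean} outside CI [{self.ci_low}, {self.ci_high}]"
                )
        return self

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None

    def se(self) -> float:
        """Standard error: from the CI when printed, imputed otherwise."""
        if self.has_ci:
            return ci_to_se(self.ci_low, self.ci_high)
        return impute_se(self.mean, self.input_class)


class RateInput(_Uncertain):
    """A cumulative event probability over a stated window of days."""

    mean: float = Field(ge=0.0, le=1.0)
    period_days: int = Field(gt=0)
    input_class: InputClass = InputClass.probability

    @model_validator(mode="after")
    def _check_bounds(self) -> "RateInput":
        if self.ci_low is not None and not (0.0 <= self.ci_low and self.ci_high <= 1.0):
            raise ValueError("rate CI must lie in [0, 1]")
        return self


class EffectInput(_Uncertain):
    """A multiplicative treatment effect (hazard or risk ratio)."""

    mean: float = Field(gt=0.0)
    input_class: InputClass = InputClass.relative_risk

    @model_validator(mode="after")
    def _check_positive(self) -> "EffectInput":
        if self.ci_low is not None and self.ci_low <= 0.0:
            raise ValueError("effect CI must be positive")
        return self


class CostInput(_Uncertain):
    """A unit cost in 2022 USD with an explicit accounting unit."""

    mean: float = Field(ge=0.0)
    unit: CostUnit
    input_class: InputClass = InputClass.cost
    #: Whether the PSA samples this cost (inputs flagged as assumptions
    #: without a variance are held fixed by default).
    sample_in_psa: bool = True


#: Settings fields whose defaults are analyst assumptions rather than
#: published values (the tornado structure implies them; no source prints
#: them).
ASSUMPTION_FIELDS = frozenset(
    {
        "hospital_los_days",
        "hospital_hold_days",
        "eoc_los_days",
        "eoc_hold_days",
        "er_to_hosp_fraction",
        "late_window_days",
        "post_readmission_additive",
    }
)


class Settings(BaseModel):
    """Run settings: horizon, discounting, thresholds, and structural knobs.

    ``hospital_los_days`` is the billed length of stay per admission (days of
    hospital per-day cost charged per readmission); ``hospital_hold_days`` is
    the number of daily cycles the cohort actually spends in the hospital
    state. Keeping the two separate lets length of stay act as a pure cost
    multiplier (the default) or as a genuine sojourn (set hold = los).
    """

    model_config = ConfigDict(validate_assignment=True)

    horizon_days: int = Field(default=1825, ge=1)
    cycle_days: int = Field(default=1)
    discount_rate_annual: float = Field(default=0.03, ge=0.0)
    wtp_per_readmission_avoided: float = Field(default=10737.0, ge=0.0)
    wtp_alternative: float = Field(default=17830.0, ge=0.0)
    effect_window_days: int = Field(default=90, ge=0)
    eoc_fraction: float = Field(default=0.025, ge=0.0, le=1.0)
    device_wear_months: int = Field(default=2, ge=0)
    psa_iterations: int = Field(default=1000, ge=1)
    owsa_fraction: float = Field(default=0.10, ge=0.0)
    # Structural assumptions (not printed anywhere; see docs/methods.md).
    hospital_los_days: float = Field(default=6.87, gt=0.0)
    hospital_hold_days: int = Field(default=1, ge=1)
    eoc_los_days: float = Field(default=5.0, gt=0.0)
    eoc_hold_days: int = Field(default=1, ge=1)
    er_to_hosp_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    late_window_days: int = Field(default=275, ge=1)
    post_readmission_additive: bool = False
    seed: int = Field(default=20220101, ge=0)

    assumption_fields: ClassVar[frozenset[str]] = ASSUMPTION_FIELDS

    @model_validator(mode="after")
    def _check(self) -> "Settings":
        if self.cycle_days != 1:
            raise ValueError("the engine is built on a 1-day cycle")
        if self.horizon_days < self.effect_window_days:
            raise ValueError("horizon_days must be >= effect_window_days")
        return self

    @property
    def assumption_derived(self) -> tuple[str, ...]:
        """Assumption-backed fields still at their package defaults."""
        return tuple(
            sorted(f for f in ASSUMPTION_FIELDS if f not in self.model_fields_set)
        )


#: Required entries and their human-readable labels (used in errors).
REQUIRED_RATES = {
    "hosp_early": "hospitalization rate at 3 months, SOC",
    "hosp_late": "hospitalization rate after 3 mo, SOC",
    "er_early": "emergency room visit rate at 3 mo, SOC",
    "er_late": "emergency room visit rate after 3 mo, SOC",
    "mort_early": "mortality rate at 3 mo, SOC",
    "mort_late": "mortality rate after 3 mo, SOC",
}
REQUIRED_EFFECTS = {
    "hr_hosp": "HFMS impact on hospitalization, hazard ratio",
    "rr_mort": "HFMS impact on mortality, risk ratio",
}
REQUIRED_COSTS = {
    "device_monthly": "cost of HFMS per month",
    "outpatient_daily": "outpatient care costs per day",
    "er_visit": "emergency room cost per visit",
    "hospital_daily": "cost of hospital stay per day",
    "icu_daily": "intensive care unit stay per day",
    "post_readmission_outpatient": "outpatient care costs after readmission",
}


class ModelInputs(BaseModel):
    """The complete, validated parameter set for one scenario."""

    model_config = ConfigDict(validate_assignment=True)

    rates: dict[str, RateInput]
    effects: dict[str, EffectInput]
    costs: dict[str, CostInput]
    settings: Settings = Field(default_factory=Settings)

    @model_validator(mode="after")
    def _check_complete(self) -> "ModelInputs":
        for block, required in (
            (self.rates, REQUIRED_RATES),
            (self.effects, REQUIRED_EFFECTS),
            (self.costs, REQUIRED_COSTS),
        ):
            missing = [f"{label} ({key})" for key, label in required.items() if key not in block]
            if missing:
                raise ValueError("missing required inputs: " + "; ".join(missing))
        return self

    def uncertain_inputs(self) -> dict[str, _Uncertain]:
        """Named inputs that carry sampling uncertainty in the PSA."""
        out: dict[str, _Uncertain] = {}
        out.update({f"rates.{k}": v for k, v in self.rates.items()})
        out.update({f"effects.{k}": v for k, v in self.effects.items()})
        out.update(
            {f"costs.{k}": v for k, v in self.costs.items() if v.sample_in_psa}
        )
        return out

    def get_param(self, name: str) -> _Uncertain:
        block, key = name.split(".", 1)
        return getattr(self, block)[key]

    def with_mean(self, name: str, mean: float) -> "ModelInputs":
        """Copy of the inputs with one named mean replaced (CI dropped)."""
        block, key = name.split(".", 1)
        new = self.model_copy(deep=True)
        entry = getattr(new, block)[key]
        update = {"mean": mean, "ci_low": None, "ci_high": None}
        getattr(new, block)[key] = entry.model_copy(update=update)
        return new


def _to_config_dict(inputs: ModelInputs) -> dict:
    def enc(entry: _Uncertain) -> dict:
        d: dict = {"mean": entry.mean}
        if entry.has_ci:
            d["ci"] = [entry.ci_low, entry.ci_high]
        for extra in ("period_days", "unit", "sample_in_psa"):
            if hasattr(entry, extra):
                val = getattr(entry, extra)
                d[extra] = val.value if isinstance(val, enum.Enum) else val
        return d

    return {
        "rates": {k: enc(v) for k, v in inputs.rates.items()},
        "effects": {k: enc(v) for k, v in inputs.effects.items()},
        "costs": {k: enc(v) for k, v in inputs.costs.items()},
        "settings": inputs.settings.model_dump(mode="json"),
    }


def _from_config_dict(raw: dict) -> ModelInputs:
    def dec(d: dict) -> dict:
        d = dict(d)
        ci = d.pop("ci", None)
        if ci is not None:
            d["ci_low"], d["ci_high"] = ci
        return d

    try:
        return ModelInputs.model_validate(
            {
                "rates": {k: dec(v) for k, v in raw.get("rates", {}).items()},
                "effects": {k: dec(v) for k, v in raw.get("effects", {}).items()},
                "costs": {k: dec(v) for k, v in raw.get("costs", {}).items()},
                "settings": raw.get("settings", {}),
            }
        )
    except Exception as exc:  # re-raise with a config-oriented message
        raise ValueError(f"invalid model configuration: {exc}") from exc


def load_inputs(config_path: str | Path) -> ModelInputs:
    """Load and validate a YAML model configuration."""
    path = Path(config_path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return _from_config_dict(raw)


def save_inputs(inputs: ModelInputs, config_path: str | Path) -> None:
    """Write a ModelInputs back to YAML (round-trips exactly)."""
    with Path(config_path).open("w") as fh:
        yaml.safe_dump(_to_config_dict(inputs), fh, sort_keys=False)


def base_case_path() -> Path:
    """Path of the packaged base-case configuration."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def load_base_case() -> ModelInputs:
    """The packaged base case (Table-1 values plus documented defaults)."""
    return load_inputs(base_case_path())
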