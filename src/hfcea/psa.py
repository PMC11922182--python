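"""Probabilistic sensitivity analysis (PSA).

Each uncertain input is assigned a parametric distribution by input class —
beta for probabilities, log-normal for relative risks, gamma for costs,
normal for other continuous inputs — with parameters moment-matched to the
input's mean and standard error (from the printed 95% CI when available,
imputed otherwise). Every iteration draws all inputs jointly and
independently, reruns both arms deterministically, and records the
incremental cost and effect; the scatter of iterations summarises decision
uncertainty on the cost-effectiveness plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deterministic import evaluate
from .metrics import quadrant
from .parameters import InputClass, ModelInputs

__all__ = ["ParamDistribution", "PSAResults", "fit_distribution", "run_psa", "summarize"]

_FAMILY_BY_CLASS = {
    InputClass.probability: "beta",
    InputClass.relative_risk: "lognormal",
    InputClass.cost: "gamma",
    InputClass.continuous: "normal",
}


@dataclass(frozen=True)
class ParamDistribution:
    """A fitted sampling distribution for one uncertain input.

    Moment-matched: the distribution's mean equals the input mean exactly
    and its standard deviation equals the target standard error (both up to
    floating-point error). A zero standard error yields a point mass.
    """

    name: str
    family: str
    mean: float
    se: float
    params: dict[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "point":
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size=size)
        if self.family == "normal":
            return rng.normal(self.mean, self.se, size=size)
        raise ValueError(f"unknown family {self.family!r}")

    def fitted_mean(self) -> float:
        """Analytic mean under the fitted parameters (moment-match check)."""
        p = self.params
        if self.family == "point":
            return self.mean
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "lognormal":
            return math.exp(p["mu"] + p["sigma"] ** 2 / 2)
        return self.mean

    def fitted_sd(self) -> float:
        p = self.params
        if self.family == "point":
            return 0.0
        if self.family == "beta":
            s = p["alpha"] + p["beta"]
            return math.sqrt(p["alpha"] * p["beta"] / (s**2 * (s + 1)))
        if self.family == "gamma":
            return math.sqrt(p["shape"]) * p["scale"]
        if self.family == "lognormal":
            m = self.fitted_mean()
            return m * math.sqrt(math.exp(p["sigma"] ** 2) - 1)
        return self.se


def fit_distribution(
    name: str, mean: float, se: float, input_class: InputClass | str
) -> ParamDistribution:
    """Moment-match the class-specific family to (mean, se)."""
    cls = InputClass(input_class)
    if se < 0:
        raise ValueError(f"{name}: se must be >= 0")
    if se == 0:
        return ParamDistribution(name, "point", mean, 0.0)
    family = _FAMILY_BY_CLASS[cls]
    v = se * se
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"{name}: beta requires mean in (0, 1), got {mean}")
        if v >= mean * (1.0 - mean):
            raise ValueError(
                f"{name}: variance {v:.3g} >= mean(1-mean) = "
                f"{mean * (1 - mean):.3g}; beta moment matching infeasible — "
                "reduce the standard error"
            )
        k = mean * (1.0 - mean) / v - 1.0
        params = {"alpha": mean * k, "beta": (1.0 - mean) * k}
    elif family == "gamma":
        if mean <= 0:
            raise ValueError(f"{name}: gamma requires mean > 0")
        params = {"shape": mean * mean / v, "scale": v / mean}
    elif family == "lognormal":
        if mean <= 0:
            raise ValueError(f"{name}: lognormal requires mean > 0")
        sigma2 = math.log1p(v / (mean * mean))
        params = {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
    else:  # normal
        params = {}
    return ParamDistribution(name, family, mean, se, params)


def fit_all(inputs: ModelInputs, se_scale: float = 1.0) -> dict[str, ParamDistribution]:
    """Fitted distributions for every PSA-sampled input, keyed by name."""
    out = {}
    for name, entry in inputs.uncertain_inputs().items():
        out[name] = fit_distribution(
            name, entry.mean, entry.se() * se_scale, entry.input_class
        )
    return out


@dataclass
class PSAResults:
    """Per-iteration PSA outputs plus the thresholds used."""

    iterations: pd.DataFrame = field(repr=False)  # one row per iteration
    draws: pd.DataFrame = field(repr=False)  # sampled input values
    wtp: float
    wtp_alternative: float
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.iterations)

    def quadrant_fractions(self) -> pd.Series:
        frac = self.iterations["quadrant"].value_counts(normalize=True)
        return frac.reindex(["I", "II", "III", "IV"], fill_value=0.0)

    def fraction_under_wtp(self, wtp: float | None = None) -> float:
        wtp = self.wtp if wtp is None else wtp
        nmb = wtp * (-self.iterations["delta_eff"]) - self.iterations["delta_cost"]
        return float((nmb >= 0).mean())

    def running_sd(self, column: str = "delta_cost") -> np.ndarray:
        """Running standard deviation over iterations 1..n (ddof=1)."""
        x = self.iterations[column].to_numpy()
        n = np.arange(1, len(x) + 1)
        csum = np.cumsum(x)
        csum2 = np.cumsum(x * x)
        var = np.full(len(x), np.nan)
        var[1:] = (csum2[1:] - csum[1:] ** 2 / n[1:]) / (n[1:] - 1)
        return np.sqrt(np.maximum(var, 0.0))

    def summary(self) -> dict[str, pd.DataFrame | float]:
        return summarize(self)


def run_psa(
    inputs: ModelInputs,
    n: int | None = None,
    seed: int | None = None,
    se_scale: float = 1.0,
) -> PSAResults:
    """Run the PSA: joint independent input draws, full model per draw.

    Reproducible given ``seed``; each iteration draws from its own RNG
    substream (spawned from the master seed), so results do not depend on
    execution order. ``se_scale`` rescales every standard error (0 turns
    each distribution into a point mass, reproducing the base case).
    """
    st = inputs.settings
    n = st.psa_iterations if n is None else int(n)
    seed = st.seed if seed is None else seed
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = fit_all(inputs, se_scale=se_scale)
    names = sorted(dists)
    streams = np.random.SeedSequence(seed).spawn(n)
    rows = []
    draw_rows = []
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        values = {name: float(dists[name].sample(rng)) for name in names}
        draw_rows.append(values)
        run = evaluate(_with_values(inputs, values))
        cea = run.cea
        rows.append(
            {
                "iteration": i,
                "cost_soc": cea.cost_soc,
                "cost_hfms": cea.cost_hfms,
                "eff_soc": cea.eff_soc,
                "eff_hfms": cea.eff_hfms,
                "delta_cost": cea.delta_cost,
                "delta_eff": cea.delta_eff,
                "nmb": cea.nmb,
                "under_wtp": cea.under_wtp,
                "quadrant": quadrant(cea.delta_cost, cea.delta_eff),
            }
        )
    return PSAResults(
        iterations=pd.DataFrame(rows),
        draws=pd.DataFrame(draw_rows),
        wtp=st.wtp_per_readmission_avoided,
        wtp_alternative=st.wtp_alternative,
        seed=seed,
    )


def _with_values(inputs: ModelInputs, values: dict[str, float]) -> ModelInputs:
    """Inputs copy with sampled means substituted (CIs dropped; the sampled
    value is exact, not an estimate with an interval)."""
    update: dict[str, dict] = {"rates": {}, "effects": {}, "costs": {}}
    for name, value in values.items():
        block, key = name.split(".", 1)
        update[block][key] = value
    new_blocks = {}
    for block in ("rates", "effects", "costs"):
        entries = dict(getattr(inputs, block))
        for key, value in update[block].items():
            entries[key] = entries[key].model_copy(
                update={"mean": value, "ci_low": None, "ci_high": None}
            )
        new_blocks[block] = entries
    return inputs.model_copy(update=new_blocks)


def summarize(results: PSAResults, wtp: float | None = None) -> dict:
    """Percentile-based PSA summary.

    Median and 95% credible interval (2.5th/97.5th percentiles, linear
    interpolation) of cost and readmissions per arm, the quadrant
    fractions, and the fraction of iterations under the primary and
    alternative WTP thresholds.
    """
    if results.n == 0:
        raise ValueError("empty PSA results")
    wtp = results.wtp if wtp is None else wtp
    it = results.iterations
    per_arm = []
    for arm, cost_col, eff_col in (
        ("SOC", "cost_soc", "eff_soc"),
        ("HFMS", "cost_hfms", "eff_hfms"),
    ):
        for quantity, col in (("cost", cost_col), ("readmissions", eff_col)):
            lo, med, hi = np.percentile(it[col], [2.5, 50.0, 97.5])
            per_arm.append(
                {
                    "arm": arm,
                    "quantity": quantity,
                    "median": med,
                    "cri_low": lo,
                    "cri_high": hi,
                }
            )
    return {
        "per_arm": pd.DataFrame(per_arm),
        "quadrant_fractions": results.quadrant_fractions(),
        "fraction_under_wtp": results.fraction_under_wtp(wtp),
        "fraction_under_wtp_alternative": results.fraction_under_wtp(
            results.wtp_alternative
        ),
    }
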