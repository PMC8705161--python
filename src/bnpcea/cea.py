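"""Incremental cost-effectiveness analytics.

Convention throughout: the intervention (BNP-guided care) is compared
against the comparator (standard clinical assessment), so increments are
BNP minus STANDARD.  A strategy is *dominant* when it saves money and gains
QALYs, *dominated* in the mirror case; otherwise the ICER dC/dE is reported
together with the net monetary benefit at the willingness-to-pay threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .engine import ArmTotals, run_cohort
from .params import Arm, ParameterBundle, with_overrides

__all__ = [
    "CEAResult",
    "incremental",
    "icer",
    "nmb",
    "compare_arms",
    "run_base_case",
    "run_subgroups",
    "run_scenarios",
    "SubgroupSpec",
    "ScenarioSpec",
]


@dataclass
class CEAResult:
    bnp: ArmTotals | None
    standard: ArmTotals | None
    delta_cost: float
    delta_qaly: float
    classification: str            # "dominant" | "dominated" | "icer" | "tie"
    icer_value: float | None       # present iff classification == "icer"
    nmb: float
    wtp: float

    @property
    def icer_display(self) -> str:
        """Integer display of the ICER, truncated toward zero."""
        if self.classification != "icer":
            return self.classification.capitalize()
        return str(math.trunc(self.icer_value))


def incremental(cost_a: float, qaly_a: float, cost_b: float, qaly_b: float) -> tuple[float, float]:
    """(delta_cost, delta_qaly), intervention *a* minus comparator *b*."""
    return cost_a - cost_b, qaly_a - qaly_b


def _classify(delta_cost: float, delta_qaly: float) -> tuple[str, float | None]:
    if delta_qaly == 0.0:
        if delta_cost < 0.0:
            return "dominant", None
        if delta_cost > 0.0:
            return "dominated", None
        return "tie", None
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return "dominant", None
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return "dominated", None
    return "icer", delta_cost / delta_qaly


def icer(delta_cost: float, delta_qaly: float, wtp: float = 20800.0) -> CEAResult:
    """Quadrant classification and ratio for one (dC, dE) pair."""
    classification, value = _classify(delta_cost, delta_qaly)
    return CEAResult(
        bnp=None,
        standard=None,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        classification=classification,
        icer_value=value,
        nmb=nmb(delta_cost, delta_qaly, wtp),
        wtp=wtp,
    )


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit: wtp * dE - dC; positive iff cost-effective."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly - delta_cost


def compare_arms(bnp: ArmTotals, standard: ArmTotals, wtp: float) -> CEAResult:
    d_cost, d_qaly = incremental(bnp.cost, bnp.qaly, standard.cost, standard.qaly)
    classification, value = _classify(d_cost, d_qaly)
    return CEAResult(
        bnp=bnp,
        standard=standard,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        classification=classification,
        icer_value=value,
        nmb=nmb(d_cost, d_qaly, wtp),
        wtp=wtp,
    )


def run_base_case(bundle: ParameterBundle) -> CEAResult:
    """Deterministic two-arm model run at the bundle's point estimates."""
    bnp = run_cohort(Arm.BNP, bundle).totals()
    std = run_cohort(Arm.STANDARD, bundle).totals()
    return compare_arms(bnp, std, bundle.config.wtp_threshold)


@dataclass
class SubgroupSpec:
    label: str
    start_age: float
    overrides: dict | None = None  # ModelConfig field overrides


@dataclass
class ScenarioSpec:
    label: str
    utilities: dict | None = None       # replacement state-utility values
    horizon_years: float | None = None


@dataclass
class LabelledResult:
    label: str
    result: CEAResult


def run_subgroups(bundle: ParameterBundle, specs: list[SubgroupSpec]) -> list[LabelledResult]:
    """One full two-arm run per age subgroup.

    The model carries no subgroup-specific clinical inputs, so subgroup
    differences are purely age-driven through background mortality.
    """
    out = []
    for spec in specs:
        overrides = dict(spec.overrides or {})
        overrides["start_age"] = spec.start_age
        sub = with_overrides(bundle, **overrides)
        out.append(LabelledResult(spec.label, run_base_case(sub)))
    return out


def run_scenarios(bundle: ParameterBundle, specs: list[ScenarioSpec]) -> list[LabelledResult]:
    """One full two-arm run per scenario; the base bundle is never mutated."""
    out = []
    for spec in specs:
        scen = bundle.copy()
        if spec.utilities is not None:
            unknown = set(spec.utilities) - set(scen.utilities.values)
            if unknown:
                raise ValueError(f"unknown utility state(s) in scenario '{spec.label}': {sorted(unknown)}")
            scen.utilities.values.update(spec.utilities)
        if spec.horizon_years is not None:
            scen.config = replace(scen.config, horizon_years=spec.horizon_years)
        out.append(LabelledResult(spec.label, run_base_case(scen)))
    return out
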