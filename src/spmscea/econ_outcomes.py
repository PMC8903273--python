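"""Discounted costs, life-years and QALYs, and incremental comparisons.

Costs and utilities are valued on start-of-cycle occupancy with no
half-cycle correction; the value accrued for cycle ``t`` is discounted by
``(1 + rate)**(-t)``, so the baseline cycle is undiscounted.  Dead occupancy
never accrues management cost or (dis)utility.  The year-1 versus later
administration/monitoring tariff is keyed to model time: the first cycle
uses the year-1 tariff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disease_model import (
    N_EDSS,
    ArmSpec,
    CohortTrace,
    expected_relapses,
    run_cohort,
)
from .exceptions import ConfigError, InvalidParameterError


@dataclass(frozen=True)
class UtilitySet:
    """Annual QALY weight per EDSS level (may be negative at EDSS 8-9)."""

    utility_by_edss: np.ndarray
    low_by_edss: np.ndarray | None = None
    high_by_edss: np.ndarray | None = None

    def __post_init__(self) -> None:
        u = np.asarray(self.utility_by_edss, dtype=float)
        object.__setattr__(self, "utility_by_edss", u)
        if u.shape != (N_EDSS,):
            raise InvalidParameterError(f"expected {N_EDSS} utilities")
        if np.any(u > 1.0):
            raise InvalidParameterError("utilities cannot exceed 1")

    def validate_monotone(self) -> None:
        """Check non-increasing utility in EDSS (base-case inputs only).

        PSA replicates draw levels independently and may transiently invert
        adjacent levels, so this is not enforced at construction.
        """
        if np.any(np.diff(self.utility_by_edss) > 1e-12):
            raise InvalidParameterError("utilities must be non-increasing in EDSS")


@dataclass(frozen=True)
class CostSet:
    """Annual cost inputs for one strategy (EUR).

    ``annual_units`` is the drug quantity required per 365.25-day year in
    pack units (tablets, vials); fractional packs are paid for.
    """

    management_by_edss: np.ndarray
    relapse_cost: float
    drug_price_ex_factory: float
    pack_size: float
    annual_units: float
    admin_monitoring_year1: float
    admin_monitoring_later: float

    def __post_init__(self) -> None:
        m = np.asarray(self.management_by_edss, dtype=float)
        object.__setattr__(self, "management_by_edss", m)
        if m.shape != (N_EDSS,):
            raise InvalidParameterError(f"expected {N_EDSS} management costs")
        if np.any(m < 0.0):
            raise InvalidParameterError("management costs must be non-negative")
        for name in (
            "relapse_cost",
            "drug_price_ex_factory",
            "admin_monitoring_year1",
            "admin_monitoring_later",
        ):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.annual_units > 0.0 and self.pack_size <= 0.0:
            raise ConfigError("pack_size must be positive when annual_units > 0")


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime outcomes for one strategy."""

    name: str
    total_cost: float
    life_years: float
    qalys: float


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of intervention versus reference."""

    delta_cost: float
    delta_qaly: float
    icer: float  # NaN when delta_qaly == 0
    nmb: float
    wtp: float
    icer_defined: bool
    dominant: bool  # cheaper and more effective
    dominated: bool  # dearer and less effective


def discount_factor(cycle: int, rate: float) -> float:
    """Discount weight ``(1 + rate)**(-cycle)``; cycle 0 is undiscounted."""
    if rate < 0.0:
        raise InvalidParameterError("discount rate must be non-negative")
    if cycle < 0:
        raise InvalidParameterError("cycle must be non-negative")
    return (1.0 + rate) ** (-cycle)


def annual_drug_cost(cost_set: CostSet) -> float:
    """Drug acquisition cost per patient-year: packs/year x ex-factory price."""
    if cost_set.annual_units == 0.0:
        return 0.0
    packs_per_year = cost_set.annual_units / cost_set.pack_size
    return packs_per_year * cost_set.drug_price_ex_factory


def accumulate(
    trace: CohortTrace,
    utilities: UtilitySet,
    costs: CostSet,
    arm: ArmSpec,
    relapse_probs: np.ndarray,
    rate: float,
) -> ArmResult:
    """Reduce a cohort trace to discounted cost, LYs and QALYs.

    Each of the trace's ``horizon`` cycles is valued on its start-of-cycle
    occupancy; the terminal state is not valued (it starts no year).
    """
    rp = np.asarray(relapse_probs, dtype=float)
    if rp.shape != (N_EDSS,):
        raise ConfigError(f"relapse_probs must have {N_EDSS} entries")
    drug = annual_drug_cost(costs)
    total_cost = 0.0
    life_years = 0.0
    qalys = 0.0
    for t in range(len(trace) - 1):
        state = trace.state(t)
        d = discount_factor(t, rate)
        live = state.live_by_edss
        life_years += d * live.sum()
        qalys += d * float(live @ utilities.utility_by_edss)
        admin = costs.admin_monitoring_year1 if t == 0 else costs.admin_monitoring_later
        cycle_cost = (
            float(live @ costs.management_by_edss)
            + expected_relapses(state, rp, arm.rr_arr) * costs.relapse_cost
            + state.on_treatment.sum() * (drug + admin)
        )
        total_cost += d * cycle_cost
    return ArmResult(
        name=arm.name, total_cost=total_cost, life_years=life_years, qalys=qalys
    )


def compare(reference: ArmResult, intervention: ArmResult, wtp: float) -> CEAResult:
    """Incremental cost, QALYs, ICER and net monetary benefit.

    Deltas are intervention minus reference.  Dominance cases are flagged,
    never raised; the ICER is NaN (``icer_defined=False``) when the QALY
    difference is exactly zero.
    """
    delta_cost = intervention.total_cost - reference.total_cost
    delta_qaly = intervention.qalys - reference.qalys
    defined = delta_qaly != 0.0
    icer = delta_cost / delta_qaly if defined else float("nan")
    nmb = wtp * delta_qaly - delta_cost
    return CEAResult(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        nmb=nmb,
        wtp=wtp,
        icer_defined=defined,
        dominant=(delta_cost < 0.0 and delta_qaly > 0.0),
        dominated=(delta_cost > 0.0 and delta_qaly < 0.0),
    )


@dataclass(frozen=True)
class CeaRun:
    """Paired arm outcomes plus their incremental comparison."""

    reference: ArmResult
    intervention: ArmResult
    comparison: CEAResult


def run_cea(params, wtp: float | None = None, horizon: int | None = None) -> CeaRun:
    """Run both strategies through the cohort model and compare them.

    ``params`` is a full parameter bundle (see
    :class:`spmscea.cli_io.ModelParams`): two strategies, the natural-history
    matrix, mortality, utilities and shared clinical inputs.
    """
    if wtp is None:
        wtp = params.wtp
    results = []
    for strategy in (params.reference, params.intervention):
        trace = run_cohort(strategy.arm, params, horizon=horizon)
        results.append(
            accumulate(
                trace,
                params.utilities,
                strategy.costs,
                strategy.arm,
                params.relapse_probs,
                params.discount_rate,
            )
        )
    ref, inter = results
    return CeaRun(reference=ref, intervention=inter, comparison=compare(ref, inter, wtp))
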