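"""Three-year budget-impact analysis of siponimod market entry.

The budget model is deliberately simpler than the cost-effectiveness engine:
the eligible prevalent population (from a multiplicative epidemiology
funnel) is held constant over the horizon, its baseline EDSS occupancy is
frozen, and the two market scenarios differ only in per-year DMT shares.
The budget impact is the difference in total payer expenditure between the
with-siponimod and without-siponimod worlds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .disease_model import N_EDSS
from .exceptions import ConfigError, InvalidParameterError

SHARE_TOL = 1e-9
WITH_LABEL = "with-siponimod"
WITHOUT_LABEL = "without-siponimod"
SIPONIMOD = "siponimod"

FUNNEL_STAGES = (
    "national_population",
    "prevalent_ms",
    "spms",
    "age_edss_3_65",
    "active_spms",
    "treated",
    "eligible",
)


@dataclass(frozen=True)
class EpidemiologyFunnel:
    """Multiplicative eligible-population funnel for Italy."""

    national_population: int
    ms_prevalence: float
    spms_share: float
    age_edss_share: float
    active_share: float
    treated_share: float
    eligible_share: float

    def __post_init__(self) -> None:
        if self.national_population <= 0:
            raise InvalidParameterError("national_population must be positive")
        for name in (
            "ms_prevalence",
            "spms_share",
            "age_edss_share",
            "active_share",
            "treated_share",
            "eligible_share",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")

    @property
    def proportions(self) -> tuple[float, ...]:
        return (
            self.ms_prevalence,
            self.spms_share,
            self.age_edss_share,
            self.active_share,
            self.treated_share,
            self.eligible_share,
        )


@dataclass(frozen=True)
class DmtCostSpec:
    """Per-patient annual cost components of one DMT (EUR).

    ``annual_units / pack_size`` packs are bought per year; administration
    and monitoring tariffs differ between a patient's first year on the DMT
    and later years; adverse-event management is a flat annual cost.
    """

    name: str
    drug_price_ex_factory: float = 0.0
    pack_size: float = 1.0
    annual_units: float = 0.0
    admin_monitoring_year1: float = 0.0
    admin_monitoring_later: float = 0.0
    ae_cost_annual: float = 0.0

    def __post_init__(self) -> None:
        if self.annual_units > 0.0 and self.pack_size <= 0.0:
            raise ConfigError(f"{self.name}: pack_size must be positive")
        for f in (
            "drug_price_ex_factory",
            "annual_units",
            "admin_monitoring_year1",
            "admin_monitoring_later",
            "ae_cost_annual",
        ):
            if getattr(self, f) < 0.0:
                raise InvalidParameterError(f"{self.name}: {f} must be non-negative")


@dataclass(frozen=True)
class MarketScenario:
    """Per-year DMT market shares over the treated eligible population."""

    label: str
    shares: dict[str, np.ndarray]  # DMT -> share per year
    n_years: int = field(default=3)

    def __post_init__(self) -> None:
        shares = {k: np.asarray(v, dtype=float) for k, v in self.shares.items()}
        object.__setattr__(self, "shares", shares)
        lengths = {v.shape[0] for v in shares.values()}
        if len(lengths) != 1:
            raise ConfigError(f"{self.label}: all DMTs must cover the same years")
        n_years = lengths.pop()
        object.__setattr__(self, "n_years", n_years)
        stacked = np.vstack(list(shares.values()))
        if np.any(stacked < -SHARE_TOL) or np.any(stacked > 1.0 + SHARE_TOL):
            raise ConfigError(f"{self.label}: shares must lie in [0, 1]")
        sums = stacked.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > SHARE_TOL):
            raise ConfigError(f"{self.label}: per-year shares must sum to 1, got {sums}")

    def share(self, dmt: str, year: int) -> float:
        return float(self.shares.get(dmt, np.zeros(self.n_years))[year])


@dataclass(frozen=True)
class BiaResult:
    """Annual and total budgets for both scenarios and their difference."""

    years: np.ndarray
    budget_with: np.ndarray
    budget_without: np.ndarray
    annual_difference: np.ndarray
    total_difference: float
    percent_difference: float  # of the without-siponimod total budget
    treated_counts: dict[str, np.ndarray]  # per DMT, with-siponimod scenario
    eligible: int


def eligibility_funnel(f: EpidemiologyFunnel, rounding: str = "nearest") -> list[int]:
    """Patient counts at each funnel stage.

    The running product is carried unrounded between stages; each stage is
    integerized only for reporting (``nearest`` rounds half away from zero,
    ``truncate`` floors).  Carrying the exact product is what reproduces the
    published Table of counts; re-multiplying already-rounded stages does not.
    """
    if rounding not in ("nearest", "truncate"):
        raise ConfigError(f"unknown rounding rule {rounding!r}")

    def integerize(x: float) -> int:
        return math.floor(x + 0.5) if rounding == "nearest" else math.floor(x)

    counts = [int(f.national_population)]
    running = float(f.national_population)
    for p in f.proportions:
        running *= p
        counts.append(integerize(running))
    return counts


def per_patient_annual_cost(dmt: DmtCostSpec, year_on_treatment: str) -> float:
    """Drug acquisition + administration/monitoring + AE management, EUR/year."""
    if year_on_treatment not in ("first", "later"):
        raise ConfigError(f"year_on_treatment must be 'first' or 'later', got {year_on_treatment!r}")
    drug = 0.0
    if dmt.annual_units > 0.0:
        drug = dmt.annual_units / dmt.pack_size * dmt.drug_price_ex_factory
    admin = (
        dmt.admin_monitoring_year1
        if year_on_treatment == "first"
        else dmt.admin_monitoring_later
    )
    return drug + admin + dmt.ae_cost_annual


def _scenario_budget(
    scenario: MarketScenario,
    baseline_shares: dict[str, float],
    dmt_costs: dict[str, DmtCostSpec],
    eligible: int,
    disease_cost_per_patient: float,
) -> np.ndarray:
    """Annual budget of one scenario.

    A DMT's share in excess of its previous-year share (the market before
    the horizon for year 1) is costed at the first-year tariff; the rest at
    the later-year tariff.
    """
    budgets = np.zeros(scenario.n_years)
    for year in range(scenario.n_years):
        total = disease_cost_per_patient
        for dmt, spec in dmt_costs.items():
            s = scenario.share(dmt, year)
            prev = (
                baseline_shares.get(dmt, 0.0)
                if year == 0
                else scenario.share(dmt, year - 1)
            )
            new = max(0.0, s - prev)
            cont = s - new
            total += new * per_patient_annual_cost(spec, "first")
            total += cont * per_patient_annual_cost(spec, "later")
        budgets[year] = eligible * total
    return budgets


def run_bia(
    funnel: EpidemiologyFunnel,
    scenario_without: MarketScenario,
    scenario_with: MarketScenario,
    dmt_costs: dict[str, DmtCostSpec],
    management_by_edss: np.ndarray,
    relapse_probs: np.ndarray,
    relapse_cost: float,
    baseline_distribution: np.ndarray,
    rounding: str = "nearest",
) -> BiaResult:
    """Budget difference between the with- and without-siponimod scenarios.

    Disease-management and relapse costs use the baseline EDSS occupancy of
    the eligible population, held fixed over the horizon; they are identical
    across scenarios and cancel in the difference, but are included so each
    scenario's budget is a complete payer expenditure.
    """
    if scenario_with.n_years != scenario_without.n_years:
        raise ConfigError("scenarios must cover the same number of years")
    if any(np.any(v > SHARE_TOL) for k, v in scenario_without.shares.items() if k == SIPONIMOD):
        raise ConfigError("the without-siponimod scenario must have zero siponimod share")
    universe = set(scenario_with.shares) | set(scenario_without.shares)
    missing = universe - set(dmt_costs)
    if missing:
        raise ConfigError(f"no cost specification for DMTs: {sorted(missing)}")

    dist = np.asarray(baseline_distribution, dtype=float)
    mgmt = np.asarray(management_by_edss, dtype=float)
    rel = np.asarray(relapse_probs, dtype=float)
    if not dist.shape == mgmt.shape == rel.shape == (N_EDSS,):
        raise ConfigError(f"distribution, management and relapse inputs must have {N_EDSS} entries")
    dist = dist / dist.sum()
    disease_cost = float(dist @ mgmt + dist @ rel * relapse_cost)

    eligible = eligibility_funnel(funnel, rounding=rounding)[-1]
    baseline_shares = {
        dmt: scenario_without.share(dmt, 0) for dmt in scenario_without.shares
    }
    costs_universe = {d: dmt_costs[d] for d in universe}
    b_without = _scenario_budget(
        scenario_without, baseline_shares, costs_universe, eligible, disease_cost
    )
    b_with = _scenario_budget(
        scenario_with, baseline_shares, costs_universe, eligible, disease_cost
    )
    diff = b_with - b_without
    counts = {
        dmt: np.array(
            [round(scenario_with.share(dmt, y) * eligible) for y in range(scenario_with.n_years)]
        )
        for dmt in sorted(universe)
    }
    return BiaResult(
        years=np.arange(1, scenario_with.n_years + 1),
        budget_with=b_with,
        budget_without=b_without,
        annual_difference=diff,
        total_difference=float(diff.sum()),
        percent_difference=float(100.0 * diff.sum() / b_without.sum()),
        treated_counts=counts,
        eligible=eligible,
    )
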