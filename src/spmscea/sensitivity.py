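"""One-way and probabilistic sensitivity analysis, CEAC, CDP-3 scenario.

Parameter uncertainty follows standard cost-effectiveness practice: beta
distributions for probabilities and utilities (location-shifted beta where
the published range is negative), gamma for costs, and lognormal for hazard
ratios and relative risks with ``sigma = (ln high - ln low) / (2 * 1.96)``.
Published ranges and 95% confidence intervals are treated as 95% interval
endpoints; moments are matched with the base value as the mean and
``(high - low) / 3.92`` as the standard deviation.  Draws are independent
across parameters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .disease_model import N_EDSS, TransitionMatrix
from .econ_outcomes import CeaRun, run_cea
from .exceptions import ConfigError

_MANAGEMENT_BANDS = {"edss0_3": slice(0, 4), "edss4_6": slice(4, 7), "edss7_9": slice(7, 10)}


# ---------------------------------------------------------------------------
# parameter access by name
# ---------------------------------------------------------------------------

def get_parameter(params, name: str) -> float:
    """Read a sensitivity parameter off a ModelParams bundle by name."""
    head, _, tail = name.partition(".")
    if head in ("reference", "intervention"):
        return getattr(getattr(params, head).arm, tail)
    if head == "utility":
        return float(params.utilities.utility_by_edss[_edss_index(tail)])
    if head == "relapse_prob":
        return float(params.relapse_probs[_edss_index(tail)])
    if name.startswith("cost.management."):
        band = name.rsplit(".", 1)[1]
        sl = _band_slice(band)
        return float(params.reference.costs.management_by_edss[sl][0])
    if name == "cost.relapse":
        return float(params.reference.costs.relapse_cost)
    raise ConfigError(f"unknown parameter name {name!r}")


def apply_parameters(params, overrides: dict[str, float]):
    """Return a new parameter bundle with named parameters replaced."""
    arm_over: dict[str, dict[str, float]] = {"reference": {}, "intervention": {}}
    utilities = None
    relapse = None
    management = None
    relapse_cost = None
    for name, value in overrides.items():
        head, _, tail = name.partition(".")
        if head in ("reference", "intervention"):
            if tail not in ("hr_cdp6", "rr_arr", "hr_discontinuation", "baseline_discontinuation"):
                raise ConfigError(f"unknown parameter name {name!r}")
            arm_over[head][tail] = value
        elif head == "utility":
            if utilities is None:
                utilities = params.utilities.utility_by_edss.copy()
            utilities[_edss_index(tail)] = value
        elif head == "relapse_prob":
            if relapse is None:
                relapse = params.relapse_probs.copy()
            relapse[_edss_index(tail)] = value
        elif name.startswith("cost.management."):
            if management is None:
                management = params.reference.costs.management_by_edss.copy()
            management[_band_slice(name.rsplit(".", 1)[1])] = value
        elif name == "cost.relapse":
            relapse_cost = value
        else:
            raise ConfigError(f"unknown parameter name {name!r}")

    new = params
    strategies = {}
    for role in ("reference", "intervention"):
        strategy = getattr(params, role)
        arm = strategy.arm
        if arm_over[role]:
            arm = dataclasses.replace(arm, **arm_over[role])
        costs = strategy.costs
        cost_over = {}
        if management is not None:
            cost_over["management_by_edss"] = management
        if relapse_cost is not None:
            cost_over["relapse_cost"] = relapse_cost
        if cost_over:
            costs = dataclasses.replace(costs, **cost_over)
        if arm is not strategy.arm or costs is not strategy.costs:
            strategy = dataclasses.replace(strategy, arm=arm, costs=costs)
        strategies[role] = strategy
    replacements = {"reference": strategies["reference"], "intervention": strategies["intervention"]}
    if utilities is not None:
        replacements["utilities"] = dataclasses.replace(
            params.utilities, utility_by_edss=utilities
        )
    if relapse is not None:
        replacements["relapse_probs"] = relapse
    return dataclasses.replace(new, **replacements)


def _edss_index(token: str) -> int:
    if not token.startswith("edss"):
        raise ConfigError(f"expected an edssN token, got {token!r}")
    i = int(token[4:])
    if not 0 <= i < N_EDSS:
        raise ConfigError(f"EDSS level {i} out of range")
    return i


def _band_slice(band: str) -> slice:
    if band not in _MANAGEMENT_BANDS:
        raise ConfigError(f"unknown management band {band!r}")
    return _MANAGEMENT_BANDS[band]


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty distribution of one named model parameter."""

    name: str
    kind: str  # beta | gamma | lognormal
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "gamma", "lognormal"):
            raise ConfigError(f"{self.name}: unknown distribution kind {self.kind!r}")
        if not self.low <= self.base <= self.high:
            raise ConfigError(
                f"{self.name}: base {self.base} outside bounds ({self.low}, {self.high})"
            )
        if self.kind == "lognormal" and self.low <= 0.0:
            raise ConfigError(f"{self.name}: lognormal bounds must be positive")
        if self.kind == "gamma" and self.base <= 0.0:
            raise ConfigError(f"{self.name}: gamma base must be positive")

    @property
    def degenerate(self) -> bool:
        return self.low == self.high

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the fitted distribution (base returned when degenerate)."""
        if self.degenerate:
            return self.base if size is None else np.full(size, self.base)
        sd = (self.high - self.low) / (2.0 * 1.96)
        if self.kind == "lognormal":
            sigma = (math.log(self.high) - math.log(self.low)) / (2.0 * 1.96)
            return rng.lognormal(mean=math.log(self.base), sigma=sigma, size=size)
        if self.kind == "gamma":
            shape = (self.base / sd) ** 2
            scale = sd**2 / self.base
            return rng.gamma(shape=shape, scale=scale, size=size)
        # beta: plain on [0, 1] when the range allows, else location-shifted
        if 0.0 <= self.low and self.high <= 1.0:
            lo, hi = 0.0, 1.0
        else:
            pad = 0.5 * (self.high - self.low)
            lo, hi = self.low - pad, self.high + pad
        width = hi - lo
        m = (self.base - lo) / width
        v = (sd / width) ** 2
        if v >= m * (1.0 - m):
            raise ConfigError(
                f"{self.name}: variance too large for a beta fit on [{lo}, {hi}]"
            )
        nu = m * (1.0 - m) / v - 1.0
        return lo + width * rng.beta(m * nu, (1.0 - m) * nu, size=size)


def default_distributions(params) -> list[ParameterDistribution]:
    """The default PSA/OWSA parameter set from the published ranges.

    Hazard ratios and relative risks are lognormal, utilities beta,
    management costs gamma, relapse probabilities beta.  Mortality
    multipliers and the transition matrix are not varied by default.
    """
    dists = []
    for name, (low, high) in sorted(params.ranges.items()):
        base = get_parameter(params, name)
        if name.endswith((".hr_cdp6", ".rr_arr", ".hr_discontinuation")):
            kind = "lognormal"
        elif name.startswith("cost."):
            kind = "gamma"
        else:  # utilities and relapse probabilities
            kind = "beta"
        dists.append(ParameterDistribution(name=name, kind=kind, base=base, low=low, high=high))
    return dists


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    name: str
    nmb_low: float  # NMB with the parameter at its low bound
    nmb_high: float  # NMB with the parameter at its high bound
    nmb_base: float

    @property
    def span(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def run_owsa(
    params, distributions: list[ParameterDistribution] | None = None, wtp: float | None = None
) -> list[TornadoEntry]:
    """Tornado analysis: NMB with each parameter at its bounds, others at base.

    Entries are sorted by decreasing span.  The base-case NMB stored on each
    entry is the deterministic NMB, computed once.
    """
    if distributions is None:
        distributions = default_distributions(params)
    if wtp is None:
        wtp = params.wtp
    base_nmb = run_cea(params, wtp=wtp).comparison.nmb
    entries = []
    for dist in distributions:
        nmbs = []
        for bound in (dist.low, dist.high):
            if bound == dist.base:
                nmbs.append(base_nmb)
                continue
            varied = apply_parameters(params, {dist.name: bound})
            nmbs.append(run_cea(varied, wtp=wtp).comparison.nmb)
        entries.append(
            TornadoEntry(name=dist.name, nmb_low=nmbs[0], nmb_high=nmbs[1], nmb_base=base_nmb)
        )
    return sorted(entries, key=lambda e: e.span, reverse=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsaDraws:
    """PSA replicates: parameter assignments and incremental outcomes."""

    assignments: pd.DataFrame  # one column per parameter, one row per replicate
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    reference_name: str
    intervention_name: str
    seed: int
    n: int


def sample_psa(
    params,
    distributions: list[ParameterDistribution] | None = None,
    n: int = 5000,
    seed: int = 0,
    vary_matrix: bool = False,
    dirichlet_concentration: float = 100.0,
) -> PsaDraws:
    """Monte-Carlo PSA: independent draws, one full model run per replicate.

    With ``vary_matrix=True`` each replicate also resamples every row of the
    natural-history matrix from a Dirichlet centred on it with the given
    concentration (off by default; the published analysis does not state
    whether the matrix was varied).
    """
    if n < 1:
        raise ConfigError("PSA needs at least one replicate")
    if distributions is None:
        distributions = default_distributions(params)
    rng = np.random.default_rng(seed)
    records = []
    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    for k in range(n):
        draw = {d.name: float(d.sample(rng)) for d in distributions}
        replicate = apply_parameters(params, draw)
        if vary_matrix:
            rows = [
                rng.dirichlet(np.maximum(row, 1e-12) * dirichlet_concentration)
                for row in params.natural_matrix.probs
            ]
            replicate = dataclasses.replace(
                replicate, natural_matrix=TransitionMatrix(np.vstack(rows))
            )
        result = run_cea(replicate).comparison
        d_cost[k] = result.delta_cost
        d_qaly[k] = result.delta_qaly
        records.append(draw)
    return PsaDraws(
        assignments=pd.DataFrame.from_records(records),
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        reference_name=params.reference.arm.name,
        intervention_name=params.intervention.arm.name,
        seed=seed,
        n=n,
    )


def ceac(draws: PsaDraws, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA replicates.

    For each willingness-to-pay value, the fraction of replicates in which
    each arm has the highest net benefit; ties favour the reference arm, so
    the per-WTP probabilities sum to one across the two arms.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100_001, 1000)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ConfigError("the WTP grid must be non-empty")
    inb = wtp_grid[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    p_int = (inb > 0.0).mean(axis=1)
    return pd.DataFrame(
        {
            "wtp": wtp_grid,
            draws.reference_name: 1.0 - p_int,
            draws.intervention_name: p_int,
        }
    )


def probability_cost_effective(draws: PsaDraws, wtp: float) -> float:
    """Probability the intervention is cost-effective at a single WTP."""
    return float((wtp * draws.delta_qaly - draws.delta_cost > 0.0).mean())


# ---------------------------------------------------------------------------
# CDP-3 alternative scenario
# ---------------------------------------------------------------------------

def cdp3_scenario(params, wtp: float | None = None) -> CeaRun:
    """Re-run the base-case pipeline with 3-month-confirmed progression HRs.

    Identical in every other input; only the progression hazard ratios of
    the two arms are substituted.
    """
    varied = apply_parameters(
        params,
        {
            "reference.hr_cdp6": params.cdp3_hr["reference"],
            "intervention.hr_cdp6": params.cdp3_hr["intervention"],
        },
    )
    return run_cea(varied, wtp=wtp)
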