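"""Multi-state EDSS disability-progression engine.

The disease model is an annual-cycle Markov cohort model on the Expanded
Disability Status Scale (EDSS).  The live state space is the 10 integer EDSS
levels 0-9, duplicated into an on-treatment and an off-treatment branch, plus
a single absorbing death state: 21 states in total.  Each cycle applies, in
this fixed order,

1. death, with an age/sex background probability scaled by an EDSS-specific
   mortality multiplier;
2. treatment discontinuation among on-treatment survivors below the stopping
   level (annual probability ``1 - (1 - baseline)**hr``);
3. an EDSS move, using the treatment-adjusted matrix on the on-treatment
   branch and the natural-history matrix off treatment;
4. the stopping rule: anyone on treatment who arrives at or above the stop
   level (EDSS 7 by default) is moved to the off-treatment branch.

Treatment efficacy enters as a hazard ratio on confirmed disability
progression applied on the rate scale: the aggregate per-row probability of
moving to any higher EDSS level ``p`` becomes ``1 - (1 - p)**hr``,
redistributed over the higher destinations in their original proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigError,
    InvalidMatrixError,
    InvalidParameterError,
    OutOfRangeError,
)

N_EDSS = 10
#: Index layout of the full state vector: on-treatment EDSS 0-9, then
#: off-treatment EDSS 0-9, then death.
ON = slice(0, N_EDSS)
OFF = slice(N_EDSS, 2 * N_EDSS)
DEAD = 2 * N_EDSS
N_STATES = 2 * N_EDSS + 1

ROW_SUM_TOL = 1e-12
MASS_TOL = 1e-9
#: Cohort runs stop once the live mass falls below this fraction.
LIVE_MASS_CUTOFF = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Annual row-stochastic transition probabilities over live EDSS levels.

    Death is handled separately by :class:`MortalityModel`; rows must sum to
    one over the 10 live destinations.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_EDSS, N_EDSS):
            raise InvalidMatrixError(f"expected ({N_EDSS},{N_EDSS}) matrix, got {p.shape}")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise InvalidMatrixError("transition probabilities must lie in [0, 1]")
        bad = np.abs(p.sum(axis=1) - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            rows = np.flatnonzero(bad).tolist()
            raise InvalidMatrixError(f"rows {rows} do not sum to 1 within {ROW_SUM_TOL}")

    @classmethod
    def from_csv(cls, path) -> "TransitionMatrix":
        """Load a 10x10 matrix from CSV with EDSS header row and row labels."""
        import pandas as pd

        frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if frame.shape != (N_EDSS, N_EDSS):
            raise InvalidMatrixError(
                f"{path}: expected a {N_EDSS}x{N_EDSS} labelled matrix, got {frame.shape}"
            )
        return cls(frame.to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        import pandas as pd

        labels = [f"EDSS{i}" for i in range(N_EDSS)]
        pd.DataFrame(self.probs, index=labels, columns=labels).to_csv(path)


@dataclass(frozen=True)
class ArmSpec:
    """One treatment strategy: relative efficacy, discontinuation, stop rule.

    ``hr_cdp6`` and ``rr_arr`` are versus placebo (the natural-history
    matrix); ``hr_discontinuation`` is versus the reference arm whose annual
    discontinuation probability is ``baseline_discontinuation``.
    ``stop_edss`` may be 10, meaning treatment is never stopped.
    """

    name: str
    hr_cdp6: float
    rr_arr: float
    baseline_discontinuation: float
    hr_discontinuation: float = 1.0
    stop_edss: int = 7

    def __post_init__(self) -> None:
        if self.hr_cdp6 <= 0.0:
            raise InvalidParameterError(f"{self.name}: hr_cdp6 must be > 0")
        if self.rr_arr <= 0.0:
            raise InvalidParameterError(f"{self.name}: rr_arr must be > 0")
        if self.hr_discontinuation <= 0.0:
            raise InvalidParameterError(f"{self.name}: hr_discontinuation must be > 0")
        if not 0.0 <= self.baseline_discontinuation < 1.0:
            raise InvalidParameterError(
                f"{self.name}: baseline_discontinuation must lie in [0, 1)"
            )
        if not 0 <= self.stop_edss <= N_EDSS:
            raise InvalidParameterError(f"{self.name}: stop_edss must lie in [0, {N_EDSS}]")

    @property
    def annual_discontinuation(self) -> float:
        """Arm-specific annual stopping probability, 1 - (1-baseline)^HR."""
        return 1.0 - (1.0 - self.baseline_discontinuation) ** self.hr_discontinuation


@dataclass(frozen=True)
class MortalityModel:
    """Background life table by age/sex plus EDSS mortality multipliers.

    The multiplier acts on the rate scale: the sex-mix-weighted background
    probability ``q`` becomes ``1 - (1 - q)**multiplier``, capped at one.
    """

    ages: np.ndarray
    q_male: np.ndarray
    q_female: np.ndarray
    edss_multipliers: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        qm = np.asarray(self.q_male, dtype=float)
        qf = np.asarray(self.q_female, dtype=float)
        mult = np.asarray(self.edss_multipliers, dtype=float)
        for name, arr in (("q_male", qm), ("q_female", qf)):
            if arr.shape != ages.shape:
                raise InvalidParameterError(f"{name} must match the age grid")
            if np.any(arr < 0.0) or np.any(arr > 1.0):
                raise InvalidParameterError(f"{name} probabilities must lie in [0, 1]")
        beyond30 = ages >= 30.0
        for name, arr in (("q_male", qm), ("q_female", qf)):
            if np.any(np.diff(arr[beyond30]) < 0.0):
                raise InvalidParameterError(f"{name} must be non-decreasing beyond age 30")
        if mult.shape != (N_EDSS,):
            raise InvalidParameterError(f"expected {N_EDSS} EDSS multipliers")
        if not np.isclose(mult[0], 1.0):
            raise InvalidParameterError("the EDSS-0 mortality multiplier must equal 1.0")
        if np.any(np.diff(mult) < 0.0):
            raise InvalidParameterError("EDSS mortality multipliers must be non-decreasing")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_male", qm)
        object.__setattr__(self, "q_female", qf)
        object.__setattr__(self, "edss_multipliers", mult)

    def background_probability(self, age: float, male_fraction: float) -> float:
        """Sex-mix-weighted annual all-cause death probability at ``age``."""
        if not 0.0 <= male_fraction <= 1.0:
            raise InvalidParameterError("male_fraction must lie in [0, 1]")
        if age < self.ages[0] or age > self.ages[-1]:
            raise OutOfRangeError(
                f"age {age} outside life table range "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        qm = float(np.interp(age, self.ages, self.q_male))
        qf = float(np.interp(age, self.ages, self.q_female))
        return male_fraction * qm + (1.0 - male_fraction) * qf

    def death_probabilities(self, age: float, male_fraction: float) -> np.ndarray:
        """EDSS-specific annual death probabilities at ``age`` (length 10)."""
        q = self.background_probability(age, male_fraction)
        return np.minimum(1.0, 1.0 - (1.0 - q) ** self.edss_multipliers)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"age": self.ages, "q_male": self.q_male, "q_female": self.q_female}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CohortState:
    """Occupancy of every model state at one cycle."""

    occupancy: np.ndarray  # length N_STATES, on/off/dead layout
    age: float
    cycle: int

    @property
    def on_treatment(self) -> np.ndarray:
        return self.occupancy[ON]

    @property
    def off_treatment(self) -> np.ndarray:
        return self.occupancy[OFF]

    @property
    def live_by_edss(self) -> np.ndarray:
        return self.occupancy[ON] + self.occupancy[OFF]

    @property
    def dead(self) -> float:
        return float(self.occupancy[DEAD])

    @property
    def live_mass(self) -> float:
        return float(self.occupancy[:DEAD].sum())

    def mean_edss(self) -> float:
        """Mean EDSS among the surviving cohort."""
        live = self.live_by_edss
        total = live.sum()
        if total <= 0.0:
            return float("nan")
        return float(live @ np.arange(N_EDSS) / total)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of a cohort run, one row per annual cycle."""

    occupancy: np.ndarray  # (horizon + 1, N_STATES)
    start_age: float
    horizon: int = field(default=0)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "horizon", occ.shape[0] - 1)

    def __len__(self) -> int:
        return self.occupancy.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(len(self))

    def state(self, cycle: int) -> CohortState:
        return CohortState(
            occupancy=self.occupancy[cycle],
            age=self.start_age + cycle,
            cycle=cycle,
        )

    @property
    def states(self) -> list[CohortState]:
        return [self.state(t) for t in range(len(self))]

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = (
            [f"on_edss{i}" for i in range(N_EDSS)]
            + [f"off_edss{i}" for i in range(N_EDSS)]
            + ["dead"]
        )
        frame = pd.DataFrame(self.occupancy, columns=cols)
        frame.insert(0, "age", self.ages)
        frame.insert(0, "cycle", np.arange(len(self)))
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def adjust_progression(matrix: TransitionMatrix, hr: float) -> TransitionMatrix:
    """Apply a disability-progression hazard ratio to a transition matrix.

    For each row the aggregate probability of moving to any strictly higher
    EDSS level, ``p``, is replaced by ``1 - (1 - p)**hr`` (the standard
    rate-scale conversion), redistributed across the higher destinations
    proportionally to their original shares.  The difference is absorbed by
    the stay probability; improvement probabilities are untouched, so the
    result remains row-stochastic.
    """
    if hr <= 0.0:
        raise InvalidParameterError("hazard ratio must be > 0")
    p = matrix.probs.copy()
    if hr == 1.0:  # exact identity, bit for bit
        return TransitionMatrix(p)
    for i in range(N_EDSS):
        up = p[i, i + 1 :]
        agg = up.sum()
        if agg <= 0.0:
            continue
        new_agg = 1.0 - (1.0 - agg) ** hr
        if p[i, i] + agg - new_agg < 0.0:
            raise InvalidParameterError(
                f"hazard ratio {hr} increases row {i}'s progression mass beyond "
                "what its stay probability can absorb"
            )
        p[i, i + 1 :] = up * (new_agg / agg)
        p[i, i] += agg - new_agg
    return TransitionMatrix(p)


def combined_death_probability(
    age: float, male_fraction: float, edss: int, mm: MortalityModel
) -> float:
    """Annual death probability at ``age`` for the given EDSS level.

    The sex-mix-weighted background probability is scaled on the rate scale
    by the EDSS multiplier and capped at one.
    """
    if not 0 <= edss < N_EDSS:
        raise InvalidParameterError(f"edss must lie in [0, {N_EDSS - 1}]")
    return float(mm.death_probabilities(age, male_fraction)[edss])


def _cycle_operator(
    q_death: np.ndarray,
    m_on: np.ndarray,
    m_off: np.ndarray,
    p_disc: float,
    stop_edss: int,
) -> np.ndarray:
    """Assemble the full 21x21 annual operator from its pieces.

    ``q_death`` is the EDSS-specific death probability vector; ``m_on`` and
    ``m_off`` are the EDSS-move matrices on and off treatment.  On-treatment
    rows at or above the stop level discontinue with probability one, which
    keeps the operator well defined for baseline mass seeded there.
    """
    surv = 1.0 - q_death
    levels = np.arange(N_EDSS)
    eff_disc = np.where(levels >= stop_edss, 1.0, p_disc)
    low = levels < stop_edss  # destinations that keep treatment going

    t = np.zeros((N_STATES, N_STATES))
    stay_on = surv[:, None] * (1.0 - eff_disc)[:, None] * m_on
    t[ON, ON] = stay_on * low[None, :]
    t[ON, OFF] = surv[:, None] * eff_disc[:, None] * m_off + stay_on * (~low)[None, :]
    t[ON, DEAD] = q_death
    t[OFF, OFF] = surv[:, None] * m_off
    t[OFF, DEAD] = q_death
    t[DEAD, DEAD] = 1.0
    return t


def build_cycle_operator(
    arm: ArmSpec,
    natural: TransitionMatrix,
    mm: MortalityModel,
    age: float,
    male_fraction: float,
) -> np.ndarray:
    """Full annual transition operator over (EDSS x treatment status) + death.

    Event order within a cycle is fixed: death competes first, survivors on
    treatment below the stop level may discontinue, survivors then move
    between EDSS levels (adjusted matrix on treatment, natural matrix off),
    and finally anyone arriving at or above the stop level while on treatment
    is moved to the off-treatment branch.
    """
    q = mm.death_probabilities(age, male_fraction)
    m_on = adjust_progression(natural, arm.hr_cdp6).probs
    return _cycle_operator(q, m_on, natural.probs, arm.annual_discontinuation, arm.stop_edss)


def run_cohort(arm: ArmSpec, params, horizon: int | None = None) -> CohortTrace:
    """Run the cohort through annual cycles from the baseline distribution.

    ``params`` supplies ``natural_matrix``, ``mortality``,
    ``baseline_distribution`` (fractions over EDSS levels summing to one),
    ``start_age`` and ``male_fraction``; see :class:`spmscea.cli_io.ModelParams`.
    The default horizon runs to ``params.max_age`` (age 100); the run also
    terminates early once live mass drops below ``LIVE_MASS_CUTOFF``.
    """
    base = np.asarray(params.baseline_distribution, dtype=float)
    if base.shape != (N_EDSS,):
        raise ConfigError(f"baseline distribution must have {N_EDSS} entries")
    if abs(base.sum() - 1.0) > 1e-6:
        raise ConfigError("baseline distribution must sum to 1 within 1e-6")
    if horizon is None:
        horizon = int(round(getattr(params, "max_age", 100.0) - params.start_age))
    if horizon < 1:
        raise ConfigError("horizon must be at least 1 cycle")

    natural = params.natural_matrix
    mm = params.mortality
    m_on = adjust_progression(natural, arm.hr_cdp6).probs
    p_disc = arm.annual_discontinuation

    v = np.zeros(N_STATES)
    v[ON] = base  # baseline cohort starts on treatment
    rows = [v]
    for t in range(horizon):
        if v[:DEAD].sum() < LIVE_MASS_CUTOFF:
            break
        age = params.start_age + t
        q = mm.death_probabilities(age, params.male_fraction)
        op = _cycle_operator(q, m_on, natural.probs, p_disc, arm.stop_edss)
        v = v @ op
        rows.append(v)
    return CohortTrace(occupancy=np.vstack(rows), start_age=params.start_age)


def expected_relapses(
    state: CohortState, relapse_probs: np.ndarray, arm_rr: float
) -> float:
    """Population-fraction-weighted relapse count for one cycle.

    The arm's annualised-relapse-rate relative risk applies on the
    on-treatment branch only.
    """
    rp = np.asarray(relapse_probs, dtype=float)
    if rp.shape != (N_EDSS,):
        raise InvalidParameterError(f"relapse_probs must have {N_EDSS} entries")
    return float(state.on_treatment @ rp * arm_rr + state.off_treatment @ rp)
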