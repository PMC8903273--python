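"""Generators for the model inputs that have no published source.

Three inputs of the original analyses exist only in unpublished appendix
material: the placebo-arm annual EDSS transition matrix, the background
life table, and the year-by-year DMT market shares.  This module generates
structurally faithful stand-ins so the whole pipeline runs and is testable
offline.  None of the generated objects claims to equal the unpublished
data; see ``docs/methods.md`` for what the defaults were calibrated to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .budget_impact import SIPONIMOD, WITH_LABEL, WITHOUT_LABEL, MarketScenario
from .disease_model import N_EDSS, MortalityModel, TransitionMatrix
from .exceptions import ConfigError


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic-input generators.

    Progression/improvement intensities are annual probabilities of a
    one-level EDSS move at level 0, scaled by ``progression_gradient**level``
    across levels; two-level jumps carry ``jump_fraction`` of the one-level
    mass.  Mortality is Gompertz, ``h(age) = a * exp(b * age)``.  Market
    uptake of siponimod is logistic with ceiling ``uptake_ceiling``, scaled
    by ``uptake_rate`` (0 disables entry).
    """

    seed: int = 0
    progression_intensity: float = 0.30
    improvement_intensity: float = 0.04
    progression_gradient: float = 0.97
    jump_fraction: float = 0.15
    jitter_sd: float = 0.05
    gompertz_a: float = 1.65e-5
    gompertz_b: float = 0.10
    male_mortality_factor: float = 1.6
    age_min: int = 18
    age_max: int = 100
    uptake_rate: float = 1.0
    uptake_ceiling: float = 0.42
    sipo_count_year1: int = 405
    sipo_count_year3: int = 2236
    calibration_eligible: int = 5827
    ifn_displacement: tuple[float, float, float] = (0.012, 0.016, 0.0)
    market_without: dict[str, float] = field(
        default_factory=lambda: {"interferon beta-1b": 0.60, "ocrelizumab": 0.40, "untreated": 0.0}
    )
    baseline_discontinuation: float = 0.10
    ae_costs: dict[str, float] = field(
        default_factory=lambda: {
            SIPONIMOD: 150.0,
            "interferon beta-1b": 300.0,
            "ocrelizumab": 200.0,
            "untreated": 0.0,
        }
    )

    def __post_init__(self) -> None:
        for name in ("progression_intensity", "improvement_intensity", "jump_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.baseline_discontinuation < 1.0:
            raise ConfigError("baseline_discontinuation must lie in [0, 1)")
        if self.uptake_rate < 0.0:
            raise ConfigError("uptake_rate must be non-negative")


def gen_transition_matrix(cfg: SyntheticConfig) -> TransitionMatrix:
    """Band-dominant row-stochastic annual EDSS transition matrix.

    Mass concentrates on staying and one-level moves, with small two-level
    jumps; progression mass exceeds improvement mass at every level.  A
    seeded multiplicative log-normal jitter makes the matrix non-degenerate
    while remaining deterministic for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    p = np.zeros((N_EDSS, N_EDSS))
    for i in range(N_EDSS):
        scale = cfg.progression_gradient**i
        up1 = cfg.progression_intensity * scale
        down1 = cfg.improvement_intensity * scale
        moves: dict[int, float] = {}
        if i + 1 < N_EDSS:
            moves[i + 1] = up1
        if i + 2 < N_EDSS:
            moves[i + 2] = cfg.jump_fraction * up1
        if i - 1 >= 0:
            moves[i - 1] = down1
        if i - 2 >= 0:
            moves[i - 2] = cfg.jump_fraction * down1
        for j in moves:
            moves[j] *= math.exp(rng.normal(0.0, cfg.jitter_sd))
        off_mass = sum(moves.values())
        if off_mass > 1.0:
            raise ConfigError(f"row {i}: move intensities sum to {off_mass:.3f} > 1")
        up_mass = sum(v for j, v in moves.items() if j > i)
        down_mass = sum(v for j, v in moves.items() if j < i)
        if i + 1 < N_EDSS and up_mass < down_mass:
            raise ConfigError(f"row {i}: improvement mass exceeds progression mass")
        p[i, i] = 1.0 - off_mass
        for j, v in moves.items():
            p[i, j] = v
    return TransitionMatrix(p)


def gen_life_table(cfg: SyntheticConfig, edss_multipliers=None) -> MortalityModel:
    """Gompertz background life table by single year of age and sex.

    Annual probabilities are ``1 - exp(-h)`` with hazard
    ``h = a * exp(b * age)``; male hazards are ``male_mortality_factor``
    times female hazards.  Defaults are calibrated so the female probability
    at age 48 is about 2 per 1000, a plausible general-population level.
    """
    if cfg.gompertz_a <= 0.0 or cfg.gompertz_b < 0.0:
        raise ConfigError("gompertz_a must be > 0 and gompertz_b >= 0")
    if edss_multipliers is None:
        edss_multipliers = np.array(
            [1.00, 1.43, 1.60, 1.64, 1.67, 1.84, 2.27, 3.10, 4.45, 6.45]
        )
    ages = np.arange(cfg.age_min, cfg.age_max + 1, dtype=float)
    hazard = cfg.gompertz_a * np.exp(cfg.gompertz_b * ages)
    return MortalityModel(
        ages=ages,
        q_male=1.0 - np.exp(-hazard * cfg.male_mortality_factor),
        q_female=1.0 - np.exp(-hazard),
        edss_multipliers=np.asarray(edss_multipliers, dtype=float),
    )


def _logistic_shares(cfg: SyntheticConfig, eligible: int) -> np.ndarray:
    """Siponimod market share in years 1-3 from the logistic uptake curve.

    The curve's rate and midpoint are solved exactly so the treated counts
    hit the two calibration anchors (year-1 and year-3 counts at the
    calibration population), then scaled to the actual eligible population
    and by ``uptake_rate``.
    """
    if eligible <= 0:
        raise ConfigError("eligible population must be positive")
    if cfg.uptake_rate == 0.0:
        return np.zeros(3)
    k = cfg.uptake_ceiling
    s1 = cfg.sipo_count_year1 / cfg.calibration_eligible
    s3 = cfg.sipo_count_year3 / cfg.calibration_eligible
    if not 0.0 < s1 < k or not s1 < s3 < k:
        raise ConfigError(
            "logistic calibration infeasible: anchor shares must satisfy "
            f"0 < {s1:.3f} < {s3:.3f} < ceiling {k}"
        )
    e1 = k / s1 - 1.0
    e3 = k / s3 - 1.0
    rate = 0.5 * math.log(e1 / e3)
    midpoint = 1.0 + math.log(e1) / rate
    years = np.arange(1, 4, dtype=float)
    shares = k / (1.0 + np.exp(-rate * (years - midpoint)))
    return cfg.uptake_rate * shares


def gen_market_scenarios(
    cfg: SyntheticConfig, eligible: int
) -> tuple[MarketScenario, MarketScenario]:
    """The without- and with-siponimod market scenarios over 3 years.

    The without-siponimod scenario holds ``market_without`` shares flat.
    In the with-siponimod scenario the displaced share comes from interferon
    beta-1b by the configured per-year amounts (concentrated in years 1-2)
    and from ocrelizumab for the remainder, so ocrelizumab absorbs most of
    the displacement in the final year.
    """
    sipo = _logistic_shares(cfg, eligible)
    without_shares = {dmt: np.full(3, s) for dmt, s in cfg.market_without.items()}
    without_shares[SIPONIMOD] = np.zeros(3)

    ifn = "interferon beta-1b"
    ocr = "ocrelizumab"
    if ifn not in cfg.market_without or ocr not in cfg.market_without:
        raise ConfigError("market_without must include interferon beta-1b and ocrelizumab")
    d_ifn = cfg.uptake_rate * np.asarray(cfg.ifn_displacement, dtype=float)
    d_ifn = np.minimum(d_ifn, sipo)  # cannot displace more than siponimod takes
    d_ocr = sipo - d_ifn
    with_shares = {dmt: np.full(3, s) for dmt, s in cfg.market_without.items()}
    with_shares[SIPONIMOD] = sipo
    with_shares[ifn] = with_shares[ifn] - d_ifn
    with_shares[ocr] = with_shares[ocr] - d_ocr
    if np.any(with_shares[ifn] < 0.0) or np.any(with_shares[ocr] < 0.0):
        raise ConfigError(
            "calibration infeasible: siponimod uptake exceeds the displaceable "
            "interferon/ocrelizumab share"
        )
    return (
        MarketScenario(label=WITHOUT_LABEL, shares=without_shares),
        MarketScenario(label=WITH_LABEL, shares=with_shares),
    )


def write_bundle(cfg: SyntheticConfig, out_dir) -> dict[str, str]:
    """Write the full synthetic input bundle to ``out_dir``.

    Emits the transition-matrix CSV, the life-table CSV and a YAML file with
    the two market scenarios; returns the file paths written.  Outputs are
    byte-identical for a fixed config.
    """
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix_path = out / "transition_matrix.csv"
    life_path = out / "life_table.csv"
    scen_path = out / "market_scenarios.yaml"

    gen_transition_matrix(cfg).to_csv(matrix_path)
    gen_life_table(cfg).to_csv(life_path)
    without, with_ = gen_market_scenarios(cfg, cfg.calibration_eligible)
    payload = {
        sc.label: {dmt: [float(x) for x in v] for dmt, v in sorted(sc.shares.items())}
        for sc in (without, with_)
    }
    scen_path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return {
        "transition_matrix": str(matrix_path),
        "life_table": str(life_path),
        "market_scenarios": str(scen_path),
    }
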