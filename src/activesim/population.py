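"""Synthetic population of adult women in an 8-ward city.

Generates agents with age, height, initial body composition, home and
work locations, income, car and smartphone access, and a per-day
baseline propensity to exercise.  The population emulates the 167,356
African American women aged 18-65 of the study city; the demographic
marginals are parametric stand-ins (no census microdata is read), with
ward population shares anchored at the two published ward denominators
(ward 6: 20,739; ward 7: 32,729) and the remainder split evenly.

Body composition is initialised by splitting the BMI-implied weight
into fat and lean mass with the Deurenberg body-fat equation for women,
and caloric intake is calibrated so that each agent's weight is exactly
stationary in the absence of class participation (no compensatory
eating: intake never changes during a simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import ward_rect
from .metabolism import MetabolicParams, total_expenditure

N_STUDY_POPULATION = 167_356
_S6 = 20_739 / N_STUDY_POPULATION
_S7 = 32_729 / N_STUDY_POPULATION
_REST = (1.0 - _S6 - _S7) / 6
#: default ward population shares (wards 1..8)
DEFAULT_WARD_SHARES = (_REST, _REST, _REST, _REST, _REST, _S6, _S7, _REST)

#: default car ownership by ward (invented; lowest in the least-served wards)
DEFAULT_CAR_OWNERSHIP = (0.62, 0.62, 0.62, 0.62, 0.62, 0.68, 0.45, 0.55)

AGENT_COLUMNS = [
    "id", "age", "height", "fat_mass", "lean_mass", "ward_id",
    "home_x", "home_y", "work_x", "work_y", "income",
    "has_car", "has_smartphone", "baseline_exercise_prob", "intake",
]

__all__ = [
    "N_STUDY_POPULATION",
    "DEFAULT_WARD_SHARES",
    "DEFAULT_CAR_OWNERSHIP",
    "AGENT_COLUMNS",
    "Agent",
    "PopulationSpec",
    "init_body_composition",
    "generate_population",
    "calibrate_intake",
    "write_population_csv",
    "read_population_csv",
]


@dataclass
class Agent:
    """One simulated woman (scalar view of a population row)."""

    id: int
    age: float
    height: float
    fat_mass: float
    lean_mass: float
    ward_id: int
    home_xy: tuple[float, float]
    work_xy: tuple[float, float]
    income: float
    has_car: bool
    has_smartphone: bool
    baseline_exercise_prob: float
    intake: float = float("nan")

    @property
    def weight(self) -> float:
        return self.fat_mass + self.lean_mass

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


@dataclass(frozen=True)
class PopulationSpec:
    """Parametric description of the synthetic population.

    The defaults emulate the study population: 167,356 women aged
    18-65, ~80% smartphone ownership, initial BMI lognormal with a
    median of 30.2 kg/m^2 (initial overweight/obesity prevalence is a
    modelling choice: the study reports only year-5 outcomes).
    """

    n_agents: int = N_STUDY_POPULATION
    ward_shares: tuple = DEFAULT_WARD_SHARES
    smartphone_ownership: float = 0.80
    car_ownership: tuple = DEFAULT_CAR_OWNERSHIP
    age_range: tuple = (18.0, 65.0)
    height_mean: float = 1.63
    height_sd: float = 0.07
    bmi_median: float = 30.2
    bmi_sigma: float = 0.23  # sdlog of the lognormal
    bmi_range: tuple = (16.0, 55.0)
    income_median: float = 45_000.0
    income_sigma: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("PopulationSpec.n_agents must be positive")
        if len(self.ward_shares) != 8:
            raise ValueError("PopulationSpec.ward_shares must list 8 wards")
        if abs(sum(self.ward_shares) - 1.0) > 1e-9:
            raise ValueError("PopulationSpec.ward_shares must sum to 1")
        for name in ("smartphone_ownership",):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"PopulationSpec.{name} must be a probability")
        if any(not 0.0 <= p <= 1.0 for p in self.car_ownership):
            raise ValueError("PopulationSpec.car_ownership entries must be probabilities")
        if self.height_mean <= 0 or self.height_sd < 0:
            raise ValueError("PopulationSpec.height_distribution parameters invalid")
        if self.bmi_median <= 10 or self.bmi_sigma <= 0:
            raise ValueError("PopulationSpec.bmi_distribution parameters invalid")


def init_body_composition(bmi, age, height):
    """Split BMI-implied weight into (fat, lean) mass.

    Uses the Deurenberg equation for women, BF% = 1.2*BMI + 0.23*age - 5.4,
    with the fat fraction clamped to [0.05, 0.60].  Fat and lean always
    sum exactly to ``bmi * height**2``.
    """
    bmi = np.asarray(bmi, dtype=float)
    age = np.asarray(age, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be strictly positive")
    if np.any(bmi <= 10):
        raise ValueError("bmi must exceed 10")
    weight = bmi * height**2
    bf = np.clip((1.2 * bmi + 0.23 * age - 5.4) / 100.0, 0.05, 0.60)
    fat = bf * weight
    lean = weight - fat
    if fat.ndim == 0:
        return float(fat), float(lean)
    return fat, lean


def calibrate_intake(lean_mass, metabolic: MetabolicParams):
    """Daily intake (kcal) making weight stationary with zero participation.

    With no class exercise the only expenditure is maintenance TEE, so
    the calibrated intake is exactly the initial TEE; it is stored on
    the agent and never changed afterwards.
    """
    return total_expenditure(lean_mass, metabolic)


def generate_population(
    spec: PopulationSpec,
    metabolic: MetabolicParams | None = None,
    ward_size_km: float = 4.0,
) -> pd.DataFrame:
    """Generate the agent table (one row per agent, ``AGENT_COLUMNS``).

    Ward membership is multinomial in the configured shares; smartphone
    and car flags are Bernoulli at their configured (per-ward, for cars)
    rates; home and work locations are uniform within the home ward's
    rectangle.  The result is reproducible for a fixed ``spec.seed``.

    ``baseline_exercise_prob`` is initialised to NaN here and set by the
    scenario; intake is calibrated against ``metabolic`` (defaults used
    when omitted).
    """
    metabolic = metabolic or MetabolicParams()
    n = spec.n_agents
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xA,)))

    ward_id = rng.choice(np.arange(1, 9), size=n, p=np.asarray(spec.ward_shares) / sum(spec.ward_shares))
    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    height = np.clip(rng.normal(spec.height_mean, spec.height_sd, size=n), 1.40, 1.95)
    bmi = np.clip(
        np.exp(rng.normal(np.log(spec.bmi_median), spec.bmi_sigma, size=n)),
        spec.bmi_range[0], spec.bmi_range[1],
    )
    fat, lean = init_body_composition(bmi, age, height)

    rects = np.array([ward_rect(w, ward_size_km) for w in range(1, 9)])  # (8, 4)
    x0, y0, x1, y1 = (rects[ward_id - 1, k] for k in range(4))
    home_x = rng.uniform(x0, x1)
    home_y = rng.uniform(y0, y1)
    work_x = rng.uniform(x0, x1)
    work_y = rng.uniform(y0, y1)

    income = np.exp(rng.normal(np.log(spec.income_median), spec.income_sigma, size=n))
    car_rate = np.asarray(spec.car_ownership)[ward_id - 1]
    has_car = rng.random(n) < car_rate
    has_smartphone = rng.random(n) < spec.smartphone_ownership

    pop = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "height": height,
            "fat_mass": fat,
            "lean_mass": lean,
            "ward_id": ward_id,
            "home_x": home_x,
            "home_y": home_y,
            "work_x": work_x,
            "work_y": work_y,
            "income": income,
            "has_car": has_car,
            "has_smartphone": has_smartphone,
            "baseline_exercise_prob": np.full(n, np.nan),
            "intake": calibrate_intake(lean, metabolic),
        }
    )
    return pop


def write_population_csv(population: pd.DataFrame, path) -> None:
    population.to_csv(path, index=False, columns=AGENT_COLUMNS)


def read_population_csv(path) -> pd.DataFrame:
    pop = pd.read_csv(path)
    missing = set(AGENT_COLUMNS) - set(pop.columns)
    if missing:
        raise ValueError(f"population file missing columns: {sorted(missing)}")
    return pop
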