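"""Replicate simulations, scenario contrasts and summary statistics.

The engine advances the whole population one day at a time: evening
prompts from the app -> the five-gate participation decision -> class
energy expenditure -> the two-compartment mass update.  Years are 364
days (52 exact weeks) so minutes-per-week aggregation is exact; the
default horizon is 5 years and experiments run 10 replicates.

Replicates share the same synthetic city (population + centers) and
differ only in their behavior/app random streams.  Streams are laid out
so that scenarios run under the same master seed are compared under
common random numbers: the same agent sees the same uniforms on the
same day in every scenario, and the app can only move gate thresholds
upward.  Consequently the no-app scenario and an engagement triple with
zero awareness are bit-identical, and participation is monotone in
every engagement component — the property the paired scenario
contrasts rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .app import sample_app_states
from .config import DAYS_PER_YEAR, ScenarioConfig
from .environment import access_profile, build_environment
from .metabolism import bmi_category
from .population import generate_population

__all__ = [
    "SimulationResult",
    "OutcomeSummary",
    "build_world",
    "run_simulation",
    "run_experiment",
    "run_grid",
    "participation_metrics",
    "compare",
    "t_ci",
]

METRICS = [
    "percent_ever_exercised",
    "mean_pa_min_per_week",
    "overweight_prev",
    "obesity_prev",
    "mean_bmi",
    "mean_bmi_obese",
    "daily_participation_pct",
    "monthly_participation_pct",
]

MONTH_DAYS = 30


@dataclass
class SimulationResult:
    """Output of one replicate: final agent table plus aggregates."""

    agents: pd.DataFrame
    time_series: pd.DataFrame
    daily_counts: np.ndarray
    monthly_fractions: np.ndarray
    access_fraction: float
    app_counts: dict
    n_days: int

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def daily_rate(self) -> float:
        """Mean % of the population attending on a given day."""
        return float(self.daily_counts.mean() / self.n_agents * 100.0)

    @property
    def monthly_rate(self) -> float:
        """Mean % attending at least once per 30-day window."""
        return float(self.monthly_fractions.mean() * 100.0)

    @property
    def ever_rate(self) -> float:
        """% of the population attending at least once over the horizon."""
        return float(self.agents["ever"].mean() * 100.0)


def build_world(config: ScenarioConfig) -> dict:
    """Generate the city shared by all replicates of an experiment.

    The population (with its calibrated intakes and the scenario's
    baseline exercise probability), the recreation centers, and the
    per-agent accessibility profile depend only on the population seed
    and the environment spec — not on the engagement triple — so
    scenarios differing only in the app share one world.
    """
    pop = generate_population(
        config.population, config.metabolic, config.environment.ward_size_km
    )
    pop["baseline_exercise_prob"] = config.baseline_exercise_prob
    centers = build_environment(config.environment, config.population.seed)
    profile = access_profile(pop, centers, config.environment)
    return {"population": pop, "centers": centers, "profile": profile}


def _streams(config: ScenarioConfig, replicate: int) -> tuple:
    behavior = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xB0, replicate))
    )
    app = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0xA9, replicate))
    )
    return behavior, app


def run_simulation(
    config: ScenarioConfig, replicate: int = 0, world: dict | None = None
) -> SimulationResult:
    """Run one replicate of a scenario.

    Deterministic for a fixed (config, replicate).  ``world`` may be
    passed in to share the generated city across replicates/scenarios.
    """
    if world is None:
        world = build_world(config)
    pop = world["population"]
    profile = world["profile"]
    n = len(pop)
    T = config.horizon_days
    env = config.environment
    met = config.metabolic
    gates = config.gates

    access = profile["access"]
    class_day = profile["class_day"]  # (n, 7)
    geofence = profile["geofence"]
    if not access.any():
        warnings.warn("no agent has objective access to any center; participation will be zero")

    rng_b, rng_a = _streams(config, replicate)

    # per-agent habit multiplier on the preparedness gate (identity when off);
    # drawn unconditionally to keep streams aligned across configurations
    habit = np.exp(rng_b.normal(0.0, 1.0, size=n) * gates.habit_sd)
    p5_base = np.clip(gates.p_prepared * habit, 0.0, 1.0)
    p5_app = np.clip(gates.p_prepared_app * habit, 0.0, 1.0)

    states = sample_app_states(
        n,
        config.engagement,
        config.attrition,
        rng_a,
        has_smartphone=pop["has_smartphone"].to_numpy(),
    )
    notif = states["notifications"]
    churn_day = states["churn_day"]
    app_counts = {
        "n_aware": int(states["aware"].sum()),
        "n_download": int(states["downloaded"].sum()),
        "n_notify": int(notif.sum()),
    }

    fat = pop["fat_mass"].to_numpy(dtype=float).copy()
    lean = pop["lean_mass"].to_numpy(dtype=float).copy()
    height2 = pop["height"].to_numpy(dtype=float) ** 2
    intake = pop["intake"].to_numpy(dtype=float)
    # the scenario owns the baseline propensity, so one world can serve a
    # whole baseline x engagement grid
    baseline = np.full(n, config.baseline_exercise_prob)

    duration = env.class_duration
    mets_eff = env.class_intensity - 1.0 if met.met_resting_subtracted else env.class_intensity
    kcal_per_kg = mets_eff * duration / 60.0
    intro = config.app_intro_day

    ever = np.zeros(n, dtype=bool)
    total_minutes = np.zeros(n, dtype=float)
    year_minutes = np.zeros(n, dtype=float)
    daily_counts = np.zeros(T, dtype=np.int64)
    window_hit = np.zeros(n, dtype=bool)
    monthly_fractions = []
    ts_rows = []

    for d in range(T):
        wd = d % 7
        ds = d - intro
        # evening prompt sent the night before for today's classes
        prompted = notif & (ds - 1 >= 0) & (ds - 1 < churn_day) & class_day[:, wd]
        geo = notif & (ds >= 0) & (ds < churn_day) & geofence

        u = rng_b.random((n, 4))
        g3 = np.where(geo, gates.p_perceived_access_app, gates.p_perceived_access)
        g4 = np.where(prompted, gates.p_class_awareness_app, gates.p_class_awareness)
        g5 = np.where(prompted, p5_app, p5_base)
        part = (
            (u[:, 0] < baseline)
            & class_day[:, wd]
            & (u[:, 1] < g3)
            & (u[:, 2] < g4)
            & (u[:, 3] < g5)
        )

        daily_counts[d] = part.sum()
        ever |= part
        window_hit |= part
        minutes = np.where(part, duration, 0.0)
        total_minutes += minutes
        year_minutes += minutes

        ex = np.where(part, kcal_per_kg * (fat + lean), 0.0)
        net = intake - met.pal * (met.rmr_slope * lean + met.rmr_intercept) - ex
        p = met.forbes_c / (met.forbes_c + fat)
        lean = np.maximum(lean + p * net / met.rho_lean, met.lean_floor)
        fat = np.maximum(fat + (1.0 - p) * net / met.rho_fat, met.fat_floor)

        if (d + 1) % MONTH_DAYS == 0:
            monthly_fractions.append(window_hit.mean())
            window_hit[:] = False
        if (d + 1) % DAYS_PER_YEAR == 0:
            bmi = (fat + lean) / height2
            ts_rows.append(
                {
                    "year": (d + 1) // DAYS_PER_YEAR,
                    "mean_bmi": bmi.mean(),
                    "obesity_prev": (bmi >= 30).mean() * 100.0,
                    "overweight_prev": ((bmi >= 25) & (bmi < 30)).mean() * 100.0,
                    "percent_ever_exercised": ever.mean() * 100.0,
                    "pa_min_per_week": year_minutes.mean() / (DAYS_PER_YEAR / 7.0),
                }
            )
            year_minutes[:] = 0.0

    bmi = (fat + lean) / height2
    agents = pop[["id", "ward_id", "height", "age"]].copy()
    agents["fat_mass"] = fat
    agents["lean_mass"] = lean
    agents["bmi"] = bmi
    agents["category"] = bmi_category(bmi)
    agents["ever"] = ever
    agents["total_minutes"] = total_minutes
    agents["pa_min_per_week"] = total_minutes / (T / 7.0)

    return SimulationResult(
        agents=agents,
        time_series=pd.DataFrame(ts_rows),
        daily_counts=daily_counts,
        monthly_fractions=np.asarray(monthly_fractions),
        access_fraction=float(access.mean()),
        app_counts=app_counts,
        n_days=T,
    )


def _agent_metrics(agents: pd.DataFrame, daily_rate=np.nan, monthly_rate=np.nan) -> dict:
    bmi = agents["bmi"]
    obese = bmi >= 30
    return {
        "percent_ever_exercised": agents["ever"].mean() * 100.0,
        "mean_pa_min_per_week": agents["pa_min_per_week"].mean(),
        "overweight_prev": ((bmi >= 25) & ~obese).mean() * 100.0,
        "obesity_prev": obese.mean() * 100.0,
        "mean_bmi": bmi.mean(),
        "mean_bmi_obese": bmi[obese].mean() if obese.any() else np.nan,
        "daily_participation_pct": daily_rate,
        "monthly_participation_pct": monthly_rate,
    }


def t_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi) across replicates; t-distribution, df = R - 1.

    With a single replicate the CI is undefined and reported as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.nan, np.nan, np.nan
    mean = float(v.mean())
    if v.size < 2:
        return mean, np.nan, np.nan
    half = stats.t.ppf(0.5 + confidence / 2.0, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return mean, mean - half, mean + half


@dataclass
class OutcomeSummary:
    """Replicate-level outcomes of one scenario.

    ``replicates`` has one row per replicate with every population
    metric; ``wards`` one row per (replicate, ward); ``time_series``
    one row per (replicate, year).  ``summary()`` and
    ``ward_summary()`` aggregate with means and 95% CIs computed
    across replicates only.
    """

    config: ScenarioConfig
    replicates: pd.DataFrame
    wards: pd.DataFrame
    time_series: pd.DataFrame
    access_fraction: float

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in METRICS:
            mean, lo, hi = t_ci(self.replicates[metric].dropna())
            rows.append({"metric": metric, "mean": mean, "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows)

    def ward_summary(self) -> pd.DataFrame:
        rows = []
        for ward, grp in self.wards.groupby("ward_id"):
            for metric in [m for m in METRICS if m in grp.columns]:
                mean, lo, hi = t_ci(grp[metric].dropna())
                rows.append(
                    {"ward_id": ward, "metric": metric, "mean": mean, "ci_lo": lo, "ci_hi": hi}
                )
        return pd.DataFrame(rows)

    def __getitem__(self, metric: str) -> tuple[float, float, float]:
        return t_ci(self.replicates[metric].dropna())


def run_experiment(
    config: ScenarioConfig, world: dict | None = None, progress: bool = False
) -> OutcomeSummary:
    """Run all replicates of a scenario and aggregate.

    Replicates share the generated city and differ in behavioral/app
    randomness; every metric is reported as a mean with a 95% t CI
    across replicates.
    """
    if world is None:
        world = build_world(config)
    rep_rows, ward_rows, ts_rows = [], [], []
    for rep in range(config.replicates):
        res = run_simulation(config, replicate=rep, world=world)
        row = _agent_metrics(res.agents, res.daily_rate, res.monthly_rate)
        row["replicate"] = rep
        row.update(res.app_counts)
        rep_rows.append(row)
        for ward, grp in res.agents.groupby("ward_id"):
            wrow = _agent_metrics(grp)
            wrow.update({"replicate": rep, "ward_id": int(ward)})
            ward_rows.append(wrow)
        ts = res.time_series.copy()
        ts["replicate"] = rep
        ts_rows.append(ts)
        if progress:
            print(f"  replicate {rep + 1}/{config.replicates} done", flush=True)
    return OutcomeSummary(
        config=config,
        replicates=pd.DataFrame(rep_rows),
        wards=pd.DataFrame(ward_rows),
        time_series=pd.concat(ts_rows, ignore_index=True),
        access_fraction=float(world["profile"]["access"].mean()),
    )


def run_grid(configs: dict, world: dict | None = None, progress: bool = False) -> dict:
    """Run a named family of scenarios sharing one city (CRN pairing)."""
    if world is None:
        first = next(iter(configs.values()))
        world = build_world(first)
    out = {}
    for name, cfg in configs.items():
        if progress:
            print(f"scenario {name}", flush=True)
        out[name] = run_experiment(cfg, world=world, progress=progress)
    return out


def participation_metrics(participation: np.ndarray) -> tuple[float, float, float]:
    """(daily %, monthly %, ever %) from a (days, agents) attendance matrix.

    daily: mean over days of the share attending that day; monthly:
    mean over complete 30-day windows of the share attending at least
    once in the window; ever: share attending at least once overall.
    Requires at least 30 days so one monthly window exists.
    """
    part = np.asarray(participation, dtype=bool)
    T, n = part.shape
    if T < MONTH_DAYS:
        raise ValueError("need at least 30 days of records")
    daily = part.mean() * 100.0
    n_windows = T // MONTH_DAYS
    windows = part[: n_windows * MONTH_DAYS].reshape(n_windows, MONTH_DAYS, n)
    monthly = windows.any(axis=1).mean(axis=1).mean() * 100.0
    ever = part.any(axis=0).mean() * 100.0
    return float(daily), float(monthly), float(ever)


def compare(treated: OutcomeSummary, control: OutcomeSummary) -> pd.DataFrame:
    """Paired per-replicate deltas (treated - control) with 95% t CIs.

    Scenarios must share seed and replicate count (common random
    numbers pair the replicates); a delta is flagged significant when
    its CI excludes zero.
    """
    if len(treated.replicates) != len(control.replicates):
        raise ValueError("scenarios must have the same number of replicates")
    if treated.config.seed != control.config.seed:
        raise ValueError("paired comparison requires a shared master seed")
    rows = []
    for metric in METRICS:
        diff = (treated.replicates[metric] - control.replicates[metric]).dropna()
        mean, lo, hi = t_ci(diff)
        significant = bool(np.isfinite(lo) and (lo > 0 or hi < 0))
        rows.append(
            {"metric": metric, "delta": mean, "ci_lo": lo, "ci_hi": hi, "significant": significant}
        )
    return pd.DataFrame(rows)
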