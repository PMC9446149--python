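import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import activesim as asim
from activesim.cli import main as cli_main
from activesim.config import save_config
from activesim.experiment import t_ci


def saturating_config(n=300, years=1, seed=5):
    """Everyone has access, classes daily, every gate certain."""
    return asim.ScenarioConfig(
        population=asim.PopulationSpec(n_agents=n, seed=seed, car_ownership=(1.0,) * 8),
        environment=asim.EnvironmentSpec(
            centers_per_ward=(2,) * 8, class_days=tuple(range(7)), drive_reach_km=50.0
        ),
        gates=asim.GateParams(
            p_perceived_access=1.0, p_class_awareness=1.0, p_prepared=1.0,
            p_perceived_access_app=1.0, p_class_awareness_app=1.0, p_prepared_app=1.0,
        ),
        baseline_exercise_prob=1.0,
        horizon_years=years,
        replicates=1,
        seed=seed,
    )


class TestRunSimulation:
    def test_deterministic_for_fixed_seed(self, small_config, small_world):
        a = asim.run_simulation(small_config, 0, small_world)
        b = asim.run_simulation(small_config, 0, small_world)
        pd.testing.assert_frame_equal(a.agents, b.agents)
        assert np.array_equal(a.daily_counts, b.daily_counts)

    def test_null_scenario_zero_participation_and_weight_change(self, small_world):
        cfg = asim.ScenarioConfig(
            population=asim.PopulationSpec(n_agents=2000, seed=11),
            baseline_exercise_prob=0.0,
            horizon_years=1,
            replicates=1,
            seed=11,
        )
        res = asim.run_simulation(cfg, 0, small_world)
        assert res.daily_counts.sum() == 0
        start = small_world["population"]
        drift = np.abs(
            res.agents["fat_mass"].to_numpy() + res.agents["lean_mass"].to_numpy()
            - start["fat_mass"].to_numpy() - start["lean_mass"].to_numpy()
        )
        assert drift.max() < 1e-9

    def test_saturating_scenario_everyone_exercises_in_first_week(self):
        res = asim.run_simulation(saturating_config())
        assert res.ever_rate == 100.0
        assert (res.daily_counts[:7] == res.n_agents).all()
        # weekly minutes cap: daily classes at 50 min = 350 min/week
        assert res.agents["pa_min_per_week"].max() == pytest.approx(350.0)

    def test_infeasible_config_warns_and_runs(self):
        cfg = asim.ScenarioConfig(
            population=asim.PopulationSpec(n_agents=100, seed=1, car_ownership=(0.0,) * 8),
            environment=asim.EnvironmentSpec(
                centers_per_ward=(0,) * 8, walk_reach_km=0.1, drive_reach_km=0.1
            ),
            horizon_years=1,
            replicates=1,
        )
        with pytest.warns(UserWarning, match="objective access"):
            res = asim.run_simulation(cfg)
        assert res.daily_counts.sum() == 0


class TestParticipationMetrics:
    def test_universal_daily_attendance(self):
        part = np.ones((60, 40), dtype=bool)
        assert asim.participation_metrics(part) == (100.0, 100.0, 100.0)

    def test_single_attendance_counting(self):
        part = np.zeros((1820, 100), dtype=bool)
        part[5, 0] = True
        daily, monthly, ever = asim.participation_metrics(part)
        assert daily == pytest.approx(100.0 / (1820 * 100))
        # exactly one of the 60 complete windows has a participant
        assert monthly == pytest.approx((1.0 / 100) / 60 * 100)
        assert ever == pytest.approx(1.0)

    def test_rate_ordering_daily_monthly_ever(self, rng):
        part = rng.random((364, 200)) < 0.02
        daily, monthly, ever = asim.participation_metrics(part)
        assert daily <= monthly <= ever

    def test_requires_thirty_days(self):
        with pytest.raises(ValueError, match="30 days"):
            asim.participation_metrics(np.zeros((10, 5), dtype=bool))


class TestConfidenceIntervals:
    def test_single_replicate_ci_undefined(self):
        mean, lo, hi = t_ci([3.0])
        assert mean == 3.0 and np.isnan(lo) and np.isnan(hi)

    def test_identical_replicates_zero_width(self):
        mean, lo, hi = t_ci([2.0, 2.0, 2.0])
        assert mean == lo == hi == 2.0

    def test_matches_scipy_t_interval(self):
        vals = [1.0, 2.0, 4.0, 3.0, 2.5]
        from scipy import stats

        mean, lo, hi = t_ci(vals)
        ref = stats.t.interval(
            0.95, len(vals) - 1, loc=np.mean(vals), scale=stats.sem(vals)
        )
        assert (lo, hi) == pytest.approx(ref)


class TestRunExperiment:
    def test_self_comparison_is_exactly_zero(self, small_config, small_world):
        summary = asim.run_experiment(small_config, world=small_world)
        delta = asim.compare(summary, summary)
        assert (delta["delta"].abs() < 1e-12).all()
        assert not delta["significant"].any()

    def test_summary_shapes_and_bounds(self, small_config, small_world):
        summary = asim.run_experiment(small_config, world=small_world)
        table = summary.summary()
        assert set(table["metric"]) == set(asim.experiment.METRICS)
        prev = summary.replicates[["overweight_prev", "obesity_prev"]]
        assert ((prev.sum(axis=1) <= 100) & (prev >= 0).all(axis=1)).all()
        wards = summary.ward_summary()
        assert set(summary.wards["ward_id"]) == set(range(1, 9))
        assert len(wards) > 0

    def test_mismatched_replicates_rejected(self, small_config, small_world):
        a = asim.run_experiment(small_config, world=small_world)
        b = asim.run_experiment(small_config.replace(replicates=1), world=small_world)
        with pytest.raises(ValueError, match="replicates"):
            asim.compare(a, b)

    def test_mismatched_seeds_rejected(self, small_config, small_world):
        a = asim.run_experiment(small_config, world=small_world)
        b = asim.run_experiment(small_config.replace(seed=99), world=small_world)
        with pytest.raises(ValueError, match="seed"):
            asim.compare(a, b)


class TestWardStructure:
    def test_uniform_environment_symmetric_wards(self):
        cfg = asim.ScenarioConfig(
            population=asim.PopulationSpec(
                n_agents=8000, seed=21, ward_shares=(0.125,) * 8, car_ownership=(0.6,) * 8
            ),
            environment=asim.EnvironmentSpec(centers_per_ward=(3,) * 8),
            horizon_years=1,
            replicates=1,
            seed=21,
        )
        res = asim.run_simulation(cfg)
        rates = res.agents.groupby("ward_id")["ever"].mean()
        # same placement law in every ward: rates agree within sampling noise
        assert rates.max() - rates.min() < 0.25

    def test_better_served_ward_exercises_more(self):
        # 2-ward contrast: ward 1 packed with centers; distant ward 8 has
        # none, and without cars its agents are structurally excluded
        cfg = asim.ScenarioConfig(
            population=asim.PopulationSpec(
                n_agents=10_000, seed=8,
                ward_shares=(0.5, 0, 0, 0, 0, 0, 0, 0.5),
                car_ownership=(0.0,) * 8,
            ),
            environment=asim.EnvironmentSpec(
                centers_per_ward=(10, 0, 0, 0, 0, 0, 0, 0), walk_reach_km=1.5
            ),
            horizon_years=1,
            replicates=1,
            seed=8,
        )
        res = asim.run_simulation(cfg)
        by_ward = res.agents.groupby("ward_id")["ever"].mean()
        assert by_ward[1] > by_ward[8]
        assert by_ward[8] == 0.0


class TestCli:
    def test_run_and_validate(self, tmp_path):
        cfg = asim.ScenarioConfig(
            population=asim.PopulationSpec(n_agents=300, seed=2),
            horizon_years=1,
            replicates=1,
            seed=2,
        )
        cfg_path = tmp_path / "scenario.yaml"
        save_config(cfg, cfg_path)
        runner = CliRunner()
        out = tmp_path / "out"
        res = runner.invoke(cli_main, ["run", "--config", str(cfg_path), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "agents.csv").exists() and (out / "timeseries.csv").exists()
        res = runner.invoke(cli_main, ["validate", "--config", str(cfg_path)])
        assert res.exit_code == 0
        assert "daily participation" in res.output

    def test_experiment_writes_summary_tables(self, tmp_path):
        cfg = asim.ScenarioConfig(
            population=asim.PopulationSpec(n_agents=200, seed=3),
            horizon_years=1,
            replicates=2,
            seed=3,
        )
        cfg_path = tmp_path / "scenario.yaml"
        save_config(cfg, cfg_path)
        out = tmp_path / "exp"
        res = CliRunner().invoke(
            cli_main, ["experiment", "--config", str(cfg_path), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        summary = pd.read_csv(out / "summary.csv")
        assert {"metric", "mean", "ci_lo", "ci_hi"} <= set(summary.columns)
        assert (out / "wards.csv").exists() and (out / "timeseries.csv").exists()
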