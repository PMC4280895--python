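"""Design shell: sample-size search, curves, fixture simulation, IO and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from scipy import stats

from survassure import (
    PriorSpec,
    SurvivalDataset,
    TrialDesign,
    assurance_curve,
    event_prob_exponential,
    power_exponential,
    sample_size_for_power,
    simulate_survival_dataset,
)
from survassure.cli import main as cli_main
from survassure.exponential import success_prob_exponential
from survassure.io import (
    prior_from_config,
    read_quartile_judgement,
    read_roulette_judgement,
)


class TestSampleSizeSearch:
    def test_constructed_power_function_returns_known_n(self):
        z = stats.norm.ppf(0.975)
        c = (stats.norm.ppf(0.8) + z) / np.sqrt(100)  # power hits 0.8 exactly at n=100

        def power_fn(n):
            return stats.norm.cdf(np.sqrt(n) * c - z)

        assert sample_size_for_power(power_fn, 0.8) == 100

    def test_already_sufficient_at_minimum(self):
        assert sample_size_for_power(lambda n: 0.9, 0.5) == 1

    def test_exponential_design_matches_linear_scan(self):
        d = TrialDesign.balanced(3, 5, 10)

        def power_fn(n):
            return power_exponential(0.102, 0.0446, d.with_per_group(n))

        n_star = sample_size_for_power(power_fn, 0.8)
        scan = next(n for n in range(1, 1000) if power_fn(n) >= 0.8)
        assert n_star == scan
        assert power_fn(n_star) >= 0.8 > power_fn(n_star - 1)

    def test_unreachable_target_raises(self):
        with pytest.raises(ValueError, match="not reachable"):
            sample_size_for_power(lambda n: 0.1, 0.9, n_max=1000)


class TestAssuranceCurve:
    def test_point_priors_reproduce_one_sided_power_curve(self):
        d = TrialDesign.balanced(3, 5, 10)
        curve = assurance_curve(
            "exponential",
            (PriorSpec("point", (0.6,)), PriorSpec("point", (0.2,)), 5.0),
            d,
            n_grid=[50, 100, 200],
            M=200,
            rng_seed=1,
        )
        l1 = -np.log(0.6) / 5
        l2 = -np.log(0.8) / 5
        for n, a in zip(curve.n, curve.assurance):
            expected = success_prob_exponential(l1, l2, d.with_per_group(int(n)))
            assert a == pytest.approx(expected, abs=1e-12)

    def test_curve_never_exceeds_cap(self):
        d = TrialDesign.balanced(3, 5, 10)
        s1p, rhop = PriorSpec("beta", (60, 40)), PriorSpec("normal", (0.2, 0.05))
        curve = assurance_curve(
            "exponential", (s1p, rhop, 5.0), d, n_grid=[50, 200, 1000, 5000],
            M=20000, rng_seed=2,
        )
        from survassure import joint_rates_sample

        s1, s2 = joint_rates_sample(s1p, rhop, 10**5, 3)
        cap = (s2 > s1).mean()
        assert np.all(curve.assurance <= cap + 3 * curve.assurance_se + 0.01)

    def test_common_random_numbers_give_monotone_curve(self):
        d = TrialDesign.balanced(3, 5, 10)
        curve = assurance_curve(
            "exponential",
            (PriorSpec("beta", (60, 40)), PriorSpec("normal", (0.2, 0.001)), 5.0),
            d,
            n_grid=[25, 50, 100, 200, 400],
            M=5000,
            rng_seed=4,
            power_params=(0.102, 0.0446),
        )
        assert np.all(np.diff(curve.assurance) > -1e-12)
        assert np.all(np.diff(curve.power) > 0)

    def test_tight_prior_crossing_close_to_power_crossing(self):
        # strong prior belief in the design effect: assurance-based and
        # power-based sample sizes agree within ~20%
        d = TrialDesign.balanced(3, 5, 10)
        n_power = sample_size_for_power(
            lambda n: power_exponential(0.102, 0.0446, d.with_per_group(n)), 0.8
        )
        grid = np.arange(60, 241, 10)
        curve = assurance_curve(
            "exponential",
            (PriorSpec("beta", (60, 40)), PriorSpec("normal", (0.2, 0.001)), 5.0),
            d,
            n_grid=grid,
            M=20000,
            rng_seed=5,
        )
        n_assur = grid[np.argmax(curve.assurance >= 0.8)]
        assert abs(n_assur - n_power) <= 0.2 * n_power


class TestFixtureSimulation:
    def test_no_censoring_when_trial_never_ends(self):
        ds = simulate_survival_dataset("exponential", {"rate": 0.3}, 500, 3, np.inf, 0)
        assert ds.n_events == 500

    def test_tiny_follow_up_censors_nearly_everyone(self):
        ds = simulate_survival_dataset("exponential", {"rate": 1e-4}, 500, 3, 3, 0)
        assert ds.n_events < 5

    def test_event_fraction_matches_closed_form(self):
        d = TrialDesign.balanced(3, 5, 10)
        ds = simulate_survival_dataset("exponential", {"rate": 0.102}, 10**5, 3, 5, 12)
        p = event_prob_exponential(0.102, d)
        se = np.sqrt(p * (1 - p) / ds.n)
        assert abs(ds.n_events / ds.n - p) < 3 * se

    def test_reproducible_by_seed(self):
        a = simulate_survival_dataset("weibull", {"shape": 0.5, "scale": 1.6}, 100, 3, 5, 7)
        b = simulate_survival_dataset("weibull", {"shape": 0.5, "scale": 1.6}, 100, 3, 5, 7)
        assert np.array_equal(a.time, b.time) and np.array_equal(a.event, b.event)


class TestFileIO:
    def test_roulette_and_quartile_round_trip(self, tmp_path):
        roulette = tmp_path / "roulette.csv"
        roulette.write_text(
            "lower,upper,chips\n0.0,0.1,2\n0.1,0.2,10\n0.2,0.3,6\n0.3,0.4,2\n"
        )
        j = read_roulette_judgement(roulette)
        assert j.total_chips == 20
        assert j.bin_edges[0] == 0.0 and j.bin_edges[-1] == 0.4

        quart = tmp_path / "quartiles.csv"
        quart.write_text("q25,q50,q75\n0.15,0.2,0.23\n")
        q = read_quartile_judgement(quart)
        assert (q.q25, q.q50, q.q75) == (0.15, 0.2, 0.23)

    def test_prior_config_round_trip(self):
        spec = PriorSpec("normal", (0.2, 0.05), lower=-0.6, upper=0.4)
        assert prior_from_config(spec.to_dict()) == spec
        assert prior_from_config({"family": "point", "value": 0.2}).params == (0.2,)

    def test_survival_dataset_file_round_trip(self, tmp_path):
        ds = SurvivalDataset(np.array([0.8, 1.0, 3.1]), np.array([1, 0, 1]))
        path = tmp_path / "arm.tsv"
        ds.to_file(path)
        back = SurvivalDataset.from_file(path)
        assert np.allclose(back.time, ds.time)
        assert np.array_equal(back.event, ds.event)


ASSURANCE_CFG = """
model: exponential
design: {R: 3, T: 5, n1: 100, n2: 100, alpha: 0.05}
t0: 5
priors:
  s1: {family: beta, params: [60, 40]}
  rho: {family: normal, params: [0.2, 0.05]}
M: 2000
seed: 11
"""


class TestCLI:
    def test_assurance_prints_result_table(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(ASSURANCE_CFG)
        out = tmp_path / "res.json"
        runner = CliRunner()
        result = runner.invoke(cli_main, ["assurance", "--config", str(cfg), "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert "assurance:" in result.output
        saved = json.loads(out.read_text())
        assert 0 < saved["assurance"] < 1

    def test_curve_writes_reproducible_table(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(ASSURANCE_CFG + "n_grid: [50, 100]\n")
        runner = CliRunner()
        outputs = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            res = runner.invoke(cli_main, ["curve", "--config", str(cfg), "--out", str(out)])
            assert res.exit_code == 0, res.output
            outputs.append(out.read_bytes())
        assert outputs[0] == outputs[1]
        df = pd.read_csv(tmp_path / "a.csv")
        assert list(df["n_per_group"]) == [50, 100]

    def test_dp_posterior_reports_anchor_survival(self, tmp_path, km_data):
        data_path = tmp_path / "control.tsv"
        km_data.to_file(data_path)
        cfg = tmp_path / "dp.yaml"
        cfg.write_text(
            "design: {R: 5, T: 10, n1: 100, n2: 100}\n"
            "dp: {c0: 1.0, anchor_time: 5, anchor_survival: 0.5}\n"
            "t0: 7\nn_iter: 3000\nburn_in: 500\nseed: 3\n"
        )
        runner = CliRunner()
        res = runner.invoke(
            cli_main, ["dp-posterior", "--data", str(data_path), "--config", str(cfg)]
        )
        assert res.exit_code == 0, res.output
        mean = float(res.output.split("posterior mean S1(7):")[1].split("\n")[0])
        assert abs(mean - 0.525) < 0.1

    def test_missing_required_field_fails_cleanly(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("model: exponential\ndesign: {R: 3, T: 5, n1: 10, n2: 10}\n")
        out = tmp_path / "never.json"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["assurance", "--config", str(cfg), "--out", str(out)])
        assert res.exit_code != 0
        assert not out.exists()

    def test_simulate_and_fit_prior_smoke(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "sim.yaml"
        cfg.write_text(
            "model: exponential\nparams: {rate: 0.102}\nn: 200\nR: 3\nT: 5\nseed: 1\n"
        )
        out = tmp_path / "arm.tsv"
        res = runner.invoke(cli_main, ["simulate", "--config", str(cfg), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert SurvivalDataset.from_file(out).n == 200

        quart = tmp_path / "q.csv"
        quart.write_text("q25,q50,q75\n0.15,0.2,0.23\n")
        res = runner.invoke(
            cli_main, ["fit-prior", str(quart), "--kind", "quartiles", "--family", "beta"]
        )
        assert res.exit_code == 0, res.output
        assert "ssq:" in res.output
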