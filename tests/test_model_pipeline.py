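import json
import warnings

import numpy as np
import pytest
from click.testing import CliRunner

from camarkov import (CAConfig, CAMarkov, largest_remainder,
                      project_class_areas, run_forecast_leg,
                      run_validation_leg)
from camarkov.cli import main as cli_main
from camarkov.pipeline import write_bundle


@pytest.fixture(scope="module")
def fitted(scenario_small):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CAMarkov.from_scenario(scenario_small, use=("t0", "t1")).fit(seed=3)


class TestModelFacade:
    def test_fit_exposes_transition_and_roc(self, fitted):
        assert fitted.P.shape == (6, 6)
        assert np.allclose(fitted.P.sum(axis=1), 1.0)
        assert set(fitted.roc.index) == set(range(1, 7))
        assert ((fitted.roc >= 0) & (fitted.roc <= 1)).all()

    def test_summary_mentions_fit_quality(self, fitted):
        text = fitted.summary()
        assert "Transition probability matrix" in text
        assert "ROC" in text
        assert "Grassland" in text

    def test_simulate_respects_markov_quantities(self, scenario_small, fitted):
        sc = scenario_small
        out = fitted.simulate(steps=1)
        counts = np.array([sc.t1.class_counts()[k]
                           for k in fitted.transition.classes], dtype=float)
        targets = largest_remainder(
            project_class_areas(fitted.transition, counts, 1), sc.t1.n_valid)
        got = np.array([out.class_counts()[k]
                        for k in fitted.transition.classes])
        assert np.array_equal(got, targets)

    def test_incongruent_inputs_rejected(self, scenario_small):
        sc = scenario_small
        small = sc.t0.with_codes(sc.t0.codes[:32, :32])
        with pytest.raises(ValueError, match="congruent"):
            CAMarkov(small, sc.t1, sc.drivers)


class TestValidationLeg:
    def test_report_is_complete_and_reproducible(self, scenario_small):
        sc = scenario_small
        kwargs = dict(n_per_class=500, ca_config=CAConfig(seed=3), seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_validation_leg(sc.t0, sc.t1, sc.t2, sc.drivers, **kwargs)
            b = run_validation_leg(sc.t0, sc.t1, sc.t2, sc.drivers, **kwargs)
        for key in ("kappa", "band", "counts", "per_class_roc", "transition_P"):
            assert key in a
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_static_world_scores_perfect_kappa(self, scenario_small):
        # if nothing changes between dates, the simulation reproduces t2 exactly
        sc = scenario_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_validation_leg(sc.t0, sc.t0, sc.t0, sc.drivers,
                                     n_per_class=300, seed=1)
        assert rep["kappa"] == pytest.approx(1.0)


class TestForecastLeg:
    def test_bundle_contents_and_count_audit(self, scenario_small, tmp_path):
        sc = scenario_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = run_forecast_leg(sc.t1, sc.t2, sc.drivers,
                                      earlier=[sc.t0], n_per_class=500, seed=2)
        res = bundle["results"]
        forecast = bundle["forecast"]
        assert forecast.label == "2030"
        counts = np.array([sc.t2.class_counts()[k]
                           for k in res.transition.classes], dtype=float)
        targets = largest_remainder(
            project_class_areas(res.transition, counts, 1), sc.t2.n_valid)
        got = np.array([forecast.class_counts()[k]
                        for k in res.transition.classes])
        assert np.array_equal(got, targets)
        # BC trend sign matches the two-endpoint difference
        bc = bundle["bc_table"]
        years = sorted(c for c in bc.columns)
        endpoint = bc.loc["total", years[-1]] - bc.loc["total", years[0]]
        if endpoint != 0:
            assert np.sign(bundle["bc_trend"]["total"]) == np.sign(endpoint)
        out = write_bundle(bundle, tmp_path / "bundle", seed=2)
        for name in ("forecast.tif", "transition.json", "suitability.json",
                     "biocapacity.csv", "metrics.csv", "metrics_change.csv",
                     "run.json"):
            assert (out / name).exists()

    def test_missing_forecast_epoch_falls_back_to_latest(self, scenario_small):
        sc = scenario_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bundle = run_forecast_leg(sc.t1, sc.t2, sc.drivers,
                                      n_per_class=300, seed=0)
        rep = bundle["bc_reports"]["2030"]
        # forecast epoch inherits the 2030 == 2020 factor assumption
        assert rep.table.loc[1, "yf"] == pytest.approx(2.02)
        assert rep.table.loc[1, "eqf"] == pytest.approx(2.50)


class TestCLI:
    def test_synth_markov_validate_round_trip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "scenario"
        r = runner.invoke(cli_main, ["synth", "--out", str(out),
                                     "--seed", "5", "--size", "48"])
        assert r.exit_code == 0, r.output
        for name in ("t0.tif", "t1.tif", "t2.tif", "truth.json"):
            assert (out / name).exists()
        r = runner.invoke(cli_main, ["markov", str(out / "t0.tif"),
                                     str(out / "t1.tif"),
                                     "--out", str(tmp_path / "P.json")])
        assert r.exit_code == 0, r.output
        P = np.asarray(json.loads((tmp_path / "P.json").read_text())["P"])
        assert np.allclose(P.sum(axis=1), 1.0)
        r = runner.invoke(cli_main, ["validate", str(out / "t1.tif"),
                                     str(out / "t1.tif")])
        assert r.exit_code == 0
        assert "kappa = 1.0000" in r.output

    def test_metrics_and_biocapacity_commands(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "scenario"
        runner.invoke(cli_main, ["synth", "--out", str(out),
                                 "--seed", "2", "--size", "48"])
        r = runner.invoke(cli_main, ["biocapacity", str(out / "t0.tif")])
        assert r.exit_code == 0 and "total BC (2000)" in r.output
        r = runner.invoke(cli_main, ["metrics", str(out / "t0.tif"),
                                     str(out / "t2.tif")])
        assert r.exit_code == 0
        assert "SHDI" in r.output and "change" in r.output
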