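import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from camarkov import (DriverStack, LandCoverGrid, compare_driver_subsets,
                      fit_class_logistic, fit_suitability_models,
                      predict_suitability, roc_area, sample_observations)
from camarkov.raster import DEFAULT_LEGEND
from camarkov.suitability import ClassLogit, LogisticModelSet

from _oracles import roc_oracle


def _obs_from_arrays(X, y, names):
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "code", np.where(y == 1, 1, 2))
    df.insert(0, "col", 0)
    df.insert(0, "row", 0)
    return df


class TestRocArea:
    def test_perfect_and_inverted_ranking(self):
        labels = np.array([0, 0, 1, 1])
        assert roc_area(np.array([1, 2, 3, 4]), labels) == 1.0
        assert roc_area(np.array([4, 3, 2, 1]), labels) == 0.0

    def test_four_point_example(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_area(scores, labels) == pytest.approx(0.75)

    def test_matches_pairwise_oracle_and_sklearn(self, rng):
        scores = rng.standard_normal(200)
        labels = (rng.random(200) < 0.4).astype(int)
        ours = roc_area(scores, labels)
        oracle = roc_oracle(scores[labels == 1], scores[labels == 0])
        assert ours == pytest.approx(oracle, abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.permutation(100).astype(float)
        labels = np.array([0, 1] * 50)
        assert roc_area(scores, labels) + roc_area(-scores, labels) \
            == pytest.approx(1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both label values"):
            roc_area(np.array([1.0, 2.0]), np.array([1, 1]))


class TestSampling:
    def test_sampled_values_equal_lattice_lookup(self, scenario_small):
        sc = scenario_small
        obs = sample_observations(sc.t0, sc.drivers, n_per_class=50, seed=3)
        rr = obs["row"].to_numpy()
        cc = obs["col"].to_numpy()
        assert np.array_equal(obs["code"].to_numpy(), sc.t0.codes[rr, cc])
        for name in sc.drivers.names:
            assert np.array_equal(obs[name].to_numpy(), sc.drivers[name][rr, cc])

    def test_deterministic_given_seed(self, scenario_small):
        sc = scenario_small
        a = sample_observations(sc.t0, sc.drivers, n_per_class=40, seed=8)
        b = sample_observations(sc.t0, sc.drivers, n_per_class=40, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_single_class_grid_gives_degenerate_responses(self):
        grid = LandCoverGrid(np.ones((40, 40), dtype=np.int32),
                             legend=dict(DEFAULT_LEGEND))
        drivers = DriverStack(layers={"slope": np.zeros((40, 40))})
        with pytest.warns(UserWarning):
            obs = sample_observations(grid, drivers, n_per_class=5000, seed=0)
        assert (obs["code"] == 1).all()
        with pytest.raises(ValueError, match="degenerate response"):
            fit_class_logistic(obs, 1)

    def test_small_class_sampled_entirely_with_warning(self, scenario_small):
        sc = scenario_small
        with pytest.warns(UserWarning, match="sampling all"):
            obs = sample_observations(sc.t0, sc.drivers, n_per_class=5000, seed=0)
        counts = sc.t0.class_counts()
        sampled = obs["code"].value_counts()
        for k, n in counts.items():
            assert sampled[k] == min(n, 5000)


class TestFitting:
    def test_null_drivers_give_flat_model(self, rng):
        n = 10_000
        X = rng.standard_normal((n, 2))
        y = (rng.random(n) < 0.5).astype(int)
        fit = fit_class_logistic(_obs_from_arrays(X, y, ["a", "b"]), 1)
        assert all(abs(b) < 0.1 for b in fit.coefficients.values())
        assert 0.45 <= fit.roc <= 0.60

    def test_parameter_recovery(self, rng):
        n = 10_000
        X = rng.standard_normal((n, 2))
        eta = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_class_logistic(_obs_from_arrays(X, y, ["a", "b"]), 1)
        assert fit.coefficients["a"] == pytest.approx(2.0, abs=0.2)
        assert fit.coefficients["b"] == pytest.approx(-1.0, abs=0.2)

    def test_duplicated_driver_keeps_predictions_stable(self, rng):
        n = 2000
        X = rng.standard_normal((n, 1))
        eta = 1.5 * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        base = fit_class_logistic(_obs_from_arrays(X, y, ["a"]), 1)
        dup = fit_class_logistic(
            _obs_from_arrays(np.column_stack([X, X]), y, ["a", "a2"]), 1)
        assert np.isfinite(list(dup.coefficients.values())).all()
        shape = (1, 1)
        for x in (-1.0, 0.0, 2.0):
            d1 = DriverStack(layers={"a": np.full(shape, x)})
            d2 = DriverStack(layers={"a": np.full(shape, x),
                                     "a2": np.full(shape, x)})
            p1 = predict_suitability(LogisticModelSet({1: base}), d1)[1][0, 0]
            p2 = predict_suitability(LogisticModelSet({1: dup}), d2)[1][0, 0]
            assert p1 == pytest.approx(p2, abs=1e-3)


class TestPredict:
    def _stack(self, value):
        return DriverStack(layers={"x": np.full((2, 2), float(value))})

    def test_zero_linear_predictor_gives_half(self):
        m = ClassLogit(1, intercept=0.0, coefficients={"x": 0.0}, roc=0.5,
                       subset=["x"])
        atlas = predict_suitability(LogisticModelSet({1: m}), self._stack(3.0))
        assert (atlas[1] == 0.5).all()

    def test_saturation(self):
        m = ClassLogit(1, intercept=20.0, coefficients={"x": 0.0}, roc=1.0,
                       subset=["x"])
        atlas = predict_suitability(LogisticModelSet({1: m}), self._stack(0.0))
        assert (atlas[1] > 0.999999).all()

    def test_hand_evaluated_probability(self):
        m = ClassLogit(1, intercept=0.5, coefficients={"x": -1.0}, roc=0.9,
                       subset=["x"])
        atlas = predict_suitability(LogisticModelSet({1: m}), self._stack(2.0))
        assert atlas[1][0, 0] == pytest.approx(1 / (1 + np.exp(1.5)), abs=1e-9)

    def test_missing_driver_named(self):
        m = ClassLogit(1, intercept=0.0, coefficients={"slope": 1.0}, roc=0.5,
                       subset=["slope"])
        with pytest.raises(KeyError, match="slope"):
            predict_suitability(LogisticModelSet({1: m}), self._stack(0.0))

    def test_monotone_in_each_driver(self, scenario_small):
        sc = scenario_small
        models = fit_suitability_models(sc.t1, sc.drivers, n_per_class=300,
                                        seed=0, classes=[1])
        m = models[1]
        base = {n: np.zeros((1, 1)) for n in m.subset}
        for name, b in m.coefficients.items():
            lo = DriverStack(layers={**base, name: np.full((1, 1), -1.0)})
            hi = DriverStack(layers={**base, name: np.full((1, 1), +1.0)})
            p_lo = predict_suitability(models, lo)[1][0, 0]
            p_hi = predict_suitability(models, hi)[1][0, 0]
            assert (p_hi - p_lo) * np.sign(b) >= 0


class TestSubsetComparison:
    def test_same_subset_twice_is_identical(self, scenario_small):
        sc = scenario_small
        names = sc.drivers.names
        table = compare_driver_subsets(sc.t1, sc.drivers,
                                       {"full": names, "again": names},
                                       n_per_class=200, seed=4)
        assert np.allclose(table["full"], table["again"])

    def test_dropping_informative_socioeconomic_layers_costs_roc(
            self, scenario_default):
        sc = scenario_default
        full = sc.drivers.names
        reduced = [n for n in full if n not in
                   ("livestock_density", "agri_output", "husbandry_output",
                    "eco_investment")]
        table = compare_driver_subsets(sc.t1, sc.drivers,
                                       {"full": full, "reduced": reduced},
                                       n_per_class=2000, seed=4)
        # grassland and cultivated load on the county layers by construction
        assert table.loc[3, "difference"] > 0
        assert table.loc[1, "difference"] > 0

    def test_unknown_driver_rejected(self, scenario_small):
        sc = scenario_small
        with pytest.raises(KeyError, match="no_such"):
            compare_driver_subsets(sc.t1, sc.drivers, {"bad": ["no_such"]},
                                   n_per_class=100, seed=0)

    def test_empty_subset_rejected(self, scenario_small):
        sc = scenario_small
        with pytest.raises(ValueError, match="empty"):
            compare_driver_subsets(sc.t1, sc.drivers, {"bad": []},
                                   n_per_class=100, seed=0)
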