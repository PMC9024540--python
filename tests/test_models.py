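import numpy as np
import pandas as pd
import pytest

import ensemblesdm.models as models_mod
from ensemblesdm.evaluation import roc_auc
from ensemblesdm.models import (ALGORITHMS, ModelingDataset, SurfaceRangeEnvelope,
                                build_dataset, fit, fit_suite, make_splits,
                                sample_pseudo_absences)
from ensemblesdm.occurrences import OccurrenceSet
from ensemblesdm.raster import GridGeoreference, RasterStack
from ensemblesdm.synthetic import ClimateSpec, generate_climate


def _grid_stack(rows, cols, n_layers=1, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n_layers, rows, cols))
    res = 1.0 if max(rows, cols) <= 90 else 0.25  # stay inside lon/lat bounds
    return RasterStack([f"bio{i + 1:02d}" for i in range(n_layers)], data,
                       GridGeoreference(0.0, rows * res, res, -res))


class TestPseudoAbsences:
    def test_exhaustive_four_cells(self):
        stack = _grid_stack(2, 2)
        occ = OccurrenceSet([0.5], [1.5])  # cell (0, 0)
        pa = sample_pseudo_absences(stack, occ, 3, seed=0)
        got = {tuple(p) for p in pa}
        assert got == {(1.5, 1.5), (0.5, 0.5), (1.5, 0.5)}

    def test_same_seed_identical(self):
        stack = _grid_stack(20, 20)
        occ = OccurrenceSet([0.5], [19.5])
        a = sample_pseudo_absences(stack, occ, 50, seed=5)
        b = sample_pseudo_absences(stack, occ, 50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_large_draw_distinct_and_avoids_presences(self):
        stack = _grid_stack(200, 200)
        lons, lats = stack.georef.cell_centers([0, 120], [0, 40])
        occ = OccurrenceSet(lons, lats)
        pa = sample_pseudo_absences(stack, occ, 10_000, seed=1)
        cells = set(map(tuple, np.column_stack(stack.georef.cell_index(pa[:, 0],
                                                                       pa[:, 1]))))
        assert len(cells) == 10_000
        prows, pcols = stack.georef.cell_index(occ.lons, occ.lats)
        assert not cells & set(zip(prows, pcols))

    def test_insufficient_cells_error_reports_counts(self):
        stack = _grid_stack(2, 2)
        occ = OccurrenceSet([0.5], [1.5])
        with pytest.raises(ValueError, match="3 eligible"):
            sample_pseudo_absences(stack, occ, 4, seed=0)


def _toy_dataset(n_pres=10, n_abs=10, seed=0, k=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n_pres + n_abs, k)),
                     columns=[f"v{i}" for i in range(k)])
    y = np.r_[np.ones(n_pres, int), np.zeros(n_abs, int)]
    w = np.ones_like(y, dtype=float)
    return ModelingDataset(X, y, w)


class TestSplits:
    def test_balanced_ten_ten_gives_eight_eight(self):
        ds = _toy_dataset(10, 10)
        make_splits(ds, train_frac=0.8, reps=1, seed=0)
        train = ds.splits[0]
        assert ds.y[train].sum() == 8 and (1 - ds.y[train]).sum() == 8

    def test_three_reps_are_distinct(self):
        ds = _toy_dataset(50, 50)
        make_splits(ds, reps=3, seed=0)
        assert len(ds.splits) == 3
        assert not np.array_equal(ds.splits[0], ds.splits[1])
        assert not np.array_equal(ds.splits[1], ds.splits[2])

    def test_prevalence_preserved_with_extreme_imbalance(self):
        ds = _toy_dataset(37, 10_000, seed=1)
        make_splits(ds, train_frac=0.8, reps=3, seed=2)
        for train in ds.splits:
            # stratification keeps class counts within one point of 80%
            assert abs(ds.y[train].sum() - 0.8 * 37) <= 1
            assert abs((ds.y[train] == 0).sum() - 8000) <= 1

    def test_tiny_class_rejected(self):
        ds = _toy_dataset(1, 10)
        with pytest.raises(ValueError, match="at least 2"):
            make_splits(ds)

    def test_train_and_validation_disjoint_and_exhaustive(self):
        ds = _toy_dataset(30, 30)
        make_splits(ds, reps=3, seed=4)
        for train in ds.splits:
            assert train.sum() + (~train).sum() == len(ds.y)


class TestSurfaceRangeEnvelope:
    def test_envelope_matches_empirical_quantiles(self, rng):
        X = rng.random((400, 3))
        y = np.ones(400, int)
        sre = SurfaceRangeEnvelope(quantile=0.025).fit(X, y)
        np.testing.assert_allclose(sre.lower_, np.quantile(X, 0.025, axis=0))
        np.testing.assert_allclose(sre.upper_, np.quantile(X, 0.975, axis=0))
        assert np.all(sre.lower_ > 0.0) and np.all(sre.upper_ < 1.0)

    def test_presence_median_predicts_one(self, rng):
        X = rng.normal(size=(100, 2))
        sre = SurfaceRangeEnvelope().fit(X, np.ones(100, int))
        med = np.median(X, axis=0, keepdims=True)
        assert sre.predict_proba(med)[0, 1] == 1.0

    def test_predictions_are_binary(self, rng):
        X = rng.normal(size=(50, 2))
        sre = SurfaceRangeEnvelope().fit(X, np.ones(50, int))
        p = sre.predict_proba(rng.normal(size=(200, 2)))[:, 1]
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_envelope_contains_species_optimum(self, suite_bundle):
        """On the virtual species, the SRE envelope on the dominant driving
        layer brackets the true optimum response mean."""
        study = suite_bundle["study"]
        ds = suite_bundle["dataset"]
        m = next(m for m in suite_bundle["suite"].models if m.algorithm == "SRE")
        i = m.feature_names.index(study.stack.names[study.species.driving_layers[0]])
        mu = study.species.response_means[0]
        assert m.estimator.lower_[i] < mu < m.estimator.upper_[i]


class TestFit:
    def test_glm_perfectly_separable_training_auc_is_one(self):
        X = pd.DataFrame({"v": np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]})
        ds = ModelingDataset(X, np.r_[np.ones(20, int), np.zeros(20, int)],
                             np.ones(40))
        make_splits(ds, reps=1, seed=0)
        m = fit("GLM", ds, 1)
        assert roc_auc(ds.y[ds.splits[0]], m.predict(ds.X[ds.splits[0]])) == 1.0

    def test_unknown_algorithm_rejected(self):
        ds = _toy_dataset()
        make_splits(ds, reps=1, seed=0)
        with pytest.raises(ValueError, match="unknown algorithm"):
            fit("SVM", ds, 1)

    def test_degenerate_fold_marks_failure(self):
        ds = _toy_dataset(10, 10)
        ds.splits = [np.r_[np.ones(10, bool), np.zeros(10, bool)]]  # presences only
        m = fit("GLM", ds, 1)
        assert m.failed and "single class" in m.failure_reason


class TestFitSuite:
    def test_default_suite_has_27_models(self, suite_bundle):
        suite = suite_bundle["suite"]
        assert len(suite) == 27 and not suite.failures
        assert {m.algorithm for m in suite.models} == set(ALGORITHMS)
        assert {m.repetition for m in suite.models} == {1, 2, 3}

    def test_one_rep_gives_nine_models(self):
        ds = _toy_dataset(40, 40, seed=3)
        make_splits(ds, reps=1, seed=0)
        assert len(fit_suite(ds, seed=0)) == 9

    def test_scorers_stay_in_unit_interval_sre_binary(self, suite_bundle):
        X = suite_bundle["dataset"].X.iloc[:200]
        for m in suite_bundle["suite"].models:
            p = m.predict(X)
            assert p.min() >= 0.0 and p.max() <= 1.0
            if m.algorithm == "SRE":
                assert set(np.unique(p)) <= {0.0, 1.0}

    def test_single_model_failure_shrinks_suite_and_is_logged(self, monkeypatch):
        ds = _toy_dataset(40, 40, seed=3)
        make_splits(ds, reps=3, seed=0)
        real = models_mod._make_estimator
        calls = {"n": 0}

        def flaky(algorithm, random_state):
            if algorithm == "ANN":
                calls["n"] += 1
                if calls["n"] == 1:
                    raise RuntimeError("synthetic convergence failure")
            return real(algorithm, random_state)

        monkeypatch.setattr(models_mod, "_make_estimator", flaky)
        suite = fit_suite(ds, seed=0)
        assert len(suite) == 26
        assert len(suite.failures) == 1
        assert "convergence" in suite.failures[0].failure_reason


def test_build_dataset_balances_class_weight():
    stack = generate_climate(ClimateSpec(n_layers=2, grid_shape=(50, 50), seed=5))
    lons, lats = stack.georef.cell_centers([2, 3, 4], [2, 3, 4])
    occ = OccurrenceSet(lons, lats)
    pa = sample_pseudo_absences(stack, occ, 300, seed=0)
    ds = build_dataset(stack, occ, pa)
    assert ds.weights[ds.y == 0].sum() == pytest.approx(ds.weights[ds.y == 1].sum())
    # presence and pseudo-absence cells never coincide
    assert len(ds.y) == 303 and ds.y.sum() == 3
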