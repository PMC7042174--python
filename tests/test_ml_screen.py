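"""Trained scoring models, the training protocol, and the fraction sweep."""

import numpy as np
import pandas as pd
import pytest

from usrml import evaluation
from usrml.ml_screen import (
    FractionSweepConfig,
    ScreeningModel,
    TrainingProtocolConfig,
    ann_score,
    cv_grid_search,
    fit_ann,
    fit_gmm,
    fit_isolation_forest,
    fraction_sweep,
    gmm_score,
    if_score,
    molecule_score,
    oversample_actives,
    record_fits,
    select_lec_rows,
    split_train_test,
    train_and_screen,
)
from usrml.records import Label
from usrml.synthetic_fixtures import ScenarioConfig, make_screening_scenario


def _frame(n_act=10, n_dec=90, n_conf=3, seed=0, separation=6.0):
    s = make_screening_scenario(
        ScenarioConfig(
            n_actives=n_act, n_decoys=n_dec, n_conformers_per_mol=n_conf,
            separation=separation, rng_seed=seed,
        )
    )
    return s.descriptors, s.feature_columns


class TestSplit:
    def test_stratified_proportions(self):
        frame, _ = _frame()
        config = TrainingProtocolConfig(rng_seed=7)
        train, test = split_train_test(frame, config)
        test_mols = test[["mol_id", "label"]].drop_duplicates()
        assert len(test_mols) == 20
        assert (test_mols["label"] == "active").sum() == 2

    def test_same_seed_identical_split(self):
        frame, _ = _frame()
        config = TrainingProtocolConfig(rng_seed=3)
        t1 = split_train_test(frame, config)
        t2 = split_train_test(frame, config)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])

    def test_molecule_level_disjointness(self):
        frame, _ = _frame(seed=5)
        train, test = split_train_test(frame, TrainingProtocolConfig(rng_seed=1))
        assert not (set(train.mol_id) & set(test.mol_id))
        assert set(train.mol_id) | set(test.mol_id) == set(frame.mol_id)

    def test_tiny_class_fatal(self):
        frame, _ = _frame(n_act=1, n_dec=20)
        with pytest.raises(ValueError, match="stratify"):
            split_train_test(frame, TrainingProtocolConfig())


class TestGmm:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(size=(200, 4))
        model = fit_gmm(X, 1, TrainingProtocolConfig(rng_seed=0))
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(
            model.covariances[0], np.cov(X.T, bias=True) + 1e-6 * np.eye(4), atol=1e-5
        )

    def test_weights_normalised(self, rng):
        X = rng.normal(size=(300, 3))
        model = fit_gmm(X, 3, TrainingProtocolConfig(rng_seed=0))
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_score_closed_form_at_mean(self):
        X = np.random.default_rng(0).normal(size=(500, 2))
        model = fit_gmm(X, 1, TrainingProtocolConfig(rng_seed=0))
        log_at_mean = gmm_score(model, model.means[0][None, :])[0]
        sigma = model.covariances[0]
        expected = -0.5 * np.log(np.linalg.det(2 * np.pi * sigma))
        assert log_at_mean == pytest.approx(expected, abs=1e-8)

    def test_score_decreases_away_from_mean(self):
        X = np.random.default_rng(1).normal(size=(500, 2))
        model = fit_gmm(X, 1, TrainingProtocolConfig(rng_seed=0))
        direction = np.array([1.0, 0.3])
        scores = [
            gmm_score(model, (model.means[0] + t * direction)[None, :])[0]
            for t in (0.0, 1.0, 2.0, 5.0)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_density_integrates_to_one_by_monte_carlo(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 2))
        model = fit_gmm(X, 2, TrainingProtocolConfig(rng_seed=0))
        # importance sampling with a wide uniform box around the data
        lo, hi = -8.0, 8.0
        u = rng.uniform(lo, hi, size=(10**6, 2))
        density = np.exp(gmm_score(model, u))
        integral = density.mean() * (hi - lo) ** 2
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_two_component_parameter_recovery(self):
        mu = np.full(12, 2.0)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            comp = rng.integers(0, 2, size=5000)
            X = np.where(comp[:, None] == 0, -mu, mu) + rng.normal(size=(5000, 12))
            model = fit_gmm(X, 2, TrainingProtocolConfig(rng_seed=seed))
            est = model.means[np.argsort(model.means[:, 0])]
            np.testing.assert_allclose(est[0], -mu, atol=0.1)
            np.testing.assert_allclose(est[1], mu, atol=0.1)

    def test_dimension_mismatch_fatal(self, rng):
        model = fit_gmm(rng.normal(size=(50, 3)), 1, TrainingProtocolConfig())
        with pytest.raises(ValueError, match="dimension"):
            gmm_score(model, np.zeros((1, 5)))


class TestIsolationForest:
    def test_far_outlier_scores_lowest(self, rng):
        X = np.vstack([rng.normal(size=(100, 5)), np.full((1, 5), 10.0)])
        model = fit_isolation_forest(X[:-1], TrainingProtocolConfig(rng_seed=0))
        scores = if_score(model, X)
        assert np.argmin(scores) == 100

    def test_training_point_outscores_distant_point(self, rng):
        X = rng.normal(size=(100, 5))
        model = fit_isolation_forest(X, TrainingProtocolConfig(rng_seed=0))
        assert if_score(model, X[:1])[0] > if_score(model, np.full((1, 5), 8.0))[0]

    def test_same_seed_identical_scores(self, rng):
        X = rng.normal(size=(80, 4))
        a = if_score(fit_isolation_forest(X, TrainingProtocolConfig(rng_seed=5)), X)
        b = if_score(fit_isolation_forest(X, TrainingProtocolConfig(rng_seed=5)), X)
        np.testing.assert_array_equal(a, b)


class TestAnn:
    def test_separable_classes_learned(self, rng):
        n = 400
        X = np.vstack([
            rng.normal(4.0, 1.0, size=(n // 4, 12)),
            rng.normal(0.0, 1.0, size=(3 * n // 4, 12)),
        ])
        y = np.array([1.0] * (n // 4) + [0.0] * (3 * n // 4))
        model = fit_ann(X, y, TrainingProtocolConfig(rng_seed=0), hidden_size=100)
        X_test = np.vstack([
            rng.normal(4.0, 1.0, size=(50, 12)),
            rng.normal(0.0, 1.0, size=(150, 12)),
        ])
        scores = ann_score(model, X_test)
        from sklearn.metrics import roc_auc_score
        auc = roc_auc_score([1] * 50 + [0] * 150, scores)
        assert auc > 0.95

    def test_oversampling_balances_rows(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([1] * 10 + [0] * 50)
        Xb, yb = oversample_actives(X, y, seed=0)
        assert (yb == 1).sum() == 50
        assert (yb == 0).sum() == 50

    def test_single_class_fatal(self, rng):
        with pytest.raises(ValueError):
            fit_ann(rng.normal(size=(10, 3)), np.ones(10), TrainingProtocolConfig())


class TestMoleculeScore:
    def test_max_rule(self):
        assert molecule_score([-3.2, -1.1, -7.0]) == -1.1

    def test_single_conformer(self):
        assert molecule_score([0.4]) == 0.4

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            molecule_score([])


class TestGridSearch:
    def test_single_point_grid_short_circuits(self):
        frame, cols = _frame()
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 2}]}, rng_seed=0
        )
        params, table = cv_grid_search(frame, cols, "gmm", config)
        assert params == {"n_components": 2}
        assert len(table) == 1

    def test_recovers_true_component_count(self):
        """4 well-separated active clusters: CV must prefer M=4 over M=1."""
        s = make_screening_scenario(
            ScenarioConfig(
                n_actives=40, n_decoys=100, n_conformers_per_mol=3,
                active_modes=4, separation=12.0, rng_seed=2,
            )
        )
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 1}, {"n_components": 4}]}, rng_seed=0
        )
        params, table = cv_grid_search(s.descriptors, s.feature_columns, "gmm", config)
        assert params == {"n_components": 4}
        assert table.mean_score.notna().all()

    def test_tie_break_first_in_grid_order(self, monkeypatch):
        frame, cols = _frame(seed=3)
        import usrml.ml_screen as m

        monkeypatch.setattr(m, "_validation_metric", lambda *a, **k: 0.5)
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 1}, {"n_components": 2}]}, rng_seed=0
        )
        params, _ = cv_grid_search(frame, cols, "gmm", config)
        assert params == {"n_components": 1}


class TestTrainAndScreen:
    def test_end_to_end_gmm_separable(self):
        frame, cols = _frame(n_act=15, n_dec=150, separation=8.0, seed=4)
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 1}, {"n_components": 2}]}, rng_seed=0
        )
        trained, ranking = train_and_screen(frame, cols, "gmm", config)
        assert evaluation.roc_auc(ranking) > 0.95
        test_ids = {m.mol_id for m in ranking}
        assert test_ids < set(frame.mol_id)  # ranking covers only the test set

    def test_same_seed_identical_ranking(self):
        frame, cols = _frame(seed=6)
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 1}]}, rng_seed=9
        )
        r1 = train_and_screen(frame, cols, "gmm", config)[1]
        r2 = train_and_screen(frame, cols, "gmm", config)[1]
        assert [(m.mol_id, m.score) for m in r1] == [(m.mol_id, m.score) for m in r2]

    def test_lec_mode_single_descriptor_per_molecule(self):
        frame, cols = _frame()
        reduced = select_lec_rows(frame)
        assert reduced.groupby("mol_id").size().max() == 1
        assert (reduced["conf_id"] == 0).all()  # no energy column -> lowest conf_id

    def test_lec_selects_minimum_energy(self):
        frame = pd.DataFrame(
            {
                "mol_id": ["a", "a", "b"],
                "conf_id": [0, 1, 0],
                "label": ["active"] * 3,
                "energy": [5.0, 1.0, 2.0],
                "m01": [0.1, 0.2, 0.3],
            }
        )
        reduced = select_lec_rows(frame)
        assert reduced.set_index("mol_id").loc["a", "conf_id"] == 1

    def test_one_class_hygiene(self):
        """No decoy descriptor may ever reach GMM / isolation-forest fitting."""
        frame, cols = _frame(seed=8)
        config = TrainingProtocolConfig(
            grids={
                "gmm": [{"n_components": 1}, {"n_components": 2}],
                "iforest": [{"n_trees": 50}, {"n_trees": 100}],
            },
            rng_seed=0,
        )
        for family in ("gmm", "iforest"):
            with record_fits() as audit:
                train_and_screen(frame, cols, family, config)
            assert audit, "fits must be recorded"
            for entry in audit:
                assert entry["labels"] is not None
                assert set(entry["labels"]) == {Label.ACTIVE.value}


class TestFractionSweep:
    def test_sixteen_cells(self):
        frame, cols = _frame(n_act=12, n_dec=60, seed=10)
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 1}]}, rng_seed=0
        )
        table = fraction_sweep(frame, cols, "gmm", FractionSweepConfig(), config)
        assert len(table) == 16
        assert set(table["mode"]) == {"full", "lec"}
        assert table["fraction"].nunique() == 8

    def test_model_object_interface_matches_function(self):
        frame, cols = _frame(seed=12)
        config = TrainingProtocolConfig(
            grids={"gmm": [{"n_components": 1}]}, rng_seed=4
        )
        res = ScreeningModel(frame, cols, family="gmm", config=config).fit()
        trained, ranking = train_and_screen(frame, cols, "gmm", config)
        assert [m.mol_id for m in res.ranking] == [m.mol_id for m in ranking]
        assert "EF 1%" in res.summary()
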