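from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dwel import (ForestSettings, accuracy_metrics, confusion_matrix,
                  cross_validate, fis_summary, load_model, predict,
                  predict_proba, save_model, stratified_split, train)


def spectral_table(n_per_class, leaf_ndi=0.3, wood_ndi=0.0, sd=0.02, seed=0):
    """Separable synthetic spectral features (leaf NDI ~ 0.3, wood ~ 0)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = np.array(["leaf"] * n_per_class + ["wood"] * n_per_class)
    ndi = np.where(labels == "leaf",
                   rng.normal(leaf_ndi, sd, n), rng.normal(wood_ndi, sd, n))
    rho_nir = rng.normal(0.43, 0.02, n)
    rho_swir = rho_nir * (1 - ndi) / (1 + ndi)
    return pd.DataFrame({"rho_nir": rho_nir, "rho_swir": rho_swir,
                         "ndi": ndi}), labels


class TestTrainPredict:
    def test_separable_samples_trained_to_high_accuracy(self):
        X, y = spectral_table(200, seed=1)
        model = train(X, y, "spectral", seed=1)
        labels, probs = predict(model, X)
        assert np.mean(labels == y) >= 0.99
        assert np.all((probs >= 0.5) & (probs <= 1.0))

    def test_spectral_set_has_exactly_three_importances(self):
        X, y = spectral_table(50, seed=2)
        model = train(X, y, "spectral", ForestSettings(n_estimators=50), seed=2)
        assert len(model.importances) == 3
        assert model.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.importances >= 0).all()

    def test_robust_to_ten_percent_label_noise(self):
        X, y = spectral_table(400, seed=3)
        rng = np.random.default_rng(3)
        noisy = y.copy()
        flip = rng.choice(len(y), size=int(0.1 * len(y)), replace=False)
        noisy[flip] = np.where(noisy[flip] == "leaf", "wood", "leaf")
        model = train(X, noisy, "spectral",
                      ForestSettings(n_estimators=200), seed=3)
        Xt, yt = spectral_table(200, seed=30)
        labels, _ = predict(model, Xt)
        assert np.mean(labels == yt) >= 0.9

    def test_single_class_input_is_error(self):
        X, y = spectral_table(20, seed=4)
        with pytest.raises(ValueError):
            train(X, np.array(["leaf"] * len(y)), "spectral")

    def test_predict_deterministic_and_threshold_consistent(self):
        X, y = spectral_table(50, seed=5)
        model = train(X, y, "spectral", ForestSettings(n_estimators=50), seed=5)
        rows = pd.concat([X.iloc[[0]]] * 8, ignore_index=True)
        labels, probs = predict(model, rows)
        assert len(set(labels)) == 1 and len(set(probs)) == 1
        proba = predict_proba(model, X)
        labels_all, _ = predict(model, X)
        assert (np.where(proba["leaf"] >= 0.5, "leaf", "wood")
                == labels_all).all()

    def test_feature_mismatch_error_names_columns(self):
        X, y = spectral_table(20, seed=6)
        model = train(X, y, "spectral", ForestSettings(n_estimators=10), seed=6)
        with pytest.raises(ValueError, match="ndi"):
            predict(model, X[["rho_nir", "rho_swir"]])

    def test_model_archive_round_trip(self, tmp_path):
        X, y = spectral_table(30, seed=7)
        model = train(X, y, "spectral", ForestSettings(n_estimators=20), seed=7)
        p = tmp_path / "model.joblib"
        save_model(model, p)
        back = load_model(p)
        assert back.attribute_set == "spectral"
        assert back.feature_names == model.feature_names
        np.testing.assert_array_equal(predict(back, X)[0], predict(model, X)[0])


class TestCrossValidate:
    def test_stratified_split_counts_exact_for_balanced_classes(self):
        y = np.array(["leaf"] * 100 + ["wood"] * 100)
        tr, te = stratified_split(y, train_fraction=0.75, seed=0)
        assert len(tr) == 150 and len(te) == 50
        assert np.sum(y[tr] == "leaf") == 75 and np.sum(y[tr] == "wood") == 75
        assert np.sum(y[te] == "leaf") == 25 and np.sum(y[te] == "wood") == 25

    def test_split_reproducible_for_fixed_seed(self):
        y = np.array(["leaf", "wood"] * 50)
        a = stratified_split(y, seed=9)
        b = stratified_split(y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_perfect_separation_gives_unity(self):
        X, y = spectral_table(100, sd=0.005, seed=8)
        rep = cross_validate(X, y, "spectral",
                             settings=ForestSettings(n_estimators=100), seed=8)
        assert rep.overall == 1.0

    def test_small_class_is_error(self):
        X, y = spectral_table(100, seed=9)
        y = y.copy()
        y[y == "wood"] = "leaf"
        y[:3] = "wood"
        with pytest.raises(ValueError):
            cross_validate(X, y, "spectral")

    def test_overlapping_classes_track_bayes_rate(self):
        """Held-out accuracy approaches the analytic Bayes rate.

        One overlapping Gaussian feature with class-mean separation delta
        gives Bayes error Phi(-delta / 2 sd). Tree depth is capped so the
        forest behaves as a smooth threshold rule rather than memorising
        the overlap region.
        """
        sd = 0.1
        delta = 0.2
        bayes_err = norm.cdf(-delta / (2 * sd))
        overalls = []
        for seed in range(20):
            X, y = spectral_table(200, leaf_ndi=delta, wood_ndi=0.0,
                                  sd=sd, seed=seed)
            # keep only the overlapping feature informative
            X = X.assign(rho_nir=0.43, rho_swir=0.30)
            rep = cross_validate(
                X, y, "spectral",
                settings=ForestSettings(n_estimators=200, max_depth=4),
                seed=seed)
            overalls.append(rep.overall)
        assert np.mean(overalls) == pytest.approx(1 - bayes_err, abs=0.05)


class TestAccuracyMetrics:
    def test_diagonal_matrix(self):
        rep = accuracy_metrics([[50, 0], [0, 50]])
        assert rep.overall == 1.0
        assert all(v == 1.0 for v in rep.producers.values())
        assert all(v == 1.0 for v in rep.users.values())

    def test_worked_arithmetic(self):
        rep = accuracy_metrics([[40, 10], [5, 45]])
        assert rep.overall == pytest.approx(0.85)
        assert rep.producers["leaf"] == pytest.approx(0.8)
        assert rep.producers["wood"] == pytest.approx(0.9)
        assert rep.users["leaf"] == pytest.approx(40 / 45)
        assert rep.users["wood"] == pytest.approx(45 / 55)

    def test_transpose_swaps_producers_and_users(self):
        cm = np.array([[40, 10], [5, 45]])
        a, b = accuracy_metrics(cm), accuracy_metrics(cm.T)
        assert a.producers == b.users and a.users == b.producers

    def test_empty_column_gives_sentinel(self):
        rep = accuracy_metrics([[10, 0], [5, 0]])
        assert np.isnan(rep.users["wood"])

    def test_confusion_matrix_orientation(self):
        cm = confusion_matrix(["leaf", "leaf", "wood"], ["leaf", "wood", "wood"])
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])


def _stub(importances, names=("a", "b"), aset="spectral"):
    return SimpleNamespace(attribute_set=aset, feature_names=list(names),
                           importances=pd.Series(importances, index=list(names)))


class TestFisSummary:
    def test_identical_models_have_zero_cv(self):
        X, y = spectral_table(50, seed=10)
        m1 = train(X, y, "spectral", ForestSettings(n_estimators=30), seed=10)
        m2 = train(X, y, "spectral", ForestSettings(n_estimators=30), seed=10)
        s = fis_summary([m1, m2])
        np.testing.assert_allclose(s["cv"], 0.0, atol=1e-12)

    def test_two_model_arithmetic(self):
        s = fis_summary([_stub([0.6, 0.4]), _stub([0.4, 0.6])])
        np.testing.assert_allclose(s["mean"], [0.5, 0.5])
        np.testing.assert_allclose(s["cv"], [0.2, 0.2])  # population std

    def test_mixed_attribute_sets_rejected(self):
        with pytest.raises(ValueError):
            fis_summary([_stub([1.0, 0.0]), _stub([1.0, 0.0], aset="spatial")])

    def test_spectral_importances_more_stable_than_spatial_across_scans(self):
        """When geometry varies across scans but spectra do not, spatial
        importances scatter more than spectral ones."""
        rng = np.random.default_rng(20)
        spectral_models, spatial_models = [], []
        sp_cols = [f"pc1_s{i:02d}" for i in range(1, 17)] + \
                  [f"pc2_s{i:02d}" for i in range(1, 17)]
        for scan in range(4):
            n = 200
            y = np.array(["leaf"] * n + ["wood"] * n)
            ndi = np.where(y == "leaf", rng.normal(0.3, 0.05, 2 * n),
                           rng.normal(0.0, 0.05, 2 * n))
            Xspec = pd.DataFrame({"rho_nir": rng.normal(0.43, 0.03, 2 * n),
                                  "rho_swir": rng.normal(0.3, 0.1, 2 * n),
                                  "ndi": ndi})
            # geometry: a different scale band is informative in each scan
            Xspat = pd.DataFrame(
                {c: rng.normal(0.4, 0.05, 2 * n) for c in sp_cols})
            info = sp_cols[4 * scan:4 * scan + 4]
            for c in info:
                Xspat[c] = np.where(y == "leaf",
                                    rng.normal(0.35, 0.05, 2 * n),
                                    rng.normal(0.8, 0.05, 2 * n))
            st = ForestSettings(n_estimators=100)
            spectral_models.append(train(Xspec, y, "spectral", st, seed=scan))
            spatial_models.append(train(Xspat, y, "spatial", st, seed=scan))
        cv_spec = fis_summary(spectral_models)["cv"].mean()
        cv_spat = fis_summary(spatial_models)["cv"].mean()
        assert cv_spec < cv_spat
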