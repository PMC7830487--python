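import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, spearmanr

import sproutspec as sp
from sproutspec.chemometrics import (
    PCAModel,
    load_plsr_json,
    save_model_json,
)
from sproutspec.errors import ConfigError, DataError, FoldDesignError

from conftest import make_spectra


# ======================================================================
# PCA


class TestPCA:
    def test_rank1_line(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.column_stack([t, t]) + rng.normal(scale=1e-6, size=(200, 2))
        model = sp.pca_fit(X, 2)
        np.testing.assert_allclose(
            np.abs(model.loadings[0]), [1 / np.sqrt(2)] * 2, atol=1e-4
        )
        assert model.explained_var_pct[0] > 99.99

    def test_eigen_oracle_4x3(self):
        X = np.array([[1, 2, 0], [3, 1, 4], [0, 5, 2], [2, 2, 2]], dtype=float)
        C = np.cov(X, rowvar=False)  # 3x3 covariance
        # independent oracle: roots of the explicit characteristic cubic
        tr = np.trace(C)
        minors = (
            C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
            + C[0, 0] * C[2, 2] - C[0, 2] * C[2, 0]
            + C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1]
        )
        det = np.linalg.det(C)
        oracle = np.sort(np.roots([1.0, -tr, minors, -det]).real)[::-1]
        model = sp.pca_fit(X, 3)
        # singular values relate to covariance eigenvalues via s^2/(n-1)
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        s2 = np.sort(np.linalg.norm(Xc @ model.loadings.T, axis=0) ** 2)[::-1]
        np.testing.assert_allclose(s2 / (n - 1), oracle, atol=1e-10)

    def test_loadings_orthonormal(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        model = sp.pca_fit(proc, 10)
        G = model.loadings @ model.loadings.T
        np.testing.assert_allclose(G, np.eye(10), atol=1e-8)

    def test_scores_zero_mean_and_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 5))
        model = sp.pca_fit(X, 5)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-10)
        recon = model.scores @ model.loadings + model.center
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_explained_var_monotone_and_bounded(self, extract_preprocessed):
        model = sp.pca_fit(extract_preprocessed[0], 10)
        assert np.all(np.diff(model.explained_var_pct) <= 1e-12)
        assert model.explained_var_pct.sum() <= 100.0 + 1e-9

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        model = sp.pca_fit(X, 4)
        for load in model.loadings:
            assert load[np.argmax(np.abs(load))] > 0

    def test_pc1_tracks_germination_time(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        model = sp.pca_fit(proc, 2)
        rho = spearmanr(
            model.scores[:, 0], proc.meta["germination_h"].to_numpy()
        ).statistic
        assert abs(rho) > 0.9

    def test_n_pcs_too_large(self):
        with pytest.raises(ConfigError):
            sp.pca_fit(np.zeros((3, 5)) + np.arange(5), 4)


# ======================================================================
# LDA


class TestPcaLda:
    def test_separable_gaussians(self):
        rng = np.random.default_rng(0)
        a = rng.normal([0, 0], 0.1, size=(30, 2))
        b = rng.normal([5, 5], 0.1, size=(30, 2))
        X = np.vstack([a, b])
        labels = np.array(["a"] * 30 + ["b"] * 30)
        model = sp.pca_lda_fit(X, labels, n_pcs=2)
        pred = model.classify_spectra(X)
        assert np.mean(pred == labels) == 1.0
        # root1 in PC space aligns with the projected centroid difference
        pca_scores = model.pca.transform(X)
        diff = pca_scores[30:].mean(axis=0) - pca_scores[:30].mean(axis=0)
        diff /= np.linalg.norm(diff)
        cos = abs(model.canonical_axes[0] @ diff)
        assert cos > 0.99

    def test_permuted_labels_near_chance(self):
        """Permutation oracle: random labels give chance-level CV accuracy."""
        rng = np.random.default_rng(123)
        n_classes, per_class, reps = 3, 12, 200
        correct, total = 0, 0
        for _ in range(reps):
            X = rng.normal(size=(n_classes * per_class, 6))
            labels = np.repeat(np.arange(n_classes), per_class)
            labels = rng.permutation(labels)
            s = make_spectra(
                X,
                wavelengths=np.arange(6) * 10.0 + 1300,
                sample_id=[f"s{i}" for i in range(len(labels))],
                germination_h=[0] * len(labels),
                replicate=rng.integers(1, 4, size=len(labels)).tolist(),
                scan=[1] * len(labels),
                mode=["transmission"] * len(labels),
            )
            try:
                m, conf, _ = sp.crossval_lda(
                    s, labels, sp.CVScheme("replicate_3fold"), n_pcs=5
                )
            except FoldDesignError:
                continue  # a class missing from some calibration fold
            correct += conf.trace()
            total += conf.sum()
        # no skill: never above the 99% binomial band; cross-validation
        # introduces a small negative bias, so allow a tolerant lower edge
        hi = binom.ppf(0.995, total, 1.0 / n_classes)
        assert correct <= hi
        assert correct / total == pytest.approx(1.0 / n_classes, abs=0.05)

    def test_fixture_centroids_ordered_by_time(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        labels = proc.meta["germination_h"].to_numpy()
        model = sp.pca_lda_fit(proc, labels, n_pcs=10)
        root1 = model.class_centroids[:, 0]
        order = np.argsort([float(c) for c in model.class_labels])
        diffs = np.diff(root1[order])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_single_class_is_100pct(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 4))
        s = make_spectra(
            X,
            wavelengths=np.arange(4) * 10.0 + 1300,
            sample_id=[f"s{i}" for i in range(9)],
            germination_h=[0] * 9,
            replicate=[1, 1, 1, 2, 2, 2, 3, 3, 3],
            scan=[1] * 9,
            mode=["transmission"] * 9,
        )
        labels = np.array(["only"] * 9)
        m, conf, _ = sp.crossval_lda(s, labels, sp.CVScheme("replicate_3fold"), n_pcs=3)
        assert m.accuracy_recognition_pct == 100.0
        assert m.accuracy_prediction_pct == 100.0


class TestCrossvalLda:
    def test_fixture_100pct_prediction(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        labels = proc.meta["germination_h"].to_numpy()
        m, conf, classes = sp.crossval_lda(
            proc, labels, sp.CVScheme("replicate_3fold"), n_pcs=10
        )
        assert m.accuracy_prediction_pct == 100.0
        assert conf.sum() == proc.n_samples
        assert np.all(conf == np.diag(np.diag(conf)))

    def test_folds_partition(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        folds = sp.CVScheme("replicate_3fold").folds(proc.meta)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(proc.n_samples))

    def test_group_kfold_keeps_times_together(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        folds = sp.CVScheme("group_kfold_by_time", k=6, seed=3).folds(proc.meta)
        times = proc.meta["germination_h"].to_numpy()
        seen = {}
        for f, idx in enumerate(folds):
            for t in np.unique(times[idx]):
                assert seen.setdefault(t, f) == f

    def test_bad_replicates_raise(self):
        s = make_spectra(np.zeros((2, 3)) + [[0.0, 1, 2], [3, 4, 5]], replicate=[1, 7])
        with pytest.raises(FoldDesignError):
            sp.CVScheme("replicate_3fold").folds(s.meta)

    def test_validation_rows_do_not_influence_fold_models(self, extract_preprocessed):
        """Leakage guard: perturbing rows of replicate 3 (a validation
        fold) must not change how folds 1 and 2 classify their own
        held-out data."""
        proc, _ = extract_preprocessed
        labels = proc.meta["germination_h"].to_numpy()
        scheme = sp.CVScheme("replicate_3fold")
        reps = proc.meta["replicate"].to_numpy()

        def fold_accuracies(data):
            accs = []
            for val_rep in (1, 2):
                cal = data.absorbance[reps != val_rep]
                val = data.absorbance[(reps == val_rep) & (reps != 3)]
                pca = sp.pca_fit(cal, 10)
                from sproutspec.chemometrics import _lda_from_scores

                model = _lda_from_scores(pca.transform(cal), labels[reps != val_rep], 10)
                pred = model.classify_scores(pca.transform(val))
                accs.append(np.mean(pred == labels[(reps == val_rep) & (reps != 3)]))
            return accs

        base = fold_accuracies(proc)
        tampered = proc.copy()
        tampered.absorbance[reps == 3] += 100.0
        # folds 1/2 exclude replicate-3 rows from calibration entirely
        m1, _, _ = sp.crossval_lda(proc, labels, scheme, 10)
        m2, _, _ = sp.crossval_lda(tampered, labels, scheme, 10)
        # replicate-3 rows only affect their own fold's predictions
        assert fold_accuracies(tampered) == base
        assert m1.accuracy_recognition_pct == m2.accuracy_recognition_pct


# ======================================================================
# PLSR


class TestPlsrFit:
    def test_rank1_exact(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=30)
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.outer(t, direction)
        y = 2.0 + 3.0 * t
        model = sp.plsr_fit(X, y, 1)
        assert model.metrics.r2 == pytest.approx(1.0, abs=1e-10)
        assert model.metrics.rmsec == pytest.approx(0.0, abs=1e-8)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = sp.plsr_fit(X, y, 3)
        # OLS oracle by normal equations on centred data
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        np.testing.assert_allclose(model.predict(X), Xc @ beta + y.mean(), atol=1e-8)

    def test_sequential_equals_regression_vector(self, standard_preprocessed):
        proc = standard_preprocessed
        y = proc.meta["analyte_conc"].to_numpy(dtype=float)
        model = sp.plsr_fit(proc, y, 3)
        np.testing.assert_allclose(
            model.predict(proc.absorbance),
            model.predict_sequential(proc.absorbance),
            atol=1e-8,
        )

    def test_regression_vector_peaks_near_analyte_bands(self, standard_fixture):
        # SG smoothing only: SNV folds the overlapping water bands into
        # the regression vector and shifts its lobes
        proc = sp.preprocess_pipeline(
            standard_fixture,
            sp.PreprocessConfig(apply_snv=False, window=sp.WavelengthWindow(1300, 1600)),
        )
        y = proc.meta["analyte_conc"].to_numpy(dtype=float)
        model = sp.plsr_fit(proc, y, 2)
        b = np.abs(model.regression_vector)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(b, height=0.5 * b.max())
        peak_nm = proc.wavelengths[peaks]
        for center in (1414.0, 1477.0, 1503.0):
            assert np.min(np.abs(peak_nm - center)) <= 10.0

    def test_zero_variance_y_rejected(self):
        with pytest.raises(DataError):
            sp.plsr_fit(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5), 2)

    def test_json_round_trip(self, tmp_path, standard_preprocessed):
        proc = standard_preprocessed
        y = proc.meta["analyte_conc"].to_numpy(dtype=float)
        model = sp.plsr_fit(proc, y, 2)
        path = tmp_path / "model.json"
        save_model_json(model, path)
        again = load_plsr_json(path)
        np.testing.assert_allclose(again.predict(proc.absorbance), model.predict(proc.absorbance))


class TestPlsrCrossval:
    def test_noiseless_1lv_system_selects_1(self):
        rng = np.random.default_rng(0)
        t = np.repeat(np.arange(7.0), 3) + rng.normal(scale=1e-9, size=21)
        X = np.outer(t, [1.0, 2.0, -1.0, 0.5])
        y = 1.0 + 2.0 * t
        meta = pd.DataFrame(
            {"germination_h": np.repeat(np.arange(0, 42, 6), 3), "replicate": [1, 2, 3] * 7}
        )
        scheme = sp.CVScheme("group_kfold_by_time", k=3, seed=0)
        model, metrics = sp.plsr_crossval(X, y, scheme, max_lv=4, meta=meta)
        assert model.n_lv == 1
        assert metrics.r2 == pytest.approx(1.0, abs=1e-8)

    def test_null_response_r2cv_low(self):
        """y independent of X -> grouped CV must not show skill."""
        rng = np.random.default_rng(99)
        r2cvs = []
        times = np.repeat(np.arange(0, 126, 6), 3)
        meta = pd.DataFrame({"germination_h": times, "replicate": [1, 2, 3] * 21})
        scheme = sp.CVScheme("group_kfold_by_time", k=6, seed=1)
        for _ in range(200):
            X = rng.normal(size=(63, 5))
            y = rng.normal(size=63)
            _, metrics = sp.plsr_crossval(X, y, scheme, max_lv=4, meta=meta)
            r2cvs.append(metrics.r2_cv)
        assert np.mean(r2cvs) <= 0.1
        assert np.mean(np.array(r2cvs) > 0.1) < 0.1

    def test_water_fixture_selects_2lv(self, extract_preprocessed):
        proc, truth = extract_preprocessed
        agg = sp.aggregate_scans(proc, level="scan")
        per_rep = truth.groupby(["sample_id", "replicate"], sort=False)["water_pct"].mean()
        y = np.array([per_rep[(r.sample_id, r.replicate)] for r in agg.meta.itertuples()])
        pca = sp.pca_fit(agg, 10)
        nm = sp.select_important_wavelengths(pca)
        cols = [agg.nearest_index(v) for v in nm]
        X = sp.SpectraSet(agg.wavelengths[cols], agg.absorbance[:, cols], agg.meta)
        scheme = sp.CVScheme("group_kfold_by_time", k=6, seed=1)
        model, metrics = sp.plsr_crossval(X, y, scheme, max_lv=10)
        assert model.n_lv == 2
        assert metrics.r2_cv > 0.96

    def test_max_lv_capped_silently(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        meta = pd.DataFrame(
            {"germination_h": np.repeat([0, 6, 12, 18], 3), "replicate": [1, 2, 3] * 4}
        )
        scheme = sp.CVScheme("group_kfold_by_time", k=2, seed=0)
        model, _ = sp.plsr_crossval(X, y, scheme, max_lv=50, meta=meta)
        assert model.n_lv <= 3


# ======================================================================
# Important wavelengths


def _pca_model_from_loadings(loadings, wavelengths):
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    return PCAModel(
        center=np.zeros(loadings.shape[1]),
        loadings=loadings,
        scores=np.zeros((2, loadings.shape[0])),
        explained_var_pct=np.full(loadings.shape[0], 50.0),
        wavelengths=np.asarray(wavelengths, dtype=float),
    )


class TestSelectWavelengths:
    def test_single_bump(self):
        wl = np.arange(1300.0, 1601.0, 2.0)
        bump = np.exp(-0.5 * ((wl - 1454.0) / 8.0) ** 2)
        model = _pca_model_from_loadings(bump, wl)
        assert sp.select_important_wavelengths(model, pcs=[1]) == [1454.0]

    def test_two_equal_bumps(self):
        wl = np.arange(1300.0, 1601.0, 1.0)  # 1 nm grid so 1393 is on-grid
        curve = np.exp(-0.5 * ((wl - 1393.0) / 6.0) ** 2) + np.exp(
            -0.5 * ((wl - 1522.0) / 6.0) ** 2
        )
        # direct peak-scan oracle
        oracle = [
            float(wl[i])
            for i in range(1, len(wl) - 1)
            if curve[i] > curve[i - 1] and curve[i] > curve[i + 1]
            and curve[i] >= 0.5 * curve.max()
        ]
        model = _pca_model_from_loadings(curve, wl)
        assert sp.select_important_wavelengths(model, pcs=[1]) == oracle == [1393.0, 1522.0]

    def test_fixture_peaks_near_generator_bands(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        model = sp.pca_fit(proc, 2)
        selected = sp.select_important_wavelengths(model)
        assert selected, "no wavelengths selected"
        # every selected wavelength near a configured generator band
        bands = [1380.0, 1412.0, 1414.0, 1452.0, 1477.0, 1503.0, 1512.0]
        for nm in selected:
            assert min(abs(nm - b) for b in bands) <= 12.0

    def test_sample_order_invariance(self, extract_preprocessed):
        proc, _ = extract_preprocessed
        rng = np.random.default_rng(0)
        perm = rng.permutation(proc.n_samples)
        shuffled = sp.SpectraSet(
            proc.wavelengths, proc.absorbance[perm], proc.meta.iloc[perm]
        )
        a = sp.select_important_wavelengths(sp.pca_fit(proc, 2))
        b = sp.select_important_wavelengths(sp.pca_fit(shuffled, 2))
        assert a == b

    def test_empty_result_warns(self):
        wl = np.arange(1300.0, 1401.0, 2.0)
        model = _pca_model_from_loadings(np.linspace(1, 2, wl.size), wl)
        with pytest.warns(UserWarning):
            out = sp.select_important_wavelengths(model, pcs=[1], prominence_frac=2.0)
        assert out == []


# ======================================================================
# Metrics


class TestRegressionMetrics:
    def test_perfect(self):
        m = sp.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == 1.0 and m.rmsec == 0.0

    def test_hand_arithmetic(self):
        m = sp.regression_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        assert m.rmsec == pytest.approx(np.sqrt(4.0 / 3.0))
        assert m.r2 == pytest.approx(-1.0)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 4.0, 7.0])
        m = sp.regression_metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_constant_y_true_rejected(self):
        with pytest.raises(DataError):
            sp.regression_metrics([2.0, 2.0], [1.0, 3.0])
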