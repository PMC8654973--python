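"""Observation assembly, LOL, Yeo-Johnson, logistic fit and bundle contracts."""

import numpy as np
import pandas as pd
import pytest

from icumotion import model as md
from icumotion.features import FEATURES, WindowFeatureSeries
from icumotion.synthetic import EXTREMITIES


def complete_series(rng, n_windows=80):
    cols = [(p, f) for p in EXTREMITIES for f in FEATURES]
    vals = np.abs(rng.normal(size=(n_windows, len(cols)))) + 0.01
    frame = pd.DataFrame(vals, columns=pd.MultiIndex.from_tuples(
        cols, names=["placement", "feature"]))
    return WindowFeatureSeries(patient_id="P0", frame=frame,
                               starts=np.arange(n_windows) * 5.0, window_s=5.0)


class TestAssembly:
    def test_column_count_for_3min_window(self):
        schema = md.ColumnSchema(n_steps=36)
        assert schema.n_columns == 6 * 7 * 36 + 6 == 1518

    def test_column_count_for_6h_window(self):
        schema = md.ColumnSchema(n_steps=4320)
        assert schema.n_columns == 6 * 7 * 4320 + 6 == 181_446

    def test_metadata_bijective_with_columns(self):
        schema = md.ColumnSchema(n_steps=12)
        meta = schema.metadata()
        assert len(meta) == schema.n_columns
        assert not meta.duplicated().any()

    def test_row_layout_and_pda(self, rng):
        series = complete_series(rng, n_windows=40)
        row = md.assemble_observation(series, eval_time=150.0, duration_s=60.0)
        assert row.shape == (6 * 7 * 12 + 6,)
        # first 12 entries: RE x SMA over the 12 steps, in time order
        arr = series.frame.loc[:, ("RE", "SMA")].to_numpy()[18:30]
        np.testing.assert_allclose(row[:12], arr)
        # trailing 6 entries are per-placement PDA values in [0, 1]
        assert np.all((row[-6:] >= 0) & (row[-6:] <= 1))

    def test_insufficient_history_raises(self, rng):
        series = complete_series(rng, n_windows=10)
        with pytest.raises(md.InsufficientHistoryError):
            md.assemble_observation(series, eval_time=20.0, duration_s=60.0)

    def test_matrix_skips_early_evaluations(self, rng):
        series = complete_series(rng, n_windows=40)
        evals = [("P0", 10.0, 5), ("P0", 150.0, 2), ("P0", 180.0, 6)]
        obs = md.assemble_matrix({"P0": series}, evals, duration_s=60.0)
        assert len(obs.values) == 2
        np.testing.assert_array_equal(obs.scores, [2, 6])


class TestNormalizer:
    def test_48_combinations(self, rng):
        series = complete_series(rng)
        obs = md.assemble_matrix({"P0": series}, [("P0", 200.0, 3)], 60.0)
        norm = md.fit_column_normalizer(obs.values, obs.schema)
        assert len(norm.loc) == 48 and len(norm.scale) == 48

    def test_mean_sd_mode_centers_training_pool(self, rng):
        series = complete_series(rng, n_windows=120)
        evals = [("P0", t, 3) for t in np.arange(100.0, 590.0, 30.0)]
        obs = md.assemble_matrix({"P0": series}, evals, 60.0)
        norm = md.fit_column_normalizer(obs.values, obs.schema, mode="mean_sd")
        Xn = norm.apply(obs.values, obs.schema)
        meta = obs.schema.metadata()
        for p in ("RE", "LW"):
            cols = np.flatnonzero((meta.placement == p) & (meta.feature == "SMA"))
            pool = Xn[:, cols].ravel()
            assert abs(pool.mean()) < 1e-9
            assert pool.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_training_statistics_reused_for_validation(self, rng):
        series = complete_series(rng, n_windows=120)
        evals = [("P0", t, 3) for t in np.arange(100.0, 590.0, 30.0)]
        obs = md.assemble_matrix({"P0": series}, evals, 60.0)
        norm = md.fit_column_normalizer(obs.values, obs.schema)
        once = norm.apply(obs.values, obs.schema)
        # validation rows are transformed with the same statistics (no refit):
        other = norm.apply(obs.values[:3], obs.schema)
        np.testing.assert_allclose(other, once[:3], atol=1e-12)


def brute_force_lol(X, y, d):
    """Step-by-step reference: mean difference, class centering, SVD, Gram-Schmidt."""
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    dirs = [mu1 - mu0]
    Xc = X.astype(float).copy()
    Xc[y == 0] -= mu0
    Xc[y == 1] -= mu1
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    dirs += [Vt[i] for i in range(Vt.shape[0])]
    basis = []
    for v in dirs:
        w = v.copy()
        for b in basis:
            w = w - (w @ b) * b
        if np.linalg.norm(w) > 1e-10:
            basis.append(w / np.linalg.norm(w))
        if len(basis) == d:
            break
    return np.stack(basis, axis=1)


class TestLOL:
    def test_first_direction_is_mean_difference(self, rng):
        n = 500
        X = np.vstack([rng.normal(0, 0.1, size=(n, 5)),
                       rng.normal(0, 0.1, size=(n, 5)) + np.eye(5)[0] * 2])
        y = np.repeat([0, 1], n)
        proj = md.fit_lol(X, y, d=3)
        assert abs(proj.loadings[:, 0] @ np.eye(5)[0]) > 0.99

    def test_columns_orthonormal(self, rng):
        X = rng.normal(size=(40, 9))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        proj = md.fit_lol(X, y, d=4)
        G = proj.loadings.T @ proj.loadings
        np.testing.assert_allclose(G, np.eye(4), atol=1e-8)

    def test_matches_brute_force_oracle_on_small_matrices(self, rng):
        for _ in range(25):
            n = rng.integers(6, 13)
            p = rng.integers(3, 9)
            d = int(rng.integers(2, min(n, p) + 1))
            X = rng.normal(size=(n, p))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            proj = md.fit_lol(X, y, d=d)
            ref = brute_force_lol(X, y, d)
            assert ref.shape == proj.loadings.shape
            # identical subspaces direction-by-direction (sign-insensitive)
            cos = np.abs(np.sum(proj.loadings * ref, axis=0))
            np.testing.assert_allclose(cos, np.ones(proj.d), atol=1e-8)
            # and identical projected data up to per-direction sign
            signs = np.sign(np.sum(proj.loadings * ref, axis=0))
            np.testing.assert_allclose(X @ proj.loadings,
                                       (X @ ref) * signs, atol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            md.fit_lol(rng.normal(size=(10, 4)), np.zeros(10), d=2)


class TestYeoJohnson:
    def test_identity_lambda_on_normal_data(self, rng):
        Z = rng.normal(size=(2000, 1))
        _, params = md.yeo_johnson_fit_apply(Z)
        assert 0.7 <= params.lmbdas[0] <= 1.3

    def test_roundtrip(self, rng):
        Z = rng.normal(size=(300, 4)) * [0.1, 1, 5, 20]
        T, params = md.yeo_johnson_fit_apply(Z)
        back = md.yeo_johnson_invert(T, params)
        np.testing.assert_allclose(back, Z, atol=1e-8)

    def test_transform_standardizes(self, rng):
        Z = rng.gamma(2.0, 1.0, size=(500, 2))
        T, _ = md.yeo_johnson_fit_apply(Z)
        np.testing.assert_allclose(T.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(T.std(axis=0), 1, atol=1e-9)


class TestLogistic:
    def test_intercept_only_closed_form(self, rng):
        y = np.zeros(100)
        y[:30] = 1
        Z = np.zeros((100, 1))
        beta, cov, flagged = md.fit_logistic(Z, y)
        assert beta[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)
        assert abs(beta[1]) < 1e-6

    def test_separable_data_triggers_ridge_but_orders_classes(self, rng):
        Z = np.concatenate([rng.uniform(-2, -1, 20), rng.uniform(1, 2, 20)])[:, None]
        y = np.repeat([0, 1], 20)
        beta, _, flagged = md.fit_logistic(Z, y)
        assert flagged
        p = md.predict_proba(beta, Z)
        assert p[y == 1].min() > p[y == 0].max()

    def test_row_duplication_invariance(self, rng):
        Z = rng.normal(size=(60, 3))
        y = (Z[:, 0] + rng.normal(0, 1, 60) > 0).astype(float)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        b1, _, _ = md.fit_logistic(Z, y)
        b2, _, _ = md.fit_logistic(np.vstack([Z, Z]), np.concatenate([y, y]))
        np.testing.assert_allclose(b1, b2, atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            md.fit_logistic(rng.normal(size=(10, 2)), np.ones(10))


class TestPredictClassify:
    def test_boundary_half_is_positive_class(self):
        assert md.classify(0.5) == 1
        assert md.classify(0.4999) == 0

    def test_zero_coefficients_give_half(self, rng):
        beta = np.zeros(4)
        p = md.predict_proba(beta, rng.normal(size=(10, 3)))
        np.testing.assert_allclose(p, 0.5)


@pytest.fixture
def fitted_results(rng):
    series = complete_series(rng, n_windows=200)
    times = np.arange(100.0, 990.0, 15.0)
    scores = rng.integers(1, 7, size=len(times))
    evals = [("P0", t, s) for t, s in zip(times, scores)]
    obs = md.assemble_matrix({"P0": series}, evals, duration_s=60.0)
    return md.ThresholdModel(obs, threshold=3, d=4).fit(), obs


class TestThresholdModel:
    def test_training_predictions_reproducible(self, fitted_results):
        res, obs = fitted_results
        np.testing.assert_array_equal(res.predict(obs.values),
                                      res.bundle.train_predictions)

    def test_probabilities_in_open_interval(self, fitted_results):
        res, obs = fitted_results
        p = res.predict(obs.values)
        assert np.all((p > 0) & (p < 1))

    def test_schema_mismatch_named(self, fitted_results, rng):
        res, _ = fitted_results
        with pytest.raises(md.SchemaMismatchError, match="columns"):
            res.predict(rng.normal(size=(1, 100)))

    def test_bundle_json_roundtrip_preserves_predictions(self, fitted_results):
        res, obs = fitted_results
        back = md.ModelBundle.from_json(res.bundle.to_json())
        np.testing.assert_allclose(back.predict(obs.values),
                                   res.predict(obs.values), atol=1e-12)

    def test_summary_mentions_configuration(self, fitted_results):
        res, _ = fitted_results
        text = res.summary()
        assert "GCSm > 3" in text and "d = 4" in text


def test_multi_d_fast_path_matches_per_d_fits(rng):
    """Shared normalizer/LOL/YJ with prefix slicing equals separate fits."""
    series = complete_series(rng, n_windows=60)
    times = np.arange(100.0, 295.0, 15.0)
    scores = rng.integers(1, 7, size=len(times))
    obs = md.assemble_matrix({"P0": series},
                             [("P0", t, s) for t, s in zip(times, scores)], 60.0)
    bundles = md.fit_bundles_multi_d(obs, 3, [2, 4])
    for d in (2, 4):
        direct = md.ThresholdModel(obs, threshold=3, d=d).fit()
        np.testing.assert_allclose(bundles[d].predict(obs.values),
                                   direct.predict(obs.values), atol=1e-10)


def test_default_window_ladder_has_19_durations():
    assert len(md.DEFAULT_WINDOWS_S) == 19
    assert md.DEFAULT_WINDOWS_S[0] == 180
    assert md.DEFAULT_WINDOWS_S[-1] == 24 * 3600
    assert 27 * 60 in md.DEFAULT_WINDOWS_S and 6 * 3600 in md.DEFAULT_WINDOWS_S


def test_d_grid_spans_2_to_20():
    assert md.D_GRID == tuple(range(2, 21))
    assert len(md.D_GRID) == 19
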