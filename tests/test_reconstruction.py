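"""DBM matching, GLLiM/DBL regression and the clipping rules."""

import numpy as np
import pytest

from vascmrf.gllim import GLLiM, load_model, save_model
from vascmrf.reconstruct import (EstimateVector, clip_estimates,
                                 clip_parameter_table, dbl_predict,
                                 dbl_predict_batch, dbl_train, dbm_match,
                                 dbm_match_batch, reconstruct_maps)


class TestDBM:
    def test_self_match_is_exact(self, dict_small):
        idx, score = dbm_match_batch(dict_small.signals, dict_small)
        assert np.array_equal(idx, np.arange(len(dict_small)))
        assert score == pytest.approx(np.ones(len(dict_small)))

    def test_single_query_returns_row_parameters(self, dict_small):
        e = dbm_match(dict_small.signals[7], dict_small)
        row = dict_small.params.iloc[7]
        assert e.bvf == row["bvf"]
        assert e.so2 == row["so2"]
        assert e.match_score == pytest.approx(1.0)

    def test_equals_brute_force_scan(self, dict_small):
        rng = np.random.default_rng(3)
        queries = dict_small.signals[:20] + rng.normal(0, 0.01, (20, 64))
        idx, score = dbm_match_batch(queries, dict_small)
        qn = queries / np.linalg.norm(queries, axis=1, keepdims=True)
        for i in range(20):
            dots = np.array([qn[i] @ s for s in dict_small.signals])
            assert idx[i] == int(np.argmax(dots))
            assert score[i] == pytest.approx(dots.max())

    def test_length_mismatch_fails(self, dict_small):
        with pytest.raises(ValueError, match="length"):
            dbm_match(np.ones(10), dict_small)


class TestClipping:
    def test_upper_bounds_fire(self):
        e = EstimateVector(bvf=101.0, radius=10.0, so2=50.0, t2=60.0)
        c = clip_estimates(e)
        assert c.bvf == 100.0 and c.clipped_flags["bvf"]
        assert c.so2 == 50.0 and not c.clipped_flags["so2"]

    def test_so2_above_100_clipped(self):
        c = clip_estimates(EstimateVector(bvf=3.0, radius=5.0, so2=105.0,
                                          t2=60.0))
        assert c.so2 == 100.0 and c.clipped_flags["so2"]

    def test_negative_radius_clipped_to_zero(self):
        c = clip_estimates(EstimateVector(bvf=3.0, radius=-3.0, so2=70.0,
                                          t2=60.0))
        assert c.radius == 0.0 and c.clipped_flags["radius"]

    def test_t2_has_no_upper_clip(self):
        c = clip_estimates(EstimateVector(bvf=3.0, radius=5.0, so2=70.0,
                                          t2=500.0))
        assert c.t2 == 500.0 and not c.clipped_flags["t2"]

    def test_in_range_is_identity_and_idempotent(self):
        e = EstimateVector(bvf=3.0, radius=5.0, so2=70.0, t2=60.0)
        c1 = clip_estimates(e)
        c2 = clip_estimates(c1)
        assert (c1.bvf, c1.radius, c1.so2, c1.t2) == (3.0, 5.0, 70.0, 60.0)
        assert not any(c1.clipped_flags.values())
        assert (c2.bvf, c2.radius, c2.so2, c2.t2) == (c1.bvf, c1.radius,
                                                      c1.so2, c1.t2)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            clip_parameter_table(np.array([[np.nan, 1.0, 1.0, 1.0]]))


def affine_dataset(n=600, L=4, D=16, noise=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    T = rng.uniform(-1, 1, (n, L)) * np.array([5.0, 3.0, 40.0, 20.0])
    A = rng.normal(0, 1, (D, L))
    b = rng.normal(0, 1, D)
    X = T @ A.T + b + rng.normal(0, noise, (n, D))
    return T, X


class TestGLLiM:
    def test_recovers_affine_map_with_one_component(self):
        T, X = affine_dataset()
        model = GLLiM(n_components=1, seed=0).fit(T[:500], X[:500])
        pred, sd = model.predict(X[500:])
        ss_res = ((pred - T[500:]) ** 2).sum(0)
        ss_tot = ((T[500:] - T[500:].mean(0)) ** 2).sum(0)
        r2 = 1 - ss_res / ss_tot
        assert np.all(r2 > 0.99)
        assert sd.shape == pred.shape

    def test_loglik_nondecreasing(self):
        T, X = affine_dataset(n=400, noise=0.05, seed=1)
        model = GLLiM(n_components=4, seed=2).fit(T, X)
        ll = np.array(model.loglik_path_)
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_same_seed_same_model(self):
        T, X = affine_dataset(n=300, noise=0.05)
        a = GLLiM(n_components=3, seed=11).fit(T, X)
        b = GLLiM(n_components=3, seed=11).fit(T, X)
        assert np.array_equal(a.pi_, b.pi_)
        assert np.array_equal(a.A_, b.A_)

    def test_too_few_rows_rejected(self):
        T, X = affine_dataset(n=50)
        with pytest.raises(ValueError, match="10 x n_components"):
            GLLiM(n_components=10).fit(T, X)

    def test_model_roundtrip(self, tmp_path):
        T, X = affine_dataset(n=300, noise=0.05)
        model = GLLiM(n_components=2, seed=0).fit(T, X)
        save_model(model, tmp_path / "m.h5")
        loaded = load_model(tmp_path / "m.h5")
        a, _ = model.predict(X[:10])
        b, _ = loaded.predict(X[:10])
        assert np.allclose(a, b)


class TestDBL:
    def test_training_rows_predicted_near_truth(self, dict_small):
        model = dbl_train(dict_small, n_components=10, seed=0)
        pred, flags, sd = dbl_predict_batch(model, dict_small.signals)
        truth = dict_small.parameter_array()
        # within-sample error well below the parameter ranges
        assert np.abs(pred[:, 2] - truth[:, 2]).mean() < 10.0  # so2 pp
        assert np.abs(pred[:, 3] - truth[:, 3]).mean() < 6.0   # t2 ms

    def test_estimates_leave_the_grid(self, dict_small):
        model = dbl_train(dict_small, n_components=10, seed=0)
        rng = np.random.default_rng(0)
        noisy = dict_small.signals + rng.normal(0, 0.005,
                                                dict_small.signals.shape)
        pred, _, _ = dbl_predict_batch(model, noisy)
        grid_values = set(np.round(dict_small.params["so2"], 9))
        off_grid = [p for p in np.round(pred[:, 2], 9)
                    if p not in grid_values]
        assert len(off_grid) > 0

    def test_single_prediction_is_clipped_with_flags(self, dict_small):
        model = dbl_train(dict_small, n_components=10, seed=0)
        e = dbl_predict(model, dict_small.signals[0])
        assert 0.0 <= e.bvf <= 100.0
        assert 0.0 <= e.so2 <= 100.0
        assert e.posterior_sd is not None and e.posterior_sd["so2"] > 0


class TestMaps:
    def test_dbm_maps_reproduce_planted_dictionary_rows(self, dict_small):
        rows = np.arange(16).reshape(4, 4)
        series = dict_small.signals[rows.ravel()].reshape(4, 4, -1)
        maps = reconstruct_maps(series, dict_small, "dbm")
        truth = dict_small.parameter_array()[rows.ravel()].reshape(4, 4, 4)
        for j, name in enumerate(("bvf", "radius", "so2", "t2")):
            assert np.array_equal(maps.maps[name], truth[:, :, j])

    def test_masked_voxels_are_nan_not_zero(self, dict_small):
        series = np.tile(dict_small.signals[0], (3, 3, 1))
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        maps = reconstruct_maps(series, dict_small, "dbm", mask=mask)
        assert np.isfinite(maps.maps["bvf"][0, 0])
        assert np.isnan(maps.maps["bvf"][1, 1])

    def test_method_object_mismatch_fails(self, dict_small):
        series = np.tile(dict_small.signals[0], (2, 2, 1))
        with pytest.raises(TypeError):
            reconstruct_maps(series, dict_small, "dbl")
        with pytest.raises(ValueError, match="unknown method"):
            reconstruct_maps(series, dict_small, "nearest")
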