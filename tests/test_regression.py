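import numpy as np
import pytest

from oleospec.regression import (
    fit_pcr,
    fit_plsr,
    load_model,
    predict,
    save_model,
    select_components,
)


def simpls_coef(X, y, f):
    """Independent SIMPLS route (de Jong) for univariate y."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    p_dim = X.shape[1]
    s = Xc.T @ yc
    W = np.zeros((p_dim, f))
    q = np.zeros(f)
    V = np.zeros((p_dim, f))
    for a in range(f):
        r = s.copy()
        t = Xc @ r
        nt = np.linalg.norm(t)
        t /= nt
        r /= nt
        p = Xc.T @ t
        q[a] = yc @ t
        v = p.copy()
        for j in range(a):
            v -= (V[:, j] @ p) * V[:, j]
        v /= np.linalg.norm(v)
        s = s - v * (v @ s)
        W[:, a] = r
        V[:, a] = v
    return W @ q


def random_problem(seed, n=20, p=10):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + 0.1 * rng.standard_normal(n)
    return X, y


class TestPcr:
    def test_full_rank_equals_ols(self):
        X, y = random_problem(0)
        model = fit_pcr(X, y, n_components=10)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        ols_pred = Xc @ beta + y.mean()
        np.testing.assert_allclose(predict(model, X), ols_pred, atol=1e-8)

    def test_exact_one_factor_data(self):
        rng = np.random.default_rng(1)
        t = rng.standard_normal(15)
        p = rng.standard_normal(6)
        X = np.outer(t, p)
        y = 2 * t
        model = fit_pcr(X, y, n_components=1)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-10)

    def test_loadings_orthonormal(self):
        X, y = random_problem(2)
        model = fit_pcr(X, y, n_components=6)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-10)

    def test_reconstruction_error_non_increasing(self):
        X, y = random_problem(3)
        Xc = X - X.mean(axis=0)
        errs = []
        for f in range(1, 9):
            model = fit_pcr(X, y, n_components=f)
            scores = Xc @ model.loadings
            errs.append(np.linalg.norm(Xc - scores @ model.loadings.T))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(4)
        t = rng.standard_normal(12)
        X = np.outer(t, rng.standard_normal(5))  # rank 1 after centering
        with pytest.raises(ValueError):
            fit_pcr(X, t, n_components=3)


class TestPlsr:
    def test_single_predictor_perfect_fit(self):
        x = np.linspace(0, 1, 12)[:, None]
        y = 2 * x.ravel()
        model = fit_plsr(x, y, n_components=1)
        np.testing.assert_allclose(predict(model, x), y, atol=1e-12)

    def test_full_rank_equals_ols(self):
        X, y = random_problem(5)
        model = fit_plsr(X, y, n_components=10)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(predict(model, X), Xc @ beta + y.mean(), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("f", [2, 4, 7])
    def test_nipals_matches_simpls(self, seed, f):
        X, y = random_problem(seed)
        model = fit_plsr(X, y, n_components=f)
        np.testing.assert_allclose(model.coef, simpls_coef(X, y, f), atol=1e-8)

    def test_matches_sklearn_predictions(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_problem(6)
        for f in (2, 5):
            ours = predict(fit_plsr(X, y, n_components=f), X)
            theirs = PLSRegression(n_components=f, scale=False).fit(X, y).predict(X).ravel()
            np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_score_orthogonality(self):
        X, y = random_problem(7)
        model = fit_plsr(X, y, n_components=6)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-10

    def test_sample_order_invariance(self):
        X, y = random_problem(8)
        rng = np.random.default_rng(9)
        perm = rng.permutation(20)
        a = fit_plsr(X, y, n_components=4)
        b = fit_plsr(X[perm], y[perm], n_components=4)
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)

    def test_pcr_and_plsr_coincide_at_full_rank(self):
        X, y = random_problem(10)
        pa = predict(fit_pcr(X, y, n_components=10), X)
        pb = predict(fit_plsr(X, y, n_components=10), X)
        np.testing.assert_allclose(pa, pb, atol=1e-8)

    def test_zero_variance_y_rejected(self):
        X, _ = random_problem(11)
        with pytest.raises(ValueError):
            fit_plsr(X, np.ones(20), n_components=2)


class TestPredict:
    def test_reproduces_fitted_values(self):
        X, y = random_problem(12)
        model = fit_plsr(X, y, n_components=3)
        np.testing.assert_allclose(predict(model, X), (X - model.x_mean) @ model.coef + model.y_mean)

    def test_constant_shift_in_y(self):
        X, y = random_problem(13)
        a = predict(fit_plsr(X, y, 3), X)
        b = predict(fit_plsr(X, y + 5.0, 3), X)
        np.testing.assert_allclose(b, a + 5.0, atol=1e-10)

    def test_mean_spectrum_predicts_mean_response(self):
        X, y = random_problem(14)
        model = fit_plsr(X, y, 4)
        assert predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_column_mismatch_rejected(self):
        X, y = random_problem(15)
        model = fit_plsr(X, y, 2)
        with pytest.raises(ValueError):
            predict(model, X[:, :5])

    def test_save_load_roundtrip(self, tmp_path):
        X, y = random_problem(16)
        for fit in (fit_plsr, fit_pcr):
            model = fit(X, y, 3)
            path = tmp_path / "model.json"
            save_model(model, str(path))
            back = load_model(str(path))
            np.testing.assert_allclose(predict(back, X), predict(model, X), atol=1e-12)


class TestSelectComponents:
    def test_noiseless_rank_two_signal(self):
        rng = np.random.default_rng(17)
        t = rng.standard_normal((40, 2))
        P = rng.standard_normal((2, 12))
        X = t @ P
        y = t[:, 0] + 0.5 * t[:, 1]
        assert select_components(X, y, f_max=6, seed=0) == 2

    def test_pure_noise_parsimony(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        assert select_components(X, y, f_max=8, seed=0) == 1

    def test_deterministic(self):
        X, y = random_problem(19, n=30)
        a = select_components(X, y, f_max=8, seed=4)
        b = select_components(X, y, f_max=8, seed=4)
        assert a == b
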