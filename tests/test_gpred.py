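"""GBLUP fitting, prediction, cross-validation and selection gains."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pinebreed import gpred, relate, syndata


def neg2_restricted_loglik(lam, y, X, G):
    """Dense evaluation of the profiled restricted likelihood (oracle)."""
    n, p = X.shape
    V = lam * G + np.eye(n)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    ypy = float(r @ Vi @ r)
    return (
        (n - p) * np.log(ypy / (n - p))
        + float(np.linalg.slogdet(V)[1])
        + float(np.linalg.slogdet(XtVX)[1])
    )


def sim_grm(n, n_loci, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_loci)
    M = rng.binomial(2, p, size=(n, n_loci)).astype(float)
    Z = M - 2 * p
    return Z @ Z.T / (2 * np.sum(p * (1 - p)))


class TestRemlFit:
    def test_gls_mean_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5, 1, 30)
        model = gpred.reml_fit(y, G=np.eye(30))
        # with G = I the two variances are confounded into an equal-variance
        # model whose GLS mean is the arithmetic mean
        assert model.beta[0] == pytest.approx(y.mean(), rel=1e-6)

    def test_matches_dense_grid_search(self):
        """REML optimum agrees with an independent dense grid (1e-4 log10 steps)."""
        rng = np.random.default_rng(1)
        n = 6
        G = sim_grm(n, 60, 2) + 0.05 * np.eye(n)
        y = rng.normal(0, 1, n) + np.linalg.cholesky(G) @ rng.normal(0, 1, n)
        X = np.ones((n, 1))
        model = gpred.reml_fit(y, X, G)
        grid = 10 ** np.arange(-3, 3, 1e-3)
        vals = [neg2_restricted_loglik(l, y, X, G) for l in grid]
        best = grid[int(np.argmin(vals))]
        fine = best * 10 ** np.arange(-1e-3, 1e-3, 1e-4)
        vals_f = [neg2_restricted_loglik(l, y, X, G) for l in fine]
        best = fine[int(np.argmin(vals_f))]
        assert np.log10(model.ratio) == pytest.approx(np.log10(best), abs=1e-3)

    def test_h2_parameter_recovery(self):
        """sigma2_g / (sigma2_g + sigma2_e) recovers simulated h2 = 0.5."""
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 200
            G = sim_grm(n, 1000, seed)
            g = np.linalg.cholesky(G + 1e-8 * np.eye(n)) @ rng.normal(0, 1, n)
            g *= np.sqrt(0.5) / g.std()
            y = g + rng.normal(0, np.sqrt(0.5), n)
            m = gpred.reml_fit(y, G=G)
            ests.append(m.sigma2_g / (m.sigma2_g + m.sigma2_e))
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gpred.reml_fit(np.ones(10), G=np.eye(10))
        with pytest.raises(ValueError, match="PSD"):
            gpred.reml_fit(np.arange(4.0), G=np.array(
                [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, -2.0]]
            ))


class TestGebvPredict:
    def test_self_prediction_identity(self):
        rng = np.random.default_rng(3)
        n = 12
        G = sim_grm(n, 100, 3)
        y = rng.normal(0, 1, n)
        m = gpred.reml_fit(y, G=G)
        pred = gpred.gebv_predict(m, G)
        np.testing.assert_allclose(pred, m.ahat.to_numpy(), atol=1e-10)

    def test_duplicate_clone_gets_identical_gebv(self):
        rng = np.random.default_rng(4)
        n = 10
        G = sim_grm(n, 80, 4)
        y = rng.normal(0, 1, n)
        m = gpred.reml_fit(y, G=G)
        pred = gpred.gebv_predict(m, G[[0], :])
        assert pred[0] == pytest.approx(m.ahat.iloc[0], abs=1e-10)

    def test_matches_joint_mme_oracle(self):
        """New-clone GEBV equals the explicit Henderson MME joint solve."""
        rng = np.random.default_rng(5)
        n, n_new = 10, 2
        Gfull = sim_grm(n + n_new, 150, 6) + 0.05 * np.eye(n + n_new)
        G = Gfull[:n, :n]
        y = np.linalg.cholesky(Gfull)[: n] @ rng.normal(0, 1, n + n_new) + rng.normal(0, 0.5, n)
        m = gpred.reml_fit(y, G=G)
        pred = gpred.gebv_predict(m, Gfull[n:, :n])
        # MME with all n + n_new clones, Z mapping obs -> first n clones
        lam_inv = m.sigma2_e / m.sigma2_g
        X = np.ones((n, 1))
        Z = np.hstack([np.eye(n), np.zeros((n, n_new))])
        Ginv = np.linalg.inv(Gfull)
        C = np.block(
            [
                [X.T @ X, X.T @ Z],
                [Z.T @ X, Z.T @ Z + lam_inv * Ginv],
            ]
        )
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(C, rhs)
        u = sol[1:]
        np.testing.assert_allclose(pred, u[n:], atol=1e-8)
        np.testing.assert_allclose(m.ahat.to_numpy(), u[:n], atol=1e-8)


class TestCrossValidate:
    def test_high_signal_gives_high_r(self):
        # noiseless genetic signal spanned by few markers (strong relatedness)
        rng = np.random.default_rng(6)
        n, n_loci = 99, 60
        p = rng.uniform(0.1, 0.9, n_loci)
        M = rng.binomial(2, p, size=(n, n_loci)).astype(float)
        Z = M - 2 * p
        G = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        g = Z @ rng.normal(0, 1, n_loci)
        res = gpred.cross_validate(g, G, k=9, seed=1)
        assert res.r_mean > 0.9

    def test_null_phenotypes_give_zero_r(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            n = 60
            G = sim_grm(n, 500, seed + 1)
            y = rng.normal(0, 1, n)
            means.append(gpred.cross_validate(y, G, k=6, seed=seed).r_mean)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * max(se, 0.02)

    def test_seed_determinism_and_fold_partition(self):
        rng = np.random.default_rng(8)
        n = 45
        G = sim_grm(n, 300, 9)
        y = rng.normal(0, 1, n)
        a = gpred.cross_validate(y, G, k=5, seed=3)
        b = gpred.cross_validate(y, G, k=5, seed=3)
        assert a.r_mean == b.r_mean
        np.testing.assert_array_equal(a.per_fold_r, b.per_fold_r)
        folds = gpred.make_folds(n, 5, np.random.default_rng(3))
        assert sorted(np.concatenate(folds).tolist()) == list(range(n))

    def test_small_fold_rejected(self):
        G = sim_grm(7, 100, 10)
        with pytest.raises(ValueError, match="fold too small"):
            gpred.cross_validate(np.arange(7.0), G, k=3, seed=0)

    def test_r_increases_with_h2(self):
        """Mean predictive ability is monotone in simulated heritability."""
        grid = [0.1, 0.3, 0.5, 0.7]
        means = {h: [] for h in grid}
        for seed in range(20):
            G = sim_grm(80, 800, 3000 + seed)
            L = np.linalg.cholesky(G + 1e-8 * np.eye(80))
            rng = np.random.default_rng(seed)
            gvec = L @ rng.normal(0, 1, 80)
            gvec = gvec / gvec.std()
            noise = rng.normal(0, 1, 80)
            for h in grid:
                y = np.sqrt(h) * gvec + np.sqrt(1 - h) * noise
                means[h].append(gpred.cross_validate(y, G, k=8, seed=seed).r_mean)
        avg = [np.mean(means[h]) for h in grid]
        assert all(a < b for a, b in zip(avg, avg[1:]))

    def test_identity_grm_gives_no_prediction(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 60)
        res = gpred.cross_validate(y, np.eye(60), k=6, seed=2)
        assert abs(res.r_mean) < 0.35  # no relatives -> no signal, only noise


class TestPermutationNull:
    def test_extreme_observed_gives_min_p(self):
        # near-noiseless low-rank signal: observed r_y beats every permutation
        rng = np.random.default_rng(13)
        n, n_loci = 60, 30
        p = rng.uniform(0.1, 0.9, n_loci)
        M = rng.binomial(2, p, size=(n, n_loci)).astype(float)
        Z = M - 2 * p
        G = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        g = Z @ rng.normal(0, 1, n_loci)
        res = gpred.permutation_null(g, G, B=49, seed=5, k=6)
        assert res.r_mean > 0.9
        assert res.p_value == pytest.approx(1 / 50)

    def test_null_centered(self):
        rng = np.random.default_rng(15)
        n = 50
        G = sim_grm(n, 400, 16)
        y = rng.normal(0, 1, n)
        res = gpred.permutation_null(y, G, B=200, seed=6, k=5)
        null = res.null_distribution
        assert abs(null.mean()) < 2 * null.std(ddof=1) / np.sqrt(len(null)) + 0.02

    def test_exhaustive_matches_enumeration_oracle(self):
        """Sampled-with-enumeration-flag p equals a direct itertools count."""
        rng = np.random.default_rng(17)
        n = 5
        G = sim_grm(n, 100, 18) + 0.1 * np.eye(n)
        y = rng.normal(0, 1, n)
        res = gpred.permutation_null(y, G, B=120, seed=7, k=2, min_fold=2, exhaustive=True)
        # oracle: enumerate all 120 permutations, recompute r_y via cross_validate
        folds = gpred.make_folds(n, 2, np.random.default_rng(7), min_fold=2)
        engine = gpred._CVEngine(G, folds)
        observed = engine.evaluate(y)[0].mean()
        null = [
            engine.evaluate(y[np.array(p)])[0].mean()
            for p in itertools.permutations(range(n))
        ]
        p_oracle = (1 + sum(v >= observed for v in null)) / (len(null) + 1)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert len(res.null_distribution) == 120


class TestSelectionGain:
    def test_published_style_arithmetic(self):
        assert gpred.gain_percent(51.67, 31.26) == pytest.approx(65.3, abs=0.05)
        assert gpred.gain_percent(321.67, 267.61) == pytest.approx(20.2, abs=0.05)

    def test_top_decile_and_subset(self):
        vals = pd.Series(np.arange(1.0, 21.0), index=[f"c{i}" for i in range(20)])
        top = gpred.selection_gain(vals, top_fraction=0.10)
        assert top.n_selected == 2
        assert top.mean_selected == pytest.approx(19.5)
        whole = gpred.selection_gain(vals, subset_ids=list(vals.index))
        assert whole.gain_pct == pytest.approx(0.0)

    def test_non_positive_baseline_rejected(self):
        vals = pd.Series([-1.0, 0.5, 0.5] + [0.0] * 9)
        with pytest.raises(ValueError, match="baseline"):
            gpred.selection_gain(vals, top_fraction=0.5)


def test_gebv_shrinkage_bound(small_dataset):
    grm = relate.compute_grm(small_dataset.clones)
    rng = np.random.default_rng(19)
    n = grm.n
    g = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n)) @ rng.normal(0, 1, n)
    y = g + rng.normal(0, 1, n)
    m = gpred.reml_fit(y, G=grm.values)
    assert m.ahat.to_numpy().var() <= m.sigma2_g * np.diag(grm.values).mean() + 1e-8
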