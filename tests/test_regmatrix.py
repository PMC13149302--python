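"""Normalization, HVG selection, and the elastic-net fit against oracles."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.linear_model import ElasticNet

from perturbcircuit import (
    SimulationConfig,
    build_design,
    elastic_net_objective,
    fit_elastic_net,
    fit_regulatory_matrix,
    generate_truth,
    normalize,
    select_hvgs,
    simulate_counts,
)
from perturbcircuit.regmatrix import _cd_multi
from perturbcircuit.qc import assign_guides


def _adata(matrix, genes=None, cells=None):
    matrix = np.asarray(matrix, dtype=float)
    return ad.AnnData(
        X=sp.csr_matrix(matrix),
        obs=pd.DataFrame(index=cells or [f"c{i}" for i in range(matrix.shape[0])]),
        var=pd.DataFrame(index=genes or [f"G{i}" for i in range(matrix.shape[1])]),
    )


class TestNormalize:
    def test_zero_count_stays_zero(self):
        norm = normalize(_adata([[0, 5], [3, 2]]))
        assert norm.X[0, 0] == 0.0

    def test_direct_formula(self):
        m = np.zeros((1, 2))
        m[0] = [100, 9900]  # cell total 10,000
        norm = normalize(_adata(m), scale_factor=10_000)
        assert norm.X[0, 0] == pytest.approx(np.log(101.0))

    def test_per_cell_operation(self):
        """Normalized values of a cell depend only on that cell's counts."""
        a = normalize(_adata([[1, 2, 3], [4, 5, 6]]))
        b = normalize(_adata([[1, 2, 3], [40, 50, 60]]))
        np.testing.assert_allclose(a.X.toarray()[0], b.X.toarray()[0])

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            normalize(_adata([[0, 0], [1, 1]]))


class TestSelectHVGs:
    def test_constant_gene_dropped(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(5.0, size=(100, 30)).astype(float)
        m[:, 0] = 4.0  # constant
        hvgs = select_hvgs(normalize(_adata(m)))
        assert "G0" not in hvgs

    def test_high_mean_gene_dropped(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(3.0, size=(200, 25)).astype(float)
        m[:, 1] = rng.poisson(4000.0, size=200)  # log1p(mean) >> 3
        hvgs = select_hvgs(normalize(_adata(m)))
        assert "G1" not in hvgs

    def test_condition_inflated_genes_selected(self):
        """Genes whose mean shifts strongly between conditions acquire excess
        dispersion and are preferentially selected (>= 80% of planted)."""
        rng = np.random.default_rng(2)
        n, g = 800, 300
        mu = rng.lognormal(0.5, 0.8, size=g)
        m = rng.poisson(mu[None, :] * np.ones((n, 1))).astype(float)
        planted = rng.choice(g, 20, replace=False)
        m[: n // 2, planted] = rng.poisson(
            mu[planted][None, :] * np.exp(1.0), size=(n // 2, len(planted)))
        # scale factor matched to sequencing depth so normalized means sit on
        # the conventional threshold scale
        depth = float(m.sum(axis=1).mean())
        hvgs = select_hvgs(normalize(_adata(m), scale_factor=depth))
        hit = sum(f"G{i}" in hvgs for i in planted) / len(planted)
        assert hit >= 0.8


def _ols(y, X):
    Xi = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return coef[1:], coef[0]


class TestFitElasticNet:
    def setup_method(self):
        rng = np.random.default_rng(0)
        n = 50
        X = np.zeros((n, 3))
        X[:15, 0] = 1
        X[15:30, 1] = 1
        X[30:40, 2] = 1
        self.X = X
        self.y = X @ np.array([0.5, -0.3, 0.8]) + 0.2 + rng.normal(0, 0.3, n)

    def test_lambda_zero_matches_ols(self):
        beta, b0, ok = fit_elastic_net(self.y, self.X, lam=0.0, alpha=0.5)
        oracle_beta, oracle_b0 = _ols(self.y, self.X)
        assert ok
        np.testing.assert_allclose(beta, oracle_beta, atol=1e-6)
        assert b0 == pytest.approx(oracle_b0, abs=1e-6)

    def test_huge_lambda_full_shrinkage(self):
        beta, b0, _ = fit_elastic_net(self.y, self.X, lam=1e6, alpha=0.5)
        np.testing.assert_allclose(beta, 0.0)
        assert b0 == pytest.approx(self.y.mean())

    def test_ridge_closed_form_single_predictor(self):
        """alpha=0 with one unit-variance predictor shrinks the OLS slope by
        1 / (1 + lambda / var)."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=0)  # var(x) = 1 after centering
        y = 2.0 * x + rng.normal(0, 0.5, 200)
        lam = 0.7
        beta, _, _ = fit_elastic_net(y, x[:, None], lam=lam, alpha=0.0,
                                     tol=1e-12)
        ols_slope, _ = _ols(y, x[:, None])
        assert beta[0] == pytest.approx(ols_slope[0] / (1 + lam), rel=1e-6)

    def test_matches_sklearn_elastic_net(self):
        """Independent cross-check: sklearn optimizes the same objective."""
        lam, alpha = 0.05, 0.6
        beta, b0, _ = fit_elastic_net(self.y, self.X, lam=lam, alpha=alpha,
                                      tol=1e-12)
        sk = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                        tol=1e-10, max_iter=100_000).fit(self.X, self.y)
        np.testing.assert_allclose(beta, sk.coef_, atol=1e-6)
        assert b0 == pytest.approx(sk.intercept_, abs=1e-6)

    def test_objective_nonincreasing_over_sweeps(self):
        n = len(self.y)
        xbar = self.X.mean(axis=0)
        ybar = self.y.mean()
        Xc = self.X - xbar
        yc = self.y - ybar
        gram = Xc.T @ Xc / n
        xty = (Xc.T @ yc / n)[:, None]
        lam, alpha = 0.05, 0.5
        prev = np.inf
        beta = None
        for sweeps in range(1, 15):
            beta, _, _ = _cd_multi(gram, xty, lam, alpha, max_iter=sweeps,
                                   tol=0.0)
            b = beta[:, 0]
            obj = elastic_net_objective(self.y, self.X, b,
                                        ybar - xbar @ b, lam, alpha)
            assert obj <= prev + 1e-12
            prev = obj

    def test_sparsity_monotone_in_lambda(self):
        nnz = []
        for lam in [0.0, 0.01, 0.05, 0.1, 0.5, 1.0]:
            beta, _, _ = fit_elastic_net(self.y, self.X, lam=lam, alpha=1.0)
            nnz.append(int(np.sum(beta != 0)))
        assert nnz == sorted(nnz, reverse=True)


def _toy_assignments(cells, perts):
    return pd.DataFrame({
        "status": "singlet",
        "perturbation": perts,
        "sgRNA_id": [f"sg{p}" for p in perts],
    }, index=pd.Index(cells, name="barcode"))


class TestFitRegulatoryMatrix:
    def _toy(self, n_per=40, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        cells, perts, rows = [], [], []
        for i, grp in enumerate(["A", "B", "NTC"]):
            for c in range(n_per):
                cells.append(f"{grp}{c:03d}")
                perts.append(grp)
                base = np.array([1.0, 1.0, 1.0, 1.0])
                if grp == "A":
                    base[0] += 1.0
                if grp == "B":
                    base[1] -= 0.8
                rows.append(base + noise * rng.normal(size=4))
        X = np.exp(np.array(rows))  # positive "counts"
        adata = _adata(X, cells=cells)
        norm = ad.AnnData(X=sp.csr_matrix(np.array(rows)),
                          obs=pd.DataFrame(index=cells),
                          var=adata.var.copy())
        return norm, _toy_assignments(cells, perts)

    def test_noiseless_sign_recovery(self):
        norm, assignments = self._toy(noise=0.0)
        fit = fit_regulatory_matrix(norm, assignments, list(norm.var_names),
                                    seed=0)
        assert fit.beta.loc["A", "G0"] > 0.5
        assert fit.beta.loc["B", "G1"] < -0.4
        assert fit.beta.loc["A", "G2"] == pytest.approx(0.0, abs=1e-8)

    def test_control_baseline_in_intercept(self):
        """With lambda=0 (plain fit) the intercept equals the control mean."""
        norm, assignments = self._toy(noise=0.05, seed=3)
        fit = fit_regulatory_matrix(
            norm, assignments, list(norm.var_names), seed=0,
            lambda_grid=[0.0], adaptive_gamma=0.0, debias=False,
            standardize=False, lambda_selection="min", split=(0.8, 0.1, 0.1),
        )
        # reconstruct the training control mean: intercept must match it
        from perturbcircuit.regmatrix import _stratified_split
        from perturbcircuit.config import stream_rng

        labels = assignments["perturbation"]
        train, _, _ = _stratified_split(labels, (0.8, 0.1, 0.1),
                                        stream_rng(0, "split"))
        ctrl_train = [c for c in sorted(train)
                      if assignments.loc[c, "perturbation"] == "NTC"]
        ctrl_mean = norm[ctrl_train].X.toarray().mean(axis=0)
        np.testing.assert_allclose(fit.intercepts.to_numpy(), ctrl_mean,
                                   atol=1e-8)

    def test_deterministic_under_cell_permutation(self):
        norm, assignments = self._toy(noise=0.1, seed=1)
        fit1 = fit_regulatory_matrix(norm, assignments,
                                     list(norm.var_names), seed=5)
        order = np.random.default_rng(0).permutation(norm.n_obs)
        norm2 = norm[order].copy()
        fit2 = fit_regulatory_matrix(norm2, assignments.iloc[order],
                                     list(norm.var_names), seed=5)
        pd.testing.assert_frame_equal(fit1.beta, fit2.beta)
        assert fit1.lambda_ == fit2.lambda_

    def test_null_data_fully_shrunk(self):
        """With no real effects the selected lambda zeroes >=95% of beta."""
        cfg = SimulationConfig(n_genes=300, n_targets=4, n_programs=2,
                               cells_per_guide=50, n_control_cells=120,
                               doublet_rate=0.0)
        truth = generate_truth(cfg, seed=8)
        truth.beta_true.iloc[:, :] = 0.0
        adata, guides = simulate_counts(truth, seed=8)
        assignments = assign_guides(guides, cell_ids=list(adata.obs_names))
        norm = normalize(adata)
        hvgs = select_hvgs(norm)
        fit = fit_regulatory_matrix(norm, assignments, hvgs, seed=8)
        assert (fit.beta.to_numpy() == 0).mean() >= 0.95


class TestBuildDesign:
    def test_control_rows_zero_and_indicators_binary(self, small_screen):
        adata, guides = small_screen
        assignments = assign_guides(guides, cell_ids=list(adata.obs_names))
        design = build_design(assignments)
        singlets = assignments[assignments["status"] == "singlet"]
        ctrl = singlets.index[singlets["perturbation"] == "NTC"]
        assert (design.loc[design.index.intersection(ctrl)].sum(axis=1) == 0).all()
        assert set(np.unique(design.to_numpy())) <= {0.0, 1.0}
        non_ctrl = design.sum(axis=1)
        assert ((non_ctrl == 0) | (non_ctrl == 1)).all()
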