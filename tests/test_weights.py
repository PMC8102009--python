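"""Weight-trainer checks against independent small-scale oracles, the
row-sparsity contract of the group penalty, and GReX imputation."""

import numpy as np
import pytest

from tsatwas import (
    ElasticNetWeights,
    GroupLassoWeights,
    ScenarioConfig,
    impute_grex,
    read_weights,
    simulate_gene_trait_pair,
    weights_to_table,
    write_weights,
)
from tsatwas.exceptions import StructuralError
from tsatwas.simulate import draw_effects, simulate_expression, simulate_genotypes


def _cd_lasso(x, y, alpha, n_iter=5000, tol=1e-12):
    """Brute-force coordinate-descent lasso oracle for tiny problems.

    Minimizes ||y - b0 - X w||^2 / (2n) + alpha * ||w||_1.
    """
    n, m = x.shape
    b0 = y.mean()
    r = y - b0
    w = np.zeros(m)
    col_ss = (x**2).sum(axis=0) / n
    for _ in range(n_iter):
        w_old = w.copy()
        for j in range(m):
            r = r + x[:, j] * w[j]
            rho = x[:, j] @ r / n
            w[j] = np.sign(rho) * max(abs(rho) - alpha, 0.0) / col_ss[j]
            r = r - x[:, j] * w[j]
        if np.max(np.abs(w - w_old)) < tol:
            break
    return w


def _group_objective(x, e, w, alpha):
    n = x.shape[0]
    resid = e - x @ w
    return (resid**2).sum() / (2 * n) + alpha * np.linalg.norm(w, axis=1).sum()


@pytest.fixture(scope="module")
def training_data():
    cfg = ScenarioConfig(n_tissues=3, m_eqtl=10, m_mt=6, m_null=8,
                         cor_tissue=0.6, n_total=450, n_eqtl_train=300,
                         n_twas=150, seed=31)
    panel, eff, expr, _ = simulate_gene_trait_pair(cfg)
    xs = panel.standardized
    return xs[panel.train_rows], expr.expression[panel.train_rows], panel, expr


class TestElasticNet:
    def test_pure_lasso_matches_coordinate_descent_oracle(self, rng):
        # 3 SNPs, one true effect; compare at the CV-chosen penalty
        n = 500
        x = rng.standard_normal((n, 3))
        x = (x - x.mean(0)) / x.std(0)
        y = 0.5 * x[:, 1] + rng.standard_normal(n) * 0.5
        model = ElasticNetWeights(l1_ratio=1.0, random_state=0).fit(x, y[:, None])
        w_oracle = _cd_lasso(x, y, model.alpha_[0])
        np.testing.assert_allclose(model.W_[:, 0], w_oracle, atol=1e-6)

    def test_no_signal_flags_unexpressed(self):
        cfg = ScenarioConfig(n_tissues=2, m_eqtl=10, m_mt=4, m_null=6,
                             h2_snp_expr=0.0, cor_tissue=0.2,
                             n_total=300, n_eqtl_train=200, n_twas=100, seed=32)
        panel = simulate_genotypes(cfg)
        eff = draw_effects(cfg)
        expr = simulate_expression(panel, eff, cfg)
        model = ElasticNetWeights(random_state=0).fit(
            panel.standardized[panel.train_rows], expr.expression[panel.train_rows])
        # the CV-optimal model under the null is (almost always) empty
        assert np.abs(model.W_).max() < 0.05
        assert not model.expressed_mask_.any()

    def test_constant_expression_column_unexpressed_not_error(self, training_data):
        x, e, *_ = training_data
        e = e.copy()
        e[:, 1] = 3.14
        model = ElasticNetWeights(random_state=0).fit(x, e)
        assert not model.expressed_mask_[1]
        assert model.expressed_mask_[0]

    def test_heldout_prediction_beats_chance(self):
        # h2=0.3 signal should give positive held-out R^2 nearly always
        wins = 0
        n_rep = 20
        for s in range(n_rep):
            cfg = ScenarioConfig(n_tissues=1, m_mt=0, m_eqtl=15, m_null=10,
                                 n_total=450, n_eqtl_train=300, n_twas=150, seed=300 + s)
            panel, eff, expr, _ = simulate_gene_trait_pair(cfg)
            xs = panel.standardized
            model = ElasticNetWeights(random_state=0, n_alphas=16, alpha_eps=3e-2,
                                      cv=3).fit(xs[panel.train_rows],
                                                expr.expression[panel.train_rows])
            pred = model.predict(xs[panel.twas_rows])[:, 0]
            truth = expr.expression[panel.twas_rows, 0]
            r2 = 1 - ((truth - pred) ** 2).sum() / ((truth - truth.mean()) ** 2).sum()
            wins += r2 > 0
        assert wins >= int(0.85 * n_rep)


class TestGroupLasso:
    def test_single_tissue_reduces_to_lasso(self, rng):
        n = 300
        x = rng.standard_normal((n, 5))
        x = (x - x.mean(0)) / x.std(0)
        y = 0.4 * x[:, 0] - 0.2 * x[:, 3] + rng.standard_normal(n) * 0.6
        gl = GroupLassoWeights(random_state=0).fit(x, y[:, None])
        w_oracle = _cd_lasso(x, y, gl.alpha_)
        np.testing.assert_allclose(gl.W_[:, 0], w_oracle, atol=1e-6)

    def test_toy_objective_matches_dense_grid_search(self, rng):
        # 2 SNPs x 2 tissues: solver objective vs brute-force grid minimum
        n = 120
        x = rng.standard_normal((n, 2))
        x = (x - x.mean(0)) / x.std(0)
        e = np.column_stack([0.6 * x[:, 0], 0.5 * x[:, 0] + 0.2 * x[:, 1]])
        e = e + rng.standard_normal((n, 2)) * 0.4
        e = e - e.mean(0)
        gl = GroupLassoWeights(random_state=0, tol=1e-10).fit(x, e)
        my_obj = _group_objective(x, e, gl.W_, gl.alpha_)
        # vectorized dense grid over all four weights
        g = np.linspace(-1.0, 1.0, 41)
        a, b, c, d = np.meshgrid(g, g, g, g, indexing="ij")
        w1 = np.stack([a.ravel(), b.ravel()], axis=1)  # SNP 1 row
        w2 = np.stack([c.ravel(), d.ravel()], axis=1)  # SNP 2 row
        n = x.shape[0]
        # residual sum of squares expanded via the 2x2 Gram matrix
        xtx = x.T @ x
        xte = x.T @ e
        ete = (e**2).sum()
        fit0 = (w1[:, 0] * xte[0, 0] + w2[:, 0] * xte[1, 0])
        fit1 = (w1[:, 1] * xte[0, 1] + w2[:, 1] * xte[1, 1])
        quad0 = (w1[:, 0]**2 * xtx[0, 0] + 2 * w1[:, 0] * w2[:, 0] * xtx[0, 1]
                 + w2[:, 0]**2 * xtx[1, 1])
        quad1 = (w1[:, 1]**2 * xtx[0, 0] + 2 * w1[:, 1] * w2[:, 1] * xtx[0, 1]
                 + w2[:, 1]**2 * xtx[1, 1])
        rss = ete - 2 * (fit0 + fit1) + quad0 + quad1
        pen = np.linalg.norm(w1, axis=1) + np.linalg.norm(w2, axis=1)
        objs = rss / (2 * n) + gl.alpha_ * pen
        assert my_obj <= objs.min() + 1e-4

    def test_row_sparsity_shared_support(self, training_data):
        x, e, *_ = training_data
        gl = GroupLassoWeights(random_state=0).fit(x, e)
        row_norm = np.linalg.norm(gl.W_, axis=1)
        active = row_norm > 0
        # a SNP is jointly zero or jointly eligible across tissues
        assert np.any(active)
        zero_rows = gl.W_[~active]
        assert np.all(zero_rows == 0.0)

    def test_large_penalty_gives_all_zero_weights(self, training_data, rng):
        from sklearn.linear_model import MultiTaskLasso
        x, e, *_ = training_data
        model = MultiTaskLasso(alpha=1e3).fit(x, e - e.mean(0))
        assert np.all(model.coef_ == 0.0)

    def test_permutation_invariance(self, training_data, rng):
        x, e, *_ = training_data
        perm = rng.permutation(x.shape[1])
        a = GroupLassoWeights(random_state=5, tol=1e-8).fit(x, e)
        b = GroupLassoWeights(random_state=5, tol=1e-8).fit(x[:, perm], e)
        np.testing.assert_allclose(b.W_, a.W_[perm], atol=1e-5)

    def test_elastic_net_permutation_invariance(self, training_data, rng):
        x, e, *_ = training_data
        perm = rng.permutation(x.shape[1])
        a = ElasticNetWeights(random_state=5, tol=1e-8).fit(x, e)
        b = ElasticNetWeights(random_state=5, tol=1e-8).fit(x[:, perm], e)
        np.testing.assert_allclose(b.W_, a.W_[perm], atol=1e-5)


class TestImputation:
    def test_zero_weights_give_zero_grex_and_empty_mask(self, training_data):
        x, e, panel, _ = training_data
        model = GroupLassoWeights(random_state=0).fit(x, e)
        model.W_ = np.zeros_like(model.W_)
        model.expressed_mask_ = np.any(model.W_ != 0, axis=0)
        grex = impute_grex(model, panel)
        assert not grex.mask.any()
        assert np.all(np.isnan(grex.grex))

    def test_unit_weight_is_identity_passthrough(self, training_data):
        x, e, panel, _ = training_data
        model = ElasticNetWeights(random_state=0).fit(x, e)
        model.W_ = np.zeros_like(model.W_)
        model.W_[4, 2] = 1.0
        model.expressed_mask_ = np.any(model.W_ != 0, axis=0)
        grex = impute_grex(model, panel)
        np.testing.assert_allclose(grex.grex[:, 2], panel.standardized[:, 4])

    def test_random_weights_match_matrix_product_oracle(self, training_data, rng):
        x, e, panel, _ = training_data
        model = ElasticNetWeights(random_state=0).fit(x, e)
        w = rng.standard_normal(model.W_.shape)
        model.W_ = w
        model.expressed_mask_ = np.ones(w.shape[1], dtype=bool)
        grex = impute_grex(model, panel, rows=panel.twas_rows)
        oracle = panel.standardized[panel.twas_rows] @ w
        np.testing.assert_allclose(grex.grex, oracle, atol=1e-10)

    def test_snp_mismatch_raises_structural_error(self, training_data):
        x, e, panel, _ = training_data
        model = ElasticNetWeights(random_state=0).fit(x[:, :-2], e)
        with pytest.raises(StructuralError):
            impute_grex(model, panel)


def test_weight_table_round_trip(tmp_path, training_data):
    x, e, panel, _ = training_data
    model = GroupLassoWeights(random_state=0).fit(x, e)
    table = weights_to_table(model, "geneA", panel.snp_ids)
    path = tmp_path / "weights.tsv"
    write_weights(table, path)
    back = read_weights(path)
    merged = table.merge(back, on=["gene_id", "snp_id", "ref", "alt", "tissue"])
    assert len(merged) == len(table) > 0
    np.testing.assert_array_equal(merged["weight_x"].values, merged["weight_y"].values)
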