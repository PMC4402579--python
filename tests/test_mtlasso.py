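import numpy as np
import pandas as pd
import pytest

from minet import mtlasso as mt
from minet.mtlasso import (
    CorrelationGraph,
    MtLassoConfig,
    association_subnetworks,
    build_correlation_graph,
    extract_eqtls,
    fit,
    lambda_max,
    objective,
)

from conftest import expression_frame


def graph(nodes, edges):
    if edges:
        i, j, r = zip(*edges)
    else:
        i, j, r = (), (), ()
    return CorrelationGraph(
        list(nodes), np.array(i, int), np.array(j, int), np.array(r, float)
    )


def standardize(a):
    a = np.asarray(a, float)
    return (a - a.mean(0)) / a.std(0)


class TestBuildCorrelationGraph:
    def test_identical_features_fully_correlated(self, rng):
        base = rng.standard_normal(30)
        m = expression_frame(np.vstack([base, base]))
        g = build_correlation_graph(m, threshold=0.7)
        assert g.n_edges == 1
        assert g.r[0] == pytest.approx(1.0)
        assert g.weight[0] == pytest.approx(1.0)

    def test_negated_feature_negative_sign(self, rng):
        base = rng.standard_normal(30)
        m = expression_frame(np.vstack([base, -base]))
        g = build_correlation_graph(m, threshold=0.7)
        assert g.sign[0] == -1.0 and g.weight[0] == pytest.approx(1.0)

    def test_independent_features_stay_unconnected(self, rng):
        m = expression_frame(rng.standard_normal((20, 200)))
        g = build_correlation_graph(m, threshold=0.7)
        assert g.n_edges == 0

    def test_constant_feature_excluded_with_warning(self, rng):
        values = rng.standard_normal((3, 20))
        values[1] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            g = build_correlation_graph(expression_frame(values), threshold=0.0)
        assert 1 not in set(g.edges_i) | set(g.edges_j)


class TestObjective:
    def test_zero_matrix_gives_squared_norm_of_y(self, rng):
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((12, 4))
        terms = objective(np.zeros((3, 4)), x, y, None, None, 1.0, 1.0, 1.0)
        assert terms["total"] == pytest.approx(np.sum(y**2))

    def test_all_penalties_off_reduces_to_rss(self, rng):
        x = rng.standard_normal((12, 3))
        y = rng.standard_normal((12, 4))
        b = rng.standard_normal((3, 4))
        terms = objective(b, x, y, None, None, 0.0, 0.0, 0.0)
        assert terms["total"] == pytest.approx(np.sum((y - x @ b) ** 2))

    def test_matches_hand_summed_fixture(self):
        # 2 miRNAs x 2 genes, one signed edge in each graph; every term
        # summed independently below, element by element
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, 0.0]])
        b = np.array([[1.0, -1.0], [0.5, 2.0]])
        g_gene = graph(["g0", "g1"], [(0, 1, 0.9)])     # w=.9, sign=+1
        g_mirna = graph(["m0", "m1"], [(0, 1, -0.8)])   # w=.8, sign=-1
        lam, gamma1, gamma2 = 0.7, 1.3, 2.1

        rss = 0.0
        for i in range(3):
            for k in range(2):
                pred = sum(x[i, j] * b[j, k] for j in range(2))
                rss += (y[i, k] - pred) ** 2
        l1 = lam * sum(abs(b[j, k]) for j in range(2) for k in range(2))
        gene_fusion = gamma1 * 0.9 * sum(
            abs(b[j, 0] - (+1) * b[j, 1]) for j in range(2)
        )
        mirna_fusion = gamma2 * 0.8 * sum(
            abs(b[0, k] - (-1) * b[1, k]) for k in range(2)
        )
        terms = objective(b, x, y, g_gene, g_mirna, lam, gamma1, gamma2)
        assert terms["rss"] == pytest.approx(rss)
        assert terms["l1"] == pytest.approx(l1)
        assert terms["gene_fusion"] == pytest.approx(gene_fusion)
        assert terms["mirna_fusion"] == pytest.approx(mirna_fusion)
        assert terms["total"] == pytest.approx(rss + l1 + gene_fusion + mirna_fusion)

    def test_mismatched_graph_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        y = rng.standard_normal((10, 4))
        bad = graph(["g0"], [])
        with pytest.raises(ValueError, match="dimension|graph"):
            objective(np.zeros((3, 5)), x, y, bad, None, 0.0, 1.0, 0.0)


def make_problem(rng, n=80, j=8, k=10, noise=0.1):
    x = rng.standard_normal((n, j))
    b_true = rng.standard_normal((j, k)) * (rng.random((j, k)) < 0.3)
    y = x @ b_true + noise * rng.standard_normal((n, k))
    xdf = expression_frame(x.T, prefix="m")
    ydf = expression_frame(y.T, prefix="g")
    return xdf, ydf, b_true


class TestFit:
    def test_full_shrinkage_gives_zero_matrix(self, rng):
        xdf, ydf, _ = make_problem(rng)
        xs = standardize(xdf.to_numpy().T)
        ys = standardize(ydf.to_numpy().T)
        lam = 2.0 * lambda_max(xs, ys)
        cfg = MtLassoConfig(lam=lam, gamma1=0.0, gamma2=0.0)
        b, _ = fit(xdf, ydf, cfg)
        assert np.all(b.to_numpy() == 0.0)

    def test_unpenalized_fit_matches_least_squares(self, rng):
        xdf, ydf, _ = make_problem(rng)
        cfg = MtLassoConfig(lam=0.0, gamma1=0.0, gamma2=0.0, tol=1e-12,
                            max_iter=5000)
        b, info = fit(xdf, ydf, cfg)
        xs = standardize(xdf.to_numpy().T)
        ys = standardize(ydf.to_numpy().T)
        b_ols = np.linalg.lstsq(xs, ys, rcond=None)[0]
        rel = np.linalg.norm(b.to_numpy() - b_ols) / np.linalg.norm(b_ols)
        assert rel <= 1e-4

    def test_lasso_mode_matches_coordinate_descent_oracle(self, rng):
        from sklearn.linear_model import Lasso

        xdf, ydf, _ = make_problem(rng)
        n = xdf.shape[1]
        lam = 8.0
        cfg = MtLassoConfig(lam=lam, gamma1=0.0, gamma2=0.0, tol=1e-12,
                            max_iter=20000)
        b, _ = fit(xdf, ydf, cfg)
        xs = standardize(xdf.to_numpy().T)
        ys = standardize(ydf.to_numpy().T)
        for k in range(ys.shape[1]):
            oracle = Lasso(alpha=lam / (2 * n), fit_intercept=False,
                           tol=1e-12, max_iter=100000).fit(xs, ys[:, k])
            np.testing.assert_allclose(
                b.to_numpy()[:, k], oracle.coef_, atol=1e-3
            )

    @pytest.mark.parametrize("edge_r, relation", [(1.0, "equal"), (-1.0, "opposite")])
    def test_fusion_limit_couples_columns(self, rng, edge_r, relation):
        # one strong gene-graph edge: for huge gamma1 the two columns of
        # B converge to equality (positive r) or sign-flipped equality
        n = 50
        x = rng.standard_normal((n, 5))
        y = x @ rng.standard_normal((5, 2)) + 0.1 * rng.standard_normal((n, 2))
        xdf = expression_frame(x.T, prefix="m")
        ydf = expression_frame(y.T, prefix="g")
        g_gene = graph(["g0", "g1"], [(0, 1, edge_r)])
        g_mirna = graph([f"m{j}" for j in range(5)], [])
        cfg = MtLassoConfig(lam=0.0, gamma1=1e4, gamma2=0.0,
                            smoothing_mu=1e-3, tol=1e-14, max_iter=20000)
        b, _ = fit(xdf, ydf, cfg, g_gene=g_gene, g_mirna=g_mirna)
        values = b.to_numpy()
        if relation == "equal":
            np.testing.assert_allclose(values[:, 0], values[:, 1], atol=1e-3)
        else:
            np.testing.assert_allclose(values[:, 0], -values[:, 1], atol=1e-3)

    def test_objective_trace_non_increasing(self, rng):
        xdf, ydf, _ = make_problem(rng, n=60, j=10, k=12)
        cfg = MtLassoConfig(lam=5.0, gamma1=2.0, gamma2=2.0,
                            corr_threshold=0.3)
        _, info = fit(xdf, ydf, cfg)
        trace = np.array(info["objective_trace"])
        assert np.all(np.diff(trace) <= 1e-9)

    def test_nan_input_rejected(self, rng):
        xdf, ydf, _ = make_problem(rng)
        xdf.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit(xdf, ydf, MtLassoConfig(lam=1.0, gamma1=0.0, gamma2=0.0))

    def test_permuted_response_yields_far_fewer_eqtls(self, normalized_cohort):
        # destroying the sample pairing must destroy nearly all signal
        _, mirna, gene, _ = normalized_cohort
        lam = 0.3 * lambda_max(
            standardize(mirna.to_numpy().T), standardize(gene.to_numpy().T)
        )
        cfg = MtLassoConfig(lam=lam, gamma1=0.02 * lam, gamma2=0.02 * lam)
        b_real, _ = fit(mirna, gene, cfg)
        # one absolute extraction cutoff, set by the real fit's scale;
        # a relative cutoff would rescale itself to the null's noise floor
        eps = 0.1 * float(np.abs(b_real.to_numpy()).max())
        cfg_extract = MtLassoConfig(nonzero_eps=eps)
        n_real = len(extract_eqtls(b_real, cfg_extract))

        perm = np.random.default_rng(7).permutation(gene.shape[1])
        gene_perm = pd.DataFrame(
            gene.to_numpy()[:, perm], index=gene.index, columns=gene.columns
        )
        b_null, _ = fit(mirna, gene_perm, cfg)
        n_null = len(extract_eqtls(b_null, cfg_extract))
        assert n_real > 0
        assert n_null <= 0.1 * n_real


class TestExtraction:
    def test_zero_matrix_gives_no_eqtls(self):
        b = pd.DataFrame(np.zeros((2, 3)), index=["m0", "m1"],
                         columns=["g0", "g1", "g2"])
        assert extract_eqtls(b, MtLassoConfig()).empty

    def test_eps_above_max_gives_empty(self, rng):
        b = pd.DataFrame(rng.standard_normal((2, 2)),
                         index=["m0", "m1"], columns=["g0", "g1"])
        cfg = MtLassoConfig(nonzero_eps=10 + float(np.abs(b.to_numpy()).max()))
        assert extract_eqtls(b, cfg).empty

    def test_sorted_by_magnitude_descending(self):
        b = pd.DataFrame([[0.1, -3.0], [2.0, 0.0]],
                         index=["m0", "m1"], columns=["g0", "g1"])
        out = extract_eqtls(b, MtLassoConfig(nonzero_eps=0.0))
        assert list(out["coefficient"].abs()) == sorted(
            out["coefficient"].abs(), reverse=True
        )

    def test_subnetworks_empty_without_eqtls(self):
        b = pd.DataFrame(np.zeros((2, 2)), index=["m0", "m1"],
                         columns=["g0", "g1"])
        g_gene = graph(["g0", "g1"], [(0, 1, 0.9)])
        g_mirna = graph(["m0", "m1"], [(0, 1, 0.8)])
        mirna_edges, gene_edges = association_subnetworks(
            b, g_gene, g_mirna, MtLassoConfig()
        )
        assert mirna_edges == [] and gene_edges == []

    def test_subnetworks_full_when_everything_perturbed(self):
        b = pd.DataFrame(np.ones((2, 2)), index=["m0", "m1"],
                         columns=["g0", "g1"])
        g_gene = graph(["g0", "g1"], [(0, 1, 0.9)])
        g_mirna = graph(["m0", "m1"], [(0, 1, 0.8)])
        mirna_edges, gene_edges = association_subnetworks(
            b, g_gene, g_mirna, MtLassoConfig(nonzero_eps=0.0)
        )
        assert mirna_edges == g_mirna.edge_list()
        assert gene_edges == g_gene.edge_list()

    def test_subnetworks_match_brute_force_restriction(self, rng):
        j, k = 6, 8
        b_values = rng.standard_normal((j, k)) * (rng.random((j, k)) < 0.2)
        b = pd.DataFrame(b_values, index=[f"m{i}" for i in range(j)],
                         columns=[f"g{i}" for i in range(k)])
        g_mirna = graph([f"m{i}" for i in range(j)],
                        [(0, 1, 0.9), (2, 3, -0.8), (4, 5, 0.75)])
        g_gene = graph([f"g{i}" for i in range(k)],
                       [(0, 1, 0.85), (2, 5, 0.7), (6, 7, -0.9)])
        cfg = MtLassoConfig(nonzero_eps=0.0)
        eqtls = extract_eqtls(b, cfg)
        pm, pg = set(eqtls["mirna_id"]), set(eqtls["gene_id"])
        mirna_edges, gene_edges = association_subnetworks(b, g_gene, g_mirna, cfg)
        assert mirna_edges == [
            e for e in g_mirna.edge_list() if e[0] in pm or e[1] in pm
        ]
        assert gene_edges == [
            e for e in g_gene.edge_list() if e[0] in pg and e[1] in pg
        ]
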