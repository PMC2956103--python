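import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tgx.errors import FormatError, ValidationError
from tgx.io import PhenotypeTable, ScoreTable
from tgx.network import (assemble_features, estimate_pcor, export_network,
                         read_edge_list, select_edges, shrinkage_intensity)
from tgx.synthetic import population_pcor

from conftest import exact_correlation_data


def features_from_array(x, n_phenotypes=0, seed_names="f"):
    p = x.shape[1]
    names = [f"{seed_names}{i}" for i in range(p)]
    df = pd.DataFrame(x, index=[f"c{i}" for i in range(x.shape[0])], columns=names)
    scores = ScoreTable(scores=df.iloc[:, :p - n_phenotypes].T)
    phenos = (PhenotypeTable(table=df.iloc[:, p - n_phenotypes:])
              if n_phenotypes else None)
    return assemble_features(scores, phenos)


def brute_force_pcor(x):
    """Partial correlations via full regression residuals (the defining
    construction), independent of the matrix-inversion path."""
    n, p = x.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            z = np.column_stack([np.ones(n), x[:, others]])
            beta_i, *_ = np.linalg.lstsq(z, x[:, i], rcond=None)
            beta_j, *_ = np.linalg.lstsq(z, x[:, j], rcond=None)
            ri = x[:, i] - z @ beta_i
            rj = x[:, j] - z @ beta_j
            out[i, j] = out[j, i] = ri @ rj / np.sqrt((ri @ ri) * (rj @ rj))
    return out


class TestAssembleFeatures:
    def test_blocks_intersected_and_standardized(self):
        rng = np.random.default_rng(0)
        scores = ScoreTable(scores=pd.DataFrame(
            rng.normal(size=(4, 10)), index=[f"s{i}" for i in range(4)],
            columns=[f"c{i}" for i in range(10)]))
        pheno = PhenotypeTable(table=pd.DataFrame(
            rng.normal(size=(8, 2)), index=[f"c{i}" for i in range(2, 10)],
            columns=["ALT", "liver_weight"]))
        feats = features_from_array  # noqa: F841 (clarity)
        fm = assemble_features(scores, pheno)
        assert fm.data.shape == (8, 6)
        assert np.allclose(fm.data.mean(), 0, atol=1e-10)
        assert np.allclose(fm.data.var(ddof=1), 1, atol=1e-10)
        assert set(fm.kinds) == {"gene_set", "phenotype"}

    def test_rows_with_missing_phenotype_dropped(self):
        rng = np.random.default_rng(1)
        scores = ScoreTable(scores=pd.DataFrame(
            rng.normal(size=(3, 6)), index=list("abc"),
            columns=[f"c{i}" for i in range(6)]))
        tab = pd.DataFrame(rng.normal(size=(6, 1)),
                           index=[f"c{i}" for i in range(6)], columns=["ALT"])
        tab.iloc[0, 0] = np.nan
        fm = assemble_features(scores, PhenotypeTable(table=tab))
        assert fm.data.shape[0] == 5

    def test_zero_variance_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(5, 6)),
                            index=[f"c{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(6)])
        data["s0"] = 3.14
        with caplog.at_level("WARNING"):
            fm = assemble_features(ScoreTable(scores=data.T))
        assert "s0" not in fm.data.columns
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_too_few_conditions_is_error(self):
        scores = ScoreTable(scores=pd.DataFrame(
            [[1.0, 2.0], [0.0, 1.0]], index=["s1", "s2"], columns=["c1", "c2"]))
        with pytest.raises(ValidationError, match="at least 3"):
            assemble_features(scores)

    def test_duplicate_feature_names_across_blocks_rejected(self):
        rng = np.random.default_rng(3)
        scores = ScoreTable(scores=pd.DataFrame(
            rng.normal(size=(2, 5)), index=["ALT", "s2"],
            columns=[f"c{i}" for i in range(5)]))
        pheno = PhenotypeTable(table=pd.DataFrame(
            rng.normal(size=(5, 1)), index=[f"c{i}" for i in range(5)],
            columns=["ALT"]))
        with pytest.raises(ValidationError, match="ALT"):
            assemble_features(scores, pheno)


class TestEstimatePcor:
    def test_equicorrelated_closed_form(self):
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        fm = features_from_array(exact_correlation_data(corr, n=200, seed=0))
        net = estimate_pcor(fm, shrinkage=0.0)
        off = net.pcor.to_numpy()[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, 1.0 / 3.0, atol=1e-10)

    @pytest.mark.parametrize("p", [4, 8])
    def test_matches_regression_residual_oracle(self, p):
        rng = np.random.default_rng(p)
        a = rng.normal(size=(p, p))
        cov = a @ a.T + p * np.eye(p)
        x = rng.multivariate_normal(np.zeros(p), cov, size=400)
        fm = features_from_array(x)
        net = estimate_pcor(fm, shrinkage=0.0)
        oracle = brute_force_pcor(fm.data.to_numpy())
        np.testing.assert_allclose(net.pcor.to_numpy(), oracle, atol=1e-8)

    def test_full_shrinkage_gives_identity(self):
        rng = np.random.default_rng(5)
        fm = features_from_array(rng.normal(size=(20, 6)))
        net = estimate_pcor(fm, shrinkage=1.0)
        np.testing.assert_allclose(net.pcor.to_numpy(), np.eye(6), atol=1e-12)

    def test_independent_features_have_small_pcor(self):
        rng = np.random.default_rng(6)
        fm = features_from_array(rng.standard_normal((4000, 5)))
        net = estimate_pcor(fm, shrinkage=0.0)
        off = net.pcor.to_numpy()[np.triu_indices(5, 1)]
        assert np.abs(off).max() < 5.0 / np.sqrt(4000)

    def test_singular_unshrunken_matrix_advises_shrinkage(self):
        rng = np.random.default_rng(7)
        fm = features_from_array(rng.standard_normal((5, 10)))
        with pytest.raises(ValidationError, match="shrinkage"):
            estimate_pcor(fm, shrinkage=0.0)

    def test_shrinkage_path_continuous_to_zero(self):
        rng = np.random.default_rng(8)
        fm = features_from_array(rng.standard_normal((50, 4)))
        lams = np.linspace(0, 1, 21)
        paths = np.array([estimate_pcor(fm, shrinkage=l).pcor.to_numpy()[0, 1]
                          for l in lams])
        assert abs(paths[-1]) < 1e-12
        assert np.abs(np.diff(paths)).max() < 0.1  # no jumps on a fine grid

    def test_auto_shrinkage_in_unit_interval(self):
        rng = np.random.default_rng(9)
        fm = features_from_array(rng.standard_normal((30, 8)))
        net = estimate_pcor(fm, shrinkage="auto")
        assert 0.0 <= net.shrinkage <= 1.0
        assert net.shrinkage == shrinkage_intensity(fm.data)


class TestSelectEdges:
    def _net(self):
        rho = np.eye(4)
        rho[0, 1] = rho[1, 0] = 0.9
        rho[2, 3] = rho[3, 2] = -0.01
        fm_names = [f"f{i}" for i in range(4)]
        from tgx.network import PartialCorrelationNetwork
        return PartialCorrelationNetwork(
            pcor=pd.DataFrame(rho, index=fm_names, columns=fm_names),
            kinds=pd.Series("gene_set", index=fm_names),
            shrinkage=0.0, n_observations=100)

    def test_abs_threshold_semantics(self):
        edges = select_edges(self._net(), rule="abs_threshold", threshold=0.1)
        assert len(edges) == 1
        assert {edges.loc[0, "source"], edges.loc[0, "target"]} == {"f0", "f1"}

    def test_top_k_cardinality(self):
        assert len(select_edges(self._net(), rule="top_k", k=3)) == 3
        with pytest.raises(ValidationError):
            select_edges(self._net(), rule="top_k", k=7)

    def test_perm_fdr_on_independent_features_selects_few_edges(self):
        rng = np.random.default_rng(11)
        fm = features_from_array(rng.standard_normal((100, 10)))
        net = estimate_pcor(fm, shrinkage=0.0)
        edges = select_edges(net, rule="perm_fdr", q=0.05, features=fm,
                             n_permutations=100, seed=1)
        assert len(edges) <= 5  # ~0.05 * 45 expected under the null

    def test_perm_fdr_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        fm = features_from_array(rng.standard_normal((60, 6)))
        net = estimate_pcor(fm, shrinkage="auto")
        e1 = select_edges(net, rule="perm_fdr", q=0.2, features=fm,
                          n_permutations=50, seed=9)
        e2 = select_edges(net, rule="perm_fdr", q=0.2, features=fm,
                          n_permutations=50, seed=9)
        pd.testing.assert_frame_equal(e1, e2)


class TestExport:
    def _small(self):
        rng = np.random.default_rng(13)
        x = rng.multivariate_normal(
            np.zeros(3), [[1, 0.7, 0], [0.7, 1, -0.5], [0, -0.5, 1]], size=200)
        fm = features_from_array(x, n_phenotypes=1)
        net = estimate_pcor(fm, shrinkage=0.1)
        edges = select_edges(net, rule="abs_threshold", threshold=0.1)
        return net, edges

    def test_graphml_loads_with_attributes(self, tmp_path):
        net, edges = self._small()
        export_network(net, edges, tmp_path / "n.graphml", fmt="graphml")
        g = nx.read_graphml(tmp_path / "n.graphml")
        assert set(g.nodes) == set(net.node_names())
        _, _, attrs = next(iter(g.edges(data=True)))
        assert {"weight", "sign"} <= set(attrs)
        assert any(d["kind"] == "phenotype" for _, d in g.nodes(data=True))

    def test_dot_encodes_sign_as_color(self, tmp_path):
        net, edges = self._small()
        assert (edges["pcor"] < 0).any() and (edges["pcor"] > 0).any()
        export_network(net, edges, tmp_path / "n.dot", fmt="dot")
        text = (tmp_path / "n.dot").read_text()
        assert "color=green" in text and "color=purple" in text
        assert "penwidth" in text

    def test_tsv_round_trip(self, tmp_path):
        net, edges = self._small()
        export_network(net, edges, tmp_path / "e.tsv", fmt="tsv")
        back = read_edge_list(tmp_path / "e.tsv")
        pd.testing.assert_frame_equal(back, edges)

    def test_unknown_format_rejected(self, tmp_path):
        net, edges = self._small()
        with pytest.raises(FormatError):
            export_network(net, edges, tmp_path / "x.bin", fmt="binary")


def test_planted_graph_edges_outrank_null_pairs():
    """Data from a known sparse precision matrix: ranking by |pcor| puts
    planted edges first (single-seed sanity check; the averaged version is an
    acceptance test)."""
    from tgx.synthetic import random_sparse_precision, simulate_features
    omega, chosen = random_sparse_precision(10, 8, seed=3)
    scores, phenos, truth = simulate_features(500, omega, seed=4)
    fm = assemble_features(scores)
    net = estimate_pcor(fm, shrinkage="auto")
    edges = select_edges(net, rule="top_k", k=8)
    got = {frozenset((a, b)) for a, b in zip(edges["source"], edges["target"])}
    true = {frozenset(e) for e in truth.edges}
    assert len(got & true) >= 7

    # population partial correlations follow the precision matrix exactly
    rho = population_pcor(omega)
    for i, j in chosen:
        assert abs(rho[i, j]) > 1e-6
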