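import shutil
import subprocess

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from scipy.optimize import brentq

from ppnet import (
    EdgeSet,
    GeneSetCollection,
    IndividualNetwork,
    LabelVector,
    ValidationError,
    edge_matrix,
    estimate_variance_prior,
    gsea_preranked,
    largest_component,
    moderated_t_stats,
    top_edges_network,
)
from tests_oracle_helpers import running_sum_es_oracle, union_find_components


def make_labels(n1, n2):
    ids = [f"s{i}" for i in range(n1 + n2)]
    return LabelVector(pd.Series(["a"] * n1 + ["b"] * n2, index=ids)), ids


class TestEdgeMatrix:
    def test_shape_and_ids(self, rng, small_edges):
        nets = [
            IndividualNetwork(f"s{k}", small_edges, rng.uniform(size=4))
            for k in range(3)
        ]
        m = edge_matrix(nets)
        assert m.shape == (4, 3)
        assert list(m.index) == [f"{a}|{b}" for a, b in small_edges.pairs]

    def test_column_order_independent_of_input_order(self, rng, small_edges):
        nets = [
            IndividualNetwork(f"s{k}", small_edges, rng.uniform(size=4))
            for k in range(4)
        ]
        m1 = edge_matrix(nets)
        m2 = edge_matrix(nets[::-1])
        pd.testing.assert_frame_equal(m1, m2)


def simulate_edge_matrix(rng, n_edges=30, n1=10, n2=10, diff_edges=0, effect=1.0):
    labels, ids = make_labels(n1, n2)
    vals = rng.normal(scale=rng.uniform(0.5, 2.0, size=n_edges)[:, None],
                      size=(n_edges, n1 + n2))
    vals[:diff_edges, n1:] += effect
    m = pd.DataFrame(vals, index=[f"gA{k}|gB{k}" for k in range(n_edges)], columns=ids)
    return m, labels


class TestModeratedT:
    def test_no_squeeze_equals_ordinary_two_sample_t(self, rng):
        m, labels = simulate_edge_matrix(rng)
        table = moderated_t_stats(m, labels, prior_df=0)
        for eid in m.index:
            a = m.loc[eid, [f"s{i}" for i in range(10)]]
            b = m.loc[eid, [f"s{i}" for i in range(10, 20)]]
            t_ref = stats.ttest_ind(b, a, equal_var=True)
            assert table.loc[eid, "t"] == pytest.approx(t_ref.statistic, abs=1e-10)
            assert table.loc[eid, "p_value"] == pytest.approx(t_ref.pvalue, abs=1e-10)

    def test_equal_residual_variances_are_squeeze_fixed_point(self, rng):
        # identical residual patterns per edge -> log-variances have zero spread
        base = rng.normal(size=20)
        labels, ids = make_labels(10, 10)
        rows = [base + k for k in range(8)]  # shifted copies: same variance
        m = pd.DataFrame(rows, index=[f"e{k}|f{k}" for k in range(8)], columns=ids)
        table = moderated_t_stats(m, labels)
        # posterior variances identical across edges, close to the common s2
        s2 = np.var(base[:10], ddof=1) * 9 / 18 + np.var(base[10:], ddof=1) * 9 / 18
        tvals = np.abs(table["t"].to_numpy())
        betas = np.abs(table["coef"].to_numpy())
        ratio = betas / tvals
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)
        post_var = (ratio[0] ** 2) / (1 / 10 + 1 / 10)
        assert post_var == pytest.approx(s2, rel=0.12)

    def test_beta_s2_and_prior_match_bruteforce(self, rng):
        m, labels = simulate_edge_matrix(rng)
        table = moderated_t_stats(m, labels)
        g1 = [f"s{i}" for i in range(10)]
        g2 = [f"s{i}" for i in range(10, 20)]
        s2_list = []
        for eid in m.index:
            a, b = m.loc[eid, g1].to_numpy(), m.loc[eid, g2].to_numpy()
            beta = b.mean() - a.mean()
            s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 18
            s2_list.append(s2)
            assert table.loc[eid, "coef"] == pytest.approx(beta, abs=1e-12)
        # independent moment solve for the prior
        z = np.log(np.array(s2_list))
        excess = z.var(ddof=1) - special.polygamma(1, 9.0)
        assert excess > 0
        d0_ref = 2.0 * brentq(
            lambda x: special.polygamma(1, x) - excess, 1e-6, 1e8
        )
        s0_ref = np.exp(
            z.mean() - special.polygamma(0, 9.0)
            + special.polygamma(0, d0_ref / 2) - np.log(d0_ref / 18.0)
        )
        d0, s0 = table.attrs["prior_df"], table.attrs["prior_var"]
        assert d0 == pytest.approx(d0_ref, rel=1e-6)
        assert s0 == pytest.approx(s0_ref, rel=1e-6)
        # posterior variance formula reproduces the reported t
        for eid, s2 in zip(m.index, s2_list):
            post = (d0 * s0 + 18 * s2) / (d0 + 18)
            t_ref = table.loc[eid, "coef"] / np.sqrt(post * (0.2))
            assert table.loc[eid, "t"] == pytest.approx(t_ref, abs=1e-10)

    def test_bh_adjustment_monotone(self, rng):
        m, labels = simulate_edge_matrix(rng, diff_edges=5, effect=2.0)
        table = moderated_t_stats(m, labels).sort_values("p_value")
        adj = table["adj_p_value"].to_numpy()
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= table["p_value"].to_numpy() - 1e-12).all()

    def test_differential_edges_rank_first(self, rng):
        m, labels = simulate_edge_matrix(rng, diff_edges=5, effect=3.0)
        table = moderated_t_stats(m, labels)
        top5 = set(table.index[:5])
        assert len(top5 & {f"gA{k}|gB{k}" for k in range(5)}) >= 4

    def test_small_group_rejected(self, rng):
        m, labels = simulate_edge_matrix(rng, n1=1, n2=19)
        with pytest.raises(ValidationError, match=">= 2"):
            moderated_t_stats(m, labels)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma_reference(self, rng, tmp_path):
        """Cross-check moderated t against the empirical-Bayes reference in R."""
        m, labels = simulate_edge_matrix(rng, n_edges=40)
        m.to_csv(tmp_path / "m.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("%s", row.names
            = 1, check.names = FALSE))
            group <- factor(c(rep("a", 10), rep("b", 10)), levels = c("a", "b"))
            design <- model.matrix(~group)
            fit <- eBayes(lmFit(m, design))
            out <- topTable(fit, coef = 2, number = Inf, sort.by = "none")
            write.table(data.frame(id = rownames(out), t = out$t, p = out$P.Value),
                        "%s", sep = "\t", row.names = FALSE, quote = FALSE)
            cat(fit$df.prior, fit$s2.prior, sep = "\n")
            """ % (tmp_path / "m.tsv", tmp_path / "out.tsv")
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        d0_ref, s0_ref = (float(x) for x in res.stdout.split())
        table = moderated_t_stats(m, labels)
        assert table.attrs["prior_df"] == pytest.approx(d0_ref, rel=1e-3)
        assert table.attrs["prior_var"] == pytest.approx(s0_ref, rel=1e-3)
        for eid in m.index:
            assert table.loc[eid, "t"] == pytest.approx(ref.loc[eid, "t"], rel=1e-4)
            assert table.loc[eid, "p_value"] == pytest.approx(ref.loc[eid, "p"], rel=1e-3)


class TestVariancePrior:
    def test_zero_excess_gives_infinite_prior_df(self):
        d0, s0 = estimate_variance_prior(np.full(10, 2.0), df=10)
        assert np.isinf(d0)
        assert s0 > 0


class TestTopEdgesNetwork:
    @staticmethod
    def _stats_table(rng, n=20):
        return pd.DataFrame(
            {
                "coef": rng.normal(size=n),
                "t": rng.normal(scale=3, size=n),
            },
            index=[f"g{k}|g{k + 1}" for k in range(n)],
        ).sort_values("t", key=lambda s: -s.abs())

    def test_too_few_edges_rejected(self, rng):
        with pytest.raises(ValidationError, match="available"):
            top_edges_network(self._stats_table(rng, 5), n=10)

    def test_single_sign_class_when_all_positive(self, rng):
        table = self._stats_table(rng)
        table["coef"] = np.abs(table["coef"])
        g = top_edges_network(table, n=10)
        assert {d["sign"] for _, _, d in g.edges(data=True)} == {"up"}

    def test_node_t_masked_below_threshold(self, rng):
        table = self._stats_table(rng, 4)
        node_stats = pd.DataFrame({"t": [0.5, 2.5]}, index=["g0", "g1"])
        g = top_edges_network(table, n=4, node_stats=node_stats, node_t_threshold=1.5)
        assert g.nodes["g0"]["t"] == 0.0
        assert g.nodes["g1"]["t"] == 2.5

    def test_planted_block_dominates_top_edges(self, rng):
        labels, ids = make_labels(15, 15)
        block = [f"b{i}|b{j}" for i in range(5) for j in range(i + 1, 5)]
        noise = [f"n{k}|m{k}" for k in range(40)]
        vals = rng.normal(size=(len(block) + len(noise), 30))
        vals[: len(block), 15:] += 2.0
        m = pd.DataFrame(vals, index=block + noise, columns=ids)
        table = moderated_t_stats(m, labels)
        top10 = table.index[:10]
        assert sum(e in set(block) for e in top10) >= 8


class TestLargestComponent:
    def test_chain_beats_isolated_edge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        assert largest_component(g) == ["a", "b", "c"]

    def test_fully_connected_returns_all(self):
        g = nx.complete_graph(["x", "y", "z"])
        assert largest_component(g) == ["x", "y", "z"]

    def test_matches_union_find_oracle(self, rng):
        nodes = [f"n{k}" for k in range(30)]
        edges = [
            tuple(rng.choice(nodes, size=2, replace=False)) for _ in range(25)
        ]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        comps = union_find_components(nodes, edges)
        comps.sort(key=lambda c: (-len(c), c[0]))
        assert largest_component(g) == comps[0]


class TestGSEA:
    @staticmethod
    def _ranking(rng, n=20):
        vals = np.sort(rng.normal(scale=2, size=n))[::-1]
        return pd.Series(vals, index=[f"g{k:02d}" for k in range(n)])

    def test_small_overlap_dropped(self, rng):
        ranked = self._ranking(rng)
        sets = {"tiny": ["g00", "g01"], "ok": [f"g{k:02d}" for k in range(12)]}
        table = gsea_preranked(ranked, sets, min_size=10, n_perm=200, seed=0)
        assert "tiny" not in table.index and "ok" in table.index

    def test_single_top_gene_analytic_es(self, rng):
        ranked = self._ranking(rng)
        table = gsea_preranked(
            ranked, {"top": [ranked.index[0]]}, min_size=1, n_perm=200, seed=0
        )
        # running sum peaks right after the first gene: ES = 1 (full hit mass)
        assert table.loc["top", "es"] == pytest.approx(1.0)
        oracle = running_sum_es_oracle(ranked, [ranked.index[0]])
        assert table.loc["top", "es"] == pytest.approx(oracle, abs=1e-12)

    def test_es_matches_running_sum_oracle(self, rng):
        ranked = self._ranking(rng)
        sets = {
            "head": [f"g{k:02d}" for k in range(0, 12)],
            "tail": [f"g{k:02d}" for k in range(8, 20)],
            "spread": [f"g{k:02d}" for k in range(0, 20, 2)],
        }
        table = gsea_preranked(ranked, sets, min_size=10, n_perm=500, seed=0)
        for name, members in sets.items():
            oracle = running_sum_es_oracle(ranked, members)
            assert table.loc[name, "es"] == pytest.approx(oracle, abs=1e-12)

    def test_pvalues_stable_across_seeds(self, rng):
        ranked = self._ranking(rng)
        sets = {"head": [f"g{k:02d}" for k in range(0, 12)]}
        p = [
            gsea_preranked(ranked, sets, min_size=10, n_perm=500, seed=s)
            .loc["head", "p_value"]
            for s in (1, 2)
        ]
        se = np.sqrt(max(p[0], 1 / 500) * (1 - min(p[0], 1 - 1 / 500)) / 500)
        assert abs(p[0] - p[1]) <= 3 * se + 2 / 500

    def test_reversed_ranking_flips_es_sign(self, rng):
        ranked = self._ranking(rng)
        sets = {"head": [f"g{k:02d}" for k in range(0, 12)]}
        fwd = gsea_preranked(ranked, sets, min_size=10, n_perm=200, seed=0)
        rev = gsea_preranked(-ranked, sets, min_size=10, n_perm=200, seed=0)
        assert np.sign(fwd.loc["head", "es"]) == -np.sign(rev.loc["head", "es"])

    def test_es_scale_invariant_in_statistic(self, rng):
        ranked = self._ranking(rng)
        sets = {"head": [f"g{k:02d}" for k in range(0, 12)]}
        a = gsea_preranked(ranked, sets, min_size=10, n_perm=200, seed=0)
        b = gsea_preranked(ranked * 3.5, sets, min_size=10, n_perm=200, seed=0)
        assert a.loc["head", "es"] == pytest.approx(b.loc["head", "es"], abs=1e-12)

    def test_empty_ranking_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            gsea_preranked(pd.Series(dtype=float), {"s": ["g"]}, n_perm=200)

    def test_fgsea_like_qvalues_bounded(self, rng):
        ranked = self._ranking(rng)
        sets = {
            "head": [f"g{k:02d}" for k in range(0, 12)],
            "spread": [f"g{k:02d}" for k in range(0, 20, 2)],
        }
        table = gsea_preranked(ranked, sets, min_size=10, n_perm=300, seed=0)
        assert ((table["fdr_q"] >= 0) & (table["fdr_q"] <= 1)).all()
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()
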