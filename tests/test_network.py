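import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from modoc.network import (
    ModulePartition,
    SparseNetwork,
    build_network,
    detect_modules,
    module_expression_summary,
    modularity,
    select_informative_genes,
)
from modoc.synthetic import SyntheticConfig, simulate_expression

from _oracles import naive_topk_edges, newman_modularity
from conftest import make_expression


class TestInformativeGenes:
    def test_fraction_one_keeps_all(self, synth_expression):
        em, _ = synth_expression
        assert set(select_informative_genes(em, fraction=1.0)) == set(em.gene_ids)

    def test_constant_gene_ranks_last(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 8))
        vals[2] = 1.0  # constant
        em = make_expression(vals, [f"g{i}" for i in range(5)], ["D0", "D3"], 4)
        assert "g2" not in select_informative_genes(em, fraction=0.5)

    def test_planted_genes_survive_default_selection(self, synth_expression):
        """At the default amplitude, >=95% of planted-module genes sit in the
        top half of the variance ranking."""
        em, truth = synth_expression
        selected = set(select_informative_genes(em, fraction=0.5))
        planted = set(truth.assignment.index)
        assert len(planted & selected) / len(planted) >= 0.95

    def test_invalid_fraction_rejected(self, synth_expression):
        em, _ = synth_expression
        with pytest.raises(ValueError):
            select_informative_genes(em, fraction=0.0)


class TestBuildNetwork:
    def test_perfectly_correlated_quartet_is_complete_graph(self):
        base = np.arange(8.0)
        vals = np.stack([base + i for i in range(4)])
        em = make_expression(vals, list("abcd"), ["D0", "D3"], 4)
        net = build_network(em, retained_per_gene=3)
        assert len(net.edges) == 6  # complete graph on 4 nodes
        assert np.allclose(net.edges["weight"], 1.0)

    def test_matches_naive_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(20, 12))
        genes = [f"g{i:02d}" for i in range(20)]
        em = make_expression(vals, genes, ["D0", "D3", "D5"], 4)
        net = build_network(em, retained_per_gene=3)
        got = {tuple(sorted(e)) for e in zip(net.edges["gene_a"], net.edges["gene_b"])}
        want, rho = naive_topk_edges(vals, genes, k=3)
        assert got == want
        # weights are the Spearman correlations
        for _, row in net.edges.iterrows():
            i, j = genes.index(row["gene_a"]), genes.index(row["gene_b"])
            assert row["weight"] == pytest.approx(rho[i, j], abs=1e-9)

    def test_anticorrelated_partners_never_retained_with_positive_options(self):
        # two mutually anti-correlated quartets: every gene has 3 perfect
        # positive partners, so no rho=-1 cross edge may survive
        base = np.arange(8.0)
        vals = np.stack([base + i for i in range(4)] + [-base + i for i in range(4)])
        genes = list("abcd") + list("wxyz")
        em = make_expression(vals, genes, ["D0", "D3"], 4)
        net = build_network(em, retained_per_gene=3)
        for _, row in net.edges.iterrows():
            same_group = (row["gene_a"] in "abcd") == (row["gene_b"] in "abcd")
            assert same_group
            assert row["weight"] == pytest.approx(1.0)

    def test_zero_variance_gene_excluded(self):
        vals = np.vstack([np.arange(8.0), np.arange(8.0) * 2, np.ones(8), np.arange(8.0) ** 2])
        em = make_expression(vals, list("abcd"), ["D0", "D3"], 4)
        net = build_network(em)
        assert "c" not in net.nodes


def two_clique_network() -> SparseNetwork:
    edges = []
    for clique in (list("abcd"), list("wxyz")):
        for i, u in enumerate(clique):
            for v in clique[i + 1 :]:
                edges.append((u, v, 1.0))
    return SparseNetwork(
        nodes=list("abcdwxyz"),
        edges=pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"]),
    )


class TestDetectModules:
    def test_two_disconnected_cliques(self):
        part = detect_modules(two_clique_network(), n_iterations=10, seed=0)
        assert len(part.module_ids) == 2
        assert part.stability.eq(1.0).all()
        groups = {m: set(part.genes_in(m)) for m in part.module_ids}
        assert set(map(frozenset, groups.values())) == {
            frozenset("abcd"),
            frozenset("wxyz"),
        }

    def test_same_seed_identical_partition(self):
        net = two_clique_network()
        a = detect_modules(net, n_iterations=5, seed=3)
        b = detect_modules(net, n_iterations=5, seed=3)
        pd.testing.assert_series_equal(a.assignment, b.assignment)
        assert a.best_modularity == b.best_modularity

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            detect_modules(two_clique_network(), n_iterations=0)

    def test_reported_q_equals_recomputed_newman_modularity(self, pipeline_result):
        net = pipeline_result["network"]
        part = pipeline_result["partition"]
        membership = part.assignment.to_dict()
        edges = list(zip(net.edges["gene_a"], net.edges["gene_b"]))
        weights = np.clip(net.edges["weight"].to_numpy(), 0, None)
        q = newman_modularity(edges, weights, membership)
        assert part.best_modularity == pytest.approx(q, abs=1e-9)
        assert part.best_modularity == pytest.approx(
            modularity(net, part.assignment), abs=1e-9
        )

    def test_recovery_degrades_as_noise_doubles(self):
        """Mean recovery ARI over 5 seeds is non-increasing as noise doubles."""
        means = []
        for noise in (0.5, 1.0, 2.0):
            aris = []
            for seed in range(5):
                cfg = SyntheticConfig(
                    n_genes=400, n_modules=4, module_sizes=(60,) * 4,
                    noise_sd=noise, rng_seed=seed,
                )
                em, truth = simulate_expression(cfg)
                genes = select_informative_genes(em, fraction=0.7)
                net = build_network(em.subset_genes(genes))
                part = detect_modules(net, n_iterations=10, seed=seed)
                common = [g for g in net.nodes if g in truth.assignment.index]
                aris.append(
                    adjusted_rand_score(
                        truth.assignment[common], part.assignment[common]
                    )
                )
            means.append(np.mean(aris))
        assert means[0] >= means[1] >= means[2]


class TestModuleSummary:
    def test_identical_genes_summary_equals_member_profile(self):
        vals = np.stack([np.arange(8.0)] * 3)
        em = make_expression(vals, list("abc"), ["D0", "D3", "D5", "D6"], 2)
        part = ModulePartition(
            assignment=pd.Series(1, index=list("abc")),
            stability=pd.Series(1.0, index=list("abc")),
        )
        summary, z = module_expression_summary(part, em)
        member = z.loc["a"]
        for tp in em.time_points:
            samples = em.sample_meta.index[em.sample_meta["time_point"] == tp]
            assert summary.loc[1, tp] == pytest.approx(np.median(member[samples]))

    def test_constant_gene_excluded_from_z(self):
        vals = np.vstack([np.arange(8.0), np.full(8, 2.0)])
        em = make_expression(vals, list("ab"), ["D0", "D3"], 4)
        part = ModulePartition(
            assignment=pd.Series(1, index=list("ab")),
            stability=pd.Series(1.0, index=list("ab")),
        )
        _, z = module_expression_summary(part, em)
        assert "b" not in z.index

    def test_planted_late_on_module_peaks_at_final_time_point(self, pipeline_result):
        truth = pipeline_result["truth"]
        part = pipeline_result["partition"]
        summary = pipeline_result["module_summary"]
        late_truth = truth.module_meta.index[
            truth.module_meta["kinetic_class"] == "late-on"
        ]
        for tm in late_truth:
            genes = set(truth.genes_in(tm))
            best = max(
                part.module_ids, key=lambda m: len(genes & set(part.genes_in(m)))
            )
            profile = summary.loc[best]
            assert profile.idxmax() == profile.index[-1]
            assert part.module_meta.loc[best, "kinetic_class"] == "late-on"
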