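"""Variation-graph construction, haplotype walks and topology statistics."""

import itertools

import numpy as np
import pytest

from augref.coords import apply_alleles
from augref.graphbuild import (
    build_graph,
    embed_haplotypes,
    graph_stats,
    select_variants,
)
from augref.synthpop import (
    ReferenceSequence,
    Variant,
    VariantPanel,
    generate_reference,
    simulate_population,
)


def enumerate_kmer_paths(graph, k):
    """Oracle: enumerate all k-length sequence paths by exhaustive walk."""
    paths = set()

    def extend(chain, need):
        node = chain[-1]
        if need <= 0:
            paths.add(tuple(chain))
            return
        for s in graph.successors(node):
            extend(chain + [s], need - len(graph.nodes[s]))

    for n, seq in graph.nodes.items():
        for off in range(len(seq)):
            for s_chain in [[n]]:
                remaining = k - (len(seq) - off)
                # tag start offset so identical chains from different
                # offsets stay distinct
                before = len(paths)
                collect = set()

                def rec(chain, need):
                    if need <= 0:
                        collect.add((off, tuple(chain)))
                        return
                    for s in graph.successors(chain[-1]):
                        rec(chain + [s], need - len(graph.nodes[s]))

                rec([n], remaining)
                paths |= collect
    return paths


class TestBuildGraph:
    def test_linear_single_node(self, toy_ref):
        g = build_graph(toy_ref, [], max_node_len=32)
        assert g.n_nodes == 1 and g.n_edges == 0
        assert g.spell(g.backbone) == toy_ref.sequence

    def test_snp_bubble(self, toy_ref):
        g = build_graph(toy_ref, [Variant("t", 3, "T", "G")], max_node_len=32)
        assert sorted(g.nodes.values()) == ["ACG", "ACGT", "G", "T"]
        assert g.n_nodes == 4 and g.n_edges == 4

    def test_deletion_bypass(self, toy_ref):
        g = build_graph(toy_ref, [Variant("t", 2, "GTA", "G")], max_node_len=32)
        assert sorted(g.nodes.values()) == ["ACG", "CGT", "TA"]
        assert g.n_nodes == 3 and g.n_edges == 3

    def test_insertion_node(self, toy_ref):
        g = build_graph(toy_ref, [Variant("t", 3, "T", "TAA")], max_node_len=32)
        assert "AA" in g.nodes.values()
        # backbone split at offset 4: ACGT | ACGT plus insertion node
        assert g.n_nodes == 3 and g.n_edges == 3

    def test_backbone_spelling_invariant(self, small_ref):
        panel = simulate_population(small_ref, [("A", 5)], 200, seed=3)
        g = build_graph(small_ref, panel.variants)
        assert g.spell(g.backbone) == small_ref.sequence

    def test_chunking_respects_max_node_len(self, small_ref):
        g = build_graph(small_ref, [], max_node_len=32)
        lens = [len(s) for s in g.nodes.values()]
        assert max(lens) < 64  # remainder merged into the final chunk
        assert g.n_edges == g.n_nodes - 1
        assert graph_stats(g).edge_node_ratio < 1

    def test_monotonicity_in_variant_count(self, small_ref):
        panel = simulate_population(small_ref, [("A", 8)], 150, seed=4)
        g0 = build_graph(small_ref, [])
        prev_nodes, prev_edges = g0.n_nodes, g0.n_edges
        for n in (30, 80, 150):
            g = build_graph(small_ref, panel.variants[:n])
            assert g.n_nodes >= prev_nodes and g.n_edges >= prev_edges
            assert (g.n_edges - prev_edges) >= (g.n_nodes - prev_nodes)
            prev_nodes, prev_edges = g.n_nodes, g.n_edges
        assert graph_stats(g).edge_node_ratio > 1.0

    def test_dag_invariant(self, small_ref):
        panel = simulate_population(small_ref, [("A", 5)], 100, seed=6)
        g = build_graph(small_ref, panel.variants)
        order = {n: i for i, n in enumerate(g.topo_order())}
        assert all(order[u] < order[v] for u, v in g.edges)

    def test_overlapping_variants_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            build_graph(
                toy_ref,
                [Variant("t", 2, "GTA", "G"), Variant("t", 3, "T", "A")],
            )

    def test_out_of_range_rejected(self, toy_ref):
        with pytest.raises(ValueError):
            build_graph(toy_ref, [Variant("t", 7, "TA", "T")])


class TestSelectVariants:
    @pytest.fixture()
    def panel(self, small_ref):
        return simulate_population(
            small_ref, [("A", 10), ("B", 10), ("C", 10)], 300, seed=11
        )

    def test_threshold_is_strict(self, small_ref):
        variants = [Variant("chrS", p, "A", "T") for p in (10, 20, 30)]
        H = np.zeros((20, 3), dtype=np.int8)
        H[:1, 0] = 1   # AF 0.05... build explicit AFs 0.04/0.05/0.06 needs 100 haps
        panel = simulate_population(small_ref, [("A", 50)], 0, seed=0)
        H = np.zeros((100, 3), dtype=np.int8)
        H[:4, 0] = 1
        H[:5, 1] = 1
        H[:6, 2] = 1
        panel = VariantPanel(
            variants, [(f"s{i}", "A") for i in range(50)], H, ref_length=1000
        )
        vs = select_variants(panel, "threshold", pop="A", threshold=0.05)
        assert [v.pos for v in vs.variants] == [30]  # only AF 0.06 passes

    def test_threshold_one_empty(self, panel):
        assert len(select_variants(panel, "threshold", pop="A", threshold=1.0)) == 0

    def test_count_matched_minimum(self, panel):
        counts = {
            p: int((panel.af(p) > 0.1).sum()) for p in panel.populations
        }
        m = min(counts.values())
        for target in panel.populations:
            order = [target] + [p for p in panel.populations if p != target]
            vs = select_variants(panel, "count_matched", pop=order, threshold=0.1,
                                 seed=3)
            assert len(vs) == m
            assert (panel.af(target)[vs.indices] > 0.1).all()

    def test_personalized_subset_of_threshold_zero(self, panel):
        sid, pop = panel.samples[0]
        pers = select_variants(panel, "personalized", sample=sid)
        thr0 = select_variants(panel, "threshold", pop=pop, threshold=0.0)
        assert set(pers.indices) <= set(thr0.indices)

    def test_exclude_samples_drops_private_alleles(self, panel):
        sid = panel.samples[0][0]
        vs_all = select_variants(panel, "threshold", pop="A", threshold=0.0)
        vs_excl = select_variants(
            panel, "threshold", pop="A", threshold=0.0, exclude_samples=[sid]
        )
        dropped = set(vs_all.indices) - set(vs_excl.indices)
        others = np.delete(np.arange(panel.haplotypes.shape[0]), [0, 1])
        for j in dropped:
            assert panel.haplotypes[others, j].sum() == 0

    def test_random_pool_size_and_errors(self, panel):
        vs = select_variants(panel, "random_pool", n_target=50, seed=1)
        assert len(vs) == 50
        with pytest.raises(ValueError):
            select_variants(panel, "random_pool", n_target=panel.n_variants + 1)

    def test_pan_uses_pooled_frequency(self, panel):
        vs = select_variants(panel, "pan", threshold=0.2)
        assert (panel.af(None)[vs.indices] > 0.2).all()


class TestHaplotypeWalks:
    def test_reference_haplotype_walks_backbone(self, tiny_panel):
        ref, panel = tiny_panel
        g = build_graph(ref, panel.variants)
        hi = embed_haplotypes(g, panel, ["s2"])
        assert hi.walks[("s2", 2)] == g.backbone  # all-reference haplotype

    def test_snp_walk(self, toy_ref):
        v = Variant("t", 3, "T", "G")
        g = build_graph(toy_ref, [v])
        panel = VariantPanel(
            [v], [("s1", "A")], np.array([[1], [0]], np.int8), ref_length=8
        )
        hi = embed_haplotypes(g, panel, ["s1"])
        assert [g.nodes[n] for n in hi.walks[("s1", 1)]] == ["ACG", "G", "ACGT"]
        assert [g.nodes[n] for n in hi.walks[("s1", 2)]] == ["ACG", "T", "ACGT"]

    def test_walk_spelling_matches_applied_alleles(self, small_ref):
        panel = simulate_population(
            small_ref, [("A", 4)], 20, indel_fraction=0.4, seed=13
        )
        g = build_graph(small_ref, panel.variants)
        hi = embed_haplotypes(g, panel)
        for (sid, hap), walk in hi.walks.items():
            ind = panel.sample_haplotype(sid, hap)
            carried = [panel.variants[j] for j in np.nonzero(ind)[0]]
            expected, _ = apply_alleles(small_ref, carried)
            assert g.spell(walk) == expected

    def test_absent_variants_fall_back_to_reference(self, small_ref):
        panel = simulate_population(small_ref, [("A", 4)], 30, seed=14)
        g = build_graph(small_ref, panel.variants[:10])  # partial graph
        hi = embed_haplotypes(g, panel)
        in_graph = set(panel.variants[:10])
        for (sid, hap), walk in hi.walks.items():
            ind = panel.sample_haplotype(sid, hap)
            carried = [
                panel.variants[j]
                for j in np.nonzero(ind)[0]
                if panel.variants[j] in in_graph
            ]
            expected, _ = apply_alleles(small_ref, carried)
            assert g.spell(walk) == expected


class TestGraphStats:
    def test_toy_counts_and_ratio(self, toy_ref):
        g = build_graph(toy_ref, [Variant("t", 3, "T", "G")])
        st = graph_stats(g)
        assert (st.n_nodes, st.n_edges) == (4, 4)
        assert st.edge_node_ratio == 1.0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_kmer_paths_vs_exhaustive_enumeration(self, toy_ref, k):
        variants = [Variant("t", 3, "T", "G"), Variant("t", 5, "C", "A")]
        g = build_graph(toy_ref, variants, max_node_len=4)
        st = graph_stats(g, k=k, cap=100_000)
        assert st.kmer_paths == len(enumerate_kmer_paths(g, k))
        assert not st.capped

    def test_restricted_kmers_match_haplotype_string(self, toy_ref):
        v = Variant("t", 3, "T", "G")
        g = build_graph(toy_ref, [v])
        panel = VariantPanel(
            [v], [("s1", "A")], np.array([[1], [1]], np.int8), ref_length=8
        )
        hi = embed_haplotypes(g, panel, ["s1"])
        st = graph_stats(g, hapindex=hi, k=3)
        # both walks spell ACGGACGT: 6 distinct 3-mer windows
        assert st.kmer_paths == len("ACGGACGT") - 3 + 1

    def test_cap_flags(self, small_ref):
        panel = simulate_population(small_ref, [("A", 4)], 50, seed=2)
        g = build_graph(small_ref, panel.variants)
        st = graph_stats(g, k=5, cap=100)
        assert st.capped and st.kmer_paths == 100
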