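"""Homology edges, single-linkage groups and synteny-based copy labels."""
import numpy as np
import pytest

from _oracles import brute_force_shared_coding_bases, union_find_components
from phylocons.alignment_io import MafBlock, MafRow
from phylocons.orthology import (GeneModel, HomologousGroup, HomologyEdge,
                                 assign_ancestral_copies, assign_ranks,
                                 classify_orthology, cluster_groups,
                                 pairwise_gene_homology, read_gene_table,
                                 write_gene_table)


def block(rows):
    return MafBlock(rows=[MafRow(*r) for r in rows])


class TestPairwiseHomology:
    def test_fully_aligned_cds_single_edge(self):
        genes = [GeneModel("gA", "sp1", "c1", "+", ((100, 400),)),
                 GeneModel("gB", "sp2", "c1", "+", ((100, 400),))]
        b = block([("sp1.c1", 100, 300, "+", 1000, "A" * 300),
                   ("sp2.c1", 100, 300, "+", 1000, "C" * 300)])
        edges = pairwise_gene_homology([b], genes)
        assert len(edges) == 1
        assert edges[0].weight == 300

    def test_intron_only_overlap_gives_no_edge(self):
        genes = [GeneModel("gA", "sp1", "c1", "+", ((0, 50),)),
                 GeneModel("gB", "sp2", "c1", "+", ((500, 550),))]
        b = block([("sp1.c1", 100, 50, "+", 1000, "A" * 50),
                   ("sp2.c1", 100, 50, "+", 1000, "C" * 50)])
        assert pairwise_gene_homology([b], genes) == []

    def test_same_genome_rows_never_linked(self):
        genes = [GeneModel("gA", "sp1", "c1", "+", ((0, 50),)),
                 GeneModel("gB", "sp1", "c2", "+", ((0, 50),))]
        b = block([("sp1.c1", 0, 50, "+", 100, "A" * 50),
                   ("sp1.c2", 0, 50, "+", 100, "C" * 50)])
        assert pairwise_gene_homology([b], genes) == []

    def test_weights_match_base_walk_oracle(self, rng):
        """Edge weights equal an independent per-base intersection count on
        a 3-genome fixture with gaps and a negative-strand row."""
        genes = [
            GeneModel("a1", "sp1", "c1", "+", ((2, 8), (12, 20))),
            GeneModel("b1", "sp2", "c1", "+", ((0, 10),)),
            GeneModel("c1g", "sp3", "c1", "-", ((30, 38),)),
        ]
        b1 = block([
            ("sp1.c1", 0, 14, "+", 50, "ACGTACGTAC--GTAC"),
            ("sp2.c1", 0, 16, "+", 50, "ACGTACGTACGTACGT"),
            ("sp3.c1", 10, 16, "-", 50, "ACGTACGTACGTACGT"),
        ])
        got = {tuple(sorted((e.gene_a, e.gene_b))): e.weight
               for e in pairwise_gene_homology([b1], genes)}
        want = brute_force_shared_coding_bases([b1], genes)
        assert got == want


class TestClusterGroups:
    def make_genes(self, n):
        return [GeneModel(f"g{i}", f"sp{i}", "c1", "+", ((0, 10),))
                for i in range(n)]

    def test_no_edges_all_singletons(self):
        genes = self.make_genes(4)
        groups = cluster_groups([], genes)
        assert len(groups) == 4
        assert all(len(g.members) == 1 for g in groups)

    def test_chain_is_single_linkage(self):
        genes = self.make_genes(3)
        edges = [HomologyEdge("g0", "g1", 5), HomologyEdge("g1", "g2", 1)]
        groups = cluster_groups(edges, genes)
        assert len(groups) == 1 and len(groups[0].members) == 3

    def test_zero_weight_edges_dropped_by_default(self):
        genes = self.make_genes(2)
        groups = cluster_groups([HomologyEdge("g0", "g1", 0)], genes)
        assert len(groups) == 2

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 25))
            genes = self.make_genes(n)
            m = int(rng.integers(0, 2 * n))
            pairs = [(int(rng.integers(n)), int(rng.integers(n)))
                     for _ in range(m)]
            pairs = [(a, b) for a, b in pairs if a != b]
            edges = [HomologyEdge(f"g{a}", f"g{b}", 1) for a, b in pairs]
            groups = cluster_groups(edges, genes)
            got = {frozenset(int(g.gene_id[1:]) for g in grp.members)
                   for grp in groups}
            assert got == set(union_find_components(n, pairs))


class TestClassifyOrthology:
    def group(self, counts):
        members = []
        for genome, k in counts.items():
            for i in range(k):
                members.append(GeneModel(f"{genome}_{i}", genome, "c1", "+",
                                         ((i * 20, i * 20 + 10),)))
        return HomologousGroup(members)

    def test_relation_classes(self):
        rel = classify_orthology(self.group({"chicken": 1, "finch": 1}))
        assert rel[("chicken", "finch")] == "one2one"
        rel = classify_orthology(self.group({"chicken": 1, "finch": 2}))
        assert rel[("chicken", "finch")] == "one2many"
        rel = classify_orthology(self.group({"chicken": 2, "finch": 3}))
        assert rel[("chicken", "finch")] == "many2many"


def synteny_fixture(dup_context="away"):
    """Reference with genes r0..r6 in a row; one other genome with the same
    order plus a second copy of gene 3 either in context or elsewhere."""
    genes = []
    for i in range(7):
        genes.append(GeneModel(f"r{i}", "ref", "c1", "+",
                               ((i * 100, i * 100 + 60),)))
        genes.append(GeneModel(f"q{i}", "qry", "c1", "+",
                               ((i * 100, i * 100 + 60),)))
    dup_chrom = "c2" if dup_context == "away" else "c1"
    dup_start = 0 if dup_context == "away" else 320
    genes.append(GeneModel("q3b", "qry", dup_chrom, "+",
                           ((dup_start, dup_start + 60),)))
    genes = assign_ranks(genes)
    groups = []
    for i in range(7):
        members = [g for g in genes if g.gene_id in {f"r{i}", f"q{i}"}]
        if i == 3:
            members += [g for g in genes if g.gene_id == "q3b"]
        groups.append(HomologousGroup(sorted(members,
                                             key=lambda g: g.gene_id)))
    return genes, groups


class TestAssignAncestralCopies:
    def test_in_context_copy_is_ancestral(self):
        _, groups = synteny_fixture("away")
        assign_ancestral_copies(groups, "ref", window=3)
        labels = groups[3].labels
        assert labels["q3"] == "ancestral"
        assert labels["q3b"] == "novel"
        assert labels["r3"] == "ancestral"

    def test_zero_context_tie_unresolved(self):
        """Two copies that both share no flanking orthologues stay
        unresolved."""
        genes = [GeneModel("rX", "ref", "c9", "+", ((0, 60),)),
                 GeneModel("qX1", "qry", "c8", "+", ((0, 60),)),
                 GeneModel("qX2", "qry", "c7", "+", ((0, 60),))]
        genes = assign_ranks(genes)
        grp = HomologousGroup(genes)
        assign_ancestral_copies([grp], "ref")
        assert grp.labels["qX1"] == grp.labels["qX2"] == "unresolved"

    def test_duplicated_reference_unresolved(self):
        genes = assign_ranks([
            GeneModel("r1", "ref", "c1", "+", ((0, 60),)),
            GeneModel("r2", "ref", "c1", "+", ((100, 160),)),
            GeneModel("q1", "qry", "c1", "+", ((0, 60),))])
        grp = HomologousGroup(genes)
        assign_ancestral_copies([grp], "ref")
        assert set(grp.labels.values()) == {"unresolved"}

    def test_labels_match_window_enumeration(self, rng):
        """Synteny labels equal a brute-force window-match count on random
        gene orders."""
        for trial in range(10):
            n = 9
            order = rng.permutation(n)
            genes = [GeneModel(f"r{i}", "ref", "c1", "+",
                               ((i * 100, i * 100 + 50),)) for i in range(n)]
            genes += [GeneModel(f"q{i}", "qry", "c1", "+",
                                ((int(j) * 100, int(j) * 100 + 50),))
                      for j, i in enumerate(order)]
            dup_pos = n + int(rng.integers(0, 3))
            genes.append(GeneModel("q0b", "qry", "c1", "+",
                                   ((dup_pos * 100, dup_pos * 100 + 50),)))
            genes = assign_ranks(genes)
            groups = []
            for i in range(n):
                members = [g for g in genes
                           if g.gene_id in {f"r{i}", f"q{i}"}]
                if i == 0:
                    members += [g for g in genes if g.gene_id == "q0b"]
                groups.append(HomologousGroup(members))
            w = 2
            assign_ancestral_copies(groups, "ref", window=w)
            # oracle: count one2one flank matches per copy by explicit loops
            by_id = {g.gene_id: g for g in genes}
            ref_rank = by_id["r0"].rank
            ref_flank = {f"r{i}" for i in range(n)
                         if i != 0 and abs(by_id[f"r{i}"].rank - ref_rank) <= w}
            expected = {f"q{fid[1:]}" for fid in ref_flank}
            scores = {}
            for cid in ("q0", "q0b"):
                rank = by_id[cid].rank
                flank = {g.gene_id for g in genes
                         if g.genome == "qry" and g.gene_id != cid
                         and abs(g.rank - rank) <= w}
                scores[cid] = len(flank & expected)
            labels = groups[0].labels
            if scores["q0"] == scores["q0b"]:
                assert labels["q0"] == labels["q0b"] == "unresolved"
            else:
                best = max(scores, key=scores.get)
                other = "q0b" if best == "q0" else "q0"
                assert labels[best] == "ancestral"
                assert labels[other] == "novel"


class TestGeneTableIO:
    def test_round_trip(self, tmp_path):
        genes = assign_ranks([
            GeneModel("g1", "sp1", "c1", "+", ((0, 30), (50, 80))),
            GeneModel("g2", "sp1", "c1", "-", ((100, 130),))])
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        again = read_gene_table(path)
        assert {(g.gene_id, g.cds, g.strand, g.rank) for g in again} == \
            {(g.gene_id, g.cds, g.strand, g.rank) for g in genes}

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "sp", "c1", "+", ((0, 30), (20, 50)))
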