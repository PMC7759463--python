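"""Homologous groups from alignment overlap and synteny-based copy labels.

Two genes in different genomes are candidate homologues when their coding
regions share at least one aligned base in the whole-genome alignment; the
edge weight is the number of shared aligned coding bases.  Homologous
groups are the connected components of this graph (single-linkage, any
positive overlap).  Within a group, per-genome copy counts define the
pairwise relation (one-to-one, one-to-many, many-to-many), and for genomes
with several copies the copy that retains the reference's flanking-gene
context (synteny) is labeled the ancestral copy, the others novel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .alignment_io import MafBlock

LABEL_ANCESTRAL = "ancestral"
LABEL_NOVEL = "novel"
LABEL_UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered, disjoint CDS intervals (0-based half-open) and a
    rank index along its chromosome."""
    gene_id: str
    genome: str
    chrom: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    rank: int = -1

    def __post_init__(self):
        ivs = sorted(self.cds)
        if tuple(ivs) != tuple(self.cds):
            object.__setattr__(self, "cds", tuple(ivs))
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


def assign_ranks(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Recompute the per-genome, per-chromosome rank index by start coordinate."""
    genes = list(genes)
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.genome, g.chrom), []).append(g)
    out = []
    for key, members in by_key.items():
        for rank, g in enumerate(sorted(members, key=lambda g: g.start)):
            out.append(GeneModel(g.gene_id, g.genome, g.chrom, g.strand,
                                 g.cds, rank))
    return out


def read_gene_table(path) -> list[GeneModel]:
    """Read a TSV of gene_id, genome, chrom, strand, cds ("s-e;s-e")."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, genome, chrom, strand, cds = line.rstrip("\n").split("\t")[:5]
            ivs = tuple(tuple(map(int, p.split("-"))) for p in cds.split(";"))
            genes.append(GeneModel(gid, genome, chrom, strand, ivs))
    return assign_ranks(genes)


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.genome, g.chrom, g.rank)):
            cds = ";".join(f"{s}-{e}" for s, e in g.cds)
            fh.write(f"{g.gene_id}\t{g.genome}\t{g.chrom}\t{g.strand}\t{cds}\n")


@dataclass(frozen=True)
class HomologyEdge:
    """Undirected aligned-coding-base overlap between genes of two genomes."""
    gene_a: str
    gene_b: str
    weight: int


@dataclass
class HomologousGroup:
    members: list[GeneModel]
    relations: dict[tuple[str, str], str] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def copy_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g in self.members:
            counts[g.genome] = counts.get(g.genome, 0) + 1
        return counts

    def genes_of(self, genome: str) -> list[GeneModel]:
        return [g for g in self.members if g.genome == genome]


# ---------------------------------------------------------------------------
# Edge construction
# ---------------------------------------------------------------------------

class _CdsIndex:
    """Sorted-interval lookup position -> gene index per (genome, chrom)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        raw: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for gi, g in enumerate(self.genes):
            for s, e in g.cds:
                raw.setdefault((g.genome, g.chrom), []).append((s, e, gi))
        for key, ivs in raw.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            gidx = np.array([gi for _, _, gi in ivs], dtype=np.int64)
            self._tables[key] = (starts, ends, gidx)

    def lookup(self, genome: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Gene index at each position, -1 outside any CDS."""
        table = self._tables.get((genome, chrom))
        out = np.full(positions.shape, -1, dtype=np.int64)
        if table is None:
            return out
        starts, ends, gidx = table
        i = np.searchsorted(starts, positions, side="right") - 1
        valid = (i >= 0) & (positions >= 0)
        i = np.clip(i, 0, len(starts) - 1)
        valid &= positions < ends[i]
        out[valid] = gidx[i[valid]]
        return out


def pairwise_gene_homology(blocks: Iterable[MafBlock],
                           genes: Sequence[GeneModel]) -> list[HomologyEdge]:
    """Edges between genes of different genomes weighted by shared aligned
    coding bases.  Genes never touched by the alignment stay isolated."""
    index = _CdsIndex(genes)
    weights: dict[tuple[int, int], int] = {}
    genomes_with_genes = {g.genome for g in genes}
    for block in blocks:
        per_row = []
        for row in block.rows:
            if row.genome not in genomes_with_genes:
                continue
            pos = row.forward_positions()
            gi = index.lookup(row.genome, row.chrom, pos)
            if (gi >= 0).any():
                per_row.append((row.genome, gi))
        for i in range(len(per_row)):
            gen_i, gi = per_row[i]
            for j in range(i + 1, len(per_row)):
                gen_j, gj = per_row[j]
                if gen_i == gen_j:
                    continue
                both = (gi >= 0) & (gj >= 0)
                if not both.any():
                    continue
                pairs = gi[both] * (len(index.genes) + 1) + gj[both]
                uniq, counts = np.unique(pairs, return_counts=True)
                for key, cnt in zip(uniq, counts):
                    a, b = divmod(int(key), len(index.genes) + 1)
                    ka = (a, b) if a < b else (b, a)
                    weights[ka] = weights.get(ka, 0) + int(cnt)
    return [HomologyEdge(index.genes[a].gene_id, index.genes[b].gene_id, w)
            for (a, b), w in sorted(weights.items())]


# ---------------------------------------------------------------------------
# Clustering and classification
# ---------------------------------------------------------------------------

def cluster_groups(edges: Iterable[HomologyEdge], genes: Sequence[GeneModel],
                   min_weight: float = 0.0) -> list[HomologousGroup]:
    """Single-linkage groups: connected components keeping every edge with
    weight strictly above ``min_weight`` (default: any positive overlap).
    Every gene belongs to exactly one group; untouched genes are singletons.
    """
    graph = nx.Graph()
    by_id = {g.gene_id: g for g in genes}
    graph.add_nodes_from(by_id)
    for e in edges:
        if e.weight > min_weight:
            graph.add_edge(e.gene_a, e.gene_b)
    groups = []
    for comp in nx.connected_components(graph):
        members = sorted((by_id[g] for g in comp),
                         key=lambda g: (g.genome, g.chrom, g.start))
        groups.append(HomologousGroup(members))
    groups.sort(key=lambda grp: (grp.members[0].genome, grp.members[0].chrom,
                                 grp.members[0].start))
    return groups


def classify_orthology(group: HomologousGroup) -> dict[tuple[str, str], str]:
    """Relation class for every genome pair in the group: one2one,
    one2many or many2many by copy counts."""
    counts = group.copy_counts()
    genomes = sorted(counts)
    relations = {}
    for i, g1 in enumerate(genomes):
        for g2 in genomes[i + 1:]:
            c1, c2 = counts[g1], counts[g2]
            if c1 == 1 and c2 == 1:
                rel = "one2one"
            elif c1 == 1 or c2 == 1:
                rel = "one2many"
            else:
                rel = "many2many"
            relations[(g1, g2)] = rel
    group.relations = relations
    return relations


def _flank_ids(gene: GeneModel, ranked: Mapping[tuple[str, str], list[GeneModel]],
               window: int) -> set[str]:
    row = ranked[(gene.genome, gene.chrom)]
    lo = max(gene.rank - window, 0)
    return {g.gene_id for g in row[lo:gene.rank + window + 1]
            if g.gene_id != gene.gene_id}


def assign_ancestral_copies(groups: Sequence[HomologousGroup],
                            reference: str, window: int = 5
                            ) -> None:
    """Label ancestral vs novel copies by flanking-gene synteny.

    For every group in which the reference genome has exactly one copy,
    each other genome's copies are compared by how many of the reference
    copy's ``window`` flanking genes (each side) have their one-to-one
    orthologue next to the candidate copy.  The unique best copy is
    ancestral, the rest novel; ties (including all-zero) leave all copies
    unresolved.  Flanking matches are resolved only through one-to-one
    groups to avoid circularity.  Groups where the reference is absent or
    duplicated are left unresolved.
    """
    all_genes = [g for grp in groups for g in grp.members]
    ranked: dict[tuple[str, str], list[GeneModel]] = {}
    for g in all_genes:
        ranked.setdefault((g.genome, g.chrom), []).append(g)
    for row in ranked.values():
        row.sort(key=lambda g: g.rank)
    # one-to-one orthologue of a reference gene in each genome
    one2one: dict[tuple[str, str], str] = {}  # (ref gene, genome) -> gene id
    for grp in groups:
        counts = grp.copy_counts()
        if counts.get(reference, 0) != 1:
            continue
        ref_gene = grp.genes_of(reference)[0]
        for genome, cnt in counts.items():
            if genome != reference and cnt == 1:
                one2one[(ref_gene.gene_id, genome)] = \
                    grp.genes_of(genome)[0].gene_id
    for grp in groups:
        if not grp.relations:
            classify_orthology(grp)
        counts = grp.copy_counts()
        if counts.get(reference, 0) != 1:
            for g in grp.members:
                grp.labels[g.gene_id] = LABEL_UNRESOLVED
            continue
        ref_gene = grp.genes_of(reference)[0]
        grp.labels[ref_gene.gene_id] = LABEL_ANCESTRAL
        ref_flank = _flank_ids(ref_gene, ranked, window)
        for genome, cnt in counts.items():
            if genome == reference:
                continue
            copies = grp.genes_of(genome)
            if cnt == 1:
                grp.labels[copies[0].gene_id] = LABEL_ANCESTRAL
                continue
            expected = {one2one[(fid, genome)] for fid in ref_flank
                        if (fid, genome) in one2one}
            scores = [len(expected & _flank_ids(c, ranked, window))
                      for c in copies]
            best = max(scores)
            if scores.count(best) != 1:
                for c in copies:
                    grp.labels[c.gene_id] = LABEL_UNRESOLVED
            else:
                winner = copies[int(np.argmax(scores))]
                for c in copies:
                    grp.labels[c.gene_id] = (
                        LABEL_ANCESTRAL if c is winner else LABEL_NOVEL)


def write_group_table(groups: Sequence[HomologousGroup], path,
                      reference: str | None = None) -> None:
    """TSV: group id, gene id, genome, relation to reference, copy label."""
    with open(path, "w") as fh:
        fh.write("group\tgene_id\tgenome\trelation_to_ref\tlabel\n")
        for k, grp in enumerate(groups):
            for g in grp.members:
                rel = ""
                if reference and g.genome != reference:
                    key = tuple(sorted((reference, g.genome)))
                    rel = grp.relations.get(key, "")
                fh.write(f"HG{k:05d}\t{g.gene_id}\t{g.genome}\t{rel}\t"
                         f"{grp.labels.get(g.gene_id, '')}\n")
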