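"""Lineage-specific sequence detection against reconstructed ancestors.

A lineage-specific sequence is present in the genomes of a target clade
and in the reconstructed genome of the clade's most recent common ancestor
(MRCA), but aligns to nothing outside the clade.  The alignment must carry
reconstructed-ancestor rows whose "genome" names match internal node
labels of the guide tree; detection walks the alignment projected onto the
MRCA genome and reports maximal runs of MRCA positions at which every
aligned row belongs to the clade (its leaves or its internal ancestors,
the MRCA included).  Runs shorter than a minimum length are dropped to
suppress alignment-edge artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import GenomeAlignment, MafBlock
from .orthology import GeneModel
from .phylo_core import MISSING, PhyloTree
from .region_intersect import interval_length, intersect_intervals, merge_intervals

DEFAULT_MIN_LENGTH = 50


@dataclass
class LineageSpecificSegment:
    """A maximal clade-private run in MRCA coordinates."""
    chrom: str
    start: int
    end: int
    presence: dict[str, bool]  # clade leaf -> aligned anywhere in the run

    @property
    def length(self) -> int:
        return self.end - self.start


def clade_partition(tree: PhyloTree, clade_label: str
                    ) -> tuple[set[str], set[str], set[str]]:
    """Split genome names into (clade leaves, clade-internal ancestor
    labels including the MRCA, everything else in the tree)."""
    node = tree.index_of(clade_label)
    if tree.is_leaf(node):
        raise ValueError(f"{clade_label!r} is a leaf, not a clade node")
    leaves = set(tree.leaves_below(node))
    ancestors = set(tree.internal_labels_below(node))
    others = {lbl for lbl in tree.labels if lbl} - leaves - ancestors
    return leaves, ancestors, others


def find_lineage_specific_segments(blocks: Iterable[MafBlock], tree: PhyloTree,
                                   clade_label: str,
                                   min_length: int = DEFAULT_MIN_LENGTH
                                   ) -> list[LineageSpecificSegment]:
    """Segments of the clade MRCA genome unaligned outside the clade.

    The MRCA ancestor row is treated as the reference genome of the
    projection, so coordinates are MRCA coordinates.  Segment boundaries do
    not depend on how the alignment is cut into blocks.
    """
    leaves, ancestors, others = clade_partition(tree, clade_label)
    aln = GenomeAlignment.from_blocks(blocks, reference=clade_label)
    leaf_list = sorted(leaves)
    segments = []
    for chrom, (pos, X) in aln.chroms.items():
        present = X != MISSING
        gidx = {g: i for i, g in enumerate(aln.genomes)}
        outside_cols = [gidx[g] for g in aln.genomes if g in others]
        leaf_cols = [gidx[g] for g in leaf_list if g in gidx]
        clean = ~present[:, outside_cols].any(axis=1) if outside_cols else \
            np.ones(len(pos), dtype=bool)
        # maximal runs of consecutive MRCA positions that are clade-private
        for s, e in _runs(pos, clean):
            if e - s < min_length:
                continue
            sel = (pos >= s) & (pos < e)
            presence = {}
            for leaf, col in zip([g for g in leaf_list if g in gidx], leaf_cols):
                presence[leaf] = bool(present[sel, col].any())
            for leaf in leaves - set(presence):
                presence[leaf] = False
            segments.append(LineageSpecificSegment(chrom, int(s), int(e),
                                                   presence))
    segments.sort(key=lambda seg: (seg.chrom, seg.start))
    return segments


def _runs(pos: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive coordinates where mask holds."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    p = pos[idx]
    breaks = np.flatnonzero(np.diff(p) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(p) - 1]])
    return [(int(p[s]), int(p[e]) + 1) for s, e in zip(starts, ends)]


def lineage_specific_fraction(blocks: Iterable[MafBlock], mrca_label: str,
                              parent_label: str) -> float:
    """Fraction of the MRCA genome with no aligned base in its parent node.

    This is the newly-emerged-sequence fraction obtained by mapping a
    reconstructed MRCA genome back to its parent ancestor.
    """
    aln = GenomeAlignment.from_blocks(blocks, reference=mrca_label)
    total = unaligned = 0
    for chrom, (pos, X) in aln.chroms.items():
        total += len(pos)
        if parent_label in aln.genomes:
            col = aln.genomes.index(parent_label)
            unaligned += int((X[:, col] == MISSING).sum())
        else:
            unaligned += len(pos)
    if total == 0:
        raise ValueError(f"no alignment rows for MRCA {mrca_label!r}")
    return unaligned / total


def genome_to_mrca_intervals(blocks: Iterable[MafBlock], genome: str,
                             mrca_label: str) -> dict[str, np.ndarray]:
    """Intervals of ``genome`` coordinates aligned to the MRCA genome.

    Used to check whether a candidate gene's coding sequence is present in
    the reconstructed MRCA.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    for block in blocks:
        mrca_rows = [r for r in block.rows if r.genome == mrca_label]
        gen_rows = [r for r in block.rows if r.genome == genome]
        if not mrca_rows or not gen_rows:
            continue
        mpos = mrca_rows[0].forward_positions()
        for row in gen_rows:
            gpos = row.forward_positions()
            both = (mpos >= 0) & (gpos >= 0)
            for p in gpos[both]:
                raw.setdefault(row.chrom, []).append((int(p), int(p) + 1))
    return {c: merge_intervals(v) for c, v in raw.items()}


def filter_specific_genes(candidates: Sequence[GeneModel],
                          mrca_intervals: dict[str, np.ndarray],
                          min_overlap_aa: int = 20) -> list[GeneModel]:
    """Keep candidate lineage-specific genes anchored in the MRCA genome.

    A gene is retained when its CDS shares at least ``min_overlap_aa * 3``
    aligned coding bases with the reconstructed MRCA sequence; genes below
    the cutoff are presumed assembly or annotation artifacts and removed.
    """
    min_bases = 3 * min_overlap_aa
    kept = []
    for gene in candidates:
        mapped = mrca_intervals.get(gene.chrom)
        if mapped is None or not len(mapped):
            continue
        cds = np.array(gene.cds, dtype=np.int64).reshape(-1, 2)
        overlap = interval_length(intersect_intervals(cds, mapped))
        if overlap >= min_bases:
            kept.append(gene)
    return kept
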