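"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by a method deliberately
different from the implementation under test: exhaustive enumeration,
per-base set arithmetic, or plain python loops.
"""
import itertools

import numpy as np

from phylocons.phylo_core import MISSING, encode_base


def enum_column_loglik(tree, model, column, scale=1.0):
    """Exhaustive sum over all internal-node state assignments."""
    internals = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    P = {i: model.transition_matrix(tree.lengths[i] * scale)
         for i in range(tree.n_nodes)}
    total = 0.0
    for states in itertools.product(range(4), repeat=len(internals)):
        st = dict(zip(internals, states))
        prob = model.frequencies[st[tree.root]]
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            parent_state = st[tree.parent[i]]
            if tree.is_leaf(i):
                code = encode_base(column.get(tree.labels[i], "N"))
                prob *= 1.0 if code == MISSING else P[i][parent_state, code]
            else:
                prob *= P[i][parent_state, st[i]]
        total += prob
    return np.log(total)


def union_find_components(n_nodes, edges):
    """Connected components by union-find over integer node ids."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for i in range(n_nodes):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


def baseset(intervals):
    """Expand (chrom, start, end) intervals into a set of (chrom, pos)."""
    out = set()
    for chrom, s, e in intervals:
        for p in range(s, e):
            out.add((chrom, p))
    return out


def brute_force_exclusive(sets_of_intervals):
    """Per-base strict mutual exclusion over lists of (chrom,start,end)."""
    bases = [baseset(ivs) for ivs in sets_of_intervals]
    out = []
    for i, mine in enumerate(bases):
        others = set().union(*(b for j, b in enumerate(bases) if j != i)) \
            if len(bases) > 1 else set()
        out.append(mine - others)
    return out


def brute_force_codon_positions(cds_intervals, strand):
    """Genomic positions of codon positions 1/2 vs 3, by explicit walk."""
    coords = []
    for s, e in sorted(cds_intervals):
        coords.extend(range(s, e))
    if strand == "-":
        coords = coords[::-1]
    p12, p3 = [], []
    for i, c in enumerate(coords):
        (p3 if i % 3 == 2 else p12).append(c)
    return set(p12), set(p3)


def brute_force_shared_coding_bases(blocks, genes):
    """Per-base count of aligned coding positions shared by gene pairs."""
    cds_lookup = {}
    for g in genes:
        for s, e in g.cds:
            for p in range(s, e):
                cds_lookup[(g.genome, g.chrom, p)] = g.gene_id
    weights = {}
    for block in blocks:
        cols = {}
        for row in block.rows:
            pos = row.forward_positions()
            for col, p in enumerate(pos):
                if p >= 0:
                    cols.setdefault(col, []).append((row.genome, row.chrom, int(p)))
        for col, entries in cols.items():
            hits = [(g, cds_lookup[k]) for k in entries
                    if k in cds_lookup for g in [k[0]]]
            for i in range(len(hits)):
                for j in range(i + 1, len(hits)):
                    if hits[i][0] == hits[j][0]:
                        continue
                    key = tuple(sorted((hits[i][1], hits[j][1])))
                    weights[key] = weights.get(key, 0) + 1
    return weights


def sliding_codon_counts(seq, informative):
    """Frame-0 codon counting by explicit slicing."""
    counts = {}
    seq = seq.upper()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c = seq[i:i + 3]
        if c in informative:
            counts[c] = counts.get(c, 0) + 1
    return counts
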