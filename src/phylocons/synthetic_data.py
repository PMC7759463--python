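"""Seeded, ground-truthed synthetic alignments with planted selection.

The generator emulates the statistical structure of a large reference-
projected whole-genome alignment at desk scale: a neutral background
evolved along a random tree under a reversible model, chromosome classes
(macro/micro/sex) with distinct neutral rates, planted conserved and
accelerated elements at known rate multipliers, toy gene structures whose
first and second codon positions evolve slowly, ancestral-repeat labels on
neutral background, per-genome missing rows, reconstructed-ancestor rows
(the true simulated internal sequences), and optional gene scenarios:
a clade-restricted duplication placed in a new flanking-gene context, a
clade-restricted intronless retrocopy with fused exons, and a
clade-restricted insertion present in the clade MRCA.

Simulation is column-independent: there is no indel process beyond
block-level missing rows and the planted insertion, trading indel realism
for exact ground truth (every downstream contract is column-based).
All randomness flows through one seeded generator; identical seeds yield
byte-identical fixture bundles.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import MafBlock, MafRow, write_maf
from .orthology import GeneModel, assign_ranks, write_gene_table
from .phylo_core import PhyloTree, SubstitutionModel, decode_sequence
from .region_intersect import RegionSet, codon_positions

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeSpec:
    name: str
    length: int
    klass: str  # macro / micro / sex


def _default_chromosomes() -> list[ChromosomeSpec]:
    return [ChromosomeSpec("macro1", 100_000, "macro"),
            ChromosomeSpec("micro1", 50_000, "micro"),
            ChromosomeSpec("sexZ", 50_000, "sex")]


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic alignment.

    Defaults follow the avian setting the package targets: 60 taxa, a tree
    with 16.5 expected substitutions per site of total branch length, and
    class rates with the sex chromosomes 16% faster than macro-chromosomes
    and macro-chromosomes 9% faster than micro-chromosomes.
    """
    n_taxa: int = 60
    total_branch_length: float = 16.5
    chromosomes: list[ChromosomeSpec] = field(default_factory=_default_chromosomes)
    frequencies: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)
    exchangeabilities: tuple[float, ...] = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)
    class_scales: dict = field(default_factory=lambda: {
        "macro": 1.0, "micro": 1.0 / 1.09, "sex": 1.16})
    # planted elements
    conserved_fraction: float = 0.10
    conserved_rate: float = 0.3
    accelerated_fraction: float = 0.02
    accelerated_rate: float = 2.0
    element_length_mean: int = 30
    # annotation layer
    genes: bool = True
    cds12_rate: float = 0.2
    cds3_rate: float = 1.0
    utr_rate: float = 0.6
    lncrna_rate: float = 0.5
    lncrna_fraction: float = 0.02
    motif_rate: float = 0.35
    motif_fraction: float = 0.01
    repeat_fraction: float = 0.3
    # alignment shape
    missing_row_prob: float = 0.05
    block_length: int = 1000
    include_ancestors: bool = True
    reference: str = "ref"
    # gene scenarios
    duplication: bool = True
    retrocopy: bool = True
    insertion: bool = True
    lineage_chrom: str = "chrLS"
    lineage_chrom_length: int = 10_000
    insertion_length: int = 2_000
    private_length: int = 500

    def substitution_model(self) -> SubstitutionModel:
        return SubstitutionModel(self.frequencies, self.exchangeabilities)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [dataclasses.asdict(c) for c in self.chromosomes]
        d["frequencies"] = list(self.frequencies)
        d["exchangeabilities"] = list(self.exchangeabilities)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["chromosomes"] = [ChromosomeSpec(**c) for c in d.get(
            "chromosomes", [dataclasses.asdict(c) for c in _default_chromosomes()])]
        for key in ("frequencies", "exchangeabilities"):
            if key in d:
                d[key] = tuple(d[key])
        if "class_scales" in d:
            d["class_scales"] = dict(d["class_scales"])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class TruthSet:
    """Everything planted, with exact coordinates and rates."""
    elements: list[dict] = field(default_factory=list)  # chrom,start,end,kind,rate
    repeats: list[tuple[str, int, int]] = field(default_factory=list)
    class_map: dict = field(default_factory=dict)
    class_scales: dict = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)
    duplications: list[dict] = field(default_factory=list)
    retrocopies: list[dict] = field(default_factory=list)
    insertions: list[dict] = field(default_factory=list)
    target_clade: str | None = None
    node_sequences: dict = field(default_factory=dict)  # label -> {chrom: codes}
    seed: int | None = None

    def element_positions(self, kind: str, chrom: str) -> np.ndarray:
        pos = [np.arange(e["start"], e["end"]) for e in self.elements
               if e["kind"] == kind and e["chrom"] == chrom]
        return np.concatenate(pos) if pos else np.array([], dtype=np.int64)

    def region_sets(self, reference: str = "ref") -> dict[str, RegionSet]:
        """Annotation classes as interval sets in reference coordinates."""
        ref_genes = [g for g in self.genes if g.genome == reference]
        cds, utr, intron = [], [], []
        for g in ref_genes:
            for s, e in g.cds:
                cds.append((g.chrom, s, e))
            for s, e in getattr_utrs(g, self):
                utr.append((g.chrom, s, e))
            ivs = sorted(g.cds)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                intron.append((g.chrom, e1, s2))
        def of_kind(kind):
            return [(e["chrom"], e["start"], e["end"]) for e in self.elements
                    if e["kind"] == kind]
        return {
            "coding_exons": RegionSet.from_intervals("coding_exons", cds),
            "utr_exons": RegionSet.from_intervals("utr_exons", utr or of_kind("utr")),
            "introns": RegionSet.from_intervals("introns", intron),
            "lncrna": RegionSet.from_intervals("lncrna", of_kind("lncrna")),
            "motifs": RegionSet.from_intervals("motifs", of_kind("motif")),
            "ancestral_repeats": RegionSet.from_intervals(
                "ancestral_repeats", [(c, s, e) for c, s, e in self.repeats]),
        }

    def to_json(self) -> str:
        d = {
            "elements": self.elements,
            "repeats": [list(r) for r in self.repeats],
            "class_map": self.class_map,
            "class_scales": self.class_scales,
            "genes": [{"gene_id": g.gene_id, "genome": g.genome,
                       "chrom": g.chrom, "strand": g.strand,
                       "cds": [list(iv) for iv in g.cds]} for g in self.genes],
            "duplications": self.duplications,
            "retrocopies": self.retrocopies,
            "insertions": self.insertions,
            "target_clade": self.target_clade,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1, sort_keys=True)


def getattr_utrs(gene: GeneModel, truth: TruthSet) -> list[tuple[int, int]]:
    """UTR intervals recorded for a gene, if any (stored as elements)."""
    return [(e["start"], e["end"]) for e in truth.elements
            if e["kind"] == "utr" and e["chrom"] == gene.chrom
            and e.get("gene") == gene.gene_id.split("@")[0]]


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, target_total_branch_length: float, seed
                  ) -> PhyloTree:
    """Random topology by successive joins with exponential branch lengths,
    rescaled so the total branch length matches the target exactly.

    Leaves are ``ref, t01, t02, ...``; internal nodes ``anc01, anc02, ...``
    (labels usable as reconstructed-ancestor genome names).
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = ["ref"] + [f"t{i:02d}" for i in range(1, n_taxa)]
    parent = {}
    lengths = {}
    active = list(range(n_taxa))
    next_id = n_taxa
    n_internal = 0
    while len(active) > 1:
        i = int(rng.integers(len(active)))
        a = active.pop(i)
        j = int(rng.integers(len(active)))
        b = active.pop(j)
        n_internal += 1
        labels.append(f"anc{n_internal:02d}")
        parent[a] = next_id
        parent[b] = next_id
        lengths[a] = float(rng.exponential(1.0)) + 1e-3
        lengths[b] = float(rng.exponential(1.0)) + 1e-3
        active.append(next_id)
        next_id += 1
    root = active[0]
    parent[root] = -1
    lengths[root] = 0.0
    n = next_id
    par = np.array([parent[i] for i in range(n)], dtype=np.int64)
    lens = np.array([lengths[i] for i in range(n)], dtype=np.float64)
    total = lens.sum()
    lens *= target_total_branch_length / total
    return PhyloTree(labels, par, lens)


def choose_target_clade(tree: PhyloTree, exclude_leaf: str = "ref",
                        min_leaves: int = 3, max_fraction: float = 0.4) -> str:
    """Deterministically pick a labeled internal node usable as a target
    clade: enough leaves for within-clade signal, not containing the
    reference, not most of the tree."""
    n_total = len(tree.leaf_labels)
    for lo, hi in ((min_leaves, max(int(max_fraction * n_total), min_leaves)),
                   (2, n_total - 2)):
        best = None
        for node in tree.postorder:
            node = int(node)
            if tree.is_leaf(node) or not tree.labels[node]:
                continue
            leaves = tree.leaves_below(node)
            if exclude_leaf in leaves or not lo <= len(leaves) <= hi:
                continue
            if best is None or len(leaves) > len(tree.leaves_below(best)):
                best = node
        if best is not None:
            return tree.labels[best]
    raise ValueError("no suitable clade in this tree")


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _evolve(parent_states: np.ndarray, P: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    child = (u[:, None] > cum[parent_states]).sum(axis=1)
    return np.minimum(child, 3).astype(np.int8)


def simulate_node_sequences(tree: PhyloTree, model: SubstitutionModel, n: int,
                            rng: np.random.Generator,
                            site_scales: np.ndarray | float = 1.0
                            ) -> np.ndarray:
    """Evolve a root draw from the stationary distribution down the tree.

    Returns an ``(n_nodes, n)`` int8 matrix of true states for every node,
    the generative counterpart of the pruning likelihood.  ``site_scales``
    multiplies every branch length, per site.
    """
    seqs = np.empty((tree.n_nodes, n), dtype=np.int8)
    seqs[tree.root] = rng.choice(4, size=n, p=model.frequencies)
    per_site = np.ndim(site_scales) > 0
    if per_site:
        site_scales = np.asarray(site_scales, dtype=np.float64)
        values = np.unique(site_scales)
    for node in tree.postorder[::-1]:
        node = int(node)
        if node == tree.root:
            continue
        t = float(tree.lengths[node])
        parent_seq = seqs[tree.parent[node]]
        if not per_site:
            seqs[node] = _evolve(parent_seq, model.transition_matrix(t * site_scales), rng)
        else:
            child = np.empty(n, dtype=np.int8)
            for v in values:
                m = site_scales == v
                child[m] = _evolve(parent_seq[m], model.transition_matrix(t * v), rng)
            seqs[node] = child
    return seqs


def simulate_columns(tree: PhyloTree, model: SubstitutionModel, n: int,
                     scale: float = 1.0, rng=None) -> np.ndarray:
    """``(n, n_leaves)`` simulated alignment columns in tree leaf order."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seqs = simulate_node_sequences(tree, model, n, rng, site_scales=scale)
    return seqs[tree.leaf_indices].T.copy()


# ---------------------------------------------------------------------------
# Annotation planting
# ---------------------------------------------------------------------------

_GENE_LAYOUT = {"utr": 50, "exon": 150, "intron": 200, "n_exons": 3,
                "stride": 1500, "offset": 300}
#: tail of micro1 kept gene-free for the planted duplication and retrocopy
_SCENARIO_RESERVE = 2500


def _tile_genes(chrom: str, length: int, prefix: str, n_genes: int,
                genomes: Sequence[str]) -> tuple[list[GeneModel], list[dict]]:
    """Identical toy gene structures in every genome (shared coordinates):
    5'UTR, three 150-bp exons with introns, 3'UTR; every fourth gene on the
    minus strand."""
    L = _GENE_LAYOUT
    genes, utr_elements = [], []
    for k in range(n_genes):
        g0 = L["offset"] + k * L["stride"]
        span_end = g0 + 2 * L["utr"] + 3 * L["exon"] + 2 * L["intron"]
        if span_end > length:
            break
        strand = "-" if k % 4 == 3 else "+"
        cds = []
        cur = g0 + L["utr"]
        for _ in range(L["n_exons"]):
            cds.append((cur, cur + L["exon"]))
            cur += L["exon"] + L["intron"]
        cur -= L["intron"]
        utr5 = (g0, g0 + L["utr"])
        utr3 = (cur, cur + L["utr"])
        for genome in genomes:
            genes.append(GeneModel(f"{prefix}{k:02d}@{genome}", genome, chrom,
                                   strand, tuple(cds)))
        for s, e in (utr5, utr3):
            utr_elements.append({"chrom": chrom, "start": int(s), "end": int(e),
                                 "kind": "utr", "rate": None,
                                 "gene": f"{prefix}{k:02d}"})
    return genes, utr_elements


def _place_elements(free: np.ndarray, target_bases: int, mean_length: int,
                    rng: np.random.Generator, min_length: int = 10
                    ) -> list[tuple[int, int]]:
    """Greedy non-overlapping placement into unoccupied positions."""
    placed, covered = [], 0
    L = len(free)
    attempts = 0
    max_attempts = max(200, 20 * (target_bases // max(mean_length, 1) + 1))
    while covered < target_bases and attempts < max_attempts:
        attempts += 1
        ln = min(int(rng.geometric(1.0 / mean_length)) + min_length, L)
        s = int(rng.integers(0, L - ln + 1))
        if free[s:s + ln].all():
            free[s:s + ln] = False
            placed.append((s, s + ln))
            covered += ln
    placed.sort()
    return placed


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: PhyloTree, config: SimulationConfig, rng
                       ) -> tuple[list[MafBlock], TruthSet]:
    """Forward-simulate every chromosome and package the result as MAF
    blocks plus exact truth.

    Per-column rate = class scale x element multiplier; ancestor rows are
    the true simulated internal sequences.  The lineage-specific insertion
    (when enabled) restricts alignment rows inside the planted interval to
    the target clade and its internal ancestors.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    model = config.substitution_model()
    truth = TruthSet(class_scales=dict(config.class_scales))
    genomes = list(tree.leaf_labels)
    if config.reference not in genomes:
        raise ValueError(f"tree has no leaf named {config.reference!r}")

    chromosomes = list(config.chromosomes)
    scenarios = config.duplication or config.retrocopy or config.insertion
    if config.insertion and all(c.name != config.lineage_chrom for c in chromosomes):
        chromosomes.append(ChromosomeSpec(config.lineage_chrom,
                                          config.lineage_chrom_length, "micro"))
    clade = choose_target_clade(tree) if scenarios else None
    truth.target_clade = clade
    if clade is not None:
        clade_node = tree.index_of(clade)
        clade_leaves = set(tree.leaves_below(clade_node))
        clade_ancestors = set(tree.internal_labels_below(clade_node))
    row_filters: list[tuple[str, int, int, set[str]]] = []

    gene_plan = {"macro1": ("G", 20), "micro1": ("H", 10)} if config.genes else {}

    for spec in chromosomes:
        truth.class_map[spec.name] = spec.klass
        L = spec.length
        site_rate = np.ones(L)
        free = np.ones(L, dtype=bool)
        # --- genes ---
        if spec.name in gene_plan:
            prefix, n_genes = gene_plan[spec.name]
            usable = L
            if spec.name == "micro1" and (config.duplication or config.retrocopy):
                # reserve a tail for the planted copies; keep elements and
                # repeat labels out of it too, since the scenario blocks
                # overwrite the reference projection there
                usable = max(0, L - _SCENARIO_RESERVE)
                free[usable:] = False
            genes, utrs = _tile_genes(spec.name, usable, prefix, n_genes,
                                      genomes)
            truth.genes.extend(genes)
            truth.elements.extend(utrs)
            ref_genes = [g for g in genes if g.genome == config.reference]
            for g in ref_genes:
                p12, p3 = codon_positions(g)
                site_rate[p12] = config.cds12_rate
                site_rate[p3] = config.cds3_rate
                lo = min(s for s, _ in g.cds) - _GENE_LAYOUT["utr"]
                hi = max(e for _, e in g.cds) + _GENE_LAYOUT["utr"]
                free[max(lo, 0):min(hi, L)] = False
            for e in utrs:
                if e["chrom"] == spec.name:
                    site_rate[e["start"]:e["end"]] = config.utr_rate
                    e["rate"] = config.utr_rate
        # --- planted elements ---
        for kind, frac, rate, mean_len in (
                ("conserved", config.conserved_fraction, config.conserved_rate,
                 config.element_length_mean),
                ("accelerated", config.accelerated_fraction,
                 config.accelerated_rate, config.element_length_mean),
                ("lncrna", config.lncrna_fraction, config.lncrna_rate, 120),
                ("motif", config.motif_fraction, config.motif_rate, 15)):
            if frac <= 0:
                continue
            for s, e in _place_elements(free, int(frac * L), mean_len, rng):
                site_rate[s:e] = rate
                truth.elements.append({"chrom": spec.name, "start": s, "end": e,
                                       "kind": kind, "rate": rate})
        # --- ancestral repeats label neutral leftover space ---
        if config.repeat_fraction > 0:
            n_free = int(free.sum())
            for s, e in _place_elements(free, int(config.repeat_fraction * n_free),
                                        200, rng, min_length=50):
                truth.repeats.append((spec.name, s, e))
        # --- evolve ---
        scales = site_rate * config.class_scales[spec.klass]
        seqs = simulate_node_sequences(tree, model, L, rng, site_scales=scales)
        for i, lbl in enumerate(tree.labels):
            if lbl:
                truth.node_sequences.setdefault(lbl, {})[spec.name] = seqs[i]

    # --- lineage-specific filters on the dedicated chromosome ---
    if config.insertion and clade is not None:
        cl = config.lineage_chrom
        L = next(c.length for c in chromosomes if c.name == cl)
        s = L // 2 - config.insertion_length // 2
        e = s + config.insertion_length
        allowed = clade_leaves | clade_ancestors
        row_filters.append((cl, s, e, allowed))
        truth.insertions.append({"chrom": cl, "start": s, "end": e,
                                 "clade": clade})
        private_leaf = sorted(clade_leaves)[0]
        p0 = min(e + 1000, L - config.private_length)
        p1 = p0 + config.private_length
        row_filters.append((cl, p0, p1, {private_leaf}))
        truth.insertions.append({"chrom": cl, "start": p0, "end": p1,
                                 "clade": private_leaf, "private": True})

    blocks = _emit_blocks(tree, chromosomes, truth, config, row_filters, rng)
    if scenarios:
        blocks, truth = plant_gene_scenarios(blocks, truth, tree, config, rng)
    truth.genes = assign_ranks(truth.genes)
    return blocks, truth


def _emit_blocks(tree: PhyloTree, chromosomes: Sequence[ChromosomeSpec],
                 truth: TruthSet, config: SimulationConfig,
                 row_filters: Sequence[tuple[str, int, int, set[str]]],
                 rng: np.random.Generator) -> list[MafBlock]:
    blocks = []
    ancestor_labels = [lbl for i, lbl in enumerate(tree.labels)
                       if lbl and not tree.is_leaf(i)]
    for spec in chromosomes:
        L = spec.length
        cuts = set(range(0, L, config.block_length)) | {L}
        for chrom, s, e, _ in row_filters:
            if chrom == spec.name:
                cuts |= {s, e}
        cuts = sorted(cuts)
        for a, b in zip(cuts, cuts[1:]):
            flt = [allowed for chrom, s, e, allowed in row_filters
                   if chrom == spec.name and s <= a and b <= e]
            block = MafBlock()
            for lbl in tree.leaf_labels:
                if any(lbl not in allowed for allowed in flt):
                    continue
                if lbl != config.reference and rng.random() < config.missing_row_prob:
                    continue
                text = decode_sequence(truth.node_sequences[lbl][spec.name][a:b])
                block.rows.append(MafRow(f"{lbl}.{spec.name}", a, b - a, "+",
                                         L, text))
            if config.include_ancestors:
                for lbl in ancestor_labels:
                    if any(lbl not in allowed for allowed in flt):
                        continue
                    text = decode_sequence(truth.node_sequences[lbl][spec.name][a:b])
                    block.rows.append(MafRow(f"{lbl}.{spec.name}", a, b - a,
                                             "+", L, text))
            if block.rows:
                blocks.append(block)
    return blocks


# ---------------------------------------------------------------------------
# Gene scenarios
# ---------------------------------------------------------------------------

def plant_gene_scenarios(blocks: list[MafBlock], truth: TruthSet,
                         tree: PhyloTree, config: SimulationConfig,
                         rng: np.random.Generator
                         ) -> tuple[list[MafBlock], TruthSet]:
    """Plant the duplication / retrocopy / lineage-specific-gene scenarios.

    (i)  Duplication in a new context: clade genomes get a second copy of a
         reference gene at a locus on another chromosome whose flanking
         genes differ, linked to the source gene by extra alignment blocks.
    (ii) Retrocopy: clade genomes get an intronless copy of a multi-exon
         gene; the extra blocks map each source exon onto consecutive
         slices of the fused copy.
    (iii) Lineage-specific genes: CDS models inside the planted insertion
         (anchored in the clade MRCA) and inside the single-leaf private
         region (not anchored; a decoy the MRCA-overlap filter removes).
    """
    clade = truth.target_clade
    if clade is None:
        return blocks, truth
    clade_node = tree.index_of(clade)
    clade_leaves = sorted(tree.leaves_below(clade_node))
    genomes = list(tree.leaf_labels)

    def gene_of(prefix_k: str, genome: str) -> GeneModel:
        for g in truth.genes:
            if g.gene_id == f"{prefix_k}@{genome}":
                return g
        raise KeyError(prefix_k)

    def linking_blocks(src: GeneModel, dst_chrom: str,
                       dst_ivs: Sequence[tuple[int, int]]) -> list[MafBlock]:
        out = []
        L_dst = next(c.length for c in config.chromosomes if c.name == dst_chrom) \
            if any(c.name == dst_chrom for c in config.chromosomes) else \
            max(e for _, e in dst_ivs) + 1000
        L_src = len(truth.node_sequences[config.reference][src.chrom])
        for (ss, se), (ds, de) in zip(src.cds, dst_ivs):
            block = MafBlock()
            text = decode_sequence(
                truth.node_sequences[config.reference][src.chrom][ss:se])
            block.rows.append(MafRow(f"{config.reference}.{src.chrom}",
                                     ss, se - ss, "+", L_src, text))
            for leaf in clade_leaves:
                t = decode_sequence(truth.node_sequences[leaf][dst_chrom][ds:de])
                block.rows.append(MafRow(f"{leaf}.{dst_chrom}", ds, de - ds,
                                         "+", L_dst, t))
            out.append(block)
        return out

    # scenario loci sit in the reserved gene-free tail of micro1
    micro_len = next((c.length for c in config.chromosomes
                      if c.name == "micro1"), None)
    g_names = sorted({g.gene_id.split("@")[0] for g in truth.genes
                      if g.genome == config.reference and g.chrom == "macro1"})
    h_ends = [e for g in truth.genes
              if g.genome == config.reference and g.chrom == "micro1"
              for _, e in g.cds]
    anchor = (max(h_ends) + _GENE_LAYOUT["utr"]) if h_ends \
        else _GENE_LAYOUT["offset"]
    d0 = anchor + 150
    r0 = d0 + 1000
    if config.genes and (config.duplication or config.retrocopy):
        if micro_len is None or r0 + 450 > micro_len or len(g_names) < 2:
            raise ValueError("genome too small to place gene scenarios")

    if config.genes and config.duplication:
        src_name = g_names[len(g_names) // 2]
        dst = [(d0 + i * 350, d0 + i * 350 + 150) for i in range(3)]
        src_ref = gene_of(src_name, config.reference)
        blocks += linking_blocks(src_ref, "micro1", dst)
        for leaf in clade_leaves:
            truth.genes.append(GeneModel(f"{src_name}b@{leaf}", leaf, "micro1",
                                         "+", tuple(dst)))
        truth.duplications.append({
            "source_gene": src_name, "clade": clade, "chrom": "micro1",
            "novel_copy": f"{src_name}b", "ancestral_copy": src_name,
            "cds": [list(iv) for iv in dst]})

    if config.genes and config.retrocopy:
        remaining = [n for n in g_names
                     if not truth.duplications
                     or n != truth.duplications[-1]["source_gene"]]
        src_name = remaining[len(remaining) // 2]
        src_ref = gene_of(src_name, config.reference)
        dst = []
        cur = r0
        for s, e in src_ref.cds:  # fused: exon boundaries collapse
            dst.append((cur, cur + (e - s)))
            cur += e - s
        blocks += linking_blocks(src_ref, "micro1", dst)
        for leaf in clade_leaves:
            truth.genes.append(GeneModel(f"{src_name}r@{leaf}", leaf, "micro1",
                                         "+", ((r0, cur),)))
        truth.retrocopies.append({
            "source_gene": src_name, "clade": clade, "chrom": "micro1",
            "novel_copy": f"{src_name}r", "fused_cds": [r0, cur],
            "source_exons": [list(iv) for iv in src_ref.cds]})

    if config.insertion:
        ins = next((i for i in truth.insertions if not i.get("private")), None)
        priv = next((i for i in truth.insertions if i.get("private")), None)
        if ins is not None:
            s = ins["start"] + 100
            cds = ((s, s + 300),)
            for leaf in clade_leaves:
                truth.genes.append(GeneModel(f"LSG@{leaf}", leaf, ins["chrom"],
                                             "+", cds))
            ins["gene"] = "LSG"
            ins["gene_cds"] = [list(cds[0])]
        if priv is not None:
            leaf = priv["clade"]
            s = priv["start"] + 50
            cds = ((s, s + 300),)
            truth.genes.append(GeneModel(f"PRIV@{leaf}", leaf, priv["chrom"],
                                         "+", cds))
            priv["gene"] = "PRIV"
            priv["gene_cds"] = [list(cds[0])]
    return blocks, truth


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

def emit_fixture_bundle(config: SimulationConfig, outdir, seed: int) -> dict:
    """Write a complete, self-contained fixture directory.

    Contents: alignment.maf, tree.nwk, elements.bed, ancestral_repeats.bed,
    one BED per mutually exclusive annotation class, classes.tsv, genes.tsv,
    ancestors.fasta, truth.json and config.json.  Re-running with the same
    config and seed reproduces every file byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tree = simulate_tree(config.n_taxa, config.total_branch_length, rng)
    blocks, truth = simulate_alignment(tree, config, rng)
    truth.seed = seed

    with open(outdir / "alignment.maf", "w") as fh:
        write_maf(blocks, fh)
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    with open(outdir / "elements.bed", "w") as fh:
        for e in truth.elements:
            rate = "NA" if e["rate"] is None else f"{e['rate']:g}"
            fh.write(f"{e['chrom']}\t{e['start']}\t{e['end']}\t"
                     f"{e['kind']}:{rate}\n")
    with open(outdir / "ancestral_repeats.bed", "w") as fh:
        for chrom, s, e in truth.repeats:
            fh.write(f"{chrom}\t{s}\t{e}\tancestral_repeat\n")
    for label, rs in truth.region_sets(config.reference).items():
        rs.to_bed(outdir / f"regions_{label}.bed")
    with open(outdir / "classes.tsv", "w") as fh:
        for chrom in sorted(truth.class_map):
            fh.write(f"{chrom}\t{truth.class_map[chrom]}\n")
    write_gene_table(truth.genes, outdir / "genes.tsv")
    ancestor_labels = sorted(
        lbl for i, lbl in enumerate(tree.labels)
        if lbl and not tree.is_leaf(i))
    with open(outdir / "ancestors.fasta", "w") as fh:
        for lbl in ancestor_labels:
            for chrom in sorted(truth.node_sequences.get(lbl, {})):
                fh.write(f">{lbl}.{chrom}\n")
                seq = decode_sequence(truth.node_sequences[lbl][chrom])
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n")
    return {"tree": tree, "blocks": blocks, "truth": truth}
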