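"""Mutually exclusive functional region classes and conservation summaries.

Coding exons, UTR exons, introns, lncRNAs, ancestral repeats and motif
regions overlap; to compare their conservation fairly every base is
assigned to at most one class (a base in two or more original classes is
dropped from all of them).  Bases are then sampled per class and the
fraction carrying a significant conserved call is reported, including the
codon-position breakdown within coding sequence (positions 1-2 versus 3).

Intervals are 0-based half-open, stored as sorted, merged ``(N, 2)`` int
arrays per chromosome.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .significance_calls import CallSet

# ---------------------------------------------------------------------------
# Interval primitives (sorted, merged, half-open)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def subtract_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged interval arrays."""
    out = []
    j = 0
    b = np.asarray(b).reshape(-1, 2)
    for s, e in np.asarray(a).reshape(-1, 2):
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if be <= cur:
                k += 1
                continue
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    a = np.asarray(a).reshape(-1, 2)
    b = np.asarray(b).reshape(-1, 2)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def interval_length(a: np.ndarray) -> int:
    a = np.asarray(a).reshape(-1, 2)
    return int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0


@dataclass
class RegionSet:
    """A labeled set of disjoint intervals per chromosome."""
    label: str
    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, label: str,
                       intervals: Iterable[tuple[str, int, int]]) -> "RegionSet":
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            raw.setdefault(chrom, []).append((s, e))
        return cls(label, {c: merge_intervals(v) for c, v in raw.items()})

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                rows.append((f[0], int(f[1]), int(f[2])))
        return cls.from_intervals(label or str(path), rows)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.by_chrom):
                for s, e in self.by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{self.label}\n")

    def total_bases(self) -> int:
        return sum(interval_length(a) for a in self.by_chrom.values())

    def intervals(self) -> Iterable[tuple[str, int, int]]:
        for chrom in sorted(self.by_chrom):
            for s, e in self.by_chrom[chrom]:
                yield chrom, int(s), int(e)


def make_mutually_exclusive(sets: Sequence[RegionSet]) -> list[RegionSet]:
    """Strict exclusion: a base in k >= 2 original classes belongs to none.

    ``priority`` semantics (first class keeps contested bases) are available
    via :func:`make_priority_exclusive` for callers that prefer them.
    """
    if len(sets) < 2:
        raise ValueError("need at least two region sets")
    out = []
    for i, rs in enumerate(sets):
        others_by_chrom: dict[str, list[np.ndarray]] = {}
        for j, other in enumerate(sets):
            if j == i:
                continue
            for chrom, ivs in other.by_chrom.items():
                others_by_chrom.setdefault(chrom, []).append(ivs)
        new = {}
        for chrom, ivs in rs.by_chrom.items():
            union = merge_intervals(
                (s, e) for arr in others_by_chrom.get(chrom, [])
                for s, e in arr)
            remain = subtract_intervals(ivs, union)
            if len(remain):
                new[chrom] = remain
        out.append(RegionSet(rs.label, new))
    return out


def make_priority_exclusive(sets: Sequence[RegionSet]) -> list[RegionSet]:
    """Alternative exclusion where earlier classes keep contested bases."""
    out = []
    claimed: dict[str, np.ndarray] = {}
    for rs in sets:
        new = {}
        for chrom, ivs in rs.by_chrom.items():
            prior = claimed.get(chrom, np.zeros((0, 2), dtype=np.int64))
            remain = subtract_intervals(ivs, prior)
            if len(remain):
                new[chrom] = remain
            claimed[chrom] = merge_intervals(
                list(map(tuple, prior)) + list(map(tuple, ivs)))
        out.append(RegionSet(rs.label, new))
    return out


def sample_region_bases(region: RegionSet, n: int, seed
                        ) -> dict[str, np.ndarray]:
    """Uniform sample of ``n`` distinct bases from the region set.

    When ``n`` exceeds the region size the whole region is returned with a
    warning (small synthetic genomes).
    """
    from .neutral_model import sample_training_sites
    total = region.total_bases()
    if n >= total:
        if n > total:
            warnings.warn(f"requested {n} bases from region {region.label!r} "
                          f"of size {total}; taking all")
        picked = [(c, p) for c, s, e in region.intervals() for p in range(s, e)]
    else:
        picked = sample_training_sites(list(region.intervals()), n, seed)
    out: dict[str, list[int]] = {}
    for chrom, p in picked:
        out.setdefault(chrom, []).append(p)
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


@dataclass
class RegionClassStats:
    table: pd.DataFrame  # label, sampled, conserved, fraction


def _conserved_positions(callset: CallSet) -> dict[str, np.ndarray]:
    t = callset.table
    t = t[t["direction"] == "conserved"]
    return {chrom: np.sort(g["start"].to_numpy())
            for chrom, g in t.groupby("chrom")}


def conserved_fraction_by_region(callset: CallSet,
                                 samples: Mapping[str, Mapping[str, np.ndarray]]
                                 ) -> RegionClassStats:
    """Fraction of sampled bases per class that carry a conserved call.

    ``samples`` maps class label -> (chrom -> sampled positions).  Empty
    classes are reported with sampled = 0 and fraction 0.
    """
    calls = _conserved_positions(callset)
    rows = []
    for label, per_chrom in samples.items():
        sampled = conserved = 0
        for chrom, positions in per_chrom.items():
            sampled += len(positions)
            hits = calls.get(chrom)
            if hits is not None and len(positions):
                conserved += int(np.isin(positions, hits).sum())
        frac = conserved / sampled if sampled else 0.0
        rows.append((label, sampled, conserved, frac))
    return RegionClassStats(pd.DataFrame(
        rows, columns=["label", "sampled", "conserved", "fraction"]))


def codon_positions(gene) -> tuple[np.ndarray, np.ndarray]:
    """Genomic positions of codon positions {1,2} and {3} of a gene model.

    The reading frame is counted along the direction of transcription: on
    the minus strand the first codon base is the rightmost CDS base.
    Raises ValueError when the CDS length is not a multiple of three.
    """
    cds = sorted(gene.cds)
    coords = np.concatenate([np.arange(s, e) for s, e in cds])
    if gene.strand == "-":
        coords = coords[::-1]
    if len(coords) % 3:
        raise ValueError(f"CDS length of {gene.gene_id} not divisible by 3")
    frame = np.arange(len(coords)) % 3
    return coords[frame < 2], coords[frame == 2]


def codon_position_breakdown(callset: CallSet, genes: Sequence) -> pd.DataFrame:
    """Conserved fraction at codon positions 1-2 versus position 3.

    Genes whose CDS length is not divisible by three are skipped with a
    warning.  Returns a two-row table (pos12, pos3).
    """
    calls = _conserved_positions(callset)
    counts = {"pos12": [0, 0], "pos3": [0, 0]}  # bases, conserved
    for gene in genes:
        try:
            p12, p3 = codon_positions(gene)
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        hits = calls.get(gene.chrom, np.array([], dtype=np.int64))
        for key, coords in (("pos12", p12), ("pos3", p3)):
            counts[key][0] += len(coords)
            counts[key][1] += int(np.isin(coords, hits).sum())
    rows = [(k, b, c, (c / b if b else 0.0)) for k, (b, c) in counts.items()]
    return pd.DataFrame(rows, columns=["positions", "bases", "conserved",
                                       "fraction"])
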