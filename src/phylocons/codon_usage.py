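"""Codon-usage statistics: RSCU, Wright's effective number of codons, GC.

Counting uses the standard nuclear genetic code and covers the 59
informative codons: methionine (ATG), tryptophan (TGG) and the three stop
codons are excluded because they admit no synonymous choice.

RSCU (relative synonymous codon usage) is a codon's observed count divided
by the mean count of its synonymous family, so unbiased usage gives 1 for
every codon and the values in a family always sum to the family size.

Nc, the effective number of codons, summarizes genome- or gene-level bias
on a 20 (one codon per amino acid) to 61 (uniform synonymous usage) scale:

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

where Fk is the mean codon homozygosity of the k-fold degenerate families,
estimated per family as F = (n * sum(p_i^2) - 1) / (n - 1) from n counted
codons with within-family proportions p_i.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid for the informative codons (no Met/Trp/stop)
SYNONYMOUS: dict[str, str] = {
    codon: aa for codon, aa in _TABLE.forward_table.items()
    if codon not in ("ATG", "TGG")
}
#: amino acid -> tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(SYNONYMOUS.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] = FAMILIES[_aa] + (_codon,)

#: degeneracy class -> amino acids (2-, 3-, 4- and 6-fold families)
DEGENERACY: dict[int, tuple[str, ...]] = {}
for _aa, _codons in FAMILIES.items():
    DEGENERACY.setdefault(len(_codons), ())
    DEGENERACY[len(_codons)] = DEGENERACY[len(_codons)] + (_aa,)

NC_WEIGHTS = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


@dataclass
class CodonCounts:
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def family_counts(self, aa: str) -> np.ndarray:
        return np.array([self.counts.get(c, 0) for c in FAMILIES[aa]],
                        dtype=np.float64)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for c, n in other.counts.items():
            merged[c] = merged.get(c, 0) + n
        return CodonCounts(merged)


def count_codons(sequences: Iterable[str]) -> CodonCounts:
    """Frame-0 codon counts over the informative codons.

    Sequences whose length is not a multiple of three are trimmed with a
    warning; codons containing anything but A/C/G/T are skipped.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("no coding sequence provided")
    counts: dict[str, int] = {}
    for seq in seqs:
        if len(seq) % 3:
            warnings.warn(f"sequence length {len(seq)} not divisible by 3; "
                          "trailing bases dropped")
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if codon in SYNONYMOUS:
                counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts)


def rscu(counts: CodonCounts) -> dict[str, float]:
    """RSCU per informative codon; families without observations report NaN."""
    out: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        fam = counts.family_counts(aa)
        total = fam.sum()
        if total == 0:
            for c in codons:
                out[c] = float("nan")
            continue
        mean = total / len(codons)
        for c, n in zip(codons, fam):
            out[c] = float(n / mean)
    return out


def _family_homozygosity(fam: np.ndarray) -> float | None:
    """F = (n sum p^2 - 1)/(n - 1); None when fewer than 2 codons counted
    or the estimate is non-positive (no usable information)."""
    n = fam.sum()
    if n < 2:
        return None
    p = fam / n
    F = (n * float((p ** 2).sum()) - 1.0) / (n - 1.0)
    return F if F > 0 else None


def effective_number_of_codons(counts: CodonCounts) -> float:
    """Wright's Nc on pooled counts, clipped to the [20, 61] range.

    Per degeneracy class the mean homozygosity Fk averages the per-family
    estimates with at least two counted codons.  A missing 3-fold class
    (no isoleucine codons) is interpolated as (F2 + F4)/2 per the
    estimator's convention; a missing 2-, 4- or 6-fold class leaves Nc
    undefined (ValueError), since those classes span many amino acids.
    """
    if counts.total == 0:
        raise ValueError("no informative codons counted")
    fbar: dict[int, float] = {}
    for k, aas in DEGENERACY.items():
        vals = [f for aa in aas
                if (f := _family_homozygosity(counts.family_counts(aa))) is not None]
        if vals:
            fbar[k] = float(np.mean(vals))
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    missing = [k for k in NC_WEIGHTS if k not in fbar]
    if missing:
        raise ValueError(f"no usable codon families of degeneracy {missing}")
    nc = 2.0 + sum(w / fbar[k] for k, w in NC_WEIGHTS.items())
    return float(np.clip(nc, 20.0, 61.0))


def nc_per_gene(gene_sequences: Sequence[str]) -> float:
    """Mean of per-gene Nc values (genes with undefined Nc are skipped).

    This is the default aggregation; use
    ``effective_number_of_codons(count_codons(seqs))`` for pooled counts.
    """
    values = []
    for seq in gene_sequences:
        try:
            values.append(effective_number_of_codons(count_codons([seq])))
        except ValueError:
            continue
    if not values:
        raise ValueError("Nc undefined for every gene")
    return float(np.mean(values))


def gc_content(sequences: Iterable[str]) -> float:
    """(G+C) / (A+C+G+T); characters outside ACGT are excluded entirely."""
    gc = acgt = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        acgt += sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    return gc / acgt
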