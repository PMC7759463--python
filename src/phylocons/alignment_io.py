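"""Reference-projected alignment blocks (MAF) and scorable columns.

The scoring pipeline consumes a MAF export projected onto one reference
genome.  This module reads and writes MAF per the UCSC specification,
collapses per-genome duplicate rows into a single consensus entry (the
scoring model allows at most one entry per genome per column), and walks
blocks to produce one :class:`ReferencedColumn` per non-gap reference base.

Coordinates are 0-based half-open internally; MAF ``start``/``size`` fields
are kept in their native strand-local convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

from .phylo_core import MISSING

logger = logging.getLogger(__name__)

GAP = 5  # internal code for a gap character within a block text


@dataclass
class MafRow:
    """One ``s`` line: ``src`` is ``genome.chromosome``."""
    src: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def genome(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else ""

    def forward_positions(self) -> np.ndarray:
        """Forward-strand coordinate of each alignment column; -1 at gaps.

        For '-' strand rows the MAF start counts from the end of the source
        sequence, so the k-th aligned base sits at
        ``src_size - start - k - 1`` on the forward strand.
        """
        codes = _text_codes(self.text)
        nongap = codes != GAP
        k = np.cumsum(nongap) - 1
        if self.strand == "+":
            pos = self.start + k
        else:
            pos = self.src_size - self.start - k - 1
        return np.where(nongap, pos, -1)


@dataclass
class MafBlock:
    rows: list[MafRow] = field(default_factory=list)

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def genomes(self) -> list[str]:
        return [r.genome for r in self.rows]


class MafParseError(ValueError):
    pass


def _text_codes(text: str) -> np.ndarray:
    raw = np.frombuffer(text.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, MISSING, dtype=np.int8)
    for i, ch in enumerate("ACGT"):
        out[raw == ord(ch)] = i
    out[raw == ord("-")] = GAP
    return out


def _codes_to_text(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN-", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def read_maf(stream: TextIO | Iterable[str]) -> Iterator[MafBlock]:
    """Stream MAF blocks from a text source.

    Only ``a`` and ``s`` lines are interpreted; ``i``/``e``/``q`` lines and
    comments are skipped.  Malformed lines raise :class:`MafParseError` with
    the offending line number.
    """
    block: MafBlock | None = None
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        tag = line.split(None, 1)[0]
        if tag == "a":
            if block is not None and block.rows:
                yield block
            block = MafBlock()
        elif tag == "s":
            parts = line.split()
            if len(parts) != 7:
                raise MafParseError(f"line {lineno}: expected 7 fields on s line")
            if block is None:
                raise MafParseError(f"line {lineno}: s line before any a line")
            try:
                row = MafRow(parts[1], int(parts[2]), int(parts[3]), parts[4],
                             int(parts[5]), parts[6])
            except ValueError as exc:
                raise MafParseError(f"line {lineno}: {exc}") from exc
            if row.strand not in "+-":
                raise MafParseError(f"line {lineno}: bad strand {row.strand!r}")
            if row.start < 0 or row.start + row.size > row.src_size:
                raise MafParseError(f"line {lineno}: coordinates out of range")
            if sum(1 for c in row.text if c != "-") != row.size:
                raise MafParseError(
                    f"line {lineno}: non-gap character count != size field")
            if block.rows and len(row.text) != block.width:
                raise MafParseError(f"line {lineno}: ragged block")
            block.rows.append(row)
        # other line types ignored
    if block is not None and block.rows:
        yield block


def write_maf(blocks: Iterable[MafBlock], stream: TextIO) -> None:
    stream.write("##maf version=1\n")
    for block in blocks:
        stream.write("a\n")
        for r in block.rows:
            stream.write(
                f"s {r.src} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n")
        stream.write("\n")


# ---------------------------------------------------------------------------
# Duplicate-row merging
# ---------------------------------------------------------------------------

def merge_duplicate_rows(block: MafBlock) -> MafBlock:
    """Collapse multiple rows of the same genome into one consensus row.

    Per column the output symbol is the majority symbol among that genome's
    rows, with gaps counting as votes for gap.  Exact ties follow the
    conservative rule: a tie among two or more distinct bases yields N
    (missing); a tie between gap (or N) and a single base yields the base.

    The consensus row inherits the coordinates of the member row with the
    most aligned bases; those coordinates identify the dominant copy but no
    longer describe every symbol in the consensus text, so downstream code
    that needs per-copy coordinates (orthology) must use unmerged blocks.
    """
    by_genome: dict[str, list[MafRow]] = {}
    for r in block.rows:
        by_genome.setdefault(r.genome, []).append(r)
    if all(len(v) == 1 for v in by_genome.values()):
        return block
    out = MafBlock()
    for r in block.rows:
        rows = by_genome.get(r.genome)
        if rows is None:
            continue  # already emitted
        if len(rows) == 1:
            out.rows.append(rows[0])
        else:
            out.rows.append(_consensus_row(rows, block.width))
        del by_genome[r.genome]
    return out


def _consensus_row(rows: list[MafRow], width: int) -> MafRow:
    votes = np.zeros((6, width), dtype=np.int32)  # A C G T N -
    for r in rows:
        codes = _text_codes(r.text)
        np.add.at(votes, (codes, np.arange(width)), 1)
    top = votes.max(axis=0)
    is_top = votes == top[None, :]
    n_base_top = is_top[:4].sum(axis=0)
    base_argmax = np.argmax(votes[:4], axis=0).astype(np.int8)
    other_top = is_top[4] | is_top[5]
    consensus = np.where(
        n_base_top == 1, base_argmax,                   # unique base, or base beats gap/N tie
        np.where(n_base_top >= 2, MISSING,              # tie among bases -> N
                 np.where(is_top[5] & ~is_top[4], GAP,  # gap wins outright
                          MISSING)))                    # N wins or gap/N tie
    # a unique top that is gap or N must not be overridden by base_argmax
    consensus = np.where((n_base_top == 0) & is_top[5] & ~is_top[4], GAP, consensus)
    consensus = np.where((n_base_top == 0) & is_top[4], MISSING, consensus)
    consensus = consensus.astype(np.int8)
    anchor = max(rows, key=lambda r: r.size)
    text = _codes_to_text(consensus)
    return MafRow(anchor.src, anchor.start, int((consensus != GAP).sum()),
                  anchor.strand, anchor.src_size, text)


# ---------------------------------------------------------------------------
# Reference projection
# ---------------------------------------------------------------------------

@dataclass
class ReferencedColumn:
    """One alignment column anchored at a reference base."""
    chrom: str
    pos: int  # 0-based on the reference
    pattern: dict[str, str]  # genome -> symbol (reference always present)


def extract_reference_columns(blocks: Iterable[MafBlock], reference: str
                              ) -> Iterator[ReferencedColumn]:
    """Yield one column per non-gap reference base, duplicates pre-merged.

    Blocks lacking the reference genome are skipped with a warning.  The
    iterator preserves block order; see :class:`GenomeAlignment` for the
    array-based container that also resolves overlapping reference coverage
    (last writer wins, logged).
    """
    for block in blocks:
        block = merge_duplicate_rows(block)
        ref_rows = [r for r in block.rows if r.genome == reference]
        if not ref_rows:
            logger.warning("block without reference genome %s skipped", reference)
            continue
        ref = ref_rows[0]
        codes = {r.genome: _text_codes(r.text) for r in block.rows}
        positions = ref.forward_positions()
        ref_codes = codes[reference]
        for col in np.flatnonzero(ref_codes != GAP):
            pattern = {}
            for genome, c in codes.items():
                sym = "ACGTN-"[c[col]]
                pattern[genome] = "N" if sym == "-" else sym
            yield ReferencedColumn(ref.chrom, int(positions[col]), pattern)


class GenomeAlignment:
    """Column matrices per reference chromosome, ready for scoring.

    ``chroms`` maps chromosome -> ``(positions, X)`` where ``positions`` is a
    strictly increasing int64 array of reference coordinates and ``X`` is an
    ``(n_positions, n_genomes)`` int8 code matrix (4 = missing) in the order
    of ``genomes``.
    """

    def __init__(self, reference: str, genomes: list[str],
                 chroms: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.reference = reference
        self.genomes = genomes
        self.chroms = chroms

    @classmethod
    def from_blocks(cls, blocks: Iterable[MafBlock], reference: str,
                    genomes: Sequence[str] | None = None) -> "GenomeAlignment":
        blocks = list(blocks)
        if genomes is None:
            seen: dict[str, None] = {}
            for b in blocks:
                for g in b.genomes():
                    seen.setdefault(g, None)
            genomes = list(seen)
        genomes = list(genomes)
        gidx = {g: i for i, g in enumerate(genomes)}
        pos_chunks: dict[str, list[np.ndarray]] = {}
        mat_chunks: dict[str, list[np.ndarray]] = {}
        for block in blocks:
            block = merge_duplicate_rows(block)
            ref_rows = [r for r in block.rows if r.genome == reference]
            if not ref_rows:
                logger.warning("block without reference genome %s skipped",
                               reference)
                continue
            ref = ref_rows[0]
            ref_codes = _text_codes(ref.text)
            keep = ref_codes != GAP
            positions = ref.forward_positions()[keep]
            mat = np.full((int(keep.sum()), len(genomes)), MISSING, dtype=np.int8)
            for r in block.rows:
                if r.genome not in gidx:
                    continue
                c = _text_codes(r.text)[keep]
                mat[:, gidx[r.genome]] = np.where(c == GAP, MISSING, c)
            pos_chunks.setdefault(ref.chrom, []).append(positions)
            mat_chunks.setdefault(ref.chrom, []).append(mat)
        chroms = {}
        for chrom in pos_chunks:
            pos = np.concatenate(pos_chunks[chrom])
            mat = np.vstack(mat_chunks[chrom])
            # later blocks win at duplicated reference positions
            uniq, first_rev = np.unique(pos[::-1], return_index=True)
            take = len(pos) - 1 - first_rev
            if len(uniq) != len(pos):
                logger.warning(
                    "%d reference positions on %s covered by more than one "
                    "block; later block wins", len(pos) - len(uniq), chrom)
            chroms[chrom] = (uniq.astype(np.int64), mat[take])
        return cls(reference, genomes, chroms)

    def n_positions(self) -> int:
        return sum(len(pos) for pos, _ in self.chroms.values())
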