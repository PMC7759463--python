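"""Score-to-significance transformation and single-base calls.

Signed conservation scores encode -log10 p-values; this module converts
them back to p-values, applies Benjamini-Hochberg step-up adjustment over
the full set of scored sites (conserved and accelerated tails corrected
jointly by default), and calls every base with q below the cutoff as
significantly conserved or accelerated.  It also produces the cumulative
call curve (fraction of the genome called as the p-value rank grows) and a
simulation-based detectability threshold: the weakest conservation, as a
fraction of the neutral rate, that the tree still has power to call.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation_scoring import ScoreTrack, _score_matrix
from .phylo_core import PhyloTree, SubstitutionModel

DEFAULT_ALPHA = 0.05


def scores_to_pvalues(track: ScoreTrack) -> pd.DataFrame:
    """Per scored site: p = 10**(-|score|), direction from the score sign.

    A score of exactly zero has p = 1 and by convention the conserved
    direction (it can never be called at any sensible cutoff).
    """
    df = track.all_scores()
    score = df["score"].to_numpy()
    return pd.DataFrame({
        "chrom": df["chrom"], "pos": df["pos"], "score": score,
        "pvalue": np.power(10.0, -np.abs(score)),
        "direction": np.where(score < 0, "accelerated", "conserved"),
    })


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values on the full vector.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values,
    returned in the input order and clipped at 1.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] / (np.arange(1, n + 1) / n)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


@dataclass
class QValueTrack:
    """Scored sites with p, q and direction; one table for the genome."""
    table: pd.DataFrame  # chrom, pos, score, pvalue, qvalue, direction
    joint: bool = True


def make_qvalue_track(track: ScoreTrack, joint: bool = True) -> QValueTrack:
    """Adjust all scored sites; ``joint=False`` corrects the conserved and
    accelerated tails separately (off by default)."""
    df = scores_to_pvalues(track)
    q = np.empty(len(df))
    if joint or len(df) == 0:
        q = bh_qvalues(df["pvalue"].to_numpy())
    else:
        for direction in ("conserved", "accelerated"):
            m = (df["direction"] == direction).to_numpy()
            if m.any():
                q[m] = bh_qvalues(df["pvalue"].to_numpy()[m])
    df = df.assign(qvalue=q)
    return QValueTrack(df, joint=joint)


@dataclass
class CallSet:
    """Single-base BED intervals called at q < alpha.

    ``score_thresholds`` records the realized |score| cutoff per direction
    (the smallest significant score magnitude among the calls).
    """
    table: pd.DataFrame  # chrom, start, end, direction, qvalue, score
    alpha: float
    score_thresholds: dict = field(default_factory=dict)

    def positions(self, chrom: str, direction: str | None = None) -> np.ndarray:
        t = self.table[self.table["chrom"] == chrom]
        if direction is not None:
            t = t[t["direction"] == direction]
        return t["start"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.table.itertuples(index=False):
                neglogq = -np.log10(max(row.qvalue, 1e-300))
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t"
                         f"{row.direction}\t{neglogq:.4f}\n")


def call_significant(qtrack: QValueTrack, alpha: float = DEFAULT_ALPHA) -> CallSet:
    """Exactly the sites with q < alpha, labeled by direction."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = qtrack.table
    hit = df[df["qvalue"] < alpha]
    table = pd.DataFrame({
        "chrom": hit["chrom"].to_numpy(),
        "start": hit["pos"].to_numpy(),
        "end": hit["pos"].to_numpy() + 1,
        "direction": hit["direction"].to_numpy(),
        "qvalue": hit["qvalue"].to_numpy(),
        "score": hit["score"].to_numpy(),
    })
    thresholds = {}
    for direction in ("conserved", "accelerated"):
        s = table.loc[table["direction"] == direction, "score"]
        if len(s):
            thresholds[direction] = float(np.abs(s).min())
    return CallSet(table, alpha, thresholds)


def cumulative_call_curve(qtrack: QValueTrack, genome_size: int | None = None,
                          alpha: float = DEFAULT_ALPHA
                          ) -> tuple[pd.DataFrame, float]:
    """Cumulative genome fraction covered as columns are taken from the
    smallest p-value upward, plus the rank fraction at the FDR cutoff.

    ``genome_size`` defaults to the number of scored sites, in which case
    the curve ends at 1.  The returned cutoff fraction marks where q
    crosses ``alpha``; the curve beyond it corresponds to non-significant
    columns.
    """
    df = qtrack.table
    n = len(df)
    if n == 0:
        return pd.DataFrame({"rank_fraction": [], "genome_fraction": []}), 0.0
    if genome_size is None:
        genome_size = n
    curve = pd.DataFrame({
        "rank_fraction": np.arange(1, n + 1) / n,
        "genome_fraction": np.arange(1, n + 1) / genome_size,
    })
    n_called = int((df["qvalue"] < alpha).sum())
    return curve, n_called / n


@dataclass
class DetectabilityResult:
    threshold: float
    power_table: pd.DataFrame  # rate, power


def detectability_threshold(tree: PhyloTree, model: SubstitutionModel,
                            alpha: float = DEFAULT_ALPHA,
                            rate_grid: Sequence[float] | None = None,
                            replicates: int = 3,
                            seed=None,
                            n_signal: int = 100,
                            background_ratio: int = 19,
                            power_target: float = 0.5) -> DetectabilityResult:
    """Largest rate multiplier in the grid still detectable as conserved.

    For each grid rate r, columns simulated at r are embedded in a
    background of neutral columns (19 neutral per signal column, i.e. a 95%
    neutral genome), scored, BH-adjusted jointly, and called at ``alpha``.
    "Detectable" means at least ``power_target`` of the signal columns are
    called conserved, averaged over replicates.  Returns 0.0 when no
    non-zero grid rate is detectable.  Statistical power grows with the
    total branch length of the tree, so the threshold is non-decreasing in
    tree depth.
    """
    from .synthetic_data import simulate_columns
    if rate_grid is None:
        rate_grid = np.round(np.arange(0.0, 1.0, 0.1), 10)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for r in rate_grid:
        powers = []
        for _ in range(replicates):
            Xs = simulate_columns(tree, model, n_signal, scale=float(r), rng=rng)
            Xn = simulate_columns(tree, model, n_signal * background_ratio,
                                  scale=1.0, rng=rng)
            X = np.vstack([Xs, Xn])
            res = _score_matrix(tree, model, X)
            p = res["pvalue"]
            conserved = res["score"] > 0
            q = bh_qvalues(p)
            called = (q < alpha) & conserved
            powers.append(called[:n_signal].mean())
        rows.append((float(r), float(np.mean(powers))))
    table = pd.DataFrame(rows, columns=["rate", "power"])
    detectable = table.loc[table["power"] >= power_target, "rate"]
    threshold = float(detectable.max()) if len(detectable) else 0.0
    return DetectabilityResult(threshold, table)
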