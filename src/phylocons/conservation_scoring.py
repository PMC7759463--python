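"""Per-column conservation/acceleration (CONACC) scoring.

Each reference-anchored alignment column gets a maximum-likelihood rate
multiplier r of the neutral model, a likelihood-ratio statistic against the
neutral rate r = 1, and a signed score ``sign(1 - r) * -log10 p`` where the
p-value comes from the chi-square distribution with one degree of freedom.
Positive scores indicate conservation, negative scores acceleration.

The chi-square reference is a deliberate simplification of the boundary
mixture at r = 0; the null simulation property (p-values stochastically
larger than uniform) is what guarantees the calls stay conservative.
Columns with fewer than two informative genomes carry too little signal to
classify and are emitted unscored.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alignment_io import GenomeAlignment
from .neutral_model import NeutralModel, ThreeRateModel
from .phylo_core import (MISSING, PhyloTree, SubstitutionModel,
                         encode_columns, fit_column_scales,
                         site_log_likelihoods)

MIN_INFORMATIVE = 2
R_MAX = 10.0
_P_FLOOR = 1e-300


@dataclass
class SiteScore:
    chrom: str
    pos: int
    rhat: float
    lrt: float
    pvalue: float
    score: float
    n_informative: int


class ScoreTrack:
    """Dense per-chromosome score arrays (one frame per chromosome).

    Frames have columns ``pos, rhat, lrt, pvalue, score, n_informative``
    with positions strictly increasing; unscored reference positions are
    simply absent.
    """

    def __init__(self, frames: dict[str, pd.DataFrame]):
        for chrom, df in frames.items():
            if not np.all(np.diff(df["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        self.frames = frames

    def all_scores(self) -> pd.DataFrame:
        parts = [df.assign(chrom=c) for c, df in self.frames.items()]
        if not parts:
            return pd.DataFrame(
                columns=["pos", "rhat", "lrt", "pvalue", "score",
                         "n_informative", "chrom"])
        return pd.concat(parts, ignore_index=True)

    def n_scored(self) -> int:
        return sum(len(df) for df in self.frames.values())


def _score_matrix(tree: PhyloTree, model: SubstitutionModel, X: np.ndarray
                  ) -> dict[str, np.ndarray]:
    """Vectorized CONACC scoring of a code matrix (all columns assumed to
    have enough informative genomes). Pattern compression is applied so
    repeated columns are fitted once."""
    X = np.atleast_2d(np.asarray(X, dtype=np.int8))
    patterns, inverse = np.unique(X, axis=0, return_inverse=True)
    rhat_u, ll_hat_u = fit_column_scales(tree, model, patterns, r_max=R_MAX)
    ll1_u = site_log_likelihoods(tree, model, patterns, scale=1.0)
    lrt_u = np.maximum(2.0 * (ll_hat_u - ll1_u), 0.0)
    p_u = np.clip(chi2.sf(lrt_u, df=1), _P_FLOOR, 1.0)
    sign_u = np.where(np.abs(rhat_u - 1.0) < 1e-9, 0.0,
                      np.where(rhat_u < 1.0, 1.0, -1.0))
    score_u = sign_u * (-np.log10(p_u))
    score_u[p_u >= 1.0] = 0.0
    return {
        "rhat": rhat_u[inverse],
        "lrt": lrt_u[inverse],
        "pvalue": p_u[inverse],
        "score": score_u[inverse],
    }


def fit_column_scale(tree: PhyloTree, model: SubstitutionModel,
                     column: Mapping[str, str]) -> float | None:
    """ML rate multiplier for one column; None when fewer than two genomes
    are informative."""
    X = encode_columns([column], tree.leaf_labels)
    if int((X != MISSING).sum()) < MIN_INFORMATIVE:
        return None
    rhat, _ = fit_column_scales(tree, model, X, r_max=R_MAX)
    return float(rhat[0])


def conacc_score(tree: PhyloTree, model: SubstitutionModel,
                 column: Mapping[str, str], chrom: str = "", pos: int = -1
                 ) -> SiteScore | None:
    """Score one column; None when uninformative."""
    X = encode_columns([column], tree.leaf_labels)
    n_inf = int((X != MISSING).sum())
    if n_inf < MIN_INFORMATIVE:
        return None
    res = _score_matrix(tree, model, X)
    return SiteScore(chrom, pos, float(res["rhat"][0]), float(res["lrt"][0]),
                     float(res["pvalue"][0]), float(res["score"][0]), n_inf)


def _tree_order_matrix(alignment: GenomeAlignment, tree: PhyloTree,
                       X: np.ndarray) -> np.ndarray:
    """Reorder alignment genome columns into tree leaf order; tree leaves
    absent from the alignment become missing, alignment rows that are not
    leaves (e.g. reconstructed ancestors) are dropped."""
    out = np.full((X.shape[0], len(tree.leaf_labels)), MISSING, dtype=np.int8)
    col = {g: i for i, g in enumerate(alignment.genomes)}
    for k, leaf in enumerate(tree.leaf_labels):
        if leaf in col:
            out[:, k] = X[:, col[leaf]]
    return out


def score_genome(alignment: GenomeAlignment,
                 model: ThreeRateModel | NeutralModel,
                 class_map: Mapping[str, str] | None = None) -> ScoreTrack:
    """Score every scorable reference base under its class-scaled model.

    With a :class:`ThreeRateModel`, every chromosome must be classified
    before scoring starts (macro/micro/sex); a plain :class:`NeutralModel`
    applies one model everywhere.  Deterministic: identical inputs give
    identical tracks.
    """
    three_rate = isinstance(model, ThreeRateModel)
    if three_rate:
        missing = [c for c in alignment.chroms if class_map is None
                   or c not in class_map]
        if missing:
            raise ValueError(f"unclassified chromosomes: {missing}")
    frames = {}
    for chrom, (pos, X) in alignment.chroms.items():
        if three_rate:
            tree, sub = model.model_for(class_map[chrom])
        else:
            tree, sub = model.tree, model.model
        Xt = _tree_order_matrix(alignment, tree, X)
        n_inf = (Xt != MISSING).sum(axis=1)
        ok = n_inf >= MIN_INFORMATIVE
        if not ok.any():
            frames[chrom] = pd.DataFrame(
                {"pos": pos[:0], "rhat": [], "lrt": [], "pvalue": [],
                 "score": [], "n_informative": []})
            continue
        res = _score_matrix(tree, sub, Xt[ok])
        frames[chrom] = pd.DataFrame({
            "pos": pos[ok], "rhat": res["rhat"], "lrt": res["lrt"],
            "pvalue": res["pvalue"], "score": res["score"],
            "n_informative": n_inf[ok]})
    return ScoreTrack(frames)


def column_rate_distribution(alignment: GenomeAlignment,
                             model: ThreeRateModel | NeutralModel,
                             n: int, seed,
                             class_map: Mapping[str, str] | None = None,
                             bins=None) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Fitted rate multipliers at ``n`` randomly sampled scorable sites.

    Returns the per-site table plus a histogram (counts, bin edges).
    Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    three_rate = isinstance(model, ThreeRateModel)
    candidates = []
    for chrom, (pos, X) in alignment.chroms.items():
        tree = model.base.tree if three_rate else model.tree
        Xt = _tree_order_matrix(alignment, tree, X)
        ok = (Xt != MISSING).sum(axis=1) >= MIN_INFORMATIVE
        for i in np.flatnonzero(ok):
            candidates.append((chrom, i))
    if n > len(candidates):
        raise ValueError(f"requested {n} sites from {len(candidates)} scorable")
    pick = rng.choice(len(candidates), size=n, replace=False)
    chosen: dict[str, list[int]] = {}
    for j in sorted(pick):
        chrom, i = candidates[j]
        chosen.setdefault(chrom, []).append(i)
    rows = []
    for chrom, idx in chosen.items():
        pos, X = alignment.chroms[chrom]
        if three_rate:
            tree, sub = model.model_for(class_map[chrom])
        else:
            tree, sub = model.tree, model.model
        Xt = _tree_order_matrix(alignment, tree, X)[idx]
        rhat, _ = fit_column_scales(tree, sub, Xt, r_max=R_MAX)
        for p, r in zip(np.asarray(idx), rhat):
            rows.append((chrom, int(pos[p]), float(r)))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "rhat"])
    if bins is None:
        bins = np.linspace(0.0, 2.0, 41)
    counts, edges = np.histogram(table["rhat"], bins=bins)
    return table, counts, edges


def write_wiggle(track: ScoreTrack, path, field: str = "score",
                 decimals: int = 4) -> None:
    """fixedStep wiggle output (1-based starts per the format standard)."""
    with open(path, "w") as fh:
        for chrom, df in track.frames.items():
            pos = df["pos"].to_numpy()
            val = df[field].to_numpy()
            if len(pos) == 0:
                continue
            breaks = np.flatnonzero(np.diff(pos) != 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [len(pos)]])
            for s, e in zip(starts, ends):
                fh.write(f"fixedStep chrom={chrom} start={pos[s] + 1} step=1\n")
                for v in val[s:e]:
                    fh.write(f"{v:.{decimals}f}\n")
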