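"""Neutral substitution model estimation and chromosome-class scaling.

The null hypothesis for conservation scoring is a neutral model: a fixed
tree topology with branch lengths and a reversible nucleotide model, fitted
to putatively unconstrained sites (ancestral repeats).  Because avian
macro-, micro- and sex chromosomes evolve at measurably different neutral
rates, the base model is additionally scaled per chromosome class, giving
the three-rate model used for all scoring.

Fitting is coordinate ascent: per-edge bounded 1-D optimization of branch
lengths alternating with joint optimization of the exchangeabilities, with
equilibrium frequencies fixed at the empirical base composition of the
training columns.  Training columns are weighted by pattern multiplicity.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .phylo_core import (MISSING, PhyloTree, SubstitutionModel,
                         site_log_likelihoods)

MACRO_CHROMOSOMES = frozenset(str(i) for i in range(1, 9))
SEX_CHROMOSOMES = frozenset({"Z", "W"})
CLASSES = ("macro", "micro", "sex")


@dataclass
class NeutralModel:
    """A fitted neutral model with provenance (training size, seed, class)."""
    tree: PhyloTree
    model: SubstitutionModel
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {"tree": self.tree.to_newick(), **self.model.to_dict(),
             "provenance": self.provenance}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "NeutralModel":
        d = json.loads(text)
        return cls(PhyloTree.from_newick(d["tree"]),
                   SubstitutionModel(d["frequencies"], d["exchangeabilities"]),
                   d.get("provenance", {}))


@dataclass
class ThreeRateModel:
    """Base neutral model plus one branch-length multiplier per class."""
    base: NeutralModel
    scales: dict[str, float]

    def __post_init__(self):
        missing = [c for c in CLASSES if c not in self.scales]
        if missing:
            raise ValueError(f"scale missing for classes: {missing}")
        if any(s <= 0 for s in self.scales.values()):
            raise ValueError("class scales must be positive")

    def model_for(self, klass: str) -> tuple[PhyloTree, SubstitutionModel]:
        return self.base.tree.rescaled(self.scales[klass]), self.base.model

    def to_json(self) -> str:
        d = json.loads(self.base.to_json())
        d["class_scales"] = self.scales
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ThreeRateModel":
        d = json.loads(text)
        return cls(NeutralModel.from_json(text), d["class_scales"])


# ---------------------------------------------------------------------------
# Chromosome classification
# ---------------------------------------------------------------------------

def classify_chromosome(chrom: str, karyotype: Mapping[str, str] | None = None
                        ) -> str:
    """Assign a chromosome to macro/micro/sex.

    Autosomes 1-8 are macro-chromosomes, Z and W are sex chromosomes, and
    every other autosome is a micro-chromosome.  ``karyotype`` optionally
    maps a chromosome id to its karyotype token (an autosome number or
    Z/W) when the id itself is not informative; otherwise the token is the
    id with any leading ``chr`` stripped.
    """
    if karyotype is not None:
        if chrom not in karyotype:
            raise KeyError(chrom)
        token = karyotype[chrom]
    else:
        token = chrom
    if token.lower().startswith("chr"):
        token = token[3:]
    token = token.strip()
    if token.upper() in SEX_CHROMOSOMES:
        return "sex"
    if token.isdigit():
        return "macro" if token in MACRO_CHROMOSOMES else "micro"
    raise ValueError(f"cannot classify chromosome id {chrom!r}")


def load_class_map(path) -> dict[str, str]:
    """Read a two-column TSV of chromosome id and class (or karyotype token)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, value = line.split("\t")[:2]
            value = value.strip()
            out[chrom] = value if value in CLASSES else classify_chromosome(value)
    return out


# ---------------------------------------------------------------------------
# Training-site sampling
# ---------------------------------------------------------------------------

def sample_training_sites(regions: Sequence[tuple[str, int, int]], n: int,
                          seed) -> list[tuple[str, int]]:
    """Sample ``n`` distinct bases uniformly without replacement from BED-style
    ``(chrom, start, end)`` intervals; reproducible under ``seed``."""
    regions = list(regions)
    if not regions:
        raise ValueError("no regions to sample from")
    sizes = np.array([e - s for _, s, e in regions], dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValueError("regions must be non-empty half-open intervals")
    total = int(sizes.sum())
    if n > total:
        raise ValueError(f"requested {n} sites from {total} available bases")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = np.sort(rng.choice(total, size=n, replace=False))
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    which = np.searchsorted(offsets, flat, side="right") - 1
    out = []
    for f, w in zip(flat, which):
        chrom, start, _ = regions[w]
        out.append((chrom, int(start + f - offsets[w])))
    return out


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def compress_patterns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique column patterns and their multiplicities."""
    X = np.atleast_2d(np.asarray(X, dtype=np.int8))
    patterns, counts = np.unique(X, axis=0, return_counts=True)
    return patterns, counts.astype(np.float64)


def empirical_frequencies(X: np.ndarray, weights: np.ndarray | None = None,
                          pseudocount: float = 0.5) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=np.int8))
    if weights is None:
        weights = np.ones(X.shape[0])
    counts = np.full(4, pseudocount)
    for b in range(4):
        counts[b] += ((X == b) * weights[:, None]).sum()
    return counts / counts.sum()


def _weighted_ll(tree, model, patterns, weights, scale=1.0) -> float:
    return float(weights @ site_log_likelihoods(tree, model, patterns, scale=scale))


def fit_neutral_model(X: np.ndarray, topology: PhyloTree, *,
                      optimize_exchangeabilities: bool = True,
                      frequencies: Sequence[float] | None = None,
                      tol: float = 1e-6, max_iter: int = 50,
                      max_branch_length: float = 20.0, xatol: float = 1e-8,
                      provenance: dict | None = None) -> NeutralModel:
    """Fit branch lengths and GTR parameters to training columns.

    ``X`` is an ``(n_columns, n_leaves)`` code matrix in the leaf order of
    ``topology``.  Equilibrium frequencies default to the empirical base
    composition.  Coordinate ascent stops when the joint log-likelihood
    gains less than ``tol`` in a full sweep; the likelihood is
    non-decreasing across sweeps by construction.

    All-identical training data drives every branch length to the zero
    boundary (a warning is issued).
    """
    patterns, weights = compress_patterns(X)
    if patterns.shape[0] == 0:
        raise ValueError("no training columns")
    informative = (patterns != MISSING).sum(axis=1) >= 2
    if not informative.any():
        raise ValueError("no informative training columns")
    pi = np.asarray(frequencies, float) if frequencies is not None else \
        empirical_frequencies(patterns, weights)
    tree = topology.copy()
    if not np.any(tree.lengths > 0):
        tree.lengths[:] = 0.1
        tree.lengths[tree.root] = 0.0
    exch = np.ones(6)
    model = SubstitutionModel(pi, exch)
    ll = _weighted_ll(tree, model, patterns, weights)
    edges = [int(i) for i in tree.postorder if i != tree.root]
    for _ in range(max_iter):
        ll_prev = ll
        for e in edges:
            def neg(t, e=e):
                tree.lengths[e] = t
                return -_weighted_ll(tree, model, patterns, weights)
            res = minimize_scalar(neg, bounds=(0.0, max_branch_length),
                                  method="bounded",
                                  options={"xatol": xatol})
            tree.lengths[e] = float(res.x)
        if optimize_exchangeabilities:
            def neg_exch(logx):
                m = SubstitutionModel(pi, np.append(np.exp(logx), 1.0))
                return -_weighted_ll(tree, m, patterns, weights)
            res = minimize(neg_exch, np.log(exch[:5]), method="L-BFGS-B",
                           options={"maxiter": 200})
            exch = np.append(np.exp(res.x), 1.0)
            model = SubstitutionModel(pi, exch)
        ll = _weighted_ll(tree, model, patterns, weights)
        if ll - ll_prev < tol:
            break
    if float(tree.lengths.sum()) < 1e-6:
        warnings.warn("fitted branch lengths are at the zero boundary "
                      "(training data may be invariant)")
    prov = {"n_sites": int(np.atleast_2d(X).shape[0])}
    prov.update(provenance or {})
    return NeutralModel(tree, model, prov)


def fit_class_scale(X: np.ndarray, base: NeutralModel,
                    bounds: tuple[float, float] = (1e-3, 10.0)) -> float:
    """Single branch-length multiplier maximizing the class likelihood.

    All other parameters of the base model stay frozen; the likelihood in
    the scale is unimodal in practice and a bounded Brent search suffices.
    """
    patterns, weights = compress_patterns(X)
    if patterns.shape[0] == 0:
        raise ValueError("empty chromosome class")
    def neg(s):
        return -_weighted_ll(base.tree, base.model, patterns, weights, scale=s)
    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x)


def fit_three_rate_model(class_columns: Mapping[str, np.ndarray],
                         base: NeutralModel) -> ThreeRateModel:
    """Scale the base model separately for macro, micro and sex columns."""
    scales = {c: fit_class_scale(Xc, base) for c, Xc in class_columns.items()}
    return ThreeRateModel(base, scales)
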