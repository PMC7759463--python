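"""Phylogenetic trees, reversible nucleotide substitution models and column
likelihoods.

This module is the numerical kernel of the package.  A :class:`PhyloTree`
holds a rooted phylogeny with branch lengths measured in expected
substitutions per site; a :class:`SubstitutionModel` holds a normalized
general time-reversible (GTR) rate matrix.  Column log-likelihoods are
computed with Felsenstein's pruning algorithm, vectorized across columns so
that whole chromosomes can be scored in a handful of numpy passes.

Transition probabilities are obtained from the eigendecomposition of the
symmetrized rate matrix (reversibility guarantees a real spectrum); tiny
negative probabilities produced by round-off are clamped to zero and rows
renormalized.  Missing data (gap, N, or an absent alignment row) is treated
as fully missing and marginalized.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

#: Ordered nucleotide alphabet used throughout the package.
ALPHABET = "ACGT"
#: Integer code for a fully missing observation (gap, N, absent row).
MISSING = 4

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE.update({c.lower(): i for i, c in enumerate(ALPHABET)})

#: Canonical ordering of the six GTR exchangeabilities.
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_EXCH_INDEX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def encode_base(symbol: str) -> int:
    """Map a nucleotide symbol to its integer code; anything that is not an
    unambiguous base (gap, N, IUPAC ambiguity, ...) codes as :data:`MISSING`.
    """
    return _CODE.get(symbol, MISSING)


def encode_sequence(text: str) -> np.ndarray:
    """Vectorized :func:`encode_base` over a string."""
    raw = np.frombuffer(text.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, MISSING, dtype=np.int8)
    for i, ch in enumerate(ALPHABET):
        out[raw == ord(ch)] = i
    return out


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.int8)].tobytes().decode("ascii")


class TreeError(ValueError):
    pass


class PhyloTree:
    """A rooted tree stored as flat parent/length arrays.

    Nodes are indexed ``0 .. n_nodes-1``; ``parent[i]`` is ``-1`` for the
    single root.  Branch lengths are expected substitutions per site and
    must be finite and non-negative (the root's length is forced to zero).
    Leaf labels are unique genome identifiers; internal nodes may carry
    ancestor labels (reconstructed-ancestor "genomes").
    """

    def __init__(self, labels: Sequence[str | None], parent: Sequence[int],
                 lengths: Sequence[float]):
        self.labels = [lbl if lbl else None for lbl in labels]
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64).copy()
        n = len(self.labels)
        if not (len(self.parent) == len(self.lengths) == n):
            raise TreeError("labels, parent and lengths must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.lengths[self.root] = 0.0
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise TreeError("branch lengths must be finite and non-negative")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        leaf_labels = [self.labels[i] for i in range(n) if not self.children[i]]
        if any(lbl is None for lbl in leaf_labels):
            raise TreeError("every leaf must carry a label")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise TreeError("leaf labels must be unique")
        self.postorder = self._postorder()
        self.leaf_indices = np.array(
            [i for i in self.postorder if not self.children[i]], dtype=np.int64)
        self.leaf_labels: list[str] = [self.labels[i] for i in self.leaf_indices]
        self._leaf_col = {int(i): k for k, i in enumerate(self.leaf_indices)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string (comments stripped, underscores preserved).

        Branch lengths are required on all non-root edges; the root length,
        if present, is ignored.
        """
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:
            raise TreeError(f"cannot parse newick: {exc}") from exc
        nodes = list(dt.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        labels, parent, lengths = [], [], []
        for i, nd in enumerate(nodes):
            lbl = nd.taxon.label if nd.taxon is not None else nd.label
            labels.append(lbl)
            if nd.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise TreeError(
                        f"branch length missing on edge above {lbl or 'an internal node'}")
                lengths.append(float(nd.edge.length))
        return cls(labels, parent, lengths)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            lbl = self.labels[i] or ""
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                body = f"({inner}){lbl}"
            else:
                body = lbl
            if i == self.root:
                return body
            return f"{body}:{self.lengths[i]:.10g}"
        return fmt(self.root) + ";"

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def index_of(self, label: str) -> int:
        for i, lbl in enumerate(self.labels):
            if lbl == label:
                return i
        raise KeyError(label)

    def leaves_below(self, node: int) -> list[str]:
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if self.is_leaf(i):
                out.append(self.labels[i])
            else:
                stack.extend(self.children[i])
        return out

    def internal_labels_below(self, node: int) -> list[str]:
        """Labels of internal nodes in the subtree rooted at ``node``
        (including ``node`` itself), skipping unlabeled nodes."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if not self.is_leaf(i):
                if self.labels[i]:
                    out.append(self.labels[i])
                stack.extend(self.children[i])
        return out

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.array(order, dtype=np.int64)

    def copy(self) -> "PhyloTree":
        return PhyloTree(list(self.labels), self.parent.copy(), self.lengths.copy())

    def rescaled(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        t = self.copy()
        t.lengths *= float(factor)
        t.lengths[t.root] = 0.0
        return t


def total_branch_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths, in expected substitutions per site."""
    return float(tree.lengths.sum())


class SubstitutionModel:
    """Normalized general time-reversible nucleotide model.

    Parameters
    ----------
    frequencies
        Equilibrium frequencies over A, C, G, T; strictly positive, summing
        to one within 1e-6 (renormalized exactly).
    exchangeabilities
        The six symmetric rate parameters in :data:`EXCHANGE_ORDER`.

    The instantaneous matrix satisfies detailed balance
    (``pi_i Q_ij == pi_j Q_ji``), rows sum to zero and the expected rate is
    one substitution per site (``-sum_i pi_i Q_ii == 1``).
    """

    def __init__(self, frequencies: Sequence[float],
                 exchangeabilities: Sequence[float] = (1, 1, 1, 1, 1, 1)):
        pi = np.asarray(frequencies, dtype=np.float64)
        ex = np.asarray(exchangeabilities, dtype=np.float64)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("frequencies must be four strictly positive values")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to one")
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("exchangeabilities must be six positive values")
        pi = pi / pi.sum()
        R = np.zeros((4, 4))
        for s, (i, j) in zip(ex, _EXCH_INDEX):
            R[i, j] = R[j, i] = s
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        self.frequencies = pi
        self.exchangeabilities = ex
        self.Q = Q
        sp = np.sqrt(pi)
        S = (sp[:, None] * Q) / sp[None, :]
        S = (S + S.T) / 2.0
        w, V = np.linalg.eigh(S)
        self._w = w
        self._U = V / sp[:, None]          # P(t) = U diag(exp(w t)) W
        self._W = V.T * sp[None, :]

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        return cls([0.25] * 4)

    def transition_matrix(self, t: float) -> np.ndarray:
        """4x4 stochastic matrix ``P(t) = exp(Q t)``; ``t`` must be >= 0."""
        if not np.isfinite(t) or t < 0:
            raise ValueError("branch length must be finite and non-negative")
        if t == 0.0:
            return np.eye(4)
        P = (self._U * np.exp(self._w * t)) @ self._W
        P = np.maximum(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def to_dict(self) -> dict:
        return {
            "frequencies": self.frequencies.tolist(),
            "exchangeabilities": self.exchangeabilities.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubstitutionModel":
        return cls(d["frequencies"], d["exchangeabilities"])


def build_rate_matrix(exchangeabilities: Sequence[float],
                      frequencies: Sequence[float]) -> SubstitutionModel:
    """Construct a normalized reversible model from six exchangeabilities and
    a frequency simplex (validation errors on non-positive inputs)."""
    return SubstitutionModel(frequencies, exchangeabilities)


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


# ---------------------------------------------------------------------------
# Pruning likelihoods
# ---------------------------------------------------------------------------

_ONEHOT = np.vstack([np.eye(4), np.ones((1, 4))])  # row MISSING marginalizes


def encode_columns(columns: Iterable[Mapping[str, str]],
                   leaf_labels: Sequence[str]) -> np.ndarray:
    """Encode per-genome symbol mappings into an ``(n_columns, n_leaves)``
    int8 matrix; genomes absent from a column code as missing."""
    cols = list(columns)
    X = np.full((len(cols), len(leaf_labels)), MISSING, dtype=np.int8)
    pos = {lbl: k for k, lbl in enumerate(leaf_labels)}
    for r, col in enumerate(cols):
        for genome, symbol in col.items():
            if genome in pos:
                X[r, pos[genome]] = encode_base(symbol)
    return X


def site_log_likelihoods(tree: PhyloTree, model: SubstitutionModel,
                         X: np.ndarray, scale=1.0) -> np.ndarray:
    """Log-likelihood of each alignment column under the pruning algorithm.

    Parameters
    ----------
    X
        ``(n_columns, n_leaves)`` int8 codes in leaf order
        ``tree.leaf_labels`` (code 4 = missing, marginalized).
    scale
        Rate multiplier applied to every branch length; a scalar or a
        per-column array.

    Columns with zero non-missing genomes have likelihood one (log zero):
    marginalizing everything leaves only the stationary distribution, which
    integrates to one.  Per-node rescaling keeps partials in range on large
    trees.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.int8))
    n = X.shape[0]
    if X.shape[1] != len(tree.leaf_labels):
        raise ValueError("column matrix width must match the number of leaves")
    per_site = np.ndim(scale) > 0
    if per_site:
        scale = np.asarray(scale, dtype=np.float64)
        if scale.shape != (n,):
            raise ValueError("per-column scale must have one value per column")
        if np.any(scale < 0):
            raise ValueError("scale must be non-negative")
    elif scale < 0:
        raise ValueError("scale must be non-negative")

    partial: dict[int, np.ndarray] = {}
    logacc = np.zeros(n)
    for node in tree.postorder:
        node = int(node)
        if tree.is_leaf(node):
            partial[node] = _ONEHOT[X[:, tree._leaf_col[node]]]
            continue
        acc = None
        for child in tree.children[node]:
            L = partial.pop(child)
            t = tree.lengths[child]
            if per_site:
                e = np.exp(model._w[None, :] * (t * scale)[:, None])
                contrib = ((L @ model._W.T) * e) @ model._U.T
                np.maximum(contrib, 0.0, out=contrib)
            else:
                contrib = L @ model.transition_matrix(t * scale).T
            acc = contrib if acc is None else acc * contrib
        m = acc.max(axis=1)
        safe = m > 0
        acc[safe] /= m[safe, None]
        with np.errstate(divide="ignore"):
            logacc += np.where(safe, np.log(np.where(safe, m, 1.0)), -np.inf)
        partial[node] = acc
    lik = partial[tree.root] @ model.frequencies
    with np.errstate(divide="ignore"):
        return np.log(lik) + logacc


def column_loglik(tree: PhyloTree, model: SubstitutionModel,
                  column: Mapping[str, str], scale: float = 1.0) -> float:
    """Log-likelihood of a single column given as genome -> symbol.

    Genomes in the column must be leaves of the tree; leaves absent from the
    column are treated as missing.  An all-missing column returns 0.0 (the
    uninformative sentinel; see :func:`informative_count`).
    """
    leaves = set(tree.leaf_labels)
    unknown = [g for g in column if g not in leaves]
    if unknown:
        raise ValueError(f"column genomes not in tree: {unknown}")
    X = encode_columns([column], tree.leaf_labels)
    return float(site_log_likelihoods(tree, model, X, scale=scale)[0])


def informative_count(column: Mapping[str, str]) -> int:
    """Number of genomes with a non-missing base in the column."""
    return sum(1 for s in column.values() if encode_base(s) != MISSING)


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def fit_column_scales(tree: PhyloTree, model: SubstitutionModel, X: np.ndarray,
                      r_max: float = 10.0, tol: float = 1e-6
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-column maximum-likelihood rate multiplier on ``[0, r_max]``.

    Golden-section search with per-column brackets, vectorized so each
    iteration is a single pruning pass over all columns.  Returns
    ``(r_hat, loglik_at_r_hat)``; multipliers below 1e-4 are reported as the
    boundary value 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.int8))
    n = X.shape[0]
    a = np.zeros(n)
    b = np.full(n, float(r_max))
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = -site_log_likelihoods(tree, model, X, scale=c)
    fd = -site_log_likelihoods(tree, model, X, scale=d)
    n_iter = int(np.ceil(np.log(tol / r_max) / np.log(_INVPHI)))
    for _ in range(n_iter):
        left = fc < fd  # minimum bracketed in [a, d]
        a_new = np.where(left, a, c)
        b_new = np.where(left, d, b)
        h = b_new - a_new
        # the interior point inherited from the previous bracket
        c_new = np.where(left, b_new - _INVPHI * h, d)
        d_new = np.where(left, c, a_new + _INVPHI * h)
        fd_inherit = fc      # valid where left (old c becomes new d)
        fc_inherit = fd      # valid where not left (old d becomes new c)
        x = np.where(left, c_new, d_new)
        fx = -site_log_likelihoods(tree, model, X, scale=x)
        fc = np.where(left, fx, fc_inherit)
        fd = np.where(left, fd_inherit, fx)
        a, b, c, d = a_new, b_new, c_new, d_new
    r_hat = (a + b) / 2.0
    r_hat[r_hat < 1e-4] = 0.0
    ll = site_log_likelihoods(tree, model, X, scale=r_hat)
    return r_hat, ll
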