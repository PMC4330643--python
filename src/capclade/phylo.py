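"""Distances, neighbor-joining, column bootstrap and LG+gamma likelihood.

The phylogeny stage is a deliberate desk-scale stand-in for a full ML
topology search: trees come from neighbor joining on protein distances,
support from a nonparametric bootstrap over the 139 core match columns,
and the substitution model (LG exchangeabilities, discrete-gamma rate
heterogeneity) enters through distance estimation and through fixed-
topology likelihood scoring, which also drives the model-frequency
comparison (model vs empirical amino-acid frequencies) and the estimation
of the gamma shape parameter.  Published bootstrap percentages from ML
searches are not expected to be reproduced numerically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from . import seqio
from .anchor import MultiAlignment
from .seqio import AMINO_ACIDS

KIMURA_CAP = 5.2
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SubstitutionModel:
    """Amino-acid substitution model: exchangeabilities S, frequencies pi,
    and a discrete-gamma rate distribution (mean-of-quantile rates).

    The generator Q = S diag(pi) is normalized to one expected
    substitution per site per unit branch length.
    """

    name: str = "LG"
    S: np.ndarray = None
    pi: np.ndarray = None
    alpha: float | None = None      # None: rates homogeneous
    n_categories: int = 4

    @classmethod
    def load(cls, name: str = "LG", alpha: float | None = None, n_categories: int = 4,
             frequencies: np.ndarray | None = None) -> "SubstitutionModel":
        S, pi = seqio.load_paml_matrix(name)
        if frequencies is not None:
            pi = np.asarray(frequencies, dtype=float)
            pi = pi / pi.sum()
        return cls(name=name, S=S, pi=pi, alpha=alpha, n_categories=n_categories)

    def with_frequencies(self, pi: np.ndarray) -> "SubstitutionModel":
        pi = np.asarray(pi, dtype=float)
        return replace(self, pi=pi / pi.sum())

    def with_alpha(self, alpha: float | None) -> "SubstitutionModel":
        return replace(self, alpha=alpha)

    def rate_matrix(self) -> np.ndarray:
        Q = self.S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(self.pi * np.diag(Q)).sum()
        return Q / mean_rate

    def _eigen(self):
        # symmetrize: B = D^{1/2} Q D^{-1/2} with D = diag(pi)
        cached = getattr(self, "_eigen_cache", None)
        if cached is not None:
            return cached
        Q = self.rate_matrix()
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2)
        object.__setattr__(self, "_eigen_cache", (w, U, sq))
        return w, U, sq

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), by eigendecomposition of the symmetrized Q."""
        w, U, sq = self._eigen()
        inner = (U * np.exp(w * t)[None, :]) @ U.T
        P = inner * (sq[None, :] / sq[:, None])
        return np.clip(P, 0.0, None)

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean of each quantile bin)."""
        if self.alpha is None:
            return np.ones(1)
        a, K = self.alpha, self.n_categories
        bounds = gamma_dist.ppf(np.arange(1, K) / K, a, scale=1.0 / a)
        edges = np.concatenate(([0.0], bounds, [np.inf]))
        upper = gammainc(a + 1, a * edges[1:])
        lower = gammainc(a + 1, a * edges[:-1])
        return K * (upper - lower)


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v


@dataclass
class TreeWithSupport:
    tree: dendropy.Tree
    n_replicates: int


def _encode_row(row: str) -> np.ndarray:
    """Residues to indices; gap and X become -1 (missing)."""
    return np.array([_AA_INDEX.get(c, -1) for c in row], dtype=np.int64)


def _p_distance(a: np.ndarray, b: np.ndarray) -> float:
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no mutually non-gap columns")
    return float((a[ok] != b[ok]).sum()) / n


def pairwise_distance(
    row_a: str, row_b: str, method: str = "kimura",
    model: SubstitutionModel | None = None,
) -> float:
    """Evolutionary distance between two gapped alignment rows.

    ``poisson``: -ln(1-p); ``kimura``: -ln(1 - p - 0.2 p^2), capped at
    5.2 when the argument is non-positive; ``lg_ml``: 1-D ML branch length
    under the model (gamma-aware when the model has a shape).
    """
    a, b = _encode_row(row_a), _encode_row(row_b)
    p = _p_distance(a, b)
    if method == "poisson":
        if p >= 1.0:
            return KIMURA_CAP
        return -math.log(1.0 - p)
    if method == "kimura":
        arg = 1.0 - p - 0.2 * p * p
        if arg <= 0:
            warnings.warn(
                f"Kimura distance undefined at p={p:.3f}; capped at {KIMURA_CAP}"
            )
            return KIMURA_CAP
        return -math.log(arg)
    if method == "lg_ml":
        model = model or SubstitutionModel.load("LG")
        return _ml_pair_distance(a, b, model)
    raise ValueError(f"unknown distance method {method!r}")


def _ml_pair_distance(a: np.ndarray, b: np.ndarray, model: SubstitutionModel) -> float:
    ok = (a >= 0) & (b >= 0)
    N = np.zeros((20, 20))
    np.add.at(N, (a[ok], b[ok]), 1.0)
    rates = model.category_rates()
    pi = model.pi

    def neg_lnl(t: float) -> float:
        mix = np.zeros((20, 20))
        for r in rates:
            mix += model.transition_matrix(t * r)
        mix /= len(rates)
        joint = np.clip(pi[:, None] * mix, 1e-300, None)
        return -float((N * np.log(joint)).sum())

    res = minimize_scalar(neg_lnl, bounds=(1e-8, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def distance_matrix(
    m: MultiAlignment, method: str = "kimura",
    model: SubstitutionModel | None = None,
) -> DistanceMatrix:
    n = len(m.ids)
    d = np.zeros((n, n))
    capped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n):
            for j in range(i + 1, n):
                dij = pairwise_distance(m.matrix[i], m.matrix[j], method, model)
                if dij >= KIMURA_CAP:
                    capped += 1
                d[i, j] = d[j, i] = dij
    if capped:
        warnings.warn(f"{capped} saturated pairwise distances capped at "
                      f"{KIMURA_CAP}")
    return DistanceMatrix(ids=list(m.ids), values=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion go to the lowest (i, j) index pair; negative
    branch lengths are clamped to 0 with the deficit moved to the sister
    edge so the pair's summed length is preserved.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = []
    for label in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for ai in range(na):
            for aj in range(ai + 1, na):
                val = q[ai, aj]
                if best is None or val < best[0] - 1e-12:
                    best = (val, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances to the new node
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        k = d.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    # final three-point formulas
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels, normalized to
    the side not containing the lexicographically smallest leaf."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor_label = labels[0]
    full = set(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor_label in below:
            below = frozenset(full - below)
        if 1 < len(below) < len(full) - 1:
            out.add(below)
    return out


def bootstrap_support(
    m: MultiAlignment, B: int = 100, seed: int = 0,
    method: str = "kimura", model: SubstitutionModel | None = None,
) -> TreeWithSupport:
    """NJ tree from the full core alignment, with supports from B
    column-resampled replicates (match columns only; insertions excluded).

    Support for each internal edge of the best tree is the percentage of
    replicate trees containing that bipartition; stored as ``edge.support``
    and as the internal node label.
    """
    if B < 1:
        raise ValueError("need B >= 1")
    best = nj_tree(distance_matrix(m, method, model))
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(best)}
    rng = np.random.default_rng(seed)
    ncol = m.n_columns
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row[c] for c in cols) for row in m.matrix]
        rep = MultiAlignment(ids=list(m.ids), matrix=rep_rows,
                             insertions={i: [] for i in m.ids},
                             core_start=m.core_start)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                rep_tree = nj_tree(distance_matrix(rep, method, model))
        except ValueError:
            continue
        rep_bps = _bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for node in best.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        labels = sorted(lf.taxon.label for lf in best.leaf_node_iter())
        if labels[0] in below:
            below = frozenset(set(labels) - below)
        if bp_count := counts.get(below):
            support = 100.0 * bp_count / B
        else:
            support = 0.0 if below in counts else None
        if support is not None:
            node.edge.support = support
            node.label = f"{support:g}"
    return TreeWithSupport(tree=best, n_replicates=B)


# --- likelihood -----------------------------------------------------------


def tree_log_likelihood(
    tree: dendropy.Tree, m: MultiAlignment,
    model: SubstitutionModel | None = None,
) -> float:
    """Felsenstein pruning log-likelihood of a fixed tree over the match
    columns, with discrete-gamma rates and gaps treated as missing data."""
    model = model or SubstitutionModel.load("LG")
    rows = {sid: _encode_row(r) for sid, r in zip(m.ids, m.matrix)}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in rows:
            raise ValueError(f"leaf {leaf.taxon.label!r} has no alignment row")
    ncol = m.n_columns
    rates = model.category_rates()
    pi = model.pi
    site_mix = np.zeros(ncol)
    for rate in rates:
        partial, logscale = _prune(tree.seed_node, rows, model, rate, ncol)
        site = partial @ pi
        site_mix += np.exp(np.log(np.clip(site, 1e-300, None)) + logscale) / len(rates)
    return float(np.log(np.clip(site_mix, 1e-300, None)).sum())


def _prune(node, rows, model, rate, ncol):
    if node.is_leaf():
        codes = rows[node.taxon.label]
        L = np.zeros((ncol, 20))
        missing = codes < 0
        L[missing, :] = 1.0
        obs = ~missing
        L[np.nonzero(obs)[0], codes[obs]] = 1.0
        return L, np.zeros(ncol)
    L = np.ones((ncol, 20))
    logscale = np.zeros(ncol)
    for child in node.child_nodes():
        cl, cs = _prune(child, rows, model, rate, ncol)
        t = (child.edge.length or 0.0) * rate
        P = model.transition_matrix(t)
        L = L * (cl @ P.T)
        logscale = logscale + cs
        mx = L.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        L = L / mx[:, None]
        logscale = logscale + np.log(mx)
    return L, logscale


def empirical_frequencies(m: MultiAlignment, floor: float = 1e-6) -> np.ndarray:
    """Alignment-wide non-gap amino-acid frequencies (floored, normalized)."""
    counts = np.zeros(20)
    for row in m.matrix:
        enc = _encode_row(row)
        ok = enc >= 0
        np.add.at(counts, enc[ok], 1.0)
    freq = np.maximum(counts / max(counts.sum(), 1.0), floor)
    return freq / freq.sum()


def compare_frequency_models(
    tree: dendropy.Tree, m: MultiAlignment,
    model: SubstitutionModel | None = None,
) -> dict[str, float]:
    """Score a fixed tree under model frequencies vs empirical frequencies.

    Mirrors the survey's model-selection step in which the LG matrix's own
    frequencies gave better likelihoods than alignment-derived ones.
    """
    model = model or SubstitutionModel.load("LG", alpha=1.0)
    lnl_model = tree_log_likelihood(tree, m, model)
    emp = model.with_frequencies(empirical_frequencies(m))
    lnl_emp = tree_log_likelihood(tree, m, emp)
    return {"model_frequencies": lnl_model, "empirical_frequencies": lnl_emp}


def estimate_gamma_shape(
    tree: dendropy.Tree, m: MultiAlignment,
    model: SubstitutionModel | None = None,
    bounds: tuple[float, float] = (0.05, 10.0),
) -> float:
    """Gamma shape maximizing the fixed-topology likelihood (bounded 1-D
    golden-section/Brent search)."""
    model = model or SubstitutionModel.load("LG", alpha=1.0)

    def neg(alpha: float) -> float:
        return -tree_log_likelihood(tree, m, model.with_alpha(float(alpha)))

    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-3})
    return float(res.x)
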