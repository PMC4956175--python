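"""Binary network statistics used as matching targets and comparison
profiles: density, uni/bidirectional pair counts, the 16-class directed
3-node motif census, degree-preserving rewiring nulls with log residuals,
the all-clique census on the reciprocal skeleton, the second eigenvalue
of A A^T, and RMS log-ratio deviations between count vectors.

Motif classes are numbered 1-16 in the classic triad-census order
(by edge count, mutual dyads before asymmetric ones), which matches the
numbering used in comparative-connectomics motif profiles: class 3 is
the lone bidirectional link and class 10 the oriented 3-cycle.  The full
mapping from class number to triad code ships in ``MOTIF_CLASSES``.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import statsmodels.api as sm

from .geometry import DistanceMatrix
from .model import Connectome

__all__ = [
    "MOTIF_CLASSES",
    "GraphSummary",
    "MotifCensus",
    "CliqueCensus",
    "summarize",
    "motif_census",
    "rewire_degree_preserving",
    "motif_log_residuals",
    "clique_census",
    "rms_log_ratio",
    "second_eigenvalue",
    "connection_probability_fit",
]

#: class number (1-16) -> triad code (M-A-N counts of Mutual, Asymmetric
#: and Null dyads, plus orientation letter).  Class 3 ("102") is a lone
#: bidirectional link; class 10 ("030C") is the oriented 3-cycle.
MOTIF_CLASSES: tuple[str, ...] = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)


@dataclass(frozen=True)
class GraphSummary:
    """Scalar binary-graph summaries.

    ``m1``/``m2`` count unordered pairs connected in exactly one / both
    directions, so ``m == m1 + 2 * m2``.
    """

    n: int
    m: int
    density: float
    m1: int
    m2: int
    second_eigenvalue: float
    in_degrees: np.ndarray = field(repr=False)
    out_degrees: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class MotifCensus:
    """Counts of the 16 directed 3-node isomorphism classes.

    ``counts[k]`` is the count of class ``k + 1``; the counts sum to
    C(N, 3) because every node triple belongs to exactly one class.
    """

    counts: np.ndarray = field(repr=False)
    n_triplets: int

    def as_dict(self) -> dict[str, int]:
        return {code: int(c) for code, c in zip(MOTIF_CLASSES, self.counts)}


@dataclass(frozen=True)
class CliqueCensus:
    """Number of k-cliques (all cliques, not only maximal ones) of the
    reciprocal skeleton, for k = 1 .. max clique size."""

    counts: dict[int, int]

    @property
    def max_size(self) -> int:
        return max(self.counts)

    def as_vector(self) -> np.ndarray:
        kmax = self.max_size
        return np.array([self.counts.get(k, 0) for k in range(1, kmax + 1)])


def summarize(G: Connectome) -> GraphSummary:
    """Density, uni-/bidirectional pair counts, eigenvalue and ranked
    degree sequences of the binary adjacency."""
    a = G.adjacency
    n = G.n_areas
    m = int(a.sum())
    both = a & a.T
    m2 = int(both.sum()) // 2
    m1 = m - 2 * m2
    return GraphSummary(
        n=n,
        m=m,
        density=m / (n * (n - 1)),
        m1=m1,
        m2=m2,
        second_eigenvalue=second_eigenvalue(G),
        in_degrees=np.sort(a.sum(axis=0))[::-1],
        out_degrees=np.sort(a.sum(axis=1))[::-1],
    )


@functools.lru_cache(maxsize=1)
def _pattern_class_table() -> np.ndarray:
    """Map each of the 64 labeled 3-node edge patterns to its class 0-15.

    Bit order for a triple (i, j, k): i->j, j->i, i->k, k->i, j->k, k->j.
    Labels come from the triad census of each single-pattern graph, so
    the table is isomorphism-correct by construction.
    """
    table = np.empty(64, dtype=np.int64)
    edges = ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1))
    code_index = {code: k for k, code in enumerate(MOTIF_CLASSES)}
    for pattern in range(64):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from(e for b, e in enumerate(edges) if pattern >> b & 1)
        census = nx.triadic_census(g)
        (code,) = [c for c, v in census.items() if v == 1]
        table[pattern] = code_index[code]
    return table


@functools.lru_cache(maxsize=8)
def _triples(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
    return idx[:, 0], idx[:, 1], idx[:, 2]


def motif_census(G: Connectome) -> MotifCensus:
    """Classify every unordered node triple into one of the 16 directed
    3-node isomorphism classes (triad census).

    Each triple's 6 possible edges form a 6-bit pattern that is looked
    up in a precomputed isomorphism table, so the census is exhaustive
    over all C(N, 3) triples.
    """
    n = G.n_areas
    if n < 3:
        raise ValueError("motif census needs at least 3 nodes")
    a = G.adjacency
    i, j, k = _triples(n)
    pattern = (
        a[i, j]
        | a[j, i] << 1
        | a[i, k] << 2
        | a[k, i] << 3
        | a[j, k] << 4
        | a[k, j] << 5
    )
    counts = np.bincount(_pattern_class_table()[pattern], minlength=16)
    return MotifCensus(counts=counts.astype(np.int64), n_triplets=int(counts.sum()))


def rewire_degree_preserving(
    G: Connectome,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> Connectome:
    """Degree-preserving randomization of the binary graph.

    Attempts ``n_swaps`` double-edge swaps (a->b, c->d) => (a->d, c->b),
    rejecting any swap that would create a self-loop or a duplicate edge.
    In- and out-degrees of every node are preserved exactly; weights are
    discarded (the null is binary).  Default attempts: 10 * M.
    """
    a = G.adjacency.astype(bool)
    m = int(a.sum())
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps <= 0:
        raise ValueError("n_swaps must be positive")
    rng = np.random.default_rng(seed)
    src, tgt = np.nonzero(a)
    src, tgt = src.copy(), tgt.copy()
    adj = a.copy()
    picks = rng.integers(0, m, size=(n_swaps, 2))
    for e1, e2 in picks:
        if e1 == e2:
            continue
        x1, y1 = src[e1], tgt[e1]
        x2, y2 = src[e2], tgt[e2]
        if x1 == y2 or x2 == y1:
            continue  # would create a self-loop
        if adj[x1, y2] or adj[x2, y1]:
            continue  # would duplicate an existing edge
        adj[x1, y1] = adj[x2, y2] = False
        adj[x1, y2] = adj[x2, y1] = True
        tgt[e1], tgt[e2] = y2, y1
    return Connectome(G.labels, adj.astype(float))


def motif_log_residuals(
    G: Connectome,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    null_graphs: list[Connectome] | None = None,
) -> dict[str, np.ndarray]:
    """Log residuals ln(m_data / <m_null>) of the 16 motif counts against
    a degree-preserving rewiring ensemble.

    The 95% interval per class comes from the 2.5/97.5 percentiles of the
    null counts, mapped to the residual scale.  Classes whose null mean is
    zero are flagged (NaN residual, ``defined`` False).

    ``null_graphs`` may supply a precomputed ensemble (e.g. EDR graphs to
    use the model itself as the null); otherwise ``n_null`` rewired
    copies of ``G`` are generated.
    """
    if null_graphs is None:
        if n_null < 2:
            raise ValueError("n_null must be >= 2")
        rng = np.random.default_rng(seed)
        null_graphs = [rewire_degree_preserving(G, seed=rng) for _ in range(n_null)]
    data = motif_census(G).counts.astype(float)
    null_counts = np.array([motif_census(h).counts for h in null_graphs], dtype=float)
    mean_null = null_counts.mean(axis=0)
    defined = (mean_null > 0) & (data > 0)
    resid = np.full(16, np.nan)
    lo = np.full(16, np.nan)
    hi = np.full(16, np.nan)
    q_hi = np.percentile(null_counts, 97.5, axis=0)
    q_lo = np.percentile(null_counts, 2.5, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid[defined] = np.log(data[defined] / mean_null[defined])
        ok = defined & (q_lo > 0)
        lo[ok] = np.log(data[ok] / q_hi[ok])
        hi[ok] = np.log(data[ok] / q_lo[ok])
    return {"residual": resid, "ci_low": lo, "ci_high": hi, "defined": defined}


def _reciprocal_skeleton(G: Connectome) -> np.ndarray:
    """Undirected adjacency with an edge iff links exist in BOTH
    directions (a 'clique' here requires reciprocal completeness)."""
    a = G.adjacency
    return (a & a.T).astype(bool)


def clique_census(G: Connectome, max_k: int | None = None) -> CliqueCensus:
    """Count all cliques of every size on the reciprocal skeleton.

    Singletons count as 1-cliques (so ``counts[1] == N``) and reciprocal
    pairs as 2-cliques.  Enumeration is delegated to igraph.
    """
    sk = _reciprocal_skeleton(G)
    n = G.n_areas
    g = ig.Graph.Adjacency(sk.tolist(), mode="undirected")
    counts: dict[int, int] = {1: n}
    sizes = [len(c) for c in g.cliques(min=2, max=max_k or 0)]
    for s in sizes:
        counts[s] = counts.get(s, 0) + 1
    return CliqueCensus(counts=counts)


def rms_log_ratio(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Root-mean-square of ln(a_k / b_k) over the common support.

    Entries where either count is zero are dropped; the number dropped is
    returned alongside sigma.  sigma == 0 iff the vectors agree on their
    common support; a == e * b gives sigma == 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same length")
    support = (a > 0) & (b > 0)
    n_dropped = int(a.size - support.sum())
    if not support.any():
        raise ValueError("no common support between the count vectors")
    lr = np.log(a[support] / b[support])
    return float(np.sqrt(np.mean(lr**2))), n_dropped


def second_eigenvalue(G: Connectome) -> float:
    """Second-largest eigenvalue of the co-occurrence matrix A A^T
    (symmetric, hence real spectrum)."""
    a = G.adjacency.astype(float)
    ev = np.linalg.eigvalsh(a @ a.T)
    return float(ev[-2])


def connection_probability_fit(G: Connectome, D: DistanceMatrix) -> dict[str, float]:
    """Logistic regression of link presence on interareal distance.

    One record per ordered pair; binomial GLM with logit link:
    ``logit P(connected) = beta0 + beta1 * d``.  Perfect separation is
    flagged (``separable`` True, no estimates).
    """
    n = G.n_areas
    mask = ~np.eye(n, dtype=bool)
    y = G.adjacency[mask].astype(float)
    d = D.values[mask]
    if y.min() == y.max():
        raise ValueError("need both connected and unconnected pairs")
    X = sm.add_constant(d)
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception:
        return {"separable": True}
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e4):
        return {"separable": True}
    return {
        "separable": False,
        "beta0": float(res.params[0]),
        "beta1": float(res.params[1]),
        "se_beta0": float(res.bse[0]),
        "se_beta1": float(res.bse[1]),
    }
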