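"""EDR and CDR random connectomes over a fixed distance matrix.

The exponential distance rule (EDR) generator follows the maximum-entropy
recipe: repeatedly (i) draw a connection length ``d`` from
``p(d) = lambda * exp(-lambda d)`` restricted to ``(0, d_max]``,
(ii) choose uniformly at random an unordered area pair whose separation
falls in the same distance bin as ``d``, and (iii) insert one unit of
weight in a uniformly random direction.  Draws landing in a bin that
contains no pairs are rejected and redrawn.  Iteration stops when the
number of distinct ordered connected pairs reaches the target ``M``, so
the realized binary density matches the data exactly; accumulated
multiplicities form the edge weights, which come out log-normal-like.

``lambda == 0`` encodes the constant distance rule (CDR): the pair is
chosen uniformly among *all* pairs, removing any distance dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DistanceMatrix

__all__ = ["EDRParameters", "Connectome", "sample_edr", "sample_cdr"]


@dataclass(frozen=True)
class EDRParameters:
    """Parameters of the EDR generator.

    Parameters
    ----------
    lambda_ : float
        Decay rate in 1/mm (or 1/adimensional-unit); ``0`` encodes CDR.
    binwidth : float
        Width of the distance bins used for pair lookup.  Typical
        choices: 0.4 mm at mouse scale, 5 mm at macaque scale.
    target_edges : int, optional
        Number of distinct ordered connected pairs M to reach.
    target_density : float, optional
        Alternative to ``target_edges``: binary density rho, with
        ``M = round(rho * N * (N - 1))``.
    """

    lambda_: float
    binwidth: float = 0.4
    target_edges: int | None = None
    target_density: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.binwidth <= 0:
            raise ValueError("binwidth must be positive")
        if (self.target_edges is None) == (self.target_density is None):
            raise ValueError("give exactly one of target_edges / target_density")
        if self.target_density is not None and not 0 < self.target_density <= 1:
            raise ValueError("target_density must be in (0, 1]")
        if self.target_edges is not None and self.target_edges < 1:
            raise ValueError("target_edges must be >= 1")

    def resolve_edges(self, n_areas: int) -> int:
        if self.target_edges is not None:
            m = self.target_edges
        else:
            m = int(round(self.target_density * n_areas * (n_areas - 1)))
        if m > n_areas * (n_areas - 1):
            raise ValueError("target edges exceed N(N-1)")
        return m


@dataclass(frozen=True)
class Connectome:
    """Directed weighted graph on N named areas.

    ``weights[i, j]`` is the weight of the projection i -> j (source row,
    target column); the binary adjacency is ``weights > 0``.  The FLN
    (fraction of labeled neurons) view normalizes weights per target
    column, mirroring how tracer counts are normalized per injected area.
    """

    labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if w.shape != (n, n):
            raise ValueError(f"weight shape {w.shape} does not match {n} labels")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed (diagonal must be 0)")

    @property
    def n_areas(self) -> int:
        return len(self.labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency A = (W > 0), dtype int."""
        return (self.weights > 0).astype(int)

    @property
    def n_edges(self) -> int:
        """Number of distinct ordered connected pairs M."""
        return int((self.weights > 0).sum())

    @property
    def density(self) -> float:
        n = self.n_areas
        return self.n_edges / (n * (n - 1))

    def fln(self) -> np.ndarray:
        """Per-target (column) normalized weights; NaN columns for
        isolated targets."""
        col = self.weights.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(col > 0, self.weights / col, np.nan)
        return out

    # --- plain-text round trips -------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(self.weights, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "Connectome":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))

    def to_edgelist(self, path) -> None:
        src, tgt = np.nonzero(self.weights)
        pd.DataFrame(
            {
                "source": [self.labels[i] for i in src],
                "target": [self.labels[j] for j in tgt],
                "weight": self.weights[src, tgt],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_edgelist(cls, path, labels) -> "Connectome":
        labels = tuple(labels)
        idx = {a: k for k, a in enumerate(labels)}
        df = pd.read_csv(path)
        w = np.zeros((len(labels), len(labels)))
        for s, t, wt in df.itertuples(index=False):
            w[idx[s], idx[t]] = wt
        return cls(labels, w)


def _edge_lengths(G: Connectome, D: DistanceMatrix, weighted: bool) -> np.ndarray:
    """Lengths of realized connections, optionally repeated by weight."""
    src, tgt = np.nonzero(G.weights)
    d = D.values[src, tgt]
    if not weighted:
        return d
    return np.repeat(d, G.weights[src, tgt].astype(int))


def realized_lengths(G: Connectome, D: DistanceMatrix, multiplicity: bool = True) -> np.ndarray:
    """Connection lengths of G; with ``multiplicity`` each unit of weight
    contributes one length (the sampler's axon-length sample)."""
    return _edge_lengths(G, D, multiplicity)


def _sample(
    D: DistanceMatrix,
    params: EDRParameters,
    seed,
    force_cdr: bool = False,
) -> Connectome:
    rng = np.random.default_rng(seed)
    n = D.n_areas
    m_target = params.resolve_edges(n)
    lam = 0.0 if force_cdr else params.lambda_

    iu, ju = np.triu_indices(n, k=1)
    pair_d = D.values[iu, ju]
    dmax = float(pair_d.max())

    if lam > 0:
        # group unordered pairs by distance bin for the lookup step
        nbins = int(np.ceil(dmax / params.binwidth - 1e-12))
        pair_bin = np.minimum((pair_d / params.binwidth).astype(int), nbins - 1)
        order = np.argsort(pair_bin, kind="stable")
        sorted_i, sorted_j = iu[order], ju[order]
        bin_start = np.searchsorted(pair_bin[order], np.arange(nbins))
        bin_end = np.searchsorted(pair_bin[order], np.arange(nbins), side="right")
        bin_count = bin_end - bin_start
        trunc = 1.0 - np.exp(-lam * dmax)

    weights = np.zeros(n * n, dtype=np.int64)
    seen = np.zeros(n * n, dtype=bool)
    n_seen = 0
    batch = max(4 * m_target, 4096)

    while n_seen < m_target:
        if lam > 0:
            # truncated-exponential lengths via inverse CDF on (0, d_max]
            u = rng.random(batch)
            d = -np.log1p(-u * trunc) / lam
            k = np.minimum((d / params.binwidth).astype(int), nbins - 1)
            ok = bin_count[k] > 0  # silent redraw for empty bins
            k = k[ok]
            if k.size == 0:
                continue
            offs = rng.integers(0, bin_count[k])
            sel = bin_start[k] + offs
            a, b = sorted_i[sel], sorted_j[sel]
        else:
            sel = rng.integers(0, iu.size, size=batch)
            a, b = iu[sel], ju[sel]
        flip = rng.random(a.size) < 0.5
        src = np.where(flip, b, a)
        tgt = np.where(flip, a, b)
        ids = src * n + tgt

        # first occurrence of each id inside this batch
        uniq, first = np.unique(ids, return_index=True)
        first_mask = np.zeros(ids.size, dtype=bool)
        first_mask[first] = True
        new_mask = first_mask & ~seen[ids]
        gained = np.cumsum(new_mask)
        if n_seen + gained[-1] >= m_target:
            stop = int(np.searchsorted(gained, m_target - n_seen))
            ids = ids[: stop + 1]
            weights += np.bincount(ids, minlength=n * n)
            seen[ids] = True
            n_seen = m_target
        else:
            weights += np.bincount(ids, minlength=n * n)
            seen[ids] = True
            n_seen += int(gained[-1])
            batch *= 2

    return Connectome(D.labels, weights.reshape(n, n).astype(float))


def sample_edr(
    D: DistanceMatrix, params: EDRParameters, seed: int | np.random.Generator | None = None
) -> Connectome:
    """Draw one EDR connectome realization over the distance matrix ``D``.

    See the module docstring for the algorithm.  The same seed yields a
    bitwise-identical connectome.
    """
    return _sample(D, params, seed)


def sample_cdr(
    D: DistanceMatrix, params: EDRParameters, seed: int | np.random.Generator | None = None
) -> Connectome:
    """Draw one CDR (distance-independent) connectome: uniform pair
    choice over all pairs, same stopping rule as the EDR sampler."""
    return _sample(D, params, seed, force_cdr=True)
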