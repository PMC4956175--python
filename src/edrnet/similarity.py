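"""Chance-corrected in-link connection-similarity profiles.

Two target areas are similar when they receive projections from the same
sources.  For a pair (x, y), ``n_in`` counts the source areas from which
either both or neither receive a link (all N areas count as potential
sources; absent self-connections contribute "neither" agreements).  The
index subtracts the agreement expected if in-links were placed uniformly
at random given the two in-degrees:

    S_xy = n_in / N - [ (k_x/N)(k_y/N) + (1 - k_x/N)(1 - k_y/N) ]

so S averages to ~0 on Erdos-Renyi graphs and decays with interareal
distance under the EDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .geometry import DistanceMatrix
from .model import Connectome, EDRParameters, sample_edr

__all__ = [
    "SimilarityRecord",
    "SimilarityProfile",
    "in_link_similarity",
    "similarity_profile",
    "ensemble_similarity_density",
]


@dataclass(frozen=True)
class SimilarityRecord:
    x: str
    y: str
    n_in: int
    k_x: int
    k_y: int
    p_expected: float
    s_in: float
    distance: float


@dataclass(frozen=True)
class SimilarityProfile:
    """One record per unordered area pair (N(N-1)/2 records)."""

    records: tuple[SimilarityRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def distances(self) -> np.ndarray:
        return np.array([r.distance for r in self.records])

    def similarities(self) -> np.ndarray:
        return np.array([r.s_in for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "distance": self.distances(),
                "n_in": [r.n_in for r in self.records],
                "k_x": [r.k_x for r in self.records],
                "k_y": [r.k_y for r in self.records],
                "s_in": self.similarities(),
            }
        )


def _similarity_arrays(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_in, p_expected, S) matrices for all area pairs at once."""
    n = a.shape[0]
    a = a.astype(float)
    agree = a.T @ a + (1 - a).T @ (1 - a)  # sources where both / neither project
    k = a.sum(axis=0)
    kx = k[:, None] / n
    ky = k[None, :] / n
    p_exp = kx * ky + (1 - kx) * (1 - ky)
    s = agree / n - p_exp
    return agree, p_exp, s


def in_link_similarity(a: np.ndarray, x: int, y: int) -> SimilarityRecord:
    """Similarity record for one (x, y) index pair of a binary adjacency
    (a[i, j] = 1 iff i projects to j)."""
    if x == y:
        raise ValueError("x and y must differ")
    a = np.asarray(a)
    n = a.shape[0]
    agree, p_exp, s = _similarity_arrays(a)
    return SimilarityRecord(
        x=str(x),
        y=str(y),
        n_in=int(agree[x, y]),
        k_x=int(a[:, x].sum()),
        k_y=int(a[:, y].sum()),
        p_expected=float(p_exp[x, y]),
        s_in=float(s[x, y]),
        distance=float("nan"),
    )


def similarity_profile(G: Connectome, D: DistanceMatrix) -> SimilarityProfile:
    """In-link similarity vs distance for all unordered area pairs."""
    if G.labels != D.labels:
        raise ValueError("connectome and distance matrix labels differ")
    a = G.adjacency
    n = G.n_areas
    agree, p_exp, s = _similarity_arrays(a)
    k = a.sum(axis=0)
    iu, ju = np.triu_indices(n, k=1)
    records = tuple(
        SimilarityRecord(
            x=G.labels[i],
            y=G.labels[j],
            n_in=int(agree[i, j]),
            k_x=int(k[i]),
            k_y=int(k[j]),
            p_expected=float(p_exp[i, j]),
            s_in=float(s[i, j]),
            distance=float(D.values[i, j]),
        )
        for i, j in zip(iu, ju)
    )
    return SimilarityProfile(records)


def ensemble_similarity_density(
    D: DistanceMatrix,
    lambda_: float,
    target_density: float,
    n_graphs: int = 300,
    binwidth: float | None = None,
    grid_size: int = 64,
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Smoothed (distance, similarity) density over an EDR ensemble.

    Pools the similarity records of ``n_graphs`` EDR realizations and
    kernel-smooths them (Gaussian KDE, Silverman bandwidth) on a regular
    grid.  Returns the pooled points and the density grid.
    """
    if n_graphs < 2:
        raise ValueError("n_graphs must be >= 2")
    rng = np.random.default_rng(seed)
    if binwidth is None:
        binwidth = D.max / 20
    params = EDRParameters(
        lambda_=lambda_, binwidth=binwidth, target_density=target_density
    )
    ds, ss = [], []
    for _ in range(n_graphs):
        g = sample_edr(D, params, seed=rng)
        prof = similarity_profile(g, D)
        ds.append(prof.distances())
        ss.append(prof.similarities())
    d = np.concatenate(ds)
    s = np.concatenate(ss)
    kde = gaussian_kde(np.vstack([d, s]))
    dg = np.linspace(0, d.max(), grid_size)
    sg = np.linspace(s.min(), s.max(), grid_size)
    dd, ssg = np.meshgrid(dg, sg)
    dens = kde(np.vstack([dd.ravel(), ssg.ravel()])).reshape(grid_size, grid_size)
    return {
        "distance": d,
        "similarity": s,
        "grid_distance": dg,
        "grid_similarity": sg,
        "density": dens,
    }
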