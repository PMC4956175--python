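"""Clique-based core--periphery structure of dense directed networks.

The core is the union of all maximum-size cliques of the reciprocal
skeleton (edges require links in both directions) -- in the mouse
connectome two overlapping 11-cliques yield a 12-node core.  Block link
counts and densities quantify how much denser the core is than the
periphery, and a binomial likelihood says how (im)probable such a dense
block would be in an Erdos-Renyi graph of the same density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import igraph as ig
import numpy as np
from scipy.special import gammaln

from .measures import _reciprocal_skeleton
from .model import Connectome

__all__ = ["CorePartition", "extract_core", "block_stats", "core_likelihood"]


@dataclass(frozen=True)
class CorePartition:
    """Core/periphery node sets with directed block link counts.

    ``m_cc + m_cp + m_pc + m_pp == M`` always; densities are filled by
    :func:`block_stats` (NaN for an empty block).
    """

    core: tuple[str, ...]
    periphery: tuple[str, ...]
    m_cc: int = 0
    m_cp: int = 0
    m_pc: int = 0
    m_pp: int = 0
    density_core: float = float("nan")
    density_periphery: float = float("nan")
    density_between: float = float("nan")
    max_clique_size: int = 0
    n_maximum_cliques: int = 0

    def rounded_percent(self) -> dict[str, int]:
        """Block densities as whole percentages (reporting convention)."""
        return {
            "core": int(round(100 * self.density_core)),
            "periphery": int(round(100 * self.density_periphery)),
            "between": int(round(100 * self.density_between)),
        }


def extract_core(G: Connectome) -> CorePartition:
    """Core = union of all maximum cliques of the reciprocal skeleton.

    Deterministic and permutation-equivariant; ties (several maximum
    cliques) are all included.  Block statistics are filled in.
    """
    sk = _reciprocal_skeleton(G)
    g = ig.Graph.Adjacency(sk.tolist(), mode="undirected")
    largest = g.largest_cliques()
    if not largest or len(largest[0]) < 2:
        raise ValueError("maximum clique size must be >= 2 to define a core")
    members = sorted(set().union(*map(set, largest)))
    core = tuple(G.labels[i] for i in members)
    periphery = tuple(a for a in G.labels if a not in core)
    part = CorePartition(
        core=core,
        periphery=periphery,
        max_clique_size=len(largest[0]),
        n_maximum_cliques=len(largest),
    )
    return block_stats(G, part)


def block_stats(G: Connectome, partition: CorePartition) -> CorePartition:
    """Directed link counts and densities within/between the blocks."""
    idx = {a: k for k, a in enumerate(G.labels)}
    c = np.array([idx[a] for a in partition.core], dtype=int)
    p = np.array([idx[a] for a in partition.periphery], dtype=int)
    if set(partition.core) | set(partition.periphery) != set(G.labels):
        raise ValueError("partition does not cover the node set")
    a = G.adjacency
    m_cc = int(a[np.ix_(c, c)].sum())
    m_cp = int(a[np.ix_(c, p)].sum())
    m_pc = int(a[np.ix_(p, c)].sum())
    m_pp = int(a[np.ix_(p, p)].sum())
    nc, npd = len(c), len(p)
    dens_c = m_cc / (nc * (nc - 1)) if nc > 1 else float("nan")
    dens_p = m_pp / (npd * (npd - 1)) if npd > 1 else float("nan")
    dens_b = (m_cp + m_pc) / (2 * nc * npd) if nc and npd else float("nan")
    return replace(
        partition,
        m_cc=m_cc,
        m_cp=m_cp,
        m_pc=m_pc,
        m_pp=m_pp,
        density_core=dens_c,
        density_periphery=dens_p,
        density_between=dens_b,
    )


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def core_likelihood(n_areas: int, n_core: int, m_cc: int, p: float) -> float:
    """Chance probability of a core block this dense in an Erdos-Renyi
    digraph: C(N, n_c) * C(n_c(n_c-1), M_cc) * p^M_cc * (1-p)^(rest).

    Evaluated in log space (direct evaluation overflows the binomials).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    slots = n_core * (n_core - 1)
    if m_cc > slots:
        raise ValueError("m_cc exceeds the n_core(n_core-1) directed slots")
    logp = (
        _log_binom(n_areas, n_core)
        + _log_binom(slots, m_cc)
        + m_cc * np.log(p)
        + (slots - m_cc) * np.log1p(-p)
    )
    return float(np.exp(logp))
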