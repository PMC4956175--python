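"""Interareal distance matrices, distance-distribution statistics, and the
common adimensional template.

Distances between cortical areas are measured between area barycenters
and collected in a symmetric matrix ``D`` (mm).  Brains of different
sizes are compared by rescaling every distance by the species' mean
interareal distance ``<d>``, which maps both onto one adimensional
template with mean distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DistanceMatrix",
    "DistanceStats",
    "distance_stats",
    "rescale_adimensional",
    "variance_ratio_permutation_test",
]

#: default histogram bin widths: 0.5 mm for metric distances,
#: 0.2 for adimensional ones.
DEFAULT_BINWIDTH_MM = 0.5
DEFAULT_BINWIDTH_ADIM = 0.2


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of interareal barycenter distances.

    Parameters
    ----------
    labels : tuple of str
        Ordered area names.
    values : ndarray, shape (N, N)
        Nonnegative distances; zero diagonal, strictly positive
        off-diagonal, symmetric.
    units : {"mm", "adimensional"}
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    units: str = "mm"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        if n < 3:
            raise ValueError("a distance matrix needs at least 3 areas")
        if self.units not in ("mm", "adimensional"):
            raise ValueError(f"unknown units {self.units!r}")
        if not np.allclose(vals, vals.T, rtol=0, atol=1e-12 * max(1.0, vals.max())):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        off = vals[~np.eye(n, dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal distances must be strictly positive")

    @property
    def n_areas(self) -> int:
        return len(self.labels)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle (unordered-pair) distances as a flat array."""
        iu, ju = np.triu_indices(self.n_areas, k=1)
        return self.values[iu, ju]

    @property
    def mean(self) -> float:
        """Mean interareal distance ``<d>`` over unordered pairs."""
        return float(self.offdiagonal().mean())

    @property
    def max(self) -> float:
        return float(self.offdiagonal().max())

    @classmethod
    def from_coordinates(
        cls, labels, coords: np.ndarray, units: str = "mm"
    ) -> "DistanceMatrix":
        """Euclidean distances between 2-D (or k-D) area coordinates."""
        coords = np.asarray(coords, dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        return cls(tuple(labels), d, units)


@dataclass(frozen=True)
class DistanceStats:
    """Summary of the interareal distance distribution q(d)."""

    mean: float
    max: float
    binwidth: float
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    units: str = "mm"

    @property
    def ratio(self) -> float:
        """d_max / <d>; both species land near 2.2 on this ratio."""
        return self.max / self.mean


def distance_stats(D: DistanceMatrix, binwidth: float | None = None) -> DistanceStats:
    """Mean, maximum and binned distribution q(d) of interareal distances.

    The histogram uses left-closed bins ``[k*binwidth, (k+1)*binwidth)``
    covering ``[0, d_max]`` (the final edge is closed so the largest
    distance is counted).  ``density`` integrates to 1.
    """
    if binwidth is None:
        binwidth = DEFAULT_BINWIDTH_MM if D.units == "mm" else DEFAULT_BINWIDTH_ADIM
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    vals = D.offdiagonal()
    dmax = float(vals.max())
    nbins = max(1, int(np.ceil(dmax / binwidth - 1e-12)))
    edges = np.arange(nbins + 1) * binwidth
    counts, _ = np.histogram(vals, bins=edges)
    density = counts / (counts.sum() * binwidth)
    return DistanceStats(
        mean=float(vals.mean()),
        max=dmax,
        binwidth=float(binwidth),
        bin_edges=edges,
        counts=counts,
        density=density,
        units=D.units,
    )


def rescale_adimensional(D: DistanceMatrix) -> DistanceMatrix:
    """Divide every distance by ``<d>`` so the off-diagonal mean is 1.

    Idempotent on already-adimensional input (whose mean is 1).
    """
    mean = D.mean
    if mean == 0:
        raise ValueError("mean interareal distance is zero")
    return replace(D, values=D.values / mean, units="adimensional")


def variance_ratio_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Two-sided permutation test on the variance ratio var(x)/var(y).

    Labels are permuted across the pooled sample; a permuted ratio is
    "more extreme" than the observed ratio ``r`` when it is <= min(r, 1/r)
    or >= max(r, 1/r).  The observed ratio is included in the permutation
    distribution, so the smallest attainable p is ``1/(n_perm + 1)``.

    Returns ``{"ratio": r, "p_value": p}``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in a sample")
    r = vx / vy
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    nx = x.size
    ratios = np.empty(n_perm + 1)
    ratios[0] = r  # the observed estimate is part of the null distribution
    for k in range(n_perm):
        perm = rng.permutation(pooled)
        ratios[k + 1] = perm[:nx].var(ddof=1) / perm[nx:].var(ddof=1)
    lo, hi = min(r, 1.0 / r), max(r, 1.0 / r)
    extreme = (ratios <= lo) | (ratios >= hi)
    return {"ratio": float(r), "p_value": float(extreme.mean())}
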