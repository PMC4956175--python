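"""CSV/JSON interfaces and run manifests.

All exchange formats are plain tables: dense labeled CSV matrices for
distances and connectomes, tidy CSV for profiles and censuses, JSON for
manifests and reports.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import DistanceMatrix
from .model import Connectome

__all__ = [
    "load_distance_csv",
    "save_distance_csv",
    "load_connectome_csv",
    "write_manifest",
]


def load_distance_csv(path, units: str = "mm") -> DistanceMatrix:
    """Read a labeled distance matrix.

    Symmetry is checked at 1e-6 relative tolerance, then the matrix is
    symmetrized by averaging with its transpose (measurement round-trip
    noise); a larger asymmetry is an error.
    """
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels differ")
    vals = df.to_numpy(dtype=float)
    scale = np.abs(vals).max()
    if scale == 0 or np.abs(vals - vals.T).max() > 1e-6 * scale:
        raise ValueError("distance matrix is not symmetric (tolerance 1e-6 relative)")
    vals = (vals + vals.T) / 2
    return DistanceMatrix(tuple(df.index), vals, units)


def save_distance_csv(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.values, index=D.labels, columns=D.labels).to_csv(path)


def load_connectome_csv(path) -> Connectome:
    return Connectome.from_csv(path)


def write_manifest(path, seed: int | None, parameters: dict) -> dict:
    """Record the package version, seed and parameters of a run."""
    manifest = {
        "edrnet_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": parameters,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
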