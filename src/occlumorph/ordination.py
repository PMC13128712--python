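"""Metric MDS over distance matrices and the trophic-character network.

Ordination uses SMACOF stress majorization with a classical-scaling
(double-centred eigendecomposition) start, reporting stress-1

    stress = sqrt( sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2 )

where d is the input distance and dhat the embedded configuration distance.
The recorded stress sequence is monotone non-increasing; the run is
deterministic given the seed (the seed only matters for degenerate starts).

Because the transport distance is already a metric, no similarity-to-
distance adjustment is needed; the sqrt(1 - s) transform is nevertheless
provided for similarity inputs, off by default.

The trophic-character network compares species rows of an integer-coded
character table by unweighted Manhattan (L1) distance, with an optional
minimum spanning tree for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profile_model import ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "CharacterTable",
    "metric_mds",
    "similarity_to_distance",
    "manhattan_network",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric non-negative distance matrix with zero diagonal.

    ``groups`` optionally carries one group label (e.g. species code) per
    row for downstream colouring/summaries.
    """

    labels: list
    values: np.ndarray
    groups: Optional[list] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.isfinite(v).all():
            raise ValidationError("distances must be finite")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        scale = max(v.max(), 1.0)
        if np.abs(v - v.T).max() > 1e-9 * scale:
            raise ValidationError("distance matrix must be symmetric to 1e-9")
        if np.abs(np.diag(v)).max() > 0:
            raise ValidationError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", 0.5 * (v + v.T))
        if self.groups is not None and len(self.groups) != n:
            raise ValidationError("groups length must match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class OrdinationResult:
    """MDS configuration with its stress-1 value and iteration trace."""

    coordinates: np.ndarray
    stress: float
    stress_history: np.ndarray
    iterations: int
    converged: bool
    seed: int
    labels: Optional[list] = None
    groups: Optional[list] = None


@dataclass(frozen=True)
class CharacterTable:
    """Species x character table of ordered integer codes, no missing cells."""

    labels: list
    characters: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.characters)):
            raise ValidationError("character table shape does not match labels/characters")
        if not np.isfinite(v).all():
            raise ValidationError("character table must have no missing cells")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CharacterTable":
        return cls(labels=list(df.index), characters=list(df.columns), values=df.to_numpy(float))


def _classical_scaling(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centring start configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def metric_mds(
    D: DistanceMatrix | np.ndarray,
    k: int = 2,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-9,
) -> OrdinationResult:
    """SMACOF metric MDS minimizing stress-1, deterministic given the seed."""
    if isinstance(D, DistanceMatrix):
        labels, groups, dm = D.labels, D.groups, D.values
    else:
        dm = DistanceMatrix(labels=list(range(len(D))), values=np.asarray(D, float)).values
        labels, groups = None, None
    n = dm.shape[0]
    if k < 1:
        raise ValidationError("embedding dimension k must be >= 1")
    if n < k + 1:
        raise ValidationError(f"need at least k+1 = {k + 1} objects, got {n}")
    denom = np.sum(np.triu(dm, 1) ** 2)
    if denom == 0:
        warnings.warn("all-zero distance matrix: coincident configuration, stress 0")
        return OrdinationResult(
            coordinates=np.zeros((n, k)), stress=0.0,
            stress_history=np.array([0.0]), iterations=0, converged=True,
            seed=seed, labels=labels, groups=groups,
        )

    X = _classical_scaling(dm, k)
    if not np.any(np.abs(X) > 0):  # fully degenerate start
        rng = np.random.default_rng(seed)
        X = 1e-3 * dm.max() * rng.standard_normal((n, k))

    def config_dist(X):
        return squareform(pdist(X))

    def raw_stress(dhat):
        return np.sum(np.triu((dm - dhat), 1) ** 2)

    dhat = config_dist(X)
    history = [np.sqrt(raw_stress(dhat) / denom)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dhat > 0, dm / dhat, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n  # Guttman transform
        dhat = config_dist(X)
        history.append(np.sqrt(raw_stress(dhat) / denom))
        if history[-2] - history[-1] < tol:
            converged = True
            break
    return OrdinationResult(
        coordinates=X, stress=float(history[-1]),
        stress_history=np.asarray(history), iterations=it, converged=converged,
        seed=seed, labels=labels, groups=groups,
    )


def similarity_to_distance(s):
    """sqrt(1 - s) adjustment turning similarities in [0, 1] into distances."""
    arr = np.asarray(s, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("similarities must lie in [0, 1]")
    out = np.sqrt(1.0 - arr)
    return float(out) if np.isscalar(s) or arr.ndim == 0 else out


def manhattan_network(table: CharacterTable | pd.DataFrame, mst: bool = True) -> pd.DataFrame:
    """Complete graph of unweighted Manhattan character distances.

    Returns an edge list (a, b, weight, in_mst); ``in_mst`` marks a minimum
    spanning tree for display when requested.
    """
    if isinstance(table, pd.DataFrame):
        table = CharacterTable.from_frame(table)
    if len(table.labels) < 2:
        raise ValidationError("network needs at least two species")
    dist = squareform(pdist(table.values, metric="cityblock"))
    g = nx.Graph()
    labels = table.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g.add_edge(labels[i], labels[j], weight=float(dist[i, j]))
    mst_edges = set()
    if mst:
        tree = nx.minimum_spanning_tree(g, weight="weight")
        mst_edges = {frozenset(e) for e in tree.edges()}
    rows = [
        {
            "a": a, "b": b, "weight": d["weight"],
            "in_mst": frozenset((a, b)) in mst_edges,
        }
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["a", "b", "weight", "in_mst"])
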