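"""Gaussian interaction profile (GIP) kernel similarities.

The GIP kernel scores two microbes (or two diseases) by the Gaussian kernel
on their binary association profiles,

    S[i, j] = exp(-gamma * ||x_i - x_j||^2),

with bandwidth gamma = gamma' / mean_i(||x_i||^2): the more associations two
entities share, the closer their profiles and the higher the similarity.
Microbe profiles are the columns of the association matrix, disease profiles
its rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AssociationMatrix

__all__ = [
    "SimilarityMatrix",
    "gip_bandwidth",
    "gip_similarity",
    "microbe_similarity",
    "disease_similarity",
]


@dataclass
class SimilarityMatrix:
    """Dense symmetric similarity matrix over one node kind."""

    ids: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "microbe"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if self.kind not in ("microbe", "disease"):
            raise ValueError(f"kind must be 'microbe' or 'disease', got {self.kind!r}")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Bandwidth gamma = gamma' / mean squared row-profile norm.

    Raises ``ValueError`` when every profile is all-zero (the normaliser
    would be zero).
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("all profiles are zero: GIP bandwidth is undefined")
    return gamma_prime / mean_sq_norm


def gip_similarity(profiles: np.ndarray, gamma: float, kind: str = "microbe",
                   ids: list[str] | None = None) -> SimilarityMatrix:
    """Gaussian kernel exp(-gamma * squared distance) between all row pairs."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = profiles.shape[0]
    if n == 1:
        sq = np.zeros((1, 1))
    else:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-gamma * sq)
    np.fill_diagonal(values, 1.0)
    if ids is None:
        ids = [str(i) for i in range(n)]
    return SimilarityMatrix(ids=list(ids), values=values, kind=kind)


def microbe_similarity(assoc: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP similarity between microbes; profiles are columns of the matrix."""
    profiles = assoc.values.T
    gamma = gip_bandwidth(profiles, gamma_prime)
    return gip_similarity(profiles, gamma, kind="microbe", ids=assoc.microbes)


def disease_similarity(assoc: AssociationMatrix, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """GIP similarity between diseases; profiles are rows of the matrix."""
    profiles = assoc.values
    gamma = gip_bandwidth(profiles, gamma_prime)
    return gip_similarity(profiles, gamma, kind="disease", ids=assoc.diseases)
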