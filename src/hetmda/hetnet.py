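"""Heterogeneous disease-microbe network assembly.

The network is a single weighted adjacency matrix in block form

    P = [ SD   MD  ]
        [ MD'  SM  ]

with disease nodes first, then microbe nodes.  Within-kind edges carry GIP
similarity weights, cross-kind edges carry the binary association labels.
Self-loops (the unit diagonal of the similarity blocks) are removed by
default so random walks never step to the node they are on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, write_matrix_tsv
from .similarity import SimilarityMatrix

__all__ = ["HeterogeneousNetwork", "build_heterogeneous_network", "node_label", "parse_node_label"]

_KIND_PREFIX = {"disease": "d", "microbe": "m"}


def node_label(kind: str, identifier: str) -> str:
    """Stable unique node label; disease and microbe namespaces never collide."""
    return f"{_KIND_PREFIX[kind]}::{identifier}"


def parse_node_label(label: str) -> tuple[str, str]:
    prefix, _, identifier = label.partition("::")
    kind = {"d": "disease", "m": "microbe"}.get(prefix)
    if kind is None or not identifier:
        raise ValueError(f"malformed node label {label!r}")
    return kind, identifier


@dataclass
class HeterogeneousNetwork:
    """Weighted adjacency over disease+microbe nodes (diseases first)."""

    node_index: list[tuple[str, str]]  # (kind, identifier), diseases then microbes
    weights: np.ndarray = field(repr=False)
    n_diseases: int = 0
    self_loops_removed: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_index)
        if self.weights.shape != (n, n):
            raise ValueError(f"adjacency shape {self.weights.shape} != ({n}, {n})")
        if (self.weights < 0).any():
            raise ValueError("negative edge weight in heterogeneous network")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("heterogeneous adjacency is not symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def n_microbes(self) -> int:
        return self.n_nodes - self.n_diseases

    @property
    def labels(self) -> list[str]:
        return [node_label(kind, ident) for kind, ident in self.node_index]

    def to_edge_list(self):
        """Upper-triangle positive-weight edges as (label_a, label_b, weight)."""
        labels = self.labels
        rows, cols = np.nonzero(np.triu(self.weights, k=1))
        return [(labels[a], labels[b], float(self.weights[a, b])) for a, b in zip(rows, cols)]

    def write_tsv(self, path) -> None:
        labels = self.labels
        write_matrix_tsv(labels, labels, self.weights, path)


def build_heterogeneous_network(
    SD: SimilarityMatrix,
    SM: SimilarityMatrix,
    assoc: AssociationMatrix,
    remove_self_loops: bool = True,
) -> HeterogeneousNetwork:
    """Assemble P = [[SD, MD], [MD.T, SM]] with diseases-then-microbes order."""
    n_d, n_m = assoc.n_diseases, assoc.n_microbes
    if SD.values.shape != (n_d, n_d):
        raise ValueError(
            f"disease similarity block is {SD.values.shape}, expected ({n_d}, {n_d})"
        )
    if SM.values.shape != (n_m, n_m):
        raise ValueError(
            f"microbe similarity block is {SM.values.shape}, expected ({n_m}, {n_m})"
        )
    if SD.ids != assoc.diseases:
        raise ValueError("disease similarity ids do not match association rows")
    if SM.ids != assoc.microbes:
        raise ValueError("microbe similarity ids do not match association columns")
    n = n_d + n_m
    P = np.zeros((n, n))
    P[:n_d, :n_d] = SD.values
    P[n_d:, n_d:] = SM.values
    P[:n_d, n_d:] = assoc.values
    P[n_d:, :n_d] = assoc.values.T
    if remove_self_loops:
        np.fill_diagonal(P, 0.0)
    node_index = [("disease", d) for d in assoc.diseases] + [("microbe", m) for m in assoc.microbes]
    return HeterogeneousNetwork(
        node_index=node_index,
        weights=P,
        n_diseases=n_d,
        self_loops_removed=remove_self_loops,
    )
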