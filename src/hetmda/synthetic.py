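"""Synthetic bipartite association matrices with planted co-cluster structure.

The generator emulates the guilt-by-association signal the prediction
method relies on: diseases and microbes are partitioned into matched
blocks, and a (disease, microbe) pair is associated with high probability
inside a matched block and low probability elsewhere.  Block labels are
returned so tests can verify that GIP similarity actually recovers the
planted structure, not just an AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix

__all__ = ["SyntheticSpec", "generate_associations", "expected_associations", "hmdad_sized_fixture"]


@dataclass
class SyntheticSpec:
    """Planted-block generator settings.

    Defaults are the package's standard benchmark conditions: a 30 x 200
    matrix with 4 co-clusters, in-block association probability 0.5 and
    background probability 0.02.
    """

    n_diseases: int = 30
    n_microbes: int = 200
    n_blocks: int = 4
    within_block_prob: float = 0.5
    background_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_microbes < 1:
            raise ValueError("matrix dimensions must be positive")
        if not (1 <= self.n_blocks <= min(self.n_diseases, self.n_microbes)):
            raise ValueError("n_blocks must fit inside both dimensions")
        for prob in (self.within_block_prob, self.background_prob):
            if not (0.0 <= prob <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.within_block_prob == 0.0 and self.background_prob == 0.0:
            raise ValueError("expected density is zero; fixture would be empty")
        if self.within_block_prob <= self.background_prob:
            raise ValueError(
                "within_block_prob must exceed background_prob for recoverable signal"
            )


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    labels = np.empty(n, dtype=np.int64)
    for b, chunk in enumerate(np.array_split(np.arange(n), n_blocks)):
        labels[chunk] = b
    return labels


def generate_associations(spec: SyntheticSpec):
    """Sample an association matrix from the planted-block model.

    Returns ``(assoc, disease_blocks, microbe_blocks)`` where the block
    arrays give each entity's planted co-cluster label.  Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))
    d_blocks = _block_labels(spec.n_diseases, spec.n_blocks)
    m_blocks = _block_labels(spec.n_microbes, spec.n_blocks)
    prob = np.where(
        d_blocks[:, None] == m_blocks[None, :],
        spec.within_block_prob,
        spec.background_prob,
    )
    values = (rng.random((spec.n_diseases, spec.n_microbes)) < prob).astype(float)
    diseases = [f"D{j + 1:03d}" for j in range(spec.n_diseases)]
    microbes = [f"M{i + 1:03d}" for i in range(spec.n_microbes)]
    return AssociationMatrix(diseases, microbes, values), d_blocks, m_blocks


def expected_associations(spec: SyntheticSpec) -> float:
    """Expected number of ones under the generator, given its block partition."""
    d_blocks = _block_labels(spec.n_diseases, spec.n_blocks)
    m_blocks = _block_labels(spec.n_microbes, spec.n_blocks)
    in_block = (d_blocks[:, None] == m_blocks[None, :]).sum()
    total = spec.n_diseases * spec.n_microbes
    return float(in_block * spec.within_block_prob + (total - in_block) * spec.background_prob)


def hmdad_sized_fixture(seed: int = 0) -> AssociationMatrix:
    """A 39 x 292 synthetic matrix with ~450 associations in 5 blocks.

    Emulates the size and sparsity of the curated human microbe-disease
    association catalogue (39 diseases, 292 microbes, 450 distinct
    associations); the probabilities are set so the expected ones count is
    approximately 450.
    """
    spec = SyntheticSpec(
        n_diseases=39,
        n_microbes=292,
        n_blocks=5,
        within_block_prob=0.1775,
        background_prob=0.005,
        seed=seed,
    )
    assoc, _, _ = generate_associations(spec)
    return assoc
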