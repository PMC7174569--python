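"""Hybrid direct/indirect association scoring from node embeddings.

For microbe ``m_i`` and disease ``d_j`` the score is a similarity-weighted
vote over the known association labels:

    Score(m_i, d_j) =
        [ sum_k Sim(m_i, m_k) MD[j, k] + sum_k Sim(d_j, d_k) MD[k, i] ]
        / [ sum_k Sim(m_i, m_k) + sum_k Sim(d_j, d_k) ]

where Sim is the cosine similarity of the learned node vectors, the first
sums run over all microbes and the second over all diseases.  The direct
label MD[j, i] enters through both self-terms (Sim == 1), so a single known
association still produces a strong score; the remaining terms propagate
indirect evidence from embedding-similar neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix
from .embedding import EmbeddingTable
from .hetnet import node_label

__all__ = ["ScoreMatrix", "cosine_similarity", "score_pair", "score_all", "rank_candidates"]


@dataclass
class ScoreMatrix:
    """Real-valued disease x microbe prediction scores."""

    diseases: list[str]
    microbes: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.diseases), len(self.microbes)):
            raise ValueError("score matrix shape does not match identifier lists")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite score")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; errors on a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def _cosine_matrix(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero embedding vector")
    unit = vectors / norms
    return unit @ unit.T


def _embedding_sims(emb: EmbeddingTable, assoc: AssociationMatrix,
                    clip_negative: bool) -> tuple[np.ndarray, np.ndarray]:
    sim_m = _cosine_matrix(emb.subset([node_label("microbe", m) for m in assoc.microbes]))
    sim_d = _cosine_matrix(emb.subset([node_label("disease", d) for d in assoc.diseases]))
    if clip_negative:
        sim_m = np.maximum(sim_m, 0.0)
        sim_d = np.maximum(sim_d, 0.0)
    return sim_m, sim_d


def score_from_similarities(sim_m: np.ndarray, sim_d: np.ndarray,
                            MD: np.ndarray) -> np.ndarray:
    """Score matrix from explicit same-kind similarity matrices.

    ``sim_m`` is microbes x microbes, ``sim_d`` diseases x diseases, ``MD``
    the binary disease x microbe labels.  Exposed separately so tests can
    substitute exact similarity structures (e.g. the identity).
    """
    # numerator[j, i] = sum_k sim_m[i, k] MD[j, k] + sum_k sim_d[j, k] MD[k, i]
    numer = MD @ sim_m.T + sim_d @ MD
    denom = sim_m.sum(axis=1)[None, :] + sim_d.sum(axis=1)[:, None]
    scores = np.zeros_like(numer)
    ok = denom != 0
    if not ok.all():
        warnings.warn("zero scoring denominator; affected scores set to 0", RuntimeWarning)
    np.divide(numer, denom, out=scores, where=ok)
    return scores


def score_pair(i: int, j: int, emb: EmbeddingTable, assoc: AssociationMatrix,
               clip_negative: bool = False) -> float:
    """Score for microbe index ``i`` and disease index ``j`` (loop form)."""
    sim_m, sim_d = _embedding_sims(emb, assoc, clip_negative)
    MD = assoc.values
    numer = float(sim_m[i] @ MD[j] + sim_d[j] @ MD[:, i])
    denom = float(sim_m[i].sum() + sim_d[j].sum())
    if denom == 0.0:
        warnings.warn("zero scoring denominator; score set to 0", RuntimeWarning)
        return 0.0
    return numer / denom


def score_all(emb: EmbeddingTable, assoc: AssociationMatrix,
              clip_negative: bool = False) -> ScoreMatrix:
    """Score every disease-microbe pair (vectorised)."""
    sim_m, sim_d = _embedding_sims(emb, assoc, clip_negative)
    values = score_from_similarities(sim_m, sim_d, assoc.values)
    return ScoreMatrix(diseases=list(assoc.diseases), microbes=list(assoc.microbes), values=values)


def rank_candidates(scores: ScoreMatrix, assoc: AssociationMatrix, disease: str,
                    top_n: int = 10) -> list[tuple[str, float]]:
    """Top candidate microbes for one disease, known associations excluded.

    Sorted by score descending; ties broken by microbe list order.  Returns
    at most ``top_n`` (microbe, score) pairs.
    """
    if disease not in scores.diseases:
        raise KeyError(f"unknown disease identifier {disease!r}")
    j = scores.diseases.index(disease)
    row = scores.values[j]
    known = assoc.values[assoc.diseases.index(disease)] > 0
    candidates = [i for i in range(len(scores.microbes)) if not known[i]]
    # stable sort on negated score preserves identifier order among ties
    order = sorted(candidates, key=lambda i: -row[i])
    return [(scores.microbes[i], float(row[i])) for i in order[:top_n]]
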