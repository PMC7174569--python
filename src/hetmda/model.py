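"""Model/Results facade over the prediction pipeline.

:class:`MicrobeDiseaseLinkModel` holds the data (a binary disease x microbe
association matrix) and the hyperparameters; :meth:`fit` runs the full
pipeline — GIP similarities, heterogeneous network, biased walks, skip-gram
embedding, hybrid scoring — and returns a :class:`LinkPredictionResults`
carrying every intermediate plus the score matrix, ranked candidates and a
text summary.  Cross-validation hangs off the model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import AssociationMatrix, read_association_edgelist
from .embedding import EmbeddingParams, WalkParams, generate_walks, train_skipgram
from .evaluation import CVConfig, CVResult, kfold_cv, loocv
from .hetnet import build_heterogeneous_network
from .scoring import rank_candidates, score_all
from .similarity import disease_similarity, microbe_similarity

__all__ = ["MicrobeDiseaseLinkModel", "LinkPredictionResults"]


class MicrobeDiseaseLinkModel:
    """Heterogeneous-network link-prediction model for microbe-disease pairs.

    Parameters
    ----------
    assoc : AssociationMatrix
        Known binary associations (rows diseases, columns microbes).
    walk_params, embedding_params : optional
        Biased-walk and skip-gram settings; package defaults (p=0.5, q=4,
        walk length 10, 10 walks/node; dimension 128, window 10) otherwise.
    gamma_prime : float
        GIP bandwidth scale, default 1.
    """

    def __init__(
        self,
        assoc: AssociationMatrix,
        walk_params: WalkParams | None = None,
        embedding_params: EmbeddingParams | None = None,
        gamma_prime: float = 1.0,
    ) -> None:
        self.assoc = assoc
        self.walk_params = walk_params or WalkParams()
        self.embedding_params = embedding_params or EmbeddingParams()
        self.gamma_prime = float(gamma_prime)

    @classmethod
    def from_edgelist(cls, path, dialect: str = "disease-microbe", **kwargs):
        """Build from a two-column (disease, microbe) TSV edge list."""
        return cls(read_association_edgelist(path, dialect=dialect), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, disease_col: str = "disease",
                       microbe_col: str = "microbe", **kwargs):
        """Build from an edge-list DataFrame with disease and microbe columns."""
        pairs = list(zip(df[disease_col].astype(str), df[microbe_col].astype(str)))
        diseases = list(dict.fromkeys(d for d, _ in pairs))
        microbes = list(dict.fromkeys(m for _, m in pairs))
        values = np.zeros((len(diseases), len(microbes)))
        d_idx = {d: j for j, d in enumerate(diseases)}
        m_idx = {m: i for i, m in enumerate(microbes)}
        for d, m in pairs:
            values[d_idx[d], m_idx[m]] = 1.0
        return cls(AssociationMatrix(diseases, microbes, values), **kwargs)

    def fit(self, seed: int | None = None) -> "LinkPredictionResults":
        """Run the full pipeline and return fitted results.

        ``seed`` overrides the seed stored in the walk/embedding parameter
        objects for this fit (both stages draw from streams derived from it).
        """
        wp, ep = self.walk_params, self.embedding_params
        if seed is not None:
            wp = WalkParams(p=wp.p, q=wp.q, walk_length=wp.walk_length,
                            walks_per_node=wp.walks_per_node, seed=int(seed))
            ep = EmbeddingParams(dimension=ep.dimension, context_size=ep.context_size,
                                 epochs=ep.epochs, negative_samples=ep.negative_samples,
                                 learning_rate=ep.learning_rate, seed=int(seed))
        sm = microbe_similarity(self.assoc, self.gamma_prime)
        sd = disease_similarity(self.assoc, self.gamma_prime)
        net = build_heterogeneous_network(sd, sm, self.assoc)
        corpus = generate_walks(net, wp)
        emb = train_skipgram(corpus, ep)
        scores = score_all(emb, self.assoc)
        return LinkPredictionResults(self, sm, sd, net, corpus, emb, scores, wp, ep)

    def cross_validate(
        self,
        mode: str = "kfold",
        k: int = 5,
        repeats: int = 1,
        seed: int = 0,
        masking: str = "full_recompute",
    ) -> CVResult:
        """Evaluate by LOOCV or k-fold CV over the known associations."""
        config = CVConfig(mode=mode, k=k, repeats=repeats, seed=seed, masking=masking)
        fn = loocv if mode == "loocv" else kfold_cv
        return fn(self.assoc, self.walk_params, self.embedding_params, config,
                  gamma_prime=self.gamma_prime)


class LinkPredictionResults:
    """Fitted pipeline state: intermediates, scores and reporting helpers."""

    def __init__(self, model, microbe_sim, disease_sim, network, walks,
                 embeddings, scores, walk_params, embedding_params) -> None:
        self.model = model
        self.microbe_sim = microbe_sim
        self.disease_sim = disease_sim
        self.network = network
        self.walks = walks
        self.embeddings = embeddings
        self.scores = scores
        self.walk_params = walk_params
        self.embedding_params = embedding_params

    def top_candidates(self, disease: str, n: int = 10) -> pd.DataFrame:
        """Top-n novel microbes for a disease (known associations excluded)."""
        ranked = rank_candidates(self.scores, self.model.assoc, disease, top_n=n)
        return pd.DataFrame(
            {"rank": range(1, len(ranked) + 1),
             "microbe": [m for m, _ in ranked],
             "score": [s for _, s in ranked]}
        )

    def summary(self) -> str:
        assoc = self.model.assoc
        wp, ep = self.walk_params, self.embedding_params
        known = assoc.values > 0
        lines = [
            "Microbe-disease link prediction results",
            "=======================================",
            f"diseases x microbes   : {assoc.n_diseases} x {assoc.n_microbes}",
            f"known associations    : {assoc.n_associations}"
            f" (density {assoc.values.mean():.4f})",
            f"walk params           : p={wp.p} q={wp.q} l={wp.walk_length}"
            f" r={wp.walks_per_node} seed={wp.seed}",
            f"embedding             : dim={ep.dimension} window={ep.context_size}"
            f" epochs={ep.epochs} negative={ep.negative_samples}",
            f"score range           : [{self.scores.values.min():.4f},"
            f" {self.scores.values.max():.4f}]",
            f"mean score, known     : {self.scores.values[known].mean():.4f}",
            f"mean score, candidate : {self.scores.values[~known].mean():.4f}",
        ]
        return "\n".join(lines)
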