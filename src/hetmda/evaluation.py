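"""Cross-validated evaluation of association predictions.

Protocol: each known association (or fold of associations) is masked out of
the label matrix, the full pipeline is re-run on the masked data, and the
held-out pairs' scores are ranked against the candidate pool — all pairs
that are unverified in the ORIGINAL matrix.  AUC is the rank statistic
P(held-out positive outscores a random candidate), ties counted one half,
which equals the trapezoidal area under the ROC curve and gives exactly 0.5
for a constant predictor.

Two masking modes are provided:

``full_recompute`` (default)
    similarities, network and embedding are rebuilt for every fold from the
    masked matrix, so the test edges never influence training.  This is the
    statistically correct protocol.
``fast_fixed_embedding``
    one embedding is trained on the complete matrix and only the label
    matrix inside the scoring rule is masked per fold.  Much faster for
    leave-one-out, but the test edge leaks into the embedding; use only for
    smoke tests and exploration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

from .data_io import AssociationMatrix
from .embedding import EmbeddingParams, WalkParams, generate_walks, train_skipgram
from .hetnet import build_heterogeneous_network
from .scoring import ScoreMatrix, score_all
from .similarity import disease_similarity, microbe_similarity

__all__ = [
    "CVConfig",
    "CVResult",
    "compute_auc",
    "loocv",
    "kfold_cv",
    "topn_hits",
    "parameter_grid",
    "pipeline_scores",
]


@dataclass
class CVConfig:
    """Cross-validation settings."""

    mode: str = "kfold"
    k: int = 5
    repeats: int = 1
    seed: int = 0
    masking: str = "full_recompute"

    def __post_init__(self) -> None:
        if self.mode not in ("loocv", "kfold"):
            raise ValueError(f"mode must be 'loocv' or 'kfold', got {self.mode!r}")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if self.masking not in ("full_recompute", "fast_fixed_embedding"):
            raise ValueError(f"unknown masking mode {self.masking!r}")


@dataclass
class CVResult:
    """Cross-validation outcome.

    ``auc`` is the mean of per-fold AUCs for k-fold CV and the pooled-rank
    AUC for LOOCV.  ``positive_scores``/``candidate_scores`` pool the
    held-out and candidate-pool scores over all folds of the last repeat.
    """

    auc: float
    fold_aucs: list[float]
    roc_points: np.ndarray = field(repr=False)  # columns (fpr, tpr)
    pr_points: np.ndarray = field(repr=False)   # columns (recall, precision)
    positive_scores: np.ndarray = field(repr=False)
    candidate_scores: np.ndarray = field(repr=False)
    folds: list[list[tuple[int, int]]] = field(default_factory=list, repr=False)
    config: CVConfig | None = None

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Cross-validation summary",
            "------------------------",
            f"mode           : {cfg.mode if cfg else '?'}"
            + (f" (k={cfg.k}, repeats={cfg.repeats})" if cfg and cfg.mode == "kfold" else ""),
            f"masking        : {cfg.masking if cfg else '?'}",
            f"folds          : {len(self.fold_aucs)}",
            f"mean AUC       : {self.auc:.4f}",
            f"fold AUC range : [{min(self.fold_aucs):.4f}, {max(self.fold_aucs):.4f}]",
            f"held-out pairs : {len(self.positive_scores)}",
            f"candidate pool : {len(self.candidate_scores)}",
        ]
        return "\n".join(lines)


def compute_auc(positive_scores, candidate_scores) -> float:
    """Rank-based AUC with midrank tie handling.

    Equals the probability that a positive outranks a candidate (ties worth
    1/2), i.e. the Mann-Whitney U statistic normalised by n_pos * n_cand.
    """
    pos = np.asarray(positive_scores, dtype=float)
    cand = np.asarray(candidate_scores, dtype=float)
    if pos.size == 0 or cand.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, cand]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * cand.size))


def pipeline_scores(
    assoc: AssociationMatrix,
    walk_params: WalkParams,
    emb_params: EmbeddingParams,
    gamma_prime: float = 1.0,
) -> ScoreMatrix:
    """Full prediction pipeline: similarities -> network -> walks -> skip-gram -> scores."""
    sm = microbe_similarity(assoc, gamma_prime)
    sd = disease_similarity(assoc, gamma_prime)
    net = build_heterogeneous_network(sd, sm, assoc)
    corpus = generate_walks(net, walk_params)
    emb = train_skipgram(corpus, emb_params)
    return score_all(emb, assoc)


def _derived_params(walk_params: WalkParams, emb_params: EmbeddingParams, fold_seed: int):
    wp = WalkParams(p=walk_params.p, q=walk_params.q, walk_length=walk_params.walk_length,
                    walks_per_node=walk_params.walks_per_node, seed=fold_seed)
    ep = EmbeddingParams(dimension=emb_params.dimension, context_size=emb_params.context_size,
                         epochs=emb_params.epochs, negative_samples=emb_params.negative_samples,
                         learning_rate=emb_params.learning_rate, seed=fold_seed)
    return wp, ep


def _fold_seeds(base_seed: int, n: int, repeat: int) -> list[int]:
    ss = np.random.SeedSequence([int(base_seed), 97, int(repeat)])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _run_folds(
    assoc: AssociationMatrix,
    folds: list[list[tuple[int, int]]],
    walk_params: WalkParams,
    emb_params: EmbeddingParams,
    config: CVConfig,
    gamma_prime: float,
    repeat: int,
    score_fn=None,
):
    """Score every fold; returns per-fold (positive, candidate) score arrays."""
    cand_mask = assoc.values == 0  # candidates fixed by the original matrix
    seeds = _fold_seeds(config.seed, len(folds), repeat)
    fixed_emb = None
    if config.masking == "fast_fixed_embedding" and score_fn is None:
        wp, ep = _derived_params(walk_params, emb_params, seeds[0])
        sm = microbe_similarity(assoc, gamma_prime)
        sd = disease_similarity(assoc, gamma_prime)
        net = build_heterogeneous_network(sd, sm, assoc)
        fixed_emb = train_skipgram(generate_walks(net, wp), ep)
    per_fold = []
    for fold, fold_seed in zip(folds, seeds):
        masked = assoc.masked(fold)
        if masked.values.sum() == 0:
            warnings.warn("masking removed every association; fold skipped", RuntimeWarning)
            continue
        if score_fn is not None:
            scores = score_fn(masked, fold_seed)
        elif config.masking == "fast_fixed_embedding":
            scores = score_all(fixed_emb, masked)
        else:
            wp, ep = _derived_params(walk_params, emb_params, fold_seed)
            scores = pipeline_scores(masked, wp, ep, gamma_prime)
        pos = np.array([scores.values[j, i] for j, i in fold])
        cand = scores.values[cand_mask]
        per_fold.append((pos, cand))
    if not per_fold:
        raise ValueError("every fold was skipped; nothing to evaluate")
    return per_fold


def _curves(pos: np.ndarray, cand: np.ndarray):
    labels = np.concatenate([np.ones(pos.size), np.zeros(cand.size)])
    scores = np.concatenate([pos, cand])
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return np.column_stack([fpr, tpr]), np.column_stack([recall, precision])


def _known_pairs(assoc: AssociationMatrix) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(assoc.values)
    return [(int(j), int(i)) for j, i in zip(rows, cols)]


def loocv(
    assoc: AssociationMatrix,
    walk_params: WalkParams,
    emb_params: EmbeddingParams,
    config: CVConfig | None = None,
    gamma_prime: float = 1.0,
    score_fn=None,
) -> CVResult:
    """Leave-one-out CV: each known association is masked and ranked in turn.

    ``score_fn(masked_assoc, fold_seed) -> ScoreMatrix`` may replace the
    pipeline (used by tests to substitute oracle or constant scorers).
    """
    config = config or CVConfig(mode="loocv")
    pairs = _known_pairs(assoc)
    if len(pairs) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    folds = [[pair] for pair in pairs]
    per_fold = _run_folds(assoc, folds, walk_params, emb_params, config,
                          gamma_prime, repeat=0, score_fn=score_fn)
    pos = np.concatenate([p for p, _ in per_fold])
    cand = np.concatenate([c for _, c in per_fold])
    auc = compute_auc(pos, cand)  # pooled ranking over all folds
    fold_aucs = [compute_auc(p, c) for p, c in per_fold]
    roc, pr = _curves(pos, cand)
    return CVResult(auc=auc, fold_aucs=fold_aucs, roc_points=roc, pr_points=pr,
                    positive_scores=pos, candidate_scores=cand, folds=folds, config=config)


def make_folds(pairs: list[tuple[int, int]], k: int, seed: int) -> list[list[tuple[int, int]]]:
    """Shuffle known pairs and split into k near-equal groups (sizes differ by <=1)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    order = rng.permutation(len(pairs))
    return [[pairs[i] for i in chunk] for chunk in np.array_split(order, k)]


def kfold_cv(
    assoc: AssociationMatrix,
    walk_params: WalkParams,
    emb_params: EmbeddingParams,
    config: CVConfig | None = None,
    gamma_prime: float = 1.0,
    score_fn=None,
) -> CVResult:
    """k-fold CV over known associations; AUC averaged over folds and repeats."""
    config = config or CVConfig(mode="kfold")
    pairs = _known_pairs(assoc)
    if config.k > len(pairs):
        raise ValueError("k exceeds the number of known associations")
    all_fold_aucs: list[float] = []
    for rep in range(config.repeats):
        folds = make_folds(pairs, config.k, seed=int(config.seed) + rep)
        per_fold = _run_folds(assoc, folds, walk_params, emb_params, config,
                              gamma_prime, repeat=rep, score_fn=score_fn)
        all_fold_aucs.extend(compute_auc(p, c) for p, c in per_fold)
    pos = np.concatenate([p for p, _ in per_fold])
    cand = np.concatenate([c for _, c in per_fold])
    roc, pr = _curves(pos, cand)
    return CVResult(auc=float(np.mean(all_fold_aucs)), fold_aucs=all_fold_aucs,
                    roc_points=roc, pr_points=pr, positive_scores=pos,
                    candidate_scores=cand, folds=folds, config=config)


def topn_hits(result: CVResult, n_values: list[int]) -> list[tuple[int, int]]:
    """Held-out positives ranked in the global top N of the candidate pool.

    A positive's global rank is 1 + the number of candidate scores strictly
    greater than it (competition ranking; ties never push a positive down).
    """
    counts = []
    cand_sorted = np.sort(result.candidate_scores)
    n_cand = cand_sorted.size
    # rank = 1 + #candidates strictly above each positive
    above = n_cand - np.searchsorted(cand_sorted, result.positive_scores, side="right")
    ranks = 1 + above
    for n in n_values:
        if n <= 0:
            raise ValueError("N must be positive")
        counts.append((int(n), int((ranks <= n).sum())))
    return counts


def parameter_grid(
    assoc: AssociationMatrix,
    p_values: list[float],
    q_values: list[float],
    walk_params: WalkParams | None = None,
    emb_params: EmbeddingParams | None = None,
    config: CVConfig | None = None,
    gamma_prime: float = 1.0,
) -> pd.DataFrame:
    """Mean k-fold AUC for every (p, q) combination (rows p, columns q)."""
    if not p_values or not q_values:
        raise ValueError("parameter grids must be non-empty")
    walk_params = walk_params or WalkParams()
    emb_params = emb_params or EmbeddingParams()
    config = config or CVConfig(mode="kfold")
    table = np.zeros((len(p_values), len(q_values)))
    for a, p in enumerate(p_values):
        for b, q in enumerate(q_values):
            wp = WalkParams(p=p, q=q, walk_length=walk_params.walk_length,
                            walks_per_node=walk_params.walks_per_node, seed=walk_params.seed)
            res = kfold_cv(assoc, wp, emb_params, config, gamma_prime)
            table[a, b] = res.auc
    return pd.DataFrame(table, index=pd.Index(p_values, name="p"),
                        columns=pd.Index(q_values, name="q"))
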