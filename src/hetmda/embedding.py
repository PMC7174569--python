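"""Second-order biased random walks and skip-gram node embeddings.

Walks follow the node2vec sampling scheme: from current node ``u`` after
arriving from ``t``, the unnormalised probability of stepping to a neighbour
``x`` is ``alpha_pq(t, x) * w_ux`` where the bias ``alpha`` depends on the
graph distance ``d_tx`` between the previous node and the candidate:

    alpha = 1/p  if x == t            (return)
            1    if x is adjacent to t (stay close)
            1/q  otherwise             (move outward)

Small ``p`` encourages backtracking (local, BFS-like exploration); small
``q`` pushes the walk outward (DFS-like).  The first step of each walk has
no previous node and is purely weight-proportional.

The walk corpus is then fed to a skip-gram model with negative sampling
(the word2vec objective, each node playing the role of a word), trained by
plain SGD in a numba-compiled kernel.  Training is deterministic given the
seed: pair order, negative samples and initial vectors all derive from one
numpy Generator, and the kernel is single-threaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .hetnet import HeterogeneousNetwork

__all__ = [
    "WalkParams",
    "EmbeddingParams",
    "WalkCorpus",
    "EmbeddingTable",
    "transition_bias",
    "step_distribution",
    "generate_walks",
    "train_skipgram",
]

# stage tags keep per-stage RNG streams disjoint when derived from one seed
_WALK_TAG = 11
_SG_TAG = 23


@dataclass
class WalkParams:
    """Biased-walk settings.

    p : return parameter (>0); larger p discourages immediate backtracking.
    q : in-out parameter (>0); q > 1 keeps walks local, q < 1 pushes outward.
    walk_length : nodes per walk (a walk makes walk_length - 1 steps).
    walks_per_node : walks started from every node.
    """

    p: float = 0.5
    q: float = 4.0
    walk_length: int = 10
    walks_per_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be at least 2")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be at least 1")


@dataclass
class EmbeddingParams:
    """Skip-gram training settings.

    The window is dynamic as in word2vec: for every centre position the
    effective half-window is drawn uniformly from 1..context_size, so near
    co-occurrences are weighted more heavily than distant ones.  Defaults
    (10 epochs at learning rate 0.05) are tuned for walk corpora of a few
    thousand sentences, where the classic one-pass text settings leave the
    objective far from convergence.
    """

    dimension: int = 128
    context_size: int = 10
    epochs: int = 10
    negative_samples: int = 5
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be at least 1")
        if self.context_size < 1:
            raise ValueError("context_size must be at least 1")
        if self.epochs < 1 or self.negative_samples < 0:
            raise ValueError("invalid training parameters")


@dataclass
class WalkCorpus:
    """Walks as integer node-index sequences plus the label vocabulary."""

    walks: list[np.ndarray]
    node_labels: list[str]

    def __len__(self) -> int:
        return len(self.walks)

    def as_labels(self) -> list[list[str]]:
        return [[self.node_labels[i] for i in walk] for walk in self.walks]

    def write_text(self, path) -> None:
        """One walk per line, space-separated node labels."""
        with open(path, "w", encoding="utf-8") as fh:
            for walk in self.walks:
                fh.write(" ".join(self.node_labels[i] for i in walk) + "\n")


@dataclass
class EmbeddingTable:
    """Node label -> dense vector lookup."""

    ids: list[str]
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector per id required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding vector")
        self._index = {label: i for i, label in enumerate(self.ids)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, label: str) -> np.ndarray:
        return self.vectors[self._index[label]]

    def subset(self, labels: list[str]) -> np.ndarray:
        return self.vectors[[self._index[lb] for lb in labels]]

    def write_word2vec(self, path) -> None:
        """word2vec text format: header "count dim", then "id v1 ... vd"."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.ids)} {self.dimension}\n")
            for label, vec in zip(self.ids, self.vectors):
                fh.write(label + " " + " ".join(repr(float(v)) for v in vec) + "\n")

    @classmethod
    def read_word2vec(cls, path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            count, dim = map(int, fh.readline().split())
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        vectors = np.asarray(rows)
        if vectors.shape != (count, dim):
            raise ValueError("word2vec file header does not match contents")
        return cls(ids=ids, vectors=vectors)


def transition_bias(d_tx: int, p: float, q: float) -> float:
    """Second-order bias alpha_pq: 1/p at distance 0, 1 at 1, 1/q at 2."""
    if d_tx == 0:
        return 1.0 / p
    if d_tx == 1:
        return 1.0
    if d_tx == 2:
        return 1.0 / q
    raise ValueError(f"d_tx must be in {{0, 1, 2}}, got {d_tx}")


def step_distribution(
    net: HeterogeneousNetwork,
    prev: int | None,
    curr: int,
    params: WalkParams,
) -> np.ndarray:
    """Normalised next-step probabilities from ``curr`` given previous node.

    Returns a length-n_nodes vector; entries are zero off the neighbour set
    of ``curr``.  With ``prev is None`` (first step of a walk) the step is
    purely weight-proportional.
    """
    w = net.weights[curr]
    if not (w > 0).any():
        raise ValueError(f"node {curr} has no neighbours with positive weight")
    if prev is None:
        probs = w.copy()
    else:
        adj_prev = net.weights[prev] > 0
        alpha = np.where(adj_prev, 1.0, 1.0 / params.q)
        alpha[prev] = 1.0 / params.p
        probs = w * alpha
    return probs / probs.sum()


def _draw(cdf: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cdf, u * cdf[-1], side="right"))


def generate_walks(net: HeterogeneousNetwork, params: WalkParams) -> WalkCorpus:
    """Run ``walks_per_node`` biased walks from every node.

    Node order is reshuffled each pass.  A dead end (node with no positive
    out-weight) truncates the walk; otherwise each walk holds exactly
    ``walk_length`` nodes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), _WALK_TAG]))
    W = net.weights
    n = net.n_nodes
    adj = W > 0
    inv_p, inv_q = 1.0 / params.p, 1.0 / params.q
    first_cdf = np.cumsum(W, axis=1)  # weight-proportional first step
    walkable = W.sum(axis=1) > 0
    walks: list[np.ndarray] = []
    for _ in range(params.walks_per_node):
        for start in rng.permutation(n):
            walk = [int(start)]
            if not walkable[start]:
                walks.append(np.asarray(walk, dtype=np.int64))
                continue
            curr = int(start)
            prev = -1
            while len(walk) < params.walk_length:
                if prev < 0:
                    nxt = _draw(first_cdf[curr], rng.random())
                else:
                    alpha = np.where(adj[prev], 1.0, inv_q)
                    alpha[prev] = inv_p
                    pi = W[curr] * alpha
                    total = pi.sum()
                    if total <= 0:
                        break
                    nxt = _draw(np.cumsum(pi), rng.random())
                walk.append(int(nxt))
                prev, curr = curr, int(nxt)
                if not walkable[curr]:
                    break
            walks.append(np.asarray(walk, dtype=np.int64))
    return WalkCorpus(walks=walks, node_labels=net.labels)


@njit(cache=True)
def _sgns_epoch(w_in, w_out, centers, contexts, negatives, order, lr0, lr_min, t0, t_total):
    """One SGD epoch of skip-gram with negative sampling, word2vec-style."""
    n_pairs = order.shape[0]
    dim = w_in.shape[1]
    k = negatives.shape[1]
    grad_c = np.empty(dim, dtype=np.float32)
    for step in range(n_pairs):
        i = order[step]
        c = centers[i]
        t = t0 + step
        lr = lr0 * (1.0 - t / t_total)
        if lr < lr_min:
            lr = lr_min
        for d in range(dim):
            grad_c[d] = 0.0
        for s in range(k + 1):
            if s == 0:
                target = contexts[i]
                label = 1.0
            else:
                target = negatives[i, s - 1]
                if target == contexts[i]:
                    continue
                label = 0.0
            dot = 0.0
            for d in range(dim):
                dot += w_in[c, d] * w_out[target, d]
            if dot > 8.0:
                sig = 1.0
            elif dot < -8.0:
                sig = 0.0
            else:
                sig = 1.0 / (1.0 + np.exp(-dot))
            g = (sig - label) * lr
            for d in range(dim):
                grad_c[d] += g * w_out[target, d]
                w_out[target, d] -= g * w_in[c, d]
        for d in range(dim):
            w_in[c, d] -= grad_c[d]


def _skipgram_pairs(
    walks: list[np.ndarray], window: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(centre, context) index pairs; dynamic reduced window when rng given."""
    centers, contexts = [], []
    for walk in walks:
        L = len(walk)
        for i in range(L):
            b = window if rng is None else int(rng.integers(1, window + 1))
            lo, hi = max(0, i - b), min(L, i + b + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(walk[i])
                    contexts.append(walk[j])
    return (np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64))


def train_skipgram(corpus: WalkCorpus, params: EmbeddingParams) -> EmbeddingTable:
    """Train node vectors on the walk corpus with skip-gram + negative sampling.

    Every node in the corpus vocabulary must occur in at least one walk of
    length >= 2 (walks start from every node, so this holds for any network
    without isolated vertices).  Negative samples are drawn from the unigram
    distribution raised to the 3/4 power, as in word2vec.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    n_nodes = len(corpus.node_labels)
    counts = np.zeros(n_nodes, dtype=np.int64)
    for walk in corpus.walks:
        counts[walk] += 1
    if (counts == 0).any():
        missing = [corpus.node_labels[i] for i in np.nonzero(counts == 0)[0][:5]]
        raise ValueError(f"nodes absent from walk corpus: {missing}")

    if all(len(w) < 2 for w in corpus.walks):
        raise ValueError("walk corpus contains no co-occurrence pairs")
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), _SG_TAG]))

    w_in = ((rng.random((n_nodes, params.dimension)) - 0.5) / params.dimension).astype(np.float32)
    w_out = np.zeros((n_nodes, params.dimension), dtype=np.float32)

    noise = counts.astype(float) ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())
    # expected pairs per epoch under the dynamic window, for the lr schedule
    est_pairs = sum(min(2 * params.context_size, len(w) - 1) * len(w) for w in corpus.walks)
    t_total = float(params.epochs * max(est_pairs, 1))
    lr_min = params.learning_rate * 1e-4
    done = 0.0
    for _ in range(params.epochs):
        centers, contexts = _skipgram_pairs(corpus.walks, params.context_size, rng)
        n_pairs = centers.shape[0]
        order = rng.permutation(n_pairs)
        k = max(params.negative_samples, 1)
        negatives = np.searchsorted(
            noise_cdf, rng.random((n_pairs, k))
        ).astype(np.int64)
        if params.negative_samples == 0:
            negatives = negatives[:, :0]
        _sgns_epoch(
            w_in, w_out, centers, contexts, negatives, order,
            params.learning_rate, lr_min, done, t_total,
        )
        done += n_pairs
    return EmbeddingTable(ids=list(corpus.node_labels), vectors=w_in.astype(np.float64))
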