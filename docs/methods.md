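# Methods

## Model and assumptions

`hetmda` ranks unverified disease–microbe pairs from a binary association
matrix `MD` (rows diseases, columns microbes) under one assumption:
entities with similar association profiles tend to share further
associations. The pipeline turns that assumption into a ranking in four
steps — kernel similarities, a heterogeneous network, node embeddings, and
a similarity-weighted vote over known labels.

**GIP kernel.** For profiles `x_i` (microbe = column of `MD`, disease =
row), similarity is `exp(−γ‖x_i − x_j‖²)` with `γ = γ′ / mean_i ‖x_i‖²`.
The normalisation makes the kernel scale-free in the catalogue density:
doubling every profile's association count roughly halves γ. γ′ (default 1,
dimensionless) is the only free similarity parameter. The kernel is a
proper Gaussian kernel, hence symmetric positive semidefinite with unit
diagonal, and entries lie in (0, 1]. An entity with an all-zero profile
(possible after cross-validation masking) still has defined similarities;
only a fully zero matrix is rejected, because the bandwidth normaliser
would vanish.

**Heterogeneous network.** `P = [[SD, MD], [MDᵀ, SM]]`, diseases first.
Similarity edges are never thresholded, so each within-kind block is a
complete weighted graph; the edge set for the walk rule is "weight > 0".
The diagonal is removed by default: a self-loop of weight 1 would dominate
every step distribution, and the walk model intends neighbourhood
exploration. The bias distances d(t,x) are computed on the same
positive-weight adjacency; since the only diagonal entries removed are the
self-similarities, the d = 0 case (x = t) is handled explicitly and the
removal does not affect distances.

**Second-order walks.** From current node `u` with previous node `t`, the
step weight to `x` is `α_pq(t,x)·w_ux`, with α = 1/p, 1, 1/q for
d(t,x) = 0, 1, 2; the first step of a walk is weight-proportional. Walk
length counts *nodes* (l = 10 ⇒ 9 steps). Defaults p = 0.5, q = 4: a
mildly backtracking, locally exploring walk, which is the regime that
scores best under cross-validation on this kind of network. 10 walks per
node is the conventional choice in the node2vec literature; dead ends
truncate a walk silently (they occur only for isolated nodes). Sampling
uses on-the-fly normalisation with inverse-CDF draws from one seeded
generator; any implementation reproducing the analytic step distribution
would be equivalent, but this one is simple and exactly reproducible.

**Skip-gram embeddings.** The walk corpus (one walk = one sentence) trains
skip-gram with negative sampling: 128-dimensional vectors, symmetric
window of 10, 5 negatives drawn from the unigram distribution raised to
3/4, input vectors initialised uniform in ±0.5/dim, output vectors zero,
linear learning-rate decay to 10⁻⁴ of its start value. The window is
*dynamic* — the effective half-window is drawn uniformly from
1..context_size per centre, the word2vec convention that up-weights close
co-occurrences. Training runs 10 epochs at initial rate 0.05 by default:
the classic one-pass text-corpus settings (5 epochs at 0.025) assume
billions of tokens, whereas a walk corpus here has ~10⁴–10⁵ tokens, and
with them SGD stops far from convergence — visible as uniformly high,
poorly separated cosine similarities and a cross-validated AUC well below
what scoring directly with the GIP similarities achieves. The chosen
budget closes most of that gap; all settings are exposed in
`EmbeddingParams`. Training is single-threaded and fully deterministic
given the seed (pair order, window draws, negatives and initialisation all
derive from one generator).

**Scoring.** `Score(m_i, d_j)` is the ratio of
`Σ_k Sim(m_i,m_k)·MD(j,k) + Σ_k Sim(d_j,d_k)·MD(k,i)` to
`Σ_k Sim(m_i,m_k) + Σ_k Sim(d_j,d_k)`, with `Sim` the cosine similarity of
embedding vectors; the first sums range over microbes, the second over
diseases (the denominator's second sum is over diseases, matching the
numerator — anything else would be dimensionally inconsistent). Self-terms
are included: they contribute `Sim = 1` times the direct label, which is
what lets a single known association still produce a strong score.
Negative cosines are kept by default; with `clip_negative=True` the score
is a weighted mean of binary labels and lies in [0, 1]. A zero denominator
(pathological embeddings only) yields score 0 with a warning rather than
an abort. Ranked candidate lists exclude the already-known microbes of a
disease and break ties by microbe list order, deterministically.

## Cross-validation protocol

Held-out known associations are masked to 0; the candidate pool is every
pair unverified in the *original* matrix, so held-out positives are never
counted as negatives. AUC is the midrank Mann–Whitney statistic
(probability a positive outranks a candidate, ties at ½), identical to the
trapezoidal ROC area; a constant predictor scores exactly 0.5. k-fold CV
partitions the known pairs into near-equal shuffled groups (sizes differ
by ≤ 1) and reports the mean of per-fold AUCs (with optional repeats under
derived seeds); LOOCV reports the pooled-rank AUC over all folds.
Top-N counting assigns each held-out positive the competition rank
1 + (number of candidate scores strictly greater); ties do not push a
positive down.

Masking modes:

- `full_recompute` (default): similarities, network, walks and embedding
  are rebuilt per fold from the masked matrix. The test edge cannot leak
  into training. Cost: one full pipeline per fold.
- `fast_fixed_embedding`: one embedding trained on the complete matrix;
  only the label matrix inside the scoring rule is masked per fold. The
  test edge leaks through the embedding, so measured AUC is optimistic;
  offered for exploration and LOOCV smoke runs, never for reported
  numbers.

Per-fold seeds derive from the CV seed through a `SeedSequence`, so fold
partitions and all stage randomness are reproducible; two runs with the
same configuration are bit-identical (single-threaded).

## Synthetic data

The generator plants co-cluster structure: diseases and microbes are
partitioned into matched blocks (near-equal contiguous groups), and each
cell is Bernoulli(within_block_prob) inside a matched block, else
Bernoulli(background_prob). Defaults — 30 diseases × 200 microbes, 4
blocks, within 0.5, background 0.02 — give a sparse matrix (~14% density)
whose within-block microbes share disease profiles, i.e. exactly the
guilt-by-association signal the method assumes; block labels are returned
so tests can check that GIP similarity separates blocks, not only that AUC
is high. `hmdad_sized_fixture` emulates the size of the curated catalogue
the method is normally applied to (39 × 292 with ≈ 450 expected
associations in 5 blocks; within = 0.1775 and background = 0.005 chosen
analytically from the block partition so the expectation lands at 450).

What the generator does *not* emulate: heavy-tailed degree distributions
(real catalogues concentrate on a few well-studied diseases), correlated
annotation noise from literature curation, overlapping or nested disease
groups, and identifier-level issues. Passing tests on planted data
therefore show the pipeline recovers clean block signal through masking,
walks and embedding — they do not certify performance on real catalogues,
where the GIP kernel is known to favour well-annotated entities.

## Numerical choices and degenerate inputs

- All similarity/score arithmetic in float64; embedding training in
  float32 (the SGD noise floor dwarfs the precision difference).
- Sigmoid arguments are clamped at |8| in the trainer to avoid overflow.
- Matrix TSVs are written with shortest-round-trip float repr, so a
  write/read cycle reproduces values exactly and identical runs produce
  byte-identical files.
- Duplicate edge-list pairs collapse to one association; identifiers are
  opaque case-sensitive strings in first-appearance order (a sorted mode
  exists for order-independent output).
- Empty edge list, non-binary matrices, duplicated identifiers, zero
  vectors in cosine, empty score lists in AUC, and k > number of known
  pairs all raise immediately with specific messages.
- A fold whose masking empties the matrix is skipped with a warning
  (only possible when a fold contains every known association).

## Benchmark problem sizes

The standard benchmark (tests and `scripts/acceptance.py`) uses the
30 × 200 planted-block defaults with five-fold CV under full per-fold
retraining — 231 network nodes, ~2 300 walks and ~1.9·10⁵ training pairs
per fold — and a 10 × 30 fixture for leave-one-out. These sizes keep a
full benchmark run in the minutes range on a single core while leaving the
AUC gap to the permuted-label baseline (~0.28) far outside its seed-to-seed
variability (~0.01).

## Known limitations

- The embedding step loses similarity contrast relative to the GIP kernel
  it starts from: on planted data, scoring with raw GIP similarities
  reaches fold AUC ≈ 0.82 while embedding-cosine scoring plateaus ≈ 0.78.
  The embedding earns its keep on structures a single kernel cannot
  express (multi-hop, cross-kind paths), which the planted model does not
  exercise strongly.
- GIP similarity is degree-biased: entities with more recorded
  associations get sharper profiles. On real catalogues this inflates
  scores of well-studied microbes.
- LOOCV with `full_recompute` trains one embedding per known association;
  for catalogue-scale data (hundreds of positives) prefer k-fold, or
  accept the documented leakage of `fast_fixed_embedding`.
- Walk generation is a Python loop over steps (vectorised per step); it is
  comfortable at a few hundred nodes but not engineered for graphs orders
  of magnitude larger.
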