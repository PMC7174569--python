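# hetmda

Microbe–disease association prediction by node embedding of a heterogeneous
similarity network.

## The problem

Curated catalogues of experimentally supported microbe–disease associations
are small and sparse: a few hundred verified links between tens of diseases
and a few hundred microbes. Under the guilt-by-association premise —
microbes with similar disease profiles tend to share further associations —
the known links carry enough signal to rank the *unverified* pairs and
prioritise candidates for experimental follow-up. `hetmda` implements a
network-embedding pipeline for exactly this ranking task, for
bioinformaticians working with binary association catalogues.

## The method

Starting from the binary disease×microbe matrix `MD` (rows = diseases):

1. **GIP kernel similarities.** Microbes are compared through the Gaussian
   interaction profile kernel on their association profiles (columns of
   `MD`): `SM[i,j] = exp(−γ_m‖MD(:,i) − MD(:,j)‖²)` with bandwidth
   `γ_m = γ′ / mean_i ‖MD(:,i)‖²` (γ′ = 1 by default). `SD` is the same
   kernel on disease rows.
2. **Heterogeneous network.** One weighted graph over all nodes,
   `P = [[SD, MD], [MDᵀ, SM]]`, diseases first; the unit self-similarity
   diagonal is removed so walks never stand still.
3. **Biased random walks + skip-gram.** Second-order walks à la node2vec:
   from `u` after arriving from `t`, the step to `x` has weight
   `α_pq(t,x)·w_ux`, with `α = 1/p` when `x = t`, `1` when `x` is adjacent
   to `t`, `1/q` otherwise (defaults p = 0.5, q = 4, walk length 10, 10
   walks per node). The walk corpus trains a skip-gram model with negative
   sampling (dimension 128, window 10), giving one vector per node.
4. **Hybrid scoring.** With `Sim` the cosine similarity between embedding
   vectors, each pair is scored by a similarity-weighted vote over known
   labels, combining direct and indirect evidence:

   `Score(m_i, d_j) = [Σ_k Sim(m_i,m_k)·MD(j,k) + Σ_k Sim(d_j,d_k)·MD(k,i)]
   / [Σ_k Sim(m_i,m_k) + Σ_k Sim(d_j,d_k)]`

5. **Evaluation.** Leave-one-out and k-fold cross-validation: held-out known
   associations are masked, the pipeline is retrained on the masked matrix,
   and the held-out pairs are ranked against all unverified pairs. AUC is
   the tie-aware rank statistic (constant scores give exactly 0.5).

A planted-block synthetic generator (`hetmda.synthetic`) produces association
matrices with co-clustered structure so the whole pipeline is testable
without external data.

## Worked example

```python
from hetmda import MicrobeDiseaseLinkModel, SyntheticSpec, generate_associations

spec = SyntheticSpec(n_diseases=12, n_microbes=40, n_blocks=3,
                     within_block_prob=0.6, background_prob=0.03, seed=11)
assoc, _, _ = generate_associations(spec)

model = MicrobeDiseaseLinkModel(assoc)   # or .from_edgelist("edges.tsv")
res = model.fit(seed=11)
print(res.summary())
print(res.top_candidates("D001", n=5))
cv = model.cross_validate(mode="kfold", k=5, seed=11)
print(cv.summary())
```

prints

```
Microbe-disease link prediction results
=======================================
diseases x microbes   : 12 x 40
known associations    : 107 (density 0.2229)
walk params           : p=0.5 q=4.0 l=10 r=10 seed=11
embedding             : dim=128 window=10 epochs=10 negative=5
score range           : [-0.0080, 0.7417]
mean score, known     : 0.4770
mean score, candidate : 0.1440

 rank microbe    score
    1    M011 0.444735
    2    M034 0.296485
    ...

Cross-validation summary
------------------------
mode           : kfold (k=5, repeats=1)
masking        : full_recompute
folds          : 5
mean AUC       : 0.7749
fold AUC range : [0.7236, 0.8037]
held-out pairs : 107
candidate pool : 1865
```

Known pairs score ~3× higher than unverified ones, and the top novel
candidate for disease `D001` (microbe `M011`) lies in its planted
co-cluster — the ranking recovers the generator's hidden structure. The
cross-validated mean AUC of 0.77 means a held-out true association outranks
a random unverified pair 77% of the time.

The same pipeline is scriptable from the shell:

```bash
hetmda simulate --n-diseases 30 --n-microbes 200 --seed 1 --out edges.tsv
hetmda run --input edges.tsv --outdir run1 --seed 1   # writes manifest.yaml
hetmda evaluate edges.tsv --mode kfold --k 5 --seed 1
hetmda grid edges.tsv --p-values 0.5,2 --q-values 1,4 --seed 1
```

`run` writes every intermediate (similarities, network, walks, embeddings,
scores, per-disease rankings) plus a manifest that reproduces the run
bit-identically.

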