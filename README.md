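# ggselect

Greedy gene-set selection (GGS) and expression imputation: choose a small
panel of **directly measured (DM) genes** from a tissue's co-expression
structure so that a maximal number of unmeasured genes can be inferred by
per-gene regression — the expression analogue of tag-SNP selection.

Intended for study designers working with large sample collections (e.g.
FFPE archives) where genome-wide profiling is cost-prohibitive: given an
existing genome-wide reference dataset for the same tissue and disease,
`ggselect` tells you which k genes to assay and fits the models that
impute the rest.

## Method

From a genes × samples matrix the pipeline:

1. drops unexpressed genes (per-gene 90th-quantile expression < 5);
2. computes all pairwise Pearson correlations r_P;
3. thresholds |r_P| ≥ t into a binary adjacency matrix — the
   co-expression graph G = (V, E);
4. greedily builds the DM set: repeatedly take the highest-degree gene,
   declare every gene adjacent (in the original graph) to ≥ n DM genes
   *predictable* (n = the redundancy), and delete all edges touching the
   new DM and predictable genes — so the next pick comes from an
   uncovered neighborhood;
5. fits one regression model per predictable gene on its DM neighbors
   (random forest for ≥ 2 predictors, polynomial intercept + x + x² for
   one) on a training partition of [0, 1]-scaled expression;
6. scores the Spearman rank correlation r_S between predicted and
   measured expression on held-out and independent data, with a
   bootstrapped standard error of the mean over genes.

A ranked-degree baseline (top-k genes by degree, no edge removal) and a
candidate-gene mode (seed a signature of interest into the panel, then
augment greedily) are included, as is a synthetic-data generator with
planted block structure whose pipeline behavior is known in closed form.
See `docs/methods.md` for the full model description.

## Worked example

```python
from ggselect import (
    SyntheticSpec, generate_block_expression, quantile_filter,
    pearson_matrix, binarize, ggs_select, ranked_degree_select, GraphParams,
    predictor_sets, train_test_split, minmax_scale, train_models,
    predict_expression, evaluate,
)

# 5 planted blocks of 10 co-expressed genes (expected within-block r = 0.8),
# 100 uncorrelated genes, 60 unexpressed genes, 500 samples.
expr, truth = generate_block_expression(SyntheticSpec(seed=1))
filtered, _ = quantile_filter(expr)           # 210 -> 150 genes
adj = binarize(pearson_matrix(filtered), 0.6)

params = GraphParams(threshold=0.6, redundancy=3, dm_size=15)
sel = ggs_select(adj, params)
print(len(sel.dm_genes), len(sel.predictable_genes))   # 15 35
rd = ranked_degree_select(adj, GraphParams(0.6, 1, 5))
print(len(rd.predictable_genes))                       # 5  (GGS gets 45)

train, test = train_test_split(filtered, 2/3, seed=1)
models = train_models(minmax_scale(train), predictor_sets(adj, sel), seed=1)
pred, skipped = predict_expression(models, minmax_scale(test))
res = evaluate(pred, minmax_scale(test), n_skipped=len(skipped),
               bootstrap=1000, seed=1)
print(f"{res.mean_rs:.3f} +/- {res.bootstrap_se:.3f}")  # 0.819 +/- 0.004
```

The numbers mean: all 50 block genes are recovered as eligible; with a
15-gene panel at redundancy 3 the other 35 block genes are predictable
(3 DM genes per block, exactly the clique arithmetic), while the
ranked-degree baseline wastes its 5-gene panel inside one block and
predicts only 5 genes; and the per-gene models rank-correlate with
held-out truth at r_S ≈ 0.82 on average — above the 0.6 edge threshold
used to build the graph, because three redundant predictors average out
noise.

The same stages are exposed as a CLI:

```bash
ggs simulate --seed 1 --out synth.tsv
ggs filter --in synth.tsv --quantile 0.90 --cutoff 5 --out filtered.tsv
ggs correlate --in filtered.tsv --out corr.tsv
ggs binarize --in corr.tsv --threshold 0.6 --out adj.tsv
ggs select --adj adj.tsv --dm-size 15 --redundancy 3 --out selection.json
ggs sweep --corr corr.tsv --out sweep.tsv          # 3 x 3 x 16 = 144 runs
ggs run --config run.yaml                          # whole pipeline + manifest
```

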