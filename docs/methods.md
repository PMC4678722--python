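# Methods

## Problem and model

Genome-wide expression profiling is too expensive for very large sample
collections, but within a stable tissue/disease context genes are strongly
co-expressed. `ggselect` exploits that structure the way tag-SNP selection
exploits linkage disequilibrium: choose a small panel of directly measured
(DM) genes such that as many unmeasured genes as possible can be inferred
from them, then fit one regression model per inferable gene.

The pipeline operates on an undirected gene co-expression graph
G = (V, E): vertices are the genes that survive a low-expression filter,
and an edge joins genes *i*, *j* when |r_P(i, j)| ≥ t for a user-chosen
threshold t on the pairwise Pearson correlation across samples. Two more
parameters complete the setup: the *redundancy* n — the minimum number of
DM genes an unmeasured gene must be adjacent to before it counts as
*predictable* — and the targeted DM panel size k. Genes adjacent to at
least n other genes are *eligible*; both panels are drawn from the
eligible universe, with the adjacency restricted to eligible × eligible.

## Greedy selection

Each iteration of the greedy loop:

1. sorts genes by degree in the current (pruned) adjacency;
2. adds the maximum-degree gene to the DM set (ties go to the
   lexicographically smallest identifier, so runs are deterministic and
   testable against a naive reference);
3. moves every gene now adjacent to ≥ n DM genes into the predictable set;
4. deletes all edges incident to the new DM gene and the newly
   predictable genes.

Step 3 counts DM neighbors in the **original** adjacency, maintained as
incremental per-gene counters. This is a deliberate interpretation: under
the literal reading, where only surviving edges count, a DM gene's edges
vanish in step 4 immediately after it is selected, so no gene could ever
accumulate two DM neighbors and any redundancy above 1 would be
unsatisfiable. The literal variant is retained behind
`predictability="pruned"` for comparison; at redundancy 1 the two
coincide. Step 1 always uses the pruned matrix — edge removal is what
steers the panel away from neighborhoods that are already covered, and is
why greedy selection covers several-fold more genes than the ranked-degree
baseline (top-k genes by raw degree, no pruning), which stacks the panel
with mutually correlated hub genes.

The loop stops early when no unselected gene has pruned degree ≥ 1;
isolated leftovers add no predictive value and are never used as padding.
The shortfall is recorded in the iteration log. One gene enters the DM
set per iteration, each iteration costs O(n²) for pruning and degree
recomputation, so a run is O(kn²) time and O(n²) space (dense matrix).

User-supplied candidate genes (e.g. a prognostic signature) are all seeded
into the DM set before any greedy iteration, in bulk: counters updated,
newly predictable genes absorbed, edges pruned. By default `dm_size` then
counts *additional* greedy picks beyond the candidates
(`count_candidates_toward_size` flips to total-count semantics).
Candidates missing from the adjacency stay in the DM list — they will
still be assayed — but contribute no edges, and a warning names them.

Because the greedy state after k iterations is independent of the final
target size, the DM list at size k is a prefix of the list at any larger
size. `parameter_sweep` exploits this: one full-length run per
(threshold, redundancy) pair, with smaller panel sizes read off the
iteration log. The equivalence with direct per-size runs is asserted in
the test suite.

## Filtering and preprocessing

- **Low-expression filter**: a gene is kept when its per-gene quantile
  (default 0.90) of expression is ≥ a cutoff (default 5 on the log-like
  array scale). The quantile uses the linear-interpolation ("type 7")
  convention, the default of the common statistical environments; the
  convention matters at these small sample-quantile depths, so it is fixed
  and documented rather than left to chance.
- **RNA-seq input** is log-transformed first: log₂(x + 1) by default, base
  and pseudocount configurable.
- **Correlation** is computed on filtered, unscaled log-scale expression;
  [0, 1] min-max scaling happens only at the imputation stage.
- **Scaling scope**: min-max scaling is per gene per dataset (training,
  testing, and each validation cohort scaled independently). Evaluation
  is rank-based, so per-dataset scaling costs nothing and is robust to
  platform-level location/scale shifts; no training min/max is carried
  across datasets.
- **Splitting**: samples are shuffled by a seeded RNG and cut at
  round(f·n) (default f = 2/3); no stratification.
- **Missing values** are rejected at ingestion. The contract is simpler
  than pairwise-complete handling and keeps every downstream covariance
  well-defined.

## Imputation

For each predictable gene, its predictors are *all* DM genes adjacent to
it in the original adjacency (always ≥ redundancy of them). With ≥ 2
predictors a random forest of regression trees is fitted (default 500
trees, scikit-learn regression defaults otherwise, seeded per gene from
one stream in sorted gene order); with a single predictor, a least-squares
polynomial — intercept + x + x², degree configurable. Accuracy is the
Spearman rank correlation r_S between predicted and measured expression
across samples, summarized as the mean over genes with a bootstrapped
standard error (standard deviation of the means of B seeded
with-replacement resamples, default B = 1000). Models whose response or
any predictor is absent from an evaluation dataset are skipped and
counted, never silently dropped. Predictions are not clipped to [0, 1]
(rank evaluation makes clipping irrelevant). A gene whose predicted or
true vector is constant has undefined rank correlation; such genes are
excluded from the mean and reported in `n_undefined`.

Only *relative* expression is predicted. Absolute cross-platform
calibration is out of scope; rank-based evaluation is what makes the
models transfer across cohorts and platforms.

## Synthetic data

The generator plants a single latent factor per block:

    expr(g in block b) = 8 + 1.5 · (λ f_b + σ ε) / √(λ² + σ²)

with f_b, ε ~ N(0, 1), loading λ ∈ (0, 1] and noise σ, giving every
within-block pair expected correlation r = λ²/(λ² + σ²) and zero expected
correlation across blocks. Background genes are independent N(8, 1.5²);
low-expression genes are N(2, 0.5²), below the filter cutoff of 5, their
count being `low_expression_fraction` (default 0.4) of the expressed
genes. Defaults: 5 blocks × 10 genes, λ = 0.9, σ = 0.45 (so r = 0.8),
500 samples, 100 background genes. A paired validation cohort (same genes
and loadings, fresh samples, optionally different noise) emulates an
independent population for cross-dataset evaluation.

With these defaults the thresholded graph recovers the blocks as isolated
cliques (null correlations at n = 500 sit far below t = 0.6), so the whole
pipeline has closed-form expectations: eligibility requires block_size − 1
≥ redundancy; greedy selection visits blocks round-robin (each pick lowers
its own block's pruned degrees below fresh blocks'), a block is exhausted
the moment it holds `redundancy` DM genes, and the predictable count is
(completed blocks) × (block_size − redundancy). The test suite asserts
exact agreement between runs on generated data and these expectations.

What the generator does *not* emulate: probe effects, batch structure,
heavy-tailed expression, overlapping pathway membership (each gene belongs
to one block), or drifting co-expression between populations. Passing
tests therefore demonstrate algorithmic correctness and the qualitative
parameter response (accuracy rising with redundancy and threshold,
predictable counts falling with both), not field performance on any
particular tissue.

## Numerical choices and edge cases

- Correlation matrices are symmetrized ((R + Rᵀ)/2), clipped to [−1, 1],
  unit diagonal forced; edge ties at exactly the threshold are edges.
- Degree ties broken lexicographically everywhere (greedy and baseline).
- Constant genes are an error at scaling and correlation, naming the gene.
- An empty filter result errors with advice that the cutoff is too
  strict, rather than returning an empty matrix.
- Requested panel sizes beyond the eligible universe warn and return the
  achievable panel with `exhausted=True`.
- Every stochastic stage (split, forest, bootstrap, generator) takes an
  explicit seed; the workflow manifest records all seeds, parameters, and
  SHA-256 checksums of outputs, and reruns are byte-identical.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data at desk scale, chosen to keep full runs fast while leaving the
planted structure unambiguous: the default 5 × 10-gene blocks with 500
samples for pipeline recovery; 200 random Erdős–Rényi graphs (n ≤ 200)
for oracle equivalence; 50 random instances for the monotonicity laws;
and forests of 150–500 trees for the accuracy checks (dispatch and
determinism checks use smaller forests, accuracy assertions the default).

## Known limitations

- Only pairwise correlation is modeled; higher-order dependence is
  ignored by design.
- The greedy panel carries no optimality guarantee; it trades optimality
  for O(kn²) runtime.
- Eligibility is computed once on the full adjacency and not re-iterated
  after restriction (degrees can drop below the redundancy bound for
  redundancy ≥ 2 after removing ineligible genes); the restriction is
  optional via `restrict_eligible`.
- Gene matching across datasets is exact, case-sensitive symbol equality;
  symbol harmonization is upstream of this package.
- Cross-dataset transfer presumes a stable co-expression structure; the
  method is not suited to dynamic systems (e.g. differentiation) where
  correlations change.
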