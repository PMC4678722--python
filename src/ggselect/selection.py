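"""Greedy gene-set selection (GGS) and the ranked-degree baseline.

GGS builds a directly-measured (DM) gene panel from a binary co-expression
adjacency matrix by iterating four operations until the panel reaches the
requested size:

1. sort genes by their degree in the current (pruned) adjacency;
2. add the maximum-degree gene to the DM set;
3. move any gene now correlated to at least ``redundancy`` DM genes into
   the predictable set;
4. remove all edges incident to the new DM and newly predictable genes.

Step 3 counts DM neighbors in the ORIGINAL adjacency, maintained as
incremental per-gene counters: with literal edge removal a gene's edge to a
DM gene disappears the moment that gene is selected, which would make any
redundancy above 1 unsatisfiable.  Step 1's sorting uses the pruned working
copy, so edge removal still steers selection away from neighborhoods that
are already covered.  A ``predictability="pruned"`` variant (counting only
edges still present when each DM gene is selected) is available for
comparison.

Ties in degree are broken toward the lexicographically smallest gene
identifier, making every run deterministic and oracle-testable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graph import degrees, eligible_genes, restrict_to_eligible

__all__ = [
    "GraphParams",
    "IterationRecord",
    "SelectionResult",
    "ggs_select",
    "ranked_degree_select",
    "predictor_sets",
    "parameter_sweep",
]


@dataclass(frozen=True)
class GraphParams:
    """Selection parameters: |r| edge threshold, fold redundancy, and the
    targeted DM panel size."""

    threshold: float
    redundancy: int = 1
    dm_size: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.redundancy < 1:
            raise ValueError(f"redundancy must be >= 1, got {self.redundancy}")
        if self.dm_size < 1:
            raise ValueError(f"dm_size must be >= 1, got {self.dm_size}")


@dataclass
class IterationRecord:
    """One greedy iteration: the gene chosen, its degree in the pruned
    adjacency at selection time, and the genes that became predictable."""

    step: int
    gene: str
    pruned_degree: int
    newly_predictable: list[str]


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``dm_genes`` is in selection order (seeded candidates first);
    ``predictable_genes`` are the unmeasured genes correlated to at least
    ``params.redundancy`` DM genes in the original adjacency.
    """

    dm_genes: list[str]
    predictable_genes: set[str]
    candidate_genes: list[str]
    params: GraphParams
    iteration_log: list[IterationRecord]
    method: str = "ggs"
    n_eligible: int = 0
    exhausted: bool = False
    missing_candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.dm_genes) & self.predictable_genes
        if overlap:
            raise ValueError(f"DM and predictable sets overlap: {sorted(overlap)[:5]}")

    @property
    def n_greedy(self) -> int:
        return len(self.dm_genes) - len(self.candidate_genes)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "method": self.method,
            "dm_genes": self.dm_genes,
            "predictable_genes": sorted(self.predictable_genes),
            "candidate_genes": self.candidate_genes,
            "missing_candidates": self.missing_candidates,
            "params": asdict(self.params),
            "n_eligible": self.n_eligible,
            "exhausted": self.exhausted,
            "iteration_log": [asdict(rec) for rec in self.iteration_log],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str) -> "SelectionResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            dm_genes=payload["dm_genes"],
            predictable_genes=set(payload["predictable_genes"]),
            candidate_genes=payload["candidate_genes"],
            params=GraphParams(**payload["params"]),
            iteration_log=[IterationRecord(**r) for r in payload["iteration_log"]],
            method=payload["method"],
            n_eligible=payload["n_eligible"],
            exhausted=payload["exhausted"],
            missing_candidates=payload.get("missing_candidates", []),
        )


def _argmax_lex(score: np.ndarray, mask: np.ndarray, gene_ids: np.ndarray) -> int:
    """Index of the max-score gene among ``mask``; ties go to the
    lexicographically smallest gene identifier."""
    idx = np.flatnonzero(mask)
    best = idx[score[idx] == score[idx].max()]
    return int(min(best, key=lambda i: gene_ids[i]))


def ggs_select(
    adj: pd.DataFrame,
    params: GraphParams,
    candidates: list[str] | None = None,
    *,
    restrict_eligible: bool = True,
    count_candidates_toward_size: bool = False,
    predictability: str = "original",
) -> SelectionResult:
    """Run greedy gene-set selection on a binary adjacency matrix.

    Parameters
    ----------
    adj
        Symmetric binary genes × genes adjacency (zero diagonal).
    params
        Threshold (metadata only here — the adjacency is already
        thresholded), redundancy, and targeted DM size.
    candidates
        Optional user-supplied genes (e.g. a prognostic signature) seeded
        into the DM set before any greedy iteration.  By default
        ``params.dm_size`` counts ADDITIONAL greedy picks beyond the
        candidates; set ``count_candidates_toward_size`` for total-count
        semantics.  Candidates absent from the adjacency are kept in the
        DM list (they are still assayed) but contribute no edges; a
        warning lists them.
    restrict_eligible
        Restrict the universe to eligible genes (degree >= redundancy in
        the full adjacency) before selection.  Computed once, not
        re-iterated.
    predictability
        ``"original"`` (default) counts a gene's DM neighbors in the
        un-pruned adjacency; ``"pruned"`` counts only edges still present
        when each DM gene is selected.

    The run stops early, with ``exhausted=True``, when no unselected gene
    retains a pruned degree of at least 1: isolated leftovers add no
    predictive value and are not used as padding.
    """
    if predictability not in ("original", "pruned"):
        raise ValueError(f"predictability must be 'original' or 'pruned', got {predictability!r}")
    candidates = list(candidates or [])

    if restrict_eligible:
        universe = restrict_to_eligible(adj, params.redundancy)
    else:
        universe = adj
    gene_ids = np.asarray(universe.index, dtype=object)
    n = len(gene_ids)
    original = universe.to_numpy(dtype=np.int8)
    pruned = original.copy()
    pos = {g: i for i, g in enumerate(gene_ids)}

    dm_order: list[str] = []
    dm = np.zeros(n, dtype=bool)
    predictable = np.zeros(n, dtype=bool)
    counters = np.zeros(n, dtype=np.int64)  # DM neighbors per gene
    log: list[IterationRecord] = []

    def prune(rows: np.ndarray) -> None:
        pruned[rows, :] = 0
        pruned[:, rows] = 0

    def absorb_new_predictable() -> list[str]:
        if predictability == "original":
            counts = counters
        else:
            # literal reading: only edges still present in the pruned matrix
            # count, and a DM gene's own edges vanish right after step 3 —
            # so redundancy >= 2 is never met and the loop degenerates.
            counts = pruned[:, dm].sum(axis=1)
        new = ~dm & ~predictable & (counts >= params.redundancy)
        new_idx = np.flatnonzero(new)
        if new_idx.size:
            predictable[new_idx] = True
            prune(new_idx)
        return [gene_ids[i] for i in new_idx]

    # Seed candidates in bulk before any greedy iteration.
    missing = [c for c in candidates if c not in pos]
    if missing:
        warnings.warn(
            "candidate gene(s) absent from the adjacency and added to the DM "
            f"set without edges: {', '.join(missing)}",
            stacklevel=2,
        )
    seeded_new: list[str] = []
    if candidates:
        present = [pos[c] for c in candidates if c in pos]
        for i in present:
            if not dm[i]:
                dm[i] = True
                counters += original[:, i]
        dm_order.extend(dict.fromkeys(candidates))  # preserve order, drop dups
        seeded_new = absorb_new_predictable()  # step 3 precedes edge removal
        prune(np.asarray(present, dtype=int))
        log.append(IterationRecord(0, "<candidates>", 0, seeded_new))

    n_target = params.dm_size
    if count_candidates_toward_size:
        n_target = max(0, params.dm_size - len(dm_order))
    if n_target > n - int(dm.sum()):
        warnings.warn(
            f"requested DM size {n_target} exceeds the {n - int(dm.sum())} "
            "remaining genes in the eligible universe",
            stacklevel=2,
        )

    exhausted = False
    step = 0
    while step < n_target:
        selectable = ~dm & ~predictable
        if not selectable.any():
            exhausted = True
            break
        deg = pruned.sum(axis=1)
        i = _argmax_lex(deg, selectable, gene_ids)
        if deg[i] < 1:
            exhausted = True
            break
        step += 1
        dm[i] = True
        counters += original[:, i]
        dm_order.append(gene_ids[i])
        chosen_degree = int(deg[i])
        newly = absorb_new_predictable()  # step 3 precedes the DM gene's pruning
        prune(np.asarray([i]))
        log.append(IterationRecord(step, gene_ids[i], chosen_degree, newly))

    if exhausted:
        log.append(
            IterationRecord(step + 1, "<exhausted>", 0, [])
        )

    return SelectionResult(
        dm_genes=dm_order,
        predictable_genes={gene_ids[i] for i in np.flatnonzero(predictable)},
        candidate_genes=list(dict.fromkeys(candidates)),
        params=params,
        iteration_log=log,
        method="ggs" if predictability == "original" else "ggs-pruned",
        n_eligible=n,
        exhausted=exhausted,
        missing_candidates=missing,
    )


def ranked_degree_select(
    adj: pd.DataFrame,
    params: GraphParams,
    *,
    restrict_eligible: bool = True,
) -> SelectionResult:
    """Baseline: take the top ``dm_size`` genes by degree, no edge removal.

    Predictable genes are the non-DM genes with at least ``redundancy`` DM
    neighbors.  Because correlated hub genes are all selected, the panel
    tends to be redundant and covers far fewer genes than GGS.
    """
    universe = restrict_to_eligible(adj, params.redundancy) if restrict_eligible else adj
    deg = degrees(universe)
    order = sorted(universe.index, key=lambda g: (-deg[g], g))
    dm_list = order[: params.dm_size]
    a = universe.to_numpy(dtype=np.int8)
    pos = {g: i for i, g in enumerate(universe.index)}
    dm_idx = np.asarray([pos[g] for g in dm_list], dtype=int)
    dm_mask = np.zeros(len(universe), dtype=bool)
    dm_mask[dm_idx] = True
    dm_neighbors = a[:, dm_idx].sum(axis=1)
    pred_mask = ~dm_mask & (dm_neighbors >= params.redundancy)
    log = [
        IterationRecord(k + 1, g, int(deg[g]), [])
        for k, g in enumerate(dm_list)
    ]
    return SelectionResult(
        dm_genes=dm_list,
        predictable_genes={universe.index[i] for i in np.flatnonzero(pred_mask)},
        candidate_genes=[],
        params=params,
        iteration_log=log,
        method="ranked-degree",
        n_eligible=len(universe),
        exhausted=len(dm_list) < params.dm_size,
    )


def predictor_sets(
    adj_original: pd.DataFrame, result: SelectionResult
) -> dict[str, list[str]]:
    """Map each predictable gene to ALL its DM neighbors in the original
    (un-pruned) adjacency; these are the predictors of its regression model.

    Every list has at least ``redundancy`` entries; fewer indicates an
    internal inconsistency between the result and the adjacency.
    """
    dm_in_adj = [g for g in result.dm_genes if g in adj_original.index]
    out: dict[str, list[str]] = {}
    for gene in sorted(result.predictable_genes):
        row = adj_original.loc[gene, dm_in_adj]
        preds = sorted(np.asarray(dm_in_adj, dtype=object)[row.to_numpy() == 1])
        if len(preds) < result.params.redundancy:
            raise RuntimeError(
                f"predictable gene {gene!r} has only {len(preds)} DM neighbor(s), "
                f"fewer than redundancy {result.params.redundancy}"
            )
        out[gene] = preds
    return out


def parameter_sweep(
    corr: pd.DataFrame,
    thresholds: list[float],
    redundancies: list[int],
    dm_sizes: list[int],
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """GGS across a grid of thresholds × redundancies × DM sizes.

    Greedy selection nests: for fixed threshold and redundancy the run at
    DM size k is a prefix of the run at any larger size, so each
    (threshold, redundancy) pair is run once to the maximum size and the
    smaller sizes are read off the iteration log.  Returns one row per
    combination with the eligible-universe size, the predictable count,
    and ``n_missed`` — eligible genes neither measured nor predictable.
    """
    from .graph import binarize

    if not (thresholds and redundancies and dm_sizes):
        raise ValueError("thresholds, redundancies and dm_sizes must be non-empty")
    sizes = sorted(dm_sizes)
    rows = []
    for t in thresholds:
        adj = binarize(corr, t)
        for r in redundancies:
            universe = restrict_to_eligible(adj, r)
            res = ggs_select(
                universe,
                GraphParams(threshold=t, redundancy=r, dm_size=max(sizes)),
                candidates=candidates,
                restrict_eligible=False,
            )
            n_eligible = res.n_eligible
            n_cand_in = len(res.candidate_genes) - len(res.missing_candidates)
            greedy_log = [rec for rec in res.iteration_log if rec.gene not in ("<candidates>", "<exhausted>")]
            seeded = sum(
                len(rec.newly_predictable)
                for rec in res.iteration_log
                if rec.gene == "<candidates>"
            )
            cum = np.cumsum([len(rec.newly_predictable) for rec in greedy_log])
            for k in sizes:
                n_greedy = min(k, len(greedy_log))
                n_pred = seeded + (int(cum[n_greedy - 1]) if n_greedy else 0)
                n_dm_eligible = n_cand_in + n_greedy
                rows.append(
                    {
                        "threshold": t,
                        "redundancy": r,
                        "dm_size": k,
                        "n_dm": len(res.candidate_genes) + n_greedy,
                        "n_predictable": n_pred,
                        "n_eligible": n_eligible,
                        "n_missed": n_eligible - n_dm_eligible - n_pred,
                    }
                )
    return pd.DataFrame(rows)
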