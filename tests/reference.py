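"""Independent naive reference implementations used as test oracles.

Deliberately simple and stateless: every quantity is recomputed from
scratch each step, with no incremental bookkeeping, so agreement with the
package's optimized code is a meaningful cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def naive_pearson(x, y) -> float:
    """Textbook two-vector Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def naive_spearman(x, y) -> float:
    """Average-rank Spearman: Pearson correlation of midranks."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    return naive_pearson(midranks(list(x)), midranks(list(y)))


def bfs_components(adj: pd.DataFrame) -> list[set[str]]:
    """Connected components by explicit breadth-first search."""
    genes = list(adj.index)
    a = adj.to_numpy()
    seen: set[str] = set()
    comps = []
    for start, g in enumerate(genes):
        if g in seen:
            continue
        comp = {g}
        queue = [start]
        seen.add(g)
        while queue:
            i = queue.pop(0)
            for j in np.flatnonzero(a[i]):
                if genes[j] not in seen:
                    seen.add(genes[j])
                    comp.add(genes[j])
                    queue.append(j)
        comps.append(comp)
    return comps


def naive_ggs(
    adj: pd.DataFrame, dm_size: int, redundancy: int
) -> tuple[list[str], set[str]]:
    """Reference greedy selection: every iteration re-sorts ALL genes of the
    full pruned matrix by recomputed degree, and recounts every gene's DM
    neighbors against the original adjacency from scratch — no incremental
    state.  Lexicographic tie-break on equal degree.

    The universe is restricted once to genes with degree >= redundancy.
    """
    deg0 = adj.to_numpy().sum(axis=1)
    keep = [g for g, d in zip(adj.index, deg0) if d >= redundancy]
    original = adj.loc[keep, keep].to_numpy(dtype=np.int64)
    pruned = original.copy()
    genes = list(adj.loc[keep].index)

    dm: list[str] = []
    predictable: set[str] = set()
    for _ in range(dm_size):
        degs = pruned.sum(axis=1)  # recomputed in full
        candidates = [g for g in genes if g not in dm and g not in predictable]
        if not candidates:
            break
        ranked = sorted(candidates, key=lambda g: (-degs[genes.index(g)], g))
        best = ranked[0]
        bi = genes.index(best)
        if degs[bi] < 1:
            break
        dm.append(best)
        pruned[bi, :] = 0
        pruned[:, bi] = 0
        # recount every gene's DM neighbors in the original adjacency
        dm_idx = [genes.index(g) for g in dm]
        counts = original[:, dm_idx].sum(axis=1)
        newly = [
            g
            for i, g in enumerate(genes)
            if g not in dm and g not in predictable and counts[i] >= redundancy
        ]
        for g in newly:
            predictable.add(g)
            gi = genes.index(g)
            pruned[gi, :] = 0
            pruned[:, gi] = 0
    return dm, predictable


def naive_ranked_degree(
    adj: pd.DataFrame, dm_size: int, redundancy: int
) -> tuple[list[str], set[str]]:
    """Reference ranked-degree baseline on the eligible universe."""
    deg0 = adj.to_numpy().sum(axis=1)
    keep = [g for g, d in zip(adj.index, deg0) if d >= redundancy]
    sub = adj.loc[keep, keep]
    degs = {g: int(sub.loc[g].sum()) for g in keep}
    dm = sorted(keep, key=lambda g: (-degs[g], g))[:dm_size]
    predictable = {
        g for g in keep if g not in dm and int(sub.loc[g, dm].sum()) >= redundancy
    }
    return dm, predictable


def naive_parameter_point(
    adj: pd.DataFrame, dm_size: int, redundancy: int
) -> dict[str, int]:
    """Eligible / DM / predictable / missed counts via the naive greedy."""
    n_eligible = int((adj.to_numpy().sum(axis=1) >= redundancy).sum())
    dm, predictable = naive_ggs(adj, dm_size, redundancy)
    return {
        "n_eligible": n_eligible,
        "n_dm": len(dm),
        "n_predictable": len(predictable),
        "n_missed": n_eligible - len(dm) - len(predictable),
    }


def random_er_adjacency(rng: np.random.Generator, n: int, p: float) -> pd.DataFrame:
    """Erdős–Rényi G(n, p) as a binary adjacency DataFrame."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1)
    a = (a | a.T).astype(np.int8)
    genes = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(a, index=genes, columns=genes)
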