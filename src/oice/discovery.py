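"""Constraint-based causal skeleton discovery (PC algorithm).

Implements the classic PC procedure over a feature table: start from
the complete undirected graph, remove edges whose endpoints are
conditionally independent given subsets of their neighbours (Fisher-z
partial-correlation test at a chosen significance level), orient
v-structures from the recorded separating sets, and close under the
Meek orientation rules.  The output is a :class:`~oice.graph.PDAG`
whose remaining undirected edges are resolved by domain knowledge via
:func:`oice.graph.orient_edges`.

The implementation iterates nodes and edges in canonical column order,
so the result is deterministic given the data and the level.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import PDAG

logger = logging.getLogger(__name__)


def fisher_z_pvalue(corr: np.ndarray, n: int, i: int, j: int, cond: tuple[int, ...]) -> float:
    """p-value of the Fisher-z partial-correlation independence test."""
    idx = [i, j, *cond]
    sub = corr[np.ix_(idx, idx)]
    prec = np.linalg.pinv(sub)
    r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    r = float(np.clip(r, -0.999999, 0.999999))
    dof = n - len(cond) - 3
    if dof <= 0:
        return 1.0
    z = np.sqrt(dof) * np.arctanh(r)
    return float(2 * sps.norm.sf(abs(z)))


def discover_skeleton(
    feature_table: pd.DataFrame,
    significance: float = 0.05,
    max_cond: int | None = None,
    seed: int | None = None,
) -> PDAG:
    """PC skeleton + v-structure orientation on a feature table.

    Constant columns carry no dependence information and are excluded
    with a warning (they remain isolated nodes in the result).  ``seed``
    is accepted for interface symmetry; the procedure itself is
    deterministic.
    """
    if not 0 < significance < 1:
        raise ValueError("significance must lie in (0, 1)")
    if feature_table.shape[1] < 2 or len(feature_table) < 20:
        raise ValueError("need at least 2 features and 20 records for discovery")
    cols = list(feature_table.columns)
    const = [c for c in cols if feature_table[c].nunique() <= 1]
    if const:
        logger.warning("excluding constant columns from discovery: %s", const)
    active = [c for c in cols if c not in const]
    data = feature_table[active].to_numpy(dtype=float)
    n, d = data.shape
    corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)

    adj: dict[int, set[int]] = {i: set(range(d)) - {i} for i in range(d)}
    sepset: dict[frozenset, tuple[int, ...]] = {}
    limit = d - 2 if max_cond is None else max_cond

    level = 0
    while level <= limit:
        if all(len(adj[i] - {j}) < level for i in range(d) for j in adj[i]):
            break
        for i in range(d):
            for j in sorted(adj[i]):
                if j < i:
                    continue
                removed = False
                for cond in combinations(sorted(adj[i] - {j}), level):
                    p = fisher_z_pvalue(corr, n, i, j, cond)
                    if p > significance:
                        adj[i].discard(j)
                        adj[j].discard(i)
                        sepset[frozenset((i, j))] = cond
                        removed = True
                        break
                if not removed and level <= len(adj[j] - {i}):
                    for cond in combinations(sorted(adj[j] - {i}), level):
                        p = fisher_z_pvalue(corr, n, i, j, cond)
                        if p > significance:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            sepset[frozenset((i, j))] = cond
                            break
        level += 1

    # v-structures: i - k - j with i, j non-adjacent and k not in sepset(i, j)
    directed: set[tuple[int, int]] = set()
    for k in range(d):
        for i, j in combinations(sorted(adj[k]), 2):
            if j in adj[i]:
                continue
            if k not in sepset.get(frozenset((i, j)), ()):
                directed.add((i, k))
                directed.add((j, k))

    # conflicting v-structures can orient an edge both ways; return such
    # edges to the undirected pool for knowledge-based resolution
    conflicted = {(a, b) for (a, b) in directed if (b, a) in directed}
    directed -= conflicted

    undirected = {frozenset((i, j)) for i in range(d) for j in adj[i] if i < j}
    undirected = {
        e for e in undirected
        if tuple(e) not in directed and tuple(e)[::-1] not in directed
    }
    directed, undirected = _apply_meek(d, directed, undirected)

    pdag = PDAG(nodes=cols)
    name = {i: active[i] for i in range(d)}
    for a, b in directed:
        pdag.add_directed(name[a], name[b])
    for e in undirected:
        a, b = tuple(e)
        pdag.add_undirected(name[a], name[b])
    return pdag


def _apply_meek(d: int, directed: set, undirected: set):
    """Meek rules 1–3: propagate forced orientations without new v-structures."""

    def adjacent(a, b):
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z not adjacent to y  =>  x -> y
                r1 = any((z, x) in directed and not adjacent(z, y)
                         for z in range(d) if z not in (x, y))
                # R2: x -> z -> y  =>  x -> y
                r2 = any((x, z) in directed and (z, y) in directed
                         for z in range(d) if z not in (x, y))
                # R3: x - z1 -> y, x - z2 -> y, z1/z2 non-adjacent => x -> y
                r3 = False
                zs = [z for z in range(d)
                      if frozenset((x, z)) in undirected and (z, y) in directed]
                for z1, z2 in combinations(zs, 2):
                    if not adjacent(z1, z2):
                        r3 = True
                        break
                if r1 or r2 or r3:
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
            if changed:
                break
    return directed, undirected
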