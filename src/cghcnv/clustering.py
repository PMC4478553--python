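"""CNVR presence/absence clustering: UPGMA with bootstrap branch support.

Each test sample is encoded as a binary vector over the CNVR catalogue
(1 = the sample contributes a member call to that CNVR).  Samples are
clustered by UPGMA (size-weighted average linkage, ultrametric heights =
half the merge distance) on a binary distance (Jaccard by default), and
branch robustness is assessed with an ordinary column bootstrap: CNVR
columns are resampled with replacement, the tree rebuilt, and each original
cluster's leaf set scored by the percentage of replicate trees containing
it (BP support).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Cnvr

__all__ = ["presence_matrix", "binary_distance", "upgma",
           "bootstrap_support", "Dendrogram"]


def presence_matrix(cnvrs: Sequence[Cnvr], samples: Sequence[str]) -> pd.DataFrame:
    """Binary samples x CNVRs matrix: 1 iff the sample carries the CNVR."""
    if not samples:
        raise ValueError("samples must be non-empty")
    mat = pd.DataFrame(0, index=list(samples),
                       columns=[r.id for r in cnvrs], dtype=int)
    for r in cnvrs:
        for s in r.samples:
            if s in mat.index:
                mat.loc[s, r.id] = 1
    empty = mat.index[mat.sum(axis=1) == 0]
    if len(empty):
        import warnings
        warnings.warn(f"sample(s) with no CNVR calls: {list(empty)}")
    return mat


def binary_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Pairwise distances between binary sample profiles.

    jaccard: 1 - |intersection|/|union| (0 when both rows are empty —
    shared absence is not evidence of difference); simple_matching:
    fraction of mismatching columns.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 samples")
    x = matrix.to_numpy(dtype=bool)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                union = np.logical_or(x[i], x[j]).sum()
                inter = np.logical_and(x[i], x[j]).sum()
                dij = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "simple_matching":
                dij = np.mean(x[i] != x[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """A rooted UPGMA tree.

    ``merges`` lists (node_a, node_b, height) for the n-1 merges; node ids
    0..n-1 are leaves (in ``leaves`` order), n.. are internal in merge
    order.  Heights are ultrametric (non-decreasing).  ``bp_support`` maps
    each internal node's leaf set to its bootstrap percentage.
    """

    leaves: List[str]
    merges: List[Tuple[int, int, float]]
    bp_support: Dict[FrozenSet[str], float] = field(default_factory=dict)

    def clusters(self) -> List[FrozenSet[str]]:
        """Leaf set of every internal node, in merge order."""
        sets: List[FrozenSet[str]] = [frozenset([l]) for l in self.leaves]
        out = []
        for a, b, _ in self.merges:
            merged = sets[a] | sets[b]
            sets.append(merged)
            out.append(merged)
        return out

    def to_newick(self, with_support: bool = True) -> str:
        n = len(self.leaves)
        reps: List[str] = [name for name in self.leaves]
        heights: List[float] = [0.0] * n
        sets: List[FrozenSet[str]] = [frozenset([l]) for l in self.leaves]
        for a, b, h in self.merges:
            la = h - heights[a]
            lb = h - heights[b]
            merged = sets[a] | sets[b]
            label = ""
            if with_support and merged in self.bp_support:
                label = f"{self.bp_support[merged]:.0f}"
            reps.append(f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g}){label}")
            heights.append(h)
            sets.append(merged)
        return reps[-1] + ";"


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA clustering of a symmetric distance matrix.

    At each step the pair of clusters with the smallest average-linkage
    distance merges at half that distance; the new cluster's distance to
    any other is the size-weighted mean of its parts' distances.  Ties are
    broken on the lexicographically smallest (smallest leaf label of each
    side) pair, so the tree is deterministic.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    labels = [str(l) for l in dist.index]
    n = len(labels)

    active: Dict[int, dict] = {
        i: {"size": 1, "min_label": labels[i], "height": 0.0}
        for i in range(n)
    }
    dists: Dict[Tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: List[Tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dists.items():
            key = (dij, *sorted((active[i]["min_label"], active[j]["min_label"])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dists[(i, j)]
        new = next_id
        next_id += 1
        merges.append((i, j, dij / 2.0))
        si, sj = active[i]["size"], active[j]["size"]
        others = [k for k in active if k not in (i, j)]
        for k in others:
            dik = dists[(min(i, k), max(i, k))]
            djk = dists[(min(j, k), max(j, k))]
            dists[(min(new, k), max(new, k))] = (si * dik + sj * djk) / (si + sj)
        active[new] = {"size": si + sj,
                       "min_label": min(active[i]["min_label"], active[j]["min_label"]),
                       "height": dij / 2.0}
        for k in (i, j):
            del active[k]
        dists = {key: v for key, v in dists.items()
                 if i not in key and j not in key}
    return Dendrogram(leaves=labels, merges=merges)


def bootstrap_support(matrix: pd.DataFrame, metric: str = "jaccard",
                      n_boot: int = 1000, seed: int = 0) -> Dendrogram:
    """UPGMA tree with BP branch support from a column bootstrap.

    CNVR columns are resampled with replacement ``n_boot`` times; each
    original internal cluster's support is the percentage of replicate
    trees containing the same leaf set.  Seeded and reproducible.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 CNVR columns to bootstrap")
    tree = upgma(binary_distance(matrix, metric))
    clusters = tree.clusters()
    counts = {c: 0 for c in clusters}
    rng = np.random.default_rng(seed)
    ncol = matrix.shape[1]
    values = matrix.to_numpy()
    for _ in range(n_boot):
        cols = rng.integers(0, ncol, size=ncol)
        rep = pd.DataFrame(values[:, cols], index=matrix.index)
        rep_tree = upgma(binary_distance(rep, metric))
        rep_clusters = set(rep_tree.clusters())
        for c in counts:
            if c in rep_clusters:
                counts[c] += 1
    tree.bp_support = {c: 100.0 * k / n_boot for c, k in counts.items()}
    return tree
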