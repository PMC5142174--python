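"""Genetic distances and UPGMA dendrograms.

The default distance between two diploid individuals is one minus the mean
proportion of shared alleles (PSA) over loci typed in both; a simple
matching coefficient over identical genotypes is available as an
alternative. UPGMA merges the closest pair at height d/2 and averages
distances weighted by cluster size, producing an ultrametric rooted tree
exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diversity import GenotypeTable

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "shared_allele_distance",
    "distance_matrix",
    "upgma",
    "to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)


def _pair_psa(a1i, a2i, a1j, a2j) -> float:
    """Proportion of shared allele copies between two diploid genotypes."""
    shared = 0
    gi = [a1i, a2i]
    gj = [a1j, a2j]
    for allele in set(gi):
        shared += min(gi.count(allele), gj.count(allele))
    return shared / 2.0


def shared_allele_distance(
    table: GenotypeTable, i: int | str, j: int | str, method: str = "psa"
) -> float:
    """Distance between individuals i and j: 1 - mean per-locus allele sharing.

    Loci missing or null in either individual are skipped (pairwise deletion).
    ``method="matching"`` scores each locus 1 if the unordered genotypes are
    identical, else 0, instead of the allele-copy proportion.
    """
    if isinstance(i, str):
        i = table.individuals.index(i)
    if isinstance(j, str):
        j = table.individuals.index(j)
    typed = (table.a1[i] >= 0) & (table.a1[j] >= 0)
    if not np.any(typed):
        raise ValueError("no locus typed in both individuals")
    cols = np.flatnonzero(typed)
    if method == "psa":
        sims = [
            _pair_psa(table.a1[i, c], table.a2[i, c], table.a1[j, c], table.a2[j, c])
            for c in cols
        ]
    elif method == "matching":
        sims = [
            float(
                sorted((table.a1[i, c], table.a2[i, c]))
                == sorted((table.a1[j, c], table.a2[j, c]))
            )
            for c in cols
        ]
    else:
        raise ValueError(f"unknown method {method!r}")
    return 1.0 - float(np.mean(sims))


def distance_matrix(table: GenotypeTable, method: str = "psa") -> DistanceMatrix:
    n = table.n_individuals
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = shared_allele_distance(table, i, j, method)
    return DistanceMatrix(list(table.individuals), d)


@dataclass
class TreeNode:
    """Rooted ultrametric tree node; ``height`` is the merge height (leaves 0)."""

    name: str | None = None
    height: float = 0.0
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Classic UPGMA: iteratively merge the closest pair at height d/2,
    updating distances as the cluster-size-weighted arithmetic average.
    Ties break toward the smallest (row, col) pair in current order, making
    the result deterministic."""
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if np.any(~np.isfinite(dist.values)):
        raise ValueError("non-finite distances")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dist.labels]
    sizes = [1] * n
    d = dist.values.astype(float).copy()
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                val = d[active[ai], active[aj]]
                if best is None or val < best[0]:
                    best = (val, ai, aj)
        val, ai, aj = best
        i, j = active[ai], active[aj]
        parent = TreeNode(height=val / 2.0, children=(nodes[i], nodes[j]))
        # weighted average of distances to the merged cluster
        for a in active:
            if a in (i, j):
                continue
            d[i, a] = d[a, i] = (sizes[i] * d[i, a] + sizes[j] * d[j, a]) / (
                sizes[i] + sizes[j]
            )
        nodes[i] = parent
        sizes[i] += sizes[j]
        active.pop(aj)
    return nodes[active[0]]


def _fmt_branch(x: float) -> str:
    return str(float(round(x, 10)))


def _newick_parts(node: TreeNode, parent_height: float) -> str:
    bl = _fmt_branch(parent_height - node.height)
    if node.is_leaf:
        return f"{node.name}:{bl}"
    inner = ",".join(_newick_parts(c, node.height) for c in node.children)
    return f"({inner}):{bl}"


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths, deterministic (merge-order) children."""
    if tree.is_leaf:
        return f"{tree.name};"
    inner = ",".join(_newick_parts(c, tree.height) for c in tree.children)
    return f"({inner});"
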