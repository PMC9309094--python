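"""Genome-wide Jaccard similarity, hierarchical clustering and pair adjacency.

The similarity between two tumor copy-number profiles is the genomic Jaccard
index: the number of base pairs aberrant in both samples divided by the
base-pair length of the union of their aberrant territory. It ranges from 0
to 1, with 1 meaning complete overlap. In the default ``directional`` mode a
base only counts toward the intersection when the aberration state matches
(gain with gain, loss with loss, copy-neutral LOH with copy-neutral LOH);
``any_aberration`` mode counts any aberrant base. Copy-number magnitude is
deliberately ignored — a CN-3 and a CN-8 gain are the same territory.

Cases are grouped by agglomerative hierarchical clustering on distance
1 - Jaccard. A matched biopsy/resection pair is "adjacent" when the two
leaves form a cherry in the dendrogram, i.e. their first merge is with each
other — the strictest reading of two samples clustering next to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy

from . import intervals as iv
from .segio import (
    ConfigurationError,
    SegmentProfile,
    aberrant_intervals,
)


@dataclass(frozen=True)
class JaccardScore:
    value: float
    intersection_bp: int
    union_bp: int
    both_empty: bool = False

    def __float__(self) -> float:
        return self.value


def jaccard_detailed(
    a: SegmentProfile, b: SegmentProfile, state_mode: str = "directional"
) -> JaccardScore:
    """Genomic Jaccard score with base-pair bookkeeping.

    Intersection: in directional mode, the sum over states (gain, loss,
    cnloh) of bases aberrant with that state in both profiles; in
    any_aberration mode, bases aberrant in both regardless of state.
    Union: bases aberrant (any state) in either profile. When both profiles
    carry no aberrant base, the score is defined as 1 and flagged
    ``both_empty``.
    """
    if a.genome is not b.genome and a.genome != b.genome:
        raise ConfigurationError(
            f"profiles {a.sample_id} and {b.sample_id} use different genomes"
        )
    ints_a = aberrant_intervals(a, state_mode)
    ints_b = aberrant_intervals(b, state_mode)
    inter = 0
    for state in ints_a:
        per_a, per_b = ints_a[state], ints_b.get(state, {})
        for chrom, ivs in per_a.items():
            if chrom in per_b:
                inter += iv.total_length(iv.intersect(ivs, per_b[chrom]))
    any_a = aberrant_intervals(a, "any_aberration")["aberrant"]
    any_b = aberrant_intervals(b, "any_aberration")["aberrant"]
    union = 0
    for chrom in set(any_a) | set(any_b):
        union += iv.total_length(iv.union(any_a.get(chrom, []), any_b.get(chrom, [])))
    if union == 0:
        return JaccardScore(1.0, 0, 0, both_empty=True)
    return JaccardScore(inter / union, inter, union)


def pairwise_jaccard(
    a: SegmentProfile, b: SegmentProfile, state_mode: str = "directional"
) -> float:
    """Genomic Jaccard similarity of two filtered profiles (see module doc)."""
    return jaccard_detailed(a, b, state_mode).value


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Jaccard matrix over an ordered cohort."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match sample count")

    def loc(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def similarity_matrix(
    cohort: Sequence[SegmentProfile], state_mode: str = "directional"
) -> SimilarityMatrix:
    """All-pairs genomic Jaccard matrix; ordering follows the input cohort."""
    ids = [p.sample_id for p in cohort]
    if len(ids) < 2:
        raise ValueError("similarity matrix needs at least two profiles")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in cohort")
    n = len(cohort)
    m = np.eye(n)
    for i in range(n):
        if cohort[i].is_empty:
            m[i, i] = 1.0  # empty vs itself: both-empty convention
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_jaccard(cohort[i], cohort[j], state_mode)
    return SimilarityMatrix(sample_ids=ids, values=m)


@dataclass
class ClusterTree:
    """Hierarchical merge tree over cohort leaves (scipy linkage encoding)."""

    linkage_matrix: np.ndarray
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def leaf_index(self, sample_id: str) -> int:
        try:
            return self.leaf_labels.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            bl = parent_height - node.dist
            if node.is_leaf():
                return f"{_newick_safe(self.leaf_labels[node.id])}:{bl:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{bl:.10g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def _newick_safe(label: str) -> str:
    if any(c in label for c in "(),:; \t'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def cluster(matrix: SimilarityMatrix, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering on distance 1 - Jaccard.

    Complete linkage is the default; average and single are available. Merge
    ties are resolved deterministically by scipy's ordering over the
    condensed distance matrix (smallest pair of indices first).
    """
    if linkage not in ("complete", "average", "single"):
        raise ConfigurationError(f"unsupported linkage {linkage!r}")
    d = 1.0 - matrix.values
    if np.isnan(d).any():
        raise ValueError("similarity matrix contains NaN")
    n = d.shape[0]
    condensed = d[np.triu_indices(n, k=1)]
    z = hierarchy.linkage(condensed, method=linkage)
    return ClusterTree(linkage_matrix=z, leaf_labels=list(matrix.sample_ids))


@dataclass(frozen=True)
class PairAdjacency:
    pair: tuple[str, str]
    adjacent: bool
    jaccard: float


def sibling_pairs(
    tree: ClusterTree,
    pairs: Iterable[tuple[str, str]],
    matrix: Optional[SimilarityMatrix] = None,
) -> list[PairAdjacency]:
    """Cherry test per pair: adjacent iff the two leaves merge directly.

    ``jaccard`` is filled from the similarity matrix when given, else NaN.
    """
    z = tree.linkage_matrix
    n = tree.n_leaves
    cherries = {
        frozenset((int(a), int(b)))
        for a, b, _, _ in z
        if a < n and b < n
    }
    out = []
    for a, b in pairs:
        ia, ib = tree.leaf_index(a), tree.leaf_index(b)
        adjacent = frozenset((ia, ib)) in cherries
        score = matrix.loc(a, b) if matrix is not None else float("nan")
        out.append(PairAdjacency(pair=(a, b), adjacent=adjacent, jaccard=score))
    return out


def cut_clusters(tree: ClusterTree, k: int) -> dict[str, int]:
    """Flat partition into k groups by removing the k-1 highest merges.

    Cluster labels are renumbered 1..k in order of first appearance along
    the leaf order, so the labelling is deterministic.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    # apply the first n-k merges (scipy rows are height-sorted), skip the rest
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row, (a, b, _, _) in enumerate(tree.linkage_matrix[: n - k]):
        node = n + row
        parent[find(int(a))] = node
        parent[find(int(b))] = node
        parent[node] = node
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for i, sample_id in enumerate(tree.leaf_labels):
        root = find(i)
        if root not in relabel:
            relabel[root] = len(relabel) + 1
        out[sample_id] = relabel[root]
    return out
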