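"""Clustering of TF motifs by genomic binding-site overlap.

Two motifs that bind the same genomic locations are functionally
interchangeable at the level of footprinting; their similarity is the
overlap coefficient of their site sets (shared sites over the smaller
set), and the tree distance is 1 - overlap, so a tree depth of 0.2
corresponds to 80% shared sites. Agglomerative clustering (complete
linkage by default) with a deterministic, lexicographic tie-break builds
the tree; flat clusters are cut at distance 0.5 (motifs sharing at least
half their sites co-cluster).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .bindetect import BindingSite

DEFAULT_CUT = 0.5


@dataclass
class OverlapDistanceMatrix:
    motif_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.motif_ids)
        if self.D.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.D, self.D.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix diagonal must be 0")
        if self.D.min() < 0 or self.D.max() > 1:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class ClusterTree:
    motif_ids: list[str]  # leaf order = lexicographic
    merges: np.ndarray  # scipy-style linkage matrix
    newick: str
    clusters: dict[str, int]  # flat clusters at the cut threshold
    cut: float


def _site_trees(sites: Sequence[BindingSite]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.interval.chrom, IntervalTree()).addi(
            s.interval.start, s.interval.end
        )
    return trees


def overlap_fraction(
    sites_a: Sequence[BindingSite],
    sites_b: Sequence[BindingSite],
    min_bp: int = 1,
) -> float:
    """Overlap coefficient of two site sets.

    Fraction of sites in the *smaller* set overlapping any site of the
    other set by >= ``min_bp`` bases; 0 for an empty set.
    """
    if not sites_a or not sites_b:
        return 0.0
    small, big = (sites_a, sites_b) if len(sites_a) <= len(sites_b) else (sites_b, sites_a)
    trees = _site_trees(big)
    hit = 0
    for s in small:
        tree = trees.get(s.interval.chrom)
        if tree is None:
            continue
        # require >= min_bp overlap, i.e. other.start <= end-min_bp etc.
        for ov in tree.overlap(s.interval.start, s.interval.end):
            if min(ov.end, s.interval.end) - max(ov.begin, s.interval.start) >= min_bp:
                hit += 1
                break
    return hit / len(small)


def overlap_distance_matrix(
    site_sets: dict[str, Sequence[BindingSite]], min_bp: int = 1
) -> OverlapDistanceMatrix:
    """D[i, j] = 1 - overlap_fraction over all motif pairs (sorted ids)."""
    ids = sorted(site_sets)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - overlap_fraction(site_sets[ids[i]], site_sets[ids[j]], min_bp)
            D[i, j] = D[j, i] = d
    return OverlapDistanceMatrix(ids, D)


def _to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    parts: dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = f"{parts[a]}:{h - heights[a]:.6g}"
        lb = f"{parts[b]}:{h - heights[b]:.6g}"
        node = n + k
        parts[node] = f"({la},{lb})"
        heights[node] = h
    root = n + len(Z) - 1 if len(Z) else 0
    return parts[root] + ";"


def build_tree(
    D: OverlapDistanceMatrix,
    linkage: str = "complete",
    cut: float = DEFAULT_CUT,
) -> ClusterTree:
    """Agglomerative clustering of the overlap-distance matrix.

    Motif ids are pre-sorted lexicographically so equal-distance merges
    break ties deterministically. Flat clusters are cut at ``cut``.
    """
    ids = list(D.motif_ids)
    if len(ids) < 2:
        return ClusterTree(ids, np.empty((0, 4)), f"{ids[0]};" if ids else ";", {i: 1 for i in ids}, cut)
    order = np.argsort(ids)
    ids_sorted = [ids[i] for i in order]
    Dm = D.D[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(Dm, checks=False), method=linkage)
    flat = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return ClusterTree(
        motif_ids=ids_sorted,
        merges=Z,
        newick=_to_newick(Z, ids_sorted),
        clusters={m: int(c) for m, c in zip(ids_sorted, flat)},
        cut=cut,
    )


def cophenetic_distance(tree: ClusterTree, motif_a: str, motif_b: str) -> float:
    """Tree distance between two leaves (height of their lowest common merge)."""
    if motif_a == motif_b:
        return 0.0
    n = len(tree.motif_ids)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    ia, ib = tree.motif_ids.index(motif_a), tree.motif_ids.index(motif_b)
    for k, (a, b, h, _) in enumerate(tree.merges):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        if ia in merged and ib in merged:
            return float(h)
    raise ValueError("leaves never merge; malformed tree")
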