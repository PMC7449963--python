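"""Promoter annotation of binding sites and TF->TF network inference.

A binding site is assigned to a gene when it overlaps the gene's
promoter window, anchored at the transcription start site (TSS) and
spanning ``upstream`` bases before and ``downstream`` bases after it,
strand-aware. The network stage draws a directed edge A -> B when a
binding site of motif A with increasing binding strength (log2FC > 0,
and bound in the target condition by default) lies in the promoter of a
gene encoding motif B; levels are breadth-first distances from a chosen
source TF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .bindetect import BindingSite

DEFAULT_UPSTREAM = 10_000
DEFAULT_DOWNSTREAM = 1_000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    motif_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter(
        self, upstream: int = DEFAULT_UPSTREAM, downstream: int = DEFAULT_DOWNSTREAM
    ) -> tuple[int, int]:
        """Promoter window [lo, hi) around the TSS, strand-aware."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream + 1
        else:
            lo, hi = self.tss - downstream, self.tss + upstream + 1
        return max(0, lo), hi


INTERGENIC = "intergenic"


def annotate_promoters(
    sites: Sequence[BindingSite],
    genes: Sequence[GeneModel],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> list[list[str]]:
    """Per-site list of gene ids whose promoter windows the site overlaps.

    A site may be assigned to several genes; sites hitting none get
    the single label "intergenic".
    """
    windows = [
        (g.chrom, *g.promoter(upstream, downstream), g.gene_id) for g in genes
    ]
    out: list[list[str]] = []
    for site in sites:
        iv = site.interval
        hits = [
            gid
            for chrom, lo, hi, gid in windows
            if chrom == iv.chrom and min(hi, iv.end) > max(lo, iv.start)
        ]
        out.append(hits if hits else [INTERGENIC])
    return out


@dataclass
class TFNetwork:
    source: str
    levels: dict[str, int]  # node -> BFS level (source = 0)
    edges: list[dict]  # {source, target, n_sites, mean_log2fc}
    self_edges: list[dict] = field(default_factory=list)

    def to_files(self, edge_path: str | Path, node_path: str | Path) -> None:
        with open(edge_path, "w") as fh:
            fh.write("source\ttarget\tn_sites\tmean_log2fc\n")
            for e in self.edges + self.self_edges:
                fh.write(
                    f"{e['source']}\t{e['target']}\t{e['n_sites']}\t{e['mean_log2fc']:.4f}\n"
                )
        with open(node_path, "w") as fh:
            json.dump({"source": self.source, "levels": self.levels}, fh, indent=1)


def create_network(
    sites: Sequence[BindingSite],
    genes: Sequence[GeneModel],
    source_motif: str,
    cond_pair: tuple[str, str],
    max_level: int = 2,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    require_bound: bool = True,
) -> TFNetwork:
    """Directed TF->TF activation network seeded at ``source_motif``.

    Edge A -> B requires a site of motif A with log2FC(c1 -> c2) > 0
    (and, by default, bound in c2) inside the promoter of a gene encoding
    motif B. Nodes keep their BFS level from the source; nodes beyond
    ``max_level`` are pruned. Self-edges are recorded separately and do
    not affect levels.
    """
    c1, c2 = cond_pair
    if not any(s.motif_id == source_motif for s in sites):
        raise ValueError(f"source motif {source_motif!r} absent from site set")
    gene_motifs: dict[str, tuple[str, ...]] = {g.gene_id: g.motif_ids for g in genes}
    assignments = annotate_promoters(sites, genes, upstream, downstream)

    support: dict[tuple[str, str], list[float]] = {}
    for site, gene_ids in zip(sites, assignments):
        fc = site.log2fc.get((c1, c2))
        if fc is None or fc <= 0:
            continue
        if require_bound and not site.bound.get(c2, False):
            continue
        for gid in gene_ids:
            if gid == INTERGENIC:
                continue
            for target in gene_motifs.get(gid, ()):
                support.setdefault((site.motif_id, target), []).append(fc)

    G = nx.DiGraph()
    G.add_node(source_motif)
    for (a, b), fcs in support.items():
        if a != b:
            G.add_edge(a, b)
    levels = (
        nx.single_source_shortest_path_length(G, source_motif, cutoff=max_level)
        if source_motif in G
        else {source_motif: 0}
    )
    kept = set(levels)
    edges, self_edges = [], []
    for (a, b), fcs in sorted(support.items()):
        rec = {
            "source": a,
            "target": b,
            "n_sites": len(fcs),
            "mean_log2fc": float(sum(fcs) / len(fcs)),
        }
        if a == b:
            if a in kept:
                self_edges.append(rec)
        elif a in kept and b in kept:
            edges.append(rec)
    return TFNetwork(source=source_motif, levels=dict(levels), edges=edges, self_edges=self_edges)
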