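"""End-to-end pipeline: correct -> score -> bindetect -> aggregate ->
cluster -> network, glued by plain-text artifacts and a JSON manifest.

Stages communicate only through files (bedGraph/BED/TSV/JSON), so any
stage can be re-run or replaced independently; the manifest records
package version, parameters and input checksums for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate_metrics import aggregate, fpd
from .bias_model import correct_regions
from .bindetect import (
    classify_sites,
    differential_binding,
    normalize_scores,
    scan_motifs,
    score_sites,
    site_log2fc,
)
from .core import merge_intervals
from .footprint_scores import ScoreParams, footprint_score, fos_score
from .formats_io import (
    fragments_to_cutsites,
    read_bed,
    read_fasta,
    read_gene_table,
    read_jaspar,
    write_bedgraph,
)
from .motif_clustering import build_tree, overlap_distance_matrix
from .tf_network import create_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str
    peaks: str
    motifs: str
    fragments: dict[str, str]  # condition -> fragments BED
    outdir: str
    genes: str | None = None  # gene table enabling the network stage
    source_motif: str | None = None
    seed: int = 0
    bias_window: int = 20
    smooth_w: int = 1
    score_method: str = "combined"  # or "fos"
    fp_widths: tuple[int, ...] = (8, 10, 12, 14, 16, 18, 20)
    flank_width: int = 30
    agg_window: int | None = None
    min_sites: int = 50
    n_background: int = 100
    cluster_cut: float = 0.5
    cluster_site_set: str = "bound"  # or "all"
    max_level: int = 2

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.genome, self.peaks, self.motifs, *self.fragments.values()]
            + ([self.genes] if self.genes else [])
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        if len(self.fragments) == 0:
            raise ValueError("at least one condition with fragments is required")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in dependency order; returns the output directory."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            name: _sha256(p)
            for name, p in {
                "genome": config.genome,
                "peaks": config.peaks,
                "motifs": config.motifs,
                **{f"fragments_{c}": p for c, p in config.fragments.items()},
                **({"genes": config.genes} if config.genes else {}),
            }.items()
        },
        "stages": [],
    }

    genome = read_fasta(config.genome)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    peaks = merge_intervals(read_bed(config.peaks))
    motifs = read_jaspar(config.motifs)
    conditions = sorted(config.fragments)

    def stage_done(name: str, **extra) -> None:
        manifest["stages"].append({"name": name, "time": time.time(), **extra})
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    # 1. bias correction per condition
    scoring_tracks: dict[str, list] = {}
    bundles_by_cond: dict[str, list] = {}
    for cond in conditions:
        frags = read_bed(config.fragments[cond])
        events = fragments_to_cutsites(frags, chrom_sizes=chrom_sizes)
        model, bundles = correct_regions(
            events, genome, peaks, window=config.bias_window,
            smooth_w=config.smooth_w, seed=config.seed,
        )
        bundles_by_cond[cond] = bundles
        model.to_json(out / f"bias_model_{cond}.json")
        for kind in ("observed", "bias", "expected", "corrected"):
            write_bedgraph(
                [getattr(b, kind) for b in bundles], out / f"{kind}_{cond}.bedgraph"
            )
    stage_done("correct", conditions=conditions)

    # 2. footprint scoring
    params = ScoreParams(fp_widths=tuple(config.fp_widths), flank_width=config.flank_width)
    scorer = footprint_score if config.score_method == "combined" else fos_score
    for cond in conditions:
        tracks = [scorer(b.scoring_track(), params) for b in bundles_by_cond[cond]]
        scoring_tracks[cond] = tracks
        write_bedgraph(tracks, out / f"footprint_{cond}.bedgraph")
    stage_done("score", method=config.score_method)

    # 3. bindetect
    sites = scan_motifs(motifs, genome, peaks)
    score_sites(sites, scoring_tracks, agg_window=config.agg_window)
    normalize_scores(sites, conditions)
    classify_sites(sites, conditions, min_sites=config.min_sites, random_state=config.seed)
    pair = (conditions[0], conditions[1]) if len(conditions) >= 2 else None
    if pair:
        for s in sites:
            site_log2fc(s, *pair)
        volcano = differential_binding(
            sites, pair, n_background=config.n_background, seed=config.seed
        )
        pd.DataFrame(
            [
                {
                    "motif_id": r.motif_id,
                    "n_sites": r.n_sites,
                    **{f"mean_{c}": v for c, v in r.mean_scores.items()},
                    "differential_score": r.differential_score,
                    "p_value": r.p_value,
                }
                for r in volcano
            ]
        ).to_csv(out / "volcano.tsv", sep="\t", index=False)
    site_rows = []
    for s in sites:
        row = {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "strand": s.interval.strand,
            "motif_id": s.motif_id,
            "match_score": s.match_score,
        }
        for c in conditions:
            row[f"score_{c}"] = s.scores.get(c, 0.0)
            row[f"norm_score_{c}"] = s.norm_scores.get(c, 0.0)
            row[f"bound_{c}"] = int(s.bound.get(c, False))
        if pair:
            row["log2fc"] = s.log2fc.get(pair, 0.0)
        site_rows.append(row)
    sites_df = pd.DataFrame(site_rows)
    sites_df.to_csv(out / "sites.tsv", sep="\t", index=False)
    stage_done("bindetect", n_sites=len(sites))

    # 4. aggregate profiles + FPD per motif and condition
    agg_rows, fpd_rows = [], []
    for motif in motifs:
        msites = [s for s in sites if s.motif_id == motif.motif_id]
        if not msites:
            continue
        for cond in conditions:
            try:
                prof = aggregate(msites, [b.corrected for b in bundles_by_cond[cond]], condition=cond)
            except ValueError:
                continue
            for off, v in enumerate(prof.profile):
                agg_rows.append(
                    {"motif_id": motif.motif_id, "condition": cond, "offset": off, "mean_signal": v}
                )
            fpd_rows.append(
                {
                    "motif_id": motif.motif_id,
                    "condition": cond,
                    "n_sites": prof.n_sites,
                    "fpd": fpd(prof, motif.length),
                }
            )
    pd.DataFrame(agg_rows).to_csv(out / "profiles.tsv", sep="\t", index=False)
    pd.DataFrame(fpd_rows).to_csv(out / "fpd.tsv", sep="\t", index=False)
    stage_done("aggregate")

    # 5. motif clustering by site overlap
    site_sets = {}
    for motif in motifs:
        msites = [s for s in sites if s.motif_id == motif.motif_id]
        if config.cluster_site_set == "bound":
            msites = [s for s in msites if any(s.bound.get(c) for c in conditions)]
        if msites:
            site_sets[motif.motif_id] = msites
    if len(site_sets) >= 2:
        D = overlap_distance_matrix(site_sets)
        tree = build_tree(D, cut=config.cluster_cut)
        (out / "tree.nwk").write_text(tree.newick + "\n")
        pd.DataFrame(
            {"motif_id": list(tree.clusters), "cluster": list(tree.clusters.values())}
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    stage_done("cluster", n_motifs=len(site_sets))

    # 6. TF network (needs genes with motif links and a source motif)
    if config.genes and config.source_motif and pair:
        genes = read_gene_table(config.genes)
        net = create_network(
            sites, genes, config.source_motif, pair, max_level=config.max_level
        )
        net.to_files(out / "network_edges.tsv", out / "network_nodes.json")
        stage_done("network", n_nodes=len(net.levels))
    else:
        stage_done("network", skipped=True)

    return out
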