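"""Reading and writing of the external formats the pipeline speaks.

FASTA genomes, BED intervals, bedGraph signal tracks, JASPAR PFMs and a
minimal gene table, plus the conversion of aligned fragments into
strand-aware single-base cut events and their pileup into per-region
tracks. All interval arithmetic is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from .core import (
    CutEvent,
    CutsiteTrack,
    GenomicInterval,
    intervals_overlap,
    sort_intervals,
)
from .motifs import MotifModel

logger = logging.getLogger(__name__)

# Default Tn5 end shifts: +4 on the plus-strand cut, -5 on the minus-strand
# cut, centering both ends of the 9-bp target-site duplication.
DEFAULT_SHIFT_PLUS = 4
DEFAULT_SHIFT_MINUS = 5

_ALLOWED = set("ACGTN")


def read_fasta(path: str | Path, on_invalid: str = "N") -> dict[str, str]:
    """Read a FASTA file into {chrom: uppercase sequence}.

    Characters outside A/C/G/T/N are mapped to N when ``on_invalid="N"``
    (default) or rejected when ``on_invalid="error"``.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _ALLOWED
        if bad:
            if on_invalid == "error":
                raise ValueError(
                    f"sequence {record.id} contains invalid characters {sorted(bad)}"
                )
            seq = "".join(c if c in _ALLOWED else "N" for c in seq)
        genome[record.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path, min_fields: int = 3) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals, exactly as written (no merging)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ValueError(f"{path}:{lineno}: expected >= {min_fields} columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = iv.score if iv.score is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def fragments_to_cutsites(
    fragments: Sequence[GenomicInterval],
    shift_plus: int = DEFAULT_SHIFT_PLUS,
    shift_minus: int = DEFAULT_SHIFT_MINUS,
    chrom_sizes: dict[str, int] | None = None,
) -> list[CutEvent]:
    """Convert fragments into two cut events each.

    The plus-strand cut is at fragment start + ``shift_plus``; the
    minus-strand cut at (end - 1) - ``shift_minus``. Events falling outside
    chromosome bounds are dropped (count logged). Duplicates are kept.
    """
    events: list[CutEvent] = []
    dropped = 0
    for frag in fragments:
        size = chrom_sizes.get(frag.chrom) if chrom_sizes else None
        for pos, strand in (
            (frag.start + shift_plus, "+"),
            (frag.end - 1 - shift_minus, "-"),
        ):
            if pos < 0 or (size is not None and pos >= size):
                dropped += 1
            else:
                events.append(CutEvent(frag.chrom, pos, strand))
    if dropped:
        logger.info("fragments_to_cutsites: dropped %d out-of-bounds events", dropped)
    return events


def pileup(
    events: Iterable[CutEvent], regions: Sequence[GenomicInterval]
) -> list[CutsiteTrack]:
    """Pile cut events into per-region observed tracks.

    Regions must be non-overlapping (merge first); events outside all
    regions are ignored.
    """
    if intervals_overlap(regions):
        raise ValueError("regions overlap; merge them first (merge_intervals)")
    tracks = [
        CutsiteTrack(r, np.zeros(len(r)), kind="observed") for r in regions
    ]
    by_chrom: dict[str, list[CutsiteTrack]] = {}
    for t in tracks:
        by_chrom.setdefault(t.region.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.region.start)
    starts = {c: np.array([t.region.start for t in lst]) for c, lst in by_chrom.items()}
    for ev in events:
        lst = by_chrom.get(ev.chrom)
        if lst is None:
            continue
        i = int(np.searchsorted(starts[ev.chrom], ev.pos, side="right")) - 1
        if i >= 0 and ev.pos < lst[i].region.end:
            lst[i].values[ev.pos - lst[i].region.start] += 1
    return tracks


def write_bedgraph(tracks: Sequence[CutsiteTrack], path: str | Path) -> None:
    """Write tracks as bedGraph, merging runs of equal value into one line."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph\n')
        for t in sorted(tracks, key=lambda t: (t.region.chrom, t.region.start)):
            vals = t.values
            if len(vals) == 0:
                continue
            change = np.nonzero(np.diff(vals))[0] + 1
            run_starts = np.concatenate(([0], change))
            run_ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(run_starts, run_ends):
                fh.write(
                    f"{t.region.chrom}\t{t.region.start + s}\t{t.region.start + e}"
                    f"\t{vals[s]:.6g}\n"
                )


def read_bedgraph(
    path: str | Path,
    regions: Sequence[GenomicInterval] | None = None,
    kind: str = "observed",
) -> list[CutsiteTrack]:
    """Read a bedGraph back into tracks.

    With ``regions`` given, one track per region (positions not covered by
    the file are 0). Without, contiguous runs of coverage define the regions.
    """
    entries: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            entries.append((chrom, int(s), int(e), float(v)))
    entries.sort(key=lambda x: (x[0], x[1]))
    if regions is None:
        regions = []
        for chrom, s, e, _ in entries:
            if regions and regions[-1].chrom == chrom and regions[-1].end == s:
                regions[-1] = GenomicInterval(chrom, regions[-1].start, e)
            else:
                regions.append(GenomicInterval(chrom, s, e))
    regions = sort_intervals(regions)
    tracks = [CutsiteTrack(r, np.zeros(len(r)), kind=kind) for r in regions]
    by_chrom: dict[str, list[CutsiteTrack]] = {}
    for t in tracks:
        by_chrom.setdefault(t.region.chrom, []).append(t)
    for chrom, s, e, v in entries:
        for t in by_chrom.get(chrom, []):
            lo, hi = max(s, t.region.start), min(e, t.region.end)
            if hi > lo:
                t.values[lo - t.region.start : hi - t.region.start] = v
    return tracks


def read_jaspar(path: str | Path, **motif_kwargs) -> list[MotifModel]:
    """Read JASPAR-format PFMs (">ID name" + bracketed A/C/G/T count rows)."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            parsed = [
                (m.matrix_id or m.name, m.name or m.matrix_id, m.counts)
                for m in records
            ]
        except Exception as exc:
            raise ValueError(f"failed to parse JASPAR file {path}: {exc}") from exc
    out = []
    for motif_id, name, counts in parsed:
        pfm = np.array([counts[b] for b in "ACGT"], dtype=float)
        out.append(MotifModel(motif_id, name, pfm, **motif_kwargs))
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def write_jaspar(motifs_list: Sequence[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs_list:
            fh.write(f">{m.motif_id}\t{m.name}\n")
            for i, b in enumerate("ACGT"):
                row = " ".join(f"{v:.0f}" for v in m.pfm[i])
                fh.write(f"{b}  [ {row} ]\n")


def read_gene_table(path: str | Path) -> list["GeneModel"]:
    """Minimal gene table: chrom, start, end, strand, gene_id[, motif_ids].

    motif_ids is an optional comma-separated list of motifs the gene encodes.
    """
    from .tf_network import GeneModel

    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            chrom, start, end, strand, gene_id = fields[:5]
            motif_ids = (
                tuple(m for m in fields[5].split(",") if m) if len(fields) > 5 else ()
            )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    motif_ids=motif_ids,
                )
            )
    return genes
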