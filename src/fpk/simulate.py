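"""Synthetic ATAC-seq footprinting data with known ground truth.

The generator emulates the data-generating process the pipeline assumes:
an i.i.d. random genome, accessible peaks with per-peak accessibility
drawn log-normally, motif instances implanted at known positions, a true
Tn5 dinucleotide bias model, and footprint-shaped depletion at bound
sites. Per-base insertion intensity is

    accessibility(peak) x bias_weight(sequence) x (1 - depth * bound_mask)

and cut counts are Poisson. Events are emitted as minimal fragments whose
two shifted ends both land on the sampled cut base, keeping the simulator
independent of fragment-length modelling.

The true bias model is made reverse-complement symmetric (Tn5 acts as a
homodimer) with a fixed penalty on CG/GC dinucleotides, so a CG-rich
"anti-Tn5" motif produces a false footprint in uncorrected signal even
when never bound. Per-site bound probability scales with peak
accessibility — occupancy follows openness — which is what makes
accessibility-aware scoring informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bias_model import BiasModel, score_sequence_bias
from .bindetect import BindingSite
from .core import GenomicInterval
from .formats_io import write_bed, write_fasta
from .motifs import BASE_INDEX, BASES

ANTI_TN5_CONSENSUS = "ACGCGCGCGT"
_CG = 4 * BASE_INDEX["C"] + BASE_INDEX["G"]
_GC = 4 * BASE_INDEX["G"] + BASE_INDEX["C"]


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 100_000}
    )
    n_peaks: int = 200
    peak_width: int = 500
    conditions: tuple[str, ...] = ("cond1", "cond2")
    # motif_id -> consensus; implanted with light mutation (soft PFM)
    motifs: dict[str, str] = field(
        default_factory=lambda: {
            "TF_A": "TCATTAATGG",
            "TF_B": "GACCTGATCA",
            "TF_C": "ATGGTCCATT",
        }
    )
    sites_per_motif: int = 100
    # motif_id -> condition -> expected bound fraction
    bound_fraction: dict[str, dict[str, float]] = field(default_factory=dict)
    footprint_depth: float = 0.5
    bias_strength: float = 1.0
    reads_per_peak: float = 200.0
    anti_tn5_motif: str | None = None  # motif id for a never-bound CG-rich motif
    accessibility_sd: float = 0.8
    accessibility_coupling: float = 2.0
    # Bound TFs open the chromatin around their site: cut intensity in
    # +/- boost_halfwidth bp of flank around a bound motif is multiplied
    # by (1 + local_accessibility_boost).
    local_accessibility_boost: float = 0.5
    boost_halfwidth: int = 50
    mutation_rate: float = 0.05
    bias_window: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.footprint_depth <= 1:
            raise ValueError("footprint_depth must lie in [0, 1]")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        for motif_id, consensus in self.all_motifs().items():
            if len(consensus) > self.peak_width - 2 * self.bias_window:
                raise ValueError(f"motif {motif_id} longer than usable peak width")
        if not self.bound_fraction:
            self.bound_fraction = {
                m: {c: 0.3 for c in self.conditions} for m in self.motifs
            }
        for fracs in self.bound_fraction.values():
            for f in fracs.values():
                if not 0 <= f <= 1:
                    raise ValueError("bound fractions must lie in [0, 1]")

    def all_motifs(self) -> dict[str, str]:
        out = dict(self.motifs)
        if self.anti_tn5_motif:
            out[self.anti_tn5_motif] = ANTI_TN5_CONSENSUS
        return out


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, str]
    peaks: list[GenomicInterval]
    fragments: dict[str, list[GenomicInterval]]
    truth: pd.DataFrame
    bias_model: BiasModel
    peak_accessibility: np.ndarray

    def truth_sites(self, motif_id: str | None = None) -> list[BindingSite]:
        """Truth rows as BindingSite objects (for aggregation/clustering)."""
        rows = self.truth if motif_id is None else self.truth[self.truth.motif_id == motif_id]
        return [
            BindingSite(
                interval=GenomicInterval(r.chrom, r.start, r.end, r.strand),
                motif_id=r.motif_id,
                match_score=0.0,
            )
            for r in rows.itertuples()
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": outdir / "genome.fa", "peaks": outdir / "peaks.bed"}
        write_fasta(self.genome, paths["genome"])
        write_bed(self.peaks, paths["peaks"])
        for cond, frags in self.fragments.items():
            p = outdir / f"fragments_{cond}.bed"
            write_bed(frags, p)
            paths[f"fragments_{cond}"] = p
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["bias_model"] = outdir / "true_bias_model.json"
        self.bias_model.to_json(paths["bias_model"])
        return paths


def _symmetrize_rc(logw: np.ndarray) -> np.ndarray:
    """Average each (offset, dinuc) cell with its reverse-complement mirror."""
    k1 = logw.shape[0]
    comp = np.array([3, 2, 1, 0])
    out = np.empty_like(logw)
    for r in range(k1):
        for d in range(16):
            b1, b2 = divmod(d, 4)
            rc_d = 4 * comp[b2] + comp[b1]
            out[r, d] = 0.5 * (logw[r, d] + logw[k1 - 1 - r, rc_d])
    return out


def _double_center(logw: np.ndarray) -> np.ndarray:
    """Remove mononucleotide marginals from each per-offset 4x4 dinuc table.

    The simulated preference is a pure dinucleotide coupling: within each
    offset, weights carry no single-base marginal effect. (Mononucleotide
    components of overlapping dinucleotides leak into neighboring offsets
    of any per-offset marginal estimator; a pure coupling keeps the
    generative model identifiable by dinucleotide counting.)
    """
    t = logw.reshape(-1, 4, 4)
    t = (
        t
        - t.mean(axis=2, keepdims=True)
        - t.mean(axis=1, keepdims=True)
        + t.mean(axis=(1, 2), keepdims=True)
    )
    return t.reshape(-1, 16)


def _true_bias_model(rng: np.random.Generator, config: SimulationConfig) -> BiasModel:
    k = config.bias_window
    s = config.bias_strength
    logw = rng.normal(0.0, 0.35 * s, size=(k - 1, 16)) if s > 0 else np.zeros((k - 1, 16))
    logw[:, _CG] -= 0.6 * s
    logw[:, _GC] -= 0.6 * s
    logw = _symmetrize_rc(_double_center(logw))
    probs = np.exp(logw) / 16.0
    probs /= probs.sum(axis=1, keepdims=True)
    uniform = np.full((k - 1, 16), 1.0 / 16)
    return BiasModel(window=k, dinuc_probs=probs, background_probs=uniform)


def _place_peaks(rng: np.random.Generator, config: SimulationConfig) -> list[GenomicInterval]:
    total = sum(config.chrom_lengths.values())
    peaks: list[GenomicInterval] = []
    margin = 200
    remaining = config.n_peaks
    chroms = list(config.chrom_lengths)
    for i, chrom in enumerate(chroms):
        length = config.chrom_lengths[chrom]
        n = remaining if i == len(chroms) - 1 else round(config.n_peaks * length / total)
        n = min(n, remaining)
        remaining -= n
        usable = length - 2 * margin
        slot = usable // max(n, 1)
        if slot <= config.peak_width:
            raise ValueError("chromosomes too short for the requested peaks")
        for j in range(n):
            jitter = int(rng.integers(0, slot - config.peak_width))
            start = margin + j * slot + jitter
            peaks.append(
                GenomicInterval(chrom, start, start + config.peak_width, name=f"peak{len(peaks)}")
            )
    return peaks


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedData:
    """Generate a complete synthetic dataset; byte-reproducible per seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    genome_arrays = {
        chrom: rng.integers(0, 4, size=n).astype(np.int8)
        for chrom, n in config.chrom_lengths.items()
    }
    peaks = _place_peaks(rng, config)
    bias = _true_bias_model(rng, config)
    acc = rng.lognormal(0.0, config.accessibility_sd, size=len(peaks))
    acc_rel = acc / acc.mean()

    # Implant motif instances inside peaks at non-overlapping positions.
    inner = config.bias_window  # keep implants away from peak edges
    used: dict[int, list[tuple[int, int]]] = {}
    records = []
    motif_defs = config.all_motifs()
    for motif_id, consensus in motif_defs.items():
        L = len(consensus)
        cons_codes = np.array([BASE_INDEX[b] for b in consensus], dtype=np.int8)
        placed = 0
        attempts = 0
        while placed < config.sites_per_motif and attempts < config.sites_per_motif * 50:
            attempts += 1
            pk = int(rng.integers(0, len(peaks)))
            peak = peaks[pk]
            start = int(rng.integers(peak.start + inner, peak.end - inner - L))
            span = (start, start + L)
            if any(span[0] < e and s < span[1] for s, e in used.get(pk, [])):
                continue
            used.setdefault(pk, []).append(span)
            codes = cons_codes.copy()
            mut = rng.random(L) < config.mutation_rate
            codes[mut] = rng.integers(0, 4, size=int(mut.sum()))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                codes = (3 - codes)[::-1]
            genome_arrays[peak.chrom][span[0] : span[1]] = codes
            records.append(
                {
                    "motif_id": motif_id,
                    "chrom": peak.chrom,
                    "start": span[0],
                    "end": span[1],
                    "strand": strand,
                    "peak_id": pk,
                }
            )
            placed += 1
        # dense configs may place fewer sites; the truth table is authoritative
    truth = pd.DataFrame.from_records(records)

    # Bound labels: bound_fraction is the exact fraction of each motif's
    # sites bound per condition; which sites are bound is biased toward
    # accessible peaks (weighted sampling without replacement via
    # Gumbel-max keys), emulating occupancy following openness.
    anti_id = config.anti_tn5_motif
    for cond in config.conditions:
        bound = np.zeros(len(truth), dtype=bool)
        for motif_id, idx in truth.groupby("motif_id").groups.items():
            idx = np.asarray(idx)
            if motif_id == anti_id:
                continue
            bf = config.bound_fraction.get(motif_id, {}).get(cond, 0.0)
            k = int(round(bf * len(idx)))
            if k == 0:
                continue
            logw = config.accessibility_coupling * np.log(
                acc_rel[truth.loc[idx, "peak_id"].to_numpy()]
            )
            keys = logw + rng.gumbel(size=len(idx))
            bound[idx[np.argsort(keys)[::-1][:k]]] = True
        truth[f"bound_{cond}"] = bound

    genome = {c: "".join(BASES[i] for i in arr) for c, arr in genome_arrays.items()}

    # Per-base Poisson intensities and fragment emission.
    fragments: dict[str, list[GenomicInterval]] = {c: [] for c in config.conditions}
    truth_by_peak = truth.groupby("peak_id") if len(truth) else None
    for pk, peak in enumerate(peaks):
        w = score_sequence_bias(bias, genome, peak).values
        base_lam = w / w.sum() * config.reads_per_peak * acc_rel[pk]
        peak_rows = (
            truth_by_peak.get_group(pk)
            if truth_by_peak is not None and pk in truth_by_peak.groups
            else None
        )
        for cond in config.conditions:
            lam = base_lam.copy()
            if peak_rows is not None:
                hw = config.boost_halfwidth
                boost = 1.0 + config.local_accessibility_boost
                for r in peak_rows.itertuples():
                    if getattr(r, f"bound_{cond}"):
                        lo, hi = r.start - peak.start, r.end - peak.start
                        lam[max(lo - hw, 0) : lo] *= boost
                        lam[hi : hi + hw] *= boost
                        lam[lo:hi] *= (1.0 - config.footprint_depth) * boost
            counts = rng.poisson(lam)
            for off in np.nonzero(counts)[0]:
                pos = peak.start + int(off)
                frag = GenomicInterval(peak.chrom, pos - 4, pos + 6)
                fragments[cond].extend([frag] * int(counts[off]))

    return SimulatedData(
        config=config,
        genome=genome,
        peaks=peaks,
        fragments=fragments,
        truth=truth,
        bias_model=bias,
        peak_accessibility=acc_rel,
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC by explicit sort-and-count (rank statistic, ties averaged)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    order = np.argsort(scores, kind="mergesort")
    sorted_scores = scores[order]
    ranks = np.empty(len(scores))
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    pos_rank_sum = ranks[labels].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def truth_metrics(
    predictions: Sequence[BindingSite],
    truth: pd.DataFrame,
    condition: str,
    use_norm: bool = False,
) -> dict[str, float]:
    """Score predictions against the truth table by site coordinates.

    Matches sites on (chrom, start, end, motif_id); AUROC uses the
    per-condition site score, precision/recall the ``bound`` labels.
    """
    key_truth = {
        (r.chrom, r.start, r.end, r.motif_id): bool(getattr(r, f"bound_{condition}"))
        for r in truth.itertuples()
    }
    scores, labels, called = [], [], []
    for site in predictions:
        key = (site.interval.chrom, site.interval.start, site.interval.end, site.motif_id)
        if key not in key_truth:
            continue
        store = site.norm_scores if use_norm else site.scores
        scores.append(store.get(condition, 0.0))
        labels.append(key_truth[key])
        called.append(site.bound.get(condition, False))
    if not scores:
        raise ValueError("no overlap between predicted and truth sites")
    labels_arr = np.array(labels, dtype=bool)
    called_arr = np.array(called, dtype=bool)
    tp = int((called_arr & labels_arr).sum())
    precision = tp / called_arr.sum() if called_arr.sum() else 0.0
    recall = tp / labels_arr.sum() if labels_arr.sum() else 0.0
    return {
        "auroc": auroc(np.array(scores), labels_arr),
        "precision": float(precision),
        "recall": float(recall),
        "bound_fraction_error": float(abs(called_arr.mean() - labels_arr.mean())),
        "n": len(scores),
    }
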