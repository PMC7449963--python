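"""Binding-site detection, normalization, classification and differential
binding (the BINDetect stage).

Regions are scanned on both strands with log-odds motif matrices; each
match becomes a binding site scored per condition with the maximum
footprint-score value over the (extended) site. Condition score
distributions are quantile-normalized so per-TF comparisons reflect
relative, not global, activity shifts. A two-component Gaussian mixture
on log(1 + score) separates bound from unbound sites per motif and
condition, and per-TF differential binding is summarized as a
subsampled-background z-score with a two-sided normal p-value — the rows
of the volcano plot.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats import rankdata
from sklearn.mixture import GaussianMixture

from .core import CutsiteTrack, GenomicInterval
from .motifs import MotifModel, encode_sequence

logger = logging.getLogger(__name__)


@dataclass
class BindingSite:
    interval: GenomicInterval
    motif_id: str
    match_score: float
    scores: dict[str, float] = field(default_factory=dict)
    norm_scores: dict[str, float] = field(default_factory=dict)
    bound: dict[str, bool] = field(default_factory=dict)
    log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    outside_scored_region: bool = False


@dataclass
class TFDifferential:
    """One volcano-plot row: per-motif differential binding summary."""

    motif_id: str
    n_sites: int
    mean_scores: dict[str, float]
    differential_score: float
    p_value: float


def _sliding_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; NaN where the window has N."""
    L = logodds.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.arange(n)[:, None] + np.arange(L)[None, :]
    wins = codes[idx]
    valid = ~(wins >= 4).any(axis=1)
    scores = np.full(n, np.nan)
    safe = np.where(wins >= 4, 0, wins)
    vals = logodds[safe, np.arange(L)[None, :]].sum(axis=1)
    scores[valid] = vals[valid]
    return scores


def _resolve_overlaps(matches: list[tuple[int, float]], length: int) -> list[tuple[int, float]]:
    """Keep the higher-scoring of overlapping matches (ties -> leftmost)."""
    order = sorted(matches, key=lambda m: (-m[1], m[0]))
    taken: list[tuple[int, float]] = []
    occupied: list[tuple[int, int]] = []
    for start, score in order:
        end = start + length
        clash = any(s < end and start < e for s, e in occupied)
        if not clash:
            taken.append((start, score))
            occupied.append((start, end))
    taken.sort()
    return taken


def scan_motifs(
    motifs: Sequence[MotifModel],
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
) -> list[BindingSite]:
    """Scan merged regions with every motif on both strands.

    A site is reported where the log-odds score meets the motif's
    threshold; overlapping same-motif matches on one strand are resolved
    by keeping the higher score.
    """
    codes_cache = {c: encode_sequence(s) for c, s in genome.items()}
    sites: list[BindingSite] = []
    for region in regions:
        codes = codes_cache[region.chrom][region.start : region.end]
        for motif in motifs:
            if motif.length > len(region):
                logger.info(
                    "motif %s longer than region %s; skipped", motif.motif_id, region
                )
                continue
            for strand, mat in (("+", motif.logodds), ("-", motif.logodds_rc())):
                scores = _sliding_scores(codes, mat)
                hits = np.nonzero(scores >= motif.threshold)[0]
                matches = _resolve_overlaps(
                    [(int(i), float(scores[i])) for i in hits], motif.length
                )
                for start, score in matches:
                    sites.append(
                        BindingSite(
                            interval=GenomicInterval(
                                region.chrom,
                                region.start + start,
                                region.start + start + motif.length,
                                strand,
                            ),
                            motif_id=motif.motif_id,
                            match_score=score,
                        )
                    )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.motif_id))
    return sites


class _TrackIndex:
    """Locate the track containing a genomic interval (tracks disjoint)."""

    def __init__(self, tracks: Sequence[CutsiteTrack]):
        self.by_chrom: dict[str, tuple[list[int], list[CutsiteTrack]]] = {}
        for t in sorted(tracks, key=lambda t: (t.region.chrom, t.region.start)):
            starts, lst = self.by_chrom.setdefault(t.region.chrom, ([], []))
            starts.append(t.region.start)
            lst.append(t)

    def find(self, chrom: str, pos: int) -> CutsiteTrack | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, lst = entry
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < lst[i].region.end:
            return lst[i]
        return None


def score_sites(
    sites: Sequence[BindingSite],
    score_tracks: dict[str, Sequence[CutsiteTrack]],
    agg_window: int | None = None,
) -> list[BindingSite]:
    """Fill per-condition site scores: max footprint score over the site
    extended by ``agg_window`` bases each side (default motif length / 2).

    Sites outside every scored region get score 0 and are flagged.
    """
    indexes = {cond: _TrackIndex(tr) for cond, tr in score_tracks.items()}
    for site in sites:
        iv = site.interval
        win = agg_window if agg_window is not None else len(iv) // 2
        found = {
            cond: index.find(iv.chrom, iv.start) for cond, index in indexes.items()
        }
        n_covered = sum(t is not None for t in found.values())
        if 0 < n_covered < len(found):
            missing = [c for c, t in found.items() if t is None]
            raise ValueError(
                f"site {iv.chrom}:{iv.start}-{iv.end} has no score track for "
                f"condition(s) {missing}"
            )
        for cond, track in found.items():
            if track is None:
                site.scores[cond] = 0.0
                site.outside_scored_region = True
                continue
            vals = track.slice_values(iv.start - win, iv.end + win)
            site.scores[cond] = float(vals.max()) if len(vals) else 0.0
    return list(sites)


def normalize_scores(
    sites: Sequence[BindingSite], conditions: Sequence[str]
) -> list[BindingSite]:
    """Full quantile normalization of per-condition score distributions.

    Each condition's sorted scores are mapped onto the mean of the sorted
    scores across conditions; rank ties receive the mean of the reference
    values their ranks span.
    """
    if len(conditions) < 2:
        for site in sites:
            site.norm_scores = dict(site.scores)
        return list(sites)
    if len(sites) < 1000:
        warnings.warn(
            f"quantile normalization over only {len(sites)} sites", stacklevel=2
        )
    mat = np.array([[s.scores[c] for c in conditions] for s in sites])
    n = mat.shape[0]
    reference = np.mean(np.sort(mat, axis=0), axis=1)
    normed = np.empty_like(mat)
    ranks = np.arange(1, n + 1)
    for j in range(mat.shape[1]):
        r = rankdata(mat[:, j], method="average")
        normed[:, j] = np.interp(r, ranks, reference)
    for i, site in enumerate(sites):
        site.norm_scores = {c: float(normed[i, j]) for j, c in enumerate(conditions)}
    return list(sites)


def classify_bound(
    scores: np.ndarray,
    min_sites: int = 50,
    random_state: int = 0,
) -> tuple[np.ndarray, float | None]:
    """Two-component Gaussian mixture bound/unbound split on log(1+score).

    Returns (bound labels, threshold on the original score scale). The
    threshold is the smallest observed score whose posterior probability
    of the higher-mean component is >= 0.5. Degenerate fits (component
    means within 1e-3 or a weight below 0.01) label everything unbound.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite site scores")
    n = len(scores)
    if n < min_sites:
        warnings.warn(f"only {n} sites (<{min_sites}); labelling all unbound", stacklevel=2)
        return np.zeros(n, dtype=bool), None
    x = np.log1p(scores).reshape(-1, 1)
    if np.ptp(x) < 1e-12:
        return np.zeros(n, dtype=bool), None
    gmm = GaussianMixture(
        n_components=2, n_init=3, random_state=random_state, covariance_type="full"
    ).fit(x)
    means = gmm.means_.ravel()
    if abs(means[0] - means[1]) < 1e-3 or gmm.weights_.min() < 0.01:
        return np.zeros(n, dtype=bool), None
    hi = int(np.argmax(means))
    post = gmm.predict_proba(x)[:, hi]
    candidates = scores[post >= 0.5]
    if len(candidates) == 0:
        return np.zeros(n, dtype=bool), None
    threshold = float(candidates.min())
    return scores >= threshold, threshold


def classify_sites(
    sites: Sequence[BindingSite],
    conditions: Sequence[str],
    min_sites: int = 50,
    random_state: int = 0,
) -> dict[tuple[str, str], float | None]:
    """Run the mixture classifier per (motif, condition); fills ``bound``."""
    thresholds: dict[tuple[str, str], float | None] = {}
    by_motif: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_motif.setdefault(s.motif_id, []).append(s)
    for motif_id, motif_sites in by_motif.items():
        for cond in conditions:
            vals = np.array([s.norm_scores[cond] for s in motif_sites])
            labels, thr = classify_bound(vals, min_sites=min_sites, random_state=random_state)
            thresholds[(motif_id, cond)] = thr
            for s, lab in zip(motif_sites, labels):
                s.bound[cond] = bool(lab)
    return thresholds


def site_log2fc(
    site: BindingSite, c1: str, c2: str, pseudocount: float = 1.0
) -> float:
    """Per-site change log2((score_c2 + pc) / (score_c1 + pc))."""
    fc = float(
        np.log2(
            (site.norm_scores[c2] + pseudocount) / (site.norm_scores[c1] + pseudocount)
        )
    )
    site.log2fc[(c1, c2)] = fc
    return fc


def differential_binding(
    sites: Sequence[BindingSite],
    cond_pair: tuple[str, str],
    n_background: int = 100,
    bg_size: int | None = None,
    seed: int = 0,
) -> list[TFDifferential]:
    """Per-motif differential binding versus a subsampled background.

    The raw statistic is the difference of mean normalized scores
    (c2 - c1) over the motif's sites. Its null scale is estimated from
    ``n_background`` random subsamples (size = the motif's site count by
    default) of the union of all sites; the standardized z gets a
    two-sided normal p-value.
    """
    c1, c2 = cond_pair
    rng = np.random.default_rng(seed)
    all_diffs = np.array([s.norm_scores[c2] - s.norm_scores[c1] for s in sites])
    by_motif: dict[str, np.ndarray] = {}
    for i, s in enumerate(sites):
        by_motif.setdefault(s.motif_id, []).append(i)  # type: ignore[arg-type]
    results = []
    for motif_id in sorted(by_motif):
        idx = np.asarray(by_motif[motif_id])
        raw = float(all_diffs[idx].mean())
        size = bg_size if bg_size is not None else len(idx)
        bg = np.array(
            [
                all_diffs[rng.integers(0, len(all_diffs), size=size)].mean()
                for _ in range(n_background)
            ]
        )
        sd = bg.std(ddof=1)
        if sd == 0:
            warnings.warn(f"zero background spread for {motif_id}", stacklevel=2)
            z, p = 0.0, 1.0
        else:
            z = (raw - bg.mean()) / sd
            p = float(2 * stats.norm.sf(abs(z)))
        motif_sites = [sites[i] for i in idx]
        results.append(
            TFDifferential(
                motif_id=motif_id,
                n_sites=len(idx),
                mean_scores={
                    c1: float(np.mean([s.norm_scores[c1] for s in motif_sites])),
                    c2: float(np.mean([s.norm_scores[c2] for s in motif_sites])),
                },
                differential_score=float(z),
                p_value=p,
            )
        )
    return results
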