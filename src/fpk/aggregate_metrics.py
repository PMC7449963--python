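"""Aggregate footprint profiles, footprint depth (FPD), and the
randomized-null test for a "measurable" footprint.

An aggregate profile is the per-offset mean signal over a motif's
binding sites, centered on the motif with ``flank`` bases each side;
minus-strand sites are flipped before averaging so the motif
orientation is shared. FPD is the relative depth of the central motif
window versus the immediately flanking windows. The measurable-footprint
test compares the observed FPD against FPDs of aggregates built from
the same number of random positions within the scored regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bindetect import BindingSite, _TrackIndex
from .core import CutsiteTrack, GenomicInterval

DEFAULT_PROFILE_FLANK = 60
DEFAULT_FPD_FLANK = 20


@dataclass
class AggregateProfile:
    motif_id: str
    condition: str
    n_sites: int
    profile: np.ndarray

    @property
    def width(self) -> int:
        return len(self.profile)


def aggregate(
    sites: Sequence[BindingSite],
    tracks: Sequence[CutsiteTrack],
    flank: int = DEFAULT_PROFILE_FLANK,
    condition: str = "",
) -> AggregateProfile:
    """Mean signal over sites, centered on the motif, strand-flipped.

    Sites whose window [start - flank, end + flank) leaves the containing
    track are skipped; zero usable sites is an error.
    """
    if not sites:
        raise ValueError("no sites to aggregate")
    lengths = {len(s.interval) for s in sites}
    if len(lengths) != 1:
        raise ValueError("all sites must share one motif length")
    motif_len = lengths.pop()
    width = motif_len + 2 * flank
    index = _TrackIndex(tracks)
    rows = []
    for site in sites:
        iv = site.interval
        track = index.find(iv.chrom, iv.start)
        if track is None:
            continue
        lo, hi = iv.start - flank, iv.end + flank
        if lo < track.region.start or hi > track.region.end:
            continue
        vals = track.slice_values(lo, hi)
        if iv.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        raise ValueError("no usable sites (all windows exceed region bounds)")
    profile = np.mean(rows, axis=0)
    motif_id = sites[0].motif_id
    return AggregateProfile(motif_id, condition, len(rows), profile)


def fpd(
    profile: AggregateProfile | np.ndarray,
    motif_len: int,
    flank_for_fpd: int = DEFAULT_FPD_FLANK,
    denominator: float | None = None,
) -> float:
    """Relative footprint depth of an aggregate profile.

    (mean of the two flank windows immediately outside the motif minus
    mean of the central motif window) / flank mean; 0 when the flank mean
    is not positive. Positive = depleted center (footprint), negative =
    enriched center (anti-footprint).

    Mean-zero profiles (corrected signal) have no meaningful flank level
    of their own; pass the *observed* aggregate's flank mean as
    ``denominator`` to keep depths on one comparable scale.
    """
    values = profile.profile if isinstance(profile, AggregateProfile) else np.asarray(profile)
    width = len(values)
    if width < motif_len + 2 * flank_for_fpd:
        raise ValueError("profile narrower than motif plus FPD flanks")
    c0 = (width - motif_len) // 2
    center = values[c0 : c0 + motif_len]
    left = values[c0 - flank_for_fpd : c0]
    right = values[c0 + motif_len : c0 + motif_len + flank_for_fpd]
    flank_mean = float(np.concatenate([left, right]).mean())
    denom = flank_mean if denominator is None else denominator
    if denom <= 0:
        return 0.0
    return float((flank_mean - center.mean()) / denom)


def footprint_depths(
    sites: Sequence[BindingSite],
    bundles: Sequence["BiasTrackBundle"],
    flank: int = DEFAULT_PROFILE_FLANK,
    flank_for_fpd: int = DEFAULT_FPD_FLANK,
) -> dict[str, float]:
    """FPD of the observed, expected and corrected aggregates of one site
    set, all normalized by the observed flank level (comparable scale)."""
    motif_len = len(sites[0].interval)
    kinds = {
        "observed": [b.observed for b in bundles],
        "expected": [b.expected for b in bundles],
        "corrected": [b.corrected for b in bundles],
    }
    obs_profile = aggregate(sites, kinds["observed"], flank=flank)
    width = len(obs_profile.profile)
    c0 = (width - motif_len) // 2
    obs_flank = float(
        np.concatenate(
            [
                obs_profile.profile[c0 - flank_for_fpd : c0],
                obs_profile.profile[c0 + motif_len : c0 + motif_len + flank_for_fpd],
            ]
        ).mean()
    )
    out = {}
    for kind, tracks in kinds.items():
        prof = obs_profile if kind == "observed" else aggregate(sites, tracks, flank=flank)
        out[kind] = fpd(prof, motif_len, flank_for_fpd, denominator=obs_flank)
    return out


def measurable_footprint_test(
    sites: Sequence[BindingSite],
    tracks: Sequence[CutsiteTrack],
    regions: Sequence[GenomicInterval],
    n_null: int = 100,
    seed: int = 0,
    flank: int = DEFAULT_PROFILE_FLANK,
    flank_for_fpd: int = DEFAULT_FPD_FLANK,
) -> tuple[float, float, bool]:
    """Observed FPD versus a null of random same-size site sets.

    Null aggregates are built from positions sampled uniformly within the
    supplied regions (seeded); the footprint is "measurable" when the
    observed FPD exceeds the null's 95th percentile. Returns
    (fpd_obs, null 95th percentile, measurable).
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    motif_len = len(sites[0].interval)
    obs_profile = aggregate(sites, tracks, flank=flank)
    fpd_obs = fpd(obs_profile, motif_len, flank_for_fpd)

    rng = np.random.default_rng(seed)
    margin = flank
    candidates: list[tuple[str, int]] = []
    for r in regions:
        lo, hi = r.start + margin, r.end - margin - motif_len
        candidates.extend((r.chrom, p) for p in range(lo, hi))
    if len(candidates) < len(sites):
        raise ValueError("fewer candidate null positions than sites")
    null_fpds = np.empty(n_null)
    cand_idx = np.arange(len(candidates))
    for i in range(n_null):
        pick = rng.choice(cand_idx, size=obs_profile.n_sites, replace=True)
        null_sites = [
            BindingSite(
                interval=GenomicInterval(
                    candidates[j][0], candidates[j][1], candidates[j][1] + motif_len
                ),
                motif_id="null",
                match_score=0.0,
            )
            for j in pick
        ]
        null_fpds[i] = fpd(aggregate(null_sites, tracks, flank=flank), motif_len, flank_for_fpd)
    q95 = float(np.quantile(null_fpds, 0.95))
    return fpd_obs, q95, bool(fpd_obs > q95)
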