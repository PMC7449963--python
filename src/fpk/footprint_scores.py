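"""Continuous footprint scoring of corrected cutsite tracks.

Two scorers share a windowed geometry: a candidate footprint window of
width w centered at each position, flanked left and right by windows of
``flank_width`` bases.

* The combined footprint score rewards both the depth of the local
  depletion (flank mean minus center mean) and the accessibility of the
  locus (flank mean itself), maximized over candidate widths. Signal is
  floored at ``min_value`` first so that negative corrected values are
  not rewarded twice.
* The footprint occupancy score (FOS) is the classical pure-depletion
  baseline, (C+1)/(L+1) + (C+1)/(R+1) minimized over widths; smaller is
  more bound, so it is emitted negated to share the "higher = more
  bound" convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CutsiteTrack


@dataclass
class ScoreParams:
    fp_widths: tuple[int, ...] = (8, 10, 12, 14, 16, 18, 20)
    flank_width: int = 30
    min_value: float = 0.0

    def __post_init__(self) -> None:
        if any(w < 2 for w in self.fp_widths):
            raise ValueError("footprint widths must be >= 2")
        if self.flank_width < max(self.fp_widths) / 2:
            raise ValueError("flank_width must be >= max(fp_widths)/2")


def _window_means(values: np.ndarray, w: int, flank: int):
    """Center/left/right window means for every position, via cumsums.

    Center window at position p spans [p - w//2, p - w//2 + w); flanks of
    width ``flank`` sit immediately outside it. Positions whose windows
    leave the array are masked out (NaN).
    """
    n = len(values)
    cs = np.concatenate(([0.0], np.cumsum(values)))

    def mean(starts: np.ndarray, width: int) -> np.ndarray:
        out = np.full(n, np.nan)
        ok = (starts >= 0) & (starts + width <= n)
        s = starts[ok]
        out[ok] = (cs[s + width] - cs[s]) / width
        return out

    p = np.arange(n)
    c_start = p - w // 2
    C = mean(c_start, w)
    L = mean(c_start - flank, flank)
    R = mean(c_start + w, flank)
    return C, L, R


def footprint_score(corrected: CutsiteTrack, params: ScoreParams | None = None) -> CutsiteTrack:
    """Combined depletion + accessibility footprint score.

    score(p) = max over widths w of D(p,w) + A(p,w) with
    D = max(0, (L+R)/2 - C) and A = max(0, (L+R)/2); out-of-bounds
    positions score 0.
    """
    params = params or ScoreParams()
    values = np.maximum(corrected.values, params.min_value)
    n = len(values)
    if n < 2 * params.flank_width + max(params.fp_widths):
        warnings.warn(
            f"region {corrected.region.chrom}:{corrected.region.start}-"
            f"{corrected.region.end} too short to score; returning zeros",
            stacklevel=2,
        )
        return CutsiteTrack(corrected.region, np.zeros(n), kind="footprint")
    best = np.zeros(n)
    for w in params.fp_widths:
        C, L, R = _window_means(values, w, params.flank_width)
        flank_mean = (L + R) / 2.0
        score = np.maximum(0.0, flank_mean - C) + np.maximum(0.0, flank_mean)
        best = np.fmax(best, np.nan_to_num(score))
    return CutsiteTrack(corrected.region, best, kind="footprint")


def fos_score(track: CutsiteTrack, params: ScoreParams | None = None) -> CutsiteTrack:
    """Negated footprint occupancy score (pure depletion baseline).

    FOS(p) = min over w of (C+1)/(L+1) + (C+1)/(R+1); emitted as -FOS so
    larger = more bound. Strictly negative flank means (possible when
    min_value < 0) score the worst observed value.
    """
    params = params or ScoreParams()
    values = np.maximum(track.values, params.min_value)
    n = len(values)
    if n < 2 * params.flank_width + max(params.fp_widths):
        warnings.warn("region too short to score; returning zeros", stacklevel=2)
        return CutsiteTrack(track.region, np.zeros(n), kind="footprint")
    worst = np.inf
    best = np.full(n, np.inf)
    for w in params.fp_widths:
        C, L, R = _window_means(values, w, params.flank_width)
        with np.errstate(invalid="ignore", divide="ignore"):
            fos = (C + 1) / (L + 1) + (C + 1) / (R + 1)
        bad = (L < 0) | (R < 0)
        fos[bad] = np.inf
        best = np.fmin(best, fos)
    oob = ~np.isfinite(best)
    finite = best[~oob]
    worst = finite.max() if len(finite) else 0.0
    best[oob] = worst
    return CutsiteTrack(track.region, -best, kind="footprint")
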