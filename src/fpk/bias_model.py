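"""Tn5 sequence-bias estimation and cutsite-track correction.

The Tn5 transposase prefers certain sequence compositions around its
insertion point. That preference is modelled as a dinucleotide weight
matrix (DWM): within a window of ``window`` bases centered on the
insertion point there are ``window - 1`` overlapping ordered
dinucleotides, and the model holds, for each offset, the probability of
each of the 16 dinucleotides at insertion events versus at background
positions. The per-position bias weight is the product over offsets of
the event/background probability ratios (computed in log space).

Correction redistributes each region's total observed cuts proportionally
to the bias weight ("expected" track — what naked-DNA Tn5 alone would
produce) and subtracts it from the observed signal ("corrected" track,
mean-zero per region), leaving protein-driven structure.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import CutEvent, CutsiteTrack, GenomicInterval
from .motifs import encode_sequence

logger = logging.getLogger(__name__)

N_DINUC = 16


@dataclass
class BiasModel:
    """Dinucleotide weight matrix around the Tn5 insertion point."""

    window: int
    dinuc_probs: np.ndarray  # (window-1, 16), rows sum to 1
    background_probs: np.ndarray  # (window-1, 16), rows sum to 1
    pseudocount: float = 1.0
    # Mononucleotide probabilities per window position, (window, 4). The
    # window's joint distribution under nearest-neighbour sequence
    # preference is first-order Markov, whose likelihood is the product of
    # dinucleotide probabilities divided by the mononucleotide
    # probabilities at interior positions; uniform mono matrices reduce
    # the weight to the plain product of dinucleotide ratios.
    mono_probs: np.ndarray | None = None
    background_mono: np.ndarray | None = None
    # Exponent on the log weight, fitted by calibrate_scale().
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.dinuc_probs = np.asarray(self.dinuc_probs, dtype=float)
        self.background_probs = np.asarray(self.background_probs, dtype=float)
        expect = (self.window - 1, N_DINUC)
        if self.dinuc_probs.shape != expect or self.background_probs.shape != expect:
            raise ValueError(f"probability matrices must have shape {expect}")
        if self.mono_probs is None:
            self.mono_probs = np.full((self.window, 4), 0.25)
        if self.background_mono is None:
            self.background_mono = np.full((self.window, 4), 0.25)
        self.mono_probs = np.asarray(self.mono_probs, dtype=float)
        self.background_mono = np.asarray(self.background_mono, dtype=float)
        for mat, label in (
            (self.dinuc_probs, "dinuc"),
            (self.background_probs, "background"),
            (self.mono_probs, "mono"),
            (self.background_mono, "background mono"),
        ):
            if np.any(mat <= 0):
                raise ValueError(f"{label} probabilities must be strictly positive")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{label} probability rows must sum to 1")

    @property
    def log_ratio(self) -> np.ndarray:
        """log(event/background) per (offset, dinucleotide) cell."""
        return np.log(self.dinuc_probs / self.background_probs)

    @property
    def mono_log_ratio(self) -> np.ndarray:
        """log(event/background) mononucleotide ratio per window position."""
        return np.log(self.mono_probs / self.background_mono)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "window": self.window,
                    "pseudocount": self.pseudocount,
                    "scale": self.scale,
                    "dinuc_probs": self.dinuc_probs.tolist(),
                    "background_probs": self.background_probs.tolist(),
                    "mono_probs": self.mono_probs.tolist(),
                    "background_mono": self.background_mono.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "BiasModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            window=d["window"],
            dinuc_probs=np.array(d["dinuc_probs"]),
            background_probs=np.array(d["background_probs"]),
            pseudocount=d.get("pseudocount", 1.0),
            scale=d.get("scale", 1.0),
            mono_probs=np.array(d["mono_probs"]) if "mono_probs" in d else None,
            background_mono=(
                np.array(d["background_mono"]) if "background_mono" in d else None
            ),
        )

    @classmethod
    def identity(cls, window: int = 20) -> "BiasModel":
        flat = np.full((window - 1, N_DINUC), 1.0 / N_DINUC)
        return cls(window=window, dinuc_probs=flat.copy(), background_probs=flat.copy())


@dataclass
class BiasTrackBundle:
    """The four per-region tracks of the correction stage."""

    observed: CutsiteTrack
    bias: CutsiteTrack
    expected: CutsiteTrack
    corrected: CutsiteTrack

    @property
    def region(self) -> GenomicInterval:
        return self.observed.region

    def scoring_track(self) -> CutsiteTrack:
        """Corrected signal with the region's mean coverage restored.

        The corrected track is mean-zero per region; footprint scoring
        needs the accessibility baseline (how open the locus is) as well
        as the bias-free local structure, so the region's mean observed
        coverage is added back.
        """
        baseline = self.observed.values.mean()
        return CutsiteTrack(
            self.region, self.corrected.values + baseline, kind="corrected"
        )


def _dinuc_code_matrix(codes: np.ndarray) -> np.ndarray | None:
    """(n, k) base codes -> (n, k-1) dinucleotide codes; None rows invalid."""
    return 4 * codes[:, :-1] + codes[:, 1:]


def _window_codes(
    chrom_codes: np.ndarray, positions: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (n, window) base codes centered at each position.

    Returns the code matrix and a validity mask (fully on-chromosome and
    free of N). The window spans [pos - window//2, pos + window//2).
    """
    half = window // 2
    starts = positions - half
    ok = (starts >= 0) & (starts + window <= len(chrom_codes))
    idx = starts[ok, None] + np.arange(window)[None, :]
    mat = chrom_codes[idx]
    no_n = ~(mat >= 4).any(axis=1)
    valid = np.zeros(len(positions), dtype=bool)
    valid_idx = np.nonzero(ok)[0][no_n]
    valid[valid_idx] = True
    return mat[no_n], valid


def _count_dinucs(
    code_windows: np.ndarray, minus: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate (window-1, 16) dinucleotide and (window, 4) mononucleotide
    counts over windows.

    ``minus`` marks rows that should be reverse-complemented first
    (events on the minus strand see the opposite orientation of the
    insertion site).
    """
    k = code_windows.shape[1]
    mat = code_windows
    if minus is not None and minus.any():
        mat = mat.copy()
        flipped = 3 - mat[minus][:, ::-1]
        mat[minus] = flipped
    dinucs = _dinuc_code_matrix(mat)
    counts = np.zeros((k - 1, N_DINUC))
    for r in range(k - 1):
        counts[r] = np.bincount(dinucs[:, r], minlength=N_DINUC)
    mono = np.zeros((k, 4))
    for i in range(k):
        mono[i] = np.bincount(mat[:, i], minlength=4)
    return counts, mono


def estimate_bias(
    events: Sequence[CutEvent],
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
    window: int = 20,
    pseudocount: float = 1.0,
    stranded: bool = True,
    bg_sample: int | None = None,
    seed: int = 0,
) -> BiasModel:
    """Estimate the Tn5 DWM from observed cut events.

    Event windows are counted per dinucleotide offset (minus-strand events
    reverse-complemented when ``stranded``); the background matrix is built
    identically from every position of the supplied regions (or a seeded
    uniform subsample of ``bg_sample`` positions).
    """
    if window < 4 or window % 2:
        raise ValueError("window must be even and >= 4")
    codes = {c: encode_sequence(s) for c, s in genome.items()}

    # Vectorized region-membership filter (regions sorted per chromosome).
    reg_bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for r in regions:
        reg_bounds.setdefault(r.chrom, ([], []))  # type: ignore[arg-type]
    for chrom in reg_bounds:
        rs = sorted((r.start, r.end) for r in regions if r.chrom == chrom)
        reg_bounds[chrom] = (
            np.array([s for s, _ in rs]),
            np.array([e for _, e in rs]),
        )
    region_events: list[CutEvent] = []
    ev_by_chrom: dict[str, list[CutEvent]] = {}
    for ev in events:
        ev_by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in ev_by_chrom.items():
        if chrom not in reg_bounds:
            continue
        starts, ends = reg_bounds[chrom]
        pos = np.array([e.pos for e in evs])
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        region_events.extend(ev for ev, keep in zip(evs, inside) if keep)
    if not region_events:
        raise ValueError("no events fall within the supplied regions")
    if len(region_events) < 1000:
        warnings.warn(
            f"only {len(region_events)} events in regions; bias estimate may be noisy",
            stacklevel=2,
        )

    event_counts = np.zeros((window - 1, N_DINUC))
    event_mono = np.zeros((window, 4))
    by_chrom: dict[str, list[CutEvent]] = {}
    for ev in region_events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        positions = np.array([e.pos for e in evs])
        strands = np.array([e.strand == "-" for e in evs])
        wins, valid = _window_codes(codes[chrom], positions, window)
        minus = strands[valid] if stranded else None
        di, mo = _count_dinucs(wins, minus)
        event_counts += di
        event_mono += mo

    bg_counts = np.zeros((window - 1, N_DINUC))
    bg_positions: list[tuple[str, np.ndarray]] = [
        (r.chrom, np.arange(r.start, r.end)) for r in regions
    ]
    if bg_sample is not None:
        rng = np.random.default_rng(seed)
        flat = np.concatenate(
            [np.stack([np.full(len(p), i), p]) for i, (_, p) in enumerate(bg_positions)],
            axis=1,
        )
        take = rng.choice(flat.shape[1], size=min(bg_sample, flat.shape[1]), replace=False)
        take.sort()
        chroms = [c for c, _ in bg_positions]
        bg_positions = [
            (chroms[i], flat[1, take[flat[0, take] == i]])
            for i in range(len(chroms))
        ]
    bg_mono = np.zeros((window, 4))
    for chrom, positions in bg_positions:
        if len(positions) == 0:
            continue
        wins, _ = _window_codes(codes[chrom], np.asarray(positions), window)
        if len(wins):
            di, mo = _count_dinucs(wins)
            bg_counts += di
            bg_mono += mo

    def normalize(counts: np.ndarray) -> np.ndarray:
        c = counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    return BiasModel(
        window=window,
        dinuc_probs=normalize(event_counts),
        background_probs=normalize(bg_counts),
        mono_probs=normalize(event_mono),
        background_mono=normalize(bg_mono),
        pseudocount=pseudocount,
    )


def score_sequence_bias(
    model: BiasModel, genome: dict[str, str], region: GenomicInterval
) -> CutsiteTrack:
    """Per-position Tn5 bias weight over a region (kind="bias").

    The weight is the first-order Markov likelihood ratio of the window
    centered at pos: the product over offsets of dinucleotide
    event/background ratios, divided by the mononucleotide ratios at
    interior window positions (computed in log space, raised to the
    calibrated ``scale``). With uniform mono matrices this reduces to the
    plain product of dinucleotide ratios. Windows off the chromosome edge
    or containing N get weight 1 (background).
    """
    codes = encode_sequence(genome[region.chrom])
    positions = np.arange(region.start, region.end)
    wins, valid = _window_codes(codes, positions, model.window)
    weights = np.ones(len(positions))
    if len(wins):
        dinucs = _dinuc_code_matrix(wins)
        logr = model.log_ratio
        logw = logr[np.arange(model.window - 1)[None, :], dinucs].sum(axis=1)
        mono_lr = model.mono_log_ratio
        interior = np.arange(1, model.window - 1)
        logw -= mono_lr[interior[None, :], wins[:, 1:-1]].sum(axis=1)
        weights[valid] = np.exp(model.scale * logw)
    return CutsiteTrack(region, weights, kind="bias")


def calibrate_scale(
    model: BiasModel,
    observed_tracks: Sequence[CutsiteTrack],
    genome: dict[str, str],
    bounds: tuple[float, float] = (0.0, 3.0),
) -> float:
    """Fit the weight-scale exponent by multinomial maximum likelihood.

    Within each region, observed counts given the region total are
    multinomial with p proportional to exp(scale * log-weight); the
    per-offset marginal ratios the DWM is estimated from are not
    independent (offsets overlap), so their raw product misstates the
    dynamic range and the likelihood picks the exponent that matches it
    to the data. Returns the fitted scale and stores it on the model.
    """
    from scipy.optimize import minimize_scalar

    base = model.scale
    model.scale = 1.0
    per_region = []
    for t in observed_tracks:
        logw = np.log(score_sequence_bias(model, genome, t.region).values)
        if t.values.sum() > 0:
            per_region.append((t.values, logw))
    model.scale = base
    if not per_region:
        raise ValueError("no observed counts to calibrate against")

    def nll(gamma: float) -> float:
        total = 0.0
        for counts, logw in per_region:
            g = gamma * logw
            g -= g.max()
            total -= float(counts @ g) - counts.sum() * np.log(np.exp(g).sum())
        return total

    res = minimize_scalar(nll, bounds=bounds, method="bounded")
    model.scale = float(res.x)
    return model.scale


def expected_track(observed: CutsiteTrack, bias: CutsiteTrack) -> CutsiteTrack:
    """Redistribute the region's observed cut total proportionally to bias."""
    if observed.region != bias.region:
        raise ValueError("observed and bias tracks must share a region")
    total = observed.values.sum()
    if total == 0:
        return CutsiteTrack(observed.region, np.zeros(len(observed)), kind="expected")
    w = bias.values
    if np.any(w <= 0):
        raise ValueError("bias weights must be strictly positive")
    return CutsiteTrack(observed.region, w / w.sum() * total, kind="expected")


def correct_track(
    observed: CutsiteTrack, expected: CutsiteTrack, smooth_w: int = 1
) -> CutsiteTrack:
    """Observed minus expected, optionally after a sliding-mean smooth."""
    if observed.region != expected.region:
        raise ValueError("observed and expected tracks must share a region")
    obs, exp = observed.values, expected.values
    if smooth_w > 1:
        obs = uniform_filter1d(obs, smooth_w, mode="nearest")
        exp = uniform_filter1d(exp, smooth_w, mode="nearest")
    return CutsiteTrack(observed.region, obs - exp, kind="corrected")


def correct_regions(
    events: Iterable[CutEvent] | Sequence[CutsiteTrack],
    genome: dict[str, str],
    regions: Sequence[GenomicInterval],
    model: BiasModel | None = None,
    window: int = 20,
    smooth_w: int = 1,
    seed: int = 0,
) -> tuple[BiasModel, list[BiasTrackBundle]]:
    """Full correction stage: estimate bias (unless given) and build the
    observed/bias/expected/corrected bundle for every region."""
    from .formats_io import pileup

    if events and isinstance(next(iter(events)), CutsiteTrack):
        observed_tracks = list(events)  # pre-piled tracks
        event_list: list[CutEvent] = []
        for t in observed_tracks:
            for off, n in enumerate(t.values):
                event_list.extend(
                    [CutEvent(t.region.chrom, t.region.start + off)] * int(n)
                )
    else:
        event_list = list(events)
        observed_tracks = pileup(event_list, regions)
    if model is None:
        model = estimate_bias(event_list, genome, regions, window=window, seed=seed)
        calibrate_scale(model, observed_tracks, genome)
    bundles = []
    for obs in observed_tracks:
        bias = score_sequence_bias(model, genome, obs.region)
        exp = expected_track(obs, bias)
        corr = correct_track(obs, exp, smooth_w=smooth_w)
        bundles.append(BiasTrackBundle(obs, bias, exp, corr))
    return model, bundles
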