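"""Transcription-factor motif models.

A motif is carried as a position frequency matrix (PFM) of base counts,
from which a log2-odds scoring matrix is derived against a background base
composition. The match threshold corresponds to a motif-score p-value
(default 1e-4) under the background, computed by exact dynamic-programming
convolution of the discretized per-column score distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

DEFAULT_MATCH_PVALUE = 1e-4
_DP_GRANULARITY = 1e-3


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A=0,C=1,G=2,T=3, anything else=4)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    valid = out < 4
    out[valid] = COMPLEMENT[out[valid]]
    return out


def score_pvalue_threshold(
    logodds: np.ndarray,
    bg_freq: np.ndarray,
    pvalue: float = DEFAULT_MATCH_PVALUE,
    granularity: float = _DP_GRANULARITY,
) -> float:
    """Smallest score s with P(score >= s | background) <= pvalue.

    Exact DP over discretized scores: per-column score distributions are
    convolved on an integer grid of bin width `granularity`. The returned
    threshold is conservative by at most one bin.
    """
    q = np.rint(logodds / granularity).astype(np.int64)  # 4 x L
    # Convolve column distributions, tracking the reachable score range.
    cur_lo = 0
    cur = np.array([1.0])
    for col in range(q.shape[1]):
        col_scores = q[:, col]
        new_lo = cur_lo + int(col_scores.min())
        new_hi = cur_lo + len(cur) - 1 + int(col_scores.max())
        new = np.zeros(new_hi - new_lo + 1)
        for base in range(4):
            shift = int(col_scores[base]) - new_lo + cur_lo
            new[shift : shift + len(cur)] += bg_freq[base] * cur
        cur, cur_lo = new, new_lo
    # Survival function over the discretized score grid.
    tail = np.cumsum(cur[::-1])[::-1]
    above = np.nonzero(tail <= pvalue)[0]
    if len(above) == 0:
        idx = len(cur) - 1  # p-value unreachable for short motifs; use max
    else:
        idx = above[0]
    # Per-column rounding can shift true scores by up to granularity/2 each;
    # back the threshold off by the worst case so no qualifying site is lost.
    return (cur_lo + idx) * granularity - 0.5 * granularity * logodds.shape[1]


@dataclass
class MotifModel:
    """PFM-backed motif with derived log-odds matrix and match threshold."""

    motif_id: str
    name: str
    pfm: np.ndarray  # 4 x L counts, rows A/C/G/T
    bg_freq: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0
    match_pvalue: float = DEFAULT_MATCH_PVALUE
    logodds: np.ndarray = field(init=False)
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        if np.any(self.pfm < 0):
            raise ValueError("PFM counts must be non-negative")
        if self.length < 4:
            warnings.warn(
                f"motif {self.motif_id} is shorter than 4 bp", stacklevel=2
            )
        self.bg_freq = np.asarray(self.bg_freq, dtype=float)
        probs = (self.pfm + self.pseudocount) / (
            self.pfm.sum(axis=0) + 4 * self.pseudocount
        )
        self.logodds = np.log2(probs / self.bg_freq[:, None])
        self.threshold = score_pvalue_threshold(
            self.logodds, self.bg_freq, self.match_pvalue
        )

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=0))

    def logodds_rc(self) -> np.ndarray:
        """Log-odds matrix for scanning the reverse strand on forward codes."""
        return self.logodds[::-1, ::-1]

    @classmethod
    def from_consensus(
        cls, motif_id: str, consensus: str, counts: float = 100.0, **kwargs
    ) -> "MotifModel":
        """Degenerate PFM putting all counts on the consensus base."""
        pfm = np.zeros((4, len(consensus)))
        for j, b in enumerate(consensus.upper()):
            pfm[BASE_INDEX[b], j] = counts
        return cls(motif_id, motif_id, pfm, **kwargs)
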