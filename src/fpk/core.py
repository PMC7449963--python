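"""Core genomic containers shared across the footprinting pipeline.

Coordinates are 0-based half-open throughout (BED convention). A cut event
is the single base at which the Tn5 transposase inserted, derived from a
fragment end with a strand-specific shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class CutEvent(NamedTuple):
    """A single Tn5 insertion event at one genomic base."""

    chrom: str
    pos: int
    strand: str = "+"


TRACK_KINDS = {"observed", "expected", "corrected", "footprint", "bias"}


@dataclass
class CutsiteTrack:
    """Per-base signal over one region.

    kind "observed" holds integer cut counts; "expected" the bias-predicted
    background; "corrected" observed minus expected (sums to ~0 per region);
    "footprint" a continuous footprint score; "bias" raw sequence-bias weights.
    """

    region: GenomicInterval
    values: np.ndarray
    kind: str = "observed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region),):
            raise ValueError(
                f"track length {self.values.shape} does not match region "
                f"length {len(self.region)}"
            )
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.region)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def slice_values(self, start: int, end: int) -> np.ndarray:
        """Values over genomic [start, end), clipped to the region."""
        lo = max(start, self.region.start) - self.region.start
        hi = min(end, self.region.end) - self.region.start
        if hi <= lo:
            return np.empty(0)
        return self.values[lo:hi]


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals (strand-agnostic)."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intervals_overlap(intervals: Iterable[GenomicInterval]) -> bool:
    """True if any two intervals in the collection overlap."""
    srt = sort_intervals(intervals)
    for a, b in zip(srt, srt[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            return True
    return False
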