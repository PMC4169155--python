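"""Closed 1-based genomic intervals: subtraction and gene overlap.

Overlapping-deletion refinement: when a deletion fails to complement but an
overlapping deletion complements, the overlap cannot contain the causal
alleles and is subtracted from the candidate region.  Interval arithmetic is
closed-inclusive; lengths are end − start + 1 base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def to_bed(self) -> tuple[str, int, int]:
        """0-based half-open BED coordinates."""
        return self.chrom, self.start - 1, self.end


def refine_interval(
    focal: GenomicInterval, complementing_overlaps: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Subtract complementing overlaps from the focal interval.

    Returns the ordered residual intervals; empty (with a warning) when the
    overlaps cover the focal interval entirely.
    """
    segments = [(focal.start, focal.end)]
    for ov in complementing_overlaps:
        if ov.chrom != focal.chrom:
            raise ValueError("intervals must be on the same chromosome")
        new_segments = []
        for s, e in segments:
            if ov.end < s or ov.start > e:
                new_segments.append((s, e))
                continue
            if ov.start > s:
                new_segments.append((s, ov.start - 1))
            if ov.end < e:
                new_segments.append((ov.end + 1, e))
        segments = new_segments
    if not segments:
        warnings.warn(f"overlaps fully cover {focal.label or 'focal interval'}")
    return [
        GenomicInterval(focal.chrom, s, e, label=f"{focal.label}.{k}" if focal.label else "")
        for k, (s, e) in enumerate(sorted(segments))
    ]


def genes_in_interval(interval: GenomicInterval, annotation: pd.DataFrame) -> list[str]:
    """Genes overlapping the interval by >= 1 bp, sorted by start.

    ``annotation`` needs columns chrom, start, end, name with 1-based
    inclusive spans.
    """
    hits = annotation[
        (annotation["chrom"] == interval.chrom)
        & (annotation["start"] <= interval.end)
        & (annotation["end"] >= interval.start)
    ]
    return list(hits.sort_values("start")["name"])
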