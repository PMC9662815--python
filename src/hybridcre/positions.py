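"""Positional variant enrichment relative to summits or motif anchors.

Offsets follow the closest-nucleotide rule: for a variant whose affected
span intersects the anchor, the offset is 0; otherwise it is the signed
distance from the anchor to the nearest affected base.  The in/out
contrast is a Pearson chi-squared on the 2x2 table of variant events
inside vs outside a central window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from hybridcre.catalog import GenomeVariant
from hybridcre.motifs import MotifMatch

__all__ = [
    "PositionHistogram",
    "variant_offsets",
    "offset_histogram",
    "offset_histogram_compare",
    "pearson_chi2_2x2",
    "motif_anchored_offsets",
    "distance_to_nearest",
]


@dataclass
class PositionHistogram:
    anchor_kind: str  # {"summit", "motif"}
    halfwidth: int
    counts: dict = field(default_factory=dict)  # offset -> count
    n_regions: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def offsets(self) -> list[int]:
        return [off for off, c in sorted(self.counts.items()) for _ in range(c)]


def _variant_offset(anchor: int, variant: GenomeVariant) -> int:
    """Signed offset of the variant nucleotide nearest the anchor."""
    if variant.start <= anchor < variant.end:
        return 0
    if variant.start > anchor:
        return variant.start - anchor
    return variant.end - 1 - anchor


def variant_offsets(
    regions: Iterable[tuple[str, str, int]],
    variants: Sequence[GenomeVariant],
    halfwidth: int = 200,
) -> list[int]:
    """Offsets of variants within +/-halfwidth of each region's anchor.

    ``regions`` yields (region_id, chrom, anchor) triples; one event per
    (region, variant) pair.
    """
    by_chrom: dict[str, list[GenomeVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    offsets: list[int] = []
    for _rid, chrom, anchor in regions:
        for v in by_chrom.get(chrom, []):
            off = _variant_offset(anchor, v)
            if -halfwidth <= off <= halfwidth:
                offsets.append(off)
    return offsets


def offset_histogram(
    offsets: Sequence[int], halfwidth: int, anchor_kind: str = "summit", n_regions: int = 0
) -> PositionHistogram:
    hist = PositionHistogram(anchor_kind=anchor_kind, halfwidth=halfwidth, n_regions=n_regions)
    for off in offsets:
        if -halfwidth <= off <= halfwidth:
            hist.counts[off] = hist.counts.get(off, 0) + 1
    return hist


def pearson_chi2_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a 2x2 table."""
    (a, b), (c, d) = table
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0, 1.0
    statistic = n * (a * d - b * c) ** 2 / margins
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def offset_histogram_compare(
    as_hist: PositionHistogram,
    shared_hist: PositionHistogram,
    central_halfwidth: int = 50,
) -> tuple[float, float, np.ndarray]:
    """Chi-squared contrast of central-window occupancy between two groups.

    Builds the 2x2 table [group x (|offset| <= central_halfwidth vs the
    remainder of the window)] and applies Pearson's chi-squared with 1 df
    and no continuity correction.  Warns when any expected cell count is
    below 5.
    """
    if as_hist.halfwidth != shared_hist.halfwidth:
        raise ValueError("histograms must cover the same window")

    def _split(hist: PositionHistogram) -> tuple[int, int]:
        inside = sum(c for off, c in hist.counts.items() if abs(off) <= central_halfwidth)
        return inside, hist.total - inside

    table = np.array([_split(as_hist), _split(shared_hist)], dtype=float)
    statistic, p = pearson_chi2_2x2(table)
    n = table.sum()
    if n > 0:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        if (expected < 5).any():
            warnings.warn("expected cell count < 5 in chi-squared table", stacklevel=2)
    return statistic, p, table


def motif_anchored_offsets(
    peaks: Iterable[tuple[str, MotifMatch, Sequence[GenomeVariant]]],
    halfwidth: int = 200,
) -> list[int]:
    """Variant offsets relative to a shared motif, strand-oriented.

    ``peaks`` yields (peak_id, motif match, variants near the peak).
    Peaks with any variant overlapping the motif span are excluded
    entirely.  Offsets are measured from the motif midpoint (central
    base for odd lengths, left-of-center for even) and signed so that
    positive lies 3' of the motif on its own strand.
    """
    offsets: list[int] = []
    for _pid, match, variants in peaks:
        if any(v.start < match.end and match.start < v.end for v in variants):
            continue
        midpoint = match.start + (match.end - match.start - 1) // 2
        for v in variants:
            off = _variant_offset(midpoint, v)
            if match.strand == "-":
                off = -off
            if -halfwidth <= off <= halfwidth:
                offsets.append(off)
    return offsets


def distance_to_nearest(
    features_a: Sequence[tuple[str, int, int]],
    features_b: Sequence[tuple[str, int, int]],
    exclude_self: bool = False,
) -> list[float]:
    """Closest-edge gap from each a-interval to the nearest b-interval.

    Overlapping intervals have distance 0; chromosomes with no b
    feature yield inf.  With ``exclude_self`` an identical interval in b
    is ignored once (for self-comparisons of the same feature set).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in features_b:
        by_chrom.setdefault(chrom, []).append((start, end))
    for intervals in by_chrom.values():
        intervals.sort()

    out: list[float] = []
    for chrom, start, end in features_a:
        intervals = by_chrom.get(chrom, [])
        best = math.inf
        skipped_self = False
        for s, e in intervals:
            if exclude_self and not skipped_self and (s, e) == (start, end):
                skipped_self = True
                continue
            best = min(best, _gap(start, end, s, e))
        out.append(best)
    return out


def _gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    if start_a < end_b and start_b < end_a:
        return 0
    if start_b >= end_a:
        return start_b - end_a
    return start_a - end_b
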