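"""Binned aggregate signal profiles around anchors, split by allele class.

Profiles cover a symmetric window (default +/-1000 bp) in fixed-width
bins (default 10 bp); bin edges are half-open, [-1000, -990), ...,
[990, 1000), so events at exactly +window are excluded.  Per-group
values are simple means over regions (no library-size scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from hybridcre.motifs import scan_kmer

__all__ = ["AggregateProfile", "select_single_motif_pairs", "binned_profile"]


@dataclass
class AggregateProfile:
    window: int
    binsize: int
    bin_starts: np.ndarray
    means: dict = field(default_factory=dict)  # group -> per-bin mean signal
    n: dict = field(default_factory=dict)  # group -> number of regions

    @property
    def n_bins(self) -> int:
        return 2 * self.window // self.binsize


def select_single_motif_pairs(
    peaks: Iterable[tuple[str, str, str]],
    pattern: str,
    halfwidth: int = 75,
    summit: int | None = None,
) -> list[tuple[str, str]]:
    """Peaks with exactly one motif instance on one allele only.

    ``peaks`` yields (peak_id, maternal_seq, paternal_seq); the summit
    defaults to the sequence midpoint.  Retained are peaks where the
    union of alleles carries exactly one motif instance within
    +/-halfwidth of the summit, present on a single allele (i.e. the
    other allele's copy is variant-disrupted) and with no shared intact
    instance.  Returns (peak_id, intact_allele) pairs.
    """
    selected: list[tuple[str, str]] = []
    for peak_id, m_seq, p_seq in peaks:
        m_matches = _matches_near(m_seq, pattern, halfwidth, summit)
        p_matches = _matches_near(p_seq, pattern, halfwidth, summit)
        if len(m_matches) == 1 and len(p_matches) == 0:
            selected.append((peak_id, "maternal"))
        elif len(m_matches) == 0 and len(p_matches) == 1:
            selected.append((peak_id, "paternal"))
        # >=1 on both alleles implies a shared site; 0/0 or multi-site: excluded
    return selected


def _matches_near(seq: str, pattern: str, halfwidth: int, summit: int | None) -> list:
    anchor = len(seq) // 2 if summit is None else summit
    lo, hi = anchor - halfwidth, anchor + halfwidth + 1
    return [m for m in scan_kmer(seq, pattern) if m.start < hi and lo < m.end]


def binned_profile(
    signal_events: Sequence[tuple[str, int, float]],
    anchors: Sequence[tuple[str, int, str]],
    window: int = 1000,
    binsize: int = 10,
) -> AggregateProfile:
    """Mean binned signal around anchors, per group.

    ``signal_events`` are (chrom, position, weight); ``anchors`` are
    (chrom, anchor_position, group).  For each anchored region, event
    weights falling in [anchor - window, anchor + window) are summed per
    bin; per-group profiles are means over that group's regions.  Empty
    groups are dropped with a warning.
    """
    if window % binsize != 0:
        raise ValueError("window must be a multiple of binsize")
    n_bins = 2 * window // binsize
    events_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, weight in signal_events:
        tmp.setdefault(chrom, []).append((pos, weight))
    for chrom, items in tmp.items():
        positions = np.array([p for p, _ in items])
        weights = np.array([w for _, w in items], dtype=float)
        events_by_chrom[chrom] = (positions, weights)

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    groups_seen: list[str] = []
    for chrom, anchor, group in anchors:
        if group not in sums:
            sums[group] = np.zeros(n_bins)
            counts[group] = 0
            groups_seen.append(group)
        counts[group] += 1
        if chrom not in events_by_chrom:
            continue
        positions, weights = events_by_chrom[chrom]
        rel = positions - anchor
        mask = (rel >= -window) & (rel < window)
        if not mask.any():
            continue
        bins = (rel[mask] + window) // binsize
        sums[group] += np.bincount(bins.astype(int), weights=weights[mask], minlength=n_bins)

    profile = AggregateProfile(
        window=window,
        binsize=binsize,
        bin_starts=np.arange(-window, window, binsize),
    )
    for group in groups_seen:
        if counts[group] == 0:
            warnings.warn(f"profile group {group!r} is empty; dropped", stacklevel=2)
            continue
        profile.means[group] = sums[group] / counts[group]
        profile.n[group] = counts[group]
    return profile
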