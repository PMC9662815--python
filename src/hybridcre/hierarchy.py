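"""AP-1/TEAD co-binding structure.

Co-binding classes by summit proximity, motif-mutation enrichment at
allele-specific vs shared peaks (Fisher exact), partner-loss fractions,
and per-class k-mer presence fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from hybridcre.motifs import scan_kmer

__all__ = [
    "CobindTable",
    "EnrichmentResult",
    "classify_cobinding",
    "mutation_enrichment",
    "fisher_exact_two_sided",
    "partner_loss_fraction",
    "kmer_presence_fraction",
]


@dataclass
class CobindTable:
    """Per-locus co-binding classes and their counts."""

    assignments: dict = field(default_factory=dict)  # peak id -> class
    counts: dict = field(default_factory=dict)  # class -> count
    pairs: list = field(default_factory=list)  # (fos id, tead id) matched pairs

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def classify_cobinding(
    fos_peaks: Sequence[tuple[str, str, int]],
    tead_peaks: Sequence[tuple[str, str, int]],
    max_summit_distance: int = 100,
) -> CobindTable:
    """Assign AP1_only / TEAD_only / cobound classes by summit proximity.

    Peaks are (id, chrom, summit) triples.  A Fos and a Tead peak within
    ``max_summit_distance`` on the same chromosome are paired greedily by
    increasing distance (ties to smaller coordinates); each peak joins
    exactly one class.
    """
    candidates = []
    for fid, fchrom, fsummit in fos_peaks:
        for tid, tchrom, tsummit in tead_peaks:
            if fchrom != tchrom:
                continue
            dist = abs(fsummit - tsummit)
            if dist <= max_summit_distance:
                candidates.append((dist, fsummit, tsummit, fid, tid))
    candidates.sort()

    table = CobindTable()
    paired_fos: set[str] = set()
    paired_tead: set[str] = set()
    for _dist, _fs, _ts, fid, tid in candidates:
        if fid in paired_fos or tid in paired_tead:
            continue
        paired_fos.add(fid)
        paired_tead.add(tid)
        table.pairs.append((fid, tid))

    for fid, _c, _s in fos_peaks:
        table.assignments[fid] = "cobound" if fid in paired_fos else "AP1_only"
    for tid, _c, _s in tead_peaks:
        if tid in paired_tead:
            table.assignments[tid] = "cobound"
        else:
            table.assignments[tid] = "TEAD_only"
    table.counts = {
        "AP1_only": sum(1 for fid, _c, _s in fos_peaks if fid not in paired_fos),
        "TEAD_only": sum(1 for tid, _c, _s in tead_peaks if tid not in paired_tead),
        "cobound": len(table.pairs),
    }
    return table


@dataclass
class EnrichmentResult:
    table: np.ndarray  # rows: [allele_specific, shared]; cols: [with feature, without]
    fraction_as: float
    fraction_shared: float
    odds_ratio: float
    p: float


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins)
    whose probability does not exceed the observed one (R convention);
    a small relative tolerance guards against float round-off.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = rv.pmf(support)
    observed = rv.pmf(a)
    return float(min(1.0, probs[probs <= observed * (1 + 1e-7)].sum()))


def mutation_enrichment(
    as_has_feature: Iterable[bool],
    shared_has_feature: Iterable[bool],
) -> EnrichmentResult:
    """Enrichment of a motif feature in allele-specific vs shared peaks.

    Inputs are per-peak flags (e.g. "has a strain-specific k-mer within
    75 bp of the summit") for the two groups.
    """
    as_flags = np.fromiter((bool(x) for x in as_has_feature), dtype=bool)
    shared_flags = np.fromiter((bool(x) for x in shared_has_feature), dtype=bool)
    if as_flags.size == 0 or shared_flags.size == 0:
        raise ValueError("both groups must be nonempty")
    a, b = int(as_flags.sum()), int((~as_flags).sum())
    c, d = int(shared_flags.sum()), int((~shared_flags).sum())
    table = np.array([[a, b], [c, d]])
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return EnrichmentResult(
        table=table,
        fraction_as=a / (a + b),
        fraction_shared=c / (c + d),
        odds_ratio=float(odds),
        p=fisher_exact_two_sided(table),
    )


def partner_loss_fraction(n_joint: int, n_reference: int) -> float:
    """Percentage of reference peaks showing a concordant partner loss.

    100 * n_joint / n_reference, reported to one decimal.
    """
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not 0 <= n_joint <= n_reference:
        raise ValueError("n_joint must lie in [0, n_reference]")
    return round(100.0 * n_joint / n_reference, 1)


def kmer_presence_fraction(
    peak_class_sets: Mapping[str, Sequence[tuple[str, int]]],
    patterns: Sequence[str],
    halfwidth: int = 50,
) -> dict[str, float]:
    """Per-class fraction of peaks with >=1 k-mer match near the summit.

    ``peak_class_sets`` maps class name -> list of (sequence, summit);
    a peak counts when any listed pattern matches with its span
    intersecting the inclusive +/-halfwidth summit window.
    """
    fractions: dict[str, float] = {}
    for klass, members in peak_class_sets.items():
        if not members:
            fractions[klass] = float("nan")
            continue
        hits = 0
        for seq, summit in members:
            lo, hi = summit - halfwidth, summit + halfwidth + 1
            if any(
                m.start < hi and lo < m.end
                for pattern in patterns
                for m in scan_kmer(seq, pattern)
            ):
                hits += 1
        fractions[klass] = hits / len(members)
    return fractions
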