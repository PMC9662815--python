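"""Catalog of analyzable CRE allele pairs.

Builds the filtered set of summit-centered peaks that enter
allele-specific analysis: mappability (informative variant near the
summit), 1-kb summit deduplication, a per-group signal floor, and
exclusion of imprinted regions.

All coordinates are 0-based half-open internally; VCF conversion
happens at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "GenomeVariant",
    "CrePeak",
    "CatalogConfig",
    "make_window",
    "count_variants",
    "classify_mappable",
    "dedup_summits",
    "apply_signal_floor",
    "exclude_imprinted",
    "classify_peak",
    "build_catalog",
    "spans_overlap",
]


def spans_overlap(start_a: int, end_a: int, start_b: int, end_b: int) -> bool:
    """True iff half-open spans [start_a, end_a) and [start_b, end_b) intersect."""
    return start_a < end_b and start_b < end_a


@dataclass(frozen=True)
class GenomeVariant:
    """One SNP or indel distinguishing the maternal and paternal alleles.

    ``start``/``end`` delimit the affected *reference* span (half-open):
    a single base for SNPs, the anchor base for insertions, and all
    deleted bases for deletions.  ``ref``/``alt`` hold the VCF-style
    allele strings (left-anchored for indels).
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    kind: str  # {"snp", "insertion", "deletion"}

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"variant at {self.chrom}:{self.start} has ref == alt")
        if not self.start < self.end:
            raise ValueError(f"variant at {self.chrom}:{self.start} has start >= end")
        expected = _infer_kind(self.ref, self.alt)
        if self.kind != expected:
            raise ValueError(
                f"variant kind {self.kind!r} inconsistent with ref={self.ref!r} "
                f"alt={self.alt!r} (expected {expected!r})"
            )

    @classmethod
    def from_vcf_fields(cls, chrom: str, pos_1based: int, ref: str, alt: str) -> "GenomeVariant":
        """Build a variant from VCF CHROM/POS/REF/ALT fields.

        SNP POS=100 REF=A ALT=G -> span [99, 100).  Deletion POS=100
        REF=ACGT ALT=A -> span [100, 103) (the deleted bases).
        Insertion POS=100 REF=A ALT=ACG -> span [99, 100) (anchor base).
        """
        kind = _infer_kind(ref, alt)
        pos0 = pos_1based - 1
        if kind == "deletion":
            start, end = pos0 + len(alt), pos0 + len(ref)
        else:
            start, end = pos0, pos0 + 1
        return cls(chrom=chrom, start=start, end=end, ref=ref, alt=alt, kind=kind)

    def to_vcf_fields(self) -> tuple[str, int, str, str]:
        """Inverse of :meth:`from_vcf_fields` (CHROM, 1-based POS, REF, ALT)."""
        if self.kind == "deletion":
            pos0 = self.start - len(self.alt)
        else:
            pos0 = self.start
        return self.chrom, pos0 + 1, self.ref, self.alt


def _infer_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "snp"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


@dataclass
class CrePeak:
    """A summit-centered CRE allele pair.

    ``counts`` maps assay -> allele ("maternal"/"paternal") -> list of
    per-replicate integer counts.
    """

    id: str
    chrom: str
    summit: int
    pooled_signal: float = 0.0
    counts: dict = field(default_factory=dict)
    n_variants_150: int | None = None
    mappable: bool | None = None
    active: bool | None = None
    locale: str | None = None  # {"proximal", "distal"}
    group: Hashable = None  # condition / line grouping for the signal floor


@dataclass
class CatalogConfig:
    mappability_halfwidth: int = 60
    central_width: int = 150
    dedup_distance: int = 1000
    quintile_floor: float = 0.2
    imprint_margin: int = 100_000
    proximal_threshold: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "mappability_halfwidth",
            "central_width",
            "dedup_distance",
            "imprint_margin",
            "proximal_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"CatalogConfig.{name} must be positive")
        if not 0 < self.quintile_floor < 1:
            raise ValueError("CatalogConfig.quintile_floor must be in (0, 1)")


def make_window(summit: int, half_width: int) -> tuple[int, int]:
    """Inclusive +/-half_width window around the summit base, clipped at 0.

    Returns the half-open interval [summit - w, summit + w + 1); width is
    2w+1 except when clipped at the chromosome start.
    """
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")
    if summit < 0:
        raise ValueError("summit must be nonnegative")
    return max(0, summit - half_width), summit + half_width + 1


def count_variants(window: tuple[int, int], variants: Iterable[GenomeVariant]) -> int:
    """Number of variants whose affected span intersects the window."""
    start, end = window
    return sum(1 for v in variants if spans_overlap(v.start, v.end, start, end))


def classify_mappable(
    peak: CrePeak, variants: Iterable[GenomeVariant], half_width: int = 60
) -> bool:
    """True iff >=1 variant span intersects the inclusive +/-half_width summit window."""
    window = make_window(peak.summit, half_width)
    return any(
        v.chrom == peak.chrom and spans_overlap(v.start, v.end, *window) for v in variants
    )


def dedup_summits(peaks: Sequence[CrePeak], min_distance: int = 1000) -> list[CrePeak]:
    """Collapse summits within ``min_distance`` of one another (per chrom).

    Clusters are single-linkage (transitive) chains of summits with
    pairwise gaps <= min_distance; the maximal-``pooled_signal`` summit
    survives, ties broken by smaller coordinate.  Output is sorted by
    (chrom, summit).
    """
    kept: list[CrePeak] = []
    by_chrom: dict[str, list[CrePeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda p: p.summit)
        cluster: list[CrePeak] = []
        for p in group:
            if cluster and p.summit - cluster[-1].summit > min_distance:
                kept.append(_cluster_best(cluster))
                cluster = []
            cluster.append(p)
        if cluster:
            kept.append(_cluster_best(cluster))
    kept.sort(key=lambda p: (p.chrom, p.summit))
    return kept


def _cluster_best(cluster: list[CrePeak]) -> CrePeak:
    return max(cluster, key=lambda p: (p.pooled_signal, -p.summit))


def apply_signal_floor(
    peaks: Sequence[CrePeak],
    quantile: float = 0.2,
    grouping: Callable[[CrePeak], Hashable] | None = None,
) -> list[CrePeak]:
    """Drop peaks strictly below the per-group empirical signal quantile.

    The threshold is the linear-interpolation empirical quantile
    (numpy default); removal is strict (<), so ties at the threshold
    survive.  Groups with fewer than five peaks pass through unfiltered
    with a warning.
    """
    if grouping is None:
        grouping = lambda p: p.group  # noqa: E731
    groups: dict[Hashable, list[CrePeak]] = {}
    for p in peaks:
        groups.setdefault(grouping(p), []).append(p)
    retained: list[CrePeak] = []
    for key, members in groups.items():
        if len(members) < 5:
            warnings.warn(
                f"signal-floor group {key!r} has {len(members)} < 5 peaks; passed through",
                stacklevel=2,
            )
            retained.extend(members)
            continue
        threshold = float(np.quantile([p.pooled_signal for p in members], quantile))
        retained.extend(p for p in members if p.pooled_signal >= threshold)
    retained.sort(key=lambda p: (p.chrom, p.summit))
    return retained


def exclude_imprinted(
    peaks: Sequence[CrePeak],
    imprint_intervals: Iterable[tuple[str, int, int]],
    margin: int = 100_000,
) -> list[CrePeak]:
    """Remove peaks whose summit falls in any imprint interval expanded by ``margin``.

    Expansion is half-open on the right: a summit exactly ``margin`` past
    the interval end is retained.
    """
    intervals = list(imprint_intervals)

    def _hit(p: CrePeak) -> bool:
        return any(
            chrom == p.chrom and start - margin <= p.summit < end + margin
            for chrom, start, end in intervals
        )

    return [p for p in peaks if not _hit(p)]


def classify_peak(
    peak: CrePeak,
    tss_list: Sequence[tuple[str, int]],
    h3k27ac_intervals: Iterable[tuple[str, int, int]],
    threshold: int = 1000,
) -> tuple[str, bool]:
    """Locale (proximal/distal) by nearest-TSS distance, activity by H3K27ac overlap.

    Distance exactly equal to the threshold counts as proximal.  An empty
    TSS list yields distal with a warning.
    """
    if not tss_list:
        warnings.warn("empty TSS list: classifying all peaks as distal", stacklevel=2)
        locale = "distal"
    else:
        dists = [abs(peak.summit - pos) for chrom, pos in tss_list if chrom == peak.chrom]
        locale = "proximal" if dists and min(dists) <= threshold else "distal"
    active = any(
        chrom == peak.chrom and start <= peak.summit < end
        for chrom, start, end in h3k27ac_intervals
    )
    return locale, active


def build_catalog(
    peaks: Sequence[CrePeak],
    variants: Sequence[GenomeVariant],
    config: CatalogConfig | None = None,
    imprint_intervals: Iterable[tuple[str, int, int]] = (),
    grouping: Callable[[CrePeak], Hashable] | None = None,
) -> list[CrePeak]:
    """Full filter pipeline: mappability -> dedup -> signal floor -> imprint.

    Annotates each retained peak with ``mappable`` and ``n_variants_150``.
    Idempotent on a second application.
    """
    config = config or CatalogConfig()
    variants_by_chrom: dict[str, list[GenomeVariant]] = {}
    for v in variants:
        variants_by_chrom.setdefault(v.chrom, []).append(v)

    annotated = []
    for p in peaks:
        vlist = variants_by_chrom.get(p.chrom, [])
        mappable = classify_mappable(p, vlist, config.mappability_halfwidth)
        n150 = count_variants(
            make_window(p.summit, config.central_width // 2), vlist
        )
        annotated.append(replace_peak(p, mappable=mappable, n_variants_150=n150))

    mappable_peaks = [p for p in annotated if p.mappable]
    deduped = dedup_summits(mappable_peaks, config.dedup_distance)
    floored = apply_signal_floor(deduped, config.quintile_floor, grouping)
    return exclude_imprinted(floored, imprint_intervals, config.imprint_margin)


def replace_peak(peak: CrePeak, **kwargs) -> CrePeak:
    return replace(peak, **kwargs)
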