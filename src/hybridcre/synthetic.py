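"""Synthetic diploid locus fixtures with known ground truth.

Generates per-locus maternal (reference) sequences, plants degenerate
TF motifs near summits, derives a paternal allele by applying background
SNPs/indels plus targeted motif-disrupting SNPs, and draws
negative-binomial per-allele counts whose means drop when a governing
motif is disrupted.  Every downstream stage of the package is testable
against the recorded ground truth.

Fixture properties (not biological claims):

* one locus = one FASTA record = one chromosome;
* background variants avoid planted motif spans so disruption ground
  truth stays clean;
* insertions are anchored to the left flanking reference base (VCF
  style) and their affected span is that single base; deletions span all
  deleted bases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridcre.catalog import GenomeVariant, spans_overlap
from hybridcre.motifs import expand_iupac, reverse_complement, scan_kmer

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "PlacementTruth",
    "LocusTruth",
    "GroundTruth",
    "Placement",
    "FixtureBundle",
    "simulate_reference",
    "plant_motifs",
    "mutate_allele",
    "simulate_counts",
    "simulate_bundle",
    "write_fixture_bundle",
    "DEFAULT_EFFECT_MULTIPLIERS",
    "DEFAULT_ASSAYS",
]

DEFAULT_ASSAYS = ("ATAC", "Fos", "Tead1", "CTCF", "H3K27ac", "H3K4me1")

#: Invented calibrations of the hierarchical effect structure: losing the
#: AP-1 motif removes TEAD binding too, but not vice versa.
DEFAULT_EFFECT_MULTIPLIERS: dict[str, dict[str, float]] = {
    "AP1": {"Fos": 0.10, "ATAC": 0.30, "H3K4me1": 0.40, "H3K27ac": 0.25, "Tead1": 0.30},
    "TEAD": {"Tead1": 0.20, "ATAC": 0.70, "H3K27ac": 0.60, "Fos": 1.00},
}


@dataclass(frozen=True)
class MotifSpec:
    """A pattern to plant: id, IUPAC pattern, planting probability, and the
    maximum |offset| of the motif midpoint from the locus summit
    (offsets drawn uniformly)."""

    pattern_id: str
    pattern: str
    prob: float
    max_offset: int = 50

    def __post_init__(self) -> None:
        expand_iupac(self.pattern)
        if not 0 <= self.prob <= 1:
            raise ValueError(f"MotifSpec.prob must be in [0, 1], got {self.prob}")
        if self.max_offset < 0:
            raise ValueError("MotifSpec.max_offset must be nonnegative")


@dataclass
class SyntheticConfig:
    n_loci: int = 100
    locus_length: int = 2000
    gc_fraction: float = 0.42
    snp_rate: float = 1 / 140
    indel_rate: float = 1 / 850
    indel_max_len: int = 8
    motif_specs: tuple[MotifSpec, ...] = (
        MotifSpec("AP1", "VTGACTCAB", 0.5),
        MotifSpec("TEAD", "GGAATK", 0.5),
    )
    disruption_prob: float = 0.5
    effect_multipliers: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_MULTIPLIERS.items()}
    )
    depth_mean: float = 100.0
    dispersion: float = 20.0
    n_replicates: int = 2
    assays: tuple[str, ...] = DEFAULT_ASSAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("SyntheticConfig.n_loci must be positive")
        if self.locus_length <= 0:
            raise ValueError("SyntheticConfig.locus_length must be positive")
        for name in ("gc_fraction", "snp_rate", "indel_rate", "disruption_prob"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"SyntheticConfig.{name} must be in [0, 1], got {value}")
        if self.depth_mean <= 0:
            raise ValueError("SyntheticConfig.depth_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("SyntheticConfig.dispersion must be positive")
        if self.indel_max_len < 1:
            raise ValueError("SyntheticConfig.indel_max_len must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("SyntheticConfig.n_replicates must be >= 1")

    @property
    def summit(self) -> int:
        return self.locus_length // 2

    @classmethod
    def preset(cls, strain_class: str, **overrides) -> "SyntheticConfig":
        """Variant-density presets: 'wild_derived' (~1 per 120 bp) or
        'classical' (~1 per 1000 bp)."""
        if strain_class == "wild_derived":
            rates = dict(snp_rate=1 / 140, indel_rate=1 / 850)
        elif strain_class == "classical":
            rates = dict(snp_rate=1 / 1150, indel_rate=1 / 8000)
        else:
            raise ValueError(f"unknown strain_class {strain_class!r}")
        rates.update(overrides)
        return cls(**rates)


@dataclass(frozen=True)
class Placement:
    """A motif written into a maternal sequence."""

    locus: str
    pattern_id: str
    pattern: str
    start: int
    end: int
    strand: str
    written: str


@dataclass
class PlacementTruth:
    locus: str
    pattern_id: str
    start: int
    end: int
    strand: str
    disrupted: bool
    paternal_start: int


@dataclass
class LocusTruth:
    locus: str
    placements: list[PlacementTruth] = field(default_factory=list)
    #: per-assay true maternal:paternal mean ratio (filled by simulate_counts)
    mean_ratio: dict = field(default_factory=dict)

    @property
    def disrupted_pattern_ids(self) -> set[str]:
        return {p.pattern_id for p in self.placements if p.disrupted}


@dataclass
class GroundTruth:
    loci: dict  # locus id -> LocusTruth

    def __iter__(self):
        return iter(self.loci.values())


@dataclass
class FixtureBundle:
    config: SyntheticConfig
    sequences: dict  # locus -> maternal sequence
    paternal_sequences: dict
    placements: list
    variants: list
    ground_truth: GroundTruth
    counts: pd.DataFrame


def _locus_id(i: int) -> str:
    return f"locus_{i:05d}"


def simulate_reference(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """Per-locus reference sequences with the configured GC content."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return {
        _locus_id(i): "".join(rng.choice(bases, size=config.locus_length, p=probs))
        for i in range(config.n_loci)
    }


def plant_motifs(
    sequences: dict[str, str],
    motif_specs: tuple[MotifSpec, ...],
    rng: np.random.Generator,
    summit: int | None = None,
) -> tuple[dict[str, str], list[Placement]]:
    """Write motifs into sequences near the summit.

    Each planted subsequence is a uniformly drawn member of the
    pattern's expansion on a uniformly drawn strand; placements within a
    locus never overlap.  Positions that cannot be placed after bounded
    retries are skipped.
    """
    out: dict[str, str] = {}
    placements: list[Placement] = []
    for locus, seq in sequences.items():
        anchor = len(seq) // 2 if summit is None else summit
        chars = list(seq)
        occupied: list[tuple[int, int]] = []
        for spec in motif_specs:
            k = len(spec.pattern)
            if k > len(seq):
                raise ValueError(
                    f"pattern {spec.pattern_id!r} ({k} bp) longer than locus ({len(seq)} bp)"
                )
            if rng.random() >= spec.prob:
                continue
            members = sorted(expand_iupac(spec.pattern))
            placed = False
            for _ in range(50):
                midpoint_offset = int(rng.integers(-spec.max_offset, spec.max_offset + 1))
                start = anchor + midpoint_offset - (k - 1) // 2
                end = start + k
                if start < 0 or end > len(seq):
                    continue
                if any(spans_overlap(start, end, s, e) for s, e in occupied):
                    continue
                member = members[int(rng.integers(len(members)))]
                strand = "+" if rng.random() < 0.5 else "-"
                written = member if strand == "+" else reverse_complement(member)
                chars[start:end] = written
                occupied.append((start, end))
                placements.append(
                    Placement(locus, spec.pattern_id, spec.pattern, start, end, strand, written)
                )
                placed = True
                break
            if not placed:
                import warnings

                warnings.warn(
                    f"could not place {spec.pattern_id!r} in {locus} without overlap",
                    stacklevel=2,
                )
        out[locus] = "".join(chars)
    return out, placements


_BASES = "ACGT"


def mutate_allele(
    sequences: dict[str, str],
    placements: list[Placement],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[GenomeVariant], GroundTruth]:
    """Derive paternal sequences, the variant list, and ground truth.

    Background SNP and indel counts per locus are Poisson with the
    configured per-bp rates; background variants avoid all planted motif
    spans.  With probability ``disruption_prob`` a planted motif
    receives a SNP inside its span that removes it from the pattern's
    expansion set (verified by local re-scan).  Disruption flags are set
    by re-scanning the emitted paternal sequence.
    """
    placements_by_locus: dict[str, list[Placement]] = {}
    for pl in placements:
        placements_by_locus.setdefault(pl.locus, []).append(pl)

    all_variants: list[GenomeVariant] = []
    paternal: dict[str, str] = {}
    truth_loci: dict[str, LocusTruth] = {}

    for locus, seq in sequences.items():
        length = len(seq)
        locus_placements = placements_by_locus.get(locus, [])
        motif_spans = [(p.start, p.end) for p in locus_placements]
        occupied: list[tuple[int, int]] = list(motif_spans)
        variants: list[GenomeVariant] = []

        # -- background SNPs -------------------------------------------------
        n_snps = rng.poisson(config.snp_rate * length)
        for _ in range(n_snps):
            for _attempt in range(100):
                pos = int(rng.integers(length))
                if any(spans_overlap(pos, pos + 1, s, e) for s, e in occupied):
                    continue
                ref = seq[pos]
                alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
                variants.append(GenomeVariant(locus, pos, pos + 1, ref, alt, "snp"))
                occupied.append((pos, pos + 1))
                break

        # -- background indels ----------------------------------------------
        n_indels = rng.poisson(config.indel_rate * length)
        for _ in range(n_indels):
            for _attempt in range(100):
                size = int(rng.integers(1, config.indel_max_len + 1))
                if rng.random() < 0.5:  # insertion: anchor base + inserted seq
                    pos = int(rng.integers(length))
                    if any(spans_overlap(pos, pos + 1, s, e) for s, e in occupied):
                        continue
                    ins = "".join(_BASES[int(rng.integers(4))] for _ in range(size))
                    ref = seq[pos]
                    variants.append(
                        GenomeVariant(locus, pos, pos + 1, ref, ref + ins, "insertion")
                    )
                    occupied.append((pos, pos + 1))
                else:  # deletion: anchor base retained, [anchor+1, anchor+1+size) removed
                    anchor = int(rng.integers(0, length - size - 1))
                    start, end = anchor + 1, anchor + 1 + size
                    # keep the anchor base clear too so variants never abut/overlap
                    if any(spans_overlap(anchor, end, s, e) for s, e in occupied):
                        continue
                    ref = seq[anchor:end]
                    variants.append(
                        GenomeVariant(locus, start, end, ref, seq[anchor], "deletion")
                    )
                    occupied.append((anchor, end))
                break

        # -- targeted motif disruptions --------------------------------------
        for pl in locus_placements:
            if rng.random() >= config.disruption_prob:
                continue
            variant = _disrupting_snp(seq, pl, rng)
            if variant is not None:
                variants.append(variant)

        variants.sort(key=lambda v: v.start)
        pat_seq = _apply_variants(seq, variants)
        paternal[locus] = pat_seq
        all_variants.extend(variants)

        truth = LocusTruth(locus)
        for pl in locus_placements:
            shift = sum(
                len(v.alt) - len(v.ref) for v in variants if v.end <= pl.start
            )
            p_start = pl.start + shift
            disrupted = not _span_matches(pat_seq, p_start, pl.pattern)
            truth.placements.append(
                PlacementTruth(
                    locus, pl.pattern_id, pl.start, pl.end, pl.strand, disrupted, p_start
                )
            )
        truth_loci[locus] = truth

    return paternal, all_variants, GroundTruth(truth_loci)


def _span_matches(seq: str, start: int, pattern: str) -> bool:
    """Does any occurrence of ``pattern`` overlap [start, start+k) in ``seq``?"""
    k = len(pattern)
    lo = max(0, start - (k - 1))
    hi = min(len(seq), start + 2 * k - 1)
    return any(
        m.start < start + k and start < m.end
        for m in scan_kmer(seq[lo:hi], pattern, offset=lo)
    )


def _disrupting_snp(
    seq: str, placement: Placement, rng: np.random.Generator
) -> GenomeVariant | None:
    """A SNP inside the placement span whose application destroys the motif."""
    span_positions = list(range(placement.start, placement.end))
    rng.shuffle(span_positions)
    for pos in span_positions:
        ref = seq[pos]
        alts = [b for b in _BASES if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            mutated = seq[: pos] + alt + seq[pos + 1 :]
            if not _span_matches(mutated, placement.start, placement.pattern):
                return GenomeVariant(placement.locus, pos, pos + 1, ref, alt, "snp")
    return None  # fully degenerate patterns may be indestructible by one SNP


def _apply_variants(seq: str, variants: list[GenomeVariant]) -> str:
    """Apply non-overlapping variants (sorted by start) to a sequence."""
    out = seq
    for v in sorted(variants, key=lambda v: v.start, reverse=True):
        if v.kind == "snp":
            assert out[v.start] == v.ref, "SNP ref mismatch"
            out = out[: v.start] + v.alt + out[v.start + 1 :]
        elif v.kind == "insertion":
            assert out[v.start] == v.ref, "insertion anchor mismatch"
            out = out[: v.start + 1] + v.alt[1:] + out[v.start + 1 :]
        else:  # deletion
            out = out[: v.start] + out[v.end :]
    return out


def simulate_counts(
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Negative-binomial per-locus/assay/allele/replicate counts.

    The paternal mean is ``depth_mean`` times the product of effect
    multipliers for assays governed by motifs disrupted on the paternal
    allele; the maternal mean is ``depth_mean``.  Variance is
    mu + mu^2 / dispersion (Poisson in the large-dispersion limit).
    Also fills ``mean_ratio`` on each LocusTruth.
    """
    rows = []
    for truth in ground_truth:
        multipliers = {assay: 1.0 for assay in config.assays}
        for pattern_id in sorted(truth.disrupted_pattern_ids):
            for assay, mult in config.effect_multipliers.get(pattern_id, {}).items():
                if assay in multipliers:
                    multipliers[assay] *= mult
        truth.mean_ratio = {
            assay: (np.inf if multipliers[assay] == 0 else 1.0 / multipliers[assay])
            for assay in config.assays
        }
        for assay in config.assays:
            for allele, mult in (("maternal", 1.0), ("paternal", multipliers[assay])):
                mu = config.depth_mean * mult
                for rep in range(config.n_replicates):
                    rows.append(
                        (truth.locus, assay, allele, rep, _draw_nb(rng, mu, config.dispersion))
                    )
    return pd.DataFrame(rows, columns=["locus", "assay", "allele", "replicate", "count"])


def _draw_nb(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    if mu <= 0:
        return 0
    if dispersion >= 1e8:  # Poisson limit; avoids numeric trouble in NB sampling
        return int(rng.poisson(mu))
    p = dispersion / (dispersion + mu)
    return int(rng.negative_binomial(dispersion, p))


def simulate_bundle(config: SyntheticConfig) -> FixtureBundle:
    """Run the full generator deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sequences = simulate_reference(config, rng)
    sequences, placements = plant_motifs(sequences, config.motif_specs, rng)
    paternal, variants, truth = mutate_allele(sequences, placements, config, rng)
    counts = simulate_counts(truth, config, rng)
    return FixtureBundle(config, sequences, paternal, placements, variants, truth, counts)


def write_fixture_bundle(bundle: FixtureBundle, directory) -> dict[str, str]:
    """Write a bundle as plain-text files; returns the path map.

    Layout: reference/paternal FASTA, variants VCF (CHROM = locus id),
    summits + motif placements BED6, counts TSV, ground-truth TSVs.
    """
    import os

    from hybridcre import io as hio

    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "reference": os.path.join(directory, "reference.fa"),
        "paternal": os.path.join(directory, "paternal.fa"),
        "variants": os.path.join(directory, "variants.vcf"),
        "summits": os.path.join(directory, "summits.bed"),
        "motifs": os.path.join(directory, "motifs.bed"),
        "counts": os.path.join(directory, "counts.tsv"),
        "ground_truth": os.path.join(directory, "ground_truth.tsv"),
        "truth_ratios": os.path.join(directory, "truth_ratios.tsv"),
    }
    hio.write_fasta(bundle.sequences, paths["reference"])
    hio.write_fasta(bundle.paternal_sequences, paths["paternal"])
    contigs = {locus: len(seq) for locus, seq in bundle.sequences.items()}
    hio.write_vcf(bundle.variants, paths["variants"], contigs=contigs)
    summit = bundle.config.summit
    hio.write_bed(
        [(locus, summit, summit + 1, locus, 0, "+") for locus in bundle.sequences],
        paths["summits"],
    )
    hio.write_bed(
        [
            (pl.locus, pl.start, pl.end, pl.pattern_id, 0, pl.strand)
            for pl in bundle.placements
        ],
        paths["motifs"],
    )
    bundle.counts.to_csv(paths["counts"], sep="\t", index=False)

    truth_rows = [
        dataclasses.asdict(pt)
        for locus_truth in bundle.ground_truth
        for pt in locus_truth.placements
    ]
    pd.DataFrame(
        truth_rows,
        columns=["locus", "pattern_id", "start", "end", "strand", "disrupted", "paternal_start"],
    ).to_csv(paths["ground_truth"], sep="\t", index=False)

    ratio_rows = [
        (t.locus, assay, ratio)
        for t in bundle.ground_truth
        for assay, ratio in t.mean_ratio.items()
    ]
    pd.DataFrame(ratio_rows, columns=["locus", "assay", "maternal_paternal_ratio"]).to_csv(
        paths["truth_ratios"], sep="\t", index=False
    )
    return paths
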