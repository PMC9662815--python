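"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Biopython, VCF reading via pysam (v4 subset: 8 fixed columns,
genotypes ignored), BED6 and TSV tables via plain text / pandas.  All
coordinates are converted to 0-based half-open at this boundary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from hybridcre.catalog import CatalogConfig, GenomeVariant
from hybridcre.skew import SkewConfig

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

_VALID_ALLELE = frozenset("ACGT")


def read_fasta(path: str) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence} map.

    Duplicate record ids raise; parse errors carry the offending record.
    """
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records parsed from {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_vcf(path: str) -> list[GenomeVariant]:
    """VCF v4 subset -> GenomeVariant list (0-based spans).

    Multi-allelic records are split; records with a populated FILTER
    other than PASS are dropped; REF/ALT with characters outside ACGT
    are skipped with a warning.
    """
    import pysam

    variants: list[GenomeVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            filters = list(record.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            for alt in record.alts or ():
                if set(record.ref) - _VALID_ALLELE or set(alt) - _VALID_ALLELE:
                    warnings.warn(
                        f"skipping non-ACGT record at {record.chrom}:{record.pos}",
                        stacklevel=2,
                    )
                    continue
                variants.append(
                    GenomeVariant.from_vcf_fields(record.chrom, record.pos, record.ref, alt)
                )
    return variants


def write_vcf(
    variants: Sequence[GenomeVariant],
    path: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal VCF v4.2 (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write("##source=hybridcre\n")
        if contigs:
            for name, length in contigs.items():
                handle.write(f"##contig=<ID={name},length={length}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = sorted(variants, key=lambda v: (v.chrom, v.start))
        for v in rows:
            chrom, pos, ref, alt = v.to_vcf_fields()
            handle.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def read_bed(path: str) -> list[tuple[str, int, int, str, float, str]]:
    """BED (3-6 columns) -> list of (chrom, start, end, name, score, strand)."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return rows


def write_bed(rows: Iterable[Sequence], path: str) -> None:
    """Write rows of (chrom, start, end[, name[, score[, strand]]]) as BED."""
    with open(path, "w") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


COUNT_COLUMNS = ["locus", "assay", "allele", "replicate", "count"]


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table {path} missing columns: {sorted(missing)}")
    return df[COUNT_COLUMNS]


def write_counts(df: pd.DataFrame, path: str) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Declarative configuration for the end-to-end pipeline."""

    output_dir: str = "hybridcre_out"
    seed: int = 0
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    skew: SkewConfig = field(default_factory=SkewConfig)
    paths: dict = field(default_factory=dict)  # fasta/vcf/beds/counts/patterns/pwm
    patterns: dict = field(default_factory=dict)  # pattern id -> IUPAC string

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "synthetic": dict(self.synthetic),
            "catalog": vars(self.catalog).copy(),
            "skew": {k: v for k, v in vars(self.skew).items()},
            "paths": dict(self.paths),
            "patterns": dict(self.patterns),
        }


def load_run_config(path: str) -> RunConfig:
    """Parse a YAML run configuration; round-trips with ``to_dict``."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    catalog = CatalogConfig(**raw.get("catalog", {}))
    skew_raw = dict(raw.get("skew", {}))
    if "fold_thresholds" in skew_raw:
        skew_raw["fold_thresholds"] = tuple(skew_raw["fold_thresholds"])
    skew = SkewConfig(**skew_raw)
    return RunConfig(
        output_dir=raw.get("output_dir", "hybridcre_out"),
        seed=int(raw.get("seed", 0)),
        log_level=raw.get("log_level", "INFO"),
        synthetic=raw.get("synthetic", {}),
        catalog=catalog,
        skew=skew,
        paths=raw.get("paths", {}),
        patterns=raw.get("patterns", {}),
    )


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the configuration, for provenance lines."""
    def _default(o):
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    payload = json.dumps(config.to_dict(), sort_keys=True, default=_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
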