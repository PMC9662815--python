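"""End-to-end orchestration: simulate -> catalog -> skew -> motifs ->
positions -> hierarchy -> profiles.

Each stage writes a TSV under the output directory and contributes to a
JSON summary carrying filter counts, allele-specific fractions,
enrichment tables, the config hash and the seed.  A stage failure halts
the run with a stage-named error; earlier outputs are retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from hybridcre import __version__
from hybridcre import io as hio
from hybridcre.catalog import CrePeak, build_catalog
from hybridcre.hierarchy import mutation_enrichment, partner_loss_fraction
from hybridcre.motifs import CATALOG_PATTERNS, classify_disruption
from hybridcre.positions import offset_histogram, offset_histogram_compare, variant_offsets
from hybridcre.profiles import binned_profile, select_single_motif_pairs
from hybridcre.skew import analyze_skew
from hybridcre.synthetic import MotifSpec, SyntheticConfig, simulate_bundle, write_fixture_bundle

logger = logging.getLogger("hybridcre")

__all__ = ["run_pipeline", "build_synthetic_config"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


_FLOAT_FIELDS = ("gc_fraction", "snp_rate", "indel_rate", "disruption_prob",
                 "depth_mean", "dispersion")
_INT_FIELDS = ("n_loci", "locus_length", "indel_max_len", "n_replicates", "seed")


def build_synthetic_config(options: dict, seed: int) -> SyntheticConfig:
    opts = dict(options)
    specs = opts.pop("motif_specs", None)
    if specs is not None:
        opts["motif_specs"] = tuple(MotifSpec(**spec) for spec in specs)
    opts.setdefault("seed", seed)
    # YAML 1.1 reads bare scientific notation (1e9) as a string
    for name in _FLOAT_FIELDS:
        if name in opts:
            opts[name] = float(opts[name])
    for name in _INT_FIELDS:
        if name in opts:
            opts[name] = int(opts[name])
    return SyntheticConfig(**opts)


def run_pipeline(config: hio.RunConfig) -> dict:
    """Run all stages on a synthetic bundle; returns the summary dict."""
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    chash = hio.config_hash(config)
    logger.info("hybridcre %s | seed=%d | config=%s", __version__, config.seed, chash)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "stages": {},
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("simulate")
        syn_config = build_synthetic_config(config.synthetic, config.seed)
        bundle = simulate_bundle(syn_config)
        write_fixture_bundle(bundle, os.path.join(outdir, "fixture"))
        summary["stages"]["simulate"] = {
            "n_loci": syn_config.n_loci,
            "n_variants": len(bundle.variants),
            "n_placements": len(bundle.placements),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        _stage("catalog")
        pooled = (
            bundle.counts.query("assay == 'ATAC'")
            .groupby("locus")["count"]
            .mean()
            .to_dict()
        )
        peaks = [
            CrePeak(
                id=locus,
                chrom=locus,
                summit=syn_config.summit,
                pooled_signal=pooled.get(locus, 0.0),
            )
            for locus in bundle.sequences
        ]
        retained = build_catalog(peaks, bundle.variants, config.catalog)
        catalog_df = pd.DataFrame(
            [
                (p.id, p.chrom, p.summit, p.pooled_signal, p.n_variants_150, p.mappable)
                for p in retained
            ],
            columns=["id", "chrom", "summit", "pooled_signal", "n_variants_150", "mappable"],
        )
        catalog_df.to_csv(os.path.join(outdir, "catalog.tsv"), sep="\t", index=False)
        summary["stages"]["catalog"] = {
            "n_input": len(peaks),
            "n_retained": len(retained),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("catalog", exc) from exc

    try:
        _stage("skew")
        retained_ids = {p.id for p in retained}
        skew_results: dict[str, list] = {}
        for assay in syn_config.assays:
            sub = bundle.counts.query("assay == @assay and locus in @retained_ids")
            records = []
            for locus, grp in sub.groupby("locus"):
                m = grp.query("allele == 'maternal'")["count"].tolist()
                p_ = grp.query("allele == 'paternal'")["count"].tolist()
                records.append((locus, m, p_))
            results = analyze_skew(records, config.skew)
            skew_results[assay] = results
            pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
                os.path.join(outdir, f"skew_{assay}.tsv"), sep="\t", index=False
            )
        summary["stages"]["skew"] = {
            assay: {
                "n": len(results),
                "fraction_allele_specific": (
                    float(np.mean([r.klass == "allele_specific" for r in results]))
                    if results
                    else float("nan")
                ),
            }
            for assay, results in skew_results.items()
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("skew", exc) from exc

    try:
        _stage("motifs")
        patterns = config.patterns or {
            "AP1": CATALOG_PATTERNS["AP1_core"],
            "TEAD": CATALOG_PATTERNS["TEAD_extended"],
        }
        shift_by_locus = {
            locus: sum(
                len(v.alt) - len(v.ref)
                for v in bundle.variants
                if v.chrom == locus and v.end <= syn_config.summit
            )
            for locus in bundle.sequences
        }
        calls = []
        for p in retained:
            for pattern_id, pattern in patterns.items():
                call = classify_disruption(
                    p.id,
                    bundle.sequences[p.id],
                    bundle.paternal_sequences[p.id],
                    pattern,
                    halfwidth=75,
                    maternal_summit=p.summit,
                    paternal_summit=p.summit + shift_by_locus[p.id],
                    pattern_id=pattern_id,
                )
                calls.append(call)
        pd.DataFrame(
            [
                (c.peak_id, c.pattern_id, c.halfwidth, c.maternal_has, c.paternal_has, c.category)
                for c in calls
            ],
            columns=["peak_id", "pattern_id", "halfwidth", "maternal_has", "paternal_has", "category"],
        ).to_csv(os.path.join(outdir, "disruptions.tsv"), sep="\t", index=False)
        summary["stages"]["motifs"] = {
            pattern_id: sum(
                1 for c in calls if c.pattern_id == pattern_id and c.category == "strain_specific"
            )
            for pattern_id in patterns
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("motifs", exc) from exc

    try:
        _stage("positions")
        k27 = {r.peak_id: r for r in skew_results.get("H3K27ac", [])}
        as_regions = [
            (p.id, p.chrom, p.summit)
            for p in retained
            if p.id in k27 and k27[p.id].klass == "allele_specific"
        ]
        shared_regions = [
            (p.id, p.chrom, p.summit)
            for p in retained
            if p.id in k27 and k27[p.id].klass == "shared"
        ]
        as_off = variant_offsets(as_regions, bundle.variants, halfwidth=200)
        sh_off = variant_offsets(shared_regions, bundle.variants, halfwidth=200)
        as_hist = offset_histogram(as_off, 200, n_regions=len(as_regions))
        sh_hist = offset_histogram(sh_off, 200, n_regions=len(shared_regions))
        if as_hist.total and sh_hist.total:
            statistic, pval, _table = offset_histogram_compare(as_hist, sh_hist)
        else:
            statistic, pval = float("nan"), float("nan")
        rows = [("allele_specific", off) for off in as_off] + [
            ("shared", off) for off in sh_off
        ]
        pd.DataFrame(rows, columns=["group", "offset"]).to_csv(
            os.path.join(outdir, "offsets.tsv"), sep="\t", index=False
        )
        summary["stages"]["positions"] = {
            "n_allele_specific_events": len(as_off),
            "n_shared_events": len(sh_off),
            "chi2": statistic,
            "p": pval,
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("positions", exc) from exc

    try:
        _stage("hierarchy")
        fos = {r.peak_id: r for r in skew_results.get("Fos", [])}
        tead = {r.peak_id: r for r in skew_results.get("Tead1", [])}
        as_fos = {pid for pid, r in fos.items() if r.klass == "allele_specific"}
        as_tead = {pid for pid, r in tead.items() if r.klass == "allele_specific"}
        joint = as_fos & as_tead
        hier = {
            "n_allele_specific_fos": len(as_fos),
            "n_allele_specific_tead": len(as_tead),
            "n_joint": len(joint),
            "fos_with_tead_loss_pct": (
                partner_loss_fraction(len(joint), len(as_fos)) if as_fos else None
            ),
            "tead_with_fos_loss_pct": (
                partner_loss_fraction(len(joint), len(as_tead)) if as_tead else None
            ),
        }
        ap1_specific = {
            c.peak_id for c in calls if c.pattern_id == "AP1" and c.category == "strain_specific"
        }
        fos_ids = [pid for pid in fos]
        if as_fos and len(as_fos) < len(fos_ids):
            enr = mutation_enrichment(
                [pid in ap1_specific for pid in sorted(as_fos)],
                [pid in ap1_specific for pid in sorted(set(fos_ids) - as_fos)],
            )
            hier["ap1_mutation_enrichment"] = {
                "table": enr.table.tolist(),
                "fraction_allele_specific": enr.fraction_as,
                "fraction_shared": enr.fraction_shared,
                "odds_ratio": enr.odds_ratio,
                "p": enr.p,
            }
        summary["stages"]["hierarchy"] = hier
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("hierarchy", exc) from exc

    try:
        _stage("profiles")
        pairs = select_single_motif_pairs(
            (
                (p.id, bundle.sequences[p.id], bundle.paternal_sequences[p.id])
                for p in retained
            ),
            CATALOG_PATTERNS["AP1_core"],
            halfwidth=75,
        )
        fos_counts = (
            bundle.counts.query("assay == 'Fos'")
            .groupby(["locus", "allele"])["count"]
            .mean()
        )
        events = []
        anchors = []
        for locus, intact_allele in pairs:
            for allele in ("maternal", "paternal"):
                group = "intact" if allele == intact_allele else "mutated"
                weight = float(fos_counts.get((locus, allele), 0.0))
                events.append((f"{locus}:{allele}", syn_config.summit, weight))
                anchors.append((f"{locus}:{allele}", syn_config.summit, group))
        if anchors:
            profile = binned_profile(events, anchors)
            prof_df = pd.DataFrame({"bin_start": profile.bin_starts})
            for group, means in profile.means.items():
                prof_df[group] = means
            prof_df.to_csv(os.path.join(outdir, "profile_Fos.tsv"), sep="\t", index=False)
            central = profile.n_bins // 2
            summary["stages"]["profiles"] = {
                "n_single_motif_pairs": len(pairs),
                "central_bin_means": {
                    group: float(means[central]) for group, means in profile.means.items()
                },
            }
        else:
            summary["stages"]["profiles"] = {"n_single_motif_pairs": 0}
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("profiles", exc) from exc

    with open(os.path.join(outdir, "summary.json"), "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return summary
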