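import hashlib
from pathlib import Path

import numpy as np
import pytest

from hybridcre import io as hio
from hybridcre.motifs import expand_iupac, reverse_complement, scan_kmer
from hybridcre.synthetic import (
    MotifSpec,
    SyntheticConfig,
    mutate_allele,
    plant_motifs,
    simulate_bundle,
    simulate_counts,
    simulate_reference,
    write_fixture_bundle,
)


class TestConfigValidation:
    def test_invalid_field_named_in_error(self):
        with pytest.raises(ValueError, match="gc_fraction"):
            SyntheticConfig(gc_fraction=1.2)
        with pytest.raises(ValueError, match="dispersion"):
            SyntheticConfig(dispersion=0)
        with pytest.raises(ValueError, match="depth_mean"):
            SyntheticConfig(depth_mean=-1)

    def test_presets_match_documented_densities(self):
        wild = SyntheticConfig.preset("wild_derived")
        classical = SyntheticConfig.preset("classical")
        wild_bp = 1 / (wild.snp_rate + wild.indel_rate)
        classical_bp = 1 / (classical.snp_rate + classical.indel_rate)
        assert 85 <= wild_bp <= 170
        assert 900 <= classical_bp <= 1100


class TestSimulateReference:
    def test_deterministic(self):
        config = SyntheticConfig(n_loci=1, locus_length=100, gc_fraction=0.5, seed=7)
        seqs1 = simulate_reference(config)
        seqs2 = simulate_reference(config)
        assert seqs1 == seqs2
        (seq,) = seqs1.values()
        assert len(seq) == 100 and set(seq) <= set("ACGT")

    def test_gc_one_gives_only_gc(self):
        config = SyntheticConfig(n_loci=3, locus_length=200, gc_fraction=1.0, seed=1)
        for seq in simulate_reference(config).values():
            assert set(seq) <= {"G", "C"}

    def test_mean_gc_close_to_target(self):
        config = SyntheticConfig(n_loci=200, locus_length=2000, gc_fraction=0.42, seed=2)
        gcs = [
            (seq.count("G") + seq.count("C")) / len(seq)
            for seq in simulate_reference(config).values()
        ]
        assert 0.40 <= np.mean(gcs) <= 0.44

    def test_per_locus_gc_within_5_points_at_2kb(self):
        config = SyntheticConfig(n_loci=50, locus_length=2000, gc_fraction=0.42, seed=3)
        for seq in simulate_reference(config).values():
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            assert abs(gc - 0.42) <= 0.05


class TestPlantMotifs:
    def test_planted_subsequence_is_expansion_member(self, rng):
        config = SyntheticConfig(n_loci=50, locus_length=400, seed=4)
        seqs = simulate_reference(config)
        planted, placements = plant_motifs(
            seqs, (MotifSpec("TEAD", "GGAATK", 1.0, max_offset=20),), rng
        )
        assert len(placements) == 50
        members = expand_iupac("GGAATK")
        for pl in placements:
            written = planted[pl.locus][pl.start : pl.end]
            if pl.strand == "+":
                assert written in members
            else:
                assert reverse_complement(written) in members

    def test_probability_zero_leaves_sequences_unchanged(self, rng):
        config = SyntheticConfig(n_loci=20, locus_length=300, seed=5)
        seqs = simulate_reference(config)
        planted, placements = plant_motifs(
            seqs, (MotifSpec("AP1", "VTGACTCAB", 0.0),), rng
        )
        assert planted == seqs and placements == []

    def test_all_nine_expansions_observed_and_uniform(self, rng):
        config = SyntheticConfig(n_loci=1000, locus_length=120, seed=6)
        seqs = simulate_reference(config)
        _, placements = plant_motifs(
            seqs, (MotifSpec("AP1", "VTGACTCAB", 1.0, max_offset=10),), rng
        )
        drawn = {}
        for pl in placements:
            member = pl.written if pl.strand == "+" else reverse_complement(pl.written)
            drawn[member] = drawn.get(member, 0) + 1
        assert set(drawn) == expand_iupac("VTGACTCAB")
        # multinomial 99% bound on each of the 9 cells
        n = sum(drawn.values())
        p = 1 / 9
        sigma = np.sqrt(n * p * (1 - p))
        for count in drawn.values():
            assert abs(count - n * p) < 3.5 * sigma

    def test_pattern_longer_than_locus_rejected(self, rng):
        with pytest.raises(ValueError, match="longer than locus"):
            plant_motifs({"l": "ACGT"}, (MotifSpec("AP1", "VTGACTCAB", 1.0),), rng)

    def test_placements_do_not_overlap(self, rng):
        config = SyntheticConfig(n_loci=100, locus_length=300, seed=8)
        seqs = simulate_reference(config)
        specs = tuple(
            MotifSpec(f"m{i}", "TGASTCA", 1.0, max_offset=15) for i in range(3)
        )
        _, placements = plant_motifs(seqs, specs, rng)
        by_locus = {}
        for pl in placements:
            by_locus.setdefault(pl.locus, []).append((pl.start, pl.end))
        for spans in by_locus.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestMutateAllele:
    def test_background_snp_count_matches_poisson_mean(self, rng):
        config = SyntheticConfig(
            n_loci=500, locus_length=2000, snp_rate=1 / 100, indel_rate=0.0, seed=9
        )
        seqs = simulate_reference(config)
        _, variants, _ = mutate_allele(seqs, [], config, rng)
        assert 18 <= len(variants) / 500 <= 22

    def test_disruption_prob_zero_keeps_all_motifs_intact(self, rng):
        config = SyntheticConfig(n_loci=60, locus_length=500, disruption_prob=0.0, seed=10)
        seqs = simulate_reference(config)
        seqs, placements = plant_motifs(seqs, config.motif_specs, rng)
        paternal, _, truth = mutate_allele(seqs, placements, config, rng)
        for locus_truth in truth:
            for pt in locus_truth.placements:
                assert not pt.disrupted
                window = paternal[pt.locus]
                k = pt.end - pt.start
                pattern = next(
                    s.pattern for s in config.motif_specs if s.pattern_id == pt.pattern_id
                )
                hits = scan_kmer(window, pattern)
                assert any(
                    m.start < pt.paternal_start + k and pt.paternal_start < m.end
                    for m in hits
                )

    def test_disruption_prob_one_destroys_planted_core_ap1(self, rng):
        config = SyntheticConfig(
            n_loci=40,
            locus_length=500,
            motif_specs=(MotifSpec("AP1", "TGACTCA", 1.0, max_offset=20),),
            disruption_prob=1.0,
            snp_rate=0.0,
            indel_rate=0.0,
            seed=11,
        )
        seqs = simulate_reference(config)
        seqs, placements = plant_motifs(seqs, config.motif_specs, rng)
        paternal, variants, truth = mutate_allele(seqs, placements, config, rng)
        for locus_truth in truth:
            for pt in locus_truth.placements:
                assert pt.disrupted
                # re-scan oracle: no core AP-1 occurrence overlaps the span
                hits = scan_kmer(paternal[pt.locus], "TGACTCA")
                assert not any(
                    m.start < pt.paternal_start + 7 and pt.paternal_start < m.end
                    for m in hits
                )

    def test_every_disrupted_motif_has_overlapping_variant(self, small_bundle):
        variants_by_chrom = {}
        for v in small_bundle.variants:
            variants_by_chrom.setdefault(v.chrom, []).append(v)
        for locus_truth in small_bundle.ground_truth:
            for pt in locus_truth.placements:
                if pt.disrupted:
                    assert any(
                        v.start < pt.end and pt.start < v.end
                        for v in variants_by_chrom.get(pt.locus, [])
                    )

    def test_all_variants_report_ref_not_equal_alt(self, small_bundle):
        assert all(v.ref != v.alt for v in small_bundle.variants)

    def test_ground_truth_consistent_with_rescan(self, small_bundle):
        """Disruption flags equal motif re-scan results for every locus."""
        patterns = {s.pattern_id: s.pattern for s in small_bundle.config.motif_specs}
        for locus_truth in small_bundle.ground_truth:
            pat_seq = small_bundle.paternal_sequences[locus_truth.locus]
            mat_seq = small_bundle.sequences[locus_truth.locus]
            for pt in locus_truth.placements:
                pattern = patterns[pt.pattern_id]
                k = len(pattern)
                mat_hit = any(
                    m.start < pt.start + k and pt.start < m.end
                    for m in scan_kmer(mat_seq, pattern)
                )
                pat_hit = any(
                    m.start < pt.paternal_start + k and pt.paternal_start < m.end
                    for m in scan_kmer(pat_seq, pattern)
                )
                assert mat_hit  # planted motifs are intact on the maternal allele
                assert pt.disrupted == (not pat_hit)


class TestSimulateCounts:
    def _truth(self, config, rng, disrupt=None):
        seqs = simulate_reference(config, rng)
        seqs, placements = plant_motifs(seqs, config.motif_specs, rng)
        _, _, truth = mutate_allele(seqs, placements, config, rng)
        return truth

    def test_null_symmetry(self, rng):
        config = SyntheticConfig(
            n_loci=500, locus_length=300, disruption_prob=0.0, depth_mean=100,
            dispersion=1e9, assays=("Fos",), seed=12,
        )
        truth = self._truth(config, rng)
        counts = simulate_counts(truth, config, rng)
        totals = counts.pivot_table(
            index="locus", columns="allele", values="count", aggfunc="sum"
        )
        log2_ratio = np.log2((totals["maternal"] + 1) / (totals["paternal"] + 1))
        assert abs(log2_ratio.mean()) <= 0.1

    def test_effect_multiplier_recovered(self, rng):
        config = SyntheticConfig(
            n_loci=600,
            locus_length=300,
            motif_specs=(MotifSpec("AP1", "TGACTCA", 1.0, max_offset=20),),
            disruption_prob=1.0,
            effect_multipliers={"AP1": {"Fos": 0.25}},
            depth_mean=100,
            dispersion=1e9,
            assays=("Fos",),
            snp_rate=0.0,
            indel_rate=0.0,
            seed=13,
        )
        truth = self._truth(config, rng)
        counts = simulate_counts(truth, config, rng)
        totals = counts.pivot_table(
            index="locus", columns="allele", values="count", aggfunc="sum"
        )
        log2_ratio = np.log2(totals["maternal"] / totals["paternal"])
        assert abs(log2_ratio.mean() - 2.0) <= 0.3
        for locus_truth in truth:
            assert locus_truth.mean_ratio["Fos"] == pytest.approx(4.0)

    def test_poisson_limit_variance(self, rng):
        config = SyntheticConfig(
            n_loci=400, locus_length=300, disruption_prob=0.0, depth_mean=100,
            dispersion=1e9, assays=("ATAC",), n_replicates=1, seed=14,
        )
        truth = self._truth(config, rng)
        counts = simulate_counts(truth, config, rng)["count"].to_numpy()
        assert 0.9 <= counts.var() / counts.mean() <= 1.2

    def test_overdispersed_variance_exceeds_poisson(self, rng):
        config = SyntheticConfig(
            n_loci=400, locus_length=300, disruption_prob=0.0, depth_mean=100,
            dispersion=5.0, assays=("ATAC",), n_replicates=1, seed=15,
        )
        truth = self._truth(config, rng)
        counts = simulate_counts(truth, config, rng)["count"].to_numpy()
        # NB variance mu + mu^2/size = 100 + 2000
        assert counts.var() / counts.mean() > 5


class TestBundleDeterminismAndRoundTrip:
    def test_identical_config_yields_hash_equal_files(self, tmp_path):
        config = SyntheticConfig(n_loci=15, locus_length=500, seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture_bundle(simulate_bundle(config), d1)
        write_fixture_bundle(simulate_bundle(config), d2)
        for f1 in sorted(d1.iterdir()):
            h1 = hashlib.sha256(f1.read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / f1.name).read_bytes()).hexdigest()
            assert h1 == h2, f1.name

    def test_variant_round_trip_field_by_field(self, small_bundle, tmp_path):
        paths = write_fixture_bundle(small_bundle, tmp_path / "bundle")
        reread = hio.read_vcf(paths["variants"])
        key = lambda v: (v.chrom, v.start, v.alt)  # noqa: E731
        assert sorted(reread, key=key) == sorted(small_bundle.variants, key=key)

    def test_fasta_and_counts_round_trip(self, small_bundle, tmp_path):
        paths = write_fixture_bundle(small_bundle, tmp_path / "bundle")
        assert hio.read_fasta(paths["reference"]) == small_bundle.sequences
        assert hio.read_fasta(paths["paternal"]) == small_bundle.paternal_sequences
        reread = hio.read_counts(paths["counts"])
        assert reread.equals(small_bundle.counts)

    def test_vcf_pos_is_one_based(self, tmp_path):
        from hybridcre.catalog import GenomeVariant

        v = GenomeVariant("locus_x", 99, 100, "A", "G", "snp")
        path = tmp_path / "one.vcf"
        hio.write_vcf([v], path, contigs={"locus_x": 200})
        line = [
            l for l in Path(path).read_text().splitlines() if not l.startswith("#")
        ][0]
        assert line.split("\t")[1] == "100"

    def test_motif_bed_is_half_open(self, tmp_path):
        config = SyntheticConfig(
            n_loci=5,
            locus_length=1000,
            motif_specs=(MotifSpec("AP1", "VTGACTCAB", 1.0, max_offset=10),),
            seed=22,
        )
        bundle = simulate_bundle(config)
        paths = write_fixture_bundle(bundle, tmp_path / "bundle")
        for chrom, start, end, name, _score, _strand in hio.read_bed(paths["motifs"]):
            assert end - start == 9

    def test_unwritable_directory_raises(self, small_bundle):
        with pytest.raises(OSError):
            write_fixture_bundle(small_bundle, "/proc/definitely/not/writable")
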