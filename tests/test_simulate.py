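"""Generator contracts: determinism, canonical introns, truth round-trips,
programmed-variant structure, read simulation and normalization."""

import numpy as np
import pytest
from scipy import stats

from retsplice import io
from retsplice.events import check_splice_consensus
from retsplice.simulate import (EVENT_CLASSES, SimConfig, SimulationError,
                                build_clone_pool, emulate_normalization,
                                generate_genome, make_read_id, parse_read_id,
                                simulate_ests, spawn_variants)
from retsplice.util import revcomp


def introns_of(exons):
    exons = sorted(exons)
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


class TestGenerateGenome:
    def test_single_gene_structure_and_canonical_introns(self):
        cfg = SimConfig(seed=3, n_genes=1, n_chroms=1, chrom_len=10_000,
                        exons_per_gene=(3, 3))
        g = generate_genome(cfg)
        (gene,) = g.genes
        assert len(gene.exons) == 3
        ivs = introns_of(gene.exons)
        assert len(ivs) == 2
        for d, a in ivs:
            assert check_splice_consensus(gene.chrom, d, a, gene.strand, g)

    def test_deterministic_under_seed(self, small_cfg):
        a, b = generate_genome(small_cfg), generate_genome(small_cfg)
        assert a.chroms == b.chroms
        assert [(g.gene_id, g.exons, g.cds, g.strand) for g in a.genes] == \
               [(g.gene_id, g.exons, g.cds, g.strand) for g in b.genes]

    def test_all_introns_canonical_across_genome(self, small_genome):
        for gene in small_genome.genes:
            for d, a in introns_of(gene.exons):
                assert check_splice_consensus(gene.chrom, d, a, gene.strand,
                                              small_genome)

    def test_gff3_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=50, n_chroms=2, chrom_len=200_000)
        genome = generate_genome(cfg)
        path = tmp_path / "truth.gff3"
        io.write_gff3(genome, path)
        back = io.read_gff3(path)
        assert len(back) == 50
        by_id = {g["gene_id"]: g for g in back}
        for gene in genome.genes:
            got = by_id[gene.gene_id]
            assert got["chrom"] == gene.chrom
            assert got["strand"] == gene.strand
            assert got["exons"] == sorted(gene.exons)
            assert got["cds_genomic"] == gene.cds_genomic_spans()

    def test_chromosome_too_short_raises(self):
        cfg = SimConfig(seed=1, n_genes=40, n_chroms=1, chrom_len=8_000)
        with pytest.raises(SimulationError):
            generate_genome(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(SimulationError):
            SimConfig(intron_len=(20, 100))
        with pytest.raises(SimulationError):
            SimConfig(variant_spec={"exon_skipping": 1.5})


class TestSpawnVariants:
    def test_forced_exon_skipping_removes_internal_exon(self):
        cfg = SimConfig(seed=5, n_genes=1, n_chroms=1, chrom_len=10_000,
                        exons_per_gene=(3, 3))
        gene = generate_genome(cfg).genes[0]
        ref, var = spawn_variants(gene, {"exon_skipping": 1.0}, seed=5)
        assert var.programmed_event == "exon_skipping"
        assert len(var.exons) == 2
        assert sorted(var.exons) == [sorted(gene.exons)[0], sorted(gene.exons)[2]]

    def test_forced_intron_retention_merges_adjacent_exons(self, small_genome):
        gene = small_genome.genes[0]
        ref, var = spawn_variants(gene, {"intron_retention": 1.0}, seed=6)
        assert var.programmed_event == "intron_retention"
        assert len(var.exons) == len(gene.exons) - 1
        merged = set(var.exons) - set(gene.exons)
        assert len(merged) == 1
        (m,) = merged
        inside = [e for e in sorted(gene.exons) if m[0] <= e[0] and e[1] <= m[1]]
        assert len(inside) == 2

    def test_alt_site_variants_keep_canonical_introns(self, small_genome):
        for gene in small_genome.genes:
            for event in ("alt_5ss", "alt_3ss"):
                _, var = spawn_variants(gene, {event: 1.0}, seed=11)
                for d, a in introns_of(var.exons):
                    assert check_splice_consensus(gene.chrom, d, a, gene.strand,
                                                  small_genome), (event, d, a)

    def test_class_frequencies_within_binomial_bounds(self):
        spec = {"exon_skipping": 0.5, "alt_5ss": 0.3, "alt_3ss": 0.2,
                "intron_retention": 0.4}
        cfg = SimConfig(seed=13, n_genes=200, n_chroms=4, chrom_len=200_000)
        genome = generate_genome(cfg)
        counts = dict.fromkeys(EVENT_CLASSES, 0)
        for gene in genome.genes:
            for t in spawn_variants(gene, spec, seed=13)[1:]:
                counts[t.programmed_event] += 1
        n = len(genome.genes)
        for cls, p in spec.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts[cls] <= hi, (cls, counts[cls], (lo, hi))


class TestSimulateEsts:
    def test_error_free_reads_are_prefixes_and_rc_suffixes(self, small_cfg,
                                                           small_genome,
                                                           small_transcripts):
        refs = [t for t in small_transcripts if t.programmed_event == "none"]
        pool = build_clone_pool([t for t in refs], seed=1)
        reads = simulate_ests(pool, small_cfg, small_genome)
        assert reads
        for r in reads:
            t = pool.clones[r.clone_id]
            clone = small_genome.transcript_seq(t.exons, t.chrom, t.strand)
            if r.primer_end == "five_prime" and not r.truncated:
                assert clone.startswith(r.sequence)
            elif r.primer_end == "three_prime":
                assert clone.endswith(revcomp(r.sequence))

    def test_mismatch_count_within_poisson_bounds(self, small_genome,
                                                  small_transcripts):
        cfg = SimConfig(seed=17, error_rate=0.01, read_len=500)
        refs = [t for t in small_transcripts if t.programmed_event == "none"]
        pool = build_clone_pool(list(refs), seed=2)
        clean = simulate_ests(pool, SimConfig(seed=17, read_len=500),
                              small_genome)
        noisy = simulate_ests(pool, cfg, small_genome)
        total = sum(len(r.sequence) for r in clean)
        mismatches = sum(
            sum(a != b for a, b in zip(c.sequence, n.sequence))
            for c, n in zip(clean, noisy))
        lo, hi = stats.poisson.ppf([0.005, 0.995], total * 0.01)
        assert lo <= mismatches <= hi, (mismatches, total)

    def test_short_clone_yields_single_truncated_read(self, small_cfg,
                                                      small_genome,
                                                      small_transcripts):
        cfg = SimConfig(seed=1, read_len=100_000)
        t = small_transcripts[0]
        pool = build_clone_pool([t], seed=3)
        reads = simulate_ests(pool, cfg, small_genome,
                              ends=("five_prime", "three_prime", "internal"))
        assert len(reads) == 1
        assert reads[0].truncated
        assert reads[0].sequence == small_genome.transcript_seq(
            t.exons, t.chrom, t.strand)


class TestReadNaming:
    @pytest.mark.parametrize("end", ["five_prime", "three_prime", "internal"])
    def test_read_id_round_trip(self, end):
        rid = make_read_id("LA0ACA63YE20", end)
        meta = parse_read_id(rid)
        assert meta["clone_id"] == "LA0ACA63YE20"
        assert meta["library"] == "CA"
        assert meta["primer_end"] == end


class TestNormalization:
    def _pool(self, small_transcripts):
        refs = [t for t in small_transcripts if t.programmed_event == "none"]
        return build_clone_pool(list(refs), seed=4, skew=1.5)

    def test_flatten_one_is_identity(self, small_transcripts):
        pool = self._pool(small_transcripts)
        out = emulate_normalization(pool, 1.0)
        for c in pool.abundance:
            assert out.abundance[c] == pytest.approx(pool.abundance[c])

    def test_flatten_to_zero_limit_is_uniform(self, small_transcripts):
        pool = self._pool(small_transcripts)
        out = emulate_normalization(pool, 1e-9)
        n = len(pool.abundance)
        for f in out.abundance.values():
            assert f == pytest.approx(1.0 / n, rel=1e-5)

    def test_diversity_conserved_and_redundancy_reduced(self, small_transcripts):
        pool = self._pool(small_transcripts)
        out = emulate_normalization(pool, 0.25)
        assert set(out.abundance) == set(pool.abundance)
        assert max(out.abundance.values()) < max(pool.abundance.values())

    def test_marker_fold_drop_matches_frequency_ratio(self, small_transcripts):
        from retsplice.expression import fold_drop

        pool = self._pool(small_transcripts)
        marker = max(pool.abundance, key=pool.abundance.get)
        out = emulate_normalization(pool, 0.3)
        drop = fold_drop(pool.abundance[marker], out.abundance[marker])
        # closed form: f^0.3 / Z against f / 1
        z = sum(f ** 0.3 for f in pool.abundance.values())
        expected = pool.abundance[marker] / (pool.abundance[marker] ** 0.3 / z)
        assert drop == pytest.approx(expected)
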