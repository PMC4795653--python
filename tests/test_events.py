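"""Event-classification semantics against planted structures and an
exhaustive brute-force comparator; junction extraction rules."""

import numpy as np
import pytest

from retsplice.events import (ASEvent, check_splice_consensus, classify_events,
                              extract_junctions)
from retsplice.simulate import (SimConfig, generate_genome, spawn_variants)
from retsplice.util import revcomp


# --- independent brute-force comparator -----------------------------------

def brute_force_pair(ex_a, ex_b, strand):
    """Enumerate every interval relation between two exon chains (oracle)."""
    out = set()
    for A, B, an, bn in ((ex_a, ex_b, "A", "B"), (ex_b, ex_a, "B", "A")):
        A, B = sorted(A), sorted(B)
        b_bounds = {x for s, e in A for x in (s, e)}
        b_introns = [(B[i][1], B[i + 1][0]) for i in range(len(B) - 1)]
        for k, (s, e) in enumerate(A):
            internal = 0 < k < len(A) - 1
            for d, a in b_introns:
                if internal and d <= s and e <= a and d in b_bounds and a in b_bounds:
                    out.add(("exon_skipping", (s, e)))
                if s < d and a < e:
                    out.add(("intron_retention", (d, a)))
        all_exons = sorted(ex_a) + sorted(ex_b)
        a_introns = [(A[i][1], A[i + 1][0]) for i in range(len(A) - 1)]
        for d1, a1 in a_introns:
            for d2, a2 in b_introns:
                if a1 == a2 and d1 != d2:
                    iv = (min(d1, d2), max(d1, d2))
                    if not any(iv[0] <= s and e <= iv[1] for s, e in all_exons):
                        out.add(("alt_5ss" if strand == "+" else "alt_3ss", iv))
                if d1 == d2 and a1 != a2:
                    iv = (min(a1, a2), max(a1, a2))
                    if not any(iv[0] <= s and e <= iv[1] for s, e in all_exons):
                        out.add(("alt_3ss" if strand == "+" else "alt_5ss", iv))
    return out


def random_chain(rng, max_exons=6):
    n = int(rng.integers(2, max_exons + 1))
    cuts = np.sort(rng.choice(np.arange(10, 400, 5), size=2 * n, replace=False))
    return [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n)]


class TestClassifyEvents:
    def test_identical_chains_yield_nothing(self):
        ex = [(0, 100), (200, 300), (400, 500)]
        assert classify_events([("a", ex), ("b", list(ex))], "+") == []

    def test_single_transcript_locus_yields_nothing(self):
        assert classify_events([("a", [(0, 100), (200, 300)])], "+") == []

    def test_exon_skipping_detected_with_inclusion_form(self):
        ref = [(0, 100), (200, 300), (400, 500)]
        var = [(0, 100), (400, 500)]
        (e,) = classify_events([("ref", ref), ("var", var)], "+")
        assert e.type == "exon_skipping"
        assert e.interval == (200, 300)
        assert e.transcripts == ("ref", "var")

    def test_multi_exon_skip_emits_one_event_per_exon(self):
        """A variant lacking several consecutive internal exons produces one
        skipping call per lost exon."""
        ref = [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]
        var = [(0, 100), (800, 900)]
        evs = classify_events([("ref", ref), ("var", var)], "+")
        assert sorted(e.interval for e in evs if e.type == "exon_skipping") == \
               [(200, 300), (400, 500), (600, 700)]

    def test_alt_5ss_on_plus_strand_donor_shift(self):
        ref = [(0, 100), (200, 300)]
        var = [(0, 120), (200, 300)]  # donor slides 20 into the intron
        (e,) = classify_events([("ref", ref), ("var", var)], "+")
        assert e.type == "alt_5ss"
        assert e.interval == (100, 120)
        assert e.transcripts == ("var", "ref")

    def test_alt_site_naming_flips_on_minus_strand(self):
        ref = [(0, 100), (200, 300)]
        var = [(0, 120), (200, 300)]
        (e,) = classify_events([("ref", ref), ("var", var)], "-")
        assert e.type == "alt_3ss"

    def test_intron_retention_detected(self):
        ref = [(0, 100), (200, 300)]
        var = [(0, 300)]
        (e,) = classify_events([("ref", ref), ("var", var)], "+")
        assert e.type == "intron_retention"
        assert e.interval == (100, 200)
        assert e.transcripts == ("var", "ref")

    def test_events_deduplicated_across_pairs(self):
        ref = [(0, 100), (200, 300), (400, 500)]
        var = [(0, 100), (400, 500)]
        evs = classify_events([("r1", ref), ("r2", list(ref)), ("v", var)], "+")
        assert len([e for e in evs if e.type == "exon_skipping"]) == 1

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_brute_force_comparator(self, trial):
        rng = np.random.default_rng(900 + trial)
        n_tx = int(rng.integers(2, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        chains = [(f"t{i}", random_chain(rng)) for i in range(n_tx)]
        got = {(e.type, e.interval)
               for e in classify_events(chains, strand)}
        expected = set()
        for i in range(n_tx):
            for j in range(i + 1, n_tx):
                expected |= brute_force_pair(chains[i][1], chains[j][1], strand)
        assert got == expected

    def test_planted_classes_all_recalled(self):
        cfg = SimConfig(seed=77, n_genes=25, n_chroms=2, chrom_len=120_000)
        genome = generate_genome(cfg)
        spec = {c: 1.0 for c in ("exon_skipping", "alt_5ss", "alt_3ss",
                                 "intron_retention")}
        for gene in genome.genes:
            txs = spawn_variants(gene, spec, seed=77)
            evs = classify_events(
                [(t.transcript_id, sorted(t.exons)) for t in txs],
                gene.strand, genome=genome, chrom=gene.chrom)
            types = {e.type for e in evs}
            planted = {t.programmed_event for t in txs[1:]}
            assert planted <= types, (gene.gene_id, planted, types)


class TestSpliceConsensus:
    def test_planted_canonical_intron_true(self, small_genome):
        gene = small_genome.genes[0]
        ex = sorted(gene.exons)
        assert check_splice_consensus(gene.chrom, ex[0][1], ex[1][0],
                                      gene.strand, small_genome)

    def test_gc_ag_intron_false(self, small_genome):
        import copy

        g2 = copy.deepcopy(small_genome)
        gene = next(g for g in g2.genes if g.strand == "+")
        ex = sorted(gene.exons)
        d = ex[0][1]
        s = g2.chroms[gene.chrom]
        g2.chroms[gene.chrom] = s[:d] + "GC" + s[d + 2:]
        assert not check_splice_consensus(gene.chrom, d, ex[1][0], "+", g2)

    def test_minus_strand_reverse_complement_oracle(self, small_genome):
        """A minus-strand canonical intron shows CT..AC on the top strand."""
        gene = next(g for g in small_genome.genes if g.strand == "-")
        ex = sorted(gene.exons)
        d, a = ex[0][1], ex[1][0]
        top = small_genome.chroms[gene.chrom][d:a]
        assert top.startswith("CT") and top.endswith("AC")
        assert revcomp(top).startswith("GT") and revcomp(top).endswith("AG")
        assert check_splice_consensus(gene.chrom, d, a, "-", small_genome)


class TestExtractJunctions:
    def _genome_with(self, chrom_seq, genes):
        from retsplice.simulate import AnnotatedGenome

        return AnnotatedGenome(chroms={"chr1": chrom_seq}, genes=genes)

    def test_two_exon_construction(self, rng):
        from retsplice.util import random_dna

        seq = random_dna(rng, 600)
        g = self._genome_with(seq, [])
        entry = {"transcript_id": "t", "chrom": "chr1", "strand": "+",
                 "exons": [(10, 90), (200, 280)], "cds": (0, 160)}
        (j,) = extract_junctions([entry], g, exclude_utr=False)
        assert len(j.seq100) == 100
        # bases 31-80 of exon1 (1-based) + bases 1-50 of exon2
        assert j.seq100 == seq[40:90] + seq[200:250]
        assert (j.donor_pos, j.acceptor_pos) == (90, 200)

    def test_utr_overlapping_flank_excluded(self, rng):
        from retsplice.util import random_dna

        seq = random_dna(rng, 900)
        g = self._genome_with(seq, [])
        # 3 exons of 80; CDS covers exon2 only -> both junctions touch a UTR
        entry = {"transcript_id": "t", "chrom": "chr1", "strand": "+",
                 "exons": [(10, 90), (200, 280), (400, 480)], "cds": (80, 160)}
        assert extract_junctions([entry], g) == []
        # CDS covering everything -> both junctions kept
        entry["cds"] = (0, 240)
        assert len(extract_junctions([entry], g)) == 2

    def test_junction_mode_keeps_cds_distal_junctions(self, rng):
        """Under the junction-footprint reading, a junction 50+ coding bases
        away from the UTR survives even if its exon touches the UTR."""
        from retsplice.util import random_dna

        seq = random_dna(rng, 900)
        g = self._genome_with(seq, [])
        entry = {"transcript_id": "t", "chrom": "chr1", "strand": "+",
                 "exons": [(10, 130), (200, 320)], "cds": (60, 240)}
        assert extract_junctions([entry], g, utr_mode="exon") == []
        assert len(extract_junctions([entry], g, utr_mode="junction")) == 1

    def test_short_flank_exon_excluded(self, rng):
        from retsplice.util import random_dna

        seq = random_dna(rng, 900)
        g = self._genome_with(seq, [])
        entry = {"transcript_id": "t", "chrom": "chr1", "strand": "+",
                 "exons": [(10, 90), (200, 240), (400, 480)], "cds": (0, 200)}
        assert extract_junctions([entry], g, exclude_utr=False) == []

    def test_deduplication_by_coordinates(self, small_genome):
        entries = []
        for gene in small_genome.genes:
            for _ in range(2):  # same transcript twice
                entries.append({"transcript_id": f"{gene.gene_id}.ref",
                                "chrom": gene.chrom, "strand": gene.strand,
                                "exons": gene.exons, "cds": gene.cds})
        js = extract_junctions(entries, small_genome, exclude_utr=False)
        keys = {(j.chrom, j.strand, j.donor_pos, j.acceptor_pos) for j in js}
        assert len(keys) == len(js)

    def test_strand_consistency_under_genome_reversal(self, small_genome):
        """Reverse-complementing the genome and flipping coordinates yields
        reverse-complemented junction sequences."""
        import copy

        fwd_entries = [{"transcript_id": g.gene_id, "chrom": g.chrom,
                        "strand": g.strand, "exons": g.exons, "cds": g.cds}
                       for g in small_genome.genes]
        fwd = extract_junctions(fwd_entries, small_genome, exclude_utr=False)

        flipped = copy.deepcopy(small_genome)
        flipped.chroms = {c: revcomp(s) for c, s in flipped.chroms.items()}
        rev_entries = []
        for g in small_genome.genes:
            L = len(small_genome.chroms[g.chrom])
            rev_entries.append({
                "transcript_id": g.gene_id, "chrom": g.chrom,
                "strand": "-" if g.strand == "+" else "+",
                "exons": sorted((L - e, L - s) for s, e in g.exons),
                "cds": g.cds})
        rev = extract_junctions(rev_entries, flipped, exclude_utr=False)
        assert sorted(j.seq100 for j in fwd) == sorted(j.seq100 for j in rev)
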