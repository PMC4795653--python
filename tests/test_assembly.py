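"""Assembler contracts: overlap detection against a brute-force oracle,
read conservation, error-free reconstruction and clone status calls."""

import numpy as np
import pytest

from retsplice.assembly import (assemble, classify_clones, pairwise_overlap)
from retsplice.simulate import (ESTRead, SimConfig, build_clone_pool,
                                generate_genome, simulate_ests, spawn_variants)
from retsplice.util import random_dna, revcomp


def brute_force_overlap(a, b, min_len, min_ident):
    """Exhaustive suffix-prefix scan in both orientations (oracle)."""
    best = None
    for orient, bb in (("same", b), ("reverse", revcomp(b))):
        for L in range(min_len, min(len(a), len(b)) + 1):
            mism = sum(x != y for x, y in zip(a[-L:], bb[:L]))
            if 1 - mism / L >= min_ident and (best is None or L > best[0]):
                best = (L, orient)
    return best


class TestPairwiseOverlap:
    def test_identical_sequences_fully_overlap(self, rng):
        s = random_dna(rng, 120)
        r = pairwise_overlap(s, s)
        assert r.overlap_len == 120 and r.identity == 1.0

    def test_planted_60_base_overlap_matches_brute_force(self, rng):
        shared = random_dna(rng, 60)
        a = random_dna(rng, 140) + shared
        b = shared + random_dna(rng, 140)
        r = pairwise_overlap(a, b, min_len=40)
        oracle = brute_force_overlap(a, b, 40, 0.95)
        assert r is not None and oracle is not None
        assert (r.overlap_len, r.orientation) == oracle
        assert r.overlap_len == 60

    def test_disjoint_sequences_yield_none(self, rng):
        a, b = random_dna(rng, 200), random_dna(rng, 200)
        assert brute_force_overlap(a, b, 40, 0.95) is None
        assert pairwise_overlap(a, b) is None

    def test_reverse_orientation_detected(self, rng):
        shared = random_dna(rng, 80)
        a = random_dna(rng, 100) + shared
        b = revcomp(shared + random_dna(rng, 100))
        r = pairwise_overlap(a, b)
        assert r.orientation == "reverse" and r.overlap_len == 80

    @pytest.mark.parametrize("trial", range(10))
    def test_random_pairs_agree_with_brute_force(self, trial):
        rng = np.random.default_rng(500 + trial)
        ov = int(rng.integers(0, 90))
        core = random_dna(rng, ov)
        a = random_dna(rng, int(rng.integers(60, 150))) + core
        b = core + random_dna(rng, int(rng.integers(60, 150)))
        got = pairwise_overlap(a, b, min_len=40)
        oracle = brute_force_overlap(a, b, 40, 0.95)
        if oracle is None:
            assert got is None
        else:
            assert got.overlap_len == oracle[0]


def _reads_for(genome, transcripts, cfg, ends=("five_prime", "three_prime",
                                               "internal")):
    pool = build_clone_pool(list(transcripts), seed=42)
    return pool, simulate_ests(pool, cfg, genome, ends=ends)


class TestAssemble:
    def test_single_read_single_contig(self, rng):
        r = ESTRead("LA0AAA1YA01CM1", "LA0AAA1YA01", "five_prime",
                    random_dna(rng, 300))
        (c,) = assemble([r])
        assert c.consensus == r.sequence and c.clone_id == "LA0AAA1YA01"

    def test_error_free_tiling_reconstructs_clone(self):
        cfg = SimConfig(seed=21, n_genes=1, n_chroms=1, chrom_len=15_000,
                        exons_per_gene=(6, 6), read_len=500)
        genome = generate_genome(cfg)
        t = spawn_variants(genome.genes[0], {}, seed=21)[0]
        truth = genome.transcript_seq(t.exons, t.chrom, t.strand)
        pool, reads = _reads_for(genome, [t], cfg)
        contigs = assemble(reads)
        assert len(contigs) == 1
        assert contigs[0].consensus == truth

    def test_two_unrelated_clones_stay_separate(self):
        cfg = SimConfig(seed=22, n_genes=2, n_chroms=1, chrom_len=20_000,
                        read_len=500)
        genome = generate_genome(cfg)
        txs = [spawn_variants(g, {}, seed=22)[0] for g in genome.genes]
        pool, reads = _reads_for(genome, txs, cfg)
        contigs = assemble(reads)
        assert len(contigs) == 2
        assert {c.clone_id for c in contigs} == set(pool.clones)

    def test_read_conservation_and_idempotence(self, small_cfg, small_genome,
                                               small_transcripts):
        refs = [t for t in small_transcripts if t.programmed_event == "none"]
        pool, reads = _reads_for(small_genome, refs, small_cfg)
        contigs = assemble(reads)
        assert sum(len(c.members) for c in contigs) == len(reads)
        again = assemble([
            ESTRead(c.contig_id + "CM1", c.clone_id or c.contig_id,
                    "five_prime", c.consensus)
            for c in contigs
        ])
        assert sorted(c.consensus for c in again) == \
               sorted(c.consensus for c in contigs)


class TestClassifyClones:
    def _setup(self, seed, ends):
        cfg = SimConfig(seed=seed, n_genes=6, n_chroms=2, chrom_len=40_000,
                        read_len=600)
        genome = generate_genome(cfg)
        txs = [spawn_variants(g, {}, seed=seed)[0] for g in genome.genes]
        pool, reads = _reads_for(genome, txs, cfg, ends=ends)
        return pool, reads, assemble(reads)

    def test_five_prime_only(self):
        pool, reads, contigs = self._setup(31, ("five_prime",))
        clones, counts = classify_clones(contigs, reads)
        assert counts["five_prime_only"] == len(pool.clones)

    def test_end_joined_clones_counted(self):
        pool, reads, contigs = self._setup(32, ("five_prime", "three_prime",
                                                "internal"))
        clones, counts = classify_clones(contigs, reads)
        joined = counts["pairwise_assembled"] + counts["fully_sequenced"]
        assert joined == len(pool.clones)
        # direct 5'/3' overlap only when the clone is short enough
        for c in clones:
            t = pool.clones[c.clone_id]
            clone_len = sum(e - s for s, e in t.exons)
            if c.status == "pairwise_assembled":
                assert clone_len < 2 * 600
            elif c.status == "fully_sequenced":
                assert clone_len >= 2 * 600

    def test_planted_bridging_truth(self):
        """Only clones given 3' reads can be end-joined."""
        cfg = SimConfig(seed=33, n_genes=8, n_chroms=2, chrom_len=60_000,
                        read_len=600)
        genome = generate_genome(cfg)
        txs = [spawn_variants(g, {}, seed=33)[0] for g in genome.genes]
        pool = build_clone_pool(txs, seed=33)
        with_3p = sorted(pool.clones)[:5]
        reads = []
        for r in simulate_ests(pool, cfg, genome,
                               ends=("five_prime", "three_prime", "internal")):
            if r.primer_end == "five_prime" or r.clone_id in with_3p:
                reads.append(r)
        clones, counts = classify_clones(assemble(reads), reads)
        joined = {c.clone_id for c in clones
                  if c.status in ("pairwise_assembled", "fully_sequenced")}
        assert joined == set(with_3p)

    def test_chimeric_contig_excluded(self, rng):
        shared = random_dna(rng, 80)
        reads = [
            ESTRead("LA0AAA1YA01CM1", "LA0AAA1YA01", "five_prime",
                    random_dna(rng, 200) + shared),
            ESTRead("LA0AAA1YA02CM1", "LA0AAA1YA02", "five_prime",
                    shared + random_dna(rng, 200)),
        ]
        clones, counts = classify_clones(assemble(reads), reads)
        assert counts["chimeric"] == 2
        assert not clones
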