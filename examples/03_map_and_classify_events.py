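"""Map cDNAs onto the genome, cluster them into loci and classify the
alternative-splice events, then compare against the planted truth."""

from collections import Counter

from retsplice import (GenomeIndex, SimConfig, classify_events, cluster_loci,
                       generate_genome, refine_splice_sites, seed_and_chain,
                       spawn_variants)

cfg = SimConfig(seed=11, n_genes=20, n_chroms=2, chrom_len=100_000)
genome = generate_genome(cfg)
transcripts = []
for gene in genome.genes:
    transcripts.extend(spawn_variants(gene, cfg.variant_spec, seed=cfg.seed))

index = GenomeIndex(genome)
alignments = []
for t in transcripts:
    cdna = genome.transcript_seq(t.exons, t.chrom, t.strand)
    aln = seed_and_chain(cdna, index, query_id=t.transcript_id)
    alignments.append(refine_splice_sites(aln, genome))

loci = cluster_loci(alignments, min_shared=100)
events = []
for locus in loci:
    events.extend(classify_events(
        [(a.query_id, a.exons()) for a in locus.members], locus.strand,
        locus_id=locus.locus_id, genome=genome, chrom=locus.chrom))

planted = Counter(t.programmed_event for t in transcripts
                  if t.programmed_event != "none")
called = Counter(e.type for e in events)
print(f"{len(alignments)} cDNAs -> {len(loci)} loci "
      f"(truth: {len(genome.genes)} genes)")
print(f"{'event class':18s} {'planted':>8s} {'called':>8s}")
for cls in ("exon_skipping", "alt_5ss", "alt_3ss", "intron_retention"):
    print(f"{cls:18s} {planted[cls]:8d} {called[cls]:8d}")
print("all splice sites canonical:",
      all(e.consensus_ok for e in events))
# Called counts can exceed planted counts: comparing every transcript pair at
# a locus also reports events between two variants of the same gene.
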