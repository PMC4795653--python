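# Methods

This note records the models, parameter choices and numerical conventions
behind `retsplice`, and what the synthetic data do and do not emulate.

## Coordinates and conventions

All genomic coordinates are 0-based, half-open intervals on the top strand;
they become 1-based closed intervals only at GFF3 export.  Transcript-level
sequence operations (CDS planting, junction windows, reads) are done on the
sense strand; minus-strand genes are fully supported and exercised by the
generator (each gene's strand is drawn with probability 0.5).  A gene's
`cds` is stored in transcript coordinates and includes the stop codon
(GFF3-style); the ORF predictor reports the coding span without the stop.

## Synthetic libraries

The generator emulates the statistical structure a splice-variant survey
assumes, not retinal biology:

* **Gene models.** Per gene: 4–8 exons of 120–300 nt separated by introns of
  80–300 nt (minimum configurable down to 40 nt, the spliced aligner's
  intron/deletion boundary), UTRs of 30–100 nt confined to the terminal
  exons so internal exons are fully coding.  Intergenic gaps of 200–500 nt
  keep loci separable under the 100-shared-nucleotide clustering rule.
  Base composition is uniform i.i.d.; no isochores, repeats or codon bias.
* **Coding regions.** Each transcript gets a planted ORF: ATG start, clean
  in-frame interior, terminal stop, and a stop codon immediately upstream of
  the ATG so the true start is the first ATG of its frame segment.  With
  ~100+ coding codons against UTRs an order of magnitude shorter, the
  planted ORF outscores random open stretches at the generator's scales.
* **Splice sites.** Every intron is GT..AG on the transcript strand.  Each
  intron also carries one planted alternative donor (GT) and one alternative
  acceptor (AG) 4–20 nt inside, so alternate-splice-site variants always
  land on a canonical junction, as real splice-site selection would.
* **Programmed variants.** Each of the four event classes is realized per
  gene by an independent Bernoulli draw of its configured probability
  (defaults 0.5 each), so per-class frequencies are binomial across genes.
  Exon skipping removes one internal exon; intron retention merges two
  adjacent exons across their intron; alternate 5'/3' sites extend an exon
  into the intron to the planted site.  One event per variant transcript;
  compound variants are not generated (the classifier still reports compound
  patterns as their constituent pairwise events).
* **EST reads.** 5' reads are clone prefixes, 3' reads reverse-complemented
  suffixes (default 600 nt, the order of a Sanger pass), internal reads tile
  the middle with 100 nt overlap.  Errors are uniform substitutions at
  `error_rate` (default 0 — the property suites assert exact recovery, which
  only makes sense on error-free input); no quality values, chimeras or
  vector contamination.  Read names follow the library scheme
  `LA0<set><lib><plate>Y<well><primer>` and parse back to (library, clone,
  primer end).
* **Normalization.** Biochemical normalization is emulated as a power-law
  flattening of clone frequencies (`f ∝ f^flatten`, `flatten ∈ (0,1]`).
  This reproduces the defining observable — redundancy (the marker clone's
  fold drop) falls while diversity is conserved — but is not a model of
  hybridization kinetics.
* **Sister species.** A second genome shares a configurable fraction of
  genes.  Conserved genes keep their structure; each 100-base junction
  window receives 0–5 substitutions, scattered at most one per 20-nt
  stretch.  Scattering is deliberate: with +1/−3 scoring a 5-substitution
  cluster at a window edge truncates the optimal ungapped segment below the
  90-base hit-length threshold, which would mislabel a conserved junction at
  the generator level.  Scattered divergence keeps the planted labels
  decidable: a conserved junction's full-length hit scores ≥ 80
  (E ≈ 10⁻⁴¹ at desk-scale database sizes, below the 10⁻⁴⁰ cutoff), while
  unrelated random 100-mers never reach the conjunctive criterion.

Because the generator is this clean, passing property suites demonstrate
correctness of the operations, not robustness to real EST artifacts
(paralogy, genomic contamination, low-complexity sequence, indel errors).

## Assembly

Overlaps are ungapped; "significant overlap" is quantified as ≥ 40 bases at
≥ 95% identity (both configurable) — a deterministic proxy for
quality-weighted assembly scores, which are not reproduced.  Candidate
placements come from shared 14-mers (handling dovetail and containment
alike); `pairwise_overlap` itself scans every suffix-prefix length
exhaustively and is the contract the tests check against brute force.
Merging is greedy by (overlap length, identity) with ties broken on the
lexicographically smallest member read ids; consensus is per-column majority
vote with ties resolved to the earliest-merged read.  A clone is
*pairwise assembled* when its 5' and 3' reads overlap directly in one
contig, *fully sequenced* when they are joined only through internal reads;
contigs mixing clones are flagged chimeric and those clones excluded from
counts.  In the orchestrated pipeline the assembly stage runs on a
one-clone-per-gene pool: single-event variants are locally identical to
their reference, so a quality-blind assembler merges their reads into one
contig, which the chimera rule would then exclude and confound the status
counts.  Variant cDNAs enter the mapping/event stages directly.

## Spliced alignment

Exact k-mer seeds (k = 12) are merged into maximal runs per diagonal and
chained by an O(n²) DP maximizing covered query bases (tiny per-gap penalty
as tie-break; genomic gaps capped at 5 kb).  Genomic gaps ≥ 40 nt are
introns; smaller gaps are alignment indels; equal-size gaps on both axes are
substitution runs inside one block.  Unseeded query ends are recovered by
free end extension while bases match.  Each intron boundary is then slid
within ±10 nt to maximize matched bases plus a GT..AG bonus (default 1.0:
canonical placement wins all ties and single-match deficits; among equal
scores the smallest shift, then the leftmost, is taken).  Non-canonical
introns are kept and flagged.  Only the best chain per cDNA is kept (one
locus per clone).  Loci are single-linkage components under ≥ 100 shared
genomic bases, per chromosome and strand; an annotation-guided clustering
mode is deliberately not implemented (mutual overlap is the documented
reading).

## Event classification

Events are detected per transcript pair and deduplicated by (type, genomic
interval) within the locus — the counting unit is a distinct event, not a
supporting clone pair.  Rules: *exon skipping* — an internal exon of one
transcript lies wholly inside an intron of the other with both flanking
junctions shared; *intron retention* — an exon spans an entire intron of the
other transcript plus parts of both flanking exons; *alternate 5'/3' splice
site* — two introns share exactly one boundary, with donor = 5' side on the
transcript strand, and the differing stretch containing no complete exon of
either transcript (that situation is skipping, not an alternate site — the
suppression keeps the two classes disjoint).  The `consensus_ok` flag checks
GT..AG on the exclusion form's smallest intron containing the event
interval.  An exhaustive brute-force comparator (independent enumeration of
all interval relations) is part of the test suite.

## Junctions and specificity

A junction's sequence is the last 50 transcribed bases of the upstream exon
plus the first 50 of the downstream exon; junctions flanked by an exon
shorter than 50 transcribed bases are dropped rather than padded (every
exported sequence is exactly 100 nt).  UTR exclusion defaults to the
exon-overlap reading (drop the junction if either flanking exon overlaps a
UTR); the junction-footprint reading is available as `utr_mode="junction"`.
Junctions are deduplicated by (chromosome, strand, intron start, intron
end); `donor_pos < acceptor_pos` always holds on the genome, so on the minus
strand the biological donor sits at `acceptor_pos`.

The search is word-seeded (default word size 8, no masking or
low-complexity filtering), with ungapped bidirectional extension (X-drop 20)
on both query strands and the best hit kept per query/subject pair.
Scoring defaults to +1/−3.  E = K·m·n'·e^(−λS) with m the query length and
n' the summed subject length; edge corrections are omitted — at 100-base
scale they change nothing at the 10⁻⁴⁰ threshold.  λ solves the
moment-generating-function root to |residual| < 10⁻⁹ (scipy brentq); K uses
the standard ungapped lattice series truncated when terms fall below 10⁻¹²,
with lattice span the gcd of the attainable score values.  Both parameters
match NCBI blastn's printed ungapped (λ, K) for +1/−3, +1/−2 and +1/−1, and
a live blastn cross-check is in the test suite.  Gapped statistics are out
of scope: near-identical 100-base junction matching is dominated by
ungapped alignment, which is the documented approximation.  "Longer than
90" and "below 10⁻⁴⁰" are strict inequalities and conjunctive.

## ORF prediction and variant arithmetic

The "best ORF" contract is scored as length in codons + 50 if the frame
segment starts with ATG + 25 if it ends at a stop; the exact weighting of
the historical picker is unrecoverable, so the bonuses are declared, tunable
proxies chosen so that a complete CDS beats any stopless stretch up to 75
codons longer.  Only forward frames are scanned by default (oligo-dT primed,
orientation-known cDNA); a six-frame mode exists.  `CDS complete` ⇔ ATG and
stop both present.  Protein differences are minimal indel decompositions
from a global alignment (match +1, mismatch −10, gap open −2, extend −0.5 —
mismatches are effectively forbidden so substitution runs decompose into
indel pairs); applying the reported edits to the reference reproduces the
variant exactly, which is asserted property-style.  Where an indel sits in a
repeat, the alignment places it deterministically but the reported position
may be any equivalent placement.  Amplicon lengths are inclusive of both
primers; all binding sites are reported.

## Candidate funnel

GO filtering is lexical (case-insensitive substring), not ontology
traversal.  "Variants within the protein sequence" means variants whose
coding-region exon chains differ (UTR-only differences do not count);
"clones including the translation initiation" counts clones on variants
with an ATG or a complete CDS — a complete CDS contains its start, and the
published catalog's flags are only mutually consistent under this reading.
The packaged six-gene catalog carries the printed ATG/CDS flags plus one
extra entry encoding the source catalog's own footnote (initiation-codon
variants found but not matching the reference); its `note` column marks it.
Full-length-only variant filtering is exposed via the assembly-status input
rather than a separate toggle.

## Determinism and problem sizes

Every stochastic operation draws from a child of one root seed
(`numpy` `SeedSequence` spawning), and the pipeline manifest records SHA-256
digests of all outputs; re-running an identical configuration reproduces
identical digests.  The shipped property suites run at the package's chosen
desk scales — 100 loci across four chromosomes for event recall and
boundary exactness, ~280 genes per species (≈ 2,400 junctions) for
two-species specificity, 1,000 random 300-mers for the ORF-score bound —
sizes at which every planted structure is still individually checkable
against truth.

## Known limitations

* The assembler is ungapped and quality-blind; it cannot separate
  transcripts that differ only outside the sequenced ends, and indel
  sequencing errors would break its overlap model.
* The spliced aligner assumes mostly-exact matches (substitution errors
  only); it has no affine gap model inside blocks and keeps a single best
  chain, so paralogous multi-mapping is unmodeled.
* Junction specificity uses ungapped statistics with default-composition
  backgrounds; strongly biased base composition would shift λ and K.
* The funnel's GO matching is string-based by design and inherits the
  annotation's vocabulary.
* qPCR arithmetic assumes perfect doubling per cycle (no efficiency
  calibration) and averages replicates before Δ computation.
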