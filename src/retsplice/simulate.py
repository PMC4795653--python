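"""Synthetic normalized cDNA libraries with programmed splice variants.

The generator emulates the inputs of an EST-based splice-variant survey:
multi-exon gene models with canonical GT..AG introns on either strand, a
planted coding region per gene, programmed variants of the four classic
alternative-splicing classes, single-pass 5'/3'/internal-primer reads with
substitution errors and library-style clone naming, and a redundancy profile
that can be flattened to mimic biochemical library normalization.

Every intron additionally carries one planted alternative donor (GT) and one
planted alternative acceptor (AG) site, so alternate-splice-site variants
always land on a canonical junction, as they would after real splice-site
selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .util import STOP_CODONS, random_dna, revcomp, spawn_rng

EVENT_CLASSES = ("exon_skipping", "alt_5ss", "alt_3ss", "intron_retention")

#: Small GO vocabulary used for annotation; contains the two terms the
#: candidate funnel filters on ("transcription", "eye") among decoys.
GO_VOCAB = (
    "regulation of transcription, DNA-templated",
    "transcription factor activity",
    "eye development",
    "visual perception",
    "signal transduction",
    "lipid metabolic process",
    "cell adhesion",
    "ion transport",
)


class SimulationError(ValueError):
    """Raised when the requested structure does not fit the configuration."""


@dataclass
class SimConfig:
    """Study conditions for one simulated library/genome.

    Lengths are in bases; ranges are inclusive (lo, hi) pairs.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 120_000
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (80, 300)
    utr_len: tuple[int, int] = (30, 100)
    intergene_gap: tuple[int, int] = (200, 500)
    variant_spec: dict[str, float] = field(
        default_factory=lambda: {c: 0.5 for c in EVENT_CLASSES}
    )
    est_per_clone: int = 1
    read_len: int = 600
    error_rate: float = 0.0
    library_labels: tuple[str, ...] = ("AA", "CA")
    go_transcription_prob: float = 0.5
    go_eye_prob: float = 0.3
    minus_strand_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "utr_len",
                     "intergene_gap"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SimulationError(f"{name} must be a positive (lo, hi) range")
        if self.intron_len[0] < 40:
            raise SimulationError("minimum intron length must be >= 40")
        if self.exons_per_gene[0] < 2:
            raise SimulationError("genes need at least 2 exons")
        for cls, p in self.variant_spec.items():
            if cls not in EVENT_CLASSES:
                raise SimulationError(f"unknown event class {cls!r}")
            if not 0.0 <= p <= 1.0:
                raise SimulationError("variant probabilities must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError("error_rate must lie in [0, 1)")
        if self.utr_len[1] >= self.exon_len[0]:
            raise SimulationError("UTRs must be shorter than the shortest exon "
                                  "so internal exons stay fully coding")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]          # genomic, sorted, non-overlapping
    cds: tuple[int, int]                  # transcript coords, includes stop codon
    go_terms: set[str] = field(default_factory=set)
    # Planted alternative splice sites, keyed by sense intron index:
    # shift in bases by which the donor (resp. acceptor) may move into the
    # intron while staying canonical.
    alt_donor: dict[int, int] = field(default_factory=dict)
    alt_acceptor: dict[int, int] = field(default_factory=dict)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sense_exons(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_genomic_spans(self) -> list[tuple[int, int]]:
        """Genomic intervals covered by the CDS (for GFF3 export)."""
        spans = []
        pos = 0
        for s, e in self.sense_exons():
            length = e - s
            lo = max(self.cds[0], pos)
            hi = min(self.cds[1], pos + length)
            if lo < hi:
                if self.strand == "+":
                    spans.append((s + (lo - pos), s + (hi - pos)))
                else:
                    spans.append((e - (hi - pos), e - (lo - pos)))
            pos += length
        return sorted(spans)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    programmed_event: str = "none"
    clone_ids: list[str] = field(default_factory=list)


@dataclass
class ESTRead:
    read_id: str
    clone_id: str
    primer_end: str                       # five_prime | three_prime | internal
    sequence: str
    truncated: bool = False


@dataclass
class ClonePool:
    clones: dict[str, TranscriptModel]
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if not np.isclose(total, 1.0):
            raise SimulationError("clone frequencies must sum to 1")
        if set(self.clones) != set(self.abundance):
            raise SimulationError("clones and abundance must share keys")


@dataclass
class AnnotatedGenome:
    chroms: dict[str, str]
    genes: list[GeneModel]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript_seq(self, exons: list[tuple[int, int]], chrom: str, strand: str) -> str:
        seq = "".join(self.chroms[chrom][s:e] for s, e in sorted(exons))
        return seq if strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _safe_codon(rng: np.random.Generator) -> str:
    while True:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS:
            return c


def _plant_cds(tx: list[str], cds_start: int, cds_end: int, rng: np.random.Generator) -> None:
    """Rewrite a transcript in place so [cds_start, cds_end) is a clean ORF.

    Plants ATG..stop, removes in-frame internal stops, and puts a stop codon
    immediately upstream of the ATG so the ORF finder's frame segment starts
    exactly at the true start codon.
    """
    tx[cds_start:cds_start + 3] = "ATG"
    tx[cds_end - 3:cds_end] = "TAA"
    for p in range(cds_start + 3, cds_end - 3, 3):
        if "".join(tx[p:p + 3]) in STOP_CODONS:
            tx[p:p + 3] = _safe_codon(rng)
    if cds_start >= 3:
        tx[cds_start - 3:cds_start] = "TAA"


def _build_gene(cfg: SimConfig, rng: np.random.Generator, gene_id: str,
                chrom: str, offset: int, strand: str) -> tuple[GeneModel, str]:
    """Generate one gene; returns the model plus its genomic region sequence."""
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                 for _ in range(n_exons)]
    intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                   for _ in range(n_exons - 1)]
    tx_len = sum(exon_lens)

    utr5 = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
    utr3 = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
    cds_start, cds_end = utr5, tx_len - utr3
    cds_end -= (cds_end - cds_start) % 3
    if cds_end - cds_start < 9:
        raise SimulationError(f"{gene_id}: transcript too short for a CDS")

    tx = list(random_dna(rng, tx_len))
    _plant_cds(tx, cds_start, cds_end, rng)

    # slice the transcript into exon contents; build introns with canonical
    # ends plus one planted alternative donor and acceptor each
    exon_seqs, pos = [], 0
    for L in exon_lens:
        exon_seqs.append("".join(tx[pos:pos + L]))
        pos += L
    alt_donor, alt_acceptor = {}, {}
    intron_seqs = []
    for j, L in enumerate(intron_lens):
        intron = list(random_dna(rng, L))
        intron[0:2] = "GT"
        intron[L - 2:L] = "AG"
        max_shift = min(20, (L - 44) // 2)
        d = int(rng.integers(4, max(5, max_shift + 1)))
        a = int(rng.integers(4, max(5, max_shift + 1)))
        intron[d:d + 2] = "GT"          # alternative donor: shift d into intron
        intron[L - 2 - a:L - a] = "AG"  # alternative acceptor: shift a upstream
        alt_donor[j], alt_acceptor[j] = d, a
        intron_seqs.append("".join(intron))

    sense_region = "".join(
        exon_seqs[i] + (intron_seqs[i] if i < len(intron_seqs) else "")
        for i in range(n_exons)
    )
    region_len = len(sense_region)

    # sense-coordinate exon offsets within the region
    sense_spans, pos = [], 0
    for i, L in enumerate(exon_lens):
        sense_spans.append((pos, pos + L))
        pos += L + (intron_lens[i] if i < len(intron_lens) else 0)

    if strand == "+":
        region = sense_region
        exons = [(offset + s, offset + e) for s, e in sense_spans]
    else:
        region = revcomp(sense_region)
        exons = sorted(
            (offset + region_len - e, offset + region_len - s) for s, e in sense_spans
        )

    go: set[str] = set()
    if rng.random() < cfg.go_transcription_prob:
        go.add("regulation of transcription, DNA-templated")
        if rng.random() < 0.5:
            go.add("transcription factor activity")
    if rng.random() < cfg.go_eye_prob:
        go.add(str(rng.choice(["eye development", "visual perception"])))
    n_extra = int(rng.integers(0, 3))
    for t in rng.choice(GO_VOCAB[4:], size=n_extra, replace=False):
        go.add(str(t))

    gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons,
                     cds=(cds_start, cds_end), go_terms=go,
                     alt_donor=alt_donor, alt_acceptor=alt_acceptor)
    return gene, region


def generate_genome(cfg: SimConfig) -> AnnotatedGenome:
    """Generate chromosomes plus gene models; deterministic under cfg.seed."""
    rng = spawn_rng(cfg.seed, 1)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cursors = {c: 0 for c in chrom_names}
    parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    genes: list[GeneModel] = []

    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi % cfg.n_chroms]
        gap = int(rng.integers(cfg.intergene_gap[0], cfg.intergene_gap[1] + 1))
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        offset = cursors[chrom] + gap
        gene, region = _build_gene(cfg, rng, f"G{gi + 1:04d}", chrom, offset, strand)
        if offset + len(region) > cfg.chrom_len:
            raise SimulationError(
                f"chromosome {chrom} too short for {cfg.n_genes} genes of the "
                f"requested structure (needed > {offset + len(region)} bases)")
        parts[chrom].append(random_dna(rng, gap))
        parts[chrom].append(region)
        cursors[chrom] = offset + len(region)
        genes.append(gene)

    chroms = {}
    for c in chrom_names:
        tail = cfg.chrom_len - cursors[c]
        chroms[c] = "".join(parts[c]) + random_dna(rng, tail)
    return AnnotatedGenome(chroms=chroms, genes=genes)


# ---------------------------------------------------------------------------
# programmed splice variants
# ---------------------------------------------------------------------------

def _sense_order(exons: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    exons = sorted(exons)
    return exons if strand == "+" else list(reversed(exons))


def _apply_event(gene: GeneModel, event: str, rng: np.random.Generator
                 ) -> list[tuple[int, int]]:
    """Edit the gene's exon chain (genomic coords) to realize one event."""
    sense = _sense_order(gene.exons, gene.strand)
    n = len(sense)
    if event == "exon_skipping":
        if n < 3:
            raise SimulationError(f"{gene.gene_id}: exon skipping needs >= 3 exons")
        drop = int(rng.integers(1, n - 1))
        chain = [ex for i, ex in enumerate(sense) if i != drop]
    elif event == "intron_retention":
        j = int(rng.integers(0, n - 1))
        a, b = sense[j], sense[j + 1]
        merged = (min(a[0], b[0]), max(a[1], b[1]))
        chain = sense[:j] + [merged] + sense[j + 2:]
    elif event == "alt_5ss":
        j = int(rng.integers(0, n - 1))
        d = gene.alt_donor[j]
        s, e = sense[j]
        # donor moves d bases into the intron: sense exon j grows at its 3' end
        sense = list(sense)
        sense[j] = (s, e + d) if gene.strand == "+" else (s - d, e)
        chain = sense
    elif event == "alt_3ss":
        j = int(rng.integers(0, n - 1))
        a = gene.alt_acceptor[j]
        s, e = sense[j + 1]
        # acceptor moves a bases into the intron: sense exon j+1 grows at its 5' end
        sense = list(sense)
        sense[j + 1] = (s - a, e) if gene.strand == "+" else (s, e + a)
        chain = sense
    else:
        raise SimulationError(f"unknown event class {event!r}")
    return sorted(chain)


def spawn_variants(gene: GeneModel, spec: dict[str, float], seed: int
                   ) -> list[TranscriptModel]:
    """Reference transcript plus independently drawn programmed variants.

    Each event class in ``spec`` is realized with its stated probability
    (independent Bernoulli draws), so across many genes the per-class variant
    frequency is binomial around the configured rate.  A certain event (p == 1) on a
    gene too simple to host it raises; an uncertain one is skipped.
    """
    rng = spawn_rng(seed, 2, int(re.sub(r"\D", "", gene.gene_id) or 0))
    out = [TranscriptModel(
        transcript_id=f"{gene.gene_id}.ref", gene_id=gene.gene_id,
        chrom=gene.chrom, strand=gene.strand, exons=sorted(gene.exons),
        programmed_event="none")]
    v = 0
    for event in EVENT_CLASSES:
        p = spec.get(event, 0.0)
        if p <= 0.0 or rng.random() >= p:
            continue
        try:
            chain = _apply_event(gene, event, rng)
        except SimulationError:
            if p >= 1.0:
                raise
            continue
        v += 1
        out.append(TranscriptModel(
            transcript_id=f"{gene.gene_id}.v{v}", gene_id=gene.gene_id,
            chrom=gene.chrom, strand=gene.strand, exons=chain,
            programmed_event=event))
    return out


# ---------------------------------------------------------------------------
# clone pools, EST reads, normalization
# ---------------------------------------------------------------------------

def build_clone_pool(transcripts: list[TranscriptModel], seed: int,
                     library: str = "AA", skew: float = 1.0,
                     marker_clone: str | None = None,
                     marker_freq: float = 0.0) -> ClonePool:
    """Assign clone ids and log-normal relative abundances.

    ``skew`` is the sigma of the log-normal redundancy profile; a marker
    clone (the normalization reporter) can be spiked to a set frequency.
    """
    rng = spawn_rng(seed, 3)
    clones: dict[str, TranscriptModel] = {}
    weights: dict[str, float] = {}
    for i, t in enumerate(transcripts):
        plate = i // 384 + 1
        well = f"{'ABCDEFGHIJKLMNOP'[(i % 384) // 24]}{(i % 384) % 24 + 1:02d}"
        clone_id = f"LA0A{library}{plate}Y{well}"
        t.clone_ids.append(clone_id)
        clones[clone_id] = t
        weights[clone_id] = float(rng.lognormal(0.0, skew))
    if marker_clone is not None:
        if marker_clone not in clones:
            raise SimulationError(f"marker clone {marker_clone!r} not in pool")
        rest = sum(w for c, w in weights.items() if c != marker_clone)
        weights[marker_clone] = marker_freq / (1.0 - marker_freq) * rest
    total = sum(weights.values())
    return ClonePool(clones=clones,
                     abundance={c: w / total for c, w in weights.items()})


_PRIMER_CODE = {"five_prime": "CM1", "three_prime": "CM2", "internal": "CM3"}
_CODE_PRIMER = {v: k for k, v in _PRIMER_CODE.items()}
_READ_ID_RE = re.compile(r"^(LA0[AB][A-Z]{2}\d+Y[A-P]\d{2})(CM[123])(?:_(\d+))?$")


def make_read_id(clone_id: str, primer_end: str, copy: int = 0) -> str:
    rid = clone_id + _PRIMER_CODE[primer_end]
    return rid if copy == 0 else f"{rid}_{copy}"


def parse_read_id(read_id: str) -> dict:
    """Decompose a library read name into clone, library and primer end."""
    m = _READ_ID_RE.match(read_id)
    if not m:
        raise ValueError(f"unparseable read id {read_id!r}")
    clone_id = m.group(1)
    return {
        "clone_id": clone_id,
        "library": clone_id[4:6],
        "plate": int(clone_id[6:clone_id.index("Y")]),
        "well": clone_id[clone_id.index("Y") + 1:],
        "primer_end": _CODE_PRIMER[m.group(2)],
    }


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    for p in rng.choice(len(arr), size=n_err, replace=False):
        arr[p] = str(rng.choice([b for b in "ACGT" if b != arr[p]]))
    return "".join(arr)


def simulate_ests(pool: ClonePool, cfg: SimConfig, genome: AnnotatedGenome,
                  ends: tuple[str, ...] = ("five_prime", "three_prime"),
                  internal_overlap: int = 100) -> list[ESTRead]:
    """Single-pass reads per clone: 5' prefixes, reverse-complemented 3'
    suffixes, and internal reads tiling the unsequenced middle.

    A clone shorter than the read length yields one full-length read flagged
    truncated.  Substitution errors are applied at ``cfg.error_rate``.
    """
    if not pool.clones:
        raise SimulationError("clone pool is empty")
    rng = spawn_rng(cfg.seed, 4)
    L = cfg.read_len
    reads: list[ESTRead] = []
    for clone_id in sorted(pool.clones):
        t = pool.clones[clone_id]
        seq = genome.transcript_seq(t.exons, t.chrom, t.strand)
        for copy in range(cfg.est_per_clone):
            if len(seq) <= L:
                if "five_prime" in ends:
                    reads.append(ESTRead(make_read_id(clone_id, "five_prime", copy),
                                         clone_id, "five_prime",
                                         _mutate(seq, cfg.error_rate, rng),
                                         truncated=True))
                continue
            if "five_prime" in ends:
                reads.append(ESTRead(make_read_id(clone_id, "five_prime", copy),
                                     clone_id, "five_prime",
                                     _mutate(seq[:L], cfg.error_rate, rng)))
            if "three_prime" in ends:
                reads.append(ESTRead(make_read_id(clone_id, "three_prime", copy),
                                     clone_id, "three_prime",
                                     _mutate(revcomp(seq[-L:]), cfg.error_rate, rng)))
            if "internal" in ends:
                step = L - internal_overlap
                start = step
                k = 0
                while start + L < len(seq):
                    rid = make_read_id(clone_id, "internal", copy * 100 + k)
                    reads.append(ESTRead(rid, clone_id, "internal",
                                         _mutate(seq[start:start + L],
                                                 cfg.error_rate, rng)))
                    start += step
                    k += 1
    return reads


def emulate_normalization(pool: ClonePool, flatten: float) -> ClonePool:
    """Flatten clone redundancy: new frequency proportional to old**flatten.

    ``flatten`` = 1 leaves the pool unchanged; smaller exponents compress the
    abundance range toward uniformity without changing which clones are
    present (redundancy drops, diversity is conserved — the defining property
    of library normalization).
    """
    if not 0.0 < flatten <= 1.0:
        raise SimulationError("flatten exponent must lie in (0, 1]")
    powered = {c: f ** flatten for c, f in pool.abundance.items()}
    total = sum(powered.values())
    return ClonePool(clones=pool.clones,
                     abundance={c: w / total for c, w in powered.items()})


def derive_sister_species(genome: AnnotatedGenome, cfg: SimConfig, seed: int,
                          conserved_ids: list[str] | None = None,
                          max_junction_subs: int = 5, flank: int = 50
                          ) -> tuple[AnnotatedGenome, dict[str, str]]:
    """Build a second species' genome sharing part of the first's gene set.

    Conserved genes keep their exon-intron structure; each of their splice
    junctions' 100-base exonic windows receives 0..max_junction_subs
    substitutions, scattered at most one per 20-base stretch to emulate
    diffuse neutral divergence (clustered edits would not look like
    junction-conserving homology).  The remaining genes of the new genome
    are generated fresh and share no homology with the first species.

    Returns the new genome and the conserved-gene id map (old -> new).
    """
    rng = spawn_rng(seed, 6)
    sister = generate_genome(replace(cfg, seed=seed))
    for g in sister.genes:
        g.gene_id = "U" + g.gene_id  # unique to the sister species
    if conserved_ids is None:
        conserved_ids = [g.gene_id for g in genome.genes[::2]]

    chrom_names = sorted(sister.chroms)
    chroms = {c: sister.chroms[c] for c in chrom_names}
    id_map: dict[str, str] = {}
    for i, gid in enumerate(conserved_ids):
        src = genome.gene(gid)
        g_start = min(s for s, _ in src.exons)
        g_end = max(e for _, e in src.exons)
        region = list(genome.chroms[src.chrom][g_start:g_end])

        sense = src.sense_exons()
        for j in range(len(sense) - 1):
            up, dn = sense[j], sense[j + 1]
            if src.strand == "+":
                window = list(range(up[1] - flank, up[1])) + \
                    list(range(dn[0], dn[0] + flank))
            else:
                window = list(range(up[0], up[0] + flank)) + \
                    list(range(dn[1] - flank, dn[1]))
            n_subs = int(rng.integers(0, max_junction_subs + 1))
            bins = rng.choice(2 * flank // 20, size=min(n_subs, 2 * flank // 20),
                              replace=False)
            for b in sorted(bins):
                pos = window[int(b) * 20 + int(rng.integers(0, 20))]
                rel = pos - g_start
                old = region[rel]
                region[rel] = str(rng.choice([x for x in "ACGT" if x != old]))

        chrom = chrom_names[i % len(chrom_names)]
        gap = int(rng.integers(cfg.intergene_gap[0], cfg.intergene_gap[1] + 1))
        offset = len(chroms[chrom]) + gap
        chroms[chrom] = chroms[chrom] + random_dna(rng, gap) + "".join(region)
        new_id = gid + "C"
        id_map[gid] = new_id
        sister.genes.append(GeneModel(
            gene_id=new_id, chrom=chrom, strand=src.strand,
            exons=[(s - g_start + offset, e - g_start + offset)
                   for s, e in src.exons],
            cds=src.cds, go_terms=set(src.go_terms),
            alt_donor=dict(src.alt_donor), alt_acceptor=dict(src.alt_acceptor)))
    sister.chroms = chroms
    return sister, id_map


def sample_library(pool: ClonePool, n: int, seed: int) -> dict[str, int]:
    """Draw n clones with replacement by abundance; returns clone counts."""
    rng = spawn_rng(seed, 5)
    ids = sorted(pool.abundance)
    probs = np.array([pool.abundance[c] for c in ids])
    counts = rng.multinomial(n, probs)
    return {c: int(k) for c, k in zip(ids, counts) if k}
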