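"""Spliced alignment of cDNAs onto the genome and clustering into loci.

The aligner is seed-and-chain: exact k-mer anchors (default k = 12) are
chained colinearly to maximize covered query bases, gaps on the genomic axis
of at least ``min_intron`` bases (default 40) are called introns, and each
intron boundary is then slid locally to the placement that maximizes matched
bases plus a canonical GT..AG bonus.  Alignments are grouped into loci by
single linkage on shared genomic footprint (default >= 100 nucleotides),
per chromosome and strand.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .simulate import AnnotatedGenome
from .util import footprint_shared, merge_intervals, revcomp

log = logging.getLogger(__name__)

MIN_INTRON = 40


@dataclass
class SplicedAlignment:
    query_id: str
    chrom: str
    strand: str
    #: colinear ungapped blocks (q_start, q_end, g_start, g_end); query
    #: coordinates refer to the aligned orientation of the query (the
    #: reverse complement for strand "-")
    blocks: list[tuple[int, int, int, int]]
    identity: float = 0.0
    #: per intron, (donor 2-mer, acceptor 2-mer) on the transcript strand
    intron_dinucs: list[tuple[str, str]] = field(default_factory=list)
    canonical: list[bool] = field(default_factory=list)

    def genomic_blocks(self) -> list[tuple[int, int]]:
        return [(gs, ge) for _, _, gs, ge in self.blocks]

    def exons(self, min_intron: int = MIN_INTRON) -> list[tuple[int, int]]:
        """Genomic exons: blocks merged across sub-intron gaps."""
        out: list[tuple[int, int]] = []
        for gs, ge in self.genomic_blocks():
            if out and gs - out[-1][1] < min_intron:
                out[-1] = (out[-1][0], ge)
            else:
                out.append((gs, ge))
        return out


@dataclass
class Locus:
    locus_id: str
    chrom: str
    strand: str
    members: list[SplicedAlignment]
    footprint: list[tuple[int, int]]


class GenomeIndex:
    """Exact k-mer index over all chromosomes (build once, query many)."""

    def __init__(self, genome: AnnotatedGenome, k: int = 12):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(genome.chroms):
            seq = genome.chroms[chrom]
            for i in range(len(seq) - k + 1):
                self.index[seq[i:i + k]].append((chrom, i))


def _anchors(query: str, index: GenomeIndex) -> dict[tuple[str, int], list[tuple[int, int]]]:
    """Maximal exact runs per (chrom, diagonal): lists of (q_start, length)."""
    k = index.k
    by_diag: dict[tuple[str, int], list[int]] = defaultdict(list)
    for q in range(len(query) - k + 1):
        for chrom, g in index.index.get(query[q:q + k], ()):
            by_diag[(chrom, g - q)].append(q)
    runs: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for diag, qs in by_diag.items():
        qs.sort()
        merged = []
        start = prev = qs[0]
        for q in qs[1:]:
            if q <= prev + 1:
                prev = q
            else:
                merged.append((start, prev - start + k))
                start = prev = q
        merged.append((start, prev - start + k))
        runs[diag] = merged
    return runs


def _chain(anchors: list[tuple[int, int, str, int]], max_intron: int
           ) -> tuple[float, list[tuple[int, int, str, int]]]:
    """Best colinear chain by covered query bases (O(n^2) DP).

    Anchors are (q_start, length, chrom, g_start); all on one chromosome.
    """
    anchors = sorted(anchors)
    n = len(anchors)
    score = [0.0] * n
    back = [-1] * n
    for i, (qi, li, _, gi) in enumerate(anchors):
        score[i] = float(li)
        for j in range(i):
            qj, lj, _, gj = anchors[j]
            dq = qi - (qj + lj)
            dg = gi - (gj + lj)
            if gi <= gj or dg < -lj + 1 or dq < -lj + 1:
                continue
            if dg > max_intron:
                continue
            overlap = max(0, -dq, -dg)
            gain = li - overlap - 0.001  # tiny chain-break penalty
            if score[j] + gain > score[i]:
                score[i] = score[j] + gain
                back[i] = j
    besti = max(range(n), key=lambda i: (score[i], -anchors[i][0]))
    chain = []
    i = besti
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    return score[besti], chain[::-1]


def seed_and_chain(cdna: str, index: GenomeIndex, min_intron: int = MIN_INTRON,
                   max_intron: int = 5000, query_id: str = "query"
                   ) -> SplicedAlignment | None:
    """Map one cDNA: best colinear anchor chain over both strands.

    Returns None (and logs) when no seed is found.  Only the single best
    chain is kept: one locus per cDNA.
    """
    if len(cdna) < index.k:
        raise ValueError("query shorter than the seed size")
    best = None  # (score, strand, chain)
    for strand in ("+", "-"):
        query = cdna if strand == "+" else revcomp(cdna)
        runs = _anchors(query, index)
        per_chrom: dict[str, list[tuple[int, int, str, int]]] = defaultdict(list)
        for (chrom, diag), qruns in runs.items():
            for q, L in qruns:
                per_chrom[chrom].append((q, L, chrom, q + diag))
        for chrom in sorted(per_chrom):
            sc, chain = _chain(per_chrom[chrom], max_intron)
            if best is None or sc > best[0]:
                best = (sc, strand, chain, query)
    if best is None:
        log.warning("no seed found for query %s", query_id)
        return None
    _, strand, chain, query = best
    genome = index.genome
    chrom = chain[0][2]
    gseq = genome.chroms[chrom]

    # anchors -> ungapped blocks; small genomic/query gaps of equal size are
    # absorbed as substitution runs, genomic gaps >= min_intron become introns
    blocks: list[tuple[int, int, int, int]] = []
    q0, l0, _, g0 = chain[0]
    cur = [q0, q0 + l0, g0, g0 + l0]
    for q, L, _, g in chain[1:]:
        dq = q - cur[1]
        dg = g - cur[3]
        if dq < 0 or dg < 0:  # trim overlap with previous anchor
            t = max(-dq, -dg)
            q, g, L = q + t, g + t, L - t
            if L <= 0:
                continue
            dq, dg = q - cur[1], g - cur[3]
        if dq == dg:
            cur[1], cur[3] = q + L, g + L
        elif dg - dq >= min_intron:
            cur[1] += dq  # attach stray query bases to the upstream exon end
            cur[3] += dq
            blocks.append(tuple(cur))
            cur = [q, q + L, g, g + L]
        else:  # short indel: split blocks without an intron
            blocks.append(tuple(cur))
            cur = [q, q + L, g, g + L]
    blocks.append(tuple(cur))

    # free end extension while bases match (recovers unseeded read ends)
    qs, qe, gs, ge = blocks[0]
    while qs > 0 and gs > 0 and query[qs - 1] == gseq[gs - 1]:
        qs, gs = qs - 1, gs - 1
    blocks[0] = (qs, blocks[0][1], gs, blocks[0][3])
    qs0, qe, gs0, ge = blocks[-1]
    while qe < len(query) and ge < len(gseq) and query[qe] == gseq[ge]:
        qe, ge = qe + 1, ge + 1
    blocks[-1] = (qs0, qe, gs0, ge)

    aln = SplicedAlignment(query_id=query_id, chrom=chrom, strand=strand,
                           blocks=blocks)
    aln.identity = _identity(aln, query, gseq)
    aln._aligned_query = query  # kept for refinement  # type: ignore[attr-defined]
    return aln


def _identity(aln: SplicedAlignment, query: str, gseq: str) -> float:
    matches = aligned = 0
    for qs, qe, gs, ge in aln.blocks:
        aligned += qe - qs
        matches += sum(query[qs + i] == gseq[gs + i] for i in range(qe - qs))
    return matches / aligned if aligned else 0.0


def refine_splice_sites(aln: SplicedAlignment, genome: AnnotatedGenome,
                        scan: int = 10, gtag_bonus: float = 1.0,
                        min_intron: int = MIN_INTRON) -> SplicedAlignment:
    """Slide each intron boundary within +-scan bases to maximize matched
    query bases plus a GT..AG bonus; record intron dinucleotides.

    The bonus breaks ties in favor of canonical placements; non-canonical
    introns are kept but flagged.
    """
    query = getattr(aln, "_aligned_query", None)
    if query is None:
        raise ValueError("alignment lacks its aligned query sequence")
    gseq = genome.chroms[aln.chrom]
    blocks = [list(b) for b in aln.blocks]
    dinucs: list[tuple[str, str]] = []
    flags: list[bool] = []
    for i in range(len(blocks) - 1):
        up, dn = blocks[i], blocks[i + 1]
        if dn[2] - up[3] < min_intron or up[1] != dn[0]:
            continue  # not an intron (short gap or query-side indel)
        qj = up[1]  # query junction position
        lo = -min(scan, qj - up[0] - 1, up[3] - up[2] - 1)
        hi = min(scan, dn[1] - dn[0] - 1, dn[3] - dn[2] - 1)

        def placement_score(s: int) -> float:
            sc = 0.0
            for w in range(lo, hi):
                qpos = qj + w
                gpos = (up[3] + w) if w < s else (dn[2] + w)
                if 0 <= qpos < len(query) and 0 <= gpos < len(gseq) \
                        and query[qpos] == gseq[gpos]:
                    sc += 1.0
            d_s, d_e = up[3] + s, dn[2] + s
            if _intron_dinucs(gseq, d_s, d_e, aln.strand) == ("GT", "AG"):
                sc += gtag_bonus
            return sc

        shifts = sorted(range(lo, hi + 1), key=lambda s: (abs(s), s))
        best_s = max(shifts, key=placement_score)
        up[1] += best_s
        up[3] += best_s
        dn[0] += best_s
        dn[2] += best_s
        d, a = _intron_dinucs(gseq, up[3], dn[2], aln.strand)
        dinucs.append((d, a))
        flags.append((d, a) == ("GT", "AG"))
    aln.blocks = [tuple(b) for b in blocks]
    aln.intron_dinucs = dinucs
    aln.canonical = flags
    aln.identity = _identity(aln, query, gseq)
    return aln


def _intron_dinucs(gseq: str, g_start: int, g_end: int, strand: str
                   ) -> tuple[str, str]:
    """Donor/acceptor dinucleotides of genomic intron [g_start, g_end) on
    the transcript strand."""
    left, right = gseq[g_start:g_start + 2], gseq[g_end - 2:g_end]
    if strand == "+":
        return left, right
    return revcomp(right), revcomp(left)


def cluster_loci(alignments: list[SplicedAlignment], min_shared: int = 100
                 ) -> list[Locus]:
    """Single-linkage clustering by >= min_shared shared genomic bases,
    per chromosome and strand."""
    groups: dict[tuple[str, str], list[SplicedAlignment]] = defaultdict(list)
    for a in alignments:
        groups[(a.chrom, a.strand)].append(a)
    loci: list[Locus] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda a: a.query_id)
        parent = list(range(len(members)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        foot = [merge_intervals(a.genomic_blocks()) for a in members]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if footprint_shared(foot[i], foot[j]) >= min_shared:
                    parent[find(i)] = find(j)
        comps: dict[int, list[int]] = defaultdict(list)
        for i in range(len(members)):
            comps[find(i)].append(i)
        for idxs in sorted(comps.values(), key=lambda ix: min(foot[i][0][0] for i in ix)):
            loci.append(Locus(
                locus_id="",
                chrom=chrom, strand=strand,
                members=[members[i] for i in idxs],
                footprint=merge_intervals(
                    [iv for i in idxs for iv in foot[i]]),
            ))
    loci.sort(key=lambda L: (L.chrom, L.footprint[0][0], L.strand))
    for n, L in enumerate(loci):
        L.locus_id = f"LOC{n + 1:04d}"
    return loci


def alignments_to_bed_rows(alignments: list[SplicedAlignment]) -> list[dict]:
    return [{
        "chrom": a.chrom, "start": a.genomic_blocks()[0][0],
        "end": a.genomic_blocks()[-1][1], "name": a.query_id,
        "score": int(round(a.identity * 1000)), "strand": a.strand,
        "blocks": a.exons(),
    } for a in alignments]
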