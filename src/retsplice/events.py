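"""Alternative-splice event classification and junction extraction.

Events are detected by comparing the exon chains of every transcript pair at
a locus and are deduplicated by (type, genomic interval):

* exon skipping — an internal exon of one transcript falls wholly inside an
  intron of the other while both flanking junctions are shared;
* alternate 5'/3' splice site — two introns share one boundary but not the
  other (donor = 5' side on the transcript strand);
* intron retention — one transcript's exon spans an entire intron of the
  other plus part of both flanking exons.

Junctions are exported as the 100-base sequence spanning each exon-exon
boundary: the last 50 transcribed bases of the upstream exon followed by the
first 50 of the downstream exon, on the transcript sense strand.  By default
junctions with a flanking exon overlapping the 5' or 3' UTR are excluded, as
are junctions flanked by an exon shorter than 50 transcribed bases (keeping
every exported sequence exactly 100 bases).
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import AnnotatedGenome
from .util import revcomp

EVENT_TYPES = ("exon_skipping", "alt_5ss", "alt_3ss", "intron_retention")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    locus_id: str
    type: str
    #: (inclusion transcript, exclusion transcript): inclusion carries the
    #: extra sequence (the exon, the longer exon form, the retained intron)
    transcripts: tuple[str, str]
    interval: tuple[int, int]  # genomic, half-open
    consensus_ok: bool = True


@dataclass(frozen=True)
class SpliceJunction:
    junction_id: str
    chrom: str
    strand: str
    donor_pos: int     # genomic left end of the intron (donor_pos < acceptor_pos;
    acceptor_pos: int  # on "-" the biological donor is at acceptor_pos)
    seq100: str
    flank_exon_ids: tuple[str, str]
    utr_overlap: bool = False


def _introns(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    exons = sorted(exons)
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def _boundaries(exons: list[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for s, e in exons:
        out |= {s, e}
    return out


def _pair_events(id_a: str, ex_a: list[tuple[int, int]],
                 id_b: str, ex_b: list[tuple[int, int]],
                 strand: str) -> list[tuple[str, tuple[int, int], tuple[str, str]]]:
    """Directed comparison: events where A is the inclusion form vs B."""
    found = []
    introns_b = _introns(ex_b)
    bounds_a, bounds_b = _boundaries(ex_a), _boundaries(ex_b)
    ex_a, ex_b = sorted(ex_a), sorted(ex_b)

    # exon skipping: internal exon of A inside an intron of B, flanking
    # junctions shared by both transcripts
    for s, e in ex_a[1:-1]:
        for d, a in introns_b:
            if d <= s and e <= a and d in bounds_a and a in bounds_a:
                found.append(("exon_skipping", (s, e), (id_a, id_b)))

    # intron retention: an exon of A spans an entire intron of B plus both
    # flanking exon parts
    for s, e in ex_a:
        for d, a in introns_b:
            if s < d and a < e:
                found.append(("intron_retention", (d, a), (id_a, id_b)))

    # alternate splice sites: introns sharing exactly one boundary.  The
    # differing stretch must not contain a complete exon of either
    # transcript — that situation is exon skipping, not an alternate site.
    def _contains_whole_exon(iv: tuple[int, int]) -> bool:
        return any(iv[0] <= s and e <= iv[1] for s, e in ex_a + ex_b)

    for d1, a1 in _introns(ex_a):
        for d2, a2 in introns_b:
            if (d1, a1) == (d2, a2):
                continue
            if a1 == a2 and d1 != d2:
                iv = (min(d1, d2), max(d1, d2))
                if _contains_whole_exon(iv):
                    continue
                etype = "alt_5ss" if strand == "+" else "alt_3ss"
                incl = id_a if d1 > d2 else id_b
                excl = id_b if d1 > d2 else id_a
                found.append((etype, iv, (incl, excl)))
            elif d1 == d2 and a1 != a2:
                iv = (min(a1, a2), max(a1, a2))
                if _contains_whole_exon(iv):
                    continue
                etype = "alt_3ss" if strand == "+" else "alt_5ss"
                incl = id_a if a1 < a2 else id_b
                excl = id_b if a1 < a2 else id_a
                found.append((etype, iv, (incl, excl)))
    return found


def classify_events(transcripts: list[tuple[str, list[tuple[int, int]]]],
                    strand: str, locus_id: str = "locus",
                    genome: AnnotatedGenome | None = None,
                    chrom: str | None = None) -> list[ASEvent]:
    """All pairwise events among a locus's transcripts, deduplicated by
    (type, genomic interval).  A single-transcript locus yields no events.

    When the genome is supplied, each event's consensus_ok flag records
    whether the exclusion-form intron at the event is GT..AG.
    """
    seen: dict[tuple[str, tuple[int, int]], tuple[str, str]] = {}
    order: list[tuple[str, tuple[int, int]]] = []
    for i, (id_a, ex_a) in enumerate(transcripts):
        for id_b, ex_b in transcripts[i + 1:]:
            for direction in (( id_a, ex_a, id_b, ex_b), (id_b, ex_b, id_a, ex_a)):
                for etype, iv, pair in _pair_events(*direction, strand):
                    key = (etype, iv)
                    if key not in seen:
                        seen[key] = pair
                        order.append(key)
    exon_map = dict(transcripts)
    events = []
    for n, key in enumerate(sorted(order, key=lambda k: (k[1], k[0]))):
        etype, iv = key
        incl, excl = seen[key]
        ok = True
        if genome is not None and chrom is not None:
            # check the exclusion form's intron at the event: the smallest
            # intron containing the event interval (for retention this is the
            # retained intron itself)
            candidates = [(d, a) for d, a in _introns(exon_map[excl])
                          if d <= iv[0] and iv[1] <= a]
            if candidates:
                d, a = min(candidates, key=lambda x: x[1] - x[0])
                ok = check_splice_consensus(chrom, d, a, strand, genome)
        events.append(ASEvent(
            event_id=f"{locus_id}.e{n + 1}", locus_id=locus_id, type=etype,
            transcripts=(incl, excl), interval=iv, consensus_ok=ok))
    return events


def check_splice_consensus(chrom: str, g_start: int, g_end: int, strand: str,
                           genome: AnnotatedGenome) -> bool:
    """True iff the genomic intron [g_start, g_end) begins GT and ends AG on
    the transcript strand (CT..AC on the top strand for minus-strand genes).
    """
    seq = genome.chroms[chrom]
    if not (0 <= g_start < g_end <= len(seq)) or g_end - g_start < 4:
        raise ValueError(f"intron coordinates out of range: {g_start}-{g_end}")
    left, right = seq[g_start:g_start + 2], seq[g_end - 2:g_end]
    if strand == "+":
        return left == "GT" and right == "AG"
    return revcomp(right) == "GT" and revcomp(left) == "AG"


def _tx_offsets(sense_exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Transcript-coordinate span of each sense exon."""
    out, pos = [], 0
    for s, e in sense_exons:
        out.append((pos, pos + (e - s)))
        pos += e - s
    return out


def extract_junctions(entries: list[dict], genome: AnnotatedGenome,
                      flank: int = 50, exclude_utr: bool = True,
                      utr_mode: str = "exon") -> list[SpliceJunction]:
    """100-base junction sequences for a set of transcripts, deduplicated by
    (chrom, strand, donor_pos, acceptor_pos).

    Each entry is a dict with transcript_id, chrom, strand, exons (genomic)
    and, when UTR exclusion is on, cds as a transcript-coordinate interval.
    utr_mode "exon" drops junctions whose flanking exon overlaps a UTR;
    "junction" drops junctions whose own 100-base footprint overlaps a UTR.
    """
    if utr_mode not in ("exon", "junction"):
        raise ValueError("utr_mode must be 'exon' or 'junction'")
    out: dict[tuple[str, str, int, int], SpliceJunction] = {}
    for entry in entries:
        chrom, strand = entry["chrom"], entry["strand"]
        exons = sorted(entry["exons"])
        if len(exons) < 2:
            continue
        sense = exons if strand == "+" else list(reversed(exons))
        offs = _tx_offsets(sense)
        tx_len = offs[-1][1]
        cds = entry.get("cds")
        if exclude_utr and cds is None:
            raise ValueError(
                f"{entry.get('transcript_id')}: UTR exclusion needs a CDS")
        gseq = genome.chroms[chrom]
        for j in range(len(sense) - 1):
            up, dn = sense[j], sense[j + 1]
            if (up[1] - up[0]) < flank or (dn[1] - dn[0]) < flank:
                continue
            if exclude_utr:
                utr5 = (0, cds[0])
                utr3 = (cds[1], tx_len)
                if utr_mode == "exon":
                    spans = [offs[j], offs[j + 1]]
                else:
                    spans = [(offs[j][1] - flank, offs[j][1]),
                             (offs[j + 1][0], offs[j + 1][0] + flank)]
                overlaps = any(
                    max(s, u0) < min(e, u1)
                    for s, e in spans for u0, u1 in (utr5, utr3) if u0 < u1
                )
                if overlaps:
                    continue
            if strand == "+":
                seq100 = gseq[up[1] - flank:up[1]] + gseq[dn[0]:dn[0] + flank]
                donor, acceptor = up[1], dn[0]
            else:
                # sense exon j sits genomically downstream of sense exon j+1
                seq100 = revcomp(gseq[up[0]:up[0] + flank]) + \
                    revcomp(gseq[dn[1] - flank:dn[1]])
                donor, acceptor = dn[1], up[0]
            key = (chrom, strand, donor, acceptor)
            if key not in out:
                out[key] = SpliceJunction(
                    junction_id=f"{chrom}:{donor}-{acceptor}:{strand}",
                    chrom=chrom, strand=strand, donor_pos=donor,
                    acceptor_pos=acceptor, seq100=seq100,
                    flank_exon_ids=(f"{entry['transcript_id']}.ex{j}",
                                    f"{entry['transcript_id']}.ex{j + 1}"),
                    utr_overlap=False)
    return sorted(out.values(), key=lambda j: (j.chrom, j.donor_pos, j.acceptor_pos,
                                               j.strand))
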