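"""Greedy overlap assembly of single-pass EST reads into per-clone contigs.

Two reads are joined when they share a sufficiently long, sufficiently
identical ungapped overlap (default >= 40 bases at >= 95% identity, in either
orientation).  This is a deterministic, declared proxy for quality-weighted
assembly: overlaps are ungapped, candidates are found via shared k-mers, the
best-scoring merge is applied first, and equal scores are broken on the
lexicographically smallest read-id pair.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .simulate import ESTRead
from .util import revcomp, seq_array

log = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    read_a: str
    read_b: str
    overlap_len: int
    identity: float
    orientation: str  # "same" | "reverse"


def _mismatches(a: str, b: str) -> int:
    return int(np.count_nonzero(seq_array(a) != seq_array(b)))


def _best_suffix_prefix(a: str, b: str, min_len: int, min_ident: float
                        ) -> tuple[int, float] | None:
    """Maximal qualifying suffix(a)/prefix(b) overlap, scanning lengths
    from the longest possible downward (exhaustive, hence exact)."""
    for L in range(min(len(a), len(b)), min_len - 1, -1):
        ident = 1.0 - _mismatches(a[-L:], b[:L]) / L
        if ident >= min_ident:
            return L, ident
    return None


def pairwise_overlap(a: str, b: str, min_len: int = 40, min_ident: float = 0.95,
                     read_a: str = "a", read_b: str = "b") -> OverlapResult | None:
    """Maximal suffix-prefix overlap between two sequences, either orientation.

    Returns None when no overlap meets the length and identity thresholds.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best: OverlapResult | None = None
    for orient, bb in (("same", b), ("reverse", revcomp(b))):
        hit = _best_suffix_prefix(a, bb, min_len, min_ident)
        if hit and (best is None or hit[0] > best.overlap_len):
            best = OverlapResult(read_a, read_b, hit[0], hit[1], orient)
    return best


@dataclass
class Contig:
    contig_id: str
    consensus: str
    # members: (read_id, offset of read start in contig coords, orientation)
    members: list[tuple[str, int, str]]
    clone_id: str | None = None


@dataclass
class AssembledClone:
    clone_id: str
    status: str  # five_prime_only | pairwise_assembled | fully_sequenced | unassembled
    consensus: str = ""


@dataclass
class _Layout:
    """A growing contig: reads placed at ungapped offsets."""
    reads: list[tuple[str, int, str]]  # (read_id, offset, orient) in merge order
    seqs: dict[str, str]               # oriented read sequences

    def span(self) -> int:
        return max(off + len(self.seqs[r]) for r, off, _ in self.reads)

    def consensus(self) -> str:
        """Majority vote per column; ties go to the earliest-merged read."""
        n = self.span()
        votes: list[dict[str, int]] = [defaultdict(int) for _ in range(n)]
        first: list[str | None] = [None] * n
        for r, off, _ in self.reads:
            for i, base in enumerate(self.seqs[r]):
                votes[off + i][base] += 1
                if first[off + i] is None:
                    first[off + i] = base
        out = []
        for col, fb in zip(votes, first):
            best = max(col.values())
            winners = [b for b, k in col.items() if k == best]
            out.append(fb if fb in winners else min(winners))
        return "".join(out)


def _kmers(seq: str, k: int) -> dict[str, list[int]]:
    d: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        d[seq[i:i + k]].append(i)
    return d


def _best_offset(a: str, b: str, min_len: int, min_ident: float, k: int
                 ) -> tuple[int, int, float] | None:
    """Best ungapped placement of b against a among k-mer-supported offsets.

    Returns (offset of b relative to a, overlap_len, identity).  Handles
    dovetail overlaps and full containment alike.
    """
    ka = _kmers(a, k)
    offsets = set()
    for j in range(len(b) - k + 1):
        for i in ka.get(b[j:j + k], ()):
            offsets.add(i - j)
    best = None
    for off in sorted(offsets):
        lo, hi = max(0, off), min(len(a), off + len(b))
        L = hi - lo
        if L < min_len:
            continue
        ident = 1.0 - _mismatches(a[lo:hi], b[lo - off:hi - off]) / L
        if ident < min_ident:
            continue
        cand = (off, L, ident)
        if best is None or (L, ident) > (best[1], best[2]):
            best = cand
    return best


def assemble(reads: list[ESTRead], min_len: int = 40, min_ident: float = 0.95,
             k: int = 14) -> list[Contig]:
    """Greedy merge of reads by descending overlap length.

    Every input read ends up in exactly one contig.  Deterministic: merges of
    equal score are applied in lexicographic order of the smallest member
    read ids.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    layouts: dict[str, _Layout] = {
        r.read_id: _Layout([(r.read_id, 0, "+")], {r.read_id: r.sequence})
        for r in reads
    }

    def key(lid: str) -> str:
        return min(r for r, _, _ in layouts[lid].reads)

    cons = {lid: lay.consensus() for lid, lay in layouts.items()}
    pair_hits: dict[tuple[str, str], tuple | None] = {}

    def best_pair_hit(la: str, lb: str):
        pkey = (la, lb)
        if pkey not in pair_hits:
            found = None
            for orient in ("+", "-"):
                bseq = cons[lb] if orient == "+" else revcomp(cons[lb])
                hit = _best_offset(cons[la], bseq, min_len, min_ident, k)
                if hit and (found is None or (hit[1], hit[2]) > (found[0], found[1])):
                    found = (hit[1], hit[2], hit[0], orient)
            pair_hits[pkey] = found
        return pair_hits[pkey]

    while True:
        best = None  # (overlap_len, identity, key_a, key_b, lid_a, lid_b, off, orient)
        lids = sorted(layouts, key=key)
        for i, la in enumerate(lids):
            for lb in lids[i + 1:]:
                hit = best_pair_hit(la, lb)
                if hit is None:
                    continue
                L, ident, off, orient = hit
                cand = (L, ident, key(la), key(lb), la, lb, off, orient)
                if best is None or (L, ident) > (best[0], best[1]) or (
                        (L, ident) == (best[0], best[1])
                        and (cand[2], cand[3]) < (best[2], best[3])):
                    best = cand
        if best is None:
            break
        _, _, _, _, la, lb, off, orient = best
        pair_hits = {pk: v for pk, v in pair_hits.items()
                     if la not in pk and lb not in pk}
        A, B = layouts[la], layouts[lb]
        if orient == "-":
            span_b = B.span()
            B = _Layout(
                [(r, span_b - o - len(B.seqs[r]), "-" if s == "+" else "+")
                 for r, o, s in B.reads],
                {r: revcomp(s) for r, s in B.seqs.items()},
            )
        shift = max(0, -off)
        merged = _Layout(
            [(r, o + shift, s) for r, o, s in A.reads]
            + [(r, o + off + shift, s) for r, o, s in B.reads],
            {**A.seqs, **B.seqs},
        )
        del layouts[lb]
        del cons[lb]
        layouts[la] = merged
        cons[la] = merged.consensus()

    by_clone = {r.read_id: r.clone_id for r in reads}
    contigs = []
    for i, lid in enumerate(sorted(layouts, key=key)):
        lay = layouts[lid]
        clones = {by_clone[r] for r, _, _ in lay.reads}
        contigs.append(Contig(
            contig_id=f"CTG{i + 1:04d}",
            consensus=lay.consensus(),
            members=list(lay.reads),
            clone_id=clones.pop() if len(clones) == 1 else None,
        ))
    return contigs


def classify_clones(contigs: list[Contig], reads: list[ESTRead]
                    ) -> tuple[list[AssembledClone], dict[str, int]]:
    """Per-clone assembly status and summary counts.

    pairwise_assembled: a 5' and a 3' read of the clone sit in one contig and
    overlap directly.  fully_sequenced: both ends sit in one contig but are
    only joined through internal reads.  Contigs mixing clones are flagged as
    chimeras and their clones excluded from the counts.
    """
    meta = {r.read_id: r for r in reads}
    read_to_contig: dict[str, Contig] = {}
    chimeric_clones: set[str] = set()
    for c in contigs:
        clones = {meta[r].clone_id for r, _, _ in c.members}
        if len(clones) > 1:
            log.warning("contig %s joins clones %s: flagged chimera",
                        c.contig_id, sorted(clones))
            chimeric_clones |= clones
            continue
        for r, _, _ in c.members:
            read_to_contig[r] = c

    result: list[AssembledClone] = []
    counts = {"five_prime_only": 0, "pairwise_assembled": 0,
              "fully_sequenced": 0, "unassembled": 0, "chimeric": 0}
    for clone_id in sorted({r.clone_id for r in reads}):
        if clone_id in chimeric_clones:
            counts["chimeric"] += 1
            continue
        clone_reads = [r for r in reads if r.clone_id == clone_id]
        ends = {r.primer_end for r in clone_reads}
        status, consensus = "five_prime_only", ""
        joined = None
        for c in {id(read_to_contig[r.read_id]): read_to_contig[r.read_id]
                  for r in clone_reads if r.read_id in read_to_contig}.values():
            member_ends = {meta[r].primer_end for r, _, _ in c.members}
            if {"five_prime", "three_prime"} <= member_ends:
                joined = c
                break
        if joined is not None:
            spans = {
                e: [(o, o + len(meta[r].sequence)) for r, o, _ in joined.members
                    if meta[r].primer_end == e]
                for e in ("five_prime", "three_prime")
            }
            direct = any(
                min(a[1], b[1]) > max(a[0], b[0])
                for a in spans["five_prime"] for b in spans["three_prime"]
            )
            status = "pairwise_assembled" if direct else "fully_sequenced"
            consensus = joined.consensus
        elif "three_prime" in ends:
            status = "unassembled"
        counts[status] += 1
        result.append(AssembledClone(clone_id, status, consensus))
    return result, counts
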