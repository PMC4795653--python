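"""Best-scoring ORF prediction, protein-level variant differences, and
in-silico PCR.

The ORF score is a declared proxy for "best ORF" selection on oligo-dT
primed, orientation-known cDNA: ORF length in codons, plus 50 if the frame
segment starts with ATG, plus 25 if it ends at a stop codon.  Only the three
forward frames are scanned by default (a six-frame mode exists).  The ATG
and CDS flags of the candidate catalog derive from this prediction:
CDS complete iff the best ORF both starts with ATG and ends at a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .util import STOP_CODONS, revcomp

ATG_BONUS = 50
STOP_BONUS = 25


@dataclass
class ORFPrediction:
    frame: int
    start: int  # transcript coords of the coding span, stop codon excluded
    end: int
    has_atg: bool
    has_stop: bool
    protein: str
    score: float
    strand: str = "+"

    @property
    def cds_complete(self) -> bool:
        return self.has_atg and self.has_stop


def _frame_candidates(seq: str, frame: int) -> list[tuple[int, int, bool, bool]]:
    """Candidate ORFs (start, end, has_atg, has_stop) in one frame.

    For each stop-delimited segment the maximal-length candidate is the
    whole segment; if the segment contains an ATG, the first-ATG candidate
    is added (a later ATG can never score higher).
    """
    n = (len(seq) - frame) // 3
    if n == 0:
        return []
    codons = [seq[frame + 3 * i:frame + 3 * i + 3] for i in range(n)]
    cands = []
    seg_start = 0
    for i in range(n + 1):
        at_stop = i < n and codons[i] in STOP_CODONS
        if at_stop or i == n:
            if i > seg_start or (i == seg_start and at_stop):
                s, e = seg_start, i
                if e > s:
                    cands.append((s, e, codons[s] == "ATG", at_stop))
                    atgs = [j for j in range(s, e) if codons[j] == "ATG"]
                    if atgs and atgs[0] != s:
                        cands.append((atgs[0], e, True, at_stop))
            seg_start = i + 1
    return [(frame + 3 * s, frame + 3 * e, a, st) for s, e, a, st in cands]


def predict_cds(cdna: str, six_frame: bool = False,
                atg_bonus: int = ATG_BONUS, stop_bonus: int = STOP_BONUS
                ) -> ORFPrediction | None:
    """Highest-scoring ORF over the scanned frames.

    score = length in codons + atg_bonus * starts_with_ATG
                             + stop_bonus * ends_at_stop.
    Ties break toward ATG-containing, then longer, then leftmost, then lower
    frame.  Returns None when no codon fits.
    """
    if len(cdna) < 3:
        return None
    best: ORFPrediction | None = None
    strands = (("+", cdna), ("-", revcomp(cdna))) if six_frame else (("+", cdna),)
    for strand, seq in strands:
        for frame in (0, 1, 2):
            for start, end, has_atg, has_stop in _frame_candidates(seq, frame):
                score = (end - start) // 3 + atg_bonus * has_atg + stop_bonus * has_stop
                cand = ORFPrediction(
                    frame=frame, start=start, end=end, has_atg=has_atg,
                    has_stop=has_stop,
                    protein=str(Seq(seq[start:end]).translate()),
                    score=score, strand=strand)
                if best is None or (
                        cand.score, cand.has_atg, end - start, -start
                ) > (best.score, best.has_atg, best.end - best.start, -best.start):
                    best = cand
    return best


# ---------------------------------------------------------------------------
# protein-level differences
# ---------------------------------------------------------------------------

@dataclass
class ProteinEdit:
    kind: str      # insertion | deletion
    position: int  # 1-based residue position in the reference (insertions:
                   # number of reference residues preceding the edit)
    length: int
    sequence: str


@dataclass
class ProteinDiff:
    edits: list[ProteinEdit]
    domain_overlaps: list[tuple[str, tuple[int, int], list[ProteinEdit]]] = \
        field(default_factory=list)


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -10  # indels strongly preferred over substitution runs
    a.open_gap_score = -2
    a.extend_gap_score = -0.5
    return a


def diff_proteins(reference: str, variant: str,
                  domains: list[tuple[str, int, int]] = ()) -> ProteinDiff:
    """Minimal indel decomposition of a variant protein against a reference.

    Domains are (name, start, end) in 1-based inclusive residue coordinates
    of the reference; each is reported with the edits it overlaps (an
    insertion overlaps a domain only when it falls strictly inside it).
    Applying the edits to the reference reproduces the variant exactly.
    """
    if not reference or not variant:
        raise ValueError("proteins must be non-empty")
    edits: list[ProteinEdit] = []
    if reference != variant:
        aln = _aligner().align(reference, variant)[0]
        r_blocks, v_blocks = (
            [(int(a), int(b)) for a, b in blocks] for blocks in aln.aligned)
        rpos, vpos = 0, 0
        for (rs, re_), (vs, ve) in zip(r_blocks, v_blocks):
            if rs > rpos:
                edits.append(ProteinEdit("deletion", rpos + 1, rs - rpos,
                                         reference[rpos:rs]))
            if vs > vpos:
                edits.append(ProteinEdit("insertion", rpos, vs - vpos,
                                         variant[vpos:vs]))
            rpos, vpos = re_, ve
        if rpos < len(reference):
            edits.append(ProteinEdit("deletion", rpos + 1, len(reference) - rpos,
                                     reference[rpos:]))
        if vpos < len(variant):
            edits.append(ProteinEdit("insertion", rpos, len(variant) - vpos,
                                     variant[vpos:]))
    overlaps = []
    for name, d_start, d_end in domains:
        touching = []
        for e in edits:
            if e.kind == "deletion":
                if e.position <= d_end and e.position + e.length - 1 >= d_start:
                    touching.append(e)
            else:  # insertion after residue e.position
                if d_start <= e.position < d_end:
                    touching.append(e)
        overlaps.append((name, (d_start, d_end), touching))
    return ProteinDiff(edits=edits, domain_overlaps=overlaps)


def apply_edits(reference: str, edits: list[ProteinEdit]) -> str:
    """Reconstruct the variant from the reference plus an edit list."""
    out = reference
    for e in sorted(edits, key=lambda e: -e.position):
        if e.kind == "deletion":
            out = out[:e.position - 1] + out[e.position - 1 + e.length:]
        else:
            out = out[:e.position] + e.sequence + out[e.position:]
    return out


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not p or set(p) - set("ACGT"):
                raise ValueError("primers must be non-empty ACGT strings")


def _sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    L = len(primer)
    return [i for i in range(len(template) - L + 1)
            if sum(a != b for a, b in zip(template[i:i + L], primer))
            <= max_mismatch]


def in_silico_pcr(template: str, pair: PrimerPair, max_mismatch: int = 0
                  ) -> list[int]:
    """Amplicon lengths for a primer pair on a sense-oriented template.

    Product length runs from the forward primer's 5' end to the reverse
    primer's binding 3' end, both primers included.  All products from
    multiple binding sites are reported; an absent primer yields [].
    """
    if len(pair.forward) >= len(template) or len(pair.reverse) >= len(template):
        raise ValueError("primers must be shorter than the template")
    fwd = _sites(template, pair.forward, max_mismatch)
    rev = _sites(template, revcomp(pair.reverse), max_mismatch)
    products = []
    for f in fwd:
        for r in rev:
            end = r + len(pair.reverse)
            if end - f >= len(pair.forward) + len(pair.reverse):
                products.append(end - f)
    return sorted(products)
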