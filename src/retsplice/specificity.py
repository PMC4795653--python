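"""All-vs-all junction comparison with ungapped local search and
Karlin-Altschul E-values.

A query junction is "species specific" when no hit against the other
species' junction database is both longer than ``len_thresh`` bases and has
an E-value below ``e_thresh`` (the two conditions are conjunctive).  The
search is word-seeded (default word size 8, no low-complexity filtering),
extension is ungapped with an X-drop, both query strands are searched, and
E = K * m * n' * exp(-lambda * S) with m the query length and n' the summed
subject database length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, gcd, log

import numpy as np
from scipy.optimize import brentq

from .util import revcomp, seq_array


@dataclass
class ScoringScheme:
    match: int = 1
    mismatch: int = -3
    word_size: int = 8
    xdrop: int = 20
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not np.isclose(sum(self.base_freqs), 1.0):
            raise ValueError("base frequencies must sum to 1")

    @property
    def p_match(self) -> float:
        """Probability two random background bases match."""
        return float(sum(f * f for f in self.base_freqs))


@dataclass
class KarlinParams:
    lam: float  # nats per score unit
    K: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or not 0 < self.K < 1:
            raise ValueError("invalid Karlin parameters")


def karlin_params(s: ScoringScheme, tol: float = 1e-12, kmax: int = 500
                  ) -> KarlinParams:
    """Ungapped local-alignment statistics for a match/mismatch scheme.

    lambda is the positive root of  p*e^(lam*match) + q*e^(lam*mismatch) = 1
    (p = background match probability), solved to |residual| < 1e-9.  K is
    evaluated by the standard lattice series over the partial-sum
    distribution, truncated when terms fall below ``tol``; the lattice span
    is the gcd of the attainable score values.
    """
    p, q = s.p_match, 1.0 - s.p_match
    mean = p * s.match + q * s.mismatch
    if mean >= 0:
        raise ValueError(
            "expected per-position score must be negative for local-alignment "
            f"statistics (got {mean:.3f})")

    def f(lam: float) -> float:
        return p * exp(lam * s.match) + q * exp(lam * s.mismatch) - 1.0

    lam = float(brentq(f, 1e-9, 60.0, xtol=1e-13))
    assert abs(f(lam)) < 1e-9

    delta = gcd(abs(s.match), abs(s.mismatch))
    # sigma = sum_k (1/k) [ E(e^(lam S_k); S_k < 0) + P(S_k >= 0) ]
    sigma = 0.0
    pmf: dict[int, float] = {0: 1.0}
    step = {s.match: p, s.mismatch: q}
    for k in range(1, kmax + 1):
        new: dict[int, float] = {}
        for v, pv in pmf.items():
            for x, px in step.items():
                new[v + x] = new.get(v + x, 0.0) + pv * px
        pmf = new
        term = sum(pv * exp(lam * v) if v < 0 else pv for v, pv in pmf.items())
        sigma += term / k
        if term / k < tol:
            break
    e_xe = p * s.match * exp(lam * s.match) + q * s.mismatch * exp(lam * s.mismatch)
    K = delta * lam * exp(-2.0 * sigma) / ((1.0 - exp(-lam * delta)) * lam * e_xe)
    return KarlinParams(lam=lam, K=K)


@dataclass
class Hit:
    query_id: str
    subject_id: str
    q_span: tuple[int, int]
    s_span: tuple[int, int]
    raw_score: int
    aln_len: int
    evalue: float
    strand: str = "+"


@dataclass
class SpecificityResult:
    best_hit: dict[str, Hit | None]
    specific: dict[str, bool]
    n_specific: int
    n_total: int
    fraction_percent: float
    len_thresh: int = 90
    e_thresh: float = 1e-40


def percent_specific(n_specific: int, n_total: int) -> float:
    """Specific-junction fraction as a percentage, one decimal place."""
    if n_total <= 0:
        raise ValueError("empty junction set")
    return round(100.0 * n_specific / n_total, 1)


def _word_index(db: dict[str, str], w: int) -> dict[str, list[tuple[int, int]]]:
    idx: dict[str, list[tuple[int, int]]] = {}
    for si, sid in enumerate(sorted(db)):
        seq = db[sid]
        for i in range(len(seq) - w + 1):
            idx.setdefault(seq[i:i + w], []).append((si, i))
    return idx


def _best_segment(qarr: np.ndarray, sarr: np.ndarray, q0: int, s0: int, w: int,
                  match: int, mismatch: int, xdrop: int
                  ) -> tuple[int, int, int] | None:
    """Best ungapped segment on the seed's diagonal containing the seed.

    Extends bidirectionally from the seed with an X-drop cutoff; returns
    (score, q_start, q_end) or None if the diagonal window is empty.
    """
    diag = s0 - q0
    lo_q = max(0, -diag)
    hi_q = min(len(qarr), len(sarr) - diag)
    if hi_q <= lo_q:
        return None
    window = np.where(qarr[lo_q:hi_q] == sarr[lo_q + diag:hi_q + diag],
                      match, mismatch)
    seed_rel = q0 - lo_q
    # right extension from the seed end
    right = window[seed_rel + w:]
    best_right, run, cut = 0, 0, 0
    for v in right:
        run += v
        if run > best_right:
            best_right, cut = run, 0
        else:
            cut = best_right - run
            if cut > xdrop:
                break
    # left extension from the seed start
    left = window[:seed_rel][::-1]
    best_left, run = 0, 0
    for v in left:
        run += v
        if run > best_left:
            best_left = run
        elif best_left - run > xdrop:
            break
    seed_score = int(window[seed_rel:seed_rel + w].sum())
    score = seed_score + best_left + best_right
    # recover span lengths
    q_start = q0 - _arg_best(left, best_left)
    q_end = q0 + w + _arg_best(right, best_right)
    return score, q_start, q_end


def _arg_best(vals: np.ndarray, best: int) -> int:
    if best <= 0:
        return 0
    run = 0
    for i, v in enumerate(vals):
        run += v
        if run == best:
            return i + 1
    return 0


def search(query_db: dict[str, str], subject_db: dict[str, str],
           scheme: ScoringScheme | None = None,
           params: KarlinParams | None = None,
           both_strands: bool = True) -> list[Hit]:
    """Word-seeded, ungapped all-vs-all search; best hit per (query, subject).

    No query filtering/masking is applied.  E-values use the summed subject
    database length.
    """
    scheme = scheme or ScoringScheme()
    if not query_db or not subject_db:
        return []
    params = params or karlin_params(scheme)
    w = scheme.word_size
    sids = sorted(subject_db)
    sarrs = [seq_array(subject_db[sid]) for sid in sids]
    n_total = sum(len(a) for a in sarrs)
    idx = _word_index(subject_db, w)

    hits: dict[tuple[str, str], Hit] = {}
    for qid in sorted(query_db):
        qseq = query_db[qid]
        m = len(qseq)
        for strand in ("+", "-") if both_strands else ("+",):
            q = qseq if strand == "+" else revcomp(qseq)
            qarr = seq_array(q)
            seen_diag: set[tuple[int, int]] = set()
            for qpos in range(m - w + 1):
                for si, spos in idx.get(q[qpos:qpos + w], ()):
                    dkey = (si, spos - qpos)
                    if dkey in seen_diag:
                        continue
                    seen_diag.add(dkey)
                    seg = _best_segment(qarr, sarrs[si], qpos, spos, w,
                                        scheme.match, scheme.mismatch,
                                        scheme.xdrop)
                    if seg is None:
                        continue
                    score, q_start, q_end = seg
                    ev = params.K * m * n_total * exp(-params.lam * score)
                    key = (qid, sids[si])
                    if key not in hits or score > hits[key].raw_score:
                        diag = spos - qpos
                        hits[key] = Hit(
                            query_id=qid, subject_id=sids[si],
                            q_span=(q_start, q_end),
                            s_span=(q_start + diag, q_end + diag),
                            raw_score=score, aln_len=q_end - q_start,
                            evalue=ev, strand=strand)
    return sorted(hits.values(), key=lambda h: (h.query_id, h.evalue, h.subject_id))


def flag_specific(query_db: dict[str, str], subject_db: dict[str, str],
                  scheme: ScoringScheme | None = None,
                  len_thresh: int = 90, e_thresh: float = 1e-40,
                  hits: list[Hit] | None = None) -> SpecificityResult:
    """Flag each query junction specific unless some hit is strictly longer
    than len_thresh bases AND has E-value strictly below e_thresh."""
    if hits is None:
        hits = search(query_db, subject_db, scheme)
    best: dict[str, Hit | None] = {q: None for q in query_db}
    disqualified: set[str] = set()
    for h in hits:
        b = best.get(h.query_id)
        if b is None or h.evalue < b.evalue:
            best[h.query_id] = h
        if h.aln_len > len_thresh and h.evalue < e_thresh:
            disqualified.add(h.query_id)
    specific = {q: q not in disqualified for q in query_db}
    n_spec = sum(specific.values())
    return SpecificityResult(
        best_hit=best, specific=specific, n_specific=n_spec,
        n_total=len(query_db),
        fraction_percent=percent_specific(n_spec, len(query_db)),
        len_thresh=len_thresh, e_thresh=e_thresh)
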