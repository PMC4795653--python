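"""Shared helpers: sequence arithmetic, interval algebra, seeded RNG.

All genomic coordinates in this package are 0-based, half-open intervals on
the top strand; they are converted to 1-based closed intervals only at GFF3
export time.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Stop codons of the standard genetic code.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN alphabet)."""
    return seq.translate(_COMP)[::-1]


def seq_array(seq: str) -> np.ndarray:
    """Sequence as a uint8 array of byte codes, for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(seq_array(a) != seq_array(b)))


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Size of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def footprint_shared(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total number of genomic bases shared by two interval sets."""
    return sum(
        interval_overlap(x, y) for x in merge_intervals(a) for y in merge_intervals(b)
    )


def spawn_rng(seed: int, *tags: int) -> np.random.Generator:
    """Derive an independent child generator from a root seed and a tag path.

    Every stochastic operation in the package draws from a generator obtained
    this way, so one root seed fixes the whole pipeline.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, *tags)))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")
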