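"""Synthetic Otx2-like sequence fixtures.

These are constructed stand-ins, not the real rat Otx2 sequences (which are
not bundled): a reference cDNA and two splice-variant cDNAs built so that
the published variant arithmetic holds by construction —

* the co-amplifying primer pair (P1/P2, the published primer sequences)
  yields a 247 bp product on the reference template;
* the long variant carries an in-frame 24-nt insertion encoding the
  octapeptide GPWASCPA five residues upstream of the homeodomain
  (residues 38-97), giving a 271 bp product;
* the short variant deletes 39 nt (13 codons) inside the homeodomain,
  giving a 208 bp product.

All sequences are deterministic (fixed internal seed).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .orf import PrimerPair
from .util import STOP_CODONS, random_dna, spawn_rng

#: Published co-amplification primers (forward P1, reverse P2).
OTX2_PRIMERS = PrimerPair(name="P1/P2", forward="GGGCTGAGTCTGACCACTTC",
                          reverse="GCTGACGGCACTTAGCTCTT")

#: Octapeptide inserted in the long variant's exon 2.
OCTAPEPTIDE = "GPWASCPA"
_OCTA_CODONS = "GGTCCTTGGGCTAGCTGTCCTGCT"  # GPWASCPA, one codon per residue

HOMEODOMAIN = ("homeodomain", 38, 97)  # 1-based inclusive residue span

_N_RESIDUES = 105
_P1_NT = 45            # forward primer start within the CDS
_RC_P2_NT = 272        # reverse-primer binding site start within the CDS
_INSERTION_NT = 99     # after residue 33: 5 residues upstream of the domain
_DELETION_NT = (195, 234)  # residues 66-78: 13 codons inside the domain


@dataclass
class Otx2LikeFixture:
    primers: PrimerPair
    templates: dict[str, str]   # ref / long_variant / short_variant cDNA
    proteins: dict[str, str]
    cds_start: int              # of the reference template
    homeodomain: tuple[str, int, int]


def _reference_cds() -> str:
    rng = spawn_rng(7, 9)
    codons = []
    for _ in range(_N_RESIDUES):
        c = random_dna(rng, 3)
        while c in STOP_CODONS or c == "ATG":
            c = random_dna(rng, 3)
        codons.append(c)
    cds = list("".join(codons))
    cds[0:3] = "ATG"
    from .util import revcomp
    cds[_P1_NT:_P1_NT + 20] = OTX2_PRIMERS.forward
    cds[_RC_P2_NT - 2:_RC_P2_NT] = "CC"  # keep the overlapping codon stop-free
    cds[_RC_P2_NT:_RC_P2_NT + 20] = revcomp(OTX2_PRIMERS.reverse)
    seq = "".join(cds) + "TAA"
    assert not any(seq[i:i + 3] in STOP_CODONS
                   for i in range(0, len(seq) - 3, 3)), "internal stop planted"
    return seq


def otx2_like_fixture() -> Otx2LikeFixture:
    """Build the reference and variant templates plus their proteins."""
    cds_ref = _reference_cds()
    cds_long = cds_ref[:_INSERTION_NT] + _OCTA_CODONS + cds_ref[_INSERTION_NT:]
    cds_short = cds_ref[:_DELETION_NT[0]] + cds_ref[_DELETION_NT[1]:]

    rng = spawn_rng(7, 10)
    utr5 = random_dna(rng, 57) + "TAA"  # stop immediately upstream of the ATG
    utr3 = random_dna(rng, 60)

    templates = {name: utr5 + cds + utr3 for name, cds in
                 (("ref", cds_ref), ("long_variant", cds_long),
                  ("short_variant", cds_short))}
    proteins = {name: str(Seq(cds[:-3]).translate())
                for name, cds in (("ref", cds_ref), ("long_variant", cds_long),
                                  ("short_variant", cds_short))}
    return Otx2LikeFixture(
        primers=OTX2_PRIMERS, templates=templates, proteins=proteins,
        cds_start=len(utr5), homeodomain=HOMEODOMAIN)
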