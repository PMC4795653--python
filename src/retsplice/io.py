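"""Readers and writers for the flat formats the pipeline exchanges.

FASTA goes through Bio.SeqIO; GFF3 is read back through gffutils so that the
truth annotation written here round-trips through an independent parser.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import AnnotatedGenome


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: "AnnotatedGenome", path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS features (1-based, closed intervals)."""
    lines = ["##gff-version 3"]
    for name, seq in genome.chroms.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for gene in genome.genes:
        g_start = min(s for s, _ in gene.exons) + 1
        g_end = max(e for _, e in gene.exons)
        attrs = f"ID={gene.gene_id}"
        if gene.go_terms:
            terms = ",".join(sorted(gene.go_terms)).replace(";", " ")
            attrs += f";Ontology_term={terms}"
        lines.append(
            f"{gene.chrom}\tretsplice\tgene\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\t{attrs}"
        )
        mrna_id = f"{gene.gene_id}.t1"
        lines.append(
            f"{gene.chrom}\tretsplice\tmRNA\t{g_start}\t{g_end}\t.\t{gene.strand}\t.\t"
            f"ID={mrna_id};Parent={gene.gene_id}"
        )
        for i, (s, e) in enumerate(gene.exons):
            lines.append(
                f"{gene.chrom}\tretsplice\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                f"ID={mrna_id}.exon{i};Parent={mrna_id}"
            )
        for s, e in gene.cds_genomic_spans():
            lines.append(
                f"{gene.chrom}\tretsplice\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t0\t"
                f"ID={mrna_id}.cds;Parent={mrna_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> list[dict]:
    """Read a GFF3 annotation back into plain gene dicts (0-based half-open).

    Uses gffutils so the round-trip check does not share code with the writer.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(g, featuretype="mRNA"):
            exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
            cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        genes.append({
            "gene_id": g.id,
            "chrom": g.seqid,
            "strand": g.strand,
            "exons": exons,
            "cds_genomic": cds,
            "go_terms": set(g.attributes.get("Ontology_term", [])),
        })
    return sorted(genes, key=lambda d: d["gene_id"])


def write_bed12(rows: Iterable[dict], path: str | os.PathLike) -> None:
    """Write one BED12 line per entry.

    Each row needs: chrom, start, end, name, strand and a list of half-open
    ``blocks`` in genomic coordinates; score is optional.
    """
    with open(path, "w") as fh:
        for r in rows:
            blocks = sorted(r["blocks"])
            start = blocks[0][0]
            end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            starts = ",".join(str(s - start) for s, _ in blocks) + ","
            fh.write(
                "\t".join(map(str, [
                    r["chrom"], start, end, r["name"], r.get("score", 0),
                    r["strand"], start, end, "0,0,0", len(blocks), sizes, starts,
                ])) + "\n"
            )


def read_bed12(path: str | os.PathLike) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            rows.append({
                "chrom": f[0], "start": start, "end": int(f[2]), "name": f[3],
                "score": float(f[4]), "strand": f[5], "blocks": blocks,
            })
    return rows


def write_tsv(path: str | os.PathLike, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
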