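"""Staged candidate-selection funnel and flat catalog export.

The funnel narrows a clone catalog to characterization-ready genes:

1. keep clones whose gene carries a GO term containing "transcription"
   (case-insensitive substring match — the filter is lexical, not
   ontology-aware);
2. keep clones whose insert is fully sequenced (5' and 3' ends joined,
   directly or through internal reads);
3. collapse the surviving clones to unique genes;
4. keep genes with at least two variants whose coding-region exon chains
   differ AND at least two clones that include the translation initiation
   (an ATG-bearing or complete-CDS prediction);
5. keep genes with a GO term containing "eye".
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

from importlib import resources

from .io import write_tsv

log = logging.getLogger(__name__)

SEQUENCED_STATUSES = {"pairwise_assembled", "fully_sequenced"}


@dataclass
class VariantRecord:
    variant_id: str
    clone_ids: list[str]
    has_atg: bool
    cds_complete: bool
    event_types: list[str] = field(default_factory=list)
    #: hashable signature of the coding-region exon chain; variants with
    #: equal keys do not differ within the protein sequence
    cds_key: str = ""


@dataclass
class GeneCatalogEntry:
    gene_id: str
    species: str
    go_terms: set[str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for v in self.variants:
            key = v.cds_key or v.variant_id
            if key not in seen:
                seen.add(key)
                deduped.append(v)
        self.variants = deduped


@dataclass
class FunnelReport:
    clones_with_go_transcription: list[str]
    fully_sequenced: list[str]
    candidate_genes: list[str]
    genes_with_variant_criteria: list[str]
    genes_with_eye_go: list[str]

    @property
    def staged_counts(self) -> dict[str, int]:
        return {
            "clones_with_go_transcription": len(self.clones_with_go_transcription),
            "fully_sequenced": len(self.fully_sequenced),
            "candidate_genes": len(self.candidate_genes),
            "genes_with_variant_criteria": len(self.genes_with_variant_criteria),
            "genes_with_eye_go": len(self.genes_with_eye_go),
        }


def _has_term(terms: set[str], word: str) -> bool:
    w = word.lower()
    return any(w in t.lower() for t in terms)


def apply_funnel(catalog: list[GeneCatalogEntry],
                 go_annotation: dict[str, set[str]] | None = None,
                 assembly_status: dict[str, str] | None = None,
                 transcription_term: str = "transcription",
                 eye_term: str = "eye") -> FunnelReport:
    """Run the five funnel stages over a gene catalog.

    ``go_annotation`` supplements the per-entry GO terms; genes with no GO
    annotation at all are excluded with a warning.  ``assembly_status`` maps
    clone ids to assembly statuses; clones without a status are taken as
    fully sequenced (the catalog is assumed post-assembly).
    """
    go_annotation = go_annotation or {}
    entries = []
    for e in sorted(catalog, key=lambda e: (e.gene_id, e.species)):
        terms = set(e.go_terms) | set(go_annotation.get(e.gene_id, set()))
        if not terms:
            log.warning("gene %s has no GO annotation: excluded", e.gene_id)
            continue
        entries.append((e, terms))

    stage1: list[str] = []  # clones, gene GO matches "transcription"
    stage2: list[str] = []  # of those, fully sequenced
    gene_of_clone: dict[str, GeneCatalogEntry] = {}
    for e, terms in entries:
        if not _has_term(terms, transcription_term):
            continue
        for v in e.variants:
            for clone in v.clone_ids:
                gene_of_clone[clone] = e
                stage1.append(clone)
                status = (assembly_status or {}).get(clone, "fully_sequenced")
                if status in SEQUENCED_STATUSES:
                    stage2.append(clone)

    stage3 = sorted({gene_of_clone[c].gene_id for c in stage2})
    by_id = {e.gene_id: (e, terms) for e, terms in entries}

    stage4: list[str] = []
    for gid in stage3:
        e, _ = by_id[gid]
        surviving = [v for v in e.variants
                     if any(c in set(stage2) for c in v.clone_ids)]
        distinct_cds = {v.cds_key or v.variant_id for v in surviving}
        atg_clones = {c for v in surviving if v.has_atg or v.cds_complete
                      for c in v.clone_ids}
        if len(distinct_cds) >= 2 and len(atg_clones) >= 2:
            stage4.append(gid)

    stage5 = [gid for gid in stage4 if _has_term(by_id[gid][1], eye_term)]
    return FunnelReport(stage1, stage2, stage3, stage4, stage5)


# ---------------------------------------------------------------------------
# summary arithmetic used in pipeline reports
# ---------------------------------------------------------------------------

def total_clones(per_library_counts: dict[str, int]) -> int:
    """Total clone/EST count across libraries."""
    return sum(per_library_counts.values())


def fully_sequenced_total(pairwise_assembled: int, internal_closed: int) -> int:
    """Fully sequenced clones: directly end-joined plus closed by internal
    primer reads."""
    return pairwise_assembled + internal_closed


def candidate_gene_percent(n_candidates: int, genes_per_library: dict[str, int]
                           ) -> float:
    """Candidate genes as a percentage of all genes in the database."""
    total = sum(genes_per_library.values())
    if total <= 0:
        raise ValueError("empty gene database")
    return round(100.0 * n_candidates / total, 1)


# ---------------------------------------------------------------------------
# catalog IO
# ---------------------------------------------------------------------------

_CAT_HEADER = ["gene", "species", "variant_id", "clone_ids", "event_types",
               "atg", "cds", "cds_key", "go_terms", "note"]


def export_catalog(catalog: list[GeneCatalogEntry], report: FunnelReport | None,
                   outdir: str | os.PathLike) -> None:
    """Deterministic flat-file export: per-variant TSV, per-gene summary and
    the funnel report as JSON."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for e in sorted(catalog, key=lambda e: (e.gene_id, e.species)):
        for v in sorted(e.variants, key=lambda v: v.variant_id):
            rows.append([
                e.gene_id, e.species, v.variant_id, ";".join(v.clone_ids),
                ";".join(v.event_types), "+" if v.has_atg else "-",
                "+" if v.cds_complete else "-", v.cds_key,
                ";".join(sorted(e.go_terms)), "",
            ])
    write_tsv(os.path.join(outdir, "catalog.tsv"), _CAT_HEADER, rows)
    gene_rows = [
        [e.gene_id, e.species, len(e.variants),
         sum(len(v.clone_ids) for v in e.variants),
         ";".join(sorted(e.go_terms))]
        for e in sorted(catalog, key=lambda e: (e.gene_id, e.species))
    ]
    write_tsv(os.path.join(outdir, "genes.tsv"),
              ["gene", "species", "n_variants", "n_clones", "go_terms"], gene_rows)
    if report is not None:
        payload = dict(report.staged_counts)
        payload["final_genes"] = report.genes_with_eye_go
        with open(os.path.join(outdir, "funnel.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def read_catalog(path: str | os.PathLike) -> list[GeneCatalogEntry]:
    """Read a catalog TSV (as written by export_catalog or packaged data)."""
    entries: dict[tuple[str, str], GeneCatalogEntry] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            key = (f[col["gene"]], f[col["species"]])
            entry = entries.setdefault(key, GeneCatalogEntry(
                gene_id=key[0], species=key[1], go_terms=set(), variants=[]))
            terms = f[col["go_terms"]]
            if terms:
                entry.go_terms |= set(terms.split(";"))
            entry.variants.append(VariantRecord(
                variant_id=f[col["variant_id"]],
                clone_ids=[c for c in f[col["clone_ids"]].split(";") if c],
                has_atg=f[col["atg"]] == "+",
                cds_complete=f[col["cds"]] == "+",
                event_types=[e for e in f[col["event_types"]].split(";") if e],
                cds_key=f[col["cds_key"]] or f[col["variant_id"]],
            ))
    return sorted(entries.values(), key=lambda e: (e.gene_id, e.species))


def load_reference_catalog() -> tuple[list[GeneCatalogEntry], dict[str, set[str]]]:
    """The packaged six-gene retinal transcription-factor catalog with its
    printed ATG/CDS flags, plus its GO annotation."""
    data = resources.files("retsplice") / "data"
    with resources.as_file(data / "retina_tf_catalog.tsv") as p:
        catalog = read_catalog(p)
    go: dict[str, set[str]] = {}
    with (data / "retina_tf_go.tsv").open() as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.rstrip("\n").split("\t")
            go.setdefault(gene, set()).add(term)
    return catalog, go
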