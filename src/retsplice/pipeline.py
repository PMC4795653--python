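"""End-to-end orchestration of the simulated splice-variant survey.

One JSON-serializable configuration drives every stage in dependency order:

    simulate -> ests -> assemble -> map -> events -> junctions -> specificity
                                                  -> orf -> funnel

All randomness derives from the single root seed.  A manifest records the
parameters, per-stage summaries and SHA-256 digests of every output file, so
re-running an identical configuration reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

from . import align, assembly, events, funnel, io, orf, specificity
from .simulate import (AnnotatedGenome, SimConfig, build_clone_pool,
                       derive_sister_species, generate_genome, simulate_ests,
                       spawn_variants)

log = logging.getLogger(__name__)

STAGES = ("simulate", "assemble", "map", "events", "junctions",
          "specificity", "orf", "funnel")
_DEPS = {
    "assemble": ("simulate",),
    "map": ("simulate",),
    "events": ("map",),
    "junctions": ("simulate",),
    "specificity": ("junctions",),
    "orf": ("simulate",),
    "funnel": ("events", "orf"),
}


class StageDependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Pipeline parameters; the analysis thresholds default to the study's
    stated values (min_shared=100, flank=50, word_size=8, len_thresh=90,
    e_thresh=1e-40)."""

    seed: int = 0
    outdir: str = "retsplice_run"
    sim: SimConfig = field(default_factory=SimConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    conserved_fraction: float = 0.5
    max_junction_subs: int = 5
    seed_k: int = 12
    min_intron: int = 40
    min_shared: int = 100
    flank: int = 50
    word_size: int = 8
    len_thresh: int = 90
    e_thresh: float = 1e-40
    transcription_term: str = "transcription"
    eye_term: str = "eye"

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("sim", {}).items()})
        stages = {s: True for s in STAGES}
        stages.update(raw.pop("stages", {}))
        return cls(sim=sim, stages=stages, **raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        return d


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    for stage, deps in _DEPS.items():
        if cfg.stages.get(stage, False):
            missing = [d for d in deps if not cfg.stages.get(d, False)]
            if missing:
                raise StageDependencyError(
                    f"stage {stage!r} requires disabled stage(s) {missing}")

    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {"config": cfg.to_jsonable(), "stages": {}, "outputs": {}}
    out = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731

    genome = transcripts = sister = id_map = None
    if cfg.stages.get("simulate"):
        sim = replace(cfg.sim, seed=cfg.seed)
        genome = generate_genome(sim)
        transcripts = []
        for g in genome.genes:
            transcripts.extend(spawn_variants(g, sim.variant_spec, seed=cfg.seed))
        conserved = [g.gene_id for g in genome.genes
                     [:max(1, int(len(genome.genes) * cfg.conserved_fraction))]]
        sister, id_map = derive_sister_species(
            genome, replace(sim, seed=cfg.seed + 1), seed=cfg.seed + 1,
            conserved_ids=conserved, max_junction_subs=cfg.max_junction_subs,
            flank=cfg.flank)
        io.write_fasta(out("genome_A.fa"), sorted(genome.chroms.items()))
        io.write_fasta(out("genome_B.fa"), sorted(sister.chroms.items()))
        io.write_gff3(genome, out("truth_A.gff3"))
        io.write_gff3(sister, out("truth_B.gff3"))
        io.write_fasta(out("cdna_A.fa"), [
            (t.transcript_id, genome.transcript_seq(t.exons, t.chrom, t.strand))
            for t in transcripts])
        io.write_tsv(out("go_A.tsv"), ["gene_id", "term"],
                     [[g.gene_id, t] for g in genome.genes
                      for t in sorted(g.go_terms)])
        manifest["stages"]["simulate"] = {
            "n_genes": len(genome.genes), "n_transcripts": len(transcripts),
            "n_conserved": len(id_map),
        }

    if cfg.stages.get("assemble"):
        # one clone per gene (the reference transcript): single-event variants
        # are locally identical, so a quality-blind assembler cannot separate
        # them and clone-status accounting would be confounded
        refs = [t for t in transcripts if t.programmed_event == "none"]
        pool = build_clone_pool(refs, seed=cfg.seed)
        reads = simulate_ests(pool, replace(cfg.sim, seed=cfg.seed), genome,
                              ends=("five_prime", "three_prime", "internal"))
        io.write_fasta(out("reads.fa"), [(r.read_id, r.sequence) for r in reads])
        contigs = assembly.assemble(reads)
        clones, counts = assembly.classify_clones(contigs, reads)
        io.write_fasta(out("contigs.fa"),
                       [(c.contig_id, c.consensus) for c in contigs])
        io.write_tsv(out("clones.tsv"), ["clone_id", "status"],
                     [[c.clone_id, c.status] for c in clones])
        manifest["stages"]["assemble"] = {
            "n_reads": len(reads), "n_contigs": len(contigs), "status": counts}

    alignments = []
    if cfg.stages.get("map"):
        index = align.GenomeIndex(genome, k=cfg.seed_k)
        for t in transcripts:
            cdna = genome.transcript_seq(t.exons, t.chrom, t.strand)
            aln = align.seed_and_chain(cdna, index, min_intron=cfg.min_intron,
                                       query_id=t.transcript_id)
            if aln is not None:
                alignments.append(align.refine_splice_sites(aln, genome,
                                                            min_intron=cfg.min_intron))
        io.write_bed12(align.alignments_to_bed_rows(alignments), out("aln_A.bed12"))
        manifest["stages"]["map"] = {
            "n_aligned": len(alignments),
            "mean_identity": round(sum(a.identity for a in alignments)
                                   / max(1, len(alignments)), 4)}

    loci, all_events = [], []
    if cfg.stages.get("events"):
        loci = align.cluster_loci(alignments, min_shared=cfg.min_shared)
        for locus in loci:
            txs = [(a.query_id, a.exons(cfg.min_intron)) for a in locus.members]
            all_events.extend(events.classify_events(
                txs, locus.strand, locus_id=locus.locus_id, genome=genome,
                chrom=locus.chrom))
        io.write_tsv(out("events.tsv"),
                     ["event_id", "locus", "type", "start", "end",
                      "inclusion", "exclusion", "consensus_ok"],
                     [[e.event_id, e.locus_id, e.type, e.interval[0],
                       e.interval[1], e.transcripts[0], e.transcripts[1],
                       e.consensus_ok] for e in all_events])
        manifest["stages"]["events"] = {
            "n_loci": len(loci), "n_events": len(all_events),
            "by_type": {t: sum(1 for e in all_events if e.type == t)
                        for t in events.EVENT_TYPES}}

    junc_a = junc_b = None
    if cfg.stages.get("junctions"):
        def entries(g: AnnotatedGenome) -> list[dict]:
            return [{"transcript_id": f"{gene.gene_id}.ref", "chrom": gene.chrom,
                     "strand": gene.strand, "exons": gene.exons, "cds": gene.cds}
                    for gene in g.genes]

        junc_a = events.extract_junctions(entries(genome), genome,
                                          flank=cfg.flank)
        junc_b = events.extract_junctions(entries(sister), sister,
                                          flank=cfg.flank)
        io.write_fasta(out("junctions_A.fa"),
                       [(j.junction_id, j.seq100) for j in junc_a])
        io.write_fasta(out("junctions_B.fa"),
                       [(j.junction_id, j.seq100) for j in junc_b])
        manifest["stages"]["junctions"] = {"n_A": len(junc_a), "n_B": len(junc_b)}

    if cfg.stages.get("specificity"):
        scheme = specificity.ScoringScheme(word_size=cfg.word_size)
        qdb = {j.junction_id: j.seq100 for j in junc_a}
        sdb = {j.junction_id: j.seq100 for j in junc_b}
        result = specificity.flag_specific(qdb, sdb, scheme,
                                           len_thresh=cfg.len_thresh,
                                           e_thresh=cfg.e_thresh)
        io.write_tsv(out("specificity.tsv"),
                     ["junction_id", "specific", "best_subject", "aln_len",
                      "score", "evalue"],
                     [[q, result.specific[q],
                       result.best_hit[q].subject_id if result.best_hit[q] else "",
                       result.best_hit[q].aln_len if result.best_hit[q] else 0,
                       result.best_hit[q].raw_score if result.best_hit[q] else 0,
                       f"{result.best_hit[q].evalue:.3e}" if result.best_hit[q]
                       else ""] for q in sorted(qdb)])
        with open(out("specificity.json"), "w") as fh:
            json.dump({"n_specific": result.n_specific,
                       "n_total": result.n_total,
                       "percent_specific": result.fraction_percent},
                      fh, indent=2)
        manifest["stages"]["specificity"] = {
            "n_specific": result.n_specific, "n_total": result.n_total,
            "percent": result.fraction_percent}

    predictions = {}
    if cfg.stages.get("orf"):
        rows = []
        for t in transcripts:
            cdna = genome.transcript_seq(t.exons, t.chrom, t.strand)
            p = orf.predict_cds(cdna)
            predictions[t.transcript_id] = p
            rows.append([t.transcript_id, p.frame, p.start, p.end,
                         "+" if p.has_atg else "-",
                         "+" if p.cds_complete else "-", p.protein])
        io.write_tsv(out("orf.tsv"), ["transcript", "frame", "cds_start",
                                      "cds_end", "atg", "cds", "protein"], rows)
        manifest["stages"]["orf"] = {
            "n": len(rows),
            "n_complete": sum(1 for p in predictions.values() if p.cds_complete)}

    if cfg.stages.get("funnel"):
        catalog = _build_catalog(genome, transcripts, all_events, predictions)
        report = funnel.apply_funnel(
            catalog, transcription_term=cfg.transcription_term,
            eye_term=cfg.eye_term)
        funnel.export_catalog(catalog, report, out("funnel"))
        manifest["stages"]["funnel"] = report.staged_counts

    for name in sorted(os.listdir(cfg.outdir)):
        path = os.path.join(cfg.outdir, name)
        if os.path.isfile(path):
            manifest["outputs"][name] = _digest(path)
        elif os.path.isdir(path):
            for sub in sorted(os.listdir(path)):
                manifest["outputs"][f"{name}/{sub}"] = _digest(
                    os.path.join(path, sub))
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _build_catalog(genome, transcripts, all_events, predictions
                   ) -> list[funnel.GeneCatalogEntry]:
    """Assemble a gene catalog from simulation truth plus predicted ORFs."""
    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    event_types_by_tx: dict[str, set[str]] = {}
    for e in all_events:
        event_types_by_tx.setdefault(e.transcripts[0], set()).add(e.type)
    catalog = []
    for gid in sorted(by_gene):
        gene = genome.gene(gid)
        variants = []
        for t in by_gene[gid]:
            p = predictions.get(t.transcript_id)
            variants.append(funnel.VariantRecord(
                variant_id=t.transcript_id,
                clone_ids=list(t.clone_ids) or [t.transcript_id],
                has_atg=bool(p and p.has_atg),
                cds_complete=bool(p and p.cds_complete),
                event_types=sorted(event_types_by_tx.get(t.transcript_id, ())),
                cds_key=_cds_chain_key(t, p),
            ))
        catalog.append(funnel.GeneCatalogEntry(
            gene_id=gid, species="A", go_terms=set(gene.go_terms),
            variants=variants))
    return catalog


def _cds_chain_key(t, p) -> str:
    """Signature of the coding-region exon chain: exon intervals clipped to
    the predicted CDS span in transcript coordinates."""
    if p is None:
        return t.transcript_id
    sense = t.exons if t.strand == "+" else list(reversed(sorted(t.exons)))
    parts, pos = [], 0
    for s, e in sense:
        L = e - s
        lo, hi = max(p.start, pos), min(p.end, pos + L)
        if lo < hi:
            if t.strand == "+":
                parts.append((s + lo - pos, s + hi - pos))
            else:
                parts.append((e - (hi - pos), e - (lo - pos)))
        pos += L
    return ";".join(f"{s}-{e}" for s, e in sorted(parts))
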