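"""End-to-end processing: search -> families -> ORFs -> annotation.

``run_pipeline`` wires the stage modules together on files, mirroring a
batch run of the non-interactive processing step: translated similarity
search (built-in, or ingested from a precomputed tabular file), gene
family assignment, ORF calling with frameshift flagging and naive
single-indel correction, completeness meta-annotation, consensus
functional transfer, and (when subset labels are supplied) enrichment.

All outputs are tab-separated or FASTA text plus a JSON run manifest;
two runs with identical inputs and config produce byte-identical
output trees.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation import MetaAnnotation, TransferredAnnotation, meta_annotate, \
    transfer_annotation
from .config import PipelineConfig
from .enrichment import EnrichmentResult, enrich_subsets
from .families import FamilyAssignment, assign_best_hit, assign_majority
from .io_formats import (
    Hsp,
    Transcript,
    read_annotation_table,
    read_family_table,
    read_fasta,
    read_hits_table,
    read_labels,
    write_fasta,
    write_hits_table,
)
from .orf import OrfCall, call_orf, correct_frameshift_naive
from .search import SearchDatabase, reverse_complement

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory view of one pipeline run (also written to ``outdir``)."""

    transcripts: list[Transcript]
    hits: dict[str, list[Hsp]]
    assignments: dict[str, FamilyAssignment]
    orf_calls: dict[str, OrfCall]
    corrections: dict[str, str | None] = field(default_factory=dict)
    meta: dict[str, MetaAnnotation] = field(default_factory=dict)
    transfers: dict[str, TransferredAnnotation] = field(default_factory=dict)
    enrichment: list[EnrichmentResult] = field(default_factory=list)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    transcripts_fasta: str | Path,
    family_table: str | Path,
    outdir: str | Path,
    proteins_fasta: str | Path | None = None,
    hits_table: str | Path | None = None,
    annotation_table: str | Path | None = None,
    labels_table: str | Path | None = None,
    config: PipelineConfig | None = None,
    assignment_method: str = "best_hit",
    transfer_source: str = "family_consensus",
    correct_frameshifts: bool = True,
) -> PipelineResult:
    """Run the full processing step on files and write all outputs.

    Exactly one of ``proteins_fasta`` (built-in translated search) or
    ``hits_table`` (precomputed BLAST/RapSearch2 tabular hits) must be
    supplied.  ``annotation_table`` is required when ``transfer_source``
    involves the family consensus or the best hit's terms;
    ``labels_table`` switches on subset enrichment.
    """
    config = config or PipelineConfig()
    if (proteins_fasta is None) == (hits_table is None):
        raise ValueError("supply exactly one of proteins_fasta or hits_table")
    if assignment_method not in ("best_hit", "majority"):
        raise ValueError(f"invalid assignment_method {assignment_method!r}")
    if transfer_source not in ("family_consensus", "best_hit", "both", "none"):
        raise ValueError(f"invalid transfer_source {transfer_source!r}")
    if transfer_source != "none" and annotation_table is None:
        raise ValueError(
            f"transfer_source={transfer_source!r} requires an annotation table"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    transcripts = read_fasta(transcripts_fasta, kind="dna")
    genes = read_family_table(family_table)
    gene_terms = (read_annotation_table(annotation_table)
                  if annotation_table else {})
    labels = read_labels(labels_table) if labels_table else {}

    # --- similarity search -------------------------------------------------
    if hits_table is not None:
        lengths = {t.id: len(t.seq) for t in transcripts}
        all_hits = read_hits_table(hits_table, lengths,
                                   evalue_cutoff=config.evalue_cutoff)
    else:
        proteins = {t.id: t.seq for t in read_fasta(proteins_fasta,
                                                    kind="protein")}
        db = SearchDatabase(proteins)
        all_hits = []
        for t in transcripts:
            all_hits.extend(db.search(t, evalue_cutoff=config.evalue_cutoff))
        write_hits_table(all_hits, outdir / "hits.tsv")
    hits_by_qid: dict[str, list[Hsp]] = {}
    for h in all_hits:
        hits_by_qid.setdefault(h.qid, []).append(h)

    # --- family assignment -------------------------------------------------
    assignments: dict[str, FamilyAssignment] = {}
    for t in transcripts:
        th = hits_by_qid.get(t.id, [])
        if assignment_method == "best_hit":
            assignments[t.id] = assign_best_hit(th, genes, transcript_id=t.id)
        else:
            assignments[t.id] = assign_majority(th, genes,
                                                k=config.topk_majority,
                                                transcript_id=t.id)

    # --- ORF calling and naive correction ----------------------------------
    orf_calls: dict[str, OrfCall] = {}
    corrections: dict[str, str | None] = {}
    for t in transcripts:
        call = call_orf(t, hits_by_qid.get(t.id, []))
        orf_calls[t.id] = call
        if correct_frameshifts and call.frameshift_flagged:
            corrections[t.id] = correct_frameshift_naive(
                t, hits_by_qid.get(t.id, []))

    # --- meta-annotation ---------------------------------------------------
    members_of: dict[str, list[str]] = {}
    for g in genes.values():
        if g.family_id:
            members_of.setdefault(g.family_id, []).append(g.id)
    meta: dict[str, MetaAnnotation] = {}
    for t in transcripts:
        fam = assignments[t.id].family_id
        lengths_nt = ([genes[m].cds_length_nt for m in members_of.get(fam, [])]
                      if fam else None)
        call = orf_calls[t.id]
        meta[t.id] = meta_annotate(call.orf_len_nt, lengths_nt,
                                   call.has_start, call.has_stop,
                                   config, transcript_id=t.id)

    # --- functional transfer -----------------------------------------------
    transfers: dict[str, TransferredAnnotation] = {}
    if transfer_source != "none":
        for t in transcripts:
            a = assignments[t.id]
            family_terms = None
            if a.family_id:
                family_terms = [gene_terms.get(m, set())
                                for m in sorted(members_of[a.family_id])]
            best_terms = gene_terms.get(a.best_hit_id, set()) \
                if a.best_hit_id else set()
            transfers[t.id] = transfer_annotation(
                family_terms, best_terms, transfer_source, config,
                transcript_id=t.id)

    # --- subset enrichment -------------------------------------------------
    enrichment: list[EnrichmentResult] = []
    if labels:
        transcript_terms = {tid: tr.terms for tid, tr in transfers.items()}
        enrichment = enrich_subsets(labels, transcript_terms,
                                    [t.id for t in transcripts], config)

    result = PipelineResult(transcripts, hits_by_qid, assignments, orf_calls,
                            corrections, meta, transfers, enrichment)
    _write_outputs(result, transcripts, outdir)
    _write_manifest(
        result, config, outdir,
        inputs={k: Path(v) for k, v in {
            "transcripts": transcripts_fasta, "families": family_table,
            "proteins": proteins_fasta, "hits": hits_table,
            "annotation": annotation_table, "labels": labels_table,
        }.items() if v is not None},
    )
    return result


def _write_outputs(result: PipelineResult, transcripts: list[Transcript],
                   outdir: Path) -> None:
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("transcript_id\tfamily_id\tmethod\tvote_summary\tbest_hit_id\n")
        for t in transcripts:
            a = result.assignments[t.id]
            votes = ";".join(f"{fam}:{c}" for fam, c in sorted(a.votes.items()))
            fh.write(f"{a.transcript_id}\t{a.family_id or ''}\t{a.method}\t"
                     f"{votes}\t{a.best_hit_id or ''}\n")

    with open(outdir / "orf.tsv", "w") as fh:
        fh.write("transcript_id\tframe\torf_start\torf_end\thas_start\t"
                 "has_stop\tframeshift_flagged\tevidence_frames\n")
        for t in transcripts:
            c = result.orf_calls[t.id]
            frames = ",".join(str(f) for f in sorted(c.evidence_frames))
            fh.write(f"{c.transcript_id}\t{c.frame if c.frame is not None else ''}"
                     f"\t{c.orf_start}\t{c.orf_end}\t{int(c.has_start)}\t"
                     f"{int(c.has_stop)}\t{int(c.frameshift_flagged)}\t{frames}\n")

    orf_nt, orf_aa = [], []
    for t in transcripts:
        c = result.orf_calls[t.id]
        region = t.seq[c.orf_start:c.orf_end]
        if c.frame is not None and c.frame < 0:
            region = reverse_complement(region)
        orf_nt.append((t.id, region))
        orf_aa.append((t.id, c.protein))
    write_fasta(orf_nt, outdir / "orf_nt.fasta")
    write_fasta(orf_aa, outdir / "orf_proteins.fasta")

    corrected = [(tid, seq) for tid, seq in sorted(result.corrections.items())
                 if seq is not None]
    if corrected:
        write_fasta(corrected, outdir / "corrected.fasta")

    with open(outdir / "meta_annotation.tsv", "w") as fh:
        fh.write("transcript_id\tlabel\ttrimmed_mean\ttrimmed_sd\tthreshold\n")
        for t in transcripts:
            m = result.meta[t.id]
            fmt = lambda v: "" if v is None else f"{v:.3f}"  # noqa: E731
            fh.write(f"{m.transcript_id}\t{m.label}\t{fmt(m.trimmed_mean)}\t"
                     f"{fmt(m.trimmed_sd)}\t{fmt(m.threshold)}\n")

    if result.transfers:
        with open(outdir / "transferred_annotation.tsv", "w") as fh:
            fh.write("transcript_id\tterm_id\tterm_type\tsource\n")
            for t in transcripts:
                tr = result.transfers[t.id]
                for term_id, term_type in sorted(tr.terms):
                    fh.write(f"{t.id}\t{term_id}\t{term_type}\t{tr.source}\n")

    if result.enrichment:
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("label\tterm_id\tterm_type\tk\tn\tK\tN\tp_raw\tp_adj\t"
                     "significant\n")
            for r in result.enrichment:
                fh.write(f"{r.label}\t{r.term_id}\t{r.term_type}\t{r.k}\t{r.n}"
                         f"\t{r.K}\t{r.N}\t{r.p_raw:.6e}\t{r.p_adj:.6e}\t"
                         f"{int(r.significant)}\n")


def _write_manifest(result: PipelineResult, config: PipelineConfig,
                    outdir: Path, inputs: dict[str, Path]) -> None:
    manifest = {
        "tool": "transannot",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {name: {"path": str(path), "sha256": _sha256(path)}
                   for name, path in sorted(inputs.items())},
        "counts": {
            "transcripts": len(result.transcripts),
            "hsps": sum(len(v) for v in result.hits.values()),
            "assigned": sum(a.family_id is not None
                            for a in result.assignments.values()),
            "frameshift_flagged": sum(c.frameshift_flagged
                                      for c in result.orf_calls.values()),
            "corrected": sum(s is not None
                             for s in result.corrections.values()),
            "enrichment_tests": len(result.enrichment),
        },
    }
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, outdir / "manifest.json")
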