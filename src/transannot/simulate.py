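"""Seeded generator of reference proteomes and benchmark transcript sets.

The generator builds everything the pipeline consumes so that every
stage runs end to end with no downloads: gene families grown from a
common root protein by BLOSUM62-weighted substitution (with small
in-frame length jitter so family CDS-length statistics are
non-degenerate), back-translated coding sequences, GO/domain term
assignments covering both sides of the 50% consensus rule, and three
transcript classes — clean (full CDS plus random UTRs, random strand),
single-indel (exactly one 1-nt insertion or deletion at a uniform
position in the CDS, the classic frameshift benchmark design), and
truncated (a contiguous window of the CDS, for Partial-label tests).

Everything is driven by one ``numpy`` generator seeded from
``SimConfig.rng_seed``; identical configs give byte-identical output
files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import (
    ReferenceGene,
    Transcript,
    write_annotation_table,
    write_family_table,
    write_fasta,
)
from .search import reverse_complement

__all__ = [
    "SimConfig",
    "Reference",
    "TranscriptTruth",
    "generate_reference",
    "generate_transcripts",
    "write_reference",
    "write_transcripts",
    "read_truth_table",
    "score_benchmark",
]

_AA20 = "ARNDCQEGHILKMFPSTWYV"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOPS = sorted(_TABLE.stop_codons)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    rng_seed: int = 42
    n_families: int = 50
    species: tuple[str, ...] = ("spA", "spB", "spC", "spD")
    family_size_range: tuple[int, int] = (4, 12)
    root_protein_length_range: tuple[int, int] = (120, 500)
    substitution_rate: float = 0.15
    length_jitter_fraction: float = 0.05
    n_clean_transcripts: int = 200
    n_indel_transcripts: int = 200
    n_truncated_transcripts: int = 50
    truncation_fraction: float = 0.4
    utr_length_range: tuple[int, int] = (0, 60)
    term_pool_size: int = 100
    terms_per_family: tuple[int, int] = (1, 4)

    def __post_init__(self) -> None:
        for name in ("n_families", "n_clean_transcripts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("substitution_rate", "length_jitter_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.truncation_fraction < 1:
            raise ValueError("truncation_fraction must be in (0, 1)")


@dataclass
class Reference:
    """Generated reference content: genes with proteins, CDS, families, terms."""

    genes: dict[str, ReferenceGene]
    cds: dict[str, str]

    def proteins(self) -> dict[str, str]:
        return {gid: g.protein_seq for gid, g in self.genes.items()
                if g.protein_seq}

    def family_members(self, family_id: str) -> list[str]:
        return sorted(g.id for g in self.genes.values()
                      if g.family_id == family_id)


@dataclass
class TranscriptTruth:
    """Ground truth for one generated transcript."""

    transcript_id: str
    klass: str  # clean | indel | truncated
    source_gene: str
    family_id: str
    strand: str  # + | -
    indel_pos: int | None = None  # 0-based offset within the CDS
    indel_type: str | None = None  # ins | del
    kept_fraction: float | None = None
    cds_length: int | None = None  # source CDS length before any edit


def _substitution_weights() -> dict[str, np.ndarray]:
    """Per amino acid, replacement probabilities over the other 19,
    proportional to 2**BLOSUM62 score (similar residues preferred)."""
    m = substitution_matrices.load("BLOSUM62")
    weights = {}
    for a in _AA20:
        w = np.array([2.0 ** m[a, b] if b != a else 0.0 for b in _AA20])
        weights[a] = w / w.sum()
    return weights


_SUB_WEIGHTS = _substitution_weights()


def _mutate_protein(root: str, rate: float, rng: np.random.Generator) -> str:
    out = list(root)
    for i in range(1, len(out)):  # position 0 stays M (the start codon)
        if rng.random() < rate:
            out[i] = _AA20[rng.choice(20, p=_SUB_WEIGHTS[out[i]])]
    return "".join(out)


def _jitter_length(protein: str, max_fraction: float,
                   rng: np.random.Generator) -> str:
    if max_fraction <= 0 or rng.random() < 0.3:
        return protein
    max_block = max(1, int(max_fraction * len(protein)))
    block = int(rng.integers(1, max_block + 1))
    pos = int(rng.integers(1, max(2, len(protein) - block)))
    if rng.random() < 0.5:
        return protein[:pos] + protein[pos + block:]  # in-frame deletion
    return protein[:pos] + protein[pos:pos + block] * 2 + protein[pos + block:]


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def generate_reference(config: SimConfig | None = None) -> Reference:
    """Generate gene families, proteins, coding sequences, and terms."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.rng_seed)
    term_pool = (
        [(f"GO:{i + 1:07d}", "GO") for i in range(int(0.7 * config.term_pool_size))]
        + [(f"IPR{i + 1:06d}", "domain")
           for i in range(config.term_pool_size - int(0.7 * config.term_pool_size))]
    )
    genes: dict[str, ReferenceGene] = {}
    cds: dict[str, str] = {}
    lo_n, hi_n = config.family_size_range
    lo_len, hi_len = config.root_protein_length_range
    for fi in range(config.n_families):
        family_id = f"F{fi + 1:04d}"
        root_len = int(rng.integers(lo_len, hi_len + 1))
        root = "M" + "".join(_AA20[i] for i in rng.integers(0, 20, root_len - 1))
        size = int(rng.integers(lo_n, hi_n + 1))
        members: list[ReferenceGene] = []
        for mi in range(size):
            species = config.species[int(rng.integers(len(config.species)))]
            protein = _jitter_length(
                _mutate_protein(root, config.substitution_rate, rng),
                config.length_jitter_fraction, rng)
            gid = f"{species}_{family_id}_m{mi + 1:02d}"
            gene_cds = _back_translate(protein, rng)
            members.append(ReferenceGene(
                id=gid, species=species, family_id=family_id,
                cds_length_nt=len(gene_cds), protein_seq=protein))
            cds[gid] = gene_cds
        n_terms = int(rng.integers(config.terms_per_family[0],
                                   config.terms_per_family[1] + 1))
        term_idx = rng.choice(len(term_pool), size=n_terms, replace=False)
        for ti in sorted(term_idx):
            term = term_pool[int(ti)]
            frac = rng.uniform(0.3, 1.0)
            n_carriers = max(1, int(round(frac * size)))
            carriers = rng.choice(size, size=n_carriers, replace=False)
            for ci in carriers:
                members[int(ci)].terms.add(term)
        for g in members:
            genes[g.id] = g
    return Reference(genes=genes, cds=cds)


def _random_utr(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def generate_transcripts(
    reference: Reference, config: SimConfig | None = None
) -> tuple[list[Transcript], list[TranscriptTruth]]:
    """Generate clean, single-indel and truncated transcripts with truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.rng_seed + 1)
    gene_ids = sorted(reference.cds)
    lo_u, hi_u = config.utr_length_range
    transcripts: list[Transcript] = []
    truth: list[TranscriptTruth] = []

    def _pick_gene() -> str:
        return gene_ids[int(rng.integers(len(gene_ids)))]

    def _with_utrs(core: str) -> str:
        utr5 = _random_utr(int(rng.integers(lo_u, hi_u + 1)), rng)
        utr3 = _random_utr(int(rng.integers(lo_u, hi_u + 1)), rng)
        return utr5 + core + utr3

    def _apply_strand(seq: str) -> tuple[str, str]:
        if rng.random() < 0.5:
            return seq, "+"
        return reverse_complement(seq), "-"

    for i in range(config.n_clean_transcripts):
        gid = _pick_gene()
        seq, strand = _apply_strand(_with_utrs(reference.cds[gid]))
        tid = f"clean_{i + 1:04d}"
        transcripts.append(Transcript(tid, seq))
        truth.append(TranscriptTruth(
            tid, "clean", gid, reference.genes[gid].family_id or "", strand,
            cds_length=len(reference.cds[gid])))

    for i in range(config.n_indel_transcripts):
        gid = _pick_gene()
        gene_cds = reference.cds[gid]
        pos = int(rng.integers(len(gene_cds)))
        if rng.random() < 0.5:
            base = "ACGT"[int(rng.integers(4))]
            mutated = gene_cds[:pos] + base + gene_cds[pos:]
            indel_type = "ins"
        else:
            mutated = gene_cds[:pos] + gene_cds[pos + 1:]
            indel_type = "del"
        seq, strand = _apply_strand(_with_utrs(mutated))
        tid = f"indel_{i + 1:04d}"
        transcripts.append(Transcript(tid, seq))
        truth.append(TranscriptTruth(
            tid, "indel", gid, reference.genes[gid].family_id or "", strand,
            indel_pos=pos, indel_type=indel_type, cds_length=len(gene_cds)))

    for i in range(config.n_truncated_transcripts):
        gid = _pick_gene()
        gene_cds = reference.cds[gid]
        keep = max(3, int(config.truncation_fraction * len(gene_cds)))
        start = int(rng.integers(0, len(gene_cds) - keep + 1))
        seq, strand = _apply_strand(gene_cds[start:start + keep])
        tid = f"trunc_{i + 1:04d}"
        transcripts.append(Transcript(tid, seq))
        truth.append(TranscriptTruth(
            tid, "truncated", gid, reference.genes[gid].family_id or "", strand,
            kept_fraction=config.truncation_fraction,
            cds_length=len(gene_cds)))

    return transcripts, truth


TRUTH_HEADER = ["transcript_id", "class", "source_gene", "family_id", "strand",
                "indel_pos", "indel_type", "kept_fraction", "cds_length"]


def write_reference(reference: Reference, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = [reference.genes[gid] for gid in sorted(reference.genes)]
    write_fasta(((g.id, g.protein_seq or "") for g in genes),
                outdir / "proteins.fasta")
    write_fasta(((gid, reference.cds[gid]) for gid in sorted(reference.cds)),
                outdir / "cds.fasta")
    write_family_table(genes, outdir / "families.tsv")
    write_annotation_table({g.id: g.terms for g in genes if g.terms},
                           outdir / "annotation.tsv")


def write_transcripts(transcripts: Sequence[Transcript],
                      truth: Sequence[TranscriptTruth],
                      outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(transcripts, outdir / "transcripts.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("\t".join(TRUTH_HEADER) + "\n")
        for t in truth:
            fh.write("\t".join([
                t.transcript_id, t.klass, t.source_gene, t.family_id, t.strand,
                "" if t.indel_pos is None else str(t.indel_pos),
                t.indel_type or "",
                "" if t.kept_fraction is None else repr(t.kept_fraction),
                "" if t.cds_length is None else str(t.cds_length),
            ]) + "\n")


def read_truth_table(path: str | Path) -> list[TranscriptTruth]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != TRUTH_HEADER:
            raise ValueError(f"{path}: unexpected truth header {header}")
        out = []
        for row in reader:
            if not row:
                continue
            tid, klass, gene, fam, strand, pos, itype, kept, cds_len = row
            out.append(TranscriptTruth(
                tid, klass, gene, fam, strand,
                indel_pos=int(pos) if pos else None,
                indel_type=itype or None,
                kept_fraction=float(kept) if kept else None,
                cds_length=int(cds_len) if cds_len else None))
    return out


def score_benchmark(
    orf_calls: dict[str, "object"],
    truth: Sequence[TranscriptTruth],
    assignments: dict[str, str | None] | None = None,
    corrections: dict[str, str | None] | None = None,
    n_position_bins: int = 3,
) -> dict:
    """Benchmark metrics of a pipeline run against the generator's truth.

    Returns sensitivity (fraction of single-indel transcripts flagged;
    None when no indel transcripts exist), false-positive rate on clean
    transcripts, per-relative-position miss rates of indels in
    ``n_position_bins`` bins, and — when provided — family-assignment
    accuracy and naive-correction success rate.
    """
    truth_ids = {t.transcript_id for t in truth}
    missing = truth_ids - set(orf_calls)
    if missing:
        raise ValueError(f"ORF calls missing for {len(missing)} transcripts, "
                         f"e.g. {sorted(missing)[:3]}")
    clean = [t for t in truth if t.klass == "clean"]
    indel = [t for t in truth if t.klass == "indel"]
    flagged = {tid for tid, c in orf_calls.items() if c.frameshift_flagged}

    metrics: dict = {
        "n_clean": len(clean),
        "n_indel": len(indel),
        "fpr": (sum(t.transcript_id in flagged for t in clean) / len(clean)
                if clean else None),
        "sensitivity": (sum(t.transcript_id in flagged for t in indel)
                        / len(indel) if indel else None),
    }

    bins: list[dict] = []
    for b in range(n_position_bins):
        lo, hi = b / n_position_bins, (b + 1) / n_position_bins
        members = [
            t for t in indel
            if t.indel_pos is not None
            and lo <= _relative_indel_pos(t) < (hi if b < n_position_bins - 1
                                                else hi + 1e-9)
        ]
        n_missed = sum(t.transcript_id not in flagged for t in members)
        bins.append({
            "bin": b, "lo": lo, "hi": hi, "n": len(members),
            "miss_rate": n_missed / len(members) if members else None,
        })
    metrics["position_bins"] = bins

    if assignments is not None:
        with_truth = [t for t in truth if t.family_id]
        correct = sum(assignments.get(t.transcript_id) == t.family_id
                      for t in with_truth)
        metrics["n_family_truth"] = len(with_truth)
        metrics["family_accuracy"] = (correct / len(with_truth)
                                      if with_truth else None)
    if corrections is not None:
        attempted = {tid: c for tid, c in corrections.items()
                     if tid in {t.transcript_id for t in indel}}
        metrics["n_correction_attempted"] = len(attempted)
        if attempted:
            metrics["correction_success"] = (
                sum(c is not None for c in attempted.values()) / len(attempted)
            )
    return metrics


def _relative_indel_pos(t: TranscriptTruth) -> float:
    """Indel position as a fraction of the source CDS length."""
    if t.indel_pos is None or not t.cds_length:
        return 0.0
    return t.indel_pos / t.cds_length
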