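# Methods

This note documents the models and procedures implemented in
`transannot`, the parameters that matter, the design choices that were
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Problem setting

De novo assembled transcriptomes (RNA-Seq or EST) for species without a
reference genome need annotation before any biology can be read off
them: which reading frame is coding, whether a transcript is a fragment
or a full-length coding sequence, which gene family it belongs to, and
which functions can be transferred to it by homology. Assemblies also
contain short insertion/deletion errors that shift the reading frame
mid-transcript, so frame detection has to be robust to a frameshift
rather than assuming one frame per transcript.

`transannot` implements the non-interactive processing core of such a
pipeline: translated similarity search, gene-family assignment, ORF
extraction with frameshift flagging, completeness meta-annotation,
consensus functional transfer, subset enrichment, and gap-column editing
of family alignments.

## Translated search

Each transcript is translated in all six frames (standard genetic code;
stop codons rendered `*`; any codon containing a non-ACGT character
rendered `X`) and aligned locally against each reference protein with
Smith-Waterman, BLOSUM62, and affine gaps costing `open + g·extend`
(defaults 11/1, the common translated-search setting). The dynamic
programming itself is delegated to Biopython's `PairwiseAligner`; a k=5
exact amino-acid seed index restricts full alignments to (frame,
subject) pairs sharing at least one 5-mer. At the default raw-score
floor (40) and the pipeline E-value cutoff (1e-5) a pair with no shared
5-mer cannot produce a reportable hit in practice, and every pair that
is aligned is aligned exactly; the test suite asserts score equality
against an independent naive O(nm) dynamic program on random instances.

Raw scores S are converted with the standard gapped Karlin-Altschul
constants for BLOSUM62 (λ = 0.267, K = 0.041):
bitscore = (λS − ln K)/ln 2 and E = K·m·n·e^(−λS), with m the frame
translation length and n the total database residues. These statistics
are used only for cutoff filtering and deterministic ranking (bitscore
desc, E-value asc, subject id asc), not to reproduce any external
tool's numbers bit-exactly. Output uses the 13-column BLAST tabular
dialect (outfmt 6 plus an explicit query frame), so externally computed
hit tables are interchangeable with the built-in search. When the frame
column is absent it is derived from the coordinates: plus strand
`((qstart−1) mod 3)+1`; minus strand `−(((L−qstart) mod 3)+1)` with
`qstart` the larger coordinate — minus-strand coordinate conventions
differ between tools, so the explicit column is preferred whenever
available.

## Family assignment

Hits are ranked canonically and assignment is either **best hit** (the
family of the top-ranked hit whose subject is in the family table;
suited to species/clade proteome databases) or **majority voting** over
the families of the top k mappable hits (default k = 5; suited to
reduced per-species representative databases). Vote ties go to the tied
family containing the single best-scoring hit, so k = 1 reduces exactly
to best-hit. Transcripts with no hit get no family and, downstream, no
functional annotation.

For building reduced databases, `select_representatives` picks, per
species within a family, the member with maximal weighted degree in a
similarity graph (genes as nodes, bit scores as edge weights), ties to
the lexicographically smallest gene id. Weighted degree was chosen as
the simplest centrality that is both "central" and "connected";
closeness or eigenvector centrality would be defensible alternatives
but are not implemented.

## ORF calling and frameshift flagging

Frame evidence comes from the HSPs of the single best hit (highest
bitscore subject) only. If all of its HSPs report one frame, the
longest ORF in that frame is extracted; if two or more frames appear,
the transcript is flagged as a putative frameshift and the longest ORF
over all six frames is kept. Hitless transcripts also get the all-frame
longest ORF, unflagged, with no frame recorded.

An ORF is defined as the longest stop-codon-free codon run, not the
longest ATG-initiated run; whether the run starts with ATG and whether
it is terminated by an in-frame stop inside the transcript are recorded
separately (`has_start`, `has_stop`) because the completeness upgrade
below needs them as metadata rather than as requirements. Within a
frame, ties go to the 5′-most run. Across frames the tie-break is
longest protein, then lexicographically smallest protein, then frame
order (+1,+2,+3,−1,−2,−3): the protein-based key makes the call
invariant under reverse complementation of the input, which a pure
frame-order rule is not on exact length ties. Every call is checked, at
construction time, to re-translate its reported region to its reported
protein.

Overlapping same-frame HSPs are not merged before the consistency test;
each HSP contributes its frame independently.

### Naive single-indel correction

Flagged transcripts whose best hit shows exactly two frames on one
strand, with the HSPs separating cleanly into a 5′ and a 3′ block, are
corrected by inserting one or two `N` characters at the midpoint
between the blocks, choosing the insertion size that makes the
downstream block's frame congruent with the upstream one. Re-calling
the ORF on a corrected sequence yields a consistent, unflagged call.
The corrector deliberately refuses anything else — three or more
evidence frames, mixed strands, or overlapping blocks — and overlap is
common in practice because local alignment tends to extend a few
residues past the indel; on the default benchmark roughly a quarter of
flagged single-indel transcripts are separable and corrected. This is a
conservative, evidence-only corrector, not a self-training gene model.

## Completeness meta-annotation

A transcript's ORF length in nucleotides is compared with the CDS
lengths of its assigned family: lengths are sorted, `floor(0.1·n)`
values trimmed from each end, and the mean and sample standard
deviation (n−1 denominator) of the remainder computed. ORFs shorter
than mean − 2·SD are **Partial**; otherwise **Quasi Full Length**,
upgraded to **Full Length** when the ORF has both a start and a stop
codon. Transcripts without a family, or in families of fewer than 5
members, are **No Information**. If trimming would leave fewer than two
values the untrimmed lengths are used, with a warning.

Two choices here were genuinely open. First, the length compared is the
ORF length, not the raw transcript length: UTRs and assembly padding
make transcript length a biased proxy for coding completeness, and the
completeness question being asked is about the coding region. Second,
floor-based trimming keeps at least 80% of the data for small families,
where a ceiling rule would bite hardest. GO terms are counted exactly
as assigned, with no ontology-ancestor propagation before consensus.

## Functional transfer and enrichment

Consensus transfer gives a transcript every GO/domain term carried by
at least `consensus_fraction` (default 0.5) of its family's members —
the denominator is the family size, not the number of annotated
members. Alternatively the best hit's own terms are copied, or the
union of both taken.

Enrichment of a labelled transcript subset is the upper-tail
hypergeometric probability P(X ≥ k) of observing k term-carrying
transcripts in a subset of size n against a background of all N
transcripts in the experiment (the analysis is within-transcriptome;
the genome is never the background), Bonferroni-corrected by the number
m of distinct terms observed in that subset. Only subset-observed terms
are tested, because only enrichment (not depletion) is reported.
Counting is transcript-level: a transcript counts once per term. The
probability is computed with exact integer combinatorics for
N ≤ 1000 and with scipy's log-space survival function above that; the
exact path is verified against exhaustive enumeration of all draws for
N ≤ 12, and the raw test is calibrated (empirical type-I error
0.05 ± 0.02 at α = 0.05) under seeded permutation of term carriers.

## Alignment editing

Before tree building, family alignments are stripped of gap-dominated
columns. Stringent editing removes columns whose gap fraction is
strictly greater than 10%, plus `flank_width` columns on each side of
every such column; relaxed editing removes columns with gap fraction of
at least 25%, with no flanks. The flank width is not fixed by the
procedure this mirrors, so it defaults to the minimal value of 1 column
per side and is configurable; flanks apply to stringent mode only.
Rows of Partial-labelled transcripts, or of excluded species, can be
dropped; reference rows (no meta label) are always kept. The stringent
removed-column set always contains the relaxed set, relaxed editing is
idempotent, and editing never reorders or mutates retained residues.

## Synthetic benchmark

The generator builds the study conditions every test runs under:

* 50 families across 4 species, 4–12 members each, grown from a root
  protein of 120–500 residues by per-site substitution at rate 0.15
  with BLOSUM62-weighted replacement (similar residues preferred), so
  families stay alignable at desk scale.
* Small in-frame length jitter (a duplicated or deleted block of up to
  5% of the codons, in ~70% of members). Without length variance every
  family would have SD = 0 and the mean − 2·SD rule would degenerate:
  a full-length ORF, being the CDS minus its stop codon, would sit just
  below the mean and be called Partial.
* CDS by uniform synonymous back-translation plus a uniform stop codon.
* 1–4 functional terms per family, each assigned to a random 30–100%
  subset of members, so consensus transfer is exercised on both sides
  of the 50% rule.
* Transcripts: 200 clean (full CDS, random 0–60 nt UTRs each side,
  random strand), 200 carrying exactly one 1-nt insertion or deletion
  at a uniform position in the CDS (the classic frameshift-benchmark
  design), and 50 truncated to a contiguous 40% window of the CDS for
  Partial-label tests.

All randomness flows from one `numpy` generator per stage, seeded from
`rng_seed`; identical configs give byte-identical output files.

On these defaults (seed 42) the pipeline flags single-indel transcripts
with sensitivity well above the documented 0.60 floor at a
false-positive rate below 0.05, misses end-of-CDS indels more often
than central ones (the residual coding block on one side becomes too
short to produce a reportable HSP), and assigns ≥95% of transcripts to
their generating family. `scripts/acceptance.py` recomputes all of
these from scratch.

### What the benchmark does not show

The generator emulates none of the hard parts of real assemblies:
chimeric transcripts, allelic and splice variants, sequencing-error
profiles, uneven coverage, or biased codon usage. Because each
transcript's source gene is itself present in the reference database,
search identities are near 100% and family assignment is much easier
than in the realistic cross-species setting, where the correct
assignment rate is known to drop into the 87–98% range depending on
database breadth. Passing the synthetic benchmark therefore validates
the mechanics and determinism of the pipeline, not its field accuracy
on a real non-model transcriptome.

## Numerical and determinism notes

* All ranking keys are total orders (score, E-value, id), so results
  are independent of input row order and database insertion order.
* Coordinates are 1-based inclusive in all external tables (BLAST
  convention) and 0-based half-open internally; conversion happens only
  at I/O boundaries.
* Sequences are uppercased on read, `U` mapped to `T`; IUPAC ambiguity
  codes are tolerated and translate to `X` codons.
* Problem sizes in the test and acceptance suites (200+200+50
  benchmark transcripts, 1,000-transcript ORF suite, 1,000 enrichment
  permutations, 500 alignment-oracle instances) are the package's
  chosen desk-scale study conditions.
* The run manifest records config, input checksums, version, and
  per-stage counts — and deliberately no timestamps, so identical runs
  are byte-identical.
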