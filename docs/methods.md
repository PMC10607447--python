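# Methods

`phagecode` detects stop-codon reassignment in double-stranded DNA phage
genomes, re-annotates genomes under the inferred genetic code, and
compares genomes by nucleotide identity, translated similarity and
intergenomic similarity with threshold clustering into putative species
and genera.  This note records the models, the parameters that matter,
the numerical conventions, and the limits of what the synthetic
benchmarks demonstrate.

## The inference problem

Some tailed phages read the amber codon TAG as glutamine (NCBI
translation table 15); rarer lineages read opal TGA as tryptophan
(table 4).  Annotated under the standard bacterial code (table 11),
such genomes look pathological: characteristic genes — terminase large
subunit, tail tape measure protein, portal and capsid genes — fragment
into short same-frame ORFs separated by in-frame "stop" codons, and the
genome may carry suppressor tRNAs whose anticodon pairs with the stop
codon (anticodon CTA decodes TAG).  Re-annotation under the correct
table composes the fragments into full-length genes.  The pipeline
turns that rescue logic into an automated decision.

## ORF calling and the coding model

`find_orfs` is a deterministic six-frame caller: an ORF runs from a
start codon ({ATG, GTG, TTG} by default) to the next in-frame stop of
the genetic code in use, keeping the longest ORF per stop (minimum
length 30 aa).  There is no ribosome-binding-site model, so two
caller-level artifacts are unavoidable and must be handled
statistically:

* **start over-extension** — the longest ORF for a gene often begins at
  a chance upstream in-frame start codon, deep in non-coding or even
  antisense sequence;
* **shadow ORFs** — long open stretches antisense to, or frame-shifted
  against, real genes.

Both are suppressed with a codon-usage model (`CodingModel`)
self-trained on the codon counts of all called ORFs ≥ 100 aa (a set
dominated by real genes).  The *frame margin* of a sequence is its mean
per-codon log-likelihood minus the best of the five alternative reading
frames of the same locus; real genes score clearly positive (mean
≈ +0.3 nat/codon on synthetic data), shadows negative.  This is a
light-weight analogue of the hexamer scoring used by production
prokaryotic gene callers.  `refined_orf_set` then (1) drops ORFs whose
3'-anchored core (last ≤ 200 codons, anchored at the genuine stop) has
negative margin, (2) trims each survivor's non-coding 5' prefix in
30-codon windows to obtain its *coding span*, and (3) greedily selects
ORFs by coding-span length allowing ≤ 30 nt of span overlap (short gene
overlaps are common in phages; nested shadows are not).  Emitted
annotations additionally snap each start to the first start codon
inside the coding span; snapping discards sequence, so it requires
stronger evidence (window margin < −0.10) than overlap resolution does.

## Recoding decision

For each candidate stop codon c ∈ {TAG, TGA, TAA} the pipeline
compares the genome annotated under table 11 with the annotation under
the table that makes c a sense codon (15 for TAG, 4 for TGA; TAA has no
standard single-codon table and is scored by an explicitly unofficial
pseudo-code, flagged and never recommended).  Two statistics feed the
decision rule:

* **coding-fraction gain** — the genome fraction covered by the union
  of coding spans under the alternative table minus that under table
  11.  Rescue of fragmented genes re-covers the "dead zones" between a
  reassigned stop and the next in-frame start; on standard-code genomes
  the two coverages agree to within ≈ ±1%.
* **interrupted-gene candidates** — the number of gene-scale
  (≥ 80 aa) re-annotated ORFs that span at least one internal
  reassigned stop of type c and survive three guards: the fragment
  upstream of the first reassigned stop must itself be a callable ORF
  (≥ 30 aa) *and* read as coding in its own frame (rejecting intact
  genes extended upstream through an intergenic stop codon), and the
  rescued core downstream of the stop must read best in its own frame
  (rejecting shadow ORFs).  Counting rescued genes rather than
  fragment-pair joins is deliberate: pair joins arise by chance in the
  six-frame call set of any gene-dense genome at rates comparable to
  the true signal, while guarded gene-scale rescues are rare
  (< 1 per 50 kb) on standard-code genomes.

Codon c is recommended iff gain ≥ `g_min` (default 0.02) **and**
candidates ≥ `k_min` (default 5).  Suppressor tRNA support is recorded
as corroborating evidence but is not required — recoded phage genomes
without suppressor tRNA genes are documented.  If two codons pass, the
higher gain wins with a warning (no standard table covers a double
reassignment).  At these defaults the pipeline recovers table 15 on
100/100 synthetic recoded genomes (60 genes, 30% recoded, 1–4 ambers
per recoded gene) and never calls reassignment on 100/100 standard
genomes; sensitivity drops for genomes with fewer than ~5 detectable
recoded genes, which is the intended behaviour of `k_min`.

The pairwise `find_interruptions` operation (upstream fragment, run of
joining stops, open continuation ≥ 10 codons, joined product ≥ 60 aa)
is exposed for locus-level inspection; the readthrough continuation
does not require a start codon, since rescue continues the same gene.

## tRNA detection and suppressor classification

Suppressor classification is exact: a tRNA is a suppressor iff the
reverse complement of its anticodon is one of the three standard stops
(CTA→TAG amber, TCA→TGA opal, TTA→TAA ochre).  Detection uses a
cloverleaf heuristic rather than covariance models: a fully paired
4–5 bp anticodon stem (G·U wobble allowed) around a 7-nt loop with the
anticodon at loop positions 3–5, a T-arm with a TTC motif and ≥ 4/5
stem pairs, and an acceptor stem pairing ≥ 6/7 with plausible
cloverleaf geometry; score = paired bases + motif bonuses, minimum 20,
overlaps resolved best-first.  On random 10-kb sequence the measured
false-positive rate is ≈ 0.02 detections per genome; sensitivity on
natural tRNAs is characterized, not guaranteed — users with
tRNAscan-SE output can ingest it as GFF3 (`anticodon=` attribute or
anticodon coordinates) and get identical downstream classification.
The generator emits the same canonical cloverleaf the detector is
characterized against; this coupling means detection tests exercise
geometry and strand logic, not sensitivity to natural structural
variation.

## Genome comparison

**Nucleotide identity (NI).**  NI = matches / aligned columns of a
global alignment; by the default gap convention internal gap columns
count as mismatch columns and terminal overhang columns are excluded
(`gap_mode="exclude"` drops internal gap columns instead; the published
values this pipeline is compared against carry a ±1 percentage-point
tolerance precisely because the reference tool's convention is
version-dependent).  Scoring is match +2 / mismatch −1 / gap −5
(linear) with the deterministic tie-break diagonal > up > left.  The
gap penalty is set so that a score-optimal alignment of a
substitution-only mutant *is* the identity alignment: shift-by-one
re-pairings inside chance repeats must resolve at least four mismatches
to tie (ties trace back to the diagonal), making NI equal
1 − realized substitution fraction exactly against the generator's
mutation log at the divergences the package simulates (verified up to
15% substitutions at genome scale; near 20% a rare five-fold
resolvable repeat shift can still add a handful of matches, a property
of any score-optimal alignment rather than of this implementation).  Pairs up to ~4 Mcells get full dynamic programming;
larger pairs are aligned by chaining unique 15-mer anchors (longest
increasing subsequence; anchors stranded alone on their own diagonal
are discarded as chance matches) with full DP on the inter-anchor
segments and edlib for oversized segments.  Arguments are canonically
ordered first, so NI is exactly symmetric.

**SG (translated similarity).**  All six reading frames of both
genomes are translated under table 11 (tBLASTx-style) and searched for
ungapped BLOSUM62 local alignments: exact 4-aa seeds, X-drop 20,
HSP score ≥ 50, one extension per diagonal region.  S(a,b) is the sum
of greedily chosen HSPs non-overlapping on the query frames, averaged
over both query directions; SG = S(a,b) / min(S(a,a), S(b,b)), clamped
to [0, 1].  Self-normalization gives SG(self) = 1 exactly; unrelated
20-kb random sequences score 0 (no HSP reaches 50).

**Intergenomic similarity.**  VIRIDIC-style: twice the aligned
identities over the summed genome lengths, computed from the anchored
alignment in local mode (no terminal extension), so unalignable genome
fraction dilutes the value.  A genome versus its exact half scores
2·(L/2)/(3L/2) = 2/3.

**Clustering.**  Similarity matrices are cut at 95% (species) and 70%
(genus), the ICTV bacterial-virus conventions, with single linkage by
default; species clustering runs inside each genus cluster, so the
species partition refines the genus partition for any linkage.  The
published identity values for the three related genomes
(86.4 / 82.7 / 80.4%) yield one genus containing three species.

## Orthology and synteny

Reciprocal best hits between proteomes annotated under each genome's
recommended code (comparing recoded proteomes is essential — under
table 11 recoded genes fragment and their orthologs are missed), with
global affine-gap BLOSUM62 alignments (open −11 / extend −1,
Biopython's PairwiseAligner), thresholds 30% identity over aligned
columns and 50% coverage of the shorter protein; ties break to the
lower ORF index.  `shared_core` intersects pairwise tables through a
graph: a core gene is a connected component with exactly one ORF per
genome.  Synteny is the Kendall rank correlation of ortholog order,
strand-aware (the partner's order is reversed when most ortholog pairs
sit on opposite strands, flagged as an inversion), plus the fraction of
ortholog pairs adjacent in both genomes.

## Synthetic data

The generator emulates the structure that matters to the pipeline:
tightly packed protein-coding genes (defaults: 100 genes of 100–400
codons, 20–120 nt intergenic spacers, ~30% of genes on the minus
strand), GC steered to 44.5% (the published genomes run 44.4–44.5%),
28% of genes carrying 1–3 designed internal TAG codons, and three
suppressor tRNA genes with anticodon CTA — i.e. a phAss-1-like genome
of roughly 90–130 kb.  Genes are drawn codon-wise from a realistic
distribution: a standard average proteome amino-acid composition with
synonymous-codon weights tilted by exp(λ·GC), λ solved so expected
coding GC hits the target.  The non-uniform amino-acid usage makes
sense and antisense frames statistically distinguishable, as in every
real genome; a uniform codon distribution would be reverse-complement
symmetric and would make coding-based shadow discrimination impossible
— a property no real sequence has.  Stop codons are excluded from the
pool, so non-recoded genes contain no in-frame TAG by construction and
recoded genes contain TAG exactly at the designed positions; every
feature and every mutation event is logged in a TruthSet that scanning
the sequence reproduces exactly.

`mutate_genome` applies per-site substitutions (uniform over the three
alternatives) and 1–6 nt indels, logs every event, and remaps feature
coordinates through the indels; the log is the oracle for the NI
exactness checks.

What the synthetic benchmarks do *not* show: real phage genes have
length, strand and codon-usage structure the generator only
caricatures; real intergenic DNA contains promoters and terminators;
real tRNAs vary structurally.  Passing the synthetic suite therefore
demonstrates the statistical machinery and its calibration, not
field performance on arbitrary metagenome-assembled genomes.

## Problem sizes and determinism

The statistical checks run at the sizes stated above (60-gene genomes
for the recoding recovery/false-positive sweeps, 100 seeds per arm;
20-kb sequences for the SG null; 100–500 nt pairs for the NI oracle
equivalence, with genome-scale substitution-only pairs exercising the
anchored route).  Everything is seeded: identical spec + seed gives
byte-identical FASTA, reports and matrices.

## Known limitations

* Start calls are heuristic; over-extended starts are trimmed
  statistically, so reported per-ORF counts (e.g. "N ORFs carry
  internal reassigned stops") are caller-grade, not curated-annotation
  grade.  The published counts for the real genomes ("147 ORFs",
  "41 ORFs (28%)") are themselves caller-dependent and are reported,
  not matched.
* TAA reassignment is scored but cannot be recommended (no standard
  table), and genomes reassigning two stop codons are outside the
  decision rule.
* The tRNA detector trades sensitivity for a near-zero false-positive
  rate; use external tRNAscan-SE calls for inventory-grade tRNA counts.
* NI on genomes with large rearrangements reflects the collinear chain
  only; the no-anchor fallback flags, rather than hides, the absence of
  detectable homology.
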