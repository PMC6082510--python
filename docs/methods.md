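# Methods

## Data model and conventions

Internally all coordinates are 0-based half-open; GFF3 and SAM 1-based
coordinates are converted only at the I/O boundary, and every report prints
1-based positions. Sequences are DNA over {A,C,G,T,N}; `U` on input is
stored as `T`, and conversions are labelled in the RNA alphabet (C→U, U→C)
only after orientation into transcript sense. Gene models are ordered lists
of genomic intervals in transcript sense (ascending on `+`, descending on
`-`), so a spliced CDS and the codon address of any genomic position follow
from one mapping function. The genetic code defaults to the standard table
(NCBI 1), selectable per call; hornwort organelles use the standard code
and nothing in the pipeline assumes otherwise. Circular genomes are handled
at the feature level (an origin-spanning feature is simply two parts);
pileups and the simulator treat the sequence as linear, so reads never span
the origin.

## Pileup

Alignments are filtered to mapped, primary, non-duplicate records; CIGAR
M/=/X columns contribute counts, I/S/H nothing, and D/N leave positions
uncounted for that read. Bases below quality 20 are dropped when qualities
are present (no base filter otherwise); the MAPQ floor defaults to 0. Both
filters are configurable — the upstream mapping tools this replaces expose
no equivalent knobs, so the defaults are deliberately conservative and
explicit. Counts are kept per (position, base, read strand); transcript
sense is resolved later so the pileup stays a single-responsibility
component.

## Calling and thresholds

Editing efficiency is `n_alt / depth` over all quality-passing covering
reads — not `alt/(alt+ref)` — matching the definition of efficiency as the
proportion of cDNA reads carrying the edited nucleotide. Threshold
comparisons are inclusive ("at least"): the organelle presets are 12%
(plastome) and 5% (mitogenome) minimum edited-read fraction. The
minimum-depth floor defaults to 20 reads; observed per-site coverage in the
kind of data this targets runs from ~100× to tens of thousands, so the
floor only guards genome edges and dropouts. Only the single most frequent
non-reference base is tested per position; genuinely multi-allelic
positions surface as anomalies.

Orientation uses the containing feature's strand, falling back to the
nearest gene whose UTR-proxy flank (default 100 bp, configurable) covers
the site; otherwise the conversion is reported on the `+` strand and marked
`unknown`. Organelle annotations lack UTR features, so the flank window is
the only implementable proxy for UTR context. Sites in rRNA genes are
processed normally but flagged, since apparent rRNA "editing" in real data
is typically contamination: transparency over hard exclusion.

Anomalous conversions keep their DNA-alphabet label and a suspected cause:
`polymorphism` for the A→G/T→G/G→T signatures seen at intermediate allele
fractions when DNA from several gametophytes is mixed, `contamination` when
flagged by the screen, else `unknown`.

## Contamination screen

Instead of an online BLAST of alt-supporting reads, the screen computes
k-mer containment (k = 15 by default) of each alt read segment against the
reference locus (±200 bp) and against user-supplied decoy sequences (both
strands). If the median read scores strictly higher against a decoy, the
site is flagged and reported among the anomalies. This is a deterministic,
dependency-free decision rule with the same contract — divergent reads
better explained by a foreign sequence — and the decision threshold (median
margin > 0) is insensitive to read count. Reads shorter than k are skipped
with a warning.

## Effects and conservation

The post-edit codon substitutes the edited base at its codon offset; events
are resolved in the order start_created (codon 0, pre-codon not a start,
post-codon ATG), start_removed (reported, though not a category of the
standard summary tables), stop_created, stop_removed, synonymous, missense.
Conservation against an ortholog protein alignment is deliberately strict:
`conservative` requires the post-edit amino acid to beat the pre-edit one
in column support among the other species; ties are `non_conservative`
("improved conservation" is read literally). Codon indices map to alignment
columns by counting ungapped residues in the study-species row, so gapped
alignments are handled exactly. A missing species row or an all-gap column
yields class `unknown` (logged), which is excluded from per-class
efficiency means. Ortholog alignments are an input (aligned FASTA per
gene); the package does not run an aligner.

## Summaries and rounding

Summary percentages use the denominators the result tables imply:
conversion percentages over all accepted sites, codon-position percentages
over CDS sites, density over genome length. These report percentages are
*truncated* toward zero at two decimals — that is the convention under
which 96/102 prints as 94.11 and 108 sites in a 212,153 bp genome print as
a 0.05% density; half-up rounding would print 94.12 and the truncation
convention is applied uniformly. GC content rounds half-up to one decimal.
The amino-acid conversion matrix counts each edited *codon* once: a codon
hit by two sites contributes a single entry whose destination carries both
edits jointly, and such codons are flagged for audit. Shared sites between
two genomes match on gene (through an optional name map), aligned protein
column (via a per-gene pairwise alignment), and sense conversion.

## Structural statistics

The inverted-repeat finder returns the longest pair of *disjoint, exactly
identical* reverse-complement repeats — plastome IRs of interest are
identical copies, so no mismatch tolerance is offered and the exact-match
property keeps a clean quadratic oracle for testing. Search is binary
search over repeat length with rolling-hash matching between the genome and
its reverse complement; every hash hit is verified by direct comparison.
The quadripartite partition labels the longer single-copy gap LSC; an exact
tie goes to the gap containing position 0 (deterministic). The partition
always tiles the genome: 2·IR + LSC + SSC equals the genome length by
construction, and published organelle records that disagree with their own
arithmetic by a base or two are reported as computed, not forced into
agreement.

## The simulator

The generator emulates the study conditions of a hornwort organelle
transcriptome experiment at desk scale: the default is a 25 kb genome
(organelle-like gene density; the real mitogenome is ~212 kb — the scale is
a package choice so that 20-replicate recovery studies stay fast), 44% GC,
18 CDS genes with occasional single introns plus a tRNA and an rRNA gene,
88 C→U and 20 U→C sites spread over CDS (95, of which 17 U→C), tRNA (1),
intron (2) and UTR-proxy (10) contexts, 100 bp reads at 200× mean depth
with 0.5% iid base error. Per-site efficiencies are drawn from truncated
normals per intended class — conservative mean 0.694, synonymous 0.414
(per-class means reported for hornwort mitogenome editing),
non-conservative 0.55 (no numeric value is reported for this class; it
falls between the other two, and 0.55 sits between them), noncoding 0.50,
all with sd
0.12–0.15, truncated to (0.06, 1]. Polymorphism sites draw allele fractions
uniformly from 0.33–0.88 and conversions in *sense* orientation from
{A→G, T→G, G→T}, so no planted polymorphism can masquerade as C→U/U→C
editing regardless of local gene strand. Contaminant reads are copied from
a decoy — a 10%-divergent copy of the rRNA locus, where contamination
concentrates in real data — and aligned at the homologous position.

Because coding sequence rejects stop codons (AT-rich), raw assembly drifts
above the GC target; a retuning pass flips free intergenic bases (outside
genes, the planted IR and its junction guards) to land on the target
exactly. The planted IR's inner junction is adjusted so the repeat is
exactly maximal and recoverable at its construction length.

Synthetic ortholog alignments are generated consistently with the planted
classes: ortholog rows carry the post-edit amino acid at conservative
columns and the pre-edit one elsewhere, plus 2% background substitutions
away from edited columns. They are gap-free, so codon index equals column.

What the simulator does **not** model: realistic Illumina error profiles,
PCR duplicates, strandedness of the library (read strand is uniform; the
caller is strand-symmetric, which the test suite verifies end to end),
splice-aware reads (reads are genome-contiguous, matching an unspliced
organellar transcript model), and origin-spanning reads. Passing recovery
tests therefore demonstrate correctness of the calling logic under
binomial sampling, iid error and the modelled confounders — not robustness
to mapper artefacts or position-dependent error.

## Validation strategy and known limitations

Every numeric path is checked against an independent oracle: translation
against a hand-entered code table, pileups against a per-read CIGAR
re-walk, the IR finder against an O(n²) dynamic program, codon effects
against exhaustive 64-codon enumeration, and the full caller against
planted truth (exact recovery with noise off; precision/recall ≥ 0.98 and
efficiency MAE ≤ 0.03 at study noise levels, pooled over 20 seeded
replicates). Efficiency MAE at 200× is dominated by binomial sampling
(~0.026), not estimator bias. Genome-edge positions with shallow coverage
can let one or two error reads reach an inclusive threshold; such calls
carry non-editing conversions and land in the anomaly quarantine, but a
C→T error at an edge position can occasionally pass as a false accepted
site — the minimum-depth floor is the guard, and raising it trades edge
sensitivity for specificity. The structural metrics of the real deposited
genomes can only be checked when those sequences are supplied locally; the
corresponding test states what to provide.
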