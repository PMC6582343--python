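# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mitoforge`, in the spirit of a software methods section.

## Read quality control

A read pair is removed when either mate (i) has strictly more than 40%
of its bases at Phred quality ≤ 17, (ii) contains strictly more than 10
`N` bases, or (iii) duplicates an earlier retained pair exactly
(mate 1 vs mate 1 and mate 2 vs mate 2; qualities are ignored, and
reverse-complement orientation is *not* considered duplication). All
boundaries are strict `>` comparisons, so 40/100 low-quality bases or
exactly 10 Ns pass. When several rules fire, the pair is counted under
the first failing rule in the order low-quality → N → duplicate, making
the report deterministic. Duplicate detection keeps one SHA-1
fingerprint per retained pair; a hash collision would silently drop a
non-duplicate pair, which at library scale (≪ 2^80 pairs) is negligible.
In single-end mode the same rules apply to the lone read.

## De Bruijn assembly

K-mers are counted in canonical (strand-merged) form — the
lexicographic minimum of a k-mer and its reverse complement — with k
required odd so no k-mer is its own reverse complement. Windows
containing `N` are skipped. The graph stores one coverage value per
canonical k-mer; adjacency is resolved in both orientations at
traversal time. Three error-removal passes run in order:

1. **Absolute cutoff** — k-mers with count < 2 (default) are dropped.
2. **Relative filtration** — iteratively remove every edge whose
   coverage is strictly below 5% (default) of the maximum coverage
   among edges sharing either of its endpoint junctions, itself
   included (so an isolated edge is never removed), to a fixpoint. The
   filtration applies to edges only.
3. **Tip clipping** — dead-end unbranched paths shorter than 2k whose
   junction-side edge is strictly weaker than the strongest other edge
   at the junction are removed, to a fixpoint; an exact coverage tie
   keeps both branches.

Contigs are maximal unbranched paths, extracted starting from canonical
edges in lexicographic order, which fixes the output deterministically
with no randomness anywhere in the assembler. A path that closes on its
own start node is a circle and is emitted as a rotation with the k−1
wrap-around bases stripped; this also catches the case where a residual
error branch at one junction prevents clean cycle closure but the path
still traverses the whole circle. Linear contigs are canonicalized to
the lexicographic minimum of the sequence and its reverse complement.
Contig coverage is the arithmetic mean of edge coverages along the
path. Contigs shorter than 200 bp (mostly isolated error islands) are
discarded.

Quick mode assembles with the single k = 71. Multi-kmer mode runs each
usable k from the ladder (default 31, 51, 71, 91, capped below the read
length), pools the contigs and removes any contig fully contained in a
longer one at ≥ 99% identity over its whole length (edlib infix
alignment, both strands, with circular targets extended by a wrap
margin). Bubble popping is deliberately not implemented: with 150 bp
reads, a sequencing-error bubble requires two reads carrying the same
error to overlap by at least 2(k−1)+1 bases, which is possible at
k = 71 but impossible at k = 91 — hence the multi-kmer rerun reliably
closes circles that quick mode leaves broken, mirroring the pipeline's
automatic multi-kmer fallback when fewer than 13 complete PCGs are
found. Scaffolding (mate-pair linkage, gap filling) is out of scope;
assembly ends at contigs.

## Mitochondrial scaffold identification

Each candidate is assigned a taxon by majority vote over the best hit
per PCG locus, ties broken by the highest summed bitscore; candidates
without PCG hits stay unassigned. A candidate passes the clade filter
when its assigned taxon's lineage contains the required taxon at the
required rank (order, family or genus); unassigned candidates are
rejected.

The confident score is S_j = A · Σ Cᵢ with Cᵢ on the percent scale
(0–100) and summed over PCG annotations only (tRNA/rRNA never enter the
score or conflict rules). A is the assembler's mean edge coverage for
native contigs and a user-supplied per-sequence mean mapped depth for
external assemblies; the score is stored nowhere — it is always
recomputed from (A, Cᵢ), so the defining equation holds by
construction.

Selection ranks candidates by S_j descending (ties: longer sequence,
then id — a total order, so the result is independent of input order).
The top sequence is accepted; each later sequence is skipped entirely
if it carries any gene already recovered complete; if both the prior
and the new copy of a gene are incomplete, both sequences are kept; a
complete copy found later replaces (demotes) a prior incomplete one.
The search stops once all 13 PCGs are located complete. Independently
of conflicts, every candidate bearing ≥ 5 PCGs is flagged as retained
for identity confirmation. Every decision (accept/skip/demote/
reject/stop) is logged one line per candidate for auditability.

## Annotation

Homology hits for the same gene and strand on one sequence are merged
into a locus when their query intervals overlap or lie within 30 bp;
the lowest-evalue hit is the representative, and when one gene has
overlapping loci on both strands the strand with the higher summed
bitscore wins. The reading frame is anchored at the representative
hit's protein coordinates (codon 1 sits 3·(subject_start−1) nt upstream
of the hit's query start).

Start codons are searched in frame up to 60 nt upstream of the
anchored position first, then downstream; failing both, the boundary
stays at the hit and the start is flagged missing. Stop codons are
searched in frame up to 60 nt downstream of the locus end (a stop
beginning within the last 3 nt of the hit is accepted, since protein
hits exclude the stop). Failing that, a final in-frame `TA` or bare `T`
immediately abutting the next annotated feature (or the sequence end)
is accepted as a polyadenylation-completed stop; the neighbouring
feature boundary used for this test deliberately excludes the locus's
own coordinates. Any in-frame stop before the chosen stop flags the
annotation invalid. Minus-strand loci are refined on the reverse
complement and mapped back (start,end → L−end,L−start). Start/stop
codon sets are {ATG, ATA, GTG} / {TAA, TAG, AGA, AGG} for table 2 and
{ATG, ATA, ATT, ATC, GTG, TTG} / {TAA, TAG} for table 5, following
NCBI conventions for the two tables.

Completeness Cᵢ is the annotated length over the shortest reference
counterpart, capped at 100%: PCGs in codons (a truncated stop counts as
one codon) against the reference amino-acid length, rRNAs in
nucleotides. tRNA completeness is presence-based (100 when annotated);
covariance-model searches either find the structure or do not, and no
meaningful length ratio exists for a 70 nt cloverleaf. tRNA hits above
e-value 0.001 are discarded (≤ is kept); per feature per sequence only
the best-evalue hit survives. rRNA hits from the global search mode are
preferred, local-mode hits being used only when no global hit exists
for that feature. tRNAs may overlap PCGs (biological reality); only
same-feature duplicates are collapsed, and overlapping same-gene PCG
annotations keep the more complete copy.

The control region is called only when all 13 PCGs and both rRNAs are
at completeness 100 and all 22 tRNAs are present; the largest
inter-feature interval (wrapping the origin on circular sequences) of
length ≥ 600 bp is annotated as the D-loop. A control region spanning
the origin is reported by its longer arc — a representational
compromise, since GFF3 features cannot cross the origin; in the
pipeline this case is avoided by rotating circular contigs so the
origin falls mid-way through the largest hit-free interval (normally
the control region) before final annotation, after which the homology
and CM searches are rerun on the rotated sequence. Circularity comes
from assembler metadata, never from native detection.

## Evaluation

Full length means completeness ≥ 95%; below that a recovered gene is
partial. Types: A — all 15 genes (13 PCGs + 2 rRNAs) recovered on one
sequence; B — all 15 on ≥ 2 sequences; C — 8–14 genes; D — fewer than
8. Per-gene identity uses Biopython's global pairwise aligner with
match +1, mismatch −1, gap open −2, gap extension −1 (end gaps
penalized); identity = matches / alignment columns, gap columns
included in the denominator. Among co-optimal alignments the maximum
identity is reported (enumerated exhaustively when there are ≤ 1024
co-optimal alignments, otherwise capped). A recovered gene below 97%
identity to its reference is a false positive. When a gene is split
over several selected sequences, the single most complete copy is
evaluated — conservative, pieces are not summed.

## The simulator

The generator emulates a mammalian-style mitogenome: 13 PCGs with
realistic protein lengths (ATP8 67 aa … ND5 603 aa), 22 tRNAs of 70 nt,
rRNAs of 900/1400 nt, a human-like gene order with the usual
minus-strand genes (ND6 and 8 tRNAs), features abutting directly, and
the control region occupying the remainder of the 16 kb circle
(759 bp at defaults; a configured genome too small for ≥ 600 bp is
rejected). PCGs are clean ORFs: ATG start, sense codons sampled with
the target A+T bias, TAA stops — except ND4, which is written with a
bare `T` stop completed by polyadenylation, so the truncated-stop
annotation path is always exercised. Coding-sequence constraints bias
composition slightly, so non-coding regions are generated at a
compensated A+T probability that brings the genome-wide A+T content to
the configured 0.65 within ±0.02.

Reads are sampled uniformly on the circle (insert ~ N(300, 30²),
2×150 bp, depth 100× by default) with independent substitution errors
at 0.5% per base and constant quality Q35 — deliberately the simplest
model that passes QC: no quality gradients, no indel errors, no
adapter or duplicate structure beyond chance. NUMT decoys are 10–40%
fragments of the genome mutated to 90% identity inside random nuclear
flanks, at nuclear-like depth (2–8×); nuclear contigs are random
sequence at A+T 0.58. Hit tables are generated from the planted truth:
candidates are located on the doubled genome by edlib alignment (or by
bookkeeping for decoys), each overlapped gene region becomes a hit with
coordinates mapped onto the candidate, identity measured from the
actual substrings, and an e-value that decreases monotonically with
alignment length × identity (10^(−len·id/1000), floored at 1e−180) —
a documented surrogate, not a statistical model. Protein hits never
cover the stop codon, matching tBlastn semantics. All randomness flows
from one seeded numpy PCG64 generator per artefact (seed, seed+1,
seed+2, seed+3 for genome, reads, decoys, noise hits).

Passing tests on these fixtures therefore shows correct mechanics of
the algorithms — not robustness to coverage bias, chimeric reads,
heteroplasmy, indel-rich platforms, or real NUMT mosaicism, none of
which the generator produces.

## Problem sizes and numerical choices

The synthetic study conditions are a 16 kb genome at 100× depth
(≈ 5 300 read pairs per run); end-to-end checks use 20 fixed seeds and
the acceptance script 10 derived seeds, sizes chosen so a full
replicate batch runs in minutes on one CPU. Tolerances that matter:
A+T content ±0.02 at L = 16 000 (≈ 5σ of binomial sampling); expected
read-pair count within 10%; NUMT identity within ±2% of target;
contained-contig dedup at 99% identity; candidate-to-genome location
accepts up to 12% edit distance. Tie-breaks are all deterministic and
documented above (lexicographic traversal, longer-sequence-first
ranking, first-occurrence duplicate retention).

## Known limitations

- No scaffolding, gap closing, bubble popping or heteroplasmy handling.
- The hit tables consumed are a 14-column BLAST-tabular dialect and a
  minimal covariance-model table; the toolkit does not run the external
  homology/CM searches itself.
- Origin-spanning control regions on circular sequences are reported by
  their longer arc only.
- The identity measure depends on the stated alignment scoring; other
  scoring schemes (or megablast-style local identity) will differ near
  the 97% boundary.
- Gene-order templates other than the shipped vertebrate order are
  accepted but only the 13+22+2 animal gene complement is supported.
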