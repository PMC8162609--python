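# Methods

This note documents the models, algorithms and numerical choices behind
`pankit`, and what the synthetic fixtures do and do not establish about real
data.

## Stage 1: recovering genes missing from a reference

**Read partitioning.**  Mapping is replaced by the only thing the pipeline
consumes — a mapped/unmapped partition.  A canonical k-mer index of the
reference (k = 21, odd so no k-mer is its own reverse complement) feeds a
seed-and-extend classifier: seed hits are binned by (contig, strand,
diagonal), and a read is *mapped* when a bin collects ≥ 2 seeds and ungapped
extension along that diagonal reaches ≥ 0.90 identity over the read's
aligned span (clipped to contig bounds).  The defaults are chosen so that
substitution-error-free reads drawn from the reference always map while
reads from a gene absent from the reference never do; reads straddling a
planted-gene boundary fail the identity test and correctly join the
unmapped pool.  Gaps are not modelled: a read with an indel relative to the
reference may be called unmapped, which only moves it to assembly.  Paired
routing: both mates unmapped → pair kept; exactly one unmapped → that mate
becomes a singleton, so a mapped read is never fed to assembly.

**Pair repair.**  Before assembly, read lists are split into id-synchronized
pairs (after stripping `/1`/`/2` suffixes) and orphans, so paired input is
always well-formed.  Duplicate ids are an error, not a warning.

**Assembly.**  A de Bruijn unitig assembler: canonical 31-mer counts; k-mers
with multiplicity < 2 removed; short (< 2k) dead-end tips attached at
exactly one end removed to a fixed point (isolated short paths are kept —
they are legitimate small contigs, later subject to the 200 nt length
filter); contigs are maximal non-branching paths.  No bubble popping,
scaffolding or paired-distance use: downstream only needs ORF-bearing
contigs.  Determinism is by lexicographic k-mer iteration and emitting each
unitig as the lexicographic minimum of itself and its reverse complement,
making output independent of read order.

**Annotation.**  Plain prokaryotic ORF calling under genetic code 11: in
each of six frames, for each stop codon, the longest ORF ending at that stop
(earliest in-frame ATG/GTG/TTG after the previous stop) is called when
≥ 150 nt including the stop (a standard prokaryotic minimum, 50 aa).  There
is no ribosome-binding-site or coding-potential model, so overlapping
wrong-frame ORFs inside genuine genes are sometimes called; on synthetic
fixtures whose spacers are stop-rich this inflates counts but never misses
a planted gene, and planted genes are recovered with their exact start.

**Similarity.**  Exact affine-gap Smith–Waterman (Biopython's C aligner;
BLOSUM62 for protein, +1/−2 for nucleotide; a gap of length L costs
11 + L).  Word seeding (4-mers protein, 11-mers nucleotide) only restricts
candidate pairs — every candidate is aligned exactly — so results are
reproducible and oracle-checkable; the intended scale is CDS sets, not
genome-scale databases.  E-values use the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with fixed constants (λ = 0.267, K = 0.041 protein;
λ = 1.28, K = 0.46 nucleotide), with `n` the total subject residue count.
No edge-effect or gapped-λ refinement is applied: the e-value is a filter
threshold, not a calibrated statistic.  Hit filters: e-value ≤ 1e-10,
identity ≥ 0.70 (matches over alignment columns including gaps), and
max(query coverage, subject coverage) ≥ 0.70 — the max-of-coverages dialect
is a documented choice.  A cheaper score-only pass precedes traceback, since
the e-value filter depends on the score alone.

**New-product identification.**  Assembled CDS with no qualifying
protein-level hit against the reference's CDS set are the new products.
Mutually similar assembled CDS (same thresholds) collapse to the longest
representative so one missing gene yields one appended record.  The update
appends `new_<id>` CDS records at the end of the genome file, leaving
original records byte-identical; a second annotation round then runs on the
updated file.  Rerunning stage 1 on the updated genome identifies nothing:
gene-interior reads now map to the appended records, and the remaining
boundary reads assemble into sub-200 nt junction fragments that carry no
150 nt ORF.

## Stage 2: comparative analysis

**Gene families (GF).**  Connected components (single linkage) of the
undirected all-vs-all qualifying-hit graph, self-hits excluded; genes with
no hit are singleton families.  Single linkage was chosen over Markov
clustering deliberately: it is deterministic and exactly checkable against
a brute-force union-find oracle.  It is also the largest dialect divergence
from inflation-based family methods — fitted α values are therefore
comparable across runs of this package, not across tools.

**Curves.**  For each genome order, pan(N) (families seen), core(N)
(families in every genome so far) and new(N) = pan(N) − pan(N−1) are
computed on the presence matrix.  All G! orders are enumerated when G ≤ 7;
otherwise orders are sampled (default 1000, seeded).

**Heap's-law fit.**  `s(N) = κ·N^(−α)` is fitted by least squares on
`(ln N, ln s(N))`, `N = 2..G`, where `s` is the mean or the median of
new(N) over orders.  N = 1 is excluded (the first genome is not a discovery
event) and zero values are excluded from the log fit; when fewer than two
positive points remain the pangenome is degenerate-closed and α is reported
as infinity.  Verdict: open iff α ≤ 1.

**Unique/shared genes, distances, trees.**  Unique genes per genome count
gene copies in families confined to that genome.  The sharing histogram
bins families by the number of genomes they occupy.  Genome distances are
Jaccard on family presence sets; trees are neighbor joining (scikit-bio,
negative branch lengths clamped to 0) and UPGMA (scipy average linkage,
branch length = height difference), with leaf labels pre-sorted so ties
break lexicographically.

## Synthetic data: what it emulates

The generator emulates a bacterial strain panel at desk scale — defaults:
12 genomes, 30 core families, κ = 60, α = 0.45, gene lengths 300–900 nt,
spacers 50–150 nt, GC 0.5.  Genome `g` (canonical order) introduces exactly
`round(κ·g^(−α))` new accessory families, and each family persists over a
consecutive run of genomes, a gain-then-loss reading of accessory dynamics.

Run lengths are not free: under a *random* accumulation order the expected
new-family curve depends only on the multiplicity spectrum of the families
(how many occur in m genomes), through the exact hypergeometric
first-occurrence probabilities.  The generator therefore solves a
non-negative least squares for the spectrum whose expected curve equals
`κ·N^(−α)` and allocates run lengths per genome from that spectrum
(largest-remainder rounding, truncated to the runs that fit before the
panel ends).  This is the property a Heap's-law fit on permutation curves
actually measures, and it is what makes the generated exponent recoverable:
fitting the median 500-permutation curve recovers α across 0.3–0.9 with
replicate-mean error well under 0.05.  A simpler model — independent
presence of previously seen families at some fixed probability — does not
have this property; at presence 0.5 the permutation curve fits α ≈ 2.4
regardless of the generated exponent, because families become too
widespread for late genomes to contribute novelty.  Family membership is
deterministic given (G, κ, α); seeds affect sequences, strands and layout.

Genes are random codon strings (start codon, no in-frame stop, stop codon);
family members share one identical sequence, so clustering on fixtures is a
structural test, not a divergence test.  Spacers are bracketed by a 12 nt
block (`TTAATTAATTAA`, its own reverse complement) containing stop codons
in all six frames and no start codon, which guarantees ORF calling recovers
planted genes exactly at their annotated starts.  Reads are fixed-length
with uniform positions and strands, i.i.d. substitution errors, constant
quality `I` (qualities are never consumed), and `/1`/`/2` mate suffixes.

What passing these fixtures does *not* show about real data: behaviour
under sequence divergence within families, indel sequencing errors,
repeats and paralogs, contamination versus genuinely missing loci, or
annotation against organisms with atypical gene structure.

## Pipeline engineering

Step status lives in a single JSON state file per run directory (atomic
temp-and-rename writes; a corrupt file is an explicit error, never a silent
reset).  Each of the 13 steps hashes its effective parameters plus content
digests of the input files, chained with its upstream step's hash, so
editing any input or parameter invalidates exactly the downstream steps on
resume.  Steps communicate only through files in the run directory, which
is why kill-and-resume reproduces an uninterrupted run's tables byte for
byte.  Every plot has a machine-readable TSV/JSON sibling; plots themselves
are not a test surface.

## Problem sizes used in tests

The default suite runs on 3–12 genome panels with 8–30 core families,
genes of 300–900 nt and 20–30× read coverage; exponent-recovery checks use
the κ = 60, G = 12 panel with 500 sampled orders and three replicate
samplings per exponent.  These sizes exercise every code path, including
multi-contig assembly, pair repair and resume, while keeping the whole
suite in well under a minute of compute per module.
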