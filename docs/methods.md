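# Methods

`strucscreen` re-implements, at desk scale and without external
binaries, a comparative genome screen for conserved RNA secondary
structure: multiple-alignment blocks are cut into overlapping windows,
each window is scored for thermodynamically unusual *and* evolutionarily
conserved structure, overlapping hits are assembled into loci, locus
boundaries are re-predicted from alignment reliability, refined loci are
re-scored and tiered, and the false discovery rate is estimated from a
partially shuffled decoy screen.  A synthetic-benchmark generator with
known ground truth makes every stage testable without downloads.

## Window screen

Blocks are sliced into 120-column windows with stride 20 (windows
overlap by 100 columns).  Blocks shorter than 120 columns give one
whole-block window; when the stride lattice leaves a tail, one
end-anchored window is appended so no column goes unscreened.  Rows with
a gap fraction above 0.7 are removed (the reference row never is);
windows are then rejected when fewer than 2 rows or 50 columns remain,
or when the mean pairwise identity (MPI) falls below 40% or equals
exactly 100% (identical sequences carry no covariation signal).  MPI is
averaged over all row pairs, counting only columns where both rows are
non-gap; a switch (`count_gap_columns`) treats one-sided gaps as
mismatches instead.  Windows with more than 10 species are reduced to up
to five seeded random samples of 10 rows, each containing the reference;
the subset choice is uniform, not the original tool's optimality
heuristic — a documented simplification.

## Structure scoring

Folding is maximum-weight nested base pairing (Nussinov-style dynamic
programming) with pair weights GC=3, AU=2, GU=1 and a minimum hairpin
loop of 3.  High score means stable; the sign convention is inverted
relative to free energies.  This replaces a nearest-neighbour energy
model deliberately: it is dependency-free, exactly checkable against
exhaustive enumeration, and fast enough to power shuffle statistics.

* **z-score.**  For each ungapped sequence,
  `z = (score − mean)/sd` over scores of dinucleotide-preserving
  shuffles (Altschul–Erickson Eulerian-walk sampling, preserving exact
  dinucleotide counts and both terminal nucleotides).  `z = 0` when the
  background is degenerate.  The function default is 100 shuffles; the
  pipeline configuration uses 12, because the classifier consumes z
  averaged over up to 10 sequences, which suppresses per-sequence
  shuffle noise — a problem-size choice that keeps benchmark screens on
  one CPU core in minutes.
* **Consensus folding.**  Column pairs are scored by the mean pair
  weight over rows able to pair, minus `q = 2` times the fraction of
  rows unable to pair, plus `b = 1` per distinct directional pair type
  beyond the first (the covariation reward); columns may pair only when
  at least half the rows can.  For identical rows this reduces exactly
  to single-sequence folding.
* **SCI.**  The structure conservation index is the consensus score
  over the mean single-sequence score: 1 for identical rows, above 1
  in the presence of compensatory pairs.  *Known limitation:* for
  alignments of few, divergent sequences, chance complementarity is
  abundant and the covariation bonus rewards it, so the neutral SCI
  baseline sits near 1.0–1.3 rather than near 0 as for
  thermodynamic-model SCIs.  The classifier is calibrated against this
  baseline; SCI values from this package are comparable within the
  package only.
* **Classifier.**  A transparent logistic stand-in for a trained
  structure classifier: `P = σ(w0 + w1·z̄ + w2·SCI)` with
  `(w0, w1, w2) = (−4, 1, 3)`, calibrated on the synthetic benchmark so
  implanted structures score above 0.9 and diverged neutral windows
  score low.  Both strands can be scored (minus strand by reverse
  complement).  A second, separately configurable weight vector plays
  the role of the structural-alignment decision model used at
  re-scoring; its defaults equal the first.  Any external scorer can be
  plugged in through the `ScorerAdapter` registry (`(rows, strand) →
  ScoreResult`).

## Locus assembly and refinement

Windows with at least one sample above P = 0.5 on either strand are
hits.  Hits whose reference intervals overlap or book-end (end == start
exactly) merge into loci irrespective of strand.  Loci spanning several
alignment blocks are merged greedily left-to-right when at most 20
missing nucleotides per species can be fetched from the genome, at
least two species remain, both blocks had at most 5 species, and the
merged width stays below 400 columns; otherwise the locus splits at the
block boundary.  Fetched nucleotides and the subsequent 20-nt flanks
enter unaligned (gap-padded); a realigner adapter slot exists for an
external structural aligner, and the built-in fallback proceeds on the
padded alignment, relying on boundary reliability to trim it.

Boundary prediction is the package's stand-in for structural-alignment
reliability profiling.  Per column: if the column is paired in the
consensus structure, reliability is the fraction of rows that can form
a complementary pair there (a compensatory pair counts in full),
discounted by the length of the stacked helix the pair belongs to,
saturating at 6 pairs — 2–5-pair helices arise abundantly by chance in
any alignment and are not evidence of conserved structure, while the
extended stems of a real element score in full.  Unpaired columns score
the fraction of rows matching the modal non-gap character, down-weighted
by 0.8 because sequence agreement alone is weak evidence of reliably
aligned *structure*.  The profile is smoothed with a centred 5-column
moving average and thresholded at θ = 0.85; maximal above-threshold
runs that touch the original (un-flanked) locus are merged, including
the columns between them.  θ, the unpaired down-weight and the helix
saturation were calibrated on the benchmark so that implanted helices
(reliability ≈ 1.0) are retained while conserved neutral background
(≈ 0.55–0.8) and isolated chance helices are trimmed; with a naive
majority-character reliability and θ = 0.5, nothing that passes the
40% MPI filter would ever be trimmed.  On the benchmark the median
absolute difference between refined-locus length and implanted
structure length is ≈ 3 nt, and the locus-length histogram becomes
unimodal after refinement.

Refined loci shorter than 50 columns are dropped; the rest are
re-sampled (≤10 species) and re-classified with the structural weight
vector on their candidate strands.  A locus is *raw* when at least one
sample scores above 0.5; when both strands qualify, the higher-scoring
strand is reported and both are recorded.  High-confidence tiers: 2
species require max P > 0.99; 3–10 species > 0.9; more than 10 species
require at most one sample below 0.5 and at least one above 0.90.

## Decoy screen and FDR

Blocks are split into consecutive chunks of 100; every fifth chunk
(1-based indices divisible by 5; a final partial chunk never) has its
alignment columns permuted uniformly at random.  Column permutation
preserves the per-column conservation pattern and the gap structure —
the key property of conservation-preserving alignment shufflers — while
destroying base-pair covariation and dinucleotide adjacency; a per-row
dinucleotide-shuffle mode is available as an alternative control.  The
identical pipeline (including fetching unshuffled flanks) runs on the
decoy; the nucleotide FDR is the decoy locus nucleotides inside the
shuffled mask, scaled by the input-footprint over masked-footprint
ratio (≈ 5 when exactly one fifth is shuffled; computed adaptively
because block counts need not be multiples of 500), divided by the true
screen's locus nucleotides.  Reports are stratified by species-count
bins (2, 3–6, 7–10, >10) × MPI decades, estimated on the plus strand
and assumed equal on the minus strand.  At desk scale the shuffled mask
carries only a handful of control loci, so single-fixture FDR estimates
have large Poisson noise; the estimator itself is unbiased (true and
fully-shuffled neutral screens yield statistically indistinguishable
locus counts).

## Genome partition and downstream statistics

Gene annotation is projected hierarchically into disjoint labels:
genomic (genic/intergenic), genic (exonic/intronic), exonic
(mRNA/noncoding/other), mRNA (5'UTR/CDS/3'UTR) and noncoding
(lncRNA/sncRNA), with precedence CDS > 3'UTR > 5'UTR, mRNA > noncoding
> other, and sncRNA > lncRNA for overlapping isoforms (the precedence
is a package choice; coding capacity dominates).  Coverage enrichment
compares the fraction of locus nucleotides in a class with the fraction
of screened-input nucleotides there; over a full partition the
input-weighted mean enrichment is 1 identically.  Repeat enrichment
follows the same ratio restricted to repeat classes (with a configurable
annotated-locus floor, 1000 by default).  The mRNA meta-profile reports
hit/input coverage per 10-nt bin around start and stop codons in
spliced coordinates, excluding segments shorter than the profiled span.
GO enrichment collapses protein-coding isoforms per gene and region,
compares nucleotide coverage (COV_E) and gene counts (CNT_E; a gene
counts when a locus overlaps it with at least half the locus length),
computes two-sided Fisher exact p-values (two-sided because depletion
is as interesting as enrichment) and adjusts with Benjamini–Hochberg
within each ontology separately.  Small-RNA sensitivity counts
annotations at least 80% inside one contiguous interval of the
screened-window footprint ("filtered") and, of those, the ones at least
60% covered by a single locus on their annotated strand ("found");
percentages are rounded to the nearest integer.

## Synthetic benchmark

The generator emulates a fragmented multi-species genome alignment:

* **Phylogeny.**  An 8-species caterpillar tree rooted at the reference
  (the F81 substitution model is reversible, so re-rooting at the
  reference leaf preserves the joint distribution and keeps the
  reference row indel-free relative to the planned layout); the nearest
  sister sits at distance 0.12 and the farthest leaf at ≈ 1.5
  substitutions/site.  Branch-scale per block is lognormal(−0.1, 0.4),
  giving block MPIs from ~40% to ~95%.
* **Blocks.**  Lengths are 30 + Exponential(90) nt, clipped at 400 — a
  decaying spectrum like real fragmented alignments, where a quarter of
  aligned material sits in sub-50-column blocks that the screen must
  discard.  Species per block range from 2 to 8; 7% of small blocks are
  emitted split in two (book-ended), exercising cross-block merging.
  Indels are geometric (mean 3 nt) at 0.01 events/site/unit branch
  length, excluded from implant footprints so truth pair tables stay
  valid.
* **Implants.**  Hairpins with 26–34 base-pair stems and 5–9-nt loops
  (structures of 57–77 nt, sized so refined loci clear the 50-column
  floor) are written into the reference row; every other row carries
  the same hairpin with each pair independently switched to a different
  complementary pair with probability `compensatory_rate` (default
  0.5), preserving pairing while destroying sequence identity — the
  covariation signal the screen detects.  Implants are biased (60%)
  into 3'UTR territory.
* **Annotations.**  Gene territories tile consecutive block groups:
  65% protein-coding (two exons, an intron, short 5'UTR, long 3'UTR),
  15% lncRNA, 20% intergenic; implants double as small-RNA genes
  (miRNA/snoRNA/snRNA/scaRNA/tRNA) and BED records; ~15% of neutral
  blocks carry repeat-class annotations; protein-coding genes receive
  GO terms, one of which tracks structure-rich 3'UTRs.
* **Reproducibility.**  Every block has a private RNG stream derived
  from (seed, block index), so fixtures differing only in implant
  parameters share their neutral blocks bit-for-bit — across
  compensatory rates the comparison is paired.

What the benchmark does *not* emulate: genuine nucleotide composition
and repeat-family evolution, alignment errors and paralogous
misalignment, rate heterogeneity along the sequence, structures with
multi-loop architecture or indels inside structures (available as an
option), and transcription-level context.  Passing tests therefore
demonstrate the pipeline's internal correctness and its behaviour under
an idealised covariation signal, not performance on real genome
alignments.

## Problem sizes and numerics

Default benchmark fixtures are 800 neutral + 200 implanted blocks
(tests) and 400 + 100 / 500-neutral (acceptance script, which keeps the
decoy's shuffled fraction at exactly one fifth).  Screens in tests and
the acceptance script run on the plus strand, matching the FDR
protocol.  Degenerate inputs: zero-variance shuffle backgrounds give
z = 0; empty consensus denominators give SCI = 0; loci losing all
non-reference rows, reliability everywhere below θ, or falling under 50
columns are dropped and logged with the rule that dropped them.
Unimodality is assessed with a dip-type statistic (smallest maximal
deviation of the empirical cdf from convex-left/concave-right envelopes
over candidate modes), calibrated by Monte Carlo against uniform null
samples of the same size; integer-tied samples are dithered by ±0.5 so
that tie-induced ecdf cliffs do not masquerade as modes.  Ties in folding tracebacks resolve toward
the smallest opening index, then the smallest admissible partner.
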