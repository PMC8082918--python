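# Methods

This note documents the models, defaults and numerical choices behind
`mitofinish`, and what the synthetic validation does and does not show.

## Coordinates, identity, k-mers

All internal coordinates are 0-based half-open, matching PAF and BED; 1-based
coordinates appear only in human-readable reports. Alignment identity is
always `matches / block_len` (the PAF convention), used consistently by the
mapper, the fishing rule and the spanning-read filter. K-mers are canonical
(lexicographic minimum of a k-mer and its reverse complement), k-mers
containing non-ACGT characters are skipped, and circular sequences are
counted across the origin. The 2-bit packing used by the counters and the
exact-match engine caps k at 31 (odd k ≤ 31); the two sizes the toolkit
actually uses are k = 31 (QV) and k = 7 (repeat similarity).

## Exact-match engine and mapper

Maximal exact matches (MEMs) are found by merging runs of identical k-mer
seeds along diagonals: a maximal run of consecutive seed hits on one diagonal
is exactly a maximal match of length run + k − 1, which makes the enumeration
complete for matches ≥ the seed size without any heuristic. The default word
size is 16, the same value used for repeat-boundary self-alignment. The
seed-and-extend aligner clusters seeds into diagonal bands, chains them with
a query-gap tolerance (`match_gap`, default 500 bp; the `-z` knob), and
extends with banded edit distance (edlib). A full-length alignment is only
attempted when the seed chain already spans most of the query — a chimeric
read whose mtDNA segment covers 15% of its length cannot clear the identity
floor, so the aligner goes straight to the local segment. Reads are mapped
against a 2-copy concatemer of the circular reference and target coordinates
are folded modulo L, so origin-spanning reads map without artifacts. Ties
between equal-scoring placements break to the smallest folded target start,
then the forward strand, making output deterministic; depth computations on
concatemeric targets use *all* placements, because deterministic primary
mapping would pile every ambiguous read onto the first copy.

The default mapper stringency is `max_edit_frac = 0.25`. The fishing
stringency is deliberately loose: with error-free reads it tolerates a
reference ~20–25% diverged from the sample; combined read error plus
reference divergence beyond that erodes recall, which the tests exercise
qualitatively (divergent reference ⇒ lower but nonzero recall).

## Fishing and contig selection

A read is kept when `reference_len × query_cover / read_len ≥ 0.70`, with
`query_cover` the union of reference positions covered by all of the read's
alignment segments (so short matches to a fragmented reference still fish out
long reads), capped at 1.0 for reads that wrap the circle more than once.
The maximum-read-length guard is inclusive (`keep iff length ≤ cutoff`).
Contig selection scores the fraction of *reference* positions covered by
alignments to each contig, filters below a percentage cutoff (default 5%),
and breaks ties by longer contig, then lexicographic id.

## Circularization

Order is fixed: reliable-ends trim → overlap detection → collapse → anchor
rotation. Reliable ends are the maximal interval whose first and last
positions have short-read depth ≥ 3; internal dips are reported, not trimmed.

Overlap detection groups forward self-MEMs by diagonal (band = 5% of the
contig length), chains them with the `match_gap` tolerance, and accepts a
chain as a junction candidate only if it reaches within
`max(25, 2 × word size)` of the contig start (query side) and end (target
side). Two rejection rules implement repeat deconvolution: interior chains
(tandem arrays, dispersed duplications) are never candidates, and a candidate
whose matched bases lie entirely inside short-period (≤ 2.5 kbp)
self-overlapping regions is discarded — when the contig junction happens to
fall inside a tandem array, the array's own periodicity produces end-to-end
chains at period L − k·unit that would otherwise shave repeat units off the
collapsed circle. Among surviving candidates the ranking is largest chained
support, then closeness of the implied copy number to a whole or half pass
(concatemers arise from whole- or partial-pass reads). The collapse cuts one
period; when the head and tail copies of the overlap disagree and a depth
track is supplied, the better-supported base wins per position. Periods below
1 kbp are rejected as implausible for a mitogenome.

One genuine ambiguity remains: if the junction falls inside a tandem array
*and* the entire terminal overlap is contained in the array, the contig is
consistent with several (genome, overlap) decompositions and no sequence-only
method can pick the true one; the detector then reports no overlap rather
than guessing. With arrays ≤ 2 kbp on ≥ 14 kbp genomes this configuration is
rare (≲1% of random rotations), and it does not occur in the seeded
validation suite.

Anchor rotation searches the anchor on both strands of the doubled circle
(edlib, identity ≥ 0.8 required), reverse-complements if the best hit is on
the minus strand, and starts the output at the anchor's first base; the
operation is idempotent.

## Polishing

Haploid majority consensus from pileups over the doubled circle: a pileup
allele (base, deletion, or insertion ≤ 50 bp) replaces the assembly allele
when its support fraction strictly exceeds 0.5 at depth ≥ 3. Exact ties keep
the assembly base — a haploid consensus must be deterministic and the
reference is the better prior. Positions below the depth floor are left
unchanged and reported as low-coverage intervals. Variant calls are
normalized to the unique parsimonious, left-aligned representation: SNVs
carry no shared flanking bases; length-changing variants keep exactly one
left anchor base (the VCF convention; a pure indel cannot be represented
with non-empty alleles and zero context). A deletion starting at position 0
re-anchors on the right instead. The normalizer is validated against a
brute-force enumeration of all equivalent minimal representations.

## QV

`E = 1 − (1 − false/total)^(1/k)`, `QV = −10·log₁₀ E`, with `false` the
number of assembly k-mer positions whose canonical k-mer is absent from the
filtered read set and `total = L − k + 1` per sequence. The assembly is
evaluated as deposited (linearized), not circularly — circular counting
would add k − 1 junction k-mers that the standard evaluation of deposited
sequences never sees. Zero false k-mers yields an infinite QV, reported as
"no false k-mers". The read-set frequency floor (default 100) presumes deep
(≥ 250×) mitochondrial short-read coverage; at lower simulated coverage the
floor must be scaled down (the pipeline's default config uses 25 for its
~100× simulation) and the filter warns when nothing survives it.

## Repeats, duplications, heteroplasmy

Tandem arrays are annotated from forward self-MEMs whose query and target
footprints overlap or abut (adjacent copies); overlapping footprints are
clustered, the unit length is the smallest positive diagonal in the cluster
(the array period), the copy number is region length / unit, and the unit
consensus is a per-column majority vote over the full copies. Shared-k-mer
similarity between repeat sequences is the Jaccard index on distinct
canonical 7-mers; the alternative |A|+|B| denominator is exposed as an
option since either reading of "total k-mers of both datasets" is defensible.
A duplication is complete when it covers ≥ 95% of its source.

Spanning reads must contain the repeat interval with ≥ 1000 bp aligned
anchor on each side, have identity strictly > 0.70, and be at least
repeat + 2000 bp long. The per-read length deviation projects the repeat
boundaries into the read: the cigar projection provides an initial estimate,
then the two 100 bp reference flanks are re-located in the read by edit
alignment and the distance between them is the observed length. The
re-anchoring matters: among equally optimal alignment paths the placement of
gaps around a length polymorphism is arbitrary, and a raw cigar walk smears
a full deletion across the boundary (a structural-loss read then shows a
deviation of ~−0.8 instead of −1.0). Implied copy number rounds
observed/unit to the nearest integer, half away from zero. Reads with
relative deviation ≤ −0.95 are structural-loss candidates (alleles lacking
the repeat or duplication outright).

## Statistics

The 2×2 chi-square uses the continuity correction capped at |O − E|, so a
perfectly null table scores exactly 0 — this matches the default behaviour
of the standard implementation and reproduces the worked assembly-success
example (100/0/0/25 → 118.8, df = 1). Fisher's two-sided p sums all
fixed-margin tables whose point probability is ≤ the observed one (with a
1 + 10⁻⁷ relative slack for floating-point ties). Simulated p-values permute
column labels against row labels (equivalent in law to fixed-margin table
sampling), score the uncorrected Pearson statistic, and use the add-one
estimator `(1 + hits)/(B + 1)` with B = 10,000 by default, so p is never 0.

## Synthetic data: what it emulates, and what it does not

The generator plants a random backbone (GC 0.44) with an anchor at the
origin, tandem repeat arrays in the control region (unit 14–100 bp, arrays
up to ~2 kbp) and optional duplications; heteroplasmic alleles differ only
in repeat copy number or duplication presence, the two modes observed in
spanning-read data. Long reads start uniformly on the circle with log-normal
lengths truncated to [500 bp, 3L]; errors are i.i.d. per base with an
insertion-biased default profile (2% substitution, 6% insertion, 3%
deletion), insertions emitting one random base — the simplest model that
reproduces the positive mean length deviation seen in insertion-biased
chemistry. Short reads are 150 bp, single-end, wrapping the circle. Nuclear
background is random sequence; NUMT chimeras embed a genuine mtDNA segment
in random flanks. Read ids carry the true (allele, start, strand, length),
so fishing and heteroplasmy can be scored exactly without alignment.

Not emulated: base-quality variation, context-dependent or homopolymer
error clustering, chimeric/adapter artifacts, real NUMT divergence (the
chimeric insert is an exact mtDNA copy — the harder case for a length-based
guard), and genuine nuclear genome structure. Passing tests therefore show
correctness of the algorithms under the stated error model, not robustness
to every artifact of real instruments.

Validation problem sizes (tests and the acceptance script): 50 random
genomes for the circularization property; ~200 spanning reads for the 80/20
copy-number mixture (coverage 290× at 12 kbp mean read length); 1, 5 and 20
injected substitutions for the QV closed form at 200× short reads; a
200 mtDNA + 500 nuclear + 50 NUMT-chimeric labeled mix for fishing; 20
seeded polisher-recovery runs at 50×; 1,000 random cases for the variant
normalizer against brute force. These sizes were chosen as the smallest that
leave the binomial/recovery checks statistically meaningful.
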