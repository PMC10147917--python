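# Methods

This note records the models, parameter choices and numerical decisions
behind mitokmer, and what the synthetic validation does and does not
demonstrate about real data.

## Matching blocks and copy calling

Copy counting is alignment-free. The query gene and each read are
k-merised (k = 19) on both strands; the reverse-complement k-mers are
stored at mirrored query offsets, so a reverse-strand read produces
matches whose query offsets still ascend along the read. Matches are
clustered under the maximum-gap rule: consecutive matches more than
`gap_threshold` = 800 nt apart on the read belong to different copies.
The 800-nt threshold is meaningful for this gene geometry: consecutive
*ND6* copies in a duplicated *ND6*/*trnE*/*trnP*/CR array lie ~1.4 kbp
apart (the intervening tRNAs, control region and spacers), while matches
within one copy are at most a few hundred nt apart even after heavy k-mer
loss.

The gap rule alone cannot separate copies that abut more closely than the
threshold, so within a gap-block the caller watches the *query offset*:
within one copy the matched offsets progress with the read (modulo indel
jitter); a drop of more than k back towards zero starts a new copy.
Matches are chained greedily (at each read position, the smallest offset
≥ previous − k continues the copy), which makes the rule insensitive to
k-mers that are repeated inside the query: those always offer a forward
continuation. With both rules, error-free constructed reads with 0–5
embedded copies are counted exactly even at 1-nt copy separation.

**Support filters.** A block counts as a copy when it has ≥ `min_kmers`
member matches (default 5) and covers ≥ `min_query_coverage` of the query
(default 0.1). The two defaults play different roles. Random 19-mer
collisions are essentially eliminated by `min_kmers` alone: five chance
matches inside one 800-nt window have negligible probability, and a
single collision covers only 19/528 ≈ 0.04 of the query. The coverage
filter instead guards against degenerate queries and sets the floor for
truncated copies. Its default is deliberately low because coverage is a
*union of surviving k-mer footprints*: at a 10 % indel-dominated error
rate the mean error-free run is ~9 nt, shorter than k, so the union
coverage of a perfect full-length copy concentrates near ~0.30 and a
half-length truncated copy near ~0.15. A threshold of 0.25 — natural at
first sight, since a truncated copy covers ~0.5 error-free — silently
rejects genuine copies at exactly the noise level the method must
tolerate. At 0.1, full and truncated copies survive CLR-grade noise while
random matches remain excluded by `min_kmers`. Both thresholds are
exposed on the command line for sensitivity analysis.

**Gap anchoring.** The gap is measured between successive k-mer *start*
positions in read coordinates; whether one anchors on starts, ends or
block boundaries changes block extents by at most k − 1 = 18 nt, which is
also the resolution quoted for breakpoint positions and inversion spans.

## Read screening

A read is mitochondrial when its longest matching block against the whole
reference spans ≥ `min_block` nt (defaults 5000, with 3000 appropriate
for shorter-read libraries). The reference is doubled (seq + seq) before
indexing so reads crossing the origin of the circular molecule form one
block. NuMT inserts are typically far shorter than 5 kbp and cannot
produce a passing block; the screen therefore implements the same
"matching block ≥ N bp" contract that read extraction by mapping-block
length enforces, without wrapping an external aligner. When reproducing
results derived from a mapping-based extraction, agreement between the
two screens should be checked on the accession data.

**Anchor spanning and sidedness.** Copy counts are only comparable
between reads that span the whole duplicated region, operationalised as
carrying passing blocks for both flanking anchors (*12S* and *CYTB*). A
read with both anchors traverses exactly one of the two arcs between
them, and only the arc through the duplicated block is informative: reads
around the opposite side of the circle would contribute spurious 0-copy
(and, when they poke into the block, under-counted) classes and make any
sufficiently covered homoplasmic sample look heteroplasmic. The two arcs
are distinguished by anchor order on the read (on a forward read the
duplicated side shows *CYTB* before *12S*; the order flips on reverse
reads). Reports keep both numbers: `n_spanning` counts all both-anchor
reads, while the spectrum is built from duplicated-side reads only.

## Heteroplasmy calling

The spectrum maps copy number → number of duplicated-side spanning reads.
The verdict requires at least two classes with ≥ `min_support` = 2 reads;
classes below support are still reported, flagged `singleton`, because a
single five-copy read is worth seeing even when it cannot carry a verdict.
A copy count of zero on a duplicated-side read is reported as class 0
rather than dropped — complete loss of the counted gene from a block is a
real outcome (remnant blocks) — but does not arise in error-free data from
the bundled pools.

## Tandem repeat finding

Control-region repeats are detected by lag correlation: (1) candidate
periods d ∈ [`min_period`, `max_period`] (defaults 10–400) are seeded by
exact 7-mer self-matches at lag d; (2) for surviving lags the per-base
match profile m[i] = [s[i] = s[i+d]] is scanned for dense runs (rolling
identity ≥ `min_identity`, default 0.8); (3) within each candidate region
the period is re-estimated as the *smallest* lag whose mean adjacent-
window identity is within 0.01 of the best over all lags — exact ties
only occur for noise-free repeats, and the tolerance keeps the
fundamental period stable under point mutations instead of occasionally
hopping to a harmonic; (4) boundaries are trimmed to the maximum-scoring
segment of the match profile (match +1, mismatch −3, the break-even
slope at 0.8 identity) and then snapped to the first/last run of
min(period, 6) consecutive matches, so chance matches in the flanks move
a boundary only with probability ≈ 4⁻⁶ per position; (5) fractional
copies = region length / period, rounded to one decimal (the conventional
report, e.g. "53 bp repeated 8.8 times"), with `min_copies` = 1.9 and a
consensus motif taken column-wise by majority over period-phased windows.

Boundary wobble of a few chance-matching nucleotides is irreducible — a
random base that happens to continue the period is locally
indistinguishable from a true array base — which matters only for short
motifs (1 nt = 0.1 copies at period 10). For the 53–291 nt periods of
interest the copy number is stable to ±0.1.

**Nested repeats.** When a repeat's unit is itself (nearly) an exact
array of a shorter motif, the region is reported once, at the smallest
period within the identity tolerance; a secondary level is reported only
when the container's units diverge by more than the tolerance. Dual-level
reporting of harmonically exact nestings is not attempted: with a
single-period-per-region detector the two descriptions are statistically
indistinguishable, and suppressing one of them by identity alone proved
unstable. This is a known limitation relative to alignment-scoring repeat
finders.

## Architecture classification

A target genome is decomposed into stranded gene blocks using the same
matcher (every reference gene as query, same support filters; circular
targets are searched doubled and rotated so *trnF* starts near zero).
Classification then operates on the gene-label string, which is robust to
sequence divergence: tandem duplications are maximal runs of a primitive
(non-periodic) repeating unit, found by brute force (label strings are
tens of symbols); among equal runs that are phases of the same array, the
phase whose flanking residue forms the *longest* suffix of the unit is
chosen, because biologically a partially lost copy retains a suffix of
the unit (e.g. *trnP*/CR beside full *ND6*/*trnE*/*trnP*/CR copies) — this
simultaneously fixes the duplication phase and identifies the remnant.
Inversions are maximal runs of ≥ 2 consecutive minus-strand blocks whose
reversed label order is consistent with the canonical vertebrate gene
order (circularly); the span runs from the first to the last block of the
run, so it is accurate to ±(k − 1) nt of the underlying breakpoints.
Intergenic spacers are not modelled as blocks; identity arguments about
spacer sequence (used elsewhere to corroborate remnants) are outside this
classifier and reports say so.

## Synthetic data: what it emulates

Genomes are built from the canonical vertebrate gene complement with
realistic lengths (tRNAs ~70 nt, *ND6* 528 nt = 175 codons + stop, CR
1000 nt, rRNAs 950/1700 nt), with the duplicated block placed after
*trnT* and the unit geometry mirroring the observed one: 177 nt before
each unit copy, ~5 nt between most genes, 50 nt between *trnE* and
*trnP*, 64 nt before a remnant block. With this geometry consecutive CR
copies sit ~900 nt apart, so the 800-nt gap rule separates them exactly
as it does in the real genomes. Gene "sequences" are seeded random DNA:
structural analysis needs geometry and identity structure, not real
coding sequence. Frameshift "truncations" are modelled as 1–4-base
insertions at the DNA level (no translation machinery). One CR (the last
copy) may carry an embedded tandem repeat; the large-inversion preset
inverts the arc from the CR through *trnI* across the origin (~5.7 kbp
with its expanded CR).

Reads: variant chosen by pool frequency, origin uniform on the circle
(reads may cross the origin), length truncated-normal (default mean
12 kbp, sd 3 kbp, min 3 kbp, capped at the genome length — no multi-pass
circular reads), strand fair-coin, then i.i.d. per-base errors (defaults
sub 1 %, ins 6 %, del 4 %, an indel-dominated CLR-like profile; at most
one insertion per template base). The truth table records, per read, the
source variant, the error-free interval, whether it spans the anchors
(and via which side), and how many counted-gene copies it overlaps enough
to count, using the same overlap thresholds as the default caller.

**What passing tests do not show.** The error model has no homopolymer
bias, no chimeras, no quality values, and errors are independent across
bases; gene sequences are random, so there is no cross-gene homology and
no NuMT-like divergent paralogy beyond the explicit screening fixtures.
Recovery rates measured here are therefore upper bounds on real-data
performance, and accession-scale read counts are not reproduced at desk
scale.

## Statistics of pool recovery

Variants with more copies have longer genomes *and* longer anchor-to-
anchor arcs, so the probability that a read spans the duplicated side
differs per variant: spanning reads are a length-biased, not a raw-
frequency, sample of the pool. The class probabilities among spanning
reads are computed exactly from the generative model
(p ∝ f_v · E[max(0, min(L, G_v) − arc_v)] / G_v, quadrature over the
read-length law), and the chi-square goodness-of-fit of the observed
spanning-read classes is taken against that expectation. Pipeline
accuracy is assessed separately as per-read concordance with truth among
jointly spanning reads (≥ 95 % required at CLR noise; measured ~99 %),
because read-edge attrition under noise removes marginally spanning reads
in a length-dependent way and would otherwise be conflated with the
multinomial check.

## Problem sizes and determinism

The bundled validation uses 2000 reads for the 4/3/1/5-copy pool and
5000 for the 2/3/1/4-copy pool — enough for every expected class to be
multiply supported and for the chi-square to have power, while a full run
of suite plus acceptance script stays in the low minutes on one CPU. All
randomness flows from explicit seeds (numpy `default_rng`); simulator
outputs are bit-identical across runs with the same seed.
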