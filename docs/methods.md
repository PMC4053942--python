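# Methods

gapcast predicts how completely a microbial genome can be assembled from
long single-molecule reads, from nothing but the reference sequence and a
read-length distribution.  This note records the models, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Repeat model

A repeat is any pair of genomic loci at least `min_len` bases long (default
500) with at least `min_identity` copy identity (default 0.95).  Repeats
below the length floor are assumed resolvable by any technology and are
outside the model entirely.

**Exact maximal matches.** All replicons and their reverse complements are
concatenated with unique separator symbols; every `N` base also receives a
unique symbol, so `N` can never match anything (runs of `N` cannot fake a
repeat).  A suffix array (numpy prefix-doubling, O(n log^2 n)) plus a Kasai
LCP array yields every maximal exact match at or above the length floor:
pairs of suffixes sharing a long prefix are right-maximal by construction
and are kept only when their preceding characters differ (left-maximality).
Each unordered pair of loci is reported once; self-identity matches on the
main diagonal, including a palindromic locus matched to itself, are
discarded.  Circular replicons are extended by `min_len - 1` bases so
matches crossing the origin are seen; the self-match this creates is
shorter than `min_len` and filtered.  A repeat copy extending further than
`min_len - 1` past the origin is truncated at the extension boundary — a
documented limitation of the seam handling.

**Diverged copies.** Copies below 100% identity are recovered by chaining
co-linear exact matches (same replicon pair and orientation, gaps of at
most `max_gap` = 90 bases on both copies).  The seed length adapts to the
identity floor (0.8 x expected exact-segment length, at least 16, at most
`min_len`).  Chain identity is the matched-base fraction of the chained
span; when the genome is at hand and the two loci have equal length, the
identity is instead computed exactly base-by-base.  The matched/span
estimator systematically undercounts — every exact segment shorter than
the seed hides in a gap — and at a 0.95 floor that bias is fatal, which is
why the exact recomputation exists.  Indel-diverged copies keep the
estimate; externally computed match tables (MUMmer `show-coords -T -H`
layout) can be substituted for the whole detector.

**Reduction.** Both loci of every surviving match are projected to
intervals; intervals strictly contained in a strictly larger interval are
dropped (equal-extent duplicates collapse to one; equal-length overlaps are
both kept); the repeat count is the number of remaining intervals and the
longest is the maximum repeat size.  Note that with perfectly identical
planted copies, chance extension of each pairwise match into the background
varies by a few bases, so an n-copy family can reduce to more than n
non-nested intervals; real (diverged) repeats behave the same under any
aligner.  For simulation, overlapping or abutting intervals are merged into
disjoint blocks — the unit whose spanning decides a gap.

**Classes.** Class III: maximum repeat strictly over 7,000 bases (beyond
the rDNA operon scale, typically prophage or segmental duplication).
Class II: strictly more than 100 repeat intervals.  Class I: the rest.
Both thresholds are parameters; both comparisons are strict.

## Read-length model

Corrected single-molecule read lengths are log-normal.  Presets (mu, sigma
of natural-log length): C1 (6.69, 0.37), C2 (7.59, 0.67), XL-C2
(7.90, 0.63), XL-XL (8.02, 0.79), and a projected ZL = XL-XL with the mean
doubled (mu + ln 2, sigma unchanged).  The model mean is
exp(mu + sigma^2/2) — for C2, 2,476 bases.  Sampling truncates at
`max_len` = mean + 5 sd in linear space by redrawing; linear-space
truncation puts the XL-XL bound near 23.5 kbp, consistent with observed
maxima near 25 kbp, whereas log-space truncation (also available) would
permit ~158 kbp reads.  Redrawing avoids the probability atom that
clamping would create at the bound.  An empirical mode resamples a length
list uniformly with replacement.

`expected_seed_count` is a deliberately simple independent-errors model:
(L - k + 1)(1 - e)^k seeds against an error-free reference, exponent 2k
between two error-prone reads.  It captures the length-versus-error
trade-off qualitatively and is not calibrated to any published curve.

## Closure simulation

Per replicon, error-free reads are drawn — length from the model, start
uniform — until cumulative length first reaches coverage x replicon
length.  Circular replicons wrap; linear ones truncate reads at the end;
reads longer than the replicon are capped at its length.  A merged repeat
interval [s, e) is resolved when one read contiguously covers
[s - anchor, e + anchor), anchor = 40 bases: the minimum unique overlap an
overlap-based assembler needs on each flank.  The flanks of a merged
interval are unique with respect to every repeat above the length floor by
construction of the merge, so spanning is tested directly on coordinates;
with error-free reads this is equivalent to mapping the reads back with an
aligner.  Each unresolved interval is one gap; a circular replicon with g
gaps yields max(g, 1) contigs, a linear one g + 1.

Coverage targets each replicon independently (pooled sampling would leave
plasmid closure undefined).  Ten replicates by default; the closed-form
unresolved probability for a single repeat at constant read length,
(1 - max(0, L - R - 2a + 1)/G)^N, is the oracle the simulator is tested
against (agreement within three binomial standard errors).

**Common random numbers.** In a coverage sweep, each (model, replicon,
replicate) read stream is simulated once at the maximum coverage and lower
coverages take prefixes of it (draws are chunked so prefixes are
seed-stable).  Closure is therefore non-decreasing and gaps non-increasing
in coverage by construction, replicate by replicate — sampling noise can
never make more sequencing look worse.

## De Bruijn graph complexity

Nodes are distinct canonical k-mers (a k-mer and its reverse complement
are one node; a single-strand mode exists for sensitivity analysis), edges
are observed k-1 overlaps, and non-branching paths are maximally collapsed
with a union-find over links whose both endpoints have degree one.  A
circular replicon with no repeat of length >= k-1 collapses to one
self-adjacent unitig.  k-mers are identified by two independent 61-bit
polynomial rolling hashes of both orientations (collision probability
< 1e-20 below hundreds of megabases), so memory is proportional to genome
length and independent of k — the interesting regime is k in the
thousands.  k-mers containing N are excluded and break the walk.  The sum
of (unitig length - k + 1) equals the distinct k-mer count, an invariant
the tests enforce alongside monotonicity of the unitig count in k.

## Read processing

**Quality trimming.** The kept interval is the longest window whose mean
Phred QV strictly exceeds the threshold (54.5 by default), leftmost among
ties; the mean is over Phred values, not error probabilities (an
alternative probability-space mean is a one-line change away but not
exposed).  With prefix sums of (QV - threshold) a window is admissible iff
its prefix difference is positive; only strictly decreasing prefix minima
are useful starts and strictly decreasing suffix maxima useful ends, and a
two-pointer pass over those is O(n).  The all-windows O(n^2) scan is kept
as the property-test oracle.

**Chimera splitting.** A missed SMRTbell adapter joins a sequence to its
reverse complement; short-read alignments then terminate at the junction
in both orientations.  Both endpoints of every alignment are collected
with their strand; a position qualifies as a breakpoint when each
orientation has at least `min_support` (default 2) endpoints within
`window` (default 50 bases); qualifying positions are clustered and
reduced to the cluster median.  The support and window defaults demand
corroboration while tolerating alignment-end jitter — the source procedure
publishes no numbers.

**Gap patching.** Anchor short reads are taken within a window (default
500 bases) of a coverage gap; any other long read containing all anchors
in the same order and orientation — or fully reversed with flipped strands,
in which case its subsequence is reverse-complemented — donates the region
between the innermost anchors.  The donated candidates are combined by a
star consensus: the median-length candidate is the centre, every other is
aligned to it by banded edit distance, and each centre column is called by
plurality with centre-wins ties; insertions relative to the centre are
dropped.  This is a deliberate simplification of a full multiple
alignment; its acceptance surface is identity to the planted truth on
synthetic fixtures (>= 99% at 5% candidate noise with five candidates),
not byte equivalence with any production consensus caller.

**Subsampling.** Reads sorted longest-first (ties by input order) are kept
until cumulative length first reaches the target coverage (default 25x)
times the genome size; the selection is minimal in the sense that dropping
its shortest member falls below the target.

## Synthetic data

The generator plants repeat families (length, copy number, identity,
orientation per copy, optional pinned placements) into an i.i.d. uniform
ACGT background and emits machine-readable truth.  Divergence is by point
substitution only — exactly round((1 - identity) x length) of them —
keeping identity arithmetic exact and interval coordinates stable; there
is deliberately no indel mode in the default path.  Chance exact repeats
at or above 500 bases in a uniform background are negligible below tens of
megabases, so unplanted genomes are clean negative controls.  Reads carry
substitution errors at a requested rate and Gaussian QVs; chimeras
alternate forward and reverse-complement copies of one sampled locus with
junction positions recorded, and a tiling helper emulates the truncated
local alignments an aligner would report over the junctions.

What a green test does *not* establish: real repeats diverge with indels
and nest into families; real read-length distributions deviate from
log-normal in the extreme tail; real short-read alignments carry mapping
noise the tiling helper lacks; and the error-free closure model ignores
correction failures, coverage bias, and small replicons lost to library
size selection.  The simulation bounds what read length can resolve, not
what a particular assembler will achieve.

## Cost model

Cells = ceiling(coverage x genome size / yield per cell), computed with
exact rational arithmetic (no float-ceiling artifacts at exact-fill
boundaries); yield defaults to 300 Mbp per SMRT cell.  Costs are library
preparation plus cells x per-cell cost, held in integer cents so printed
totals are penny-exact.  The bundled prices are 2013-era worked examples,
not live data.
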