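# Methods

This note documents the models, conventions and design choices behind
`g4stress`, in the spirit of a statistics package's model documentation.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates and overlap

All intervals are 0-based half-open (BED).  The ICGC-style SSM reader is
the one 1-based boundary; it subtracts 1 on input.  Overlap is ≥ 1 bp
everywhere — abutting half-open intervals do not overlap — matching
`bedtools intersect -u` defaults.  `intersect_any` reports each query
interval at most once; `overlap_partition` uses the same ≥ 1 bp rule for
the Venn split of two peak sets (reciprocal-overlap thresholds are not
implemented).  A mutation "in" a region is its (converted) position as a
point; INDELs are located at their start coordinate and never expanded,
since SSM tables supply a single position.

Feature annotation assigns each query the highest-priority overlapping
category with default priority promoter > exon > intron > LINE > LTR >
other-repeat, else "intergenic".  The priority list is a parameter
because annotation-tool internals differ; the output is the per-query
label plus category fractions.

## PQS grammar

The scanner compiles `(?:[gG]{t,}\w{lo,hi}){k−1,}[gG]{t,}` from
`ScanParams` (defaults t=3, lo=1, hi=12, k=4), which at the defaults is
the canonical quadparser-style pattern `([gG]{3,}\w{1,12}){3,}[gG]{3,}`.
Semantics are deliberately those of the standard regex engine: leftmost,
greedy, non-overlapping (a match consumes its span).  Loops are `\w`, so
N and sub-threshold G runs may sit inside loops; only tracts require
literal G.  `n_tracts` counts maximal G-runs ≥ t inside the matched span;
motifs are never merged or trimmed.

Minus-strand motifs are found by scanning the reverse complement with
the same grammar and mirroring coordinates, which makes the
reverse-strand invariant (`scan(rc(s))` mirrored == minus-strand calls
on `s`) true by construction.  `strand_mode` defaults to `both`
(quadparser heritage); forward-only is one flag away, and the oracle
comparisons in the tests run forward-strand.

Per-region counting extracts each region's sequence and scans it
independently, so a motif must lie fully inside the region and boundary
truncation is handled identically for observed and null counts.

## Shuffle-null enrichment

The null preserves peak count and the multiset of peak lengths.  Each
peak is placed on a chromosome drawn with probability proportional to
chromosome length (restricted to chromosomes it fits on; fixed to its
source chromosome in `same_chrom` mode), start uniform over valid
positions.  Placements may overlap each other, matching the shuffle
tool's default; a rejection-sampling no-self-overlap mode exists for
small genomes, as does an `excluded` interval set (default none — no
assembly-gap masking is assumed).  Defaults: 100 iterations.

Statistics: fold = observed/mean(null); z = (observed − mean)/sd(null)
with sd the sample (ddof=1) standard deviation; empirical p uses the
add-one estimator (1 + #{null ≥ obs})/(1 + n_iter) so p is never 0 and is
floored at 1/(n_iter+1).  Sentinels: fold = ∞ (with a warning) when the
null mean is 0 but motifs were observed, NaN when both are 0; z = NaN
when the null sd is 0 (e.g. peaks = whole genome).

Null counting re-scans sequence per placement by default.  A
`motif_cache` fast path counts genome-wide motifs fully contained in each
placement; it is exact on backgrounds without boundary-truncation
artifacts and documented as an approximation otherwise.

## Spike-in quantification

Factors are min(c)/cᵢ over spike-in counts cᵢ (error on zero counts);
downsampling keeps exactly round(n·factor) reads uniformly without
replacement, seeded.  Per-region counts use ≥ 1 bp overlap with
multi-hit semantics (a read spanning k regions increments all k).

Profiles scale each region body to 1300 bp (26 bins of 50 bp) with
±2 kb native-scale flanks (40 bins each; 106 columns total).  Reads
contribute fractional overlap per genomic bin; densities are coverage /
genomic bin width / (library reads per million).  Dividing by the actual
genomic width keeps a uniform-coverage profile flat even though body
bins differ in genomic width from flank bins, and lets sub-bin regions
contribute fractionally.  Normalization order is spike-in downsampling
first, then per-million scaling; the order is recorded in CLI output
headers.  Strand orientation of regions is ignored (profiles are not
flipped for minus-strand regions).

Box summaries use linear-interpolation quartiles (the numpy default,
fixed and documented because plotting stacks differ); `iqr1.5` whiskers
clamp to the most extreme datum within 1.5×IQR of the box, `minmax` to
the data range.

## Donor-resampling burden test

Cohort = donors flagged with a high-impact lesion in the gene
(deduplicated; empty cohorts warn and downstream stages refuse them).
Counting splits substitutions and INDELs; per-donor totals are retained.
The null resamples k donors uniformly without replacement from the total
pool per iteration, independently across 504 iterations (default);
cohort donors remain in the pool by default (a flag excludes them), and
per-donor G4 counts are precomputed once so iterations are vector sums.

"Area to the right of the observation" is read as the empirical
right-tail mass with the add-one correction (the default); a Gaussian
upper tail at z is offered as the smooth alternative, and both are
reported.  The headline statistic pools substitutions + INDELs; both
classes and their separate null vectors are also emitted, so a
substitutions-only reading is recoverable.  The spectrum splits
substitutions by reference base G/C vs A/T, excludes ambiguous
references (reported separately) and tallies INDELs without a base
class.

## Synthetic generator

The generator's defaults are the package's reference study conditions:
one 100 kb chromosome, 20 planted PQS (4 tracts of GGG, loops 1–12 nt),
40 peaks of 300–1000 bp with half on motifs, 20k reads/sample at 10×
in-peak enrichment with spike-in counts {treatment: 50k, control: 100k},
and 1,000 donors of which 5% are flagged (ATRX), Poisson(20) mutations
per donor, 3× relative G4 placement rate and 80% G/C substitution share
for flagged donors, 90% substitutions / 10% INDELs overall.

*G-suppressed background.*  Background sequence is i.i.d. ACGT followed
by a single vectorized pass that replaces the third base of any G/C
3-run with A or T.  Replacements can never create a new G/C run, so the
no-≥3-run guarantee is constructive, and with loop bases drawn from
{A,C,T} (C-runs broken the same way) neither strand of the background or
loops can match the grammar.  Plants are separated by ≥ 13 bp (longer
than any legal loop, so no match bridges two plants) and the bases
flanking each plant are forced to A/T (so no match extends a planted
tract).  Together these make planted-motif recovery exact: the scanner
must return precisely the truth coordinates, and zero motifs on a plant-
free background.  The `uniform` background drops these guarantees and is
there for realism checks only.

*Peaks* fully contain a planted motif (the "on" fraction) or avoid all
motifs (rejection-sampled; an error if the genome is too saturated).
*Reads* follow a two-stratum mixture: a read falls in-region with
probability fold·c/(fold·c + 1 − c) where c is region coverage, uniform
within the stratum, 50 bp spans.  *Cohorts* place each mutation in the
G4 footprint with the analogous biased-coverage probability, positions
uniform within the stratum; substitution reference bases are read from
the genome, and flagged donors' substitutions are re-positioned (within
their stratum) until the reference base class matches a Bernoulli draw
of the configured G/C share.  Mutation tables round-trip through the
ICGC-style TSV writer/reader (1-based on disk).

*Emulated vs not.*  The generator reproduces the statistical structure
the pipeline assumes — planted motifs, controlled peak/motif coupling,
controlled read enrichment, a controlled cohort burden contrast — but
not GC-content heterogeneity, chromatin or replication-timing structure,
alignment artifacts, mutational signatures, or realistic chromosome
counts.  Passing tests therefore demonstrate correctness of the
algorithms under their stated assumptions, not robustness to genome-
scale confounders (the enrichment null, in particular, is positional
only and inherits the usual caveats about composition-matched nulls).

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen to finish in
about a minute each while leaving the statistical checks well-powered:
100 kb (toy) / 50 kb (calibration) genomes, 1,000-iteration nulls for
closed-form comparisons, 200 repetitions for calibration claims
(enrichment |z| < 3, burden type-I inside the binomial band), 100
repetitions at cohort 50 / pool 1,000 / 504 iterations for power.  The
power and type-I runs use peak-scale G4 regions (motifs padded ±230 bp),
mirroring the fact that observed G4 region sets are peak calls rather
than bare motifs.  All randomness flows through numpy Generators seeded
from a single user seed.  Ties in motif sorting break by (start, end,
strand); sample sd uses ddof=1 throughout.

## Known limitations

Reciprocal-overlap Venn thresholds, GC/chromatin-matched enrichment
nulls, strand-aware profile flipping, BAM ingestion (an adapter is the
intended route; readers consume BED-like spans), functional-impact
annotation of mutations (flags are inputs) and any thermodynamic G4
scoring are out of scope.  The rejection-based no-self-overlap shuffle
and motif-free peak placement can fail on nearly saturated toy genomes;
they raise rather than bias.
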