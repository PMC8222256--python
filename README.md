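# g4stress

Interval analytics for G-quadruplex (G4) genomics: scan sequence for
potential quadruplex sequences (PQS), test whether a peak set is enriched
for them against a shuffle null, quantify spike-in-normalized read signal
over regions, and test whether a tumor-donor cohort carries excess
mutation burden inside G4 regions.

G4 structures are four-stranded DNA folds formed by stacked guanine
tetrads in G-rich sequence.  Chromatin factors such as the remodeler
ATRX, the chaperone DAXX, the histone variant H3.3 and the
methyltransferase ESET keep G4-prone regions heterochromatinized; when
they fail, G4 persistence is linked to replication stress and elevated
mutation rates.  `g4stress` packages the computational side of that kind
of study as a tested, reusable library with a thin CLI, plus a synthetic
data generator so every stage is testable without downloading genomes or
sequencing data.

## The statistics at the core

**PQS grammar.**  A motif is `([gG]{3,}\w{1,12}){3,}[gG]{3,}` — at least
four runs of ≥ 3 guanines separated by 1–12 nt loops (G₃N₁₋₁₂G₃N₁₋₁₂G₃N₁₋₁₂G₃).
Matching is leftmost-greedy and non-overlapping, with the same grammar
applied to the reverse complement for minus-strand motifs.  A peak is
"G4" iff it contains ≥ 1 motif.

**Shuffle-null enrichment.**  Peaks are relocated uniformly at random
(preserving their number and sizes; chromosome chosen proportional to
length) and motifs recounted, by default over 100 randomizations:

    fold = observed / mean(null)
    z    = (observed − mean(null)) / sd(null)
    p    = (1 + #{null ≥ observed}) / (1 + n_iter)

**Spike-in normalization.**  With exogenous spike-in read counts cᵢ per
sample, sample *i* is randomly downsampled by factor min(c)/cᵢ, after
which per-region counts, 1300 bp scaled-body ± 2 kb metaprofiles and
box-plot summaries (linear-interpolation quartiles, 1.5×IQR or min–max
whiskers) are comparable across conditions.

**Donor-resampling mutation burden.**  For a gene (e.g. *ATRX*), the
cohort is every donor with a high-impact lesion in that gene; their
simple somatic mutations falling inside G4 regions are counted
(substitutions and INDELs separately).  The null resamples equally sized
donor sets from the full pool (default 504 iterations); the observation
is standardized by the null mean/sd and the p-value is the right-tail
mass of the null.  The substitution spectrum is split by G/C vs A/T
reference base.

## Worked example

```python
import g4stress as g

cfg = g.SimConfig(seed=0)                       # 100 kb genome, 20 planted PQS
rng = cfg.rng()
genome, truth = g.make_genome(cfg, rng)
peaks = g.make_peaks(genome, truth, cfg, rng)   # 40 peaks, half on motifs

counts = g.count_g4_in_intervals(genome, peaks)
print((g.classify_regions(counts) == "G4").sum())    # -> 20 of 40 peaks
```

Enrichment when all motifs lie inside peaks covering ~10% of the genome
(`examples/enrichment_test.py`):

```
observed motifs in peaks : 20
null mean +/- sd         : 2.10 +/- 1.45
fold enrichment          : 9.5x
z (SDs above chance)     : 12.4
empirical p (add-one)    : 0.0099
```

The null mean ≈ 20 × 0.1 matches the coverage expectation; fold ≈ 1/f and
p sits at the 1/(n_iter+1) floor.  Burden testing on a cohort with a
planted 3× G4 bias (`examples/mutation_burden.py`):

```
cohort size                 : 50
observed subs / INDELs in G4: 193 / 15
null mean +/- sd            : 105.5 +/- 10.8
standardized observation z  : 9.5
empirical p (right tail)    : 0.0020
substitution refs G/C vs A/T: 144 vs 49
```

Each `examples/*.py` script is a self-contained narrative of one
capability.  The CLI mirrors the library:

```sh
g4stress simulate --outdir fix --seed 5
g4stress scan --fasta fix/genome.fa --out motifs.bed
g4stress enrich --fasta fix/genome.fa --peaks fix/peaks.bed --seed 1 --out enrich.tsv
g4stress burden --ssm fix/ssm.tsv --donors fix/donors.tsv \
    --g4 fix/truth_g4.bed --gene ATRX --seed 1 --out burden.tsv
```

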