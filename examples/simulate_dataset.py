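"""Write a complete synthetic fixture set to disk and read it back.

Produces FASTA + truth/peaks BED + per-sample read BEDs + spike-in TSV +
donor and ICGC-style SSM TSVs, then demonstrates that the standard
readers round-trip the truth.
"""

import tempfile
from pathlib import Path

import g4stress as g
from g4stress.intervals import write_bed

outdir = Path(tempfile.mkdtemp(prefix="g4stress_"))
cfg = g.SimConfig(seed=0, n_donors=100)
rng = cfg.rng()
genome, truth = g.make_genome(cfg, rng)
peaks = g.make_peaks(genome, truth, cfg, rng)
reads = g.make_reads(genome, peaks, cfg, rng)
donors, mutations = g.make_cohort(cfg, truth, genome, rng)

genome.to_fasta(outdir / "genome.fa")
write_bed(truth, outdir / "truth_g4.bed")
write_bed(peaks, outdir / "peaks.bed")
g.write_donors_tsv(donors, outdir / "donors.tsv")
g.write_ssm_tsv(mutations, outdir / "ssm.tsv")

back_genome = g.read_fasta(outdir / "genome.fa")
back_truth = g.read_bed(outdir / "truth_g4.bed", back_genome)
back_ssm = g.read_ssm(outdir / "ssm.tsv")
print(f"wrote fixtures to {outdir}")
print(f"genome round-trip ok : {back_genome.sequences == genome.sequences}")
print(f"truth round-trip ok  : {[ (i.chrom,i.start,i.end) for i in back_truth ] == [ (i.chrom,i.start,i.end) for i in truth ]}")
print(f"ssm rows             : {len(back_ssm)} (positions back to 0-based)")
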