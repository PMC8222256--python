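"""Scan a small genome for PQS motifs and classify peaks as G4/non-G4.

Builds a synthetic 100 kb genome with 20 planted motifs, scans it with the
canonical grammar (>= 4 G-tracts of >= 3 G, 1-12 nt loops, both strands),
then classifies a peak set by whether each peak contains a motif.
"""

import g4stress as g

cfg = g.SimConfig(seed=0)
rng = cfg.rng()
genome, truth = g.make_genome(cfg, rng)
peaks = g.make_peaks(genome, truth, cfg, rng)

motifs = g.scan_g4(genome.sequences["chr1"], chrom="chr1")
print(f"planted {len(truth)} motifs, scanner found {len(motifs)}")
print(f"first motif: {motifs[0].chrom}:{motifs[0].start}-{motifs[0].end} "
      f"({motifs[0].n_tracts} tracts) {motifs[0].sequence[:30]}")

counts = g.count_g4_in_intervals(genome, peaks)
labels = g.classify_regions(counts)
n_g4 = int((labels == "G4").sum())
print(f"{n_g4}/{len(peaks)} peaks contain a G4 consensus motif "
      f"({100 * n_g4 / len(peaks):.0f}%)")
# The percentage is the G4-containing peak fraction; on real ChIP peak
# sets this is the headline "fraction of peaks with a PQS" number.
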