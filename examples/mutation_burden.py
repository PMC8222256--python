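"""Donor-resampling mutation burden at G4 regions.

A 1,000-donor catalog is simulated in which the 5% of donors flagged with
an ATRX lesion place mutations inside G4 regions at 3x the relative rate
and draw 80% of their substitutions on G/C bases.  The test counts cohort
substitutions/INDELs inside G4 regions and compares against 504 random
donor sets of the same size.
"""

import g4stress as g

cfg = g.SimConfig(seed=0)
rng = cfg.rng()
genome, truth = g.make_genome(cfg, rng)
# observed G4 regions: peak-scale windows around the motifs
g4 = g.IntervalSet(
    [g.Interval(iv.chrom, max(0, iv.start - 230),
                min(genome.chrom_lengths[iv.chrom], iv.end + 230))
     for iv in truth], genome,
)
donors, mutations = g.make_cohort(cfg, g4, genome, rng)

res = g.run_burden_test(mutations, donors, g4, "ATRX", n_iter=504, seed=1)
print(f"cohort size                 : {res.cohort_size}")
print(f"observed subs / INDELs in G4: {res.obs_sub} / {res.obs_indel}")
print(f"null mean +/- sd            : {res.null.mean:.1f} +/- {res.null.sd:.1f}")
print(f"standardized observation z  : {res.z_obs:.1f}")
print(f"empirical p (right tail)    : {res.p_empirical:.4f}")
spec = res.spectrum
print(f"substitution refs G/C vs A/T: {spec['GC']} vs {spec['AT']}")
# A z many SDs above the resampled null and p at the 1/505 floor recover
# the planted excess burden; the G/C-skewed spectrum mirrors the planted
# substitution bias.
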