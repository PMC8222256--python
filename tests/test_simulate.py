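"""Generator guarantees: reproducibility, constructive motif recovery,
peak composition, read enrichment, cohort structure, truth round-trips."""

import re

import numpy as np
import pandas as pd
import pytest

import g4stress as g
from g4stress.intervals import ValidationError


class TestGenome:
    def test_reproducible_under_seed(self):
        a_genome, a_truth = g.make_genome(g.SimConfig(seed=42))
        b_genome, b_truth = g.make_genome(g.SimConfig(seed=42))
        assert a_genome.sequences == b_genome.sequences
        assert a_truth == b_truth

    def test_suppressed_background_has_no_gc_runs_outside_plants(self):
        cfg = g.SimConfig(seed=1, chrom_lengths=(20_000,), n_planted_g4=0)
        genome, truth = g.make_genome(cfg)
        assert len(truth) == 0
        seq = genome.sequences["chr1"]
        assert re.search("GGG|CCC", seq) is None
        assert g.scan_g4(seq) == []

    def test_planted_motifs_recovered_exactly(self):
        cfg = g.SimConfig(seed=2, chrom_lengths=(60_000,), n_planted_g4=15)
        genome, truth = g.make_genome(cfg)
        motifs = g.scan_g4(genome.sequences["chr1"], chrom="chr1")
        assert [(m.start, m.end) for m in motifs] == [
            (iv.start, iv.end) for iv in truth
        ]
        assert all(m.strand == "+" for m in motifs)

    def test_rich_motifs_with_extra_tracts(self):
        cfg = g.SimConfig(seed=3, chrom_lengths=(30_000,), n_planted_g4=5,
                          motif_tracts=6)
        genome, truth = g.make_genome(cfg)
        motifs = g.scan_g4(genome.sequences["chr1"])
        assert len(motifs) == 5
        assert all(m.n_tracts == 6 for m in motifs)

    def test_multi_chromosome_packing(self):
        cfg = g.SimConfig(seed=4, chrom_lengths=(30_000, 20_000), n_planted_g4=12)
        genome, truth = g.make_genome(cfg)
        found = []
        for chrom in genome.chrom_names:
            found += g.scan_g4(genome.sequences[chrom], chrom=chrom)
        assert len(found) == 12

    def test_infeasible_packing_errors(self):
        cfg = g.SimConfig(seed=5, chrom_lengths=(500,), n_planted_g4=50)
        with pytest.raises(ValidationError):
            g.make_genome(cfg)

    def test_truth_round_trips_through_bed(self, tmp_path):
        genome, truth = g.make_genome(g.SimConfig(seed=6))
        p = tmp_path / "truth.bed"
        truth.to_bed(p)
        back = g.read_bed(p, genome)
        assert [(i.chrom, i.start, i.end, i.name) for i in back] == [
            (i.chrom, i.start, i.end, i.name) for i in truth
        ]


class TestPeaks:
    @pytest.mark.parametrize("frac,expected", [(1.0, 10), (0.0, 0), (0.5, 5)])
    def test_g4_fraction_controls_classification(self, frac, expected):
        cfg = g.SimConfig(seed=7, chrom_lengths=(80_000,), n_planted_g4=12,
                          n_peaks=10, frac_peaks_on_g4=frac)
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        peaks = g.make_peaks(genome, truth, cfg, rng)
        counts = g.count_g4_in_intervals(genome, peaks)
        assert (g.classify_regions(counts) == "G4").sum() == expected

    def test_requesting_g4_peaks_without_plants_errors(self):
        cfg = g.SimConfig(seed=8, n_planted_g4=0, frac_peaks_on_g4=0.5)
        genome, truth = g.make_genome(cfg)
        with pytest.raises(ValidationError):
            g.make_peaks(genome, truth, cfg)


class TestReads:
    def test_read_count_and_spikein_attachment(self):
        cfg = g.SimConfig(seed=9, reads_per_sample=2_000)
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        peaks = g.make_peaks(genome, truth, cfg, rng)
        readsets = g.make_reads(genome, peaks, cfg, rng)
        assert {rs.sample_id for rs in readsets} == set(cfg.spikein_counts)
        for rs in readsets:
            assert len(rs.reads) == 2_000
            assert rs.spikein_count == cfg.spikein_counts[rs.sample_id]

    def test_enrichment_fold_one_is_uniform(self):
        cfg = g.SimConfig(seed=10, reads_per_sample=20_000, enrichment_fold=1.0,
                          spikein_counts={"s": 1})
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        peaks = g.make_peaks(genome, truth, cfg, rng)
        rs = g.make_reads(genome, peaks, cfg, rng)[0]
        cov = peaks.coverage_bp() / genome.total_length
        starts_in = g.points_in_regions(
            [iv.chrom for iv in rs.reads], [iv.start for iv in rs.reads], peaks
        ).mean()
        assert starts_in == pytest.approx(cov, abs=3 * np.sqrt(cov * (1 - cov) / 20_000))

    def test_enrichment_fold_concentrates_reads(self):
        cfg = g.SimConfig(seed=11, reads_per_sample=20_000, enrichment_fold=10.0,
                          spikein_counts={"s": 1})
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        peaks = g.make_peaks(genome, truth, cfg, rng)
        rs = g.make_reads(genome, peaks, cfg, rng)[0]
        cov = peaks.coverage_bp() / genome.total_length
        frac_in = g.points_in_regions(
            [iv.chrom for iv in rs.reads], [iv.start for iv in rs.reads], peaks
        ).mean()
        expected = 10 * cov / (10 * cov + 1 - cov)
        assert frac_in == pytest.approx(expected, rel=0.05)


class TestCohort:
    def test_mutant_fraction_zero_gives_empty_cohort(self):
        cfg = g.SimConfig(seed=12, n_donors=50, mutant_fraction=0.0)
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        donors, muts = g.make_cohort(cfg, truth, genome, rng)
        with pytest.warns(UserWarning):
            assert g.select_cohort(donors, cfg.mutant_gene) == set()

    def test_cohort_size_and_reproducibility(self):
        cfg = g.SimConfig(seed=13, n_donors=200, mutant_fraction=0.1)
        genome, truth = g.make_genome(cfg, cfg.rng())

        def build():
            rng = np.random.default_rng(99)
            return g.make_cohort(cfg, truth, genome, rng)

        donors_a, muts_a = build()
        donors_b, muts_b = build()
        assert donors_a.equals(donors_b)
        assert muts_a.equals(muts_b)
        assert len(g.select_cohort(donors_a, "ATRX")) == 20

    def test_substitution_refs_match_genome(self):
        cfg = g.SimConfig(seed=14, n_donors=50)
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        donors, muts = g.make_cohort(cfg, truth, genome, rng)
        subs = muts[muts["mtype"] == "substitution"]
        for _, row in subs.head(200).iterrows():
            assert genome.sequences[row["chrom"]][row["pos"]] == row["ref"]
            assert row["alt"] != row["ref"]

    def test_ssm_round_trip_through_icgc_tsv(self, tmp_path):
        cfg = g.SimConfig(seed=15, n_donors=30)
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        donors, muts = g.make_cohort(cfg, truth, genome, rng)
        p = tmp_path / "ssm.tsv"
        g.write_ssm_tsv(muts, p)
        back = g.read_ssm(p)
        assert back["pos"].tolist() == muts["pos"].tolist()
        assert back["mtype"].tolist() == muts["mtype"].tolist()
        assert back["donor_id"].tolist() == muts["donor_id"].tolist()
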