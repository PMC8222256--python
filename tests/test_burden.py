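"""Donor-resampling burden test: cohort selection, point-in-region
counting, resampled null (vs. exhaustive enumeration on tiny pools),
standardization and spectrum."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import g4stress as g
from g4stress.burden import _per_donor_g4_counts
from g4stress.intervals import ParseError, ValidationError


def mut_table(rows):
    """rows: (donor, chrom, pos0, ref, alt, mtype)"""
    return pd.DataFrame(
        rows, columns=["donor_id", "chrom", "pos", "ref", "alt", "mtype"]
    )


G4 = g.IntervalSet([g.Interval("chr1", 100, 200)])


class TestReaders:
    def test_ssm_reader_converts_to_zero_based(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        p.write_text(
            "icgc_donor_id\tchromosome\tchromosome_start\treference_genome_allele\t"
            "mutated_to_allele\tmutation_type\textra\n"
            "D1\tchr1\t101\tG\tT\tsingle base substitution\tignored\n"
            "D2\tchr1\t150\t-\tA\tinsertion of <=200bp\tignored\n"
        )
        df = g.read_ssm(p)
        assert df["pos"].tolist() == [100, 149]
        assert df["mtype"].tolist() == ["substitution", "insertion"]
        assert "extra" not in df.columns

    def test_ssm_reader_rejects_bad_rows(self, tmp_path):
        p = tmp_path / "ssm.tsv"
        p.write_text(
            "icgc_donor_id\tchromosome\tchromosome_start\treference_genome_allele\t"
            "mutated_to_allele\tmutation_type\n"
            "D1\tchr1\t10\tGG\tT\tsingle base substitution\n"
        )
        with pytest.raises(ParseError):
            g.read_ssm(p)

    def test_donor_reader_round_trip(self, tmp_path):
        donors = pd.DataFrame({"donor_id": ["D1", "D2"], "gene": ["ATRX", ""]})
        p = tmp_path / "donors.tsv"
        g.write_donors_tsv(donors, p)
        back = g.read_donor_flags(p)
        assert back["donor_id"].tolist() == ["D1", "D2"]
        assert back["gene"].tolist() == ["ATRX", ""]


class TestCohort:
    donors = pd.DataFrame(
        {"donor_id": ["D1", "D1", "D2", "D3"], "gene": ["ATRX", "ATRX", "KRAS", ""]}
    )

    def test_flagged_donor_selected_once(self):
        assert g.select_cohort(self.donors, "ATRX") == {"D1"}

    def test_absent_gene_gives_empty_with_warning(self):
        with pytest.warns(UserWarning):
            assert g.select_cohort(self.donors, "TP53") == set()

    def test_empty_gene_symbol_rejected(self):
        with pytest.raises(ValueError):
            g.select_cohort(self.donors, "")


class TestBurdenInRegions:
    def test_substitution_inside_counts(self):
        muts = mut_table([("D1", "chr1", 150, "G", "T", "substitution")])
        obs_sub, obs_indel, per_donor = g.burden_in_regions(muts, {"D1"}, G4)
        assert (obs_sub, obs_indel) == (1, 0)
        assert per_donor.loc["D1"].tolist() == [1, 0]

    def test_insertion_inside_counts_as_indel(self):
        muts = mut_table([("D1", "chr1", 150, "-", "A", "insertion")])
        assert g.burden_in_regions(muts, {"D1"}, G4)[:2] == (0, 1)

    def test_outside_counts_zero(self):
        muts = mut_table([("D1", "chr1", 50, "G", "T", "substitution")])
        assert g.burden_in_regions(muts, {"D1"}, G4)[:2] == (0, 0)

    def test_half_open_boundaries(self):
        muts = mut_table(
            [
                ("D1", "chr1", 99, "G", "T", "substitution"),
                ("D1", "chr1", 100, "G", "T", "substitution"),
                ("D1", "chr1", 199, "G", "T", "substitution"),
                ("D1", "chr1", 200, "G", "T", "substitution"),
            ]
        )
        assert g.burden_in_regions(muts, {"D1"}, G4)[0] == 2

    def test_non_cohort_donor_ignored(self):
        muts = mut_table([("D9", "chr1", 150, "G", "T", "substitution")])
        assert g.burden_in_regions(muts, {"D1"}, G4)[:2] == (0, 0)

    def test_empty_cohort_refused(self):
        with pytest.raises(ValueError):
            g.burden_in_regions(mut_table([]), set(), G4)

    def test_chrom_namespace_mismatch(self):
        muts = mut_table([("D1", "1", 150, "G", "T", "substitution")])
        with pytest.raises(ValidationError):
            g.burden_in_regions(muts, {"D1"}, G4)


class TestNullBurden:
    muts = mut_table(
        [(f"D{i}", "chr1", 150, "G", "T", "substitution") for i in range(3)]
        + [("D0", "chr1", 150, "-", "A", "insertion")]
    )
    pool = [f"D{i}" for i in range(6)]  # D3..D5 carry nothing

    def test_k_equals_pool_gives_zero_sd(self):
        null = g.null_burden(self.muts, self.pool, G4, k=6, n_iter=10, seed=0)
        assert null.sd == 0.0
        assert set(null.counts.tolist()) == {4}

    def test_seed_reproducibility(self):
        a = g.null_burden(self.muts, self.pool, G4, k=3, n_iter=50, seed=5)
        b = g.null_burden(self.muts, self.pool, G4, k=3, n_iter=50, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_no_g4_mutations_all_zero(self):
        far = g.IntervalSet([g.Interval("chr1", 1000, 2000)])
        null = g.null_burden(self.muts, self.pool, far, k=3, n_iter=20, seed=1)
        assert null.counts.sum() == 0

    def test_k_exceeding_pool_errors(self):
        with pytest.raises(ValueError):
            g.null_burden(self.muts, self.pool, G4, k=7, n_iter=10, seed=0)

    def test_mean_matches_exhaustive_enumeration(self):
        # tiny pool: exact expectation by enumerating all k-subsets
        rng = np.random.default_rng(3)
        rows = []
        weights = {f"D{i}": int(rng.integers(0, 5)) for i in range(7)}
        for donor, w in weights.items():
            rows += [(donor, "chr1", 150, "G", "T", "substitution")] * w
        muts = mut_table(rows)
        pool = list(weights)
        k = 3
        exact = np.mean(
            [sum(weights[d] for d in combo)
             for combo in itertools.combinations(pool, k)]
        )
        null = g.null_burden(muts, pool, G4, k=k, n_iter=4000, seed=11)
        se = null.counts.std(ddof=1) / np.sqrt(null.n_iter)
        assert abs(null.mean - exact) < 3 * se + 1e-9


class TestStandardize:
    def _null(self, counts):
        counts = np.asarray(counts)
        return g.NullDistribution(
            counts, counts, np.zeros_like(counts),
            float(counts.mean()), float(counts.std(ddof=1)), len(counts),
        )

    def test_z_arithmetic(self):
        null = g.NullDistribution(np.array([8, 12]), np.array([8, 12]),
                                  np.array([0, 0]), 10.0, 2.0, 2)
        z, _ = g.standardize_and_p(16, null)
        assert z == 3.0

    def test_obs_beyond_all_nulls_gives_add_one_p(self):
        counts = np.arange(504)
        null = self._null(counts)
        _, p = g.standardize_and_p(10_000, null)
        assert p == pytest.approx(1 / 505)

    def test_gaussian_tail(self):
        null = g.NullDistribution(np.array([0, 2]), np.array([0, 2]),
                                  np.array([0, 0]), 0.0, 1.0, 2)
        z, p = g.standardize_and_p(1.96, null, mode="gaussian")
        assert p == pytest.approx(0.025, abs=0.001)

    def test_sd_zero_gives_nan_z_but_defined_empirical_p(self):
        counts = np.full(10, 5)
        null = g.NullDistribution(counts, counts, np.zeros_like(counts),
                                  5.0, 0.0, 10)
        z, p = g.standardize_and_p(7, null)
        assert math.isnan(z)
        assert p == pytest.approx(1 / 11)

    @given(st.integers(-1000, 1000))
    def test_affine_invariance_of_z(self, shift):
        counts = np.array([3, 5, 7, 9, 11])
        null_a = self._null(counts)
        null_b = self._null(counts + shift)
        za, _ = g.standardize_and_p(8, null_a)
        zb, _ = g.standardize_and_p(8 + shift, null_b)
        assert za == pytest.approx(zb)


class TestSpectrum:
    def test_base_classes(self):
        muts = mut_table(
            [
                ("D1", "chr1", 150, "G", "T", "substitution"),
                ("D1", "chr1", 151, "C", "A", "substitution"),
                ("D1", "chr1", 152, "A", "G", "substitution"),
                ("D1", "chr1", 153, "-", "A", "insertion"),
                ("D1", "chr1", 154, "N", "A", "substitution"),
            ]
        )
        spec = g.mutation_spectrum(muts, {"D1"}, G4)
        assert (spec["GC"], spec["AT"], spec["indel"], spec["ambiguous"]) == (2, 1, 1, 1)
        assert spec["by_substitution"] == {"G>T": 1, "C>A": 1, "A>G": 1}

    def test_region_filter(self):
        muts = mut_table(
            [
                ("D1", "chr1", 150, "G", "T", "substitution"),
                ("D1", "chr1", 500, "G", "T", "substitution"),
            ]
        )
        assert g.mutation_spectrum(muts, {"D1"}, G4)["GC"] == 1


class TestRunBurdenTest:
    def test_end_to_end_on_synthetic_contrast(self):
        cfg = g.SimConfig(seed=21, n_donors=300, mutant_fraction=0.1,
                          mutations_per_donor_mean=10, g4_bias_mutant=4.0)
        rng = cfg.rng()
        genome, truth = g.make_genome(cfg, rng)
        g4 = g.IntervalSet(
            [g.Interval(iv.chrom, max(0, iv.start - 200),
                        min(genome.chrom_lengths[iv.chrom], iv.end + 200))
             for iv in truth], genome,
        )
        donors, muts = g.make_cohort(cfg, g4, genome, rng)
        res = g.run_burden_test(muts, donors, g4, "ATRX", n_iter=200, seed=1)
        assert res.cohort_size == 30
        assert res.z_obs > 3
        assert res.p_empirical == pytest.approx(1 / 201)
        # flagged donors draw most substitutions on G/C references
        total_sub = res.spectrum["GC"] + res.spectrum["AT"]
        assert res.spectrum["GC"] > 0.6 * total_sub
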