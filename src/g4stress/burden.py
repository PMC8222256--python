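"""Donor-resampling mutation-burden test at G4 regions.

For a gene of interest (e.g. *ATRX*, *SETDB1*/ESET), the cohort is every
donor carrying a high-impact functional lesion in that gene.  All simple
somatic mutations (SSMs) of the cohort are intersected with the observed
G4 regions (``bedtools intersect -u`` point-in-interval semantics) and
substitutions and INDELs are counted.  The null is built by resampling
donor sets of the same size uniformly without replacement from the total
pool (default 504 iterations) and counting the same quantity.  The
observation is standardized against the null:

    z = (obs - mean(null)) / sd(null)

and the p-value is the right-tail mass of the null at the observation —
by default the empirical mass with an add-one correction,
``(1 + #{null >= obs}) / (1 + n_iter)``, with a Gaussian upper tail
offered as an alternative smooth reading.

SSM positions are 1-based on input (ICGC convention) and converted to
0-based points at the reader; an INDEL is located at its start coordinate.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalSet, ParseError, ValidationError, points_in_regions

_SSM_COLUMNS = {
    "icgc_donor_id": "donor_id",
    "chromosome": "chrom",
    "chromosome_start": "pos",
    "reference_genome_allele": "ref",
    "mutated_to_allele": "alt",
    "mutation_type": "mtype",
}

_MTYPES = ("substitution", "insertion", "deletion")


def _normalize_mtype(value: str) -> str:
    v = str(value).lower()
    if "sub" in v:
        return "substitution"
    if "ins" in v:
        return "insertion"
    if "del" in v:
        return "deletion"
    raise ParseError(f"unrecognized mutation_type {value!r}")


def read_ssm(path) -> pd.DataFrame:
    """Read an ICGC-style simple-somatic-mutation TSV.

    Required columns: icgc_donor_id, chromosome, chromosome_start,
    reference_genome_allele, mutated_to_allele, mutation_type; extra
    columns are ignored.  Positions are converted from 1-based to 0-based;
    mutation types are normalized to substitution/insertion/deletion.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SSM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"SSM table missing columns: {missing}")
    df = df[list(_SSM_COLUMNS)].rename(columns=_SSM_COLUMNS)
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
    if (df["pos"] < 1).any():
        raise ParseError("SSM positions must be >= 1 (1-based input)")
    df["pos"] = df["pos"] - 1
    df["mtype"] = df["mtype"].map(_normalize_mtype)
    bad = df[
        (df["mtype"] == "substitution")
        & ((df["ref"].str.len() != 1) | (df["alt"].str.len() != 1))
    ]
    if len(bad):
        raise ParseError(
            f"{len(bad)} substitutions with non-single-base alleles "
            f"(first at row {bad.index[0]})"
        )
    return df.reset_index(drop=True)


def read_donor_flags(path) -> pd.DataFrame:
    """Read a donor -> flagged-gene table (TSV, columns donor_id, gene).

    One row per donor/gene flag; an empty gene field means the donor is in
    the pool but carries no high-impact lesion of interest.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "donor_id" not in df.columns or "gene" not in df.columns:
        raise ParseError("donor table needs columns donor_id and gene")
    return df[["donor_id", "gene"]]


def select_cohort(donors: pd.DataFrame, gene: str) -> set[str]:
    """Donors flagged with a high-impact lesion in ``gene`` (deduplicated)."""
    if not gene:
        raise ValueError("gene symbol must be non-empty")
    cohort = set(donors.loc[donors["gene"] == gene, "donor_id"])
    if not cohort:
        warnings.warn(f"no donors flagged for gene {gene!r}; cohort is empty")
    return cohort


def _check_chrom_namespace(mutations: pd.DataFrame, g4: IntervalSet) -> None:
    if len(mutations) == 0 or len(g4) == 0:
        return
    mut_chroms = set(mutations["chrom"].unique())
    g4_chroms = {iv.chrom for iv in g4}
    if g4.genome is not None:
        unknown = mut_chroms - set(g4.genome.chrom_lengths)
        if unknown:
            raise ValidationError(f"mutation chromosomes absent from assembly: {sorted(unknown)[:5]}")
    elif not (mut_chroms & g4_chroms):
        raise ValidationError(
            "mutation and G4 region chromosome names do not overlap "
            "(namespace mismatch, e.g. '1' vs 'chr1')"
        )


def _per_donor_g4_counts(mutations: pd.DataFrame, g4: IntervalSet) -> pd.DataFrame:
    """Per-donor counts of G4-intersecting substitutions and INDELs."""
    in_g4 = points_in_regions(mutations["chrom"].to_numpy(object),
                              mutations["pos"].to_numpy(), g4)
    hit = mutations.loc[in_g4]
    is_sub = hit["mtype"] == "substitution"
    sub = hit.loc[is_sub].groupby("donor_id").size()
    indel = hit.loc[~is_sub].groupby("donor_id").size()
    out = pd.DataFrame({"sub": sub, "indel": indel}).fillna(0).astype(np.int64)
    return out


def burden_in_regions(
    mutations: pd.DataFrame, cohort: set[str], g4: IntervalSet
) -> tuple[int, int, pd.DataFrame]:
    """Count cohort mutations whose position falls inside a G4 region.

    Returns (obs_sub, obs_indel, per_donor) with substitutions and INDELs
    tallied separately and per-donor totals retained (cohort donors with
    zero G4 hits appear with zeros).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    _check_chrom_namespace(mutations, g4)
    muts = mutations[mutations["donor_id"].isin(cohort)]
    per_donor = _per_donor_g4_counts(muts, g4)
    per_donor = per_donor.reindex(sorted(cohort), fill_value=0)
    return int(per_donor["sub"].sum()), int(per_donor["indel"].sum()), per_donor


@dataclass
class NullDistribution:
    """Resampled null counts (total = substitutions + INDELs, plus each
    class separately)."""

    counts: np.ndarray
    sub_counts: np.ndarray
    indel_counts: np.ndarray
    mean: float
    sd: float
    n_iter: int


def null_burden(
    mutations: pd.DataFrame,
    pool: list[str],
    g4: IntervalSet,
    k: int,
    n_iter: int = 504,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Null by resampling ``k`` donors from ``pool`` ``n_iter`` times.

    Sampling is uniform without replacement within an iteration and
    independent across iterations.  Per-donor G4-intersecting counts are
    precomputed once, so each iteration is a vector sum.
    """
    pool = list(dict.fromkeys(pool))
    if k > len(pool):
        raise ValueError(f"cohort size {k} exceeds pool size {len(pool)}")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    _check_chrom_namespace(mutations, g4)

    per_donor = _per_donor_g4_counts(
        mutations[mutations["donor_id"].isin(set(pool))], g4
    ).reindex(pool, fill_value=0)
    subs = per_donor["sub"].to_numpy()
    indels = per_donor["indel"].to_numpy()

    sub_counts = np.empty(n_iter, dtype=np.int64)
    indel_counts = np.empty(n_iter, dtype=np.int64)
    n = len(pool)
    for i in range(n_iter):
        idx = rng.choice(n, size=k, replace=False)
        sub_counts[i] = subs[idx].sum()
        indel_counts[i] = indels[idx].sum()
    counts = sub_counts + indel_counts
    return NullDistribution(
        counts, sub_counts, indel_counts,
        float(counts.mean()), float(counts.std(ddof=1)), n_iter,
    )


def standardize_and_p(
    obs: float, null: NullDistribution, mode: str = "empirical"
) -> tuple[float, float]:
    """Standardized observation and right-tail p against the null.

    z = (obs - mean)/sd (NaN when sd == 0).  ``empirical`` p is the
    add-one right-tail mass of the null counts; ``gaussian`` is the upper
    tail of the standard normal at z.
    """
    z = (obs - null.mean) / null.sd if null.sd > 0 else math.nan
    if mode == "empirical":
        p = (1 + int((null.counts >= obs).sum())) / (1 + null.n_iter)
    elif mode == "gaussian":
        if math.isnan(z):
            raise ValueError("gaussian p undefined when null sd is 0")
        p = float(stats.norm.sf(z))
    else:
        raise ValueError("mode must be 'empirical' or 'gaussian'")
    return z, p


def mutation_spectrum(
    mutations: pd.DataFrame,
    cohort: set[str] | None = None,
    g4: IntervalSet | None = None,
) -> dict:
    """Substitution spectrum by reference-base class, plus INDEL count.

    Substitutions are split by whether the reference base is G/C or A/T
    (ambiguous bases, e.g. N, are excluded but reported); INDELs are
    tallied separately with no base class.  Optionally restricted to a
    cohort and/or to mutations inside G4 regions.
    """
    muts = mutations
    if cohort is not None:
        muts = muts[muts["donor_id"].isin(cohort)]
    if g4 is not None:
        in_g4 = points_in_regions(muts["chrom"].to_numpy(object),
                                  muts["pos"].to_numpy(), g4)
        muts = muts.loc[in_g4]
    is_sub = muts["mtype"] == "substitution"
    subs = muts.loc[is_sub]
    ref = subs["ref"].str.upper()
    gc = int(ref.isin(["G", "C"]).sum())
    at = int(ref.isin(["A", "T"]).sum())
    ambiguous = int(len(subs) - gc - at)
    by_type = Counter(
        f"{r}>{a}" for r, a in zip(ref, subs["alt"].str.upper())
        if r in "ACGT" and a in "ACGT"
    )
    return {
        "GC": gc,
        "AT": at,
        "ambiguous": ambiguous,
        "indel": int((~is_sub).sum()),
        "by_substitution": dict(by_type),
    }


@dataclass
class BurdenResult:
    gene: str
    cohort_size: int
    obs_sub: int
    obs_indel: int
    per_donor_counts: pd.DataFrame
    null: NullDistribution
    z_obs: float
    p_empirical: float
    p_gaussian: float
    spectrum: dict


def run_burden_test(
    mutations: pd.DataFrame,
    donors: pd.DataFrame,
    g4: IntervalSet,
    gene: str,
    n_iter: int = 504,
    seed: int | None = None,
    pool: list[str] | None = None,
    exclude_cohort_from_pool: bool = False,
) -> BurdenResult:
    """End-to-end burden test for one gene.

    The headline statistic pools substitutions + INDELs; both classes are
    also reported separately (and per class in the null).  The pool
    defaults to every donor in the donor table; cohort donors stay in the
    pool unless ``exclude_cohort_from_pool``.
    """
    cohort = select_cohort(donors, gene)
    if not cohort:
        raise ValueError(f"empty cohort for gene {gene!r}")
    obs_sub, obs_indel, per_donor = burden_in_regions(mutations, cohort, g4)
    if pool is None:
        pool = list(dict.fromkeys(donors["donor_id"]))
    if exclude_cohort_from_pool:
        pool = [d for d in pool if d not in cohort]
    null = null_burden(mutations, pool, g4, k=len(cohort), n_iter=n_iter, seed=seed)
    obs_total = obs_sub + obs_indel
    z, p_emp = standardize_and_p(obs_total, null, mode="empirical")
    p_gauss = float(stats.norm.sf(z)) if not math.isnan(z) else math.nan
    spectrum = mutation_spectrum(mutations, cohort, g4)
    return BurdenResult(
        gene, len(cohort), obs_sub, obs_indel, per_donor,
        null, z, p_emp, p_gauss, spectrum,
    )
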