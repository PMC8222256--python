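"""Synthetic-data generator for every pipeline stage.

The generator emulates the data-generating situations the pipeline
assumes, so everything is testable offline:

* genomes with planted PQS at known coordinates, on a background that is
  either uniform i.i.d. nucleotides or "G-suppressed" (guaranteed free of
  any run of three or more G or C, so the planted motifs are the only
  motifs and recovery can be checked to the base pair);
* peak sets with a controlled fraction of peaks fully containing a planted
  motif, the rest avoiding all motifs;
* read sets placed uniformly with a density multiplier inside chosen
  regions, plus per-sample spike-in counts;
* donor/mutation catalogs in which donors flagged with a lesion in a
  chosen gene place mutations inside G4 regions at an elevated relative
  rate and their substitutions hit G/C reference bases with an elevated
  share.

All outputs are exactly reproducible under a fixed seed, and the truth
files round-trip through the standard readers.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeAssembly, Interval, IntervalSet, ValidationError
from .quant import ReadSet

_PLANT_GAP = 13  # bp of motif-free spacing around plants: breaks any 1-12 nt loop


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale genome (one 100 kb chromosome, 20
    planted PQS on a G/C-run-suppressed background), a 40-peak set with
    half the peaks on planted motifs, spike-in read sets at 10x enrichment,
    and a 1,000-donor catalog in which 5% of donors (a 50-donor cohort)
    carry the flagged lesion, place mutations in G4 regions at 3x the
    relative rate, and draw 80% of their substitutions on G/C bases.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (100_000,)
    background_mode: str = "g_suppressed"  # or "uniform"
    n_planted_g4: int = 20
    tract_len: int = 3
    motif_tracts: int = 4
    loop_len_range: tuple[int, int] = (1, 12)
    n_peaks: int = 40
    peak_len_range: tuple[int, int] = (300, 1000)
    frac_peaks_on_g4: float = 0.5
    reads_per_sample: int = 20_000
    read_len: int = 50
    enrichment_fold: float = 10.0
    spikein_counts: Mapping[str, int] = field(
        default_factory=lambda: {"treatment": 50_000, "control": 100_000}
    )
    n_donors: int = 1_000
    mutant_gene: str = "ATRX"
    mutant_fraction: float = 0.05
    mutations_per_donor_mean: float = 20.0
    g4_bias_mutant: float = 3.0
    gc_sub_share_mutant: float = 0.8
    sub_fraction: float = 0.9

    def __post_init__(self) -> None:
        for frac in (self.frac_peaks_on_g4, self.mutant_fraction,
                     self.gc_sub_share_mutant, self.sub_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.background_mode not in ("uniform", "g_suppressed"):
            raise ValueError("background_mode must be 'uniform' or 'g_suppressed'")
        lo, hi = self.loop_len_range
        if not (0 < lo <= hi):
            raise ValueError("invalid loop_len_range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


_GC = np.frombuffer(b"GC", dtype="S1")
_AT = np.frombuffer(b"AT", dtype="S1")
_ACGT = np.frombuffer(b"ACGT", dtype="S1")
_ACT = np.frombuffer(b"ACT", dtype="S1")


def _break_gc_runs(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace the third base of any G/C 3-run with A/T.

    A/T replacements can never create a new G/C run, so a single pass
    constructively guarantees the no-3-run property.
    """
    if len(arr) < 3:
        return arr
    same = (arr[2:] == arr[1:-1]) & (arr[1:-1] == arr[:-2])
    gc = np.isin(arr[2:], _GC)
    idx = np.nonzero(same & gc)[0] + 2
    if len(idx):
        arr[idx] = rng.choice(_AT, size=len(idx))
    return arr


def _background(n: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    arr = rng.choice(_ACGT, size=n)
    if mode == "g_suppressed":
        arr = _break_gc_runs(arr, rng)
    return arr


def _motif_string(config: SimConfig, rng: np.random.Generator) -> str:
    """One planted PQS: ``motif_tracts`` G-tracts joined by loops drawn
    from {A,C,T} with C-runs broken (so no minus-strand motif arises)."""
    lo, hi = config.loop_len_range
    parts = []
    for t in range(config.motif_tracts):
        parts.append(b"G" * config.tract_len)
        if t < config.motif_tracts - 1:
            loop_len = int(rng.integers(lo, hi + 1))
            loop = _break_gc_runs(rng.choice(_ACT, size=loop_len), rng)
            parts.append(loop.tobytes())
    return b"".join(parts).decode()


def make_genome(
    config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[GenomeAssembly, IntervalSet]:
    """Build a genome with planted PQS; returns (assembly, truth intervals).

    Plants are separated by >= 13 bp so no regex match can bridge two of
    them, and the bases immediately flanking each plant are forced to A/T
    so a match can never extend beyond the planted coordinates.  On the
    g_suppressed background the planted motifs are therefore recovered
    with exact coordinates and nothing else matches.
    """
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = config.rng()

    names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    lengths = dict(zip(names, config.chrom_lengths))

    # assign plants to chromosomes proportional to length
    total = sum(config.chrom_lengths)
    plant_chroms = rng.choice(
        len(names),
        size=config.n_planted_g4,
        p=np.asarray(config.chrom_lengths, dtype=float) / total,
    )

    sequences: dict[str, str] = {}
    truth: list[Interval] = []
    plant_id = 0
    for ci, name in enumerate(names):
        clen = config.chrom_lengths[ci]
        arr = _background(clen, config.background_mode, rng)
        motifs = [_motif_string(config, rng) for _ in range((plant_chroms == ci).sum())]
        if motifs:
            need = sum(len(m) for m in motifs) + (len(motifs) + 1) * _PLANT_GAP
            if need > clen:
                raise ValidationError(
                    f"cannot pack {len(motifs)} plants into {name} ({clen} bp)"
                )
            slack = clen - need
            extra = rng.multinomial(slack, np.full(len(motifs) + 1, 1 / (len(motifs) + 1)))
            pos = 0
            for mi, motif in enumerate(motifs):
                pos += _PLANT_GAP + int(extra[mi])
                start, end = pos, pos + len(motif)
                arr[start:end] = np.frombuffer(motif.encode(), dtype="S1")
                # A/T guards so the first/last tract cannot extend
                if start > 0:
                    arr[start - 1] = rng.choice(_AT)
                if end < clen:
                    arr[end] = rng.choice(_AT)
                truth.append(Interval(name, start, end, name=f"g4_{plant_id}", strand="+"))
                plant_id += 1
                pos = end
        sequences[name] = arr.tobytes().decode()

    genome = GenomeAssembly(names, lengths, sequences)
    truth.sort(key=lambda iv: (iv.chrom, iv.start))
    return genome, IntervalSet(truth, genome)


def make_peaks(
    genome: GenomeAssembly,
    truth: IntervalSet,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Peak set with ``frac_peaks_on_g4`` of peaks fully containing a
    planted motif and the rest avoiding all motifs."""
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = config.rng()
    n_on = round(config.frac_peaks_on_g4 * config.n_peaks)
    if n_on > 0 and len(truth) == 0:
        raise ValidationError("frac_peaks_on_g4 > 0 but no planted motifs")
    lo, hi = config.peak_len_range
    truth_merged = truth.merged_arrays()
    from .intervals import _overlaps_merged

    peaks: list[Interval] = []
    order = rng.permutation(len(truth)) if len(truth) else np.array([], dtype=int)
    for i in range(n_on):
        motif = truth[int(order[i % len(truth)])]
        clen = genome.chrom_lengths[motif.chrom]
        plen = max(int(rng.integers(lo, hi + 1)), motif.length)
        lo_start = max(0, motif.end - plen)
        hi_start = min(motif.start, clen - plen)
        if hi_start < lo_start:
            raise ValidationError("peak cannot contain motif within chromosome bounds")
        start = int(rng.integers(lo_start, hi_start + 1))
        peaks.append(Interval(motif.chrom, start, start + plen, name=f"peak_{i}"))

    names = genome.chrom_names
    lengths = np.array([genome.chrom_lengths[c] for c in names], dtype=float)
    weights = lengths / lengths.sum()
    for i in range(n_on, config.n_peaks):
        plen = int(rng.integers(lo, hi + 1))
        for _ in range(1000):
            chrom = names[int(rng.choice(len(names), p=weights))]
            clen = genome.chrom_lengths[chrom]
            if clen < plen:
                continue
            start = int(rng.integers(0, clen - plen + 1))
            candidate = Interval(chrom, start, start + plen, name=f"peak_{i}")
            if not _overlaps_merged(candidate, truth_merged):
                peaks.append(candidate)
                break
        else:
            raise ValidationError(
                "could not place a motif-free peak; genome too saturated"
            )
    peaks.sort(key=lambda iv: (iv.chrom, iv.start))
    return IntervalSet(peaks, genome)


def _footprint(merged: dict[str, tuple[np.ndarray, np.ndarray]]):
    """Flatten merged intervals into parallel arrays for uniform sampling."""
    chroms: list[str] = []
    starts: list[int] = []
    lens: list[int] = []
    for chrom, (s, e) in sorted(merged.items()):
        for a, b in zip(s.tolist(), e.tolist()):
            chroms.append(chrom)
            starts.append(a)
            lens.append(b - a)
    return (
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(lens, dtype=np.int64),
    )


def _sample_footprint(fp, n: int, rng: np.random.Generator):
    """Uniform positions over a footprint; returns (chroms, positions)."""
    chroms, starts, lens = fp
    cum = np.cumsum(lens)
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right")
    offset = u - (cum[idx - 1] * (idx > 0))
    return chroms[idx], starts[idx] + offset


def _complement_merged(
    merged: dict[str, tuple[np.ndarray, np.ndarray]], genome: GenomeAssembly
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.chrom_names:
        clen = genome.chrom_lengths[chrom]
        s, e = merged.get(chrom, (np.array([], dtype=np.int64),) * 2)
        gap_starts = np.concatenate([[0], e])
        gap_ends = np.concatenate([s, [clen]])
        keep = gap_ends > gap_starts
        out[chrom] = (gap_starts[keep], gap_ends[keep])
    return out


def make_reads(
    genome: GenomeAssembly,
    regions: IntervalSet,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[ReadSet]:
    """Read sets placed uniformly with ``enrichment_fold`` x density inside
    ``regions``; per-sample spike-in counts attached."""
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = config.rng()
    merged = regions.merged_arrays()
    cov_bp = regions.coverage_bp()
    total = genome.total_length
    cov = cov_bp / total
    fold = config.enrichment_fold
    p_in = fold * cov / (fold * cov + (1 - cov)) if cov_bp else 0.0

    fp_in = _footprint(merged) if cov_bp else None
    fp_out = _footprint(_complement_merged(merged, genome))

    out: list[ReadSet] = []
    for sample, spike in config.spikein_counts.items():
        n = config.reads_per_sample
        inside = rng.random(n) < p_in
        chroms = np.empty(n, dtype=object)
        pos = np.empty(n, dtype=np.int64)
        n_in = int(inside.sum())
        if n_in:
            chroms[inside], pos[inside] = _sample_footprint(fp_in, n_in, rng)
        if n - n_in:
            chroms[~inside], pos[~inside] = _sample_footprint(fp_out, n - n_in, rng)
        reads = []
        for i in range(n):
            clen = genome.chrom_lengths[chroms[i]]
            start = int(pos[i])
            end = min(start + config.read_len, clen)
            reads.append(Interval(chroms[i], start, end, name=f"{sample}_{i}"))
        out.append(ReadSet(sample, IntervalSet(reads, genome), int(spike)))
    return out


def make_cohort(
    config: SimConfig | None = None,
    g4: IntervalSet | None = None,
    genome: GenomeAssembly | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Donor catalog and SSM table with a planted G4 burden contrast.

    Flagged donors (``mutant_fraction`` of ``n_donors``, gene
    ``mutant_gene``) place each mutation inside the G4 footprint with
    relative rate ``g4_bias_mutant`` (1 = no bias); their substitutions
    hit a G/C reference base with share ``gc_sub_share_mutant``.  Returns
    (donors, mutations) in the internal normalized form (positions
    0-based; see :func:`g4stress.burden.read_ssm`).
    """
    if config is None:
        config = SimConfig()
    if rng is None:
        rng = config.rng()
    if g4 is None or genome is None:
        raise ValueError("make_cohort needs g4 regions and a genome")

    n = config.n_donors
    donor_ids = np.array([f"DO{i:05d}" for i in range(n)], dtype=object)
    n_flagged = round(config.mutant_fraction * n)
    flagged = np.zeros(n, dtype=bool)
    flagged[rng.choice(n, size=n_flagged, replace=False)] = True
    donors = pd.DataFrame(
        {"donor_id": donor_ids,
         "gene": np.where(flagged, config.mutant_gene, "")}
    )

    merged = g4.merged_arrays()
    cov = g4.coverage_bp() / genome.total_length
    fp_in = _footprint(merged)
    fp_out = _footprint(_complement_merged(merged, genome))
    seq_arrays = {
        c: np.frombuffer(genome.sequences[c].encode(), dtype="S1")
        for c in genome.chrom_names
    }

    counts = rng.poisson(config.mutations_per_donor_mean, size=n)
    donor_idx = np.repeat(np.arange(n), counts)
    m = len(donor_idx)
    is_flagged = flagged[donor_idx]
    bias = np.where(is_flagged, config.g4_bias_mutant, 1.0)
    p_in = bias * cov / (bias * cov + (1 - cov))
    in_g4 = rng.random(m) < p_in

    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for mask, fp in ((in_g4, fp_in), (~in_g4, fp_out)):
        k = int(mask.sum())
        if k:
            chroms[mask], pos[mask] = _sample_footprint(fp, k, rng)

    is_sub = rng.random(m) < config.sub_fraction

    def ref_at(ch, po):
        return np.array([seq_arrays[c][p] for c, p in zip(ch, po)], dtype="S1")

    ref = ref_at(chroms, pos)

    # flagged donors' substitutions target G/C refs with the configured share:
    # draw the desired class, then resample positions (within the same
    # stratum) for mutations whose reference base class disagrees
    want_gc = is_flagged & is_sub & (rng.random(m) < config.gc_sub_share_mutant)
    want_at = is_flagged & is_sub & ~want_gc
    for _ in range(200):
        ref_gc = np.isin(ref, _GC)
        mismatch = (want_gc & ~ref_gc) | (want_at & ref_gc)
        if not mismatch.any():
            break
        for stratum, fp in ((in_g4, fp_in), (~in_g4, fp_out)):
            redo = mismatch & stratum
            k = int(redo.sum())
            if k:
                chroms[redo], pos[redo] = _sample_footprint(fp, k, rng)
        ref = ref_at(chroms, pos)

    ref_s = ref.astype("U1")
    alt = np.empty(m, dtype=object)
    mtype = np.empty(m, dtype=object)
    bases = "ACGT"
    alt_choice = rng.integers(0, 3, size=m)
    ins_or_del = rng.random(m) < 0.5
    ins_base = rng.integers(0, 4, size=m)
    for i in range(m):
        if is_sub[i]:
            mtype[i] = "substitution"
            options = bases.replace(ref_s[i], "") if ref_s[i] in bases else bases
            alt[i] = options[alt_choice[i] % len(options)]
        elif ins_or_del[i]:
            mtype[i] = "insertion"
            ref_s[i] = "-"
            alt[i] = bases[ins_base[i]]
        else:
            mtype[i] = "deletion"
            alt[i] = "-"

    mutations = pd.DataFrame(
        {
            "donor_id": donor_ids[donor_idx],
            "chrom": chroms,
            "pos": pos,
            "ref": ref_s.astype(object),
            "alt": alt,
            "mtype": mtype,
        }
    )
    return donors, mutations


_ICGC_MTYPE = {
    "substitution": "single base substitution",
    "insertion": "insertion of <=200bp",
    "deletion": "deletion of <=200bp",
}


def write_ssm_tsv(mutations: pd.DataFrame, path) -> None:
    """Write the internal mutation table as an ICGC-style SSM TSV
    (1-based positions, ICGC column names)."""
    out = pd.DataFrame(
        {
            "icgc_donor_id": mutations["donor_id"],
            "chromosome": mutations["chrom"],
            "chromosome_start": mutations["pos"] + 1,
            "reference_genome_allele": mutations["ref"],
            "mutated_to_allele": mutations["alt"],
            "mutation_type": mutations["mtype"].map(_ICGC_MTYPE),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_donors_tsv(donors: pd.DataFrame, path) -> None:
    donors.to_csv(path, sep="\t", index=False)
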