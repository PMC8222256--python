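"""Spike-in normalized region quantification.

Samples sequenced with an exogenous (e.g. Drosophila) chromatin spike-in
are made comparable by random downsampling: the sample with the fewest
uniquely-mapped spike-in reads keeps everything (factor 1.0) and every
other sample is downsampled by ``min_count / its_count``.  Downstream
quantities are per-region read counts (>= 1 bp overlap; a read overlapping
k regions increments all k), metaprofiles over regions scaled to a common
body length (default 1300 bp) with fixed-scale flanks (default +/- 2 kb),
and box-plot summaries (linear-interpolation quartiles, 1.5x IQR or
min/max whiskers).

Reads are modeled as genomic intervals; conversion from alignments and
duplicate removal are upstream concerns.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .intervals import IntervalSet


@dataclass
class ReadSet:
    """Uniquely-aligned read spans for one sample plus its spike-in count."""

    sample_id: str
    reads: IntervalSet
    spikein_count: int = 0

    def __post_init__(self) -> None:
        if self.spikein_count < 0:
            raise ValueError("spikein_count must be >= 0")

    def __len__(self) -> int:
        return len(self.reads)


def spikein_factors(counts: Mapping[str, int]) -> dict[str, float]:
    """Downsampling factor per sample: min(counts) / count.

    The sample with the least spike-in reads gets factor 1.0.  Zero counts
    are an error — there is nothing to normalize against.
    """
    if not counts:
        raise ValueError("no spike-in counts supplied")
    for sample, c in counts.items():
        if c <= 0:
            raise ValueError(f"sample {sample!r} has non-positive spike-in count {c}")
    least = min(counts.values())
    return {sample: least / c for sample, c in counts.items()}


def downsample_reads(
    readset: ReadSet,
    factor: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Retain exactly ``round(n * factor)`` reads, uniformly without
    replacement (original order preserved)."""
    if not (0 < factor <= 1):
        raise ValueError("factor must be in (0, 1]")
    n = len(readset.reads)
    keep = round(n * factor)
    if keep == n:
        return ReadSet(readset.sample_id, readset.reads, readset.spikein_count)
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    kept = [readset.reads[int(i)] for i in idx]
    return ReadSet(
        readset.sample_id,
        IntervalSet(kept, readset.reads.genome),
        readset.spikein_count,
    )


def _as_interval_set(reads) -> IntervalSet:
    return reads.reads if isinstance(reads, ReadSet) else reads


def _read_tree(reads: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # unique payload per read: IntervalTree would otherwise collapse
    # identical spans (duplicate reads must each contribute coverage)
    for i, iv in enumerate(reads):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def count_reads_in_regions(reads, regions: IntervalSet) -> np.ndarray:
    """Per-region read counts; a read overlapping k regions increments all k."""
    readset = _as_interval_set(reads)
    region_trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(regions):
        region_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    counts = np.zeros(len(regions), dtype=np.int64)
    for r in readset:
        tree = region_trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(r.start, r.end):
            counts[hit.data] += 1
    return counts


@dataclass
class ProfileMatrix:
    """Binned read densities over scaled regions.

    Columns run left flank (native scale), scaled body, right flank.
    ``matrix`` is regions x columns of reads-per-bp-per-million;
    ``col_means`` is its column mean.
    """

    matrix: np.ndarray
    col_means: np.ndarray
    flank_bins: int
    body_bins: int
    bin_size: int

    @property
    def n_columns(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def column_labels(self) -> list[str]:
        labels = [f"flank5_{-(self.flank_bins - i) * self.bin_size}"
                  for i in range(self.flank_bins)]
        labels += [f"body_{i}" for i in range(self.body_bins)]
        labels += [f"flank3_{(i + 1) * self.bin_size}" for i in range(self.flank_bins)]
        return labels


def scaled_average_profile(
    reads,
    regions: IntervalSet,
    body_len: int = 1300,
    flank: int = 2000,
    bin_size: int = 50,
    library_size: int | None = None,
) -> ProfileMatrix:
    """Average read-density profile over regions scaled to a common body.

    Each region body is linearly rescaled to ``body_len`` and split into
    ``body_len // bin_size`` bins; flanks of ``flank`` bp either side are
    binned at native scale.  Reads contribute by fractional overlap with
    each (genomic) bin; densities are reads per bp, per million reads in
    the library (``library_size`` defaults to the read count).  With the
    defaults the matrix has 2*2000/50 + 1300/50 = 106 columns.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    if flank % bin_size or body_len % bin_size:
        raise ValueError("flank and body_len must be multiples of bin_size")
    readset = _as_interval_set(reads)
    if library_size is None:
        library_size = len(readset)
    per_million = max(library_size, 1) / 1e6

    flank_bins = flank // bin_size
    body_bins = body_len // bin_size
    ncols = 2 * flank_bins + body_bins

    trees = _read_tree(readset)
    matrix = np.zeros((len(regions), ncols), dtype=float)
    for ri, region in enumerate(regions):
        L = region.length
        left = region.start - flank + bin_size * np.arange(flank_bins + 1)
        body = region.start + L * np.arange(1, body_bins + 1) / body_bins
        right = region.end + bin_size * np.arange(1, flank_bins + 1)
        edges = np.concatenate([left.astype(float), body, right.astype(float)])
        widths = np.diff(edges)

        tree = trees.get(region.chrom)
        if tree is None:
            continue
        coverage = np.zeros(ncols, dtype=float)
        for hit in tree.overlap(edges[0], edges[-1]):
            ov = np.minimum(hit.end, edges[1:]) - np.maximum(hit.begin, edges[:-1])
            coverage += np.clip(ov, 0.0, None)
        matrix[ri] = coverage / widths / per_million
    return ProfileMatrix(matrix, matrix.mean(axis=0), flank_bins, body_bins, bin_size)


def boxplot_summary(values, whisker_mode: str = "iqr1.5") -> dict[str, float]:
    """Five-number box-plot summary.

    Quartiles use linear interpolation.  ``iqr1.5`` whiskers clamp to the
    most extreme datum within 1.5x IQR of the box (the convention used for
    sequencing read-count boxes); ``minmax`` whiskers span the data.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    q25, median, q75 = np.percentile(v, [25, 50, 75])
    if whisker_mode == "minmax":
        lo, hi = float(v.min()), float(v.max())
    elif whisker_mode == "iqr1.5":
        iqr = q75 - q25
        lo = float(v[v >= q25 - 1.5 * iqr].min())
        hi = float(v[v <= q75 + 1.5 * iqr].max())
    else:
        raise ValueError("whisker_mode must be 'iqr1.5' or 'minmax'")
    return {
        "q25": float(q25),
        "median": float(median),
        "q75": float(q75),
        "whisker_lo": lo,
        "whisker_hi": hi,
    }
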