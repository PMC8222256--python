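"""Genome and interval data model plus the interval algebra used by every stage.

Coordinates are 0-based half-open everywhere (the BED convention).  Readers
for 1-based sources (e.g. ICGC simple-somatic-mutation tables, see
:mod:`g4stress.burden`) convert at the boundary, so no off-by-one arithmetic
leaks into analysis code.

Overlap is ``>= 1 bp`` throughout, matching the default semantics of
``bedtools intersect -u``: abutting half-open intervals do *not* overlap.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO


class ParseError(ValueError):
    """A file could not be parsed (malformed line, bad coordinates...)."""


class ValidationError(ValueError):
    """Data violate an invariant (out-of-bounds interval, unknown chromosome...)."""


_STRANDS = {None, "+", "-", "."}


@dataclass(frozen=True)
class Interval:
    """A genomic interval ``[start, end)`` on ``chrom``.

    ``name``, ``score`` and ``strand`` mirror BED columns 4-6 and are kept
    verbatim so that BED round-trips are loss-free.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self!r:.80}")
        if self.start >= self.end:
            raise ValidationError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeAssembly:
    """Named chromosome sequences and/or lengths.

    The assembly is always a parameter of an analysis, never hard-coded:
    the same code runs against mm10, hg19 or a synthetic toy genome.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None or length <= 0:
                raise ValidationError(f"chromosome {name!r} has no positive length")
            if self.sequences is not None:
                seq = self.sequences.get(name)
                if seq is None or len(seq) != length:
                    raise ValidationError(
                        f"sequence length mismatch for {name!r}: "
                        f"declared {length}, got {None if seq is None else len(seq)}"
                    )

    @classmethod
    def from_fasta(cls, path) -> "GenomeAssembly":
        names: list[str] = []
        lengths: dict[str, int] = {}
        sequences: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in sequences:
                raise ParseError(f"duplicate FASTA header: {record.id!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(f"empty FASTA record: {record.id!r}")
            names.append(record.id)
            lengths[record.id] = len(seq)
            sequences[record.id] = seq
        if not names:
            raise ParseError(f"no FASTA records found in {path}")
        return cls(names, lengths, sequences)

    def to_fasta(self, path, width: int = 80) -> None:
        if self.sequences is None:
            raise ValidationError("assembly carries no sequences")
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Extract ``[start, end)`` of ``chrom``; raises if out of bounds."""
        if self.sequences is None:
            raise ValidationError("assembly carries no sequences")
        if chrom not in self.chrom_lengths:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_lengths[chrom] or start >= end:
            raise ValidationError(
                f"region {chrom}:{start}-{end} out of bounds "
                f"(length {self.chrom_lengths[chrom]})"
            )
        return self.sequences[chrom][start:end]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)


def read_fasta(path) -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly` (uppercased)."""
    return GenomeAssembly.from_fasta(path)


class IntervalSet:
    """Ordered collection of :class:`Interval`, optionally bound to a genome.

    Binding a genome validates every interval against chromosome names and
    lengths at construction time.
    """

    def __init__(
        self,
        intervals: Iterable[Interval] = (),
        genome: GenomeAssembly | None = None,
    ) -> None:
        self.intervals: list[Interval] = list(intervals)
        self.genome = genome
        if genome is not None:
            for iv in self.intervals:
                _validate_against(iv, genome)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, idx):
        return self.intervals[idx]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @classmethod
    def from_bed(cls, path, genome: GenomeAssembly | None = None) -> "IntervalSet":
        return read_bed(path, genome)

    def to_bed(self, path) -> None:
        write_bed(self, path)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            self.genome,
        )

    def merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged, disjoint, sorted (starts, ends) arrays."""
        return _merge(self.intervals)

    def coverage_bp(self) -> int:
        """Total merged footprint in bp."""
        return sum(
            int((ends - starts).sum()) for starts, ends in self.merged_arrays().values()
        )


def _validate_against(iv: Interval, genome: GenomeAssembly) -> None:
    if iv.chrom not in genome.chrom_lengths:
        raise ValidationError(f"chromosome {iv.chrom!r} absent from assembly")
    if iv.end > genome.chrom_lengths[iv.chrom]:
        raise ValidationError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {genome.chrom_lengths[iv.chrom]}"
        )


def read_bed(path, genome: GenomeAssembly | None = None) -> IntervalSet:
    """Read BED3/BED4/BED6 into an :class:`IntervalSet`.

    Coordinates are taken verbatim as 0-based half-open.  Malformed lines
    raise :class:`ParseError` naming the line number; intervals violating a
    bound genome raise :class:`ValidationError`.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score = fields[4] if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 else None
            try:
                iv = Interval(chrom, start, end, name, score, strand)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                try:
                    _validate_against(iv, genome)
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return IntervalSet(intervals, genome)


def write_bed(intervals: Iterable[Interval], path) -> None:
    """Write tab-separated, newline-terminated BED with no header.

    Emits exactly the columns present (through the last non-None of
    name/score/strand, padding interior gaps with '.') so that valid BED
    input round-trips byte-for-byte.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            optional = [iv.name, iv.score, iv.strand]
            while optional and optional[-1] is None:
                optional.pop()
            fields.extend("." if f is None else f for f in optional)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# interval algebra


def _merge(intervals: Iterable[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda i: (i.start, i.end))
        starts: list[int] = []
        ends: list[int] = []
        for iv in ivs:
            if starts and iv.start <= ends[-1]:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return out


def _overlaps_merged(
    iv: Interval, merged: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    arrs = merged.get(iv.chrom)
    if arrs is None:
        return False
    starts, ends = arrs
    # rightmost merged interval whose start < iv.end
    idx = int(np.searchsorted(starts, iv.end, side="left"))
    return idx > 0 and int(ends[idx - 1]) > iv.start


def _check_namespace(a: IntervalSet, b: IntervalSet) -> None:
    if len(a) == 0 or len(b) == 0:
        return
    chroms_a = {iv.chrom for iv in a}
    chroms_b = {iv.chrom for iv in b}
    if not (chroms_a & chroms_b):
        raise ValidationError(
            "interval sets share no chromosome names "
            f"({sorted(chroms_a)[:3]}... vs {sorted(chroms_b)[:3]}...); "
            "likely a genome-namespace mismatch"
        )


def intersect_any(query: IntervalSet, regions: IntervalSet) -> IntervalSet:
    """``bedtools intersect -u``: each query interval reported at most once
    iff it overlaps >= 1 bp with any region.  Original order preserved."""
    merged = regions.merged_arrays()
    hits = [iv for iv in query if _overlaps_merged(iv, merged)]
    return IntervalSet(hits, query.genome)


def overlap_partition(
    a: IntervalSet, b: IntervalSet
) -> tuple[IntervalSet, IntervalSet, IntervalSet, IntervalSet]:
    """Venn partition of two peak sets by >= 1 bp overlap.

    Returns ``(a_only, a_shared, b_shared, b_only)`` with
    ``|a_only| + |a_shared| == |a|`` (and likewise for ``b``).
    """
    merged_b = b.merged_arrays()
    merged_a = a.merged_arrays()
    a_shared, a_only, b_shared, b_only = [], [], [], []
    for iv in a:
        (a_shared if _overlaps_merged(iv, merged_b) else a_only).append(iv)
    for iv in b:
        (b_shared if _overlaps_merged(iv, merged_a) else b_only).append(iv)
    return (
        IntervalSet(a_only, a.genome),
        IntervalSet(a_shared, a.genome),
        IntervalSet(b_shared, b.genome),
        IntervalSet(b_only, b.genome),
    )


def points_in_regions(
    chroms: Sequence[str], positions: Sequence[int], regions: IntervalSet
) -> np.ndarray:
    """Vectorized membership test: is point ``(chrom, pos)`` inside any region?"""
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    result = np.zeros(len(positions), dtype=bool)
    merged = regions.merged_arrays()
    for chrom, (starts, ends) in merged.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right")
        inside = (idx > 0) & (pos < ends[np.maximum(idx - 1, 0)])
        result[mask] = inside
    return result


DEFAULT_ANNOTATION_PRIORITY = (
    "promoter",
    "exon",
    "intron",
    "LINE",
    "LTR",
    "other-repeat",
)


def annotate_regions(
    query: IntervalSet,
    features: IntervalSet,
    priority: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Assign each query interval the highest-priority overlapping feature
    category (feature ``name`` is the category), else ``"intergenic"``.

    Returns per-query labels plus the fraction of queries per category.
    """
    if priority is None:
        priority = DEFAULT_ANNOTATION_PRIORITY
    seen: list[str] = []
    for iv in features:
        label = iv.name or "feature"
        if label not in seen:
            seen.append(label)
    ordered = [p for p in priority if p in seen] + [l for l in seen if l not in priority]
    merged_by_label = {
        label: _merge([iv for iv in features if (iv.name or "feature") == label])
        for label in ordered
    }
    labels: list[str] = []
    for iv in query:
        assigned = "intergenic"
        for label in ordered:
            if _overlaps_merged(iv, merged_by_label[label]):
                assigned = label
                break
        labels.append(assigned)
    fractions: dict[str, float] = {}
    if labels:
        for label in itertools.chain(ordered, ["intergenic"]):
            n = labels.count(label)
            if n:
                fractions[label] = n / len(labels)
    return labels, fractions
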