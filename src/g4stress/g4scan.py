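"""Potential-quadruplex-sequence (PQS) scanner.

The motif grammar is the quadparser-style regular expression
``([gG]{3,}\\w{1,12}){3,}[gG]{3,}``: three or more runs of >= 3 guanines,
each followed by a 1-12 nt loop, ending in a final G-run — i.e. at least
four G-tracts overall (G3 N1-12 G3 N1-12 G3 N1-12 G3).  Matching is
leftmost, greedy and non-overlapping, exactly the behaviour of the standard
regex engine the grammar is written for, so motif counts reproduce the
cited tool's counting.

Loops use ``\\w`` (any word character), so N — and even short G runs — may
appear inside loops; only the tracts require literal G/g.  The minus strand
is scanned as the same grammar on the reverse complement, with coordinates
mirrored back onto the forward strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .intervals import GenomeAssembly, IntervalSet, ValidationError

#: The canonical default grammar (four or more G3+ tracts, 1-12 nt loops).
DEFAULT_G4_REGEX = r"([gG]{3,}\w{1,12}){3,}[gG]{3,}"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_INVALID = re.compile(r"[^ACGTNacgtn]")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the PQS grammar.

    Defaults encode the canonical consensus: tracts of >= 3 G, loops of
    1-12 nt, >= 4 tracts, both strands scanned.
    """

    min_tract_len: int = 3
    loop_min: int = 1
    loop_max: int = 12
    min_tracts: int = 4
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        if self.min_tract_len < 2:
            raise ValueError("min_tract_len must be >= 2")
        if not (0 < self.loop_min <= self.loop_max):
            raise ValueError("need 0 < loop_min <= loop_max")
        if self.min_tracts < 2:
            raise ValueError("min_tracts must be >= 2")
        if self.strand_mode not in ("forward", "both"):
            raise ValueError("strand_mode must be 'forward' or 'both'")

    def pattern(self) -> str:
        """The grammar as a regex string (defaults give the canonical form)."""
        return (
            f"(?:[gG]{{{self.min_tract_len},}}"
            f"\\w{{{self.loop_min},{self.loop_max}}})"
            f"{{{self.min_tracts - 1},}}"
            f"[gG]{{{self.min_tract_len},}}"
        )


@dataclass(frozen=True)
class G4Motif:
    """One PQS match.  Coordinates are 0-based half-open on the forward
    strand of the source; ``sequence`` is the forward-strand substring."""

    chrom: str
    start: int
    end: int
    strand: str
    n_tracts: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_interval(self):
        from .intervals import Interval

        return Interval(
            self.chrom, self.start, self.end,
            name=str(self.n_tracts), score=str(self.length), strand=self.strand,
        )


def _count_tracts(matched: str, min_tract_len: int) -> int:
    """Number of maximal G-runs of >= min_tract_len inside a match span."""
    return len(re.findall(f"[gG]{{{min_tract_len},}}", matched))


def scan_g4(
    sequence: str, params: ScanParams | None = None, chrom: str = "seq"
) -> list[G4Motif]:
    """Scan a nucleotide string for PQS motifs.

    Matches are non-overlapping and leftmost-greedy per strand; with
    ``strand_mode='both'`` the reverse complement is scanned with the same
    grammar and reported with strand '-'.  Motifs are sorted by start.

    Raises ``ValueError`` listing offending positions on non-nucleotide
    characters (alphabet is A/C/G/T/N, either case).
    """
    if params is None:
        params = ScanParams()
    bad = [m.start() for m in _INVALID.finditer(sequence)]
    if bad:
        shown = ", ".join(str(p) for p in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"non-nucleotide characters at positions {shown}{more}")

    pat = re.compile(params.pattern())
    motifs: list[G4Motif] = []
    for m in pat.finditer(sequence):
        motifs.append(
            G4Motif(
                chrom, m.start(), m.end(), "+",
                _count_tracts(m.group(), params.min_tract_len), m.group(),
            )
        )
    if params.strand_mode == "both":
        rc = reverse_complement(sequence)
        L = len(sequence)
        for m in pat.finditer(rc):
            start, end = L - m.end(), L - m.start()
            motifs.append(
                G4Motif(
                    chrom, start, end, "-",
                    _count_tracts(m.group(), params.min_tract_len),
                    sequence[start:end],
                )
            )
    motifs.sort(key=lambda g: (g.start, g.end, g.strand))
    return motifs


def count_g4_in_intervals(
    genome: GenomeAssembly,
    regions: IntervalSet,
    params: ScanParams | None = None,
) -> pd.DataFrame:
    """Scan each region's sequence independently and count motifs per region.

    A motif must lie fully within a region to count (each region's sequence
    is extracted and scanned on its own, so matches cannot extend past the
    region boundary).  The returned table preserves region order; the total
    is the column sum.
    """
    if genome.sequences is None:
        raise ValidationError("genome carries no sequences")
    rows = []
    for iv in regions:
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        n = len(scan_g4(seq, params, chrom=iv.chrom))
        rows.append((iv.chrom, iv.start, iv.end, iv.name, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "n_g4"])


def scan_intervals(
    genome: GenomeAssembly,
    regions: IntervalSet,
    params: ScanParams | None = None,
) -> list[G4Motif]:
    """Like :func:`count_g4_in_intervals` but returning the motifs
    themselves, with coordinates lifted to the genome."""
    if genome.sequences is None:
        raise ValidationError("genome carries no sequences")
    out: list[G4Motif] = []
    for iv in regions:
        seq = genome.fetch(iv.chrom, iv.start, iv.end)
        for g in scan_g4(seq, params, chrom=iv.chrom):
            out.append(
                G4Motif(iv.chrom, iv.start + g.start, iv.start + g.end,
                        g.strand, g.n_tracts, g.sequence)
            )
    return out


def classify_regions(counts) -> pd.Series:
    """Label regions 'G4' (>= 1 motif) or 'non-G4' (0 motifs).

    Accepts the table from :func:`count_g4_in_intervals` or any array of
    per-region counts.
    """
    if isinstance(counts, pd.DataFrame):
        values = counts["n_g4"]
    else:
        values = pd.Series(counts)
    if (values < 0).any():
        raise ValueError("negative motif count")
    return values.map(lambda n: "G4" if n >= 1 else "non-G4").rename("g4_class")
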