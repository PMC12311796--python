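"""Genome coordinate system and standard-format I/O.

All coordinates are 0-based, half-open (BED convention). A
:class:`GenomeLayout` declares the reference space (chromosome names and
lengths) that every :class:`IntervalSet` is validated against; the layout is
the single source of truth for chromosome bounds when intervals are extended
or random controls are placed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeLayout",
    "Interval",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

_IUPAC = set("ACGTUNRYSWKMBDHV")


class BedParseError(ValueError):
    """A BED line could not be parsed; carries the offending line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(length < 1 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 1")
        object.__setattr__(
            self, "_length_of", dict(zip(self.chrom_names, self.chrom_lengths))
        )

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple(lengths.keys()), tuple(int(v) for v in lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._length_of  # type: ignore[attr-defined]

    def length(self, chrom: str) -> int:
        return self._length_of[chrom]  # type: ignore[attr-defined]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths)

    def offsets(self) -> dict[str, int]:
        """Cumulative start offset of each chromosome in a concatenated
        (global) coordinate space; used to vectorize overlap queries."""
        out: dict[str, int] = {}
        pos = 0
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            out[name] = pos
            pos += length
        return out


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A sorted collection of intervals on a shared :class:`GenomeLayout`.

    Intervals are normalized (sorted by chrom order in the layout, then
    start, then end) on construction; overlapping intervals are permitted
    unless explicitly merged.
    """

    def __init__(self, intervals: Iterable[Interval], layout: GenomeLayout):
        items = list(intervals)
        for iv in items:
            if iv.chrom not in layout:
                raise ValueError(f"chromosome {iv.chrom!r} not in layout")
            if iv.end > layout.length(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {layout.length(iv.chrom)}"
                )
        order = {name: i for i, name in enumerate(layout.chrom_names)}
        items.sort(key=lambda iv: (order[iv.chrom], iv.start, iv.end))
        self.intervals: tuple[Interval, ...] = tuple(items)
        self.layout = layout

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.layout == other.layout and all(
            a == b
            and a.name == b.name
            and a.score == b.score
            and a.strand == b.strand
            for a, b in zip(self.intervals, other.intervals)
        ) and len(self) == len(other)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self.intervals)} intervals)"

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def replace_intervals(self, intervals: Iterable[Interval]) -> "IntervalSet":
        return IntervalSet(intervals, self.layout)

    def global_coords(self):
        """(starts, ends) in concatenated genome coordinates, cached.

        Intervals never cross chromosome boundaries, so half-open interval
        arithmetic in global coordinates is exact. Starts are non-decreasing
        because normalization sorts by (chrom order, start).
        """
        import numpy as np

        cached = getattr(self, "_gcoords", None)
        if cached is None:
            offs = self.layout.offsets()
            starts = np.array(
                [offs[iv.chrom] + iv.start for iv in self.intervals], dtype=np.int64
            )
            ends = np.array(
                [offs[iv.chrom] + iv.end for iv in self.intervals], dtype=np.int64
            )
            cached = (starts, ends)
            self._gcoords = cached
        return cached


def read_bed(
    path: str | Path,
    layout: GenomeLayout,
    *,
    on_unknown_chrom: str = "skip",
) -> IntervalSet:
    """Read a BED3/BED6 file into an IntervalSet.

    Parameters
    ----------
    on_unknown_chrom : {"skip", "error"}
        Chromosomes absent from the layout are dropped with a logged count
        (tolerates scaffold contamination) or raise.
    """
    if on_unknown_chrom not in ("skip", "error"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'error'")
    intervals: list[Interval] = []
    n_skipped = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if chrom not in layout:
                if on_unknown_chrom == "error":
                    raise BedParseError(
                        f"{path}:{lineno}: chromosome {chrom!r} not in layout"
                    )
                n_skipped += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    Interval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    if n_skipped:
        logger.warning(
            "read_bed(%s): dropped %d intervals on chromosomes absent from layout",
            path,
            n_skipped,
        )
    return IntervalSet(intervals, layout)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED6; round-trips bit-identically through :func:`read_bed`."""
    with open(path, "w") as handle:
        for iv in iset:
            score = "." if iv.score is None else format(iv.score, "g")
            name = iv.name if iv.name is not None else "."
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered name->sequence map (uppercased).

    Names are truncated at the first whitespace. Characters outside the
    IUPAC nucleotide alphabet trigger a warning but are retained.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            logger.warning(
                "read_fasta(%s): record %s contains non-IUPAC characters %s",
                path,
                rec.id,
                "".join(sorted(bad)),
            )
        records[rec.id] = seq
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a two-column (name, length) TSV in chrom.sizes convention."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            names.append(fields[0])
            lengths.append(int(fields[1]))
    return GenomeLayout(tuple(names), tuple(lengths))


def write_chrom_sizes(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in zip(layout.chrom_names, layout.chrom_lengths):
            handle.write(f"{name}\t{length}\n")
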