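"""Genomic intervals, BED/narrowPeak I/O, and exact interval arithmetic.

All coordinates are 0-based, half-open (BED convention).  Strand is parsed
where present but ignored by every operation.  "Overlap" always means at
least 1 bp of shared sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "read_genome",
    "read_bed",
    "write_bed",
    "overlap_bp",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally carrying peak metadata.

    ``summit`` is an absolute coordinate (not an offset from ``start``);
    ``pvalue``/``qvalue`` follow the narrowPeak convention of -log10 values,
    so larger means more significant.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    summit: int | None = None
    pvalue: float | None = None
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def middle(self) -> int:
        return (self.start + self.end) // 2


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalSet:
    """An ordered collection of intervals with fast overlap queries.

    Backed by one interval tree per chromosome; query results are always
    identical to a brute-force scan of ``self.intervals``.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        genome: Mapping[str, int],
    ) -> None:
        self.genome = dict(genome)
        self.intervals: list[GenomicInterval] = list(intervals)
        for iv in self.intervals:
            length = self.genome.get(iv.chrom)
            if length is None:
                raise ValueError(f"chromosome {iv.chrom!r} not in genome")
            if iv.end > length:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {length}"
                )
        self._trees: dict[str, IntervalTree] = {}
        for idx, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, idx
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """All stored intervals overlapping [start, end) by >= 1 bp, in input order."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(hit.data for hit in tree.overlap(start, end))
        return [self.intervals[i] for i in hits]

    def count_overlapping(self, query: GenomicInterval) -> int:
        """Number of stored intervals overlapping the query by >= 1 bp.

        Subjects are counted as-is: duplicates and mutually overlapping
        subjects each contribute one count.
        """
        tree = self._trees.get(query.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(query.start, query.end))

    def contains_point(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.at(pos))

    def distance_to_nearest(
        self, chrom: str, pos: int, anchor_mode: str = "interval"
    ) -> float:
        """Minimal |distance| from a point to the nearest same-chromosome anchor.

        ``anchor_mode`` selects the anchor representation: ``summit`` and
        ``start`` measure to that single coordinate; ``interval`` measures to
        the nearest covered base (0 when the point lies inside an anchor).
        Returns ``math.inf`` when the chromosome holds no anchors.
        """
        if anchor_mode not in ("summit", "start", "interval"):
            raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
        ivs = [iv for iv in self.intervals if iv.chrom == chrom]
        if not ivs:
            return math.inf
        if anchor_mode == "summit":
            pts = np.array(
                [iv.summit if iv.summit is not None else iv.middle for iv in ivs]
            )
            return float(np.min(np.abs(pts - pos)))
        if anchor_mode == "start":
            pts = np.array([iv.start for iv in ivs])
            return float(np.min(np.abs(pts - pos)))
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        # distance to a half-open interval: 0 inside, else gap to nearest edge
        dist = np.maximum(starts - pos, 0) + np.maximum(pos - (ends - 1), 0)
        return float(dist.min())

    def subtract_blacklisted(self, blacklist: "IntervalSet") -> "IntervalSet":
        """Drop every interval overlapping the blacklist by >= 1 bp."""
        kept = [
            iv
            for iv in self.intervals
            if blacklist.count_overlapping(iv) == 0
        ]
        return IntervalSet(kept, self.genome)


def read_genome(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` genome file."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected chrom<TAB>length")
            genome[parts[0]] = int(parts[1])
    return genome


def _parse_float(tok: str) -> float | None:
    if tok in (".", ""):
        return None
    return float(tok)


def read_bed(
    path: str | Path,
    genome: Mapping[str, int],
    *,
    narrowpeak: bool | None = None,
) -> IntervalSet:
    """Parse BED3/BED6/narrowPeak into an :class:`IntervalSet`.

    Column 10, when present (narrowPeak dialect), is interpreted as the peak
    summit offset from ``start``; columns 7-9 as signalValue / -log10 p /
    -log10 q.  Set ``narrowpeak=False`` to ignore columns beyond 6.  Records
    on chromosomes absent from ``genome`` raise an error naming the
    chromosome; input order is preserved.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if chrom not in genome:
                raise ValueError(
                    f"{path}:{lineno}: chromosome {chrom!r} absent from genome"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = _parse_float(parts[4]) if len(parts) > 4 else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            summit = pvalue = qvalue = None
            use_np = narrowpeak if narrowpeak is not None else len(parts) >= 10
            if use_np and len(parts) >= 10:
                signal = _parse_float(parts[6])
                pvalue = _parse_float(parts[7])
                qvalue = _parse_float(parts[8])
                offset = int(float(parts[9]))
                if offset >= 0:
                    summit = start + offset
                if score is None:
                    score = signal
            try:
                intervals.append(
                    GenomicInterval(
                        chrom, start, end, name=name, score=score,
                        strand=strand, summit=summit, pvalue=pvalue,
                        qvalue=qvalue,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, genome)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED6 (name/score/strand default to '.'/0/'.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score:g}\t{iv.strand or '.'}\n"
            )
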