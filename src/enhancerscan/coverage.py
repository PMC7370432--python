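"""Read-record preprocessing and binned coverage tracks.

The model consumes per-chromosome coverage in fixed-width bins (100 bp by
default): reads are deduplicated, shifted toward their 3' end by half the
fragment length (ChIP) or half a nucleosome (MNase), counted into bins at
their shifted 5' position, control-corrected, and integerized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ReadRecord",
    "BinnedTrack",
    "FeatureSpec",
    "FeatureManifest",
    "NUCLEOSOME_BP",
    "deduplicate_reads",
    "shift_reads",
    "bin_coverage",
    "normalize_subtract_control",
    "integerize",
    "extract_window_matrix",
]

#: length of DNA wrapped around one nucleosome; MNase reads are shifted by half of it
NUCLEOSOME_BP = 149


@dataclass(frozen=True)
class ReadRecord:
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class FeatureSpec:
    """One chromatin feature: assay kind, fragment shift, control pairing."""

    name: str
    assay: str  # chip | dnase | mnase
    fragment_length: int | None = None
    control_id: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "dnase", "mnase", "control"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.assay == "chip" and self.fragment_length is None:
            raise ValueError(f"chip feature {self.name!r} needs fragment_length")


@dataclass
class FeatureManifest:
    features: list[FeatureSpec]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    @classmethod
    def from_mapping(cls, entries: Iterable[Mapping]) -> "FeatureManifest":
        return cls([FeatureSpec(**dict(e)) for e in entries])


class BinnedTrack:
    """Per-chromosome vectors of coverage in fixed-width bins."""

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        genome: Mapping[str, int],
        bin_size: int = 100,
    ) -> None:
        self.bin_size = int(bin_size)
        self.genome = dict(genome)
        self.values: dict[str, np.ndarray] = {}
        for chrom, vec in values.items():
            expected = self.n_bins(chrom)
            vec = np.asarray(vec)
            if vec.shape != (expected,):
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {vec.shape}"
                )
            self.values[chrom] = vec

    def n_bins(self, chrom: str) -> int:
        return -(-self.genome[chrom] // self.bin_size)  # ceil division

    @classmethod
    def zeros(cls, genome: Mapping[str, int], bin_size: int = 100, dtype=np.int64):
        vals = {
            c: np.zeros(-(-length // bin_size), dtype=dtype)
            for c, length in genome.items()
        }
        return cls(vals, genome, bin_size)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def same_shape_as(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome == other.genome
        )

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                vec = self.values[chrom]
                for b, v in enumerate(vec):
                    if v != 0:
                        start = b * self.bin_size
                        end = min(start + self.bin_size, self.genome[chrom])
                        fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, genome: Mapping[str, int], bin_size: int = 100,
        dtype=np.float64,
    ) -> "BinnedTrack":
        track = cls.zeros(genome, bin_size, dtype=dtype)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                start, end = int(start), int(end)
                if chrom not in genome:
                    raise ValueError(
                        f"{path}:{lineno}: chromosome {chrom!r} absent from genome"
                    )
                b0, b1 = start // bin_size, -(-end // bin_size)
                track.values[chrom][b0:b1] = float(value)
        return track


def deduplicate_reads(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """Keep one read per exact (chrom, start, end, strand) tuple.

    Reads mapping to the exact same location are treated as PCR duplicates;
    opposite-strand reads at the same coordinates are distinct.  Relative
    order of the survivors is preserved.
    """
    seen: set[tuple] = set()
    out: list[ReadRecord] = []
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def shift_reads(
    reads: Sequence[ReadRecord],
    assay: str,
    fragment_length: int | None = None,
    genome: Mapping[str, int] | None = None,
) -> list[ReadRecord]:
    """Shift reads toward their 3' direction by half the fragment length.

    ChIP reads move by ``fragment_length // 2``; MNase reads by
    ``149 // 2 = 74`` (half the nucleosomal DNA length); DNase and control
    reads are returned unshifted.  Shifted coordinates are clipped to
    ``[0, chrom_length)`` when a genome is given.
    """
    if assay in ("dnase", "control"):
        return list(reads)
    if assay == "chip":
        if fragment_length is None:
            raise ValueError("chip reads require a fragment_length")
        shift = fragment_length // 2
    elif assay == "mnase":
        shift = NUCLEOSOME_BP // 2
    else:
        raise ValueError(f"unknown assay {assay!r}")
    out = []
    for r in reads:
        delta = shift if r.strand == "+" else -shift
        start, end = r.start + delta, r.end + delta
        if genome is not None:
            length = genome[r.chrom]
            start = min(max(start, 0), length - 1)
            end = min(max(end, 1), length)
            if start >= end:
                start, end = end - 1, end
        out.append(ReadRecord(r.chrom, start, end, r.strand))
    return out


def read_position(r: ReadRecord) -> int:
    """The 5' coordinate of a read (start on +, last base on -)."""
    return r.start if r.strand == "+" else r.end - 1


def bin_coverage(
    reads: Sequence[ReadRecord],
    genome: Mapping[str, int],
    bin_size: int = 100,
) -> BinnedTrack:
    """Count reads into bins at their (shifted) 5' position.

    Point assignment makes binning conserve reads exactly: the sum over all
    bins equals the number of in-genome reads.
    """
    track = BinnedTrack.zeros(genome, bin_size, dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        if r.chrom not in genome:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        pos = min(max(read_position(r), 0), genome[r.chrom] - 1)
        by_chrom.setdefault(r.chrom, []).append(pos // bin_size)
    for chrom, bins in by_chrom.items():
        counts = np.bincount(bins, minlength=track.n_bins(chrom))
        track.values[chrom] += counts
    return track


def normalize_subtract_control(
    chip: BinnedTrack,
    control: BinnedTrack,
    chip_total: float | None = None,
    control_total: float | None = None,
    reference_total: float | None = None,
) -> BinnedTrack:
    """Library-size-normalize the control to the ChIP track and subtract it.

    Output bin = chip - (chip_total / control_total) * control; values may be
    negative (clamped later by :func:`integerize`).  ``reference_total``
    overrides ``chip_total`` for cross-sample normalization against a fixed
    reference library size.
    """
    if not chip.same_shape_as(control):
        raise ValueError("chip and control tracks have mismatched binning")
    if chip_total is None:
        chip_total = chip.total()
    if control_total is None:
        control_total = control.total()
    if control_total <= 0:
        raise ValueError("control_total must be positive")
    numer = reference_total if reference_total is not None else chip_total
    scale = numer / control_total
    vals = {
        c: chip.values[c].astype(np.float64) - scale * control.values[c]
        for c in chip.values
    }
    return BinnedTrack(vals, chip.genome, chip.bin_size)


def integerize(track: BinnedTrack) -> BinnedTrack:
    """Round half away from zero, then clamp negatives to zero. Idempotent."""
    vals = {}
    for c, v in track.values.items():
        rounded = np.sign(v) * np.floor(np.abs(v) + 0.5)
        vals[c] = np.maximum(rounded, 0).astype(np.int64)
    return BinnedTrack(vals, track.genome, track.bin_size)


def extract_window_matrix(
    track: BinnedTrack,
    anchors: Sequence[tuple[str, int]],
    window: int = 2000,
) -> tuple[np.ndarray, list[int]]:
    """Extract the d-bin window centred on each anchor point.

    Returns ``(matrix, kept)`` where ``matrix`` has one row per retained
    anchor and ``kept`` lists the indices of anchors whose window lies fully
    inside their chromosome; out-of-bounds anchors are dropped.
    """
    if window % track.bin_size:
        raise ValueError("window must be divisible by bin_size")
    d = window // track.bin_size
    half = d // 2
    rows, kept = [], []
    for i, (chrom, pos) in enumerate(anchors):
        if chrom not in track.values:
            continue
        centre_bin = pos // track.bin_size
        lo, hi = centre_bin - half, centre_bin + (d - half)
        if lo < 0 or hi > track.n_bins(chrom):
            continue
        rows.append(track.values[chrom][lo:hi])
        kept.append(i)
    if rows:
        return np.array(rows), kept
    return np.empty((0, d), dtype=np.int64), kept
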