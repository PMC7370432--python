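"""Construction of the labelled training anchors and coverage matrices.

Training positives are the summits of the n most significant co-activator
(p300-type) peaks that sit in open chromatin, at least 2 kb from any TSS
and clear of the blacklist.  Non-enhancers are n isolated promoters (TSSs
in the most significant open-chromatin peaks) plus 2n random locations:
half sampled uniformly far from any positive peak and TSS ("pure random"),
half sampled where the summed feature coverage reaches a minimum level
("random with signal"), so the classifier cannot separate classes on the
mere presence of signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coverage import BinnedTrack, extract_window_matrix
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "Anchor",
    "AnchorSet",
    "define_enhancer_anchors",
    "define_promoter_anchors",
    "sample_pure_random",
    "sample_signal_random",
    "assemble_training_matrices",
]

LABELS = ("enhancer", "promoter", "pure_random", "signal_random")
#: label -> class id used by the probabilistic model
LABEL_TO_CLASS = {
    "enhancer": "enh",
    "promoter": "prom",
    "pure_random": "rand",
    "signal_random": "rand",
}


@dataclass(frozen=True)
class Anchor:
    chrom: str
    pos: int
    label: str
    source: str = ""


@dataclass
class AnchorSet:
    anchors: list[Anchor]

    def __len__(self) -> int:
        return len(self.anchors)

    def __add__(self, other: "AnchorSet") -> "AnchorSet":
        return AnchorSet(self.anchors + other.anchors)

    def points(self) -> list[tuple[str, int]]:
        return [(a.chrom, a.pos) for a in self.anchors]

    def labels(self) -> np.ndarray:
        return np.array([a.label for a in self.anchors])


def _blacklist_window_clear(
    blacklist: IntervalSet, chrom: str, pos: int, window: int
) -> bool:
    half = window // 2
    start = max(0, pos - half)
    end = min(blacklist.genome.get(chrom, pos + half), pos + half)
    if end <= start:
        return True
    return blacklist.count_overlapping(GenomicInterval(chrom, start, end)) == 0


def _peak_sort_key(iv: GenomicInterval):
    # most significant first: ascending q (narrowPeak stores -log10 q, so
    # descending), ties by descending score then coordinate
    q = iv.qvalue if iv.qvalue is not None else -math.inf
    s = iv.score if iv.score is not None else -math.inf
    return (-q, -s, iv.chrom, iv.start)


def define_enhancer_anchors(
    p300: IntervalSet,
    dnase: IntervalSet,
    tss: IntervalSet,
    blacklist: IntervalSet,
    n: int,
    min_tss_dist: int = 2000,
    blacklist_window: int = 5000,
) -> AnchorSet:
    """Top-n co-activator peak summits as enhancer anchors.

    Peaks are ranked by significance (descending -log10 q-value, ties by
    score then coordinate); a surviving summit must fall inside an
    open-chromatin peak, lie at least ``min_tss_dist`` bp from every TSS,
    and its centred ``blacklist_window`` must avoid the blacklist.
    """
    ranked = sorted(p300.intervals, key=_peak_sort_key)
    out: list[Anchor] = []
    for iv in ranked:
        summit = iv.summit if iv.summit is not None else iv.middle
        if not dnase.contains_point(iv.chrom, summit):
            continue
        if tss.distance_to_nearest(iv.chrom, summit, "start") < min_tss_dist:
            continue
        if not _blacklist_window_clear(blacklist, iv.chrom, summit, blacklist_window):
            continue
        out.append(Anchor(iv.chrom, summit, "enhancer", source=iv.name or ""))
        if len(out) == n:
            return AnchorSet(out)
    raise ValueError(
        f"only {len(out)} enhancer anchors survive the filters, need {n}"
    )


def define_promoter_anchors(
    tss: IntervalSet,
    dnase: IntervalSet,
    blacklist: IntervalSet,
    n: int,
    min_tss_spacing: int = 2000,
    blacklist_window: int = 5000,
) -> AnchorSet:
    """Top-n isolated TSSs in the most significant open-chromatin peaks.

    A TSS qualifies if it lies inside an open-chromatin peak and no other
    TSS sits within ``min_tss_spacing`` bp.  Qualifiers are ranked by the
    significance (-log10 p) of the best peak covering them.
    """
    candidates = []
    for i, iv in enumerate(tss.intervals):
        others = [
            o for j, o in enumerate(tss.intervals)
            if j != i and o.chrom == iv.chrom
        ]
        if others and min(abs(o.start - iv.start) for o in others) <= min_tss_spacing:
            continue
        covering = [
            p for p in dnase.overlapping(iv.chrom, iv.start, iv.start + 1)
        ]
        if not covering:
            continue
        best_p = max(
            (p.pvalue if p.pvalue is not None else -math.inf) for p in covering
        )
        if not _blacklist_window_clear(blacklist, iv.chrom, iv.start, blacklist_window):
            continue
        candidates.append((best_p, iv))
    candidates.sort(key=lambda t: (-t[0], t[1].chrom, t[1].start))
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} promoter anchors survive, need {n}"
        )
    return AnchorSet(
        [
            Anchor(iv.chrom, iv.start, "promoter", source=iv.name or "")
            for _, iv in candidates[:n]
        ]
    )


def sample_pure_random(
    genome: Mapping[str, int],
    p300: IntervalSet,
    tss: IntervalSet,
    blacklist: IntervalSet,
    n: int,
    seed: int = 0,
    min_p300_dist: int = 2500,
    min_tss_dist: int = 2000,
    blacklist_window: int = 5000,
    max_draws_factor: int = 1000,
) -> AnchorSet:
    """Uniformly sampled single-bp anchors far from positives and TSSs.

    Rejection sampling: an accepted coordinate lies more than
    ``min_p300_dist`` bp from any positive peak (distance to the interval,
    0 inside), more than ``min_tss_dist`` bp from any TSS, with a clear
    blacklist window that fits the chromosome.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.float64)
    probs = lengths / lengths.sum()
    half = blacklist_window // 2
    out: list[Anchor] = []
    for _ in range(max_draws_factor * n):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        pos = int(rng.integers(genome[chrom]))
        if pos < half or pos + half > genome[chrom]:
            continue
        if p300.distance_to_nearest(chrom, pos, "interval") <= min_p300_dist:
            continue
        if tss.distance_to_nearest(chrom, pos, "start") <= min_tss_dist:
            continue
        if not _blacklist_window_clear(blacklist, chrom, pos, blacklist_window):
            continue
        out.append(Anchor(chrom, pos, "pure_random"))
        if len(out) == n:
            return AnchorSet(out)
    raise ValueError(
        f"accepted only {len(out)}/{n} pure-random anchors after "
        f"{max_draws_factor * n} draws"
    )


def sample_signal_random(
    tracks: Mapping[str, BinnedTrack],
    genome: Mapping[str, int],
    p300: IntervalSet,
    tss: IntervalSet,
    blacklist: IntervalSet,
    n: int,
    seed: int = 0,
    min_sum: int = 5,
    window: int = 2000,
    exclude_features: Sequence[str] = (),
    min_p300_dist: int = 2500,
    min_tss_dist: int = 2000,
    blacklist_window: int = 5000,
) -> AnchorSet:
    """Random anchors whose whole window carries at least a minimal signal.

    The per-bin sum of all feature tracks (nucleosome-occupancy tracks
    excluded via ``exclude_features``) must reach ``min_sum`` in every bin
    of the centred window; positive-peak, TSS and blacklist exclusions then
    apply as for pure-random anchors.  Anchors are placed at bin centres.
    """
    from scipy.ndimage import minimum_filter1d

    rng = np.random.default_rng(seed)
    feats = [f for f in tracks if f not in set(exclude_features)]
    if not feats:
        raise ValueError("no tracks left after exclusions")
    first = tracks[feats[0]]
    bs = first.bin_size
    d = window // bs
    candidates: list[tuple[str, int]] = []
    for chrom in first.values:
        total = np.zeros_like(first.values[chrom], dtype=np.int64)
        for f in feats:
            total += tracks[f].values[chrom]
        # window centred on bin b covers bins [b - d//2, b + d - d//2)
        ok = minimum_filter1d(total, size=d, mode="constant", cval=-1)
        # minimum_filter1d centres the window on each bin (origin 0)
        for b in np.flatnonzero(ok >= min_sum):
            candidates.append((chrom, int(b)))
    eligible: list[Anchor] = []
    rng.shuffle(candidates)
    for chrom, b in candidates:
        pos = b * bs + bs // 2
        if p300.distance_to_nearest(chrom, pos, "interval") <= min_p300_dist:
            continue
        if tss.distance_to_nearest(chrom, pos, "start") <= min_tss_dist:
            continue
        if not _blacklist_window_clear(blacklist, chrom, pos, blacklist_window):
            continue
        eligible.append(Anchor(chrom, pos, "signal_random"))
        if len(eligible) == n:
            return AnchorSet(eligible)
    raise ValueError(
        f"only {len(eligible)} signal-random anchors available, need {n}"
    )


def assemble_training_matrices(
    anchors: AnchorSet,
    tracks: Mapping[str, BinnedTrack],
    window: int = 2000,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, AnchorSet]:
    """Per-feature coverage matrices with aligned labels.

    Rows follow the anchor order enhancer, promoter, pure-random,
    signal-random.  An anchor whose window crosses a chromosome boundary is
    dropped consistently from every feature matrix and the label vectors.
    Returns (coverage, binary labels, class labels, kept anchors).
    """
    order = {lab: i for i, lab in enumerate(LABELS)}
    sorted_anchors = sorted(
        anchors.anchors, key=lambda a: order.get(a.label, 99)
    )
    points = [(a.chrom, a.pos) for a in sorted_anchors]
    kept_common: list[int] | None = None
    matrices: dict[str, np.ndarray] = {}
    for feat, track in tracks.items():
        mat, kept = extract_window_matrix(track, points, window)
        if kept_common is None:
            kept_common = kept
        elif kept != kept_common:
            # different genomes per feature would be a config error
            raise ValueError(f"feature {feat!r} dropped a different anchor set")
        matrices[feat] = mat
    assert kept_common is not None
    kept_anchors = [sorted_anchors[i] for i in kept_common]
    class_labels = np.array([LABEL_TO_CLASS[a.label] for a in kept_anchors])
    y = (class_labels == "enh").astype(int)
    return matrices, y, class_labels, AnchorSet(kept_anchors)
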