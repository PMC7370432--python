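"""Genome-wide window scoring, enhancer calling, and post-filtering.

Every 2 kb window (100 bp steps, aligned to bin boundaries) is scored
against the stored class models exactly as a training sample would be, and
the enhancer-class probability is thresholded.  Runs of consecutive
above-threshold windows merge into regions; the maximum-score window in a
run is the summit (exact ties broken uniformly at random under the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .classify import TrainedPredictor
from .coverage import BinnedTrack
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "WindowScoreTrack",
    "EnhancerPrediction",
    "scan_genome",
    "call_enhancers",
    "postfilter_predictions",
    "prediction_length_distribution",
]


@dataclass
class WindowScoreTrack:
    """Per-chromosome enhancer probabilities, one per window start."""

    scores: dict[str, np.ndarray]
    window: int = 2000
    step: int = 100

    def n_windows(self, chrom: str) -> int:
        return len(self.scores[chrom])

    def window_interval(self, chrom: str, idx: int) -> tuple[int, int]:
        start = idx * self.step
        return start, start + self.window

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.scores):
                for i, s in enumerate(self.scores[chrom]):
                    start = i * self.step
                    fh.write(f"{chrom}\t{start}\t{start + self.window}\t{s:.6g}\n")


@dataclass
class EnhancerPrediction:
    """One called enhancer: merged region, summit window, and its score."""

    region: GenomicInterval
    summit_window: GenomicInterval
    score: float

    @property
    def middle_bp(self) -> int:
        return (self.summit_window.start + self.summit_window.end) // 2


def n_windows(length: int, window: int, step: int) -> int:
    return (length - window) // step + 1 if length >= window else 0


def scan_genome(
    predictor: TrainedPredictor,
    tracks: Mapping[str, BinnedTrack],
    window: int = 2000,
    step: int = 100,
    chunk_size: int = 50_000,
) -> WindowScoreTrack:
    """Score every window of the genome with the trained predictor.

    Windows start at multiples of ``step`` from position 0 of each
    chromosome.  The per-window count vectors are scored through the exact
    same class-model path as training samples, so a window whose counts
    equal a training row receives an identical score.  Chromosomes shorter
    than the window yield zero windows.
    """
    feats = predictor.models.features
    first = tracks[feats[0]]
    bin_size = first.bin_size
    if step % bin_size or window % bin_size:
        raise ValueError("window and step must be multiples of the bin size")
    d = window // bin_size
    if d != predictor.models.d:
        raise ValueError(
            f"model expects d={predictor.models.d} bins, window gives {d}"
        )
    stride = step // bin_size
    out: dict[str, np.ndarray] = {}
    for chrom, length in first.genome.items():
        nw = n_windows(length, window, step)
        if nw == 0:
            out[chrom] = np.empty(0)
            continue
        probs = np.empty(nw)
        for lo in range(0, nw, chunk_size):
            hi = min(lo + chunk_size, nw)
            cov = {}
            for f in feats:
                vec = tracks[f].values[chrom]
                view = sliding_window_view(vec, d)[::stride]
                cov[f] = view[lo:hi]
            probs[lo:hi] = predictor.predict_proba(cov)
        out[chrom] = probs
    return WindowScoreTrack(out, window=window, step=step)


def call_enhancers(
    scores: WindowScoreTrack,
    threshold: float,
    seed: int = 0,
) -> list[EnhancerPrediction]:
    """Merge runs of strictly-above-threshold windows and pick one summit each.

    The summit is the maximum-score window of the run; exact score ties are
    resolved uniformly at random under the seed.  A run of m windows forms a
    region of m * step bp (one step per window), so a single-window call has
    length 100 bp even though each window spans 2 kb; the 2 kb summit window
    may extend past the region end.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    preds: list[EnhancerPrediction] = []
    w, step = scores.window, scores.step
    for chrom in sorted(scores.scores):
        s = scores.scores[chrom]
        above = s > threshold
        if not above.any():
            continue
        # run boundaries of the boolean mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        for start_i, end_i in zip(edges[::2], edges[1::2]):
            run = s[start_i:end_i]
            best = run.max()
            ties = np.flatnonzero(run == best)
            pick = int(ties[rng.integers(len(ties))]) + start_i
            region = GenomicInterval(
                chrom, int(start_i * step), int(end_i * step),
                name="enhancer", score=float(best),
            )
            summit = GenomicInterval(
                chrom, int(pick * step), int(pick * step + w),
                name="summit", score=float(best),
            )
            preds.append(EnhancerPrediction(region, summit, float(best)))
    return preds


def postfilter_predictions(
    preds: Sequence[EnhancerPrediction],
    blacklist: IntervalSet | None = None,
    training_enhancer_anchors: Sequence[tuple[str, int]] = (),
    tss: IntervalSet | None = None,
    max_training_dist: int = 1000,
    max_tss_dist: int = 2000,
) -> tuple[list[EnhancerPrediction], dict[str, int]]:
    """Remove artefact-prone and already-known predictions.

    Drops predictions whose summit window overlaps the blacklist by >= 1 bp,
    predictions within ``max_training_dist`` bp (inclusive) of a training
    enhancer anchor, and predictions whose middle base lies within
    ``max_tss_dist`` bp (inclusive) of any TSS.  Returns the survivors and a
    per-rule audit of removal counts.
    """
    anchors_by_chrom: dict[str, np.ndarray] = {}
    for c, p in training_enhancer_anchors:
        anchors_by_chrom.setdefault(c, []).append(p)  # type: ignore[arg-type]
    anchors_by_chrom = {c: np.asarray(v) for c, v in anchors_by_chrom.items()}
    kept: list[EnhancerPrediction] = []
    audit = {"blacklist": 0, "training_enhancer": 0, "tss": 0}
    for pred in preds:
        sw = pred.summit_window
        if blacklist is not None and blacklist.count_overlapping(sw) > 0:
            audit["blacklist"] += 1
            continue
        anchors = anchors_by_chrom.get(sw.chrom)
        mid = pred.middle_bp
        if anchors is not None and np.abs(anchors - mid).min() <= max_training_dist:
            audit["training_enhancer"] += 1
            continue
        if tss is not None and tss.distance_to_nearest(
            sw.chrom, mid, "start"
        ) <= max_tss_dist:
            audit["tss"] += 1
            continue
        kept.append(pred)
    return kept, audit


def prediction_length_distribution(
    preds: Sequence[EnhancerPrediction],
) -> dict[int, float]:
    """Normalized frequency of merged-region lengths (multiples of 100 bp)."""
    if not preds:
        return {}
    lengths = [p.region.length for p in preds]
    total = len(lengths)
    out: dict[int, float] = {}
    for L in lengths:
        out[L] = out.get(L, 0.0) + 1.0 / total
    return dict(sorted(out.items()))


def write_predictions_bed(
    preds: Sequence[EnhancerPrediction], path: str | Path
) -> None:
    """BED6 of merged regions (score = summit probability) plus summit TSV."""
    with open(path, "w") as fh:
        for i, p in enumerate(preds):
            fh.write(
                f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\t"
                f"enh_{i}\t{p.score:.6f}\t.\n"
            )
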