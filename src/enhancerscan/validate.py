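"""Validation of enhancer predictions against transcription-related-factor peaks.

A prediction is validated when its 2 kb summit window overlaps at least
1 bp of at least one TRF ChIP-seq peak.  Peaks from different factors are
pooled without merging, so nearby or duplicated peaks each count toward a
prediction's overlap tally; two nearby predictions may both validate
against one shared peak (a known, retained bias of the procedure).
Factor exclusions (e.g. general machinery such as RNA polymerase II,
insulators, or the factor that defined the training positives) are driven
by the peak manifest, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .scan import EnhancerPrediction, WindowScoreTrack

__all__ = [
    "ValidationReport",
    "pool_trf_peaks",
    "validate_predictions",
    "trf_overlap_histogram",
    "validation_rate_curve",
    "genome_wide_auc",
    "method_overlap",
]


@dataclass
class ValidationReport:
    validated: np.ndarray
    overlap_counts: np.ndarray
    validation_rate: float
    histogram: dict[int, float]
    genome_wide_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "validation_rate": self.validation_rate,
            "histogram": {str(k): v for k, v in self.histogram.items()},
            "genome_wide_auc": self.genome_wide_auc,
            "n_predictions": int(len(self.validated)),
        }


def _prediction_window(pred) -> GenomicInterval:
    """The interval a prediction is validated on: the 2 kb summit window for
    native predictions, the region itself for external variable-length sets."""
    if isinstance(pred, EnhancerPrediction):
        return pred.summit_window
    return pred


def pool_trf_peaks(
    peak_sets: Mapping[str, IntervalSet],
    exclude: Sequence[str] = (),
) -> IntervalSet:
    """Pool per-factor peak sets without merging, dropping excluded factors."""
    excluded = {e.lower() for e in exclude}
    pooled: list[GenomicInterval] = []
    genome: dict[str, int] = {}
    for factor, peaks in peak_sets.items():
        if factor.lower() in excluded:
            continue
        genome.update(peaks.genome)
        pooled.extend(peaks.intervals)
    return IntervalSet(pooled, genome)


def validate_predictions(
    preds: Sequence, trf_peaks: IntervalSet
) -> np.ndarray:
    """Boolean flag per prediction: >= 1 bp overlap with >= 1 TRF peak."""
    return np.array(
        [trf_peaks.count_overlapping(_prediction_window(p)) >= 1 for p in preds]
    )


def trf_overlap_histogram(
    preds: Sequence, trf_peaks: IntervalSet
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-prediction pooled-peak overlap counts and their proportions.

    The proportion at count 0 equals 1 minus the validation rate exactly.
    """
    counts = np.array(
        [trf_peaks.count_overlapping(_prediction_window(p)) for p in preds]
    )
    hist: dict[int, float] = {}
    n = len(counts)
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0.0) + 1.0 / n
    return counts, dict(sorted(hist.items()))


def validation_rate_curve(
    ranked_preds: Sequence,
    trf_peaks: IntervalSet,
    cutoffs: Sequence[int],
) -> list[float]:
    """Fraction of the top-m predictions validated, for each cutoff m.

    ``ranked_preds`` must be sorted by descending prediction score; cutoffs
    beyond the available predictions are capped with a warning.
    """
    import warnings

    flags = validate_predictions(ranked_preds, trf_peaks)
    rates = []
    for m in cutoffs:
        if m > len(flags):
            warnings.warn(
                f"cutoff {m} exceeds {len(flags)} predictions; capped",
                stacklevel=2,
            )
            m = len(flags)
        rates.append(float(flags[:m].mean()) if m else float("nan"))
    return rates


def genome_wide_auc(
    scores: WindowScoreTrack,
    enh_preds: Sequence[EnhancerPrediction],
    trf_peaks: IntervalSet,
    n: int,
    seed: int = 0,
    negative_max_score: float = 0.5,
) -> float:
    """AUC of the prediction score against TRF-overlap labels.

    Positives: the top-n predictions by score.  Negatives: n windows
    sampled uniformly from those scoring <= 0.5.  Both groups are labelled
    by the >= 1 bp TRF-overlap rule and the AUC measures how well the score
    separates validated from non-validated regions.
    """
    from .classify import compute_auc

    rng = np.random.default_rng(seed)
    top = sorted(enh_preds, key=lambda p: -p.score)[:n]
    if len(top) < n:
        raise ValueError(f"only {len(top)} predictions available, need {n}")
    pool: list[tuple[str, int]] = []
    for chrom, vec in scores.scores.items():
        for idx in np.flatnonzero(vec <= negative_max_score):
            pool.append((chrom, int(idx)))
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} eligible negative windows, need {n}")
    chosen = rng.choice(len(pool), size=n, replace=False)
    neg_windows = []
    neg_scores = []
    for i in chosen:
        chrom, idx = pool[i]
        start, end = scores.window_interval(chrom, idx)
        neg_windows.append(GenomicInterval(chrom, start, end))
        neg_scores.append(float(scores.scores[chrom][idx]))
    windows = [p.summit_window for p in top] + neg_windows
    vals = validate_predictions(windows, trf_peaks).astype(int)
    all_scores = np.array([p.score for p in top] + neg_scores)
    return compute_auc(all_scores, vals)


def method_overlap(
    preds_a: Sequence, preds_b: Sequence
) -> dict[str, int]:
    """Asymmetric >= 1 bp overlap counts between two prediction sets.

    One a-prediction spanning two b-predictions counts once in
    ``a_hits_b`` but twice in ``b_hits_a``; ``a_hits_b + a_only`` always
    equals ``len(preds_a)``.
    """
    a_windows = [_prediction_window(p) for p in preds_a]
    b_windows = [_prediction_window(p) for p in preds_b]
    genome: dict[str, int] = {}
    for iv in a_windows + b_windows:
        genome[iv.chrom] = max(genome.get(iv.chrom, 0), iv.end)
    b_set = IntervalSet(b_windows, genome)
    a_set = IntervalSet(a_windows, genome)
    a_hits = sum(1 for iv in a_windows if b_set.count_overlapping(iv) >= 1)
    b_hits = sum(1 for iv in b_windows if a_set.count_overlapping(iv) >= 1)
    return {
        "a_hits_b": a_hits,
        "b_hits_a": b_hits,
        "a_only": len(a_windows) - a_hits,
        "b_only": len(b_windows) - b_hits,
    }
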