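"""Gaussian-kernel classification of the 3K log-score matrix.

The enhancer-vs-rest decision is made by an RBF-kernel SVM on standardized
log-scores.  Hyperparameters (C, gamma) are tuned by grid search over
powers of two; performance is assessed by nested stratified 5-fold
cross-validation in which the class models, the feature standardization and
the SVM are all re-fitted inside each outer training fold, so no statistic
ever sees the outer test samples.  Decision thresholds (fixed 0.5, best
operating point, 1% FPR) are calibrated on the concatenated out-of-fold
probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .model import ClassModelSet

__all__ = [
    "HyperGrid",
    "FULL_GRID",
    "COARSE_GRID",
    "Standardizer",
    "ThresholdSet",
    "TrainedPredictor",
    "compute_auc",
    "grid_search_cv",
    "nested_cv_evaluate",
    "train_final",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class HyperGrid:
    """Powers-of-two grid for the SVM penalty C and kernel width gamma."""

    C_exponents: tuple
    gamma_exponents: tuple

    @property
    def C_values(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.C_exponents)

    @property
    def gamma_values(self) -> np.ndarray:
        return 2.0 ** np.asarray(self.gamma_exponents)


#: the full tuning grid: C = 2^-5 .. 2^25, gamma = 2^-25 .. 2^10, step 0.5
FULL_GRID = HyperGrid(
    C_exponents=tuple(np.arange(-5, 25.5, 0.5)),
    gamma_exponents=tuple(np.arange(-25, 10.5, 0.5)),
)

#: coarse 7x7 sub-grid spanning the same ranges, for routine-scale runs
COARSE_GRID = HyperGrid(
    C_exponents=(-5.0, -2.0, 0.0, 2.0, 5.0, 10.0, 15.0),
    gamma_exponents=(-15.0, -11.0, -8.0, -6.0, -4.0, -2.0, 0.0),
)


@dataclass
class Standardizer:
    """Column centering/scaling with train-only statistics.

    Constant columns pass through unscaled (sd forced to 1) with a warning.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant column(s) left unscaled",
                stacklevel=2,
            )
            mean = np.where(const, 0.0, mean)
            sd = np.where(const, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.sd


@dataclass
class ThresholdSet:
    """Decision thresholds on the enhancer-class probability."""

    fixed: float = 0.5
    best_operating_point: float = 0.5
    fpr1: float = 0.5
    target_fpr: float = 0.01
    provenance: str = ""


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC: P(random positive outscores random negative), ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def _stratified_folds(y: np.ndarray, n_splits: int, seed: int):
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _make_svc(C: float, gamma: float, seed: int = 0) -> SVC:
    # max_iter bound guards against non-convergent corners of the grid
    # (huge C with a degenerate kernel); never binding near the optimum.
    return SVC(
        C=C, gamma=gamma, kernel="rbf",
        cache_size=500, max_iter=200_000, random_state=seed,
    )


def _make_calibrated(C: float, gamma: float, seed: int = 0) -> CalibratedClassifierCV:
    """RBF SVM with a cross-fitted monotone sigmoid mapping decision
    values to class probabilities (single calibrator, not an ensemble)."""
    return CalibratedClassifierCV(
        _make_svc(C, gamma, seed=seed), method="sigmoid", cv=5, ensemble=False
    )


def grid_search_cv(
    X: np.ndarray,
    labels: Sequence[int],
    grid: HyperGrid = COARSE_GRID,
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (C, gamma) maximizing mean out-of-fold AUC over stratified folds.

    Model selection uses the SVM decision values (AUC is invariant to the
    monotone probability calibration, which would quintuple the fit cost).
    Ties break toward smaller C, then smaller gamma.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(labels)
    splits = _stratified_folds(y, folds, seed)
    for tr, _ in splits:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("stratification produced a single-class fold")
    best = (-np.inf, None, None)
    for C in sorted(grid.C_values):
        for gamma in sorted(grid.gamma_values):
            aucs = []
            for tr, va in splits:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf = _make_svc(C, gamma, seed=seed).fit(X[tr], y[tr])
                aucs.append(compute_auc(clf.decision_function(X[va]), y[va]))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best[0]:
                best = (mean_auc, C, gamma)
    return best[1], best[2], best[0]


def nested_cv_evaluate(
    coverage: Mapping[str, np.ndarray],
    labels: Sequence[int],
    class_labels: Sequence[str],
    mode: str = "bayes",
    outer_folds: int = 5,
    inner_folds: int = 5,
    grid: HyperGrid = COARSE_GRID,
    seed: int = 0,
    leak_class_models: bool = False,
) -> dict:
    """Nested stratified CV from raw coverage matrices to out-of-fold probabilities.

    For each outer fold: class models (aggregate patterns + Gamma priors)
    and the standardizer are fitted on the outer-training rows only, the
    inner grid search picks (C, gamma), and a probability-calibrated SVM
    trained on the outer-training scores predicts the held-out rows.  Every
    sample receives exactly one out-of-fold probability; the overall AUC is
    computed on the concatenated vector.

    ``leak_class_models=True`` deliberately breaks the protocol (class
    models fitted on all rows) and exists only so tests can demonstrate the
    leak is detectable; never use it for reported results.
    """
    y = np.asarray(labels)
    class_labels = np.asarray(class_labels)
    n = len(y)
    oof = np.full(n, np.nan)
    chosen = []
    leaky_models = (
        ClassModelSet.fit(coverage, class_labels) if leak_class_models else None
    )
    for fold_id, (tr, te) in enumerate(_stratified_folds(y, outer_folds, seed)):
        models = leaky_models or ClassModelSet.fit(
            {f: Y[tr] for f, Y in coverage.items()}, class_labels[tr]
        )
        X_tr = models.score_matrix({f: Y[tr] for f, Y in coverage.items()}, mode)
        X_te = models.score_matrix({f: Y[te] for f, Y in coverage.items()}, mode)
        scaler = Standardizer.fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        C, gamma, inner_auc = grid_search_cv(
            X_tr, y[tr], grid=grid, folds=inner_folds, seed=seed + fold_id
        )
        clf = _make_calibrated(C, gamma, seed=seed).fit(X_tr, y[tr])
        enh_col = list(clf.classes_).index(1)
        oof[te] = clf.predict_proba(X_te)[:, enh_col]
        chosen.append({"fold": fold_id, "C": C, "gamma": gamma,
                       "inner_auc": inner_auc})
    assert not np.isnan(oof).any()
    return {
        "oof_prob": oof,
        "auc": compute_auc(oof, y),
        "folds": chosen,
    }


@dataclass
class TrainedPredictor:
    """Everything needed to score new windows: class models, transform,
    calibrated SVM and thresholds."""

    models: ClassModelSet
    scaler: Standardizer
    svm: CalibratedClassifierCV
    mode: str
    C: float
    gamma: float
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)

    def predict_proba_scores(self, X_scores: np.ndarray) -> np.ndarray:
        """Enhancer-class probability from a raw (unstandardized) score matrix."""
        Xs = self.scaler.transform(X_scores)
        enh_col = list(self.svm.classes_).index(1)
        return self.svm.predict_proba(Xs)[:, enh_col]

    def predict_proba(self, coverage: Mapping[str, np.ndarray]) -> np.ndarray:
        return self.predict_proba_scores(
            self.models.score_matrix(coverage, self.mode)
        )

    def decision_values(self, X_scores: np.ndarray) -> np.ndarray:
        """Raw kernel decision values (probabilities are monotone in these)."""
        Xs = self.scaler.transform(X_scores)
        return self.svm.calibrated_classifiers_[0].estimator.decision_function(Xs)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "TrainedPredictor":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a TrainedPredictor")
        return obj


def train_final(
    coverage: Mapping[str, np.ndarray],
    labels: Sequence[int],
    class_labels: Sequence[str],
    mode: str = "bayes",
    C: float | None = None,
    gamma: float | None = None,
    grid: HyperGrid = COARSE_GRID,
    folds: int = 5,
    seed: int = 0,
) -> TrainedPredictor:
    """Train the final predictor on all training data.

    Hyperparameters come from a 5-fold grid search on the same data unless
    given explicitly.  Probabilities are produced by the SVM's monotone
    sigmoid calibration, cross-fitted internally on the training data only.
    """
    y = np.asarray(labels)
    models = ClassModelSet.fit(coverage, np.asarray(class_labels))
    X = models.score_matrix(coverage, mode)
    scaler = Standardizer.fit(X)
    Xs = scaler.transform(X)
    if C is None or gamma is None:
        C, gamma, _ = grid_search_cv(Xs, y, grid=grid, folds=folds, seed=seed)
    svm = _make_calibrated(C, gamma, seed=seed).fit(Xs, y)
    return TrainedPredictor(
        models=models, scaler=scaler, svm=svm, mode=mode, C=C, gamma=gamma
    )


def calibrate_thresholds(
    oof_scores: Sequence[float],
    labels: Sequence[int],
    target_fpr: float = 0.01,
    provenance: str = "",
) -> ThresholdSet:
    """Calibrate decision thresholds from out-of-fold probabilities.

    ``fpr1``: the smallest threshold t with fraction(negatives >= t) <=
    ``target_fpr``.  ``best_operating_point``: the threshold maximizing
    Youden's J = TPR - FPR (ties toward the larger threshold).
    """
    scores = np.asarray(oof_scores, dtype=np.float64)
    y = np.asarray(labels)
    neg = scores[y == 0]
    if neg.size == 0:
        raise ValueError("threshold calibration requires negatives")
    # keep every operating point: the FPR quantile lives between points
    # that drop_intermediate would discard
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    # drop the sentinel max+1 threshold; thresholds are descending
    j = tpr - fpr
    best_idx = int(np.argmax(j[1:])) + 1  # first index = largest t among ties
    bop = float(thr[best_idx])
    ok = np.where(fpr <= target_fpr)[0]
    # roc_curve thresholds descend while fpr ascends: the last qualifying
    # index is the smallest threshold meeting the FPR bound
    fpr1_idx = int(ok[-1])
    fpr1 = float(thr[fpr1_idx]) if fpr1_idx > 0 else float(thr[1])
    clip = lambda v: float(min(max(v, 1e-12), 1 - 1e-12))
    return ThresholdSet(
        fixed=0.5,
        best_operating_point=clip(bop),
        fpr1=clip(fpr1),
        target_fpr=target_fpr,
        provenance=provenance,
    )
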