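"""Poisson-Gamma scoring of coverage windows against class aggregate patterns.

A window's counts y = (y_1..y_d) for one chromatin feature are modelled as
independent Poisson draws with rates lambda_j = alpha * x_j, where x is the
class aggregate pattern (per-bin mean over the training samples of that
class) and alpha a per-sample scaling shared across bins.  Two scores
quantify the fit of y to a class:

* ML: the Poisson log-likelihood at the closed-form estimate
  alpha_hat = sum(y) / sum(x).
* Bayesian: the log posterior-predictive obtained by integrating alpha out
  against an empirical Gamma(a0, b0) prior (shape/rate) fitted to the
  training-sample alpha_hat values:

      log p(y) = logGamma(a0 + S) + a0*log(b0) + sum_j y_j*log(x_j)
               - logGamma(a0) - (a0 + S)*log(b0 + sum_j x_j)
               - sum_j logGamma(y_j + 1),        S = sum_j y_j.

Because the bins share one alpha, this does not factorize into independent
negative binomials except at d = 1.  Aggregate-pattern bins equal to zero
are floored at eps = 1/(n_class * d) before scoring so no observable count
vector maps to -inf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "CLASSES",
    "GammaPrior",
    "ClassModel",
    "ClassModelSet",
    "aggregate_pattern",
    "ml_alpha",
    "fit_gamma_prior",
    "log_likelihood_score",
    "log_posterior_predictive",
    "build_feature_matrix",
]

#: fixed class order used everywhere (column triplets of the score matrix)
CLASSES = ("enh", "prom", "rand")


@dataclass(frozen=True)
class GammaPrior:
    """Shape/rate Gamma prior for the scaling parameter (mean = a0/b0)."""

    a0: float
    b0: float
    n_zero_excluded: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a0) and self.a0 > 0):
            raise ValueError(f"shape a0 must be finite positive, got {self.a0}")
        if not (np.isfinite(self.b0) and self.b0 > 0):
            raise ValueError(f"rate b0 must be finite positive, got {self.b0}")

    @property
    def mean(self) -> float:
        return self.a0 / self.b0


def aggregate_pattern(Y: np.ndarray) -> np.ndarray:
    """Per-bin mean coverage over the samples of one class (the class profile)."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[0] == 0:
        raise ValueError("coverage matrix must be non-empty and 2-D")
    return Y.mean(axis=0)


def ml_alpha(y: np.ndarray, x: np.ndarray) -> float:
    """Closed-form maximum-likelihood scaling: sum(y) / sum(x).

    Returns 0.0 for an all-zero sample (the likelihood is then maximized at
    the boundary alpha = 0).
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    sx = x.sum()
    if sx <= 0:
        raise ValueError("degenerate aggregate pattern: sum(x) = 0")
    return float(y.sum() / sx)


def fit_gamma_prior(alphas: Sequence[float]) -> GammaPrior:
    """Maximum-likelihood Gamma (shape/rate) fit to scaling estimates.

    Zero values (all-zero samples) carry no information about the
    continuous scaling distribution; they are excluded and their count is
    reported on the returned prior.  The optimizer is initialized from the
    method-of-moments estimate, so its log-likelihood can only improve on it.
    """
    alphas = np.asarray(alphas, dtype=np.float64)
    pos = alphas[alphas > 0]
    n_zero = int(alphas.size - pos.size)
    if pos.size < 10:
        raise ValueError(f"need >= 10 positive values, got {pos.size}")
    if np.var(pos) == 0:
        raise ValueError("degenerate input: zero variance")
    m, v = pos.mean(), pos.var()
    mom_shape, mom_scale = m * m / v, v / m
    shape, _, scale = stats.gamma.fit(pos, mom_shape, floc=0, scale=mom_scale)
    return GammaPrior(a0=float(shape), b0=float(1.0 / scale), n_zero_excluded=n_zero)


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return y


def log_likelihood_score(y: np.ndarray, x: np.ndarray, alpha: float) -> float:
    """Poisson log-likelihood sum_j log Poisson(y_j | alpha * x_j).

    ``alpha = 0`` is valid only for all-zero y (score 0, the boundary
    maximum); callers floor x upstream so x_j > 0 everywhere.
    """
    y = _validate_counts(y)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if alpha == 0.0:
        return 0.0 if not y.any() else -np.inf
    lam = alpha * x
    return float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))


def log_posterior_predictive(y: np.ndarray, x: np.ndarray, prior: GammaPrior) -> float:
    """Log marginal likelihood of y with the Gamma prior integrated out."""
    y = _validate_counts(y)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if np.any(x <= 0):
        raise ValueError("aggregate pattern must be strictly positive (floor first)")
    S = y.sum()
    return float(
        gammaln(prior.a0 + S)
        + prior.a0 * np.log(prior.b0)
        + np.dot(y, np.log(x))
        - gammaln(prior.a0)
        - (prior.a0 + S) * np.log(prior.b0 + x.sum())
        - gammaln(y + 1).sum()
    )


@dataclass
class ClassModel:
    """Fitted per-feature, per-class model: floored pattern + Gamma prior."""

    x: np.ndarray
    prior: GammaPrior
    epsilon: float
    feature: str = ""
    class_id: str = ""

    @classmethod
    def fit(
        cls, Y: np.ndarray, feature: str = "", class_id: str = ""
    ) -> "ClassModel":
        """Fit pattern and empirical prior from one class's training matrix."""
        Y = np.asarray(Y, dtype=np.float64)
        x_raw = aggregate_pattern(Y)
        n, d = Y.shape
        eps = 1.0 / (n * d)
        x = np.maximum(x_raw, eps)
        alphas = Y.sum(axis=1) / x_raw.sum() if x_raw.sum() > 0 else np.zeros(n)
        try:
            prior = fit_gamma_prior(alphas)
        except ValueError:
            # degenerate class (e.g. tiny test fixture): weak default prior
            m = max(float(np.mean(alphas)), eps)
            prior = GammaPrior(a0=1.0, b0=1.0 / m)
        return cls(x=x, prior=prior, epsilon=eps, feature=feature, class_id=class_id)

    # -- vectorized scoring over an (N, d) count matrix ------------------

    def bayes_scores(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=np.float64)
        S = Y.sum(axis=1)
        a0, b0 = self.prior.a0, self.prior.b0
        return (
            gammaln(a0 + S)
            + a0 * np.log(b0)
            + Y @ np.log(self.x)
            - gammaln(a0)
            - (a0 + S) * np.log(b0 + self.x.sum())
            - gammaln(Y + 1).sum(axis=1)
        )

    def ml_scores(self, Y: np.ndarray) -> np.ndarray:
        """Log-likelihood at the per-sample ML scaling against this class."""
        Y = np.asarray(Y, dtype=np.float64)
        S = Y.sum(axis=1)
        sx = self.x.sum()
        alpha = S / sx
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                Y @ np.log(self.x)
                + S * np.log(alpha)
                - alpha * sx
                - gammaln(Y + 1).sum(axis=1)
            )
        return np.where(S == 0, 0.0, out)


class ClassModelSet:
    """All K x 3 class models plus the score-matrix construction.

    Score-matrix column order: for each feature, the (enh, prom, rand)
    triplet of log-scores, giving 3K columns.
    """

    def __init__(self, models: Mapping[str, Mapping[str, ClassModel]], d: int,
                 bin_size: int = 100) -> None:
        self.models = {k: dict(v) for k, v in models.items()}
        self.d = d
        self.bin_size = bin_size

    @property
    def features(self) -> list[str]:
        return list(self.models)

    @classmethod
    def fit(
        cls,
        coverage: Mapping[str, np.ndarray],
        class_labels: Sequence[str],
        bin_size: int = 100,
    ) -> "ClassModelSet":
        """Fit per-feature models for each class in ``CLASSES``.

        ``class_labels`` assigns each row of every coverage matrix to enh /
        prom / rand (pure-random and signal-random rows both carry "rand").
        """
        labels = np.asarray(class_labels)
        models: dict[str, dict[str, ClassModel]] = {}
        d = None
        for feat, Y in coverage.items():
            Y = np.asarray(Y)
            d = Y.shape[1] if d is None else d
            models[feat] = {}
            for cl in CLASSES:
                rows = Y[labels == cl]
                if rows.shape[0] == 0:
                    raise ValueError(f"no training rows for class {cl!r}")
                models[feat][cl] = ClassModel.fit(rows, feature=feat, class_id=cl)
        return cls(models, d=d, bin_size=bin_size)

    def score_matrix(
        self, coverage: Mapping[str, np.ndarray], mode: str = "bayes"
    ) -> np.ndarray:
        """The (N, 3K) matrix of log-scores for N samples."""
        if mode not in ("bayes", "ml"):
            raise ValueError(f"mode must be 'bayes' or 'ml', got {mode!r}")
        cols = []
        for feat in self.features:
            Y = np.asarray(coverage[feat], dtype=np.float64)
            if Y.shape[1] != self.d:
                raise ValueError(
                    f"feature {feat!r}: expected {self.d} bins, got {Y.shape[1]}"
                )
            for cl in CLASSES:
                m = self.models[feat][cl]
                cols.append(m.bayes_scores(Y) if mode == "bayes" else m.ml_scores(Y))
        return np.column_stack(cols)

    # -- plain-text serialization ----------------------------------------

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "bin_size": self.bin_size,
            "classes": list(CLASSES),
            "features": {
                feat: {
                    cl: {
                        "x": m.x.tolist(),
                        "a0": m.prior.a0,
                        "b0": m.prior.b0,
                        "epsilon": m.epsilon,
                        "n_zero_excluded": m.prior.n_zero_excluded,
                    }
                    for cl, m in per_class.items()
                }
                for feat, per_class in self.models.items()
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ClassModelSet":
        models: dict[str, dict[str, ClassModel]] = {}
        for feat, per_class in payload["features"].items():
            models[feat] = {}
            for cl, m in per_class.items():
                models[feat][cl] = ClassModel(
                    x=np.asarray(m["x"], dtype=np.float64),
                    prior=GammaPrior(m["a0"], m["b0"], m.get("n_zero_excluded", 0)),
                    epsilon=m["epsilon"],
                    feature=feat,
                    class_id=cl,
                )
        return cls(models, d=payload["d"], bin_size=payload.get("bin_size", 100))

    @classmethod
    def load(cls, path: str | Path) -> "ClassModelSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_feature_matrix(
    coverage: Mapping[str, np.ndarray],
    models: ClassModelSet,
    mode: str = "bayes",
) -> np.ndarray:
    """Convenience wrapper: score every sample against every class model."""
    return models.score_matrix(coverage, mode=mode)
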