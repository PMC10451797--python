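"""Bayesian optimization of (C, gamma) for the RBF-SVM quality model.

Sequential model-based search with a Gaussian-process surrogate and
expected-improvement acquisition over the log-transformed box
``C in [1e-2, 1e3] x gamma in [1e-3, 1e2]``. The objective is mean
stratified four-fold cross-validation accuracy. A plain log-grid search is
available as a fallback.

The search is fully determined by its seed: initial design, GP fitting and
the acquisition candidate pool all draw from one ``numpy`` generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = ["SearchSpace", "TuningResult", "tune_hyperparameters", "cv_accuracy"]

N_FOLDS = 4


@dataclass(frozen=True)
class SearchSpace:
    """Log-uniform box constraints for the SVM hyperparameters."""

    c_bounds: tuple[float, float] = (1e-2, 1e3)
    gamma_bounds: tuple[float, float] = (1e-3, 1e2)

    def log_bounds(self) -> np.ndarray:
        return np.log10(
            np.array([self.c_bounds, self.gamma_bounds], dtype=float)
        )


@dataclass
class TuningResult:
    """Outcome of the hyperparameter search."""

    c: float
    gamma: float
    cv_score: float
    trace: list[tuple[float, float, float]] = field(default_factory=list)
    method: str = "bayes"


def _check_labels(labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("hyperparameter tuning needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError(
            f"every class needs >= 2 members for stratified folds; got {dict(zip(classes, counts))}"
        )
    if counts.min() < N_FOLDS:
        warnings.warn(
            f"classes with < {N_FOLDS} members: using {int(counts.min())} folds",
            UserWarning,
            stacklevel=3,
        )
    if labels.size < 2 * N_FOLDS:
        raise ValueError(f"need >= {2 * N_FOLDS} samples for {N_FOLDS}-fold CV")


def cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    c: float,
    gamma: float,
    seed: int,
) -> float:
    """Mean stratified four-fold CV accuracy of an RBF-SVM at (C, gamma).

    The fold count drops to the smallest class size when a class has fewer
    than four members (stratified folds must hold one member of every class).
    """
    _, counts = np.unique(labels, return_counts=True)
    n_splits = min(N_FOLDS, int(counts.min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    clf = SVC(kernel="rbf", C=c, gamma=gamma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny folds may miss a class
        scores = cross_val_score(clf, features, labels, cv=cv, scoring="accuracy")
    return float(scores.mean())


def _expected_improvement(
    mu: np.ndarray, sigma: np.ndarray, best: float, xi: float = 0.01
) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best - xi) / sigma
    return (mu - best - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def tune_hyperparameters(
    features: np.ndarray,
    labels: np.ndarray,
    space: SearchSpace | None = None,
    seed: int = 0,
    n_evals: int = 32,
    method: str = "bayes",
) -> TuningResult:
    """Search (C, gamma) maximizing stratified four-fold CV accuracy.

    Parameters
    ----------
    features, labels
        Normalized feature matrix and integer class labels.
    space
        Box constraints; defaults to ``C in [1e-2, 1e3]``, ``gamma in [1e-3, 1e2]``.
    seed
        Seeds the initial design, the candidate pool and the CV folds.
    n_evals
        Total objective evaluations (default 32; the first third is a
        random space-filling design, the rest expected-improvement picks).
    method
        ``"bayes"`` (default) or ``"grid"`` fallback (a log-spaced lattice
        with approximately ``n_evals`` points).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    if space is None:
        space = SearchSpace()
    if method == "grid":
        return _grid_search(features, labels, space, seed, n_evals)
    if method != "bayes":
        raise ValueError(f"unknown search method {method!r}")

    rng = np.random.default_rng(seed)
    lo, hi = space.log_bounds()[:, 0], space.log_bounds()[:, 1]
    n_init = max(4, n_evals // 3)

    X: list[np.ndarray] = []  # points in log10 space
    y: list[float] = []

    def evaluate(point: np.ndarray) -> None:
        c, gamma = 10.0 ** point
        score = cv_accuracy(features, labels, c, gamma, seed)
        X.append(point)
        y.append(score)

    for point in rng.uniform(lo, hi, size=(n_init, 2)):
        evaluate(point)

    kernel = ConstantKernel(1.0) * RBF(length_scale=[1.0, 1.0]) + WhiteKernel(1e-4)
    for _ in range(n_evals - n_init):
        gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_restarts_optimizer=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP convergence chatter on flat objectives
            gp.fit(np.array(X), np.array(y))
        candidates = rng.uniform(lo, hi, size=(512, 2))
        mu, sigma = gp.predict(candidates, return_std=True)
        ei = _expected_improvement(mu, sigma, best=max(y))
        evaluate(candidates[int(np.argmax(ei))])

    best_idx = int(np.argmax(y))
    c, gamma = 10.0 ** X[best_idx]
    trace = [(float(10.0 ** p[0]), float(10.0 ** p[1]), s) for p, s in zip(X, y)]
    return TuningResult(c=float(c), gamma=float(gamma), cv_score=float(y[best_idx]),
                        trace=trace, method="bayes")


def _grid_search(
    features: np.ndarray,
    labels: np.ndarray,
    space: SearchSpace,
    seed: int,
    n_evals: int,
) -> TuningResult:
    side = max(2, int(np.sqrt(n_evals)))
    cs = np.logspace(*np.log10(space.c_bounds), side)
    gammas = np.logspace(*np.log10(space.gamma_bounds), side)
    trace = []
    best = (-np.inf, 0.0, 0.0)
    for c in cs:
        for gamma in gammas:
            score = cv_accuracy(features, labels, c, gamma, seed)
            trace.append((float(c), float(gamma), score))
            if score > best[0]:
                best = (score, float(c), float(gamma))
    return TuningResult(c=best[1], gamma=best[2], cv_score=best[0],
                        trace=trace, method="grid")
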