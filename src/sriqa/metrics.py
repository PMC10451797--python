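"""Agreement metrics between predicted and reference quality scores.

Four standard IQA-evaluation metrics: Pearson linear correlation (PLCC,
prediction accuracy), Spearman rank correlation (SRCC, prediction
monotonicity), exact-match accuracy, and RMSE (consistency), plus the 4x4
confusion matrix over the score classes {1, 2, 3, 4}.

Quality scores are heavily tied, so SRCC is computed as Pearson correlation
on average ranks (the standard tie-aware form); it reduces to the classic
``1 - 6*sum(d_i^2)/(N(N^2-1))`` formula when ranks are tie-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "SCORE_CLASSES",
    "plcc",
    "srcc",
    "accuracy",
    "rmse",
    "evaluate",
]

SCORE_CLASSES = (1, 2, 3, 4)


def _pair(x, y, min_len: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"expected equal-length 1-D vectors, got {x.shape}, {y.shape}")
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {x.size}")
    return x, y


def plcc(x, y) -> float:
    """Pearson linear correlation coefficient.

    Raises ``ValueError`` when either input has zero variance (the
    correlation is undefined there, e.g. constant predictions).
    """
    x, y = _pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def srcc(x, y) -> float:
    """Spearman rank-order correlation coefficient with average ranks for ties."""
    x, y = _pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for zero-variance input")
    return float(stats.spearmanr(x, y).statistic)


def accuracy(pred, truth) -> float:
    """Fraction of exactly correct predictions."""
    pred, truth = _pair(pred, truth, min_len=1)
    return float(np.mean(pred == truth))


def rmse(s, p) -> float:
    """Root mean squared error ``sqrt(sum (s_i - p_i)^2 / N)``."""
    s, p = _pair(s, p, min_len=1)
    return float(np.sqrt(np.mean((s - p) ** 2)))


@dataclass
class EvaluationReport:
    """Bundle of the four agreement metrics plus a confusion matrix.

    ``plcc``/``srcc`` are ``None`` (and flagged) when undefined, e.g. for
    constant predictions. Confusion-matrix rows index the true score, columns
    the predicted score, both over classes 1..4.
    """

    plcc: float | None
    srcc: float | None
    accuracy: float
    rmse: float
    confusion: np.ndarray
    n: int
    undefined: tuple[str, ...] = field(default=())

    def summary(self) -> str:
        def fmt(v):
            return "undefined" if v is None else f"{v:.4f}"

        lines = [
            f"N = {self.n}",
            f"PLCC     {fmt(self.plcc)}",
            f"SRCC     {fmt(self.srcc)}",
            f"Accuracy {self.accuracy:.4f}",
            f"RMSE     {self.rmse:.4f}",
            "Confusion matrix (rows = truth 1..4, cols = predicted 1..4):",
            str(self.confusion),
        ]
        return "\n".join(lines)


def evaluate(pred, truth) -> EvaluationReport:
    """Evaluate integer quality predictions against reference scores."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    for name, v in (("pred", pred), ("truth", truth)):
        if not np.isin(v, SCORE_CLASSES).all():
            raise ValueError(f"{name} contains scores outside {SCORE_CLASSES}")
    confusion = np.zeros((4, 4), dtype=int)
    for t, p in zip(truth.astype(int), pred.astype(int)):
        confusion[t - 1, p - 1] += 1
    undefined: list[str] = []
    try:
        plcc_v: float | None = plcc(pred, truth)
    except ValueError:
        plcc_v = None
        undefined.append("plcc")
    try:
        srcc_v: float | None = srcc(pred, truth)
    except ValueError:
        srcc_v = None
        undefined.append("srcc")
    return EvaluationReport(
        plcc=plcc_v,
        srcc=srcc_v,
        accuracy=accuracy(pred, truth),
        rmse=rmse(truth, pred),
        confusion=confusion,
        n=int(pred.size),
        undefined=tuple(undefined),
    )
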