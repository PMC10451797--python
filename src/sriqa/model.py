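"""The SVM quality model: normalization, tuning, fitting and prediction.

The model maps the four soft-reference quality parameters of an image to a
subjective score class in {1, 2, 3, 4}. It follows the Model/Results
convention of statsmodels: :class:`SoftReferenceIQA` holds the training
data and configuration, its :meth:`~SoftReferenceIQA.fit` tunes ``(C,
gamma)`` of an RBF-SVM by Bayesian optimization under stratified four-fold
cross-validation, retrains on all training rows, and returns a
:class:`QualityModelResults` carrying the fitted normalizer, the SVM, the
search diagnostics and a ``summary()`` table.

Feature normalization is per-feature min-max scaling to [0, 1] fitted on
the training set, with the MSE feature inverted (1 minus the scaled value)
so that all four features are positively correlated with quality. Test
values outside the training range are clipped into [0, 1].

Multiclass handling is one-vs-one decomposition of the binary soft-margin
problem (the scikit-learn default for SVC). The decision function of each
binary machine is the RBF dual expansion
``sum_i alpha_i q_i exp(-gamma ||F_i - F||^2) + b``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import FEATURE_NAMES, FeatureVector
from .optimize import SearchSpace, TuningResult, tune_hyperparameters

__all__ = [
    "Normalizer",
    "SoftReferenceIQA",
    "QualityModelResults",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: Features flagged for inversion after min-max scaling: raw MSE decreases
#: with quality, so the normalized feature is 1 minus the scaled value.
INVERTED_FEATURES = ("mse",)


@dataclass
class Normalizer:
    """Per-feature min-max scaler to [0, 1] with optional inversion.

    A constant training column carries no information; it maps to 0.5.
    """

    mins: np.ndarray
    maxs: np.ndarray
    invert: np.ndarray  # boolean per feature
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @classmethod
    def fit(cls, table: np.ndarray, feature_names=FEATURE_NAMES) -> "Normalizer":
        table = np.asarray(table, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2:
            raise ValueError("need a 2-D table with at least 2 rows")
        if np.isnan(table).any():
            raise ValueError("NaN in feature table")
        import warnings

        mins = table.min(axis=0)
        maxs = table.max(axis=0)
        constant = maxs == mins
        if constant.any():
            names = [n for n, c in zip(feature_names, constant) if c]
            warnings.warn(
                f"constant feature column(s) {names}: mapped to 0.5",
                UserWarning,
                stacklevel=2,
            )
        invert = np.array([n in INVERTED_FEATURES for n in feature_names])
        return cls(mins=mins, maxs=maxs, invert=invert,
                   feature_names=tuple(feature_names))

    def transform(self, table: np.ndarray) -> np.ndarray:
        table = np.atleast_2d(np.asarray(table, dtype=float))
        if np.isnan(table).any():
            raise ValueError("NaN in features")
        span = self.maxs - self.mins
        out = np.empty_like(table)
        constant = span == 0
        nz = ~constant
        out[:, nz] = (table[:, nz] - self.mins[nz]) / span[nz]
        out[:, constant] = 0.5
        np.clip(out, 0.0, 1.0, out=out)
        out[:, self.invert] = 1.0 - out[:, self.invert]
        return out

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "invert": self.invert.astype(int).tolist(),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            invert=np.asarray(d["invert"], dtype=bool),
            feature_names=tuple(d["feature_names"]),
        )


def train_svm(features: np.ndarray, labels: np.ndarray, c: float, gamma: float) -> SVC:
    """Fit a one-vs-one RBF-SVM at fixed (C, gamma) on normalized features."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("degenerate training set: fewer than 2 classes")
    clf = SVC(kernel="rbf", C=c, gamma=gamma, decision_function_shape="ovo")
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


class SoftReferenceIQA:
    """Quality model over soft-reference features, to be fitted to a table.

    Parameters
    ----------
    features
        ``(n, 4)`` raw feature matrix in the order ``(mse, psnr, cr, ssim)``.
    labels
        Integer quality scores in {1, 2, 3, 4}, one per row.

    Examples
    --------
    >>> model = SoftReferenceIQA.from_dataframe(df)   # doctest: +SKIP
    >>> results = model.fit(seed=1)                   # doctest: +SKIP
    >>> results.predict(df_test[list(FEATURE_NAMES)]) # doctest: +SKIP
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray):
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be (n, {len(FEATURE_NAMES)})")
        if features.shape[0] == 0:
            raise ValueError("empty training table")
        if labels.shape != (features.shape[0],):
            raise ValueError("labels must match feature rows")
        self.features = features
        self.labels = labels

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "grade") -> "SoftReferenceIQA":
        """Build the model from a feature table with columns mse/psnr/cr/ssim + label."""
        missing = [c for c in (*FEATURE_NAMES, label_col) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return cls(df[list(FEATURE_NAMES)].to_numpy(), df[label_col].to_numpy())

    def fit(
        self,
        seed: int = 0,
        search_space: SearchSpace | None = None,
        n_evals: int = 32,
        method: str = "bayes",
    ) -> "QualityModelResults":
        """Normalize, tune (C, gamma), retrain on all rows, return results."""
        normalizer = Normalizer.fit(self.features)
        normalized = normalizer.transform(self.features)
        tuning = tune_hyperparameters(
            normalized, self.labels, space=search_space, seed=seed,
            n_evals=n_evals, method=method,
        )
        svm = train_svm(normalized, self.labels, tuning.c, tuning.gamma)
        return QualityModelResults(
            model=self,
            normalizer=normalizer,
            svm=svm,
            tuning=tuning,
            seed=seed,
            _train_normalized=normalized,
        )


@dataclass
class QualityModelResults:
    """Fitted quality model: normalizer + RBF-SVM + search diagnostics."""

    model: SoftReferenceIQA | None
    normalizer: Normalizer
    svm: SVC
    tuning: TuningResult
    seed: int
    _train_normalized: np.ndarray = field(repr=False, default=None)

    # -- prediction ---------------------------------------------------

    def predict(self, features) -> np.ndarray:
        """Predict score classes for raw feature rows (array, DataFrame or FeatureVector)."""
        if isinstance(features, FeatureVector):
            return self.predict(features.as_array()[None, :])
        if isinstance(features, pd.DataFrame):
            features = features[list(FEATURE_NAMES)].to_numpy()
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return self.svm.predict(self.normalizer.transform(features)).astype(int)

    def predict_one(self, fv: FeatureVector) -> int:
        """Predict the score class of a single feature vector."""
        return int(self.predict(fv)[0])

    # -- reporting ----------------------------------------------------

    @property
    def c(self) -> float:
        return self.tuning.c

    @property
    def gamma(self) -> float:
        return self.tuning.gamma

    @property
    def cv_score(self) -> float:
        return self.tuning.cv_score

    def summary(self) -> str:
        n = self.model.features.shape[0] if self.model is not None else len(
            self._train_normalized
        )
        lines = [
            "Soft-reference ultrasound IQA model (RBF-SVM, one-vs-one)",
            "=" * 58,
            f"Training rows:        {n}",
            f"Classes:              {[int(c) for c in self.svm.classes_]}",
            f"Support vectors:      {int(self.svm.support_vectors_.shape[0])}",
            f"C (penalty):          {self.c:.6g}",
            f"gamma (kernel width): {self.gamma:.6g}",
            f"CV accuracy (4-fold): {self.cv_score:.4f}",
            f"Search:               {self.tuning.method}, "
            f"{len(self.tuning.trace)} evaluations, seed {self.seed}",
            "Features:             mse (inverted), psnr, cr, ssim "
            "— min-max scaled to [0, 1]",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------

    def save(self, path: Path | str) -> None:
        """Write the model to a versioned JSON container.

        The container stores the normalizer, the tuned hyperparameters and
        the normalized training data; loading refits the SVM, which is
        deterministic given those inputs, so predictions round-trip
        bit-exactly.
        """
        payload = {
            "format": "sriqa-quality-model",
            "version": MODEL_FORMAT_VERSION,
            "seed": self.seed,
            "c": self.tuning.c,
            "gamma": self.tuning.gamma,
            "cv_score": self.tuning.cv_score,
            "search_method": self.tuning.method,
            "normalizer": self.normalizer.to_dict(),
            "train_features_normalized": np.asarray(self._train_normalized).tolist(),
            "train_labels": np.asarray(self.svm_labels()).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    def svm_labels(self) -> np.ndarray:
        if self.model is not None:
            return self.model.labels
        return self._loaded_labels

    @classmethod
    def load(cls, path: Path | str) -> "QualityModelResults":
        try:
            payload = json.loads(Path(path).read_text())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ValueError(f"{path}: corrupt or truncated model file") from exc
        if not isinstance(payload, dict) or payload.get("format") != "sriqa-quality-model":
            raise ValueError(f"{path}: not a quality-model container")
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported model version {payload.get('version')}"
            )
        normalized = np.asarray(payload["train_features_normalized"], dtype=float)
        labels = np.asarray(payload["train_labels"], dtype=int)
        svm = train_svm(normalized, labels, payload["c"], payload["gamma"])
        tuning = TuningResult(
            c=payload["c"], gamma=payload["gamma"], cv_score=payload["cv_score"],
            trace=[], method=payload.get("search_method", "bayes"),
        )
        results = cls(
            model=None,
            normalizer=Normalizer.from_dict(payload["normalizer"]),
            svm=svm,
            tuning=tuning,
            seed=int(payload["seed"]),
            _train_normalized=normalized,
        )
        results._loaded_labels = labels
        return results


def load_model(path: Path | str) -> QualityModelResults:
    """Load a saved quality model (see :meth:`QualityModelResults.save`)."""
    return QualityModelResults.load(path)
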