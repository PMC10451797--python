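"""Global-local routing framework for breast ultrasound quality assessment.

An input image is first classified as negative (no lesion) or positive
(lesion present). Negative images are scored by a whole-image ("global")
quality scorer; positive images go down the local soft-reference path:
lesion segmentation, soft-reference feature extraction around the mask,
and SVM quality prediction. A positive image whose segmentation comes back
empty falls back to the global route with a warning — the local features
are undefined without a lesion mask.

The detector, segmenter and global scorer are pluggable components (in a
clinical deployment they would be trained networks). This module ships
desk-scale built-ins: oracle detector/segmenter backed by the phantom
manifest's ground-truth masks — the configuration where the reference is a
manual segmentation — and a naive global scorer trained on whole-image
noise/contrast summaries of lesion-free phantoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import SVC

from .features import FeatureVector, extract_feature_vector
from .image import DEFAULT_MARGIN, load_mask
from .model import QualityModelResults
from .phantom import GRADES, PhantomSpec, generate_phantom

__all__ = [
    "ComponentRegistry",
    "QualityResult",
    "RegistrationError",
    "route_and_score",
    "builtin_components",
    "global_summary_features",
]

logger = logging.getLogger("sriqa.pipeline")

#: Component signatures. ``context`` carries per-image metadata (id, paths)
#: needed by manifest-backed oracle components.
Detector = Callable[[np.ndarray, dict], bool]
Segmenter = Callable[[np.ndarray, dict], np.ndarray]
GlobalScorer = Callable[[np.ndarray], int]


class RegistrationError(ValueError):
    """A component failed its interface probe."""


@dataclass
class QualityResult:
    """Outcome of scoring one image."""

    score: int
    route: str  # "global" | "local"
    features: FeatureVector | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class ComponentRegistry:
    """Pluggable components of the global-local framework."""

    detector: Detector
    segmenter: Segmenter
    global_scorer: GlobalScorer
    local_model: QualityModelResults
    margin_fraction: float = DEFAULT_MARGIN

    def validate(self, probe_image: np.ndarray, probe_context: dict) -> None:
        """Probe every component's interface contract on one image.

        Raises :class:`RegistrationError` on any contract violation.
        """
        flag = self.detector(probe_image, probe_context)
        if not isinstance(flag, (bool, np.bool_)):
            raise RegistrationError(
                f"detector must return bool, got {type(flag).__name__}"
            )
        mask = np.asarray(self.segmenter(probe_image, probe_context))
        if mask.dtype != np.bool_ or mask.shape != probe_image.shape:
            raise RegistrationError(
                f"segmenter must return a boolean mask of shape {probe_image.shape}, "
                f"got dtype {mask.dtype}, shape {mask.shape}"
            )
        score = self.global_scorer(probe_image)
        if int(score) not in GRADES:
            raise RegistrationError(f"global scorer must return a class in {GRADES}")
        if not hasattr(self.local_model, "predict_one"):
            raise RegistrationError("local model must expose predict_one")


def route_and_score(
    image: np.ndarray, registry: ComponentRegistry, context: dict | None = None
) -> QualityResult:
    """Score one image through the global-local framework."""
    context = context or {}
    image_id = context.get("id", "<unknown>")
    positive = bool(registry.detector(image, context))
    if not positive:
        score = int(registry.global_scorer(image))
        logger.info("id=%s route=global score=%d", image_id, score)
        return QualityResult(score=score, route="global",
                             provenance={"id": image_id, "detector": "negative"})
    mask = np.asarray(registry.segmenter(image, context), dtype=bool)
    if not mask.any():
        logger.warning(
            "id=%s positive classification but empty segmentation; "
            "falling back to global route", image_id,
        )
        score = int(registry.global_scorer(image))
        return QualityResult(
            score=score, route="global",
            provenance={"id": image_id, "detector": "positive",
                        "fallback": "empty-mask"},
        )
    fv = extract_feature_vector(image, mask, registry.margin_fraction)
    score = registry.local_model.predict_one(fv)
    logger.info(
        "id=%s route=local score=%d mse=%.1f psnr=%.2f cr=%.4f ssim=%.4f",
        image_id, score, fv.mse, fv.psnr, fv.cr, fv.ssim,
    )
    return QualityResult(
        score=score, route="local", features=fv,
        provenance={"id": image_id, "detector": "positive"},
    )


def global_summary_features(image: np.ndarray) -> np.ndarray:
    """Whole-image summaries for the naive global scorer.

    Sharpness (mean gradient magnitude), residual noise (std of the image
    minus its smoothed version), intensity spread and mean level — crude
    proxies for the degradations that lower perceived quality.
    """
    img = np.asarray(image, dtype=float)
    smooth = ndimage.gaussian_filter(img, 2.0, mode="nearest")
    gy, gx = np.gradient(img)
    return np.array(
        [
            float(np.hypot(gy, gx).mean()),
            float((img - smooth).std()),
            float(img.std()),
            float(img.mean()),
        ]
    )


def _train_global_scorer(
    spec: PhantomSpec, seed: int, n_per_grade: int = 20
) -> GlobalScorer:
    """Fit a small SVM from whole-image summaries of lesion-free phantoms."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for grade in GRADES:
        for _ in range(n_per_grade):
            rec = generate_phantom(
                spec, grade, lesion=False, seed=int(rng.integers(2**31 - 1))
            )
            X.append(global_summary_features(rec.image))
            y.append(grade)
    X = np.array(X)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    clf = SVC(kernel="rbf", C=10.0, gamma="scale")
    clf.fit((X - mu) / sd, y)

    def scorer(image: np.ndarray) -> int:
        z = (global_summary_features(image) - mu) / sd
        return int(clf.predict(z[None, :])[0])

    return scorer


def builtin_components(
    manifest: pd.DataFrame,
    local_model: QualityModelResults,
    data_dir: Path | str | None = None,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    margin_fraction: float = DEFAULT_MARGIN,
) -> ComponentRegistry:
    """Registry of desk-scale built-in components.

    The detector and segmenter are oracles reading the phantom manifest:
    the detector reports the manifest's lesion flag and the segmenter
    returns the ground-truth mask (loaded from ``data_dir`` or taken from
    in-memory records). The global scorer is a naive SVM over whole-image
    summaries, trained on lesion-free phantoms drawn from ``spec``.

    The registry is validated on the first manifest row before being
    returned.
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    spec = spec or PhantomSpec()
    by_id = manifest.set_index("id")
    records = manifest.attrs.get("records")
    record_by_id = (
        {row["id"]: rec for (_, row), rec in zip(manifest.iterrows(), records)}
        if records
        else {}
    )

    def _lookup(context: dict) -> pd.Series:
        image_id = context.get("id")
        if image_id is None or image_id not in by_id.index:
            raise KeyError(f"image id {image_id!r} not in manifest")
        return by_id.loc[image_id]

    def detector(image: np.ndarray, context: dict) -> bool:
        return bool(_lookup(context)["lesion"])

    def segmenter(image: np.ndarray, context: dict) -> np.ndarray:
        row = _lookup(context)
        image_id = context["id"]
        if image_id in record_by_id:
            return record_by_id[image_id].mask
        if data_dir is None:
            raise ValueError("oracle segmenter needs data_dir or in-memory records")
        return load_mask(Path(data_dir) / row["mask"])

    registry = ComponentRegistry(
        detector=detector,
        segmenter=segmenter,
        global_scorer=_train_global_scorer(spec, seed),
        local_model=local_model,
        margin_fraction=margin_fraction,
    )

    first = manifest.iloc[0]
    if first["id"] in record_by_id:
        probe = record_by_id[first["id"]].image
    elif data_dir is not None:
        from .image import load_gray

        probe = load_gray(Path(data_dir) / first["image"])
    else:
        raise ValueError("manifest carries neither records nor data_dir")
    registry.validate(probe, {"id": first["id"]})
    return registry
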