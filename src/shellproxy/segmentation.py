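"""Pixel segmentation of SEM backscatter images.

Two routes, mirroring the two statistics of the analysis:

* supervised random-forest pixel classification on a multi-scale feature bank
  (intensity, edges, texture) for per-entity masks, trained from sparse
  user-style labels (at least 10 labeled regions per class per image);
* global mean-gray-value thresholding for the coverage statistic — the mean
  intensity over the supplied image batch is the threshold, pixels strictly
  above it count as crystalline phase.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import measure as skmeasure
from sklearn.ensemble import RandomForestClassifier

from .io import SEMImage

logger = logging.getLogger("shellproxy.segmentation")

#: Conventional multi-scale ladder (pixels) of interactive pixel-classification tools.
DEFAULT_SCALES: tuple[float, ...] = (0.7, 1.0, 1.6, 3.5, 5.0)

#: Feature families computed at every scale (one feature each).
FEATURE_FAMILIES = (
    "gaussian",
    "gradient_magnitude",
    "laplacian_of_gaussian",
    "structure_tensor_max_eig",
    "hessian_max_eig",
)


@dataclass
class FeatureStack:
    """Per-pixel feature vectors: raw intensity + 5 families x n scales."""

    features: np.ndarray  # (H, W, F) float32
    names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.features.shape[-1]

    def flat(self) -> np.ndarray:
        return self.features.reshape(-1, self.n_features)


@dataclass
class BinaryMask:
    """Per-pixel binary class assignment with its provenance."""

    mask: np.ndarray  # bool, same shape as the source image
    provenance: str  # "classifier" | "mean-threshold"
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PixelClassifier:
    """Trained random-forest pixel classifier (entity vs background)."""

    model: RandomForestClassifier
    scales: tuple[float, ...]
    classes: tuple[str, str] = ("entity", "background")
    n_label_regions: dict = field(default_factory=dict)
    seed: int = 0
    oob_accuracy: float | None = None


def _as_pixels(image: SEMImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, SEMImage) else np.asarray(image, dtype=float)


def compute_feature_stack(
    image: SEMImage | np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
) -> FeatureStack:
    """Compute the multi-scale per-pixel feature bank.

    Families per scale sigma (pixels): Gaussian-smoothed intensity, Gaussian
    gradient magnitude, Laplacian-of-Gaussian, largest structure-tensor
    eigenvalue, largest Hessian eigenvalue; plus the raw intensity.  Borders
    are handled by reflection, so the stack is deterministic and translation
    behaves as expected at the edges.
    """
    pixels = _as_pixels(image)
    if any(s <= 0 for s in scales):
        raise ValueError("feature scales must be positive")
    planes = [pixels.astype(np.float32)]
    names = ["raw"]
    for s in scales:
        smoothed = ndimage.gaussian_filter(pixels, s, mode="reflect")
        planes.append(smoothed.astype(np.float32))
        planes.append(
            ndimage.gaussian_gradient_magnitude(pixels, s, mode="reflect").astype(np.float32)
        )
        # the truncated LoG kernel has a small non-zero DC response; subtract
        # it so that constant images yield exactly zero
        r = int(4.0 * s + 0.5) * 2 + 1
        dc = float(ndimage.gaussian_laplace(np.ones((r, r)), s, mode="reflect")[r // 2, r // 2])
        log = ndimage.gaussian_laplace(pixels, s, mode="reflect") - dc * smoothed
        planes.append(log.astype(np.float32))
        st = skfeature.structure_tensor(pixels, sigma=s, mode="reflect")
        planes.append(skfeature.structure_tensor_eigenvalues(st)[0].astype(np.float32))
        hm = skfeature.hessian_matrix(
            pixels, sigma=s, mode="reflect", use_gaussian_derivatives=True
        )
        planes.append(skfeature.hessian_matrix_eigvals(hm)[0].astype(np.float32))
        names += [f"{fam}_s{s}" for fam in FEATURE_FAMILIES]
    stack = np.stack(planes, axis=-1)
    if not np.isfinite(stack).all():
        raise ValueError("non-finite feature values")
    return FeatureStack(features=stack, names=tuple(names))


def _count_label_regions(labels: np.ndarray, cls: int) -> int:
    return int(skmeasure.label(labels == cls, connectivity=2).max())


def train_pixel_classifier(
    images: list[SEMImage | np.ndarray],
    sparse_labels: list[np.ndarray],
    seed: int = 0,
    *,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    min_regions: int = 10,
    n_estimators: int = 100,
) -> PixelClassifier:
    """Train a seedable random forest from sparse per-pixel labels.

    ``sparse_labels[i]`` is an integer raster over ``images[i]``: 0 unlabeled,
    1 entity, 2 background.  Each class needs at least ``min_regions``
    connected label regions per training image.  Held-out performance is
    reported as the out-of-bag pixel accuracy.
    """
    if len(images) != len(sparse_labels) or not images:
        raise ValueError("need matching non-empty image and label lists")
    X_parts, y_parts = [], []
    region_counts: dict[str, list[int]] = {"entity": [], "background": []}
    for img, lab in zip(images, sparse_labels):
        pixels = _as_pixels(img)
        lab = np.asarray(lab)
        if lab.shape != pixels.shape:
            raise ValueError("label raster shape must match the image")
        for cls, name in ((1, "entity"), (2, "background")):
            n_reg = _count_label_regions(lab, cls)
            if n_reg == 0:
                raise ValueError(f"no labels supplied for class '{name}'")
            if n_reg < min_regions:
                raise ValueError(
                    f"class '{name}' has {n_reg} labeled regions; "
                    f"at least {min_regions} per image are required"
                )
            region_counts[name].append(n_reg)
        stack = compute_feature_stack(pixels, scales)
        sel = lab > 0
        X_parts.append(stack.features[sel])
        y_parts.append(lab[sel])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=int(seed),
        n_jobs=1,
        oob_score=True,
    )
    model.fit(X, y)
    clf = PixelClassifier(
        model=model,
        scales=tuple(scales),
        n_label_regions=region_counts,
        seed=int(seed),
        oob_accuracy=float(model.oob_score_),
    )
    logger.info(
        "trained pixel classifier on %d labeled pixels (OOB accuracy %.4f)",
        len(y),
        clf.oob_accuracy,
    )
    return clf


def predict_mask(
    classifier: PixelClassifier,
    image: SEMImage | np.ndarray,
    *,
    return_proba: bool = False,
) -> BinaryMask | tuple[BinaryMask, np.ndarray]:
    """Classify every pixel of ``image``; white = entity (majority class probability)."""
    if not isinstance(classifier, PixelClassifier) or not hasattr(classifier.model, "estimators_"):
        raise ValueError("classifier has not been trained")
    pixels = _as_pixels(image)
    stack = compute_feature_stack(pixels, classifier.scales)
    if stack.n_features != classifier.model.n_features_in_:
        raise ValueError(
            f"feature mismatch: image yields {stack.n_features} features, "
            f"classifier expects {classifier.model.n_features_in_}"
        )
    proba = classifier.model.predict_proba(stack.flat())
    entity_col = list(classifier.model.classes_).index(1)
    p_entity = proba[:, entity_col].reshape(pixels.shape)
    mask = BinaryMask(mask=p_entity > 0.5, provenance="classifier")
    if return_proba:
        return mask, p_entity.astype(np.float32)
    return mask


def binarize_mean_threshold(
    images: list[SEMImage] | SEMImage,
    *,
    per_image: bool = False,
) -> tuple[list[BinaryMask], float | list[float]]:
    """Binarize images at their mean gray value.

    By default a single global threshold — the mean intensity pooled over all
    supplied images — is applied to every image in the batch; ``per_image=True``
    instead thresholds each image at its own mean.  A pixel is white
    (crystalline phase) iff its intensity is strictly greater than the
    threshold, so a constant image yields no white pixels.
    """
    if isinstance(images, SEMImage):
        images = [images]
    if not images:
        raise ValueError("need at least one image")
    # exact (compensated) summation: the strict-inequality tie contract on
    # constant images must not depend on accumulation rounding
    import math

    if per_image:
        thresholds = [math.fsum(img.pixels.ravel()) / img.pixels.size for img in images]
        masks = [
            BinaryMask(mask=img.pixels > t, provenance="mean-threshold", threshold_value=t)
            for img, t in zip(images, thresholds)
        ]
        return masks, thresholds
    total = math.fsum(math.fsum(img.pixels.ravel()) for img in images)
    count = sum(img.pixels.size for img in images)
    threshold = total / count
    masks = [
        BinaryMask(mask=img.pixels > threshold, provenance="mean-threshold", threshold_value=threshold)
        for img in images
    ]
    return masks, threshold


def coverage(mask: BinaryMask | np.ndarray, exclusion: np.ndarray | None = None) -> float:
    """Percent of (non-excluded) pixels that are white.

    This is the coverage statistic: the share of the image occupied by the
    crystalline phase, as a lower bound given that entity rims fall below the
    mean-gray threshold.
    """
    m = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if exclusion is not None:
        exclusion = np.asarray(exclusion, dtype=bool)
        if exclusion.shape != m.shape:
            raise ValueError("exclusion mask shape must match")
        keep = ~exclusion
        if not keep.any():
            raise ValueError("all pixels excluded; coverage undefined")
        return 100.0 * float(m[keep].sum()) / float(keep.sum())
    return 100.0 * float(m.sum()) / float(m.size)


def save_classifier(classifier: PixelClassifier, path: str | Path) -> None:
    """Serialize classifier state (model, scales, seed, label counts) to one file."""
    with open(path, "wb") as fh:
        pickle.dump(classifier, fh)


def load_classifier(path: str | Path) -> PixelClassifier:
    with open(path, "rb") as fh:
        clf = pickle.load(fh)
    if not isinstance(clf, PixelClassifier):
        raise ValueError(f"{path} does not contain a PixelClassifier")
    return clf
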