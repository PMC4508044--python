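"""Reference segmentation + classification pipeline (the subject under test).

normalize (2%/98% quantiles) -> segment (Otsu threshold or Sobel edges with
morphological contour closing) -> postprocess (fill holes, opening, border
clearing, connected components) -> 8 region features -> Gaussian naive Bayes.

The eight features per object are: area, mean / max / min / median /
standard deviation of intensity, solidity and eccentricity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    binary_fill_holes,
    binary_opening,
)
from skimage.filters import sobel
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import clear_border

FEATURE_NAMES = (
    "area",
    "mean_intensity",
    "max_intensity",
    "min_intensity",
    "median_intensity",
    "std_intensity",
    "solidity",
    "eccentricity",
)


@dataclass
class SegmentationResult:
    """Foreground mask, instance labels and the resulting object count."""

    foreground: np.ndarray  # bool
    instances: np.ndarray  # int labels, 0 = background
    count: int


@dataclass
class BayesModel:
    """Gaussian naive Bayes: per-class feature means/variances and priors."""

    classes: np.ndarray  # sorted class ids
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), floored > 0
    priors: np.ndarray  # (n_classes,), sums to 1


def quantile_normalize(image: np.ndarray, p_lo: float = 2.0, p_hi: float = 98.0) -> np.ndarray:
    """Contrast-normalize by mapping the [p_lo, p_hi] percentile range to [0, 255].

    Values outside the range are clipped.  If the two percentiles coincide
    (e.g. a dominant constant background) the full min/max range is used
    instead; a truly constant image maps to all zeros.
    """
    if not p_lo < p_hi:
        raise ValueError("p_lo must be smaller than p_hi")
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, [p_lo, p_hi])
    if hi <= lo:
        lo, hi = img.min(), img.max()
        if hi <= lo:
            return np.zeros_like(img)
    return np.clip((img - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def otsu_threshold(image: np.ndarray) -> float:
    """Threshold maximizing between-class variance over a 256-bin histogram.

    Gray values are binned over [0, 255]; the returned threshold is the
    upper edge of the best background bin, so foreground is ``image >
    threshold``.  Ties take the lowest threshold.  A constant image has no
    valid split and raises ``ValueError``.
    """
    img = np.asarray(image, dtype=float)
    if np.unique(img).size < 2:
        raise ValueError("Otsu threshold is undefined for a constant image")
    hist, edges = np.histogram(img, bins=256, range=(0.0, 255.0))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]  # background weight for split after bin t
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)
    mu_total = cum_mean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean[:-1] / w0
        mu1 = (mu_total - cum_mean[:-1]) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    t = int(np.argmax(between))
    return float(edges[t + 1])


_SE3 = np.ones((3, 3), dtype=bool)


def segment_otsu(image: np.ndarray) -> np.ndarray:
    """Binary foreground by Otsu thresholding (strictly above the threshold)."""
    img = np.asarray(image, dtype=float)
    try:
        thresh = otsu_threshold(img)
    except ValueError:
        return np.zeros(img.shape, dtype=bool)
    return img > thresh


def segment_sobel(image: np.ndarray) -> np.ndarray:
    """Binary foreground from Sobel edges.

    Otsu-thresholds the Sobel gradient magnitude, dilates twice (3x3) to
    close broken contours, fills the enclosed holes and erodes twice to
    restore the object scale.  A constant image yields an empty mask.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("Sobel segmentation needs a 2-d image of at least 3x3")
    grad = sobel(img)
    if np.unique(grad).size < 2:
        return np.zeros(img.shape, dtype=bool)
    # gradient values live well below 255; threshold on the gradient's own range
    gmax = grad.max()
    edges = grad > otsu_threshold(grad * (255.0 / gmax)) * (gmax / 255.0)
    closed = binary_dilation(edges, structure=_SE3, iterations=2)
    filled = binary_fill_holes(closed)
    return binary_erosion(filled, structure=_SE3, iterations=2)


def postprocess(binary: np.ndarray) -> SegmentationResult:
    """Clean a raw foreground mask into labeled objects.

    Fill holes, open with a 3x3 square (removes specks), drop components
    touching the image border, then label 8-connected components.
    """
    mask = np.asarray(binary, dtype=bool)
    filled = binary_fill_holes(mask)
    opened = binary_opening(filled, structure=_SE3)
    cleared = clear_border(opened)
    labels = cc_label(cleared, connectivity=2)
    return SegmentationResult(
        foreground=labels > 0, instances=labels, count=int(labels.max())
    )


def extract_features(labels: np.ndarray, image: np.ndarray) -> pd.DataFrame:
    """Eight features per labeled region, indexed by instance id.

    Eccentricity comes from the region's equivalent ellipse (foci distance
    over major axis: 0 = circle, 1 = line segment); solidity is area over
    convex-hull area.
    """
    lab = np.asarray(labels)
    img = np.asarray(image, dtype=float)
    if lab.shape != img.shape:
        raise ValueError("label grid and image must have the same shape")
    rows = []
    for rp in regionprops(lab, intensity_image=img):
        vals = img[tuple(rp.coords.T)]
        rows.append(
            {
                "instance_id": rp.label,
                "area": float(rp.area),
                "mean_intensity": float(vals.mean()),
                "max_intensity": float(vals.max()),
                "min_intensity": float(vals.min()),
                "median_intensity": float(np.median(vals)),
                "std_intensity": float(vals.std()),
                "solidity": float(rp.solidity),
                "eccentricity": float(rp.eccentricity),
            }
        )
    df = pd.DataFrame(rows, columns=["instance_id", *FEATURE_NAMES])
    return df.set_index("instance_id")


def train_bayes(features: pd.DataFrame, classes) -> BayesModel:
    """Fit a Gaussian naive Bayes model with empirical priors.

    Per-class diagonal variances are floored at 1e-6 of each feature's
    global variance (itself floored at 1e-12) so single-example classes and
    constant features stay usable.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(classes)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training needs a non-empty 2-d feature table")
    if len(y) != len(X):
        raise ValueError("features and class labels differ in length")
    class_ids = np.unique(y)
    global_var = np.maximum(X.var(axis=0), 1e-12)
    floor = 1e-6 * global_var
    means = np.empty((len(class_ids), X.shape[1]))
    variances = np.empty_like(means)
    priors = np.empty(len(class_ids))
    for i, c in enumerate(class_ids):
        Xc = X[y == c]
        means[i] = Xc.mean(axis=0)
        variances[i] = np.maximum(Xc.var(axis=0), floor)
        priors[i] = len(Xc) / len(X)
    return BayesModel(classes=class_ids, means=means, variances=variances, priors=priors)


def classify(model: BayesModel, features: pd.DataFrame) -> np.ndarray:
    """Maximum-posterior class per row; ties go to the smaller class id."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model "
            f"({model.means.shape[1]})"
        )
    # log posterior up to a constant: log prior + sum log N(x; mu, var)
    log_post = np.log(model.priors)[None, :] - 0.5 * (
        np.log(2.0 * np.pi * model.variances).sum(axis=1)[None, :]
        + (
            ((X[:, None, :] - model.means[None, :, :]) ** 2) / model.variances[None, :, :]
        ).sum(axis=2)
    )
    # argmax returns the first (= smallest class id) maximum, the tie-break rule
    return model.classes[np.argmax(log_post, axis=1)]


def train_on_clean_scene(clean, method_normalize: bool = True) -> BayesModel:
    """Train the classifier on a scene's ground-truth objects.

    Features are taken from the true instance regions of the clean
    (undistorted) image, normalized exactly as the pipeline normalizes its
    input, and labeled with the true classes.
    """
    img = quantile_normalize(clean.image) if method_normalize else clean.image
    feats = extract_features(clean.truth_instances, img)
    class_of = dict(
        zip(clean.object_table["instance_id"], clean.object_table["class_id"])
    )
    y = np.array([class_of[i] for i in feats.index])
    return train_bayes(feats, y)


def run_pipeline(
    image: np.ndarray, method: str, model: BayesModel
) -> tuple[SegmentationResult, dict[int, int]]:
    """Segment and classify one image; returns labels plus class per instance.

    ``method`` selects the segmentation stage: ``"otsu"`` (threshold on
    intensity) or ``"sobel"`` (edge-based).  The classifier must have been
    trained on features extracted from an identically normalized image.
    """
    if method not in ("otsu", "sobel"):
        raise ValueError(f"method must be 'otsu' or 'sobel', got {method!r}")
    norm = quantile_normalize(np.asarray(image, dtype=float))
    fg = segment_otsu(norm) if method == "otsu" else segment_sobel(norm)
    seg = postprocess(fg)
    if seg.count == 0:
        return seg, {}
    feats = extract_features(seg.instances, norm)
    predicted = classify(model, feats)
    return seg, {int(i): int(c) for i, c in zip(feats.index, predicted)}
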