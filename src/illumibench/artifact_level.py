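"""Fuzzy artifact level A in [0, 1] aggregating shading and noise distortion.

Shading is quantified by the mean pixel value of an image (dark means
shaded), noise by the standard deviation sigma of the additive Gaussian
noise.  Each raw quantity is passed through a monotone fuzzification
function mu in [0, 1] with tunable lower/upper bounds (alpha, beta) that
saturate outliers; the two memberships are then aggregated (arithmetic mean
by default) into the artifact level A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .benchmark_generator import NOISE_VARIANCE_STEP


@dataclass(frozen=True)
class FuzzyBounds:
    """Transition band of the fuzzification: mu = 0 below alpha, 1 above beta."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha < self.beta:
            raise ValueError(
                f"fuzzy bounds require alpha < beta, got ({self.alpha}, {self.beta})"
            )


#: Default transition band on the image mean: below 40 fully shaded, above 140 unshaded.
DEFAULT_SHADING_BOUNDS = FuzzyBounds(40.0, 140.0)
#: Default band on sigma: 0 (clean) to the top of the 14-grade schedule, sqrt(125*13).
DEFAULT_NOISE_BOUNDS = FuzzyBounds(0.0, math.sqrt(NOISE_VARIANCE_STEP * 13))


@dataclass(frozen=True)
class ArtifactConfig:
    shading_bounds: FuzzyBounds = DEFAULT_SHADING_BOUNDS
    noise_bounds: FuzzyBounds = DEFAULT_NOISE_BOUNDS
    aggregator: str = "mean"

    def __post_init__(self) -> None:
        if self.aggregator not in ("mean", "max"):
            raise ValueError(f"aggregator must be 'mean' or 'max', got {self.aggregator!r}")


@dataclass(frozen=True)
class ArtifactScore:
    """Shading and noise memberships and their aggregate A, all in [0, 1]."""

    mu_shading: float
    mu_noise: float
    A: float


def fuzzy_membership(x, bounds: FuzzyBounds):
    """Monotone cubic-smoothstep membership: 0 below alpha, 1 above beta.

    Between the bounds the value is ``3 t^2 - 2 t^3`` with
    ``t = (x - alpha) / (beta - alpha)`` — the simplest C1 spline that
    saturates at both ends.  Accepts scalars or arrays.
    """
    t = np.clip((np.asarray(x, dtype=float) - bounds.alpha) / (bounds.beta - bounds.alpha), 0.0, 1.0)
    mu = 3.0 * t * t - 2.0 * t * t * t
    return float(mu) if np.isscalar(x) or np.ndim(x) == 0 else mu


def shading_level(image: np.ndarray, bounds: FuzzyBounds = DEFAULT_SHADING_BOUNDS) -> float:
    """Shading membership of an image: darker mean gray value scores higher.

    Defined as ``1 - mu(mean(image))`` so an all-bright image scores 0 and
    an all-black image 1.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("cannot score an empty image")
    return 1.0 - fuzzy_membership(img.mean(), bounds)


def noise_level(sigma: float, bounds: FuzzyBounds = DEFAULT_NOISE_BOUNDS) -> float:
    """Noise membership of a Gaussian noise standard deviation."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    return fuzzy_membership(sigma, bounds)


# Immerkaer's second-difference kernel; applied to iid N(0, sigma^2) pixels the
# response has variance 36 sigma^2, so sigma = MAD(residual) / (0.6745 * 6).
_NOISE_KERNEL = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust noise sigma estimate for images whose true sigma is unknown.

    High-pass residual (second-difference kernel) scaled to a Gaussian sigma
    through the median absolute deviation, so edges and offsets contribute
    little.  Requires at least a 16x16 image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("noise estimation needs a 2-d image of at least 16x16 pixels")
    resid = convolve(img, _NOISE_KERNEL, mode="reflect")
    inner = resid[1:-1, 1:-1]  # drop border pixels touched by reflection
    mad = np.median(np.abs(inner - np.median(inner)))
    return float(mad / (0.6745 * 6.0))


def artifact(
    image: np.ndarray,
    sigma: float | str = "estimate",
    config: ArtifactConfig | None = None,
) -> ArtifactScore:
    """Score an image's distortion level.

    ``sigma`` is the known noise standard deviation (use the benchmark
    manifest when available) or the string ``"estimate"`` to measure it from
    the image.  Returns the two memberships and their aggregate A.
    """
    config = config or ArtifactConfig()
    if isinstance(sigma, str):
        if sigma != "estimate":
            raise ValueError(f"sigma must be a number or 'estimate', got {sigma!r}")
        sigma_val = estimate_noise_sigma(image)
    else:
        sigma_val = float(sigma)
    mu_s = shading_level(image, config.shading_bounds)
    mu_n = noise_level(sigma_val, config.noise_bounds)
    A = max(mu_s, mu_n) if config.aggregator == "max" else 0.5 * (mu_s + mu_n)
    return ArtifactScore(mu_shading=mu_s, mu_noise=mu_n, A=A)
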