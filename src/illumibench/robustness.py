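"""Robustness: quality aggregated over a sweep of increasing distortion.

The canonical sweep is the diagonal series X(r, k, k+1), k = 1..B, where
shading and noise grow together.  The robustness statistic R is the mean of
the total quality Q along the series; the area under the Q-vs-A curve is an
optional alternative summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .artifact_level import ArtifactConfig, artifact
from .benchmark_generator import (
    CleanScene,
    DistortionGrid,
    SceneSpec,
    ShadingModel,
    add_noise,
    apply_shading,
    noise_sigma,
    render_scene,
    to_uint8,
)
from .pipeline import run_pipeline, train_on_clean_scene
from .quality import QualityConfig, score_result


@dataclass(frozen=True)
class SeriesSpec:
    """An ordered list of (b, n) grid cells of one scene to sweep."""

    scene_id: int
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ValueError("a series needs at least one (b, n) pair")


@dataclass
class RobustnessResult:
    """R plus the per-point (b, n, A, Q) table behind it."""

    R: float
    table: pd.DataFrame  # columns b, n, A, m1, m2, m3, Q
    auc: float | None = None


def diagonal_series(B: int) -> list[tuple[int, int]]:
    """The diagonal sweep [(1, 2), (2, 3), ..., (B, B+1)]."""
    if B < 1:
        raise ValueError(f"series length must be >= 1, got {B}")
    return [(b, b + 1) for b in range(1, B + 1)]


def robustness_mean(q_values) -> float:
    """R: the arithmetic mean of the quality values along the series."""
    q = np.asarray(list(q_values), dtype=float)
    if q.size == 0:
        raise ValueError("robustness needs at least one quality value")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("quality values must lie in [0, 1]")
    return float(q.mean())


def robustness_auc(a_values, q_values) -> float:
    """Normalized area under the Q-vs-A curve (trapezoidal).

    Points are sorted by A; the area is divided by the A-range so a flat
    Q = 1 curve scores 1 regardless of the artifact span.
    """
    a = np.asarray(list(a_values), dtype=float)
    q = np.asarray(list(q_values), dtype=float)
    if a.shape != q.shape or a.size < 2:
        raise ValueError("AUC needs two equally long lists of at least 2 points")
    order = np.argsort(a)
    a, q = a[order], q[order]
    span = a[-1] - a[0]
    if span <= 0:
        raise ValueError("AUC is undefined over a degenerate artifact range")
    if np.unique(a).size != a.size:
        raise ValueError("artifact values must be strictly increasing after sorting")
    return float(np.trapezoid(q, a) / span)


def evaluate_series(
    clean: CleanScene,
    series: SeriesSpec,
    method: str,
    shading_model: ShadingModel,
    seed: int = 42,
    artifact_config: ArtifactConfig | None = None,
    quality_config: QualityConfig | None = None,
    compute_auc: bool = False,
) -> RobustnessResult:
    """Run a pipeline over a distortion series of one scene and aggregate.

    The classifier is trained once on the clean scene's ground truth; each
    (b, n) point is then distorted in memory (shade, add noise, quantize to
    8 bit), scored for artifact level (using the known noise sigma) and for
    quality against the shared ground truth.
    """
    model = train_on_clean_scene(clean)
    truth_classes = dict(
        zip(clean.object_table["instance_id"], clean.object_table["class_id"])
    )
    rows = []
    for b, n in series.pairs:
        shaded = apply_shading(clean.image, b, shading_model)
        distorted = to_uint8(add_noise(shaded, n, seed, r=series.scene_id, b=b))
        score_a = artifact(distorted, sigma=noise_sigma(n), config=artifact_config)
        seg, predicted = run_pipeline(distorted, method, model)
        qs = score_result(
            seg.instances, predicted, clean.truth_instances, truth_classes, quality_config
        )
        rows.append(
            {"b": b, "n": n, "A": score_a.A, "m1": qs.m1, "m2": qs.m2, "m3": qs.m3, "Q": qs.Q}
        )
    table = pd.DataFrame(rows)
    R = robustness_mean(table["Q"])
    auc = None
    if compute_auc and table["A"].nunique() == len(table) and len(table) >= 2:
        auc = robustness_auc(table["A"], table["Q"])
    return RobustnessResult(R=R, table=table, auc=auc)


def evaluate_diagonal(
    scene: SceneSpec | CleanScene,
    method: str,
    grid: DistortionGrid | None = None,
    shading_model: ShadingModel | None = None,
    seed: int = 42,
    scene_id: int = 1,
    **kwargs,
) -> RobustnessResult:
    """Convenience wrapper: evaluate a pipeline on a scene's diagonal series."""
    grid = grid or DistortionGrid()
    shading_model = shading_model or ShadingModel.linear(grid.B)
    if isinstance(scene, SceneSpec):
        scene_id = scene.scene_id
        clean = render_scene(scene)
    else:
        clean = scene
    series = SeriesSpec(scene_id=scene_id, pairs=tuple(diagonal_series(grid.B)))
    return evaluate_series(clean, series, method, shading_model, seed=seed, **kwargs)
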