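"""Quality scoring of a segmentation + classification result against truth.

Three measures, each in [0, 1]:

* ``m1`` (count): agreement between detected and true object counts,
  ``max(0, 1 - |O_det - O_truth| / O_truth)``.
* ``m2`` (overlap): Jaccard index of detected vs true foreground pixels.
* ``m3`` (classification): fraction of ground-truth objects whose matched
  detection carries the correct class; unmatched truth objects count as
  errors.

The total quality ``Q`` passes each measure through an optional fuzzy
membership (identity by default) and combines them as a weighted mean.
Object correspondence uses a greedy one-to-one matching by descending pixel
overlap; any positive overlap qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .artifact_level import FuzzyBounds, fuzzy_membership


@dataclass
class Matching:
    """One-to-one detected/truth object correspondence by pixel overlap."""

    pairs: list[tuple[int, int, int]]  # (detected_id, truth_id, overlap_px)
    unmatched_detected: list[int]
    unmatched_truth: list[int]


@dataclass(frozen=True)
class QualityConfig:
    """Weights and optional per-measure fuzzification of the total quality."""

    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    bounds_m1: FuzzyBounds | None = None  # None = identity
    bounds_m2: FuzzyBounds | None = None
    bounds_m3: FuzzyBounds | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be three non-negative values summing to 1")


@dataclass(frozen=True)
class QualityScore:
    m1: float
    m2: float
    m3: float
    Q: float


def match_objects(detected: np.ndarray, truth: np.ndarray) -> Matching:
    """Greedily pair detected and truth instances by descending pixel overlap.

    Each instance appears in at most one pair and pairs require at least one
    shared pixel.  Ties are broken toward smaller (overlap-first) ids so the
    matching is deterministic.
    """
    det = np.asarray(detected)
    tru = np.asarray(truth)
    if det.shape != tru.shape:
        raise ValueError(f"label grids differ in shape: {det.shape} vs {tru.shape}")
    both = (det > 0) & (tru > 0)
    det_ids = [int(i) for i in np.unique(det) if i > 0]
    tru_ids = [int(i) for i in np.unique(tru) if i > 0]
    # overlap counts via a joint histogram of co-occurring label pairs
    overlaps: dict[tuple[int, int], int] = {}
    if both.any():
        pair_codes = det[both].astype(np.int64) * (int(tru.max()) + 1) + tru[both].astype(np.int64)
        codes, counts = np.unique(pair_codes, return_counts=True)
        base = int(tru.max()) + 1
        for code, cnt in zip(codes, counts):
            overlaps[(int(code // base), int(code % base))] = int(cnt)
    candidates = sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
    used_det: set[int] = set()
    used_tru: set[int] = set()
    pairs = []
    for (d, t), cnt in candidates:
        if d in used_det or t in used_tru:
            continue
        pairs.append((d, t, cnt))
        used_det.add(d)
        used_tru.add(t)
    return Matching(
        pairs=pairs,
        unmatched_detected=[d for d in det_ids if d not in used_det],
        unmatched_truth=[t for t in tru_ids if t not in used_tru],
    )


def count_measure(o_detected: int, o_truth: int) -> float:
    """Object-count agreement: 1 for an exact count, 0 at a 100% miscount."""
    if o_truth < 1:
        raise ValueError("count measure needs at least one ground-truth object")
    if o_detected < 0:
        raise ValueError("detected count cannot be negative")
    return max(0.0, 1.0 - abs(o_detected - o_truth) / o_truth)


def overlap_measure(detected_fg: np.ndarray, truth_fg: np.ndarray) -> float:
    """Jaccard index of the detected vs true foreground pixel sets."""
    d = np.asarray(detected_fg, dtype=bool)
    t = np.asarray(truth_fg, dtype=bool)
    if d.shape != t.shape:
        raise ValueError(f"masks differ in shape: {d.shape} vs {t.shape}")
    if not t.any():
        raise ValueError("overlap measure needs a non-empty truth foreground")
    inter = int(np.count_nonzero(d & t))
    union = int(np.count_nonzero(d | t))
    return inter / union


def classification_measure(
    matching: Matching,
    predicted: Mapping[int, int],
    truth_classes: Mapping[int, int],
    o_truth: int,
) -> float:
    """Fraction of ground-truth objects classified correctly via their match.

    A truth object scores only if it was matched to a detection whose
    predicted class equals the true class; unmatched truth objects are
    errors.  False-positive detections do not enter here (they are penalized
    through the count and overlap measures).
    """
    if o_truth < 1:
        raise ValueError("classification measure needs at least one ground-truth object")
    correct = sum(
        1
        for d, t, _ in matching.pairs
        if d in predicted and t in truth_classes and predicted[d] == truth_classes[t]
    )
    return correct / o_truth


def total_quality(
    m1: float, m2: float, m3: float, config: QualityConfig | None = None
) -> QualityScore:
    """Fuzzify the three measures and combine them into Q (weighted mean)."""
    config = config or QualityConfig()
    for name, v in (("m1", m1), ("m2", m2), ("m3", m3)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    mus = [
        fuzzy_membership(v, b) if b is not None else v
        for v, b in ((m1, config.bounds_m1), (m2, config.bounds_m2), (m3, config.bounds_m3))
    ]
    q = float(np.dot(config.weights, mus))
    return QualityScore(m1=m1, m2=m2, m3=m3, Q=q)


def score_result(
    detected_instances: np.ndarray,
    predicted_classes: Mapping[int, int],
    truth_instances: np.ndarray,
    truth_object_classes: Mapping[int, int],
    config: QualityConfig | None = None,
) -> QualityScore:
    """Full scoring of a labeled detection against instance-level truth."""
    o_truth = int(len(truth_object_classes))
    matching = match_objects(detected_instances, truth_instances)
    o_det = int(np.count_nonzero(np.unique(detected_instances)))
    m1 = count_measure(o_det, o_truth)
    m2 = overlap_measure(detected_instances > 0, truth_instances > 0)
    m3 = classification_measure(matching, predicted_classes, truth_object_classes, o_truth)
    return total_quality(m1, m2, m3, config)
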