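"""12-point skeleton extraction from silhouettes and keypoint evaluation.

The skeleton model is a fixed, named set of 12 body points (head, shoulders,
elbows, wrists, torso, knees, ankles).  Extraction is purely geometric — no
learned pose estimator — driven by the distance transform and medial axis of
the largest silhouette component.  Detected points are scored against ground
truth with a scaled Euclidean distance

    D_j = sqrt( sum_n (X_n S_n - Y_n S_n)^2 )

and a point counts as recognised in a frame when D_j <= threshold
(15 px at 640x480; scale proportionally for other resolutions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import skeletonize

from .errors import EvaluationError, ExtractionError, ParameterError

#: Canonical point order; evaluation tables use exactly this set.
POINT_NAMES = (
    "head",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "torso",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Recognition-distance threshold in pixels at 640x480.
DEFAULT_THRESHOLD_PX = 15.0


@dataclass
class SkeletonFrame:
    """Detected skeleton for one frame.

    ``points`` is a [12, 2] float array of (x, y) pixel coordinates in
    POINT_NAMES order; a missing point is (nan, nan).  ``confidence`` holds
    one value in [0, 1] per point: the distance-transform value at the point
    relative to the component's maximum, so points deep inside the silhouette
    (torso) score high and points on thin or clipped limbs score low.
    """

    points: np.ndarray
    confidence: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(len(POINT_NAMES), 2)
        self.confidence = np.clip(np.asarray(self.confidence, dtype=float), 0.0, 1.0)
        if self.confidence.shape != (len(POINT_NAMES),):
            raise ParameterError("confidence must have one value per skeleton point")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame_index,
                "point_name": POINT_NAMES,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "confidence": self.confidence,
            }
        )


def _medial_endpoints(axis: np.ndarray) -> np.ndarray:
    """Endpoints of the medial axis: skeleton pixels with <= 1 skeleton neighbour."""
    nb = ndimage.convolve(axis.astype(int), np.ones((3, 3), int), mode="constant")
    ys, xs = np.nonzero(axis & (nb <= 2))  # self + at most one neighbour
    return np.column_stack([xs, ys]).astype(float)


def extract_skeleton(
    mask: np.ndarray, frame_index: int = 0, min_area: int = 200
) -> SkeletonFrame:
    """Extract the 12-point skeleton from a binary silhouette.

    Deterministic geometric procedure on the largest connected component:
    the torso sits at the distance-transform maximum; the head at the local
    distance-transform maximum of the top band of the figure; shoulders on
    the medial axis in a row band one fifth of body height below the head;
    wrists and ankles at the extremal medial-axis endpoints of the four
    quadrants around the torso; elbows and knees at the midpoints between
    their proximal and distal neighbours.  Left/right follow image-x order.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ExtractionError("empty silhouette mask")
    lab, n_comp = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1]
    if len(order) > 1 and sizes[order[0]] == sizes[order[1]]:
        raise ExtractionError("multiple equal-size foreground components")
    comp = lab == (order[0] + 1)
    area = int(sizes[order[0]])
    if area < min_area:
        raise ExtractionError(f"largest component has {area} px < {min_area}")

    dist = ndimage.distance_transform_edt(comp)
    dmax = float(dist.max())
    axis = skeletonize(comp)
    ys, xs = np.nonzero(comp)
    top, bottom = ys.min(), ys.max()
    height = bottom - top + 1

    ty, tx = np.unravel_index(np.argmax(dist), dist.shape)
    torso = np.array([tx, ty], dtype=float)

    # Head: local distance-transform maximum of the top band (the head disk
    # centre), more stable than the topmost axis pixel which sits on the rim.
    band = np.zeros_like(comp)
    band[top: top + max(2, height // 6), :] = True
    head_region = dist * (comp & band)
    hy, hx = np.unravel_index(np.argmax(head_region), head_region.shape)
    head = np.array([hx, hy], dtype=float)

    # Shoulders: medial-axis extrema in a band ~1/5 body height below the head.
    srow = int(head[1] + 0.2 * height)
    half = max(2, height // 20)
    ay, ax_ = np.nonzero(axis)
    # cap the lateral search so a near-horizontal arm cannot masquerade as
    # a shoulder: anthropometric shoulder half-width stays below ~0.15 height
    in_band = ((ay >= srow - half) & (ay <= srow + half)
               & (np.abs(ax_ - torso[0]) < 0.16 * height))
    if in_band.any():
        bx, by = ax_[in_band], ay[in_band]
        l_i, r_i = np.argmin(bx), np.argmax(bx)
        lsho = np.array([bx[l_i], by[l_i]], dtype=float)
        rsho = np.array([bx[r_i], by[r_i]], dtype=float)
    else:  # very short figure: fall back to points beside the torso
        lsho = torso + [-0.15 * height, -0.25 * height]
        rsho = torso + [0.15 * height, -0.25 * height]

    # Extremities: medial-axis endpoints, split into quadrants around the torso.
    ends = _medial_endpoints(axis)
    nan2 = np.full(2, np.nan)

    def _pick(cands: np.ndarray, key) -> np.ndarray:
        if len(cands) == 0:
            return nan2.copy()
        return cands[np.argmax([key(c) for c in cands])]

    upper = ends[ends[:, 1] < torso[1]]
    lower = ends[ends[:, 1] >= torso[1]]
    # exclude the head-top endpoint from wrist candidates
    if len(upper):
        upper = upper[np.linalg.norm(upper - head, axis=1) > 0.12 * height]
    lwri = _pick(upper[upper[:, 0] < torso[0]] if len(upper) else upper,
                 lambda c: np.linalg.norm(c - lsho))
    rwri = _pick(upper[upper[:, 0] >= torso[0]] if len(upper) else upper,
                 lambda c: np.linalg.norm(c - rsho))
    lank = _pick(lower[lower[:, 0] < torso[0]] if len(lower) else lower,
                 lambda c: c[1])
    rank = _pick(lower[lower[:, 0] >= torso[0]] if len(lower) else lower,
                 lambda c: c[1])

    # Hip band anchors for the legs: just below the torso point.
    lhip = torso + [-0.08 * height, 0.12 * height]
    rhip = torso + [0.08 * height, 0.12 * height]
    lelb = (lsho + lwri) / 2.0
    relb = (rsho + rwri) / 2.0
    lkne = (lhip + lank) / 2.0
    rkne = (rhip + rank) / 2.0

    pts = np.array(
        [head, lsho, rsho, lelb, relb, lwri, rwri, torso, lkne, rkne, lank, rank]
    )

    conf = np.zeros(len(POINT_NAMES))
    h_img, w_img = comp.shape
    for i, p in enumerate(pts):
        if np.any(np.isnan(p)):
            continue
        x = int(np.clip(round(p[0]), 0, w_img - 1))
        y = int(np.clip(round(p[1]), 0, h_img - 1))
        conf[i] = dist[y, x] / dmax if dmax > 0 else 0.0
    return SkeletonFrame(points=pts, confidence=conf, frame_index=frame_index)


def point_distance(
    x: Sequence[float], y: Sequence[float], s: Optional[Sequence[float]] = None
) -> float:
    """Scaled Euclidean distance between detected and ground-truth coordinates.

    With the per-component scale S = 1 this is the plain Euclidean pixel
    distance; a scale vector lets callers normalise for resolution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.ones_like(x) if s is None else np.asarray(s, dtype=float)
    if x.shape != y.shape or x.shape != s.shape:
        raise ParameterError(
            f"dimension mismatch: X{x.shape}, Y{y.shape}, S{s.shape}"
        )
    if np.any(s <= 0):
        raise ParameterError("scale factors must be positive")
    return float(np.sqrt(np.sum((x * s - y * s) ** 2)))


def _aligned_distances(
    detected: Sequence[SkeletonFrame],
    truth: Sequence[np.ndarray],
    scale: Optional[np.ndarray] = None,
) -> np.ndarray:
    """[frames, points] distance matrix; nan where the detection is missing."""
    if len(detected) == 0 or len(detected) != len(truth):
        raise EvaluationError(
            f"need equal, non-zero frame counts (got {len(detected)} vs {len(truth)})"
        )
    n_pts = len(POINT_NAMES)
    out = np.full((len(detected), n_pts), np.nan)
    for f, (det, gt) in enumerate(zip(detected, truth)):
        gt = np.asarray(gt, dtype=float).reshape(n_pts, 2)
        for j in range(n_pts):
            if np.any(np.isnan(det.points[j])) or np.any(np.isnan(gt[j])):
                continue
            out[f, j] = point_distance(det.points[j], gt[j], scale)
    return out


def recognition_accuracy(
    detected: Sequence[SkeletonFrame],
    truth: Sequence[np.ndarray],
    threshold: float = DEFAULT_THRESHOLD_PX,
    scale: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Per-point fraction of frames with distance <= threshold, plus the mean.

    Missing detections count as failures; the mean is the unweighted average
    over the 12 points.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    d = _aligned_distances(detected, truth, scale)
    hits = np.where(np.isnan(d), False, d <= threshold)
    per_point = hits.mean(axis=0)
    return per_point, float(per_point.mean())


def confidence_table(
    detected: Sequence[SkeletonFrame],
    truth: Sequence[np.ndarray],
    threshold: float = DEFAULT_THRESHOLD_PX,
    scale: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-point summary: mean confidence, mean distance, recognition accuracy.

    Mirrors the standard keypoint-evaluation layout: one row per named point
    and a final ``mean`` row with the unweighted column averages rounded to
    two decimals.
    """
    d = _aligned_distances(detected, truth, scale)
    per_point, _ = recognition_accuracy(detected, truth, threshold, scale)
    conf = np.stack([f.confidence for f in detected])
    with np.errstate(invalid="ignore"):
        mean_d = np.nanmean(d, axis=0)
    rows = pd.DataFrame(
        {
            "point_name": POINT_NAMES,
            "confidence": conf.mean(axis=0),
            "distance": mean_d,
            "recognition_accuracy": per_point,
        }
    )
    mean_row = pd.DataFrame(
        {
            "point_name": ["mean"],
            "confidence": [round(float(rows["confidence"].mean()), 2)],
            "distance": [round(float(np.nanmean(rows["distance"])), 2)],
            "recognition_accuracy": [round(float(rows["recognition_accuracy"].mean()), 2)],
        }
    )
    return pd.concat([rows, mean_row], ignore_index=True)
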