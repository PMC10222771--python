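"""Per-modality feature families.

Three extractors, one per sensor modality:

* **Pearson gate** (ambient): pairwise correlation of the ambient channels
  inside a window; a window whose mean absolute correlation exceeds a small
  threshold (0.04) is flagged as "action performed" — co-activity across
  switches/PIR channels is what distinguishes an action from idle drift.
* **LPCC** (inertial): linear-prediction cepstral coefficients per channel.
  The LPC coefficients a_x come from the autocorrelation normal equations
  (Levinson-Durbin); the cepstral recursion is

      c_x = a_x + sum_{t=1}^{x-1} (t/x) c_t a_{x-t}   for 1 <= x <= p
      c_x =       sum_{t=1}^{x-1} (t/x) c_t a_{x-t}   for p <  x <= d

  with out-of-range a indices treated as zero.
* **SLIF** (vision): spider local image features — silhouette occupancy
  sampled on a polar web of rings and spokes anchored at each skeleton
  point, spoke z of ring radius x sitting at
  (x cos(2 pi z / Z), x sin(2 pi z / Z)) from the anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from statsmodels.tsa.stattools import levinson_durbin

from .errors import ParameterError
from .preprocessing import SignalWindow
from .skeleton import POINT_NAMES, SkeletonFrame

logger = logging.getLogger(__name__)

#: Mean |PC| above which a window counts as "action performed".
DEFAULT_PC_THRESHOLD = 0.04


@dataclass
class PearsonGateResult:
    """Outcome of the windowed ambient-correlation gate."""

    pc_matrix: np.ndarray  # [channels, channels], symmetric, unit diagonal
    mean_abs_pc: float
    action_flag: bool
    threshold: float = DEFAULT_PC_THRESHOLD
    degenerate: bool = False

    @property
    def feature_vector(self) -> np.ndarray:
        """Upper-triangle correlations + mean |PC| + flag, ready for fusion."""
        iu = np.triu_indices(self.pc_matrix.shape[0], k=1)
        return np.concatenate(
            [self.pc_matrix[iu], [self.mean_abs_pc, float(self.action_flag)]]
        )


@dataclass
class LPCCConfig:
    """LPC order p and cepstral coefficient count d (d >= p)."""

    p: int = 10
    d: int = 12

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ParameterError("LPC order p must be >= 1")
        if self.d < self.p:
            raise ParameterError("need d >= p cepstral coefficients")


@dataclass
class SpiderWebConfig:
    """Geometry of the spider web: ring radii, spokes, anchor points."""

    rings: tuple = (8.0, 16.0, 32.0)
    spokes: int = 16
    anchors: tuple = POINT_NAMES

    def __post_init__(self) -> None:
        radii = np.asarray(self.rings, dtype=float)
        if len(radii) == 0 or np.any(np.diff(radii) <= 0) or radii[0] <= 0:
            raise ParameterError("ring radii must be positive and strictly increasing")
        if self.spokes < 4:
            raise ParameterError("need at least 4 spokes")
        unknown = set(self.anchors) - set(POINT_NAMES)
        if unknown:
            raise ParameterError(f"unknown anchor point names: {sorted(unknown)}")

    @property
    def block_size(self) -> int:
        """Per-anchor descriptor length: occupancy samples + 1 fraction."""
        return len(self.rings) * self.spokes + 1


def pearson_correlation(g: Sequence[float], h: Sequence[float]) -> float:
    """Pearson correlation of two equal-length windows.

    Returns sum((g-gbar)(h-hbar)) / sqrt(sum((g-gbar)^2) sum((h-hbar)^2)).
    A constant input makes the denominator zero; that degenerate case
    returns 0.0 (no co-activity evidence either way).
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ParameterError(f"length mismatch: {g.shape} vs {h.shape}")
    if g.size < 2:
        raise ParameterError("need at least 2 samples")
    gc, hc = g - g.mean(), h - h.mean()
    denom = np.sqrt(np.sum(gc**2) * np.sum(hc**2))
    if denom < 1e-300:
        return 0.0
    return float(np.dot(gc, hc) / denom)


def ambient_gate(
    window: SignalWindow | np.ndarray, threshold: float = DEFAULT_PC_THRESHOLD
) -> PearsonGateResult:
    """Windowed Pearson-correlation activity gate over ambient channels.

    Computes the correlation for every unordered channel pair; the gate
    fires when the mean absolute correlation exceeds the threshold.  A
    single-channel window falls back to its lag-1 autocorrelation (logged).
    """
    data = window.data if isinstance(window, SignalWindow) else np.asarray(window, float)
    if data.ndim == 1:
        data = data[:, None]
    n_ch = data.shape[1]
    if n_ch == 1:
        logger.info("single ambient channel: gating on lag-1 autocorrelation")
        pc = pearson_correlation(data[:-1, 0], data[1:, 0])
        mat = np.array([[pc]])
        mean_abs = abs(pc)
        return PearsonGateResult(
            pc_matrix=mat, mean_abs_pc=mean_abs,
            action_flag=bool(mean_abs > threshold), threshold=threshold,
        )
    mat = np.eye(n_ch)
    degenerate = False
    vals = []
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            pc = pearson_correlation(data[:, i], data[:, j])
            if pc == 0.0 and (np.ptp(data[:, i]) == 0 or np.ptp(data[:, j]) == 0):
                degenerate = True
            mat[i, j] = mat[j, i] = pc
            vals.append(abs(pc))
    mean_abs = float(np.mean(vals))
    return PearsonGateResult(
        pc_matrix=mat, mean_abs_pc=mean_abs,
        action_flag=bool(mean_abs > threshold),
        threshold=threshold, degenerate=degenerate,
    )


def lpc_coefficients(x: Sequence[float], p: int) -> np.ndarray:
    """LPC coefficients a (length p) via the Levinson-Durbin recursion.

    ``a`` predicts x_t ~= sum_k a_k x_{t-k}; it solves the autocorrelation
    normal equations, so the prediction filter is minimum-phase.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("lpc_coefficients expects a 1-D signal")
    if len(x) <= 2 * p:
        raise ParameterError(f"signal length {len(x)} too short for order {p}")
    if not np.any(x != 0) or np.ptp(x) == 0:
        raise ParameterError("zero-energy (constant) signal has no LPC model")
    _, arcoefs, *_ = levinson_durbin(x - x.mean(), nlags=p, isacov=False)
    return np.asarray(arcoefs, dtype=float)


def lpcc(a: Sequence[float], p: Optional[int] = None, d: Optional[int] = None) -> np.ndarray:
    """Cepstral expansion c (length d) of LPC coefficients a (length p).

    Standard recursion with weight t/x; convolution terms whose a-index
    falls outside 1..p contribute zero.
    """
    a = np.asarray(a, dtype=float)
    p = len(a) if p is None else p
    if len(a) != p:
        raise ParameterError(f"len(a)={len(a)} does not match p={p}")
    d = p if d is None else d
    if d < p:
        raise ParameterError(f"need d >= p (got d={d}, p={p})")
    c = np.zeros(d)
    for x in range(1, d + 1):
        acc = 0.0
        for t in range(1, x):
            if 1 <= x - t <= p:
                acc += (t / x) * c[t - 1] * a[x - t - 1]
        c[x - 1] = acc + (a[x - 1] if x <= p else 0.0)
    return c


def lpcc_window(
    window: SignalWindow | np.ndarray, cfg: Optional[LPCCConfig] = None
) -> np.ndarray:
    """Per-window inertial feature: LPCC of each channel, concatenated.

    A channel too short or too flat for an LPC fit contributes zeros, so the
    feature length is always channels * d.
    """
    cfg = cfg or LPCCConfig()
    data = window.data if isinstance(window, SignalWindow) else np.asarray(window, float)
    if data.ndim == 1:
        data = data[:, None]
    feats = []
    for ch in range(data.shape[1]):
        try:
            a = lpc_coefficients(data[:, ch], cfg.p)
            feats.append(lpcc(a, cfg.p, cfg.d))
        except ParameterError:
            feats.append(np.zeros(cfg.d))
    return np.concatenate(feats)


def spider_web_points(
    center: Sequence[float], cfg: Optional[SpiderWebConfig] = None
) -> np.ndarray:
    """Web intersection coordinates around a centre: [rings, spokes, 2].

    Spoke z of ring radius x lies at center + (x cos(2 pi z / Z),
    x sin(2 pi z / Z)); with the image convention positive y points down,
    so z = Z/4 is directly below the anchor.
    """
    cfg = cfg or SpiderWebConfig()
    center = np.asarray(center, dtype=float)
    z = np.arange(cfg.spokes)
    ang = 2.0 * np.pi * z / cfg.spokes
    offsets = np.stack([np.cos(ang), np.sin(ang)], axis=-1)  # [spokes, 2]
    radii = np.asarray(cfg.rings, dtype=float)[:, None, None]
    return center[None, None, :] + radii * offsets[None, :, :]


def slif_descriptor(
    mask: np.ndarray,
    skeleton: SkeletonFrame,
    cfg: Optional[SpiderWebConfig] = None,
) -> np.ndarray:
    """Spider local image features for one frame.

    For each anchor skeleton point, the silhouette occupancy (0/1) at every
    web intersection, plus the anchor's overall occupancy fraction;
    off-image samples read 0.  A missing skeleton point contributes a
    zero-filled block, so the descriptor length is fixed at
    anchors * (rings * spokes + 1).
    """
    cfg = cfg or SpiderWebConfig()
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    name_to_idx = {n: i for i, n in enumerate(POINT_NAMES)}
    blocks = []
    for anchor in cfg.anchors:
        pt = skeleton.points[name_to_idx[anchor]]
        if np.any(np.isnan(pt)):
            blocks.append(np.zeros(cfg.block_size))
            continue
        web = spider_web_points(pt, cfg).reshape(-1, 2)
        xi = np.round(web[:, 0]).astype(int)
        yi = np.round(web[:, 1]).astype(int)
        inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        occ = np.zeros(len(web))
        occ[inside] = mask[yi[inside], xi[inside]].astype(float)
        blocks.append(np.concatenate([occ, [occ.mean()]]))
    return np.concatenate(blocks)


def slif_feature_names(cfg: Optional[SpiderWebConfig] = None) -> list[str]:
    """Column names matching slif_descriptor's layout."""
    cfg = cfg or SpiderWebConfig()
    names = []
    for anchor in cfg.anchors:
        for r in range(len(cfg.rings)):
            for z in range(cfg.spokes):
                names.append(f"slif_{anchor}_r{r}_z{z}")
        names.append(f"slif_{anchor}_frac")
    return names
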