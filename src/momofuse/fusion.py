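"""Window-aligned feature fusion and cross-entropy feature selection.

Fusion concatenates, per 4-s window, the ambient gate features, the
inertial LPCC block and the mean-pooled vision (SLIF) block into one
vector with recorded per-modality spans.  Selection then searches for a
binary inclusion mask over the fused dimensions with the cross-entropy
method (CEM): sample masks from an independent-Bernoulli model, score
them, refit the Bernoulli probabilities to the elite fraction, repeat.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

from .errors import FusionError, ParameterError

logger = logging.getLogger(__name__)

MODALITIES = ("ambient", "motion", "vision")


@dataclass
class FusedWindowFeature:
    """One window's concatenated multimodal feature vector."""

    vector: np.ndarray
    spans: dict  # modality name -> (start, stop) index range
    window_index: int
    label: int
    missing: tuple = ()  # modalities that were absent and zero-filled

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        stops = sorted(self.spans.values())
        covered = sum(b - a for a, b in stops)
        if covered != self.vector.size:
            raise ParameterError("spans must partition the fused vector")


@dataclass
class FeatureMask:
    """Binary inclusion vector over fused-feature dimensions."""

    include: np.ndarray
    score: float = float("nan")

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include).astype(bool)
        if not self.include.any():
            raise ParameterError("a feature mask must include at least one dimension")

    @property
    def n_selected(self) -> int:
        return int(self.include.sum())

    def to_json(self, path: str, config: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "include": self.include.astype(int).tolist(),
                    "score": None if np.isnan(self.score) else self.score,
                    "config": config or {},
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "FeatureMask":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(include=np.asarray(obj["include"], dtype=bool),
                   score=obj["score"] if obj["score"] is not None else float("nan"))


@dataclass
class CEMConfig:
    """Cross-entropy-method hyperparameters.

    population masks are sampled per iteration; the best
    ceil(population * elite_fraction) re-estimate the per-dimension
    Bernoulli probabilities, blended with the previous iterate by
    ``smoothing`` (1 = replace outright).  Probabilities are clamped to
    [floor, 1 - floor] so no dimension is absorbed prematurely.
    """

    population: int = 50
    elite_fraction: float = 0.2
    iterations: int = 30
    smoothing: float = 0.7
    init_prob: float = 0.5
    seed: int = 0
    scorer: str = "fisher"
    prob_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.population * self.elite_fraction < 2:
            raise ParameterError("population * elite_fraction must be >= 2")
        if not 0 < self.smoothing <= 1:
            raise ParameterError("smoothing must be in (0, 1]")
        if not 0 < self.init_prob < 1:
            raise ParameterError("init_prob must be in (0, 1)")
        if self.scorer not in ("fisher", "cv_loss"):
            raise ParameterError(f"unknown scorer {self.scorer!r}")


def align_and_fuse(
    ambient_feats: Optional[np.ndarray],
    motion_feats: Optional[np.ndarray],
    vision_feats: Optional[np.ndarray],
    labels: Sequence[int],
    vision_times: Optional[np.ndarray] = None,
    window_s: float = 4.0,
    window_starts: Optional[np.ndarray] = None,
) -> list[FusedWindowFeature]:
    """Fuse per-window ambient/motion tables with per-frame vision features.

    Ambient and motion tables are [windows, dims] and share the window
    index.  Vision features are per-frame [frames, dims] with timestamps;
    each frame is assigned to the window whose interval [start, start +
    window_s) contains it and frames of a window are mean-pooled.  A window
    missing any modality gets that span zero-filled and the modality
    recorded in ``missing``.
    """
    tables = {"ambient": ambient_feats, "motion": motion_feats}
    n_windows = None
    for name, tab in tables.items():
        if tab is not None:
            tab = np.asarray(tab, dtype=float)
            if tab.ndim != 2:
                raise ParameterError(f"{name} table must be 2-D")
            tables[name] = tab
            if n_windows is None:
                n_windows = len(tab)
            elif len(tab) != n_windows:
                n_windows = min(n_windows, len(tab))
                logger.info("modalities disagree on window count; truncating to %d", n_windows)
    if n_windows is None or n_windows == 0:
        raise FusionError("no overlapping windows across modalities")
    labels = np.asarray(labels)[:n_windows]
    if window_starts is None:
        window_starts = np.arange(n_windows) * window_s
    else:
        window_starts = np.asarray(window_starts, dtype=float)[:n_windows]

    dims = {
        "ambient": 0 if tables["ambient"] is None else tables["ambient"].shape[1],
        "motion": 0 if tables["motion"] is None else tables["motion"].shape[1],
    }
    pooled_vision = None
    vision_dim = 0
    if vision_feats is not None and len(vision_feats):
        vision_feats = np.asarray(vision_feats, dtype=float)
        vision_dim = vision_feats.shape[1]
        if vision_times is None:
            raise ParameterError("vision features require frame timestamps")
        vision_times = np.asarray(vision_times, dtype=float)
        pooled_vision = np.zeros((n_windows, vision_dim))
        has_vision = np.zeros(n_windows, dtype=bool)
        for w, start in enumerate(window_starts):
            sel = (vision_times >= start) & (vision_times < start + window_s)
            if sel.any():
                pooled_vision[w] = vision_feats[sel].mean(axis=0)
                has_vision[w] = True
    dims["vision"] = vision_dim

    spans, cursor = {}, 0
    for m in MODALITIES:
        spans[m] = (cursor, cursor + dims[m])
        cursor += dims[m]

    fused = []
    for w in range(n_windows):
        parts, missing = [], []
        for m in MODALITIES:
            d = dims[m]
            if d == 0:
                continue
            if m == "vision":
                if pooled_vision is not None and has_vision[w]:
                    parts.append(pooled_vision[w])
                else:
                    parts.append(np.zeros(d))
                    missing.append(m)
            else:
                parts.append(tables[m][w])
        fused.append(
            FusedWindowFeature(
                vector=np.concatenate(parts) if parts else np.empty(0),
                spans={m: s for m, s in spans.items() if s[1] > s[0]},
                window_index=w,
                label=int(labels[w]),
                missing=tuple(missing),
            )
        )
    return fused


def fused_table(fused: Sequence[FusedWindowFeature]) -> tuple[np.ndarray, np.ndarray]:
    """Stack fused windows into (X [windows, dims], y [windows])."""
    X = np.stack([f.vector for f in fused])
    y = np.array([f.label for f in fused])
    return X, y


def _fisher_ratios(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-dimension between/within class scatter ratio, softly bounded.

    The denominator mixes in 5% of the total scatter so a dimension with
    zero within-class variance scores at most 1/0.05 = 20 instead of
    exploding and drowning every other dimension.
    """
    classes = np.unique(y)
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        between += len(Xc) * (mu - grand) ** 2
        within += np.sum((Xc - mu) ** 2, axis=0)
    return between / (within + 0.05 * (between + within) + 1e-12)


def _fisher_score(X: np.ndarray, y: np.ndarray, include: np.ndarray) -> float:
    """Penalised additive Fisher criterion over the selected dimensions.

    Sum of the per-dimension ratios of the selected dims, each paying a
    fixed rent of half the mean ratio over *all* dims.  Unlike a plain
    trace ratio — which is indifferent between one informative dimension
    and ten equally informative ones — this rewards completeness while the
    rent term prunes noise dimensions.
    """
    ratios = _fisher_ratios(X, y)
    rent = 0.5 * ratios.mean()
    return float(np.sum(ratios[include] - rent))


def _cv_loss_score(X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Negative 3-fold stratified nearest-centroid error (higher better)."""
    _, counts = np.unique(y, return_counts=True)
    n_splits = int(min(3, counts.min()))
    if n_splits < 2:
        raise ParameterError("cv_loss scorer needs >= 2 samples per class")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    errs = []
    for tr, te in skf.split(X, y):
        clf = NearestCentroid().fit(X[tr], y[tr])
        errs.append(np.mean(clf.predict(X[te]) != y[te]))
    return float(-np.mean(errs))


def mask_score(
    mask: FeatureMask | np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    scorer: str = "fisher",
    seed: int = 0,
) -> float:
    """Fitness of a feature mask on labelled fused features."""
    include = mask.include if isinstance(mask, FeatureMask) else np.asarray(mask, bool)
    if not include.any():
        raise ParameterError("empty mask cannot be scored")
    if include.size != X.shape[1]:
        raise ParameterError("mask length does not match feature dimensionality")
    if len(np.unique(y)) < 2:
        raise ParameterError("scoring requires at least 2 classes")
    if scorer == "fisher":
        return _fisher_score(X, y, include)
    if scorer == "cv_loss":
        return _cv_loss_score(X[:, include], y, seed)
    raise ParameterError(f"unknown scorer {scorer!r}")


def cem_optimize(
    X: np.ndarray, y: np.ndarray, cfg: Optional[CEMConfig] = None
) -> tuple[FeatureMask, dict]:
    """Cross-entropy-method search for a high-fitness feature mask.

    Returns the best-ever mask plus a history dict with the per-iteration
    best score and Bernoulli-parameter trajectory.  Fully reproducible from
    cfg.seed.  Three consecutive iterations of all-identical scores trigger
    an early stop (degenerate landscape).
    """
    cfg = cfg or CEMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_dims = X.shape[1]
    if len(np.unique(y)) < 2:
        raise ParameterError("selection requires at least 2 classes")
    if n_dims == 1:
        return FeatureMask(include=np.ones(1, bool), score=float("nan")), {"best_scores": []}
    if cfg.population < 10:
        raise ParameterError("population must be >= 10")

    rng = np.random.default_rng(cfg.seed)
    if cfg.scorer == "fisher":  # the ratios do not depend on the mask
        ratios = _fisher_ratios(X, y)
        rent = 0.5 * ratios.mean()
    probs = np.full(n_dims, cfg.init_prob)
    n_elite = max(2, int(np.ceil(cfg.population * cfg.elite_fraction)))
    best_mask, best_score = None, -np.inf
    history = {"best_scores": [], "probs": []}
    flat_iters = 0
    for it in range(cfg.iterations):
        samples = rng.random((cfg.population, n_dims)) < probs
        empty = ~samples.any(axis=1)
        if empty.any():  # guarantee non-empty masks
            idx = rng.integers(0, n_dims, size=int(empty.sum()))
            samples[np.nonzero(empty)[0], idx] = True
        if cfg.scorer == "fisher":
            scores = samples @ (ratios - rent)
        else:
            scores = np.array(
                [mask_score(s, X, y, scorer=cfg.scorer, seed=cfg.seed) for s in samples]
            )
        order = np.argsort(scores)[::-1]
        elite = samples[order[:n_elite]]
        if scores[order[0]] > best_score:
            best_score = float(scores[order[0]])
            best_mask = samples[order[0]].copy()
        probs = cfg.smoothing * elite.mean(axis=0) + (1 - cfg.smoothing) * probs
        probs = np.clip(probs, cfg.prob_floor, 1 - cfg.prob_floor)
        history["best_scores"].append(best_score)
        history["probs"].append(probs.copy())
        if np.ptp(scores) == 0:
            flat_iters += 1
            if flat_iters >= 3:
                logger.warning("degenerate scores for 3 iterations; early stop at %d", it)
                break
        else:
            flat_iters = 0
    return FeatureMask(include=best_mask, score=best_score), history


def apply_mask(
    X: np.ndarray,
    mask: FeatureMask,
    spans: Optional[dict] = None,
) -> tuple[np.ndarray, Optional[dict]]:
    """Keep the masked columns (order preserved) and remap modality spans."""
    X = np.asarray(X)
    if mask.include.size != X.shape[1]:
        raise ParameterError("mask length does not match feature dimensionality")
    Xr = X[:, mask.include]
    if spans is None:
        return Xr, None
    new_spans, cursor = {}, 0
    for m, (a, b) in sorted(spans.items(), key=lambda kv: kv[1]):
        kept = int(mask.include[a:b].sum())
        new_spans[m] = (cursor, cursor + kept)
        cursor += kept
    return Xr, new_spans
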