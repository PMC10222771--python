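"""Per-modality loading, denoising, background subtraction and 4-s windowing.

Each modality of a recording session gets its own cleanup: ambient switch /
PIR channels go through a zero-phase Butterworth low-pass, inertial channels
through per-channel wavelet shrinkage (with orientation quaternions
renormalised to unit length), and video frames through median-background
subtraction that yields binary silhouette masks.  Cleaned ambient and
inertial streams are then cut into fixed-duration windows (4 s by default)
that carry a majority-vote activity label.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pywt
from PIL import Image
from scipy import ndimage
from scipy import signal as sps
from skimage.morphology import disk

from .errors import FormatError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: Canonical window duration in seconds.
DEFAULT_WINDOW_S = 4.0


@dataclass
class FilterConfig:
    """Parameters for all three per-modality filters.

    Attributes
    ----------
    butterworth_order, butterworth_cutoff
        Low-pass applied to ambient channels (zero-phase, forward-backward).
        Defaults: order 3, cutoff 5 Hz — activities of daily living live well
        below 5 Hz and ambient switch signals are essentially step functions.
    wavelet_name, wavelet_levels, wavelet_threshold_rule
        Wavelet shrinkage applied per inertial channel: decompose, threshold
        the detail coefficients (universal threshold, soft by default),
        reconstruct.
    background_quantile
        Per-pixel quantile across frames used as the static background
        (0.5 = median).
    mask_threshold
        Absolute intensity difference (8-bit units) above which a pixel is
        foreground.
    morph_radius
        Radius in pixels of the structuring element for morphological
        opening-then-closing of the raw mask.
    """

    butterworth_order: int = 3
    butterworth_cutoff: float = 5.0
    wavelet_name: str = "db4"
    wavelet_levels: int = 3
    wavelet_threshold_rule: str = "universal-soft"
    background_quantile: float = 0.5
    mask_threshold: float = 25.0
    morph_radius: int = 2

    def __post_init__(self) -> None:
        if self.butterworth_order < 1:
            raise ParameterError("butterworth_order must be >= 1")
        if self.wavelet_levels < 1:
            raise ParameterError("wavelet_levels must be >= 1")
        if self.wavelet_threshold_rule not in ("universal-soft", "universal-hard"):
            raise ParameterError(
                f"unknown wavelet_threshold_rule {self.wavelet_threshold_rule!r}"
            )


@dataclass
class MultimodalRecording:
    """One session of synchronised ambient / inertial / video data.

    Any modality may be absent; an absent modality is an empty array and the
    downstream feature span is zero-filled.  Label tracks are per-sample
    integer class ids aligned with each modality's own timeline.
    """

    ambient: np.ndarray  # [samples, channels]
    ambient_fs: float
    inertial: np.ndarray  # [samples, channels]
    inertial_fs: float
    frames: list  # list of 2-D uint8 arrays (grayscale) or bool arrays (masks)
    frame_fs: float
    ambient_labels: np.ndarray
    inertial_labels: np.ndarray
    frame_labels: np.ndarray
    quaternions: Optional[np.ndarray] = None  # [samples, 4], inertial timeline
    session_id: str = ""

    def __post_init__(self) -> None:
        for fs in (self.ambient_fs, self.inertial_fs, self.frame_fs):
            if fs <= 0:
                raise ParameterError("sampling rates must be positive")
        if len(self.ambient_labels) != len(self.ambient):
            raise ParameterError("ambient label track length mismatch")
        if len(self.inertial_labels) != len(self.inertial):
            raise ParameterError("inertial label track length mismatch")
        if len(self.frame_labels) != len(self.frames):
            raise ParameterError("frame label track length mismatch")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent frame shapes within session: {shapes}")

    @property
    def has_ambient(self) -> bool:
        return self.ambient.size > 0

    @property
    def has_inertial(self) -> bool:
        return self.inertial.size > 0

    @property
    def has_frames(self) -> bool:
        return len(self.frames) > 0


@dataclass
class SignalWindow:
    """A fixed-duration slice of one modality with a majority label."""

    data: np.ndarray  # [window_samples, channels]
    start_time: float
    duration: float
    label: int
    index: int = 0


def _read_timestamped_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a CSV with a leading ``timestamp`` column; return (t, values)."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read CSV file {path!r}: {exc}") from exc
    if "timestamp" not in df.columns:
        raise FormatError(f"{path!r}: missing required 'timestamp' column")
    if df.shape[1] < 2:
        raise FormatError(f"{path!r}: needs at least one data column")
    df = df.sort_values("timestamp", kind="stable")
    n_before = len(df)
    df = df.drop_duplicates(subset="timestamp", keep="first")
    if len(df) < n_before:
        logger.info("%s: dropped %d duplicated timestamp rows", path, n_before - len(df))
    t = df["timestamp"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path!r}: non-monotone timestamps after sort/dedup")
    vals = df.drop(columns="timestamp").to_numpy(dtype=float)
    return t, vals


def _regularise(t: np.ndarray, x: np.ndarray, fs: float) -> np.ndarray:
    """Resample onto a uniform grid at fs only if the timestamps are irregular."""
    if len(t) < 2:
        return x
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=1e-3, atol=1e-6):
        return x
    grid = np.arange(t[0], t[-1] + 0.5 / fs, 1.0 / fs)
    out = np.column_stack([np.interp(grid, t, x[:, c]) for c in range(x.shape[1])])
    logger.info("resampled irregular stream to %.3g Hz (%d -> %d samples)", fs, len(t), len(grid))
    return out


def _load_frames(frames_path: str) -> list:
    files = sorted(
        f for f in os.listdir(frames_path)
        if f.lower().endswith((".png", ".jpg", ".jpeg"))
    )
    frames = []
    for f in files:
        try:
            img = Image.open(os.path.join(frames_path, f)).convert("L")
        except OSError as exc:
            raise InputError(f"cannot read frame {f!r}: {exc}") from exc
        frames.append(np.asarray(img, dtype=np.uint8))
    return frames


def load_recording(
    ambient_path: Optional[str],
    inertial_path: Optional[str],
    frames_path: Optional[str],
    labels_path: Optional[str],
    ambient_fs: float = 10.0,
    inertial_fs: float = 25.0,
    frame_fs: float = 10.0,
    quaternions_path: Optional[str] = None,
    session_id: str = "",
) -> MultimodalRecording:
    """Load one session from CSV streams plus a numbered-image directory.

    CSV streams carry a ``timestamp`` column (seconds) followed by channel
    columns.  The labels CSV has columns ``timestamp,label``; each modality
    sample takes the label of the most recent label timestamp (step
    interpolation).  Missing paths yield empty, flagged modality tracks.
    """

    def _empty() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.empty((0, 0)), np.empty((0,)), np.empty(0, dtype=int)

    if labels_path is not None:
        lab_t, lab_v = _read_timestamped_csv(labels_path)
        lab_v = lab_v[:, 0].astype(int)
    else:
        lab_t, lab_v = np.empty(0), np.empty(0, dtype=int)

    def _labels_for(t: np.ndarray) -> np.ndarray:
        if len(lab_t) == 0:
            return np.zeros(len(t), dtype=int)
        idx = np.clip(np.searchsorted(lab_t, t, side="right") - 1, 0, len(lab_t) - 1)
        return lab_v[idx]

    if ambient_path is not None:
        amb_t, amb = _read_timestamped_csv(ambient_path)
        amb = _regularise(amb_t, amb, ambient_fs)
        amb_t = amb_t[0] + np.arange(len(amb)) / ambient_fs
        amb_labels = _labels_for(amb_t)
    else:
        amb, amb_t, amb_labels = _empty()
        logger.info("ambient modality absent")

    if inertial_path is not None:
        ine_t, ine = _read_timestamped_csv(inertial_path)
        ine = _regularise(ine_t, ine, inertial_fs)
        ine_t = ine_t[0] + np.arange(len(ine)) / inertial_fs
        ine_labels = _labels_for(ine_t)
    else:
        ine, ine_t, ine_labels = _empty()
        logger.info("inertial modality absent")

    quat = None
    if quaternions_path is not None:
        _, quat = _read_timestamped_csv(quaternions_path)
        if quat.shape[1] != 4:
            raise FormatError("quaternion stream must have exactly 4 channels")

    if frames_path is not None and os.path.isdir(frames_path):
        frames = _load_frames(frames_path)
    else:
        frames = []
        logger.info("vision modality absent; features will be zero-padded")
    frame_t = np.arange(len(frames)) / frame_fs
    frame_labels = _labels_for(frame_t) if frames else np.empty(0, dtype=int)

    return MultimodalRecording(
        ambient=amb, ambient_fs=ambient_fs,
        inertial=ine, inertial_fs=inertial_fs,
        frames=frames, frame_fs=frame_fs,
        ambient_labels=amb_labels, inertial_labels=ine_labels,
        frame_labels=frame_labels, quaternions=quat, session_id=session_id,
    )


def butterworth_lowpass(
    x: np.ndarray, fs: float, cutoff: float = 5.0, order: int = 3
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward) per channel.

    Applying the filter forward then backward cancels phase delay, so
    features keep their temporal alignment with the labels; the price is a
    squared magnitude response (amplitude ratio 1/2 at the cutoff instead of
    the single-pass 1/sqrt(2)).
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= fs / 2:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if len(x) <= 3 * (order + 1):
        raise ParameterError(
            f"signal of length {len(x)} too short for order-{order} zero-phase filter"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x, axis=0)
    return y[:, 0] if squeeze else y


def _wavelet_denoise_1d(x: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    levels = min(cfg.wavelet_levels, pywt.dwt_max_level(len(x), cfg.wavelet_name))
    if levels < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=levels)
    detail = coeffs[-1]
    # Universal threshold with noise scale from the finest-level MAD.
    sigma = np.median(np.abs(detail - np.median(detail))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    # Noise-floor gate: when the estimated noise threshold is negligible
    # against the signal energy, shrinkage would only bias genuine detail
    # coefficients (a clean low-frequency tone leaks into the detail bands),
    # so the signal passes through untouched.
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0 and thresh <= 0.1 * rms:
        return x.copy()
    mode = "soft" if cfg.wavelet_threshold_rule.endswith("soft") else "hard"
    coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode=mode) for c in coeffs[1:]]
    return pywt.waverec(coeffs, cfg.wavelet_name)[: len(x)]


def wavelet_quaternion_filter(
    inertial: np.ndarray,
    quaternions: Optional[np.ndarray] = None,
    cfg: Optional[FilterConfig] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Denoise inertial channels by wavelet shrinkage; renormalise quaternions.

    Each channel is decomposed (db4, 3 levels by default), the detail
    coefficients are shrunk with the universal threshold (soft rule), and the
    signal reconstructed.  Orientation quaternion rows, if present, are
    rescaled to unit norm; a near-zero row is a degenerate orientation and
    raises.
    """
    cfg = cfg or FilterConfig()
    inertial = np.asarray(inertial, dtype=float)
    if inertial.size == 0:
        raise ParameterError("inertial stream is empty")
    squeeze = inertial.ndim == 1
    if squeeze:
        inertial = inertial[:, None]
    out = np.column_stack(
        [_wavelet_denoise_1d(inertial[:, c], cfg) for c in range(inertial.shape[1])]
    )
    q_out = None
    if quaternions is not None:
        q = np.asarray(quaternions, dtype=float)
        norms = np.linalg.norm(q, axis=1)
        bad = np.nonzero(norms < 1e-8)[0]
        if bad.size:
            raise ParameterError(f"degenerate orientation at quaternion row {bad[0]}")
        q_out = q / norms[:, None]
    return (out[:, 0] if squeeze else out), q_out


def estimate_background(
    frames: Sequence[np.ndarray],
    cfg: Optional[FilterConfig] = None,
    max_frames: int = 200,
) -> np.ndarray:
    """Static background: per-pixel quantile across (a stride of) the frames.

    Valid when the camera is static and the subject occupies any given pixel
    a minority of the time.  Long sessions are subsampled to ``max_frames``
    evenly spaced frames, which leaves the per-pixel median essentially
    unchanged while bounding memory.
    """
    cfg = cfg or FilterConfig()
    if len(frames) < 3:
        raise ParameterError("background estimation needs at least 3 frames")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent frame sizes: {shapes}")
    idx = np.linspace(0, len(frames) - 1, min(len(frames), max_frames)).astype(int)
    stack = np.stack([np.asarray(frames[i], dtype=float) for i in idx])
    return np.quantile(stack, cfg.background_quantile, axis=0)


def foreground_mask(
    frame: np.ndarray, background: np.ndarray, cfg: Optional[FilterConfig] = None
) -> np.ndarray:
    """Binary silhouette: threshold |frame - background|, then open + close."""
    cfg = cfg or FilterConfig()
    m = np.abs(np.asarray(frame, dtype=float) - background) > cfg.mask_threshold
    if cfg.morph_radius > 0:
        selem = disk(cfg.morph_radius)
        m = ndimage.binary_closing(ndimage.binary_opening(m, structure=selem),
                                   structure=selem)
    return m


def subtract_background(
    frames: Sequence[np.ndarray], cfg: Optional[FilterConfig] = None
) -> list[np.ndarray]:
    """Foreground masks for a frame sequence (estimate + subtract + clean).

    Raw masks are cleaned by morphological opening (kills speckle) then
    closing (fills small holes); output masks are binary and frame-shaped.
    """
    cfg = cfg or FilterConfig()
    background = estimate_background(frames, cfg)
    return [foreground_mask(f, background, cfg) for f in frames]


def segment_windows(
    x: np.ndarray,
    fs: float,
    labels: np.ndarray,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = 0.0,
) -> list[SignalWindow]:
    """Cut a multichannel signal into fixed-duration windows.

    Window length is ``round(fs * window_s)`` samples; the step is
    ``window * (1 - overlap)``; a trailing partial window is discarded.  The
    window label is the majority class of its samples, ties broken toward the
    smaller class id.  A signal shorter than one window yields an empty list.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.ndim == 1:
        x = x[:, None]
    w = int(round(fs * window_s))
    if w < 2:
        raise ParameterError("window must span at least 2 samples")
    if not 0 <= overlap < 1:
        raise ParameterError("overlap must be in [0, 1)")
    step = max(1, int(round(w * (1.0 - overlap))))
    n = len(x)
    if n < w:
        logger.info("signal of %d samples shorter than window (%d); no windows", n, w)
        return []
    windows = []
    for i, start in enumerate(range(0, n - w + 1, step)):
        seg_labels = labels[start: start + w]
        vals, counts = np.unique(seg_labels, return_counts=True)
        label = int(vals[np.argmax(counts)])  # np.unique sorts -> ties go to smaller id
        windows.append(
            SignalWindow(
                data=x[start: start + w].copy(),
                start_time=start / fs,
                duration=window_s,
                label=label,
                index=i,
            )
        )
    return windows
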