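"""Seeded synthetic multimodal sessions with ground truth.

Emulates the structure of indoor ADL recordings (a handful of ambient
switch/PIR channels, 25 Hz-class inertial channels, a video stream of one
person in a static scene) closely enough to exercise every pipeline stage:

* **inertial**: each activity class is a class-specific sinusoid mixture
  (distinct fundamental frequency and per-channel amplitude pattern) plus
  Gaussian noise; the idle class is noise only.
* **ambient**: binary switch channels driven by a class-specific random
  telegraph; a per-class participation pattern decides which channels
  follow the driver and ``coupling`` controls how faithfully, so windowed
  inter-channel Pearson correlation separates active from idle segments.
* **vision**: an articulated stick figure (12 named joints) rendered into
  each frame over a static textured background; limb trajectories oscillate
  with class-specific gait/arm-swing parameters and the whole body drifts
  across the frame so median background subtraction stays valid.  Ground
  truth joint coordinates are stored per frame.

Sessions are fully reproducible from the seed.  Class-intrinsic parameters
(frequencies, amplitude patterns, switch patterns) depend only on the class
index so that every session draws from the same population of activities.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import dilation as morph_dilation
from skimage.morphology import erosion as morph_erosion
from skimage.morphology import disk as disk_selem

from .errors import ParameterError
from .preprocessing import MultimodalRecording
from .skeleton import POINT_NAMES

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Defaults mirror a small smart-home recording: 9 activity classes
    (class 0 is idle), 4 binary ambient channels at 10 Hz, 6 inertial
    channels at 25 Hz, 320x240 frames at 10 Hz, activity segments of 12 s
    (three 4-s windows each).
    """

    n_classes: int = 9
    session_s: Optional[float] = None  # default: segments_per_class * segment_s * n_classes
    segment_s: float = 12.0
    segments_per_class: int = 4
    ambient_channels: int = 4
    inertial_channels: int = 6
    ambient_fs: float = 10.0
    inertial_fs: float = 25.0
    frame_fs: float = 10.0
    frame_size: tuple = (320, 240)  # (width, height)
    noise_sd_ambient: float = 0.0
    noise_sd_inertial: float = 0.1
    silhouette_noise: float = 0.0  # per-frame probability of mask degradation
    coupling: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ParameterError("need at least 2 classes")
        if min(self.ambient_fs, self.inertial_fs, self.frame_fs) <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.segment_s < 8.0:
            raise ParameterError("activity segments must last at least 8 s")
        if self.session_s is None:
            self.session_s = self.segments_per_class * self.segment_s * self.n_classes
        if self.session_s < self.segment_s * self.n_classes:
            raise ParameterError(
                "session too short to give every class at least one segment"
            )


def _class_params(k: int, n_channels: int) -> dict:
    """Deterministic class-intrinsic parameters (independent of the session seed)."""
    rng = np.random.default_rng(1000 + k)
    idle = k == 0
    return {
        "freq": 0.5 if idle else 0.8 + 0.4 * k,  # Hz
        "inertial_amp": np.zeros(n_channels) if idle
        else 0.5 + rng.random(n_channels) * 1.5,
        "switch_pattern": np.zeros(n_channels, dtype=bool) if idle
        else rng.random(n_channels) < 0.6,
        "toggle_prob": 0.0 if idle else 0.04 + 0.01 * k,
        "arm_swing_deg": 1.5 if idle else 4.0 + 0.75 * k,
        "gait_amp": 0.5 if idle else 3.0 + 0.8 * k,
        "sway_amp": 0.5 if idle else 1.0 + 0.4 * k,
    }


def _segment_schedule(cfg: GeneratorConfig, rng: np.random.Generator) -> list[tuple[float, int]]:
    """(start_time, class_id) per segment; every class appears equally often."""
    n_segments = int(cfg.session_s // cfg.segment_s)
    classes = []
    while len(classes) < n_segments:
        block = np.arange(cfg.n_classes)
        rng.shuffle(block)
        classes.extend(block.tolist())
    classes = classes[:n_segments]
    return [(i * cfg.segment_s, int(c)) for i, c in enumerate(classes)]


def _labels_on_grid(schedule, fs: float, n: int, segment_s: float) -> np.ndarray:
    t = np.arange(n) / fs
    labels = np.zeros(n, dtype=int)
    for start, c in schedule:
        labels[(t >= start) & (t < start + segment_s)] = c
    return labels


def stick_figure_joints(
    t: float,
    class_params: dict,
    cx: float,
    frame_size: tuple,
    phase: float = 0.0,
) -> np.ndarray:
    """Ground-truth joint coordinates [12, 2] for one instant.

    The pose is an upright figure with raised, swinging arms and slightly
    spread, oscillating legs; all lengths scale with the frame height.
    """
    w, h = frame_size
    u = h / 240.0
    p = class_params
    sway = p["sway_amp"] * u * np.sin(2 * np.pi * 0.3 * t + phase)
    bob = 2.0 * u * np.sin(2 * np.pi * 0.25 * t + phase)
    cx = cx + sway
    swing = np.deg2rad(p["arm_swing_deg"]) * np.sin(2 * np.pi * p["freq"] * t + phase)
    gait = p["gait_amp"] * u * np.sin(2 * np.pi * p["freq"] * t + phase)

    head = np.array([cx, 50 * u + bob])
    lsho = np.array([cx - 20 * u, 78 * u + bob])
    rsho = np.array([cx + 20 * u, 78 * u + bob])
    torso = np.array([cx, 112 * u + bob])
    arm_len = 48 * u
    theta_l = np.deg2rad(122.5) + swing  # angle from vertical-down
    theta_r = np.deg2rad(122.5) - swing
    lwri = lsho + arm_len * np.array([-np.sin(theta_l), np.cos(theta_l)])
    rwri = rsho + arm_len * np.array([np.sin(theta_r), np.cos(theta_r)])
    lelb = (lsho + lwri) / 2
    relb = (rsho + rwri) / 2
    # hips sit where the extractor anchors its hip band: torso + (+-0.08H, 0.12H)
    height = 177 * u
    lhip = torso + np.array([-0.08 * height, 0.12 * height])
    rhip = torso + np.array([0.08 * height, 0.12 * height])
    # lateral stepping: both feet shift together so the legs never merge
    lank = lhip + np.array([-6 * u + gait, 85 * u - bob])
    rank = rhip + np.array([6 * u + gait, 85 * u - bob])
    lkne = (lhip + lank) / 2
    rkne = (rhip + rank) / 2
    return np.array(
        [head, lsho, rsho, lelb, relb, lwri, rwri, torso, lkne, rkne, lank, rank]
    )


def make_background(frame_size: tuple, seed: int = 0) -> np.ndarray:
    """Static textured background: a smoothed seeded random field in 0..110."""
    w, h = frame_size
    rng = np.random.default_rng(seed)
    field_img = rng.random((h, w))
    field_img = ndimage.gaussian_filter(field_img, sigma=6)
    field_img -= field_img.min()
    field_img /= max(field_img.max(), 1e-9)
    return (20 + 90 * field_img).astype(np.uint8)


def render_stick_figure(
    joints: np.ndarray,
    frame_size: tuple = (320, 240),
    background: Optional[np.ndarray] = None,
    line_width: int = 2,
    figure_intensity: int = 235,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a 12-joint pose into (binary mask, grayscale frame).

    Limbs are thick line segments, the torso an ellipse, the head a disk.
    Joints outside the frame are clipped (with a warning); the grayscale
    frame overlays the figure on the static textured background so that
    median background subtraction has something to do.
    """
    w, h = frame_size
    joints = np.asarray(joints, dtype=float).reshape(len(POINT_NAMES), 2)
    if (joints[:, 0].min() < 0 or joints[:, 0].max() >= w
            or joints[:, 1].min() < 0 or joints[:, 1].max() >= h):
        logger.warning("out-of-frame joints clipped to the frame bounds")
    clipped = np.column_stack(
        [np.clip(joints[:, 0], 0, w - 1), np.clip(joints[:, 1], 0, h - 1)]
    )
    j = {name: clipped[i] for i, name in enumerate(POINT_NAMES)}
    u = h / 240.0
    mask = np.zeros((h, w), dtype=bool)

    def seg(a, b):
        rr, cc = draw_line(int(round(a[1])), int(round(a[0])),
                           int(round(b[1])), int(round(b[0])))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True

    neck = (j["left_shoulder"] + j["right_shoulder"]) / 2
    seg(j["head"], neck)
    seg(neck, j["torso"])  # spine keeps the upper body connected to the torso
    seg(j["left_shoulder"], j["right_shoulder"])
    for side in ("left", "right"):
        seg(j[f"{side}_shoulder"], j[f"{side}_wrist"])
        # draw the leg from inside the torso ellipse so it stays connected
        hip_draw = j["torso"] + np.array([(-1 if side == "left" else 1) * 8 * u, 12 * u])
        seg(hip_draw, j[f"{side}_ankle"])
    if line_width > 0:
        mask = morph_dilation(mask, disk_selem(line_width)).astype(bool)
    rr, cc = draw_ellipse(j["torso"][1], j["torso"][0], 30 * u, 16 * u, shape=(h, w))
    mask[rr, cc] = True
    rr, cc = draw_disk((j["head"][1], j["head"][0]), 9 * u, shape=(h, w))
    mask[rr, cc] = True

    if background is None:
        background = make_background(frame_size)
    frame = background.copy()
    frame[mask] = figure_intensity
    return mask, frame


@dataclass
class SessionTruth:
    """Ground truth accompanying a generated recording."""

    joints: np.ndarray  # [frames, 12, 2]
    masks: list  # clean rendered silhouette per frame
    schedule: list  # (start_time, class_id) per segment
    config: GeneratorConfig


def generate_session(cfg: Optional[GeneratorConfig] = None) -> tuple[MultimodalRecording, SessionTruth]:
    """Generate one labelled multimodal session plus its ground truth."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    schedule = _segment_schedule(cfg, rng)
    params = {k: _class_params(k, max(cfg.ambient_channels, cfg.inertial_channels))
              for k in range(cfg.n_classes)}

    # --- inertial: class sinusoid mixture + noise -------------------------
    n_ine = int(round(cfg.session_s * cfg.inertial_fs))
    t_ine = np.arange(n_ine) / cfg.inertial_fs
    ine = rng.normal(0, cfg.noise_sd_inertial, size=(n_ine, cfg.inertial_channels))
    ine_labels = _labels_on_grid(schedule, cfg.inertial_fs, n_ine, cfg.segment_s)
    for start, c in schedule:
        sel = (t_ine >= start) & (t_ine < start + cfg.segment_s)
        p = params[c]
        phase = rng.uniform(0, 2 * np.pi, size=cfg.inertial_channels)
        for ch in range(cfg.inertial_channels):
            amp = p["inertial_amp"][ch]
            if amp > 0:
                ine[sel, ch] += amp * np.sin(2 * np.pi * p["freq"] * t_ine[sel] + phase[ch])
                # weak second harmonic makes the spectrum class-specific beyond f0
                ine[sel, ch] += 0.3 * amp * np.sin(4 * np.pi * p["freq"] * t_ine[sel] + phase[ch])

    # quaternions: slow rotation about z, unit rows
    ang = 0.2 * np.sin(2 * np.pi * 0.2 * t_ine) + rng.normal(0, 0.01, n_ine)
    quat = np.column_stack(
        [np.cos(ang / 2), np.zeros(n_ine), np.zeros(n_ine), np.sin(ang / 2)]
    )

    # --- ambient: binary switch channels with class-specific coupling ----
    n_amb = int(round(cfg.session_s * cfg.ambient_fs))
    t_amb = np.arange(n_amb) / cfg.ambient_fs
    amb = np.zeros((n_amb, cfg.ambient_channels))
    amb_labels = _labels_on_grid(schedule, cfg.ambient_fs, n_amb, cfg.segment_s)
    for start, c in schedule:
        sel = np.nonzero((t_amb >= start) & (t_amb < start + cfg.segment_s))[0]
        p = params[c]
        if p["toggle_prob"] == 0.0:
            continue  # idle: switches stay at rest
        toggles = rng.random(len(sel)) < p["toggle_prob"]
        driver = np.cumsum(toggles) % 2
        for ch in range(cfg.ambient_channels):
            if not p["switch_pattern"][ch]:
                continue
            own_toggles = rng.random(len(sel)) < p["toggle_prob"]
            own = np.cumsum(own_toggles) % 2
            follow = rng.random(len(sel)) < cfg.coupling
            amb[sel, ch] = np.where(follow, driver, own)
    if cfg.noise_sd_ambient > 0:
        amb += rng.normal(0, cfg.noise_sd_ambient, size=amb.shape)

    # --- vision: stick figure over a static background -------------------
    n_frames = int(round(cfg.session_s * cfg.frame_fs))
    t_frm = np.arange(n_frames) / cfg.frame_fs
    frame_labels = _labels_on_grid(schedule, cfg.frame_fs, n_frames, cfg.segment_s)
    background = make_background(cfg.frame_size, seed=cfg.seed)
    w, _h = cfg.frame_size
    drift_phase = rng.uniform(0, 2 * np.pi)
    seg_phases = {start: rng.uniform(0, 2 * np.pi) for start, _ in schedule}
    frames, masks = [], []
    joints_all = np.zeros((n_frames, len(POINT_NAMES), 2))
    seg_idx = 0
    for i, t in enumerate(t_frm):
        while (seg_idx + 1 < len(schedule)
               and t >= schedule[seg_idx + 1][0]):
            seg_idx += 1
        start, c = schedule[seg_idx]
        # slow drift keeps every pixel background most of the time
        cx = w / 2 + 0.22 * w * np.sin(2 * np.pi * 0.02 * t + drift_phase)
        joints = stick_figure_joints(t, params[c], cx, cfg.frame_size,
                                     phase=seg_phases[start])
        joints_all[i] = joints
        mask, frame = render_stick_figure(joints, cfg.frame_size, background)
        if cfg.silhouette_noise > 0 and rng.random() < cfg.silhouette_noise:
            mask = morph_erosion(mask, disk_selem(1)).astype(bool)
            drop = rng.random(mask.shape) < 0.5 * cfg.silhouette_noise
            mask = mask & ~drop
            frame = background.copy()
            frame[mask] = 235
        frames.append(frame)
        masks.append(mask)

    rec = MultimodalRecording(
        ambient=amb, ambient_fs=cfg.ambient_fs,
        inertial=ine, inertial_fs=cfg.inertial_fs,
        frames=frames, frame_fs=cfg.frame_fs,
        ambient_labels=amb_labels, inertial_labels=ine_labels,
        frame_labels=frame_labels, quaternions=quat,
        session_id=f"synthetic-seed{cfg.seed}",
    )
    return rec, SessionTruth(joints=joints_all, masks=masks, schedule=schedule, config=cfg)


def write_session(
    rec: MultimodalRecording, truth: SessionTruth, outdir: str
) -> None:
    """Write the exact CSV/PNG layout that load_recording reads."""
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "frames"), exist_ok=True)

    def _csv(name, fs, data, prefix):
        t = np.arange(len(data)) / fs
        df = pd.DataFrame(data, columns=[f"{prefix}{i}" for i in range(data.shape[1])])
        df.insert(0, "timestamp", t)
        df.to_csv(os.path.join(outdir, name), index=False)

    _csv("ambient.csv", rec.ambient_fs, rec.ambient, "ch")
    _csv("inertial.csv", rec.inertial_fs, rec.inertial, "imu")
    if rec.quaternions is not None:
        _csv("quaternions.csv", rec.inertial_fs, rec.quaternions, "q")
    labels = pd.DataFrame(truth.schedule, columns=["timestamp", "label"])
    labels.to_csv(os.path.join(outdir, "labels.csv"), index=False)
    for i, frame in enumerate(rec.frames):
        Image.fromarray(frame).save(os.path.join(outdir, "frames", f"frame_{i:06d}.png"))
    gt_rows = []
    for i in range(len(truth.joints)):
        for jname, (x, y) in zip(POINT_NAMES, truth.joints[i]):
            gt_rows.append({"frame": i, "point_name": jname, "x": x, "y": y})
    pd.DataFrame(gt_rows).to_csv(os.path.join(outdir, "skeleton_truth.csv"), index=False)
    cfg = truth.config
    manifest = {
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "session_id": rec.session_id,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
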