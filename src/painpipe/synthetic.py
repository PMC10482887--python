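"""Seeded synthetic cage-video generator.

Emulates the structure of a postoperative pain study in caged animals:
each subject contributes one "no_pain" and one "pain" video, the class
signal is reduced subject movement under pain, and the footage carries
the noise sources that make real cage video hard — cage-bar occlusion,
motion blur, and frames where the subject is absent or off camera.

The subject is rendered as a textured ellipse ("blob") performing a
seeded random walk over a static textured background; vertical cage
bars are composited on top. Every frame carries either a ground-truth
bounding box or an explicit absent marker, so detector and pipeline
stages can be tested against known geometry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

LABELS = ("no_pain", "pain")

#: half-axes of the subject ellipse as a fraction of min(frame height, width)
_SUBJECT_RADIUS_FRAC = (0.18, 0.13)
_BLUR_KERNEL = 5  # px, 1-D box blur along the dominant motion axis
#: per-frame sd of the relative ellipse-radius jitter, per unit motion amplitude
_SHAPE_JITTER_PER_AMPLITUDE = 0.05
_BOUT_MEAN_S = 5.0  # mean off-label behaviour bout length, seconds
_OCCLUDER_COVER_FRAC = (0.4, 0.7)  # fraction of the subject box an obstruction hides


class ConfigurationError(ValueError):
    """A SyntheticConfig field is out of range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Motion amplitudes are the per-frame-step standard deviation of the
    subject centroid's random walk, in pixels. The pain amplitude must
    be strictly below the no-pain amplitude: reduced movement is the
    behavioural pain indicator the pipeline is meant to detect.
    ``appearance_shift`` adds a class-conditional brightness offset to
    the subject texture (0 = motion is the only class signal).

    ``occluded_frame_prob`` is the per-frame chance the subject is
    heavily obstructed (pressed against a solid cage element or facing
    away): it is still localizable, so a detector returns its box, but
    the crop content is mostly occluder — the classic junk frame that
    reaches training with its video's label.

    ``atypical_bout_frac`` is the long-run fraction of time a *pain*
    video spends in normal-looking activity bursts, during which the
    subject moves with the no-pain amplitude. Pain expressed in video
    is intermittent — the visible pain level does not hold a fixed
    level throughout a recording — while baseline (no-pain) behaviour
    is consistent; the burst frames carry the pain label but look like
    no-pain, and are exactly what confidence-based frame selection is
    meant to discard.
    """

    n_subjects: int = 24
    fps: float = 60.0
    duration_s: float = 120.0
    frame_size: tuple[int, int] = (96, 128)  # (height, width)
    motion_amplitude_no_pain: float = 4.0
    motion_amplitude_pain: float = 0.2
    occlusion_bar_count: int = 3
    occlusion_bar_width: int = 3
    blur_prob: float = 0.15
    absent_frame_prob: float = 0.15
    occluded_frame_prob: float = 0.3
    appearance_shift: float = 0.0
    atypical_bout_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.fps <= 0:
            raise ConfigurationError("fps must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        h, w = self.frame_size
        if h < 16 or w < 16:
            raise ConfigurationError("frame_size must be at least 16x16 px")
        if self.motion_amplitude_no_pain < 0 or self.motion_amplitude_pain < 0:
            raise ConfigurationError("motion amplitudes must be non-negative")
        if self.motion_amplitude_pain > self.motion_amplitude_no_pain:
            raise ConfigurationError(
                "motion_amplitude_pain must not exceed motion_amplitude_no_pain "
                "(pain = reduced movement; equality makes appearance the only signal)"
            )
        for name in ("blur_prob", "absent_frame_prob", "occluded_frame_prob", "appearance_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.atypical_bout_frac < 1.0:
            raise ConfigurationError("atypical_bout_frac must lie in [0, 1)")
        if self.occlusion_bar_count < 0:
            raise ConfigurationError("occlusion_bar_count must be non-negative")
        if self.occlusion_bar_width < 0:
            raise ConfigurationError("occlusion_bar_width must be non-negative")


@dataclass
class SyntheticVideo:
    """One rendered video: frames plus per-frame ground truth."""

    subject_id: str
    video_id: str
    label: str
    fps: float
    frames: list[np.ndarray]  # H x W x 3 uint8
    boxes: list[tuple[int, int, int, int] | None]  # (x0, y0, x1, y1) half-open, or None = absent

    @property
    def frame_count(self) -> int:
        return len(self.frames)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    videos: list[SyntheticVideo] = field(default_factory=list)

    def manifest_records(self) -> list[dict]:
        return [
            {
                "subject_id": v.subject_id,
                "video_id": v.video_id,
                "label": v.label,
                "fps": v.fps,
                "frame_count": v.frame_count,
            }
            for v in self.videos
        ]


def _texture(
    rng: np.random.Generator, shape: tuple[int, int], low: int, high: int, scale: int = 8
) -> np.ndarray:
    """Smooth random texture in [low, high], uint8; smaller scale = finer grain."""
    coarse = rng.uniform(low, high, size=(max(2, shape[0] // scale), max(2, shape[1] // scale)))
    img = np.asarray(
        Image.fromarray(coarse.astype(np.uint8)).resize((shape[1], shape[0]), Image.BILINEAR)
    )
    return img.astype(np.uint8)


def _render_background(rng: np.random.Generator, size: tuple[int, int]) -> np.ndarray:
    h, w = size
    base = _texture(rng, (h, w), 60, 120)
    bg = np.stack([base, base + rng.integers(0, 10), base + rng.integers(0, 10)], axis=-1)
    return np.clip(bg, 0, 255).astype(np.uint8)


def _subject_mask(size: tuple[int, int], center: tuple[float, float], radii: tuple[float, float]) -> np.ndarray:
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _mask_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


def _apply_bars(frame: np.ndarray, count: int, width: int) -> None:
    if count <= 0 or width <= 0:
        return
    w = frame.shape[1]
    for k in range(count):
        x0 = int((k + 1) * w / (count + 1)) - width // 2
        frame[:, max(0, x0): max(0, x0) + width] = 35  # dark metal bar


def _box_blur_1d(frame: np.ndarray, axis: int) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(frame.astype(np.float32), size=_BLUR_KERNEL, axis=axis).astype(np.uint8)


def _render_video(
    cfg: SyntheticConfig, rng: np.random.Generator, subject_id: str, label: str
) -> SyntheticVideo:
    h, w = cfg.frame_size
    n_frames = int(round(cfg.fps * cfg.duration_s))
    background = _render_background(rng, (h, w))
    r = min(h, w)
    radii = (_SUBJECT_RADIUS_FRAC[0] * r, _SUBJECT_RADIUS_FRAC[1] * r)

    # class-conditional subject texture: brighter than background, plus an
    # optional appearance offset so appearance can carry the class signal
    shift = cfg.appearance_shift * 50.0 * (1 if label == "pain" else -1)
    subj_base = _texture(rng, (h, w), 140, 220).astype(np.float32) + shift
    subject_tex = np.clip(np.stack([subj_base] * 3, axis=-1), 0, 255).astype(np.uint8)

    if label == "pain":
        amplitude, other_amplitude = cfg.motion_amplitude_pain, cfg.motion_amplitude_no_pain
    else:
        amplitude, other_amplitude = cfg.motion_amplitude_no_pain, cfg.motion_amplitude_pain
    # two-state behaviour chain: typical <-> off-label bouts of ~_BOUT_MEAN_S s
    # (pain videos only: pain expression is intermittent, baseline is consistent)
    q = cfg.atypical_bout_frac if label == "pain" else 0.0
    p_exit = 1.0 / max(1, int(round(_BOUT_MEAN_S * cfg.fps)))
    p_enter = 0.0 if q == 0.0 else min(1.0, q / (1.0 - q) * p_exit)
    atypical = bool(rng.uniform() < q)
    margin_y, margin_x = radii[0] + 1, radii[1] + 1
    cy = rng.uniform(margin_y, h - margin_y)
    cx = rng.uniform(margin_x, w - margin_x)

    frames: list[np.ndarray] = []
    boxes: list[tuple[int, int, int, int] | None] = []
    tex_y = tex_x = 0.0  # body-texture scroll: limb/head movement inside the outline
    for _ in range(n_frames):
        if atypical:
            atypical = not (rng.uniform() < p_exit)
        else:
            atypical = rng.uniform() < p_enter
        eff_amplitude = other_amplitude if atypical else amplitude
        step = rng.normal(0.0, 1.0, size=2) * eff_amplitude
        cy = float(np.clip(cy + step[0], margin_y, h - margin_y))
        cx = float(np.clip(cx + step[1], margin_x, w - margin_x))
        tex_step = rng.normal(0.0, 1.0, size=2) * eff_amplitude
        tex_y += tex_step[0]
        tex_x += tex_step[1]
        # posture change scales with how much the animal moves: the body
        # outline of an active subject deforms frame to frame, a still
        # (painful) subject holds its shape
        shape_jitter = rng.normal(0.0, 1.0, size=2) * _SHAPE_JITTER_PER_AMPLITUDE * eff_amplitude
        frame_radii = (
            float(radii[0] * np.clip(1.0 + shape_jitter[0], 0.7, 1.3)),
            float(radii[1] * np.clip(1.0 + shape_jitter[1], 0.7, 1.3)),
        )
        # blur and bar-crossing obstruction are consequences of movement:
        # probabilities scale with current activity, so an animal in a
        # still (painful) state rarely produces either
        activity = eff_amplitude / max(cfg.motion_amplitude_no_pain, 1e-9)
        absent = rng.uniform() < cfg.absent_frame_prob
        occluded = rng.uniform() < cfg.occluded_frame_prob * activity
        blur = rng.uniform() < cfg.blur_prob * activity

        frame = background.copy()
        if absent:
            boxes.append(None)
        else:
            mask = _subject_mask((h, w), (cy, cx), frame_radii)
            tex = np.roll(
                subject_tex, (int(round(tex_y)), int(round(tex_x))), axis=(0, 1)
            )
            frame[mask] = tex[mask]
            box = _mask_box(mask)
            if occluded:
                # a solid cage element hides most of the body; the subject
                # remains localizable so the box stays truthful
                x0, y0, x1, y1 = box
                cover = rng.uniform(*_OCCLUDER_COVER_FRAC)
                if rng.uniform() < 0.5:
                    frame[y0:y1, x0: x0 + max(1, int(round((x1 - x0) * cover)))] = 35
                else:
                    frame[y0: y0 + max(1, int(round((y1 - y0) * cover))), x0:x1] = 35
            boxes.append(box)
        _apply_bars(frame, cfg.occlusion_bar_count, cfg.occlusion_bar_width)
        if blur and not absent:
            axis = 0 if abs(step[0]) >= abs(step[1]) else 1
            frame = _box_blur_1d(frame, axis)
        frames.append(frame)

    return SyntheticVideo(
        subject_id=subject_id,
        video_id=f"{subject_id}_{label}",
        label=label,
        fps=cfg.fps,
        frames=frames,
        boxes=boxes,
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Render ``n_subjects`` x 2 videos (one per class per subject).

    Deterministic: identical config (including seed) yields byte-identical
    frames. Each subject gets its own RNG stream derived from the master
    seed so per-subject content is stable under changes to n_subjects.
    """
    master = np.random.SeedSequence(config.seed)
    dataset = SyntheticDataset(config=config)
    for i, child in enumerate(master.spawn(config.n_subjects)):
        subject_id = f"s{i:03d}"
        rng = np.random.default_rng(child)
        for label in LABELS:
            dataset.videos.append(_render_video(config, rng, subject_id, label))
    return dataset


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write per-video PNG frame directories plus a JSON manifest.

    Returns the manifest path. Frames are zero-padded ``frame_%06d.png``;
    ground-truth boxes go to ``boxes.json`` per video (``null`` marks an
    absent frame). Round-trips losslessly through the manifest reader.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for video in dataset.videos:
        vdir = directory / video.video_id
        vdir.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(video.frames):
            Image.fromarray(frame).save(vdir / f"frame_{i:06d}.png")
        with open(vdir / "boxes.json", "w") as fh:
            json.dump([list(b) if b is not None else None for b in video.boxes], fh)
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"videos": dataset.manifest_records()}, fh, indent=2)
    return manifest_path


def centroid_displacements(video: SyntheticVideo) -> np.ndarray:
    """Euclidean ground-truth centroid displacement between consecutive
    frames where the subject is present in both; empty when fewer than
    two such pairs exist."""
    out = []
    prev = None
    for box in video.boxes:
        if box is None:
            prev = None
            continue
        c = ((box[0] + box[2]) / 2.0, (box[1] + box[3]) / 2.0)
        if prev is not None:
            out.append(float(np.hypot(c[0] - prev[0], c[1] - prev[1])))
        prev = c
    return np.asarray(out)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["frame_size"] = list(d["frame_size"])
    return d
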