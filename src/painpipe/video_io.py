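"""Video handles, manifest loading and 1 Hz frame sampling.

The canonical on-disk form is a directory of per-video PNG frame
directories with a JSON manifest (the format :func:`painpipe.synthetic.
write_fixture` writes). In-memory synthetic videos are wrapped by the
same :class:`VideoHandle` contract so the pipeline never cares where
frames come from.

Sampling follows the study protocol: one frame per second, first frame
of each second (index ``floor(t * fps)``), truncated at two minutes —
a 7200-frame 60 fps video reduces to exactly 120 frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from PIL import Image

VALID_LABELS = frozenset({"pain", "no_pain", "unlabeled"})


class ManifestFormatError(ValueError):
    """A manifest entry fails validation (e.g. unknown label)."""


class VideoReadError(IOError):
    """A video source cannot be decoded."""


@dataclass
class VideoHandle:
    """Lazy access to one video's frames.

    ``reader(i)`` returns frame ``i`` as an H x W x 3 uint8 array.
    """

    subject_id: str
    video_id: str
    label: str
    native_fps: float
    frame_count: int
    reader: Callable[[int], np.ndarray]
    boxes: list[tuple[int, int, int, int] | None] | None = None

    def __post_init__(self) -> None:
        if self.native_fps <= 0:
            raise ValueError("native_fps must be positive")
        if self.frame_count < 0:
            raise ValueError("frame_count must be non-negative")


@dataclass
class FrameRecord:
    """One sampled (and possibly later cropped) frame."""

    subject_id: str
    video_id: str
    label: str
    timestamp_s: float
    sample_index: int
    source_frame_index: int
    image: np.ndarray  # H x W x 3 uint8


def normalize_label(raw: str) -> str:
    label = str(raw).strip().lower()
    if label not in VALID_LABELS:
        raise ManifestFormatError(
            f"unknown label {raw!r}; expected one of {sorted(VALID_LABELS)}"
        )
    return label


def sample_frames(
    video: VideoHandle,
    sample_interval_s: float = 1.0,
    max_duration_s: float = 120.0,
) -> list[FrameRecord]:
    """Trim and sample: one frame per ``sample_interval_s`` seconds.

    Frame at time ``t`` is source index ``floor(t * native_fps)``. The
    sequence stops at ``max_duration_s`` or when the video runs out of
    whole seconds, whichever is first. A zero-length video yields an
    empty list.
    """
    if sample_interval_s <= 0:
        raise ValueError("sample_interval_s must be positive")
    n_by_length = int(np.floor(video.frame_count / video.native_fps) / sample_interval_s)
    n_by_trim = int(np.floor(max_duration_s / sample_interval_s))
    n = max(0, min(n_by_length, n_by_trim))
    records = []
    for k in range(n):
        t = k * sample_interval_s
        idx = int(np.floor(t * video.native_fps))
        try:
            image = video.reader(idx)
        except Exception as exc:  # pragma: no cover - backend specific
            raise VideoReadError(f"cannot read frame {idx} of {video.video_id}") from exc
        records.append(
            FrameRecord(
                subject_id=video.subject_id,
                video_id=video.video_id,
                label=video.label,
                timestamp_s=float(t),
                sample_index=k,
                source_frame_index=idx,
                image=np.asarray(image, dtype=np.uint8),
            )
        )
    return records


def _png_dir_reader(vdir: Path) -> tuple[Callable[[int], np.ndarray], int]:
    files = sorted(vdir.glob("frame_*.png"))
    if not files and not vdir.is_dir():
        raise VideoReadError(f"frame directory {vdir} does not exist")

    def read(i: int) -> np.ndarray:
        return np.asarray(Image.open(files[i]).convert("RGB"))

    return read, len(files)


def load_manifest(path: str | Path) -> list[VideoHandle]:
    """Load a fixture manifest into one :class:`VideoHandle` per video.

    Labels are case-folded and validated; ground-truth boxes are loaded
    when a ``boxes.json`` sits beside the frames.
    """
    path = Path(path)
    if not path.exists():
        raise VideoReadError(f"manifest {path} does not exist")
    with open(path) as fh:
        manifest = json.load(fh)
    root = path.parent
    handles = []
    for entry in manifest.get("videos", []):
        try:
            label = normalize_label(entry["label"])
        except ManifestFormatError as exc:
            raise ManifestFormatError(f"entry {entry.get('video_id')!r}: {exc}") from None
        vdir = root / entry["video_id"]
        reader, n_files = _png_dir_reader(vdir)
        frame_count = int(entry.get("frame_count", n_files))
        if frame_count > n_files:
            raise ManifestFormatError(
                f"entry {entry['video_id']!r}: manifest claims {frame_count} frames, "
                f"found {n_files} PNG files"
            )
        boxes = None
        boxes_path = vdir / "boxes.json"
        if boxes_path.exists():
            with open(boxes_path) as fh:
                boxes = [tuple(b) if b is not None else None for b in json.load(fh)]
        handles.append(
            VideoHandle(
                subject_id=str(entry["subject_id"]),
                video_id=str(entry["video_id"]),
                label=label,
                native_fps=float(entry["fps"]),
                frame_count=frame_count,
                reader=reader,
                boxes=boxes,
            )
        )
    return handles


def handles_from_dataset(dataset) -> list[VideoHandle]:
    """Wrap an in-memory :class:`painpipe.synthetic.SyntheticDataset`
    directly, skipping the PNG round-trip."""
    handles = []
    for video in dataset.videos:
        frames = video.frames
        handles.append(
            VideoHandle(
                subject_id=video.subject_id,
                video_id=video.video_id,
                label=normalize_label(video.label),
                native_fps=video.fps,
                frame_count=video.frame_count,
                reader=lambda i, _frames=frames: _frames[i],
                boxes=list(video.boxes),
            )
        )
    return handles
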