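"""Grayscale short-term stacking (GrayST).

A 2-D image classifier cannot see motion. GrayST restores short-term
temporal information at zero extra compute by replacing the three color
channels of an image with grayscale frames from three consecutive
sampled time steps (here 1 s apart): channel R holds the frame at t,
G at t+1, B at t+2. A static scene renders as a neutral gray image
(all channels equal); motion shows up as apparent color fringing —
which, for a species whose reduced movement indicates pain, is exactly
the class signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import FrameRecord

WINDOW = 3  # consecutive time steps stacked into the three channels

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class GrayStImage:
    """Stacked image; channel k is the grayscale frame at source_timestamps[k]."""

    subject_id: str
    video_id: str
    label: str
    source_timestamps: tuple[float, float, float]
    sample_index: int  # middle frame's sample index (representative time)
    image: np.ndarray  # H x W x 3 uint8

    @property
    def timestamp_s(self) -> float:
        return self.source_timestamps[1]


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """BT.601 luma: Y = 0.299 R + 0.587 G + 0.114 B, rounded half-up."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    y = image.astype(np.float64) @ _LUMA
    return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)


def stack_grayst(frames: list[FrameRecord], stride: int = 1) -> list[GrayStImage]:
    """Slide a width-3 window over one video's sampled frames.

    Windows advance by ``stride`` (1 = overlapping, 3 = disjoint
    triplets); output count is ``max(0, floor((N - 3) / stride) + 1)``.
    All frames must belong to one video, share a size, and be sorted by
    timestamp.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(frames) < WINDOW:
        return []
    shapes = {f.image.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame sizes: {sorted(shapes)}")
    videos = {f.video_id for f in frames}
    if len(videos) != 1:
        raise ValueError(f"frames from multiple videos: {sorted(videos)}")
    ts = [f.timestamp_s for f in frames]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("frames must be sorted by strictly increasing timestamp")

    grays = [rgb_to_gray(f.image) for f in frames]
    out = []
    for start in range(0, len(frames) - WINDOW + 1, stride):
        w = frames[start: start + WINDOW]
        out.append(
            GrayStImage(
                subject_id=w[0].subject_id,
                video_id=w[0].video_id,
                label=w[0].label,
                source_timestamps=(w[0].timestamp_s, w[1].timestamp_s, w[2].timestamp_s),
                sample_index=w[1].sample_index,
                image=np.stack(grays[start: start + WINDOW], axis=-1),
            )
        )
    return out
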