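"""Grayscale short-term stacking turns motion into apparent color.

Builds the preprocessing front end (sample at 1 Hz, detect, crop,
stack) for one subject's pair of videos and prints the cross-channel
intensity range of each stack — zero for a perfectly static scene
(neutral gray image), large when the subject moves between the three
stacked seconds.
"""

import numpy as np

from painpipe import PipelineConfig, SyntheticConfig, generate_dataset, handles_from_dataset
from painpipe.pipeline import preprocess_video

config = SyntheticConfig(
    n_subjects=2, fps=4.0, duration_s=20.0, frame_size=(48, 64), seed=3
)
handles = handles_from_dataset(generate_dataset(config))
pipeline = PipelineConfig(out_size=(32, 32))

print(f"{'video':<16}{'label':<10}{'stacks':>7}{'mean cross-channel range':>26}")
for handle in handles:
    if handle.subject_id != "s000":
        continue
    stacks, counts = preprocess_video(handle, pipeline)
    energy = np.mean(
        [(s.image.max(axis=-1).astype(int) - s.image.min(axis=-1)).mean() for s in stacks]
    )
    print(f"{handle.video_id:<16}{handle.label:<10}{len(stacks):>7}{energy:>26.1f}")

print(
    "\nThe no-pain video's stacks carry much more apparent color "
    "(cross-channel range) than the near-still pain video's: a 2-D "
    "classifier can now see short-term motion in a single image."
)
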