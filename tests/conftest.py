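import numpy as np
import pytest

from painpipe import (
    PipelineConfig,
    SyntheticConfig,
    generate_dataset,
    handles_from_dataset,
    prepare_frames,
)


def tiny_config(**kw) -> SyntheticConfig:
    """Small clean dataset: 5 subjects, 24 s @ 4 fps, no noise."""
    base = dict(
        n_subjects=5,
        fps=4.0,
        duration_s=24.0,
        frame_size=(48, 64),
        motion_amplitude_no_pain=4.0,
        motion_amplitude_pain=0.2,
        blur_prob=0.0,
        absent_frame_prob=0.0,
        occluded_frame_prob=0.0,
        atypical_bout_frac=0.0,
        appearance_shift=1.0,  # clean fixture is separable by appearance too
        seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def clean_dataset():
    return generate_dataset(tiny_config())


@pytest.fixture(scope="session")
def clean_handles(clean_dataset):
    return handles_from_dataset(clean_dataset)


@pytest.fixture(scope="session")
def clean_embeddings(clean_handles):
    cfg = PipelineConfig(out_size=(32, 32), backend_grid=4)
    embeddings, counts = prepare_frames(clean_handles, cfg)
    return embeddings, counts, cfg


def make_frame(value=0, shape=(8, 8, 3), **meta):
    """A FrameRecord with a constant image, for contract tests."""
    from painpipe.video_io import FrameRecord

    base = dict(
        subject_id="s000",
        video_id="s000_no_pain",
        label="no_pain",
        timestamp_s=0.0,
        sample_index=0,
        source_frame_index=0,
    )
    base.update(meta)
    return FrameRecord(image=np.full(shape, value, dtype=np.uint8), **base)
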