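"""Detector backends and crop geometry."""

import numpy as np
import pytest

from painpipe import (
    BoundingBox,
    Detection,
    OracleDetector,
    baseline_background_detector,
    crop_and_resize,
    detect_subject,
    generate_dataset,
    handles_from_dataset,
    sample_frames,
)
from painpipe.detect import CropError

from conftest import make_frame, tiny_config


def test_bounding_box_validation_and_iou():
    with pytest.raises(ValueError):
        BoundingBox(5, 0, 5, 10)
    a = BoundingBox(0, 0, 10, 10)
    assert a.iou(a) == 1.0
    assert a.iou(BoundingBox(10, 10, 20, 20)) == 0.0
    assert a.iou(BoundingBox(5, 0, 15, 10)) == pytest.approx(1 / 3)


def test_detection_score_iff_box():
    with pytest.raises(ValueError):
        Detection(BoundingBox(0, 0, 1, 1), None)
    with pytest.raises(ValueError):
        Detection(None, 0.5)


def test_crop_identity_on_full_frame_box():
    frame = make_frame(0, shape=(20, 30, 3))
    frame.image[:] = np.random.default_rng(0).integers(0, 255, frame.image.shape)
    out = crop_and_resize(frame, BoundingBox(0, 0, 30, 20), pad_frac=0.0, out_size=(20, 30))
    assert np.array_equal(out.image, frame.image)
    assert (out.label, out.timestamp_s, out.sample_index) == (
        frame.label, frame.timestamp_s, frame.sample_index)


def test_crop_shape_contract_and_clipping():
    frame = make_frame(100, shape=(50, 50, 3))
    out = crop_and_resize(frame, BoundingBox(10, 10, 30, 30), out_size=(40, 40))
    assert out.image.shape == (40, 40, 3)
    corner = crop_and_resize(frame, BoundingBox(0, 0, 5, 5), pad_frac=0.1, out_size=(8, 8))
    assert corner.image.shape == (8, 8, 3)


def test_degenerate_clipped_box_raises():
    frame = make_frame(0, shape=(10, 10, 3))
    with pytest.raises(CropError):
        crop_and_resize(frame, BoundingBox(20, 20, 25, 25), out_size=(4, 4))


def _two_blob_frames():
    """Static empty background for four frames, then a frame with two
    blobs of different sizes (areas 50 and 200 px^2)."""
    frames = []
    for k in range(5):
        img = np.zeros((40, 60, 3), dtype=np.uint8)
        if k == 4:
            img[5:10, 5:15] = 200      # 50 px^2
            img[20:30, 20:40] = 200    # 200 px^2
        frames.append(make_frame(0, shape=(40, 60, 3), sample_index=k, timestamp_s=float(k)))
        frames[-1].image = img
    return frames


def test_background_detector_picks_largest_component():
    frames = _two_blob_frames()
    det = baseline_background_detector(frames)
    d = detect_subject(frames[-1], det)
    assert d.found
    assert d.box.area >= 150  # the 200 px^2 blob, not the 50 px^2 one
    assert d.box.y_min >= 15


def test_background_detector_static_scene_detects_nothing():
    frames = [make_frame(90, shape=(20, 20, 3), sample_index=i) for i in range(4)]
    det = baseline_background_detector(frames)
    assert all(not detect_subject(f, det).found for f in frames)


def test_background_detector_single_frame_video():
    frame = make_frame(90, shape=(20, 20, 3))
    det = baseline_background_detector([frame])
    assert not detect_subject(frame, det).found


@pytest.mark.parametrize("seed", [0, 1])
def test_background_detector_tracks_moving_subject(seed):
    cfg = tiny_config(
        n_subjects=2, duration_s=15, occlusion_bar_count=0, appearance_shift=0.0, seed=seed
    )
    ds = generate_dataset(cfg)
    handles = handles_from_dataset(ds)
    video = next(h for h in handles if h.label == "no_pain")
    frames = sample_frames(video)
    det = baseline_background_detector(frames)
    oracle = OracleDetector([video])
    hits = total = 0
    for f in frames:
        d = detect_subject(f, det)
        truth = detect_subject(f, oracle)
        if d.found and truth.found:
            total += 1
            hits += d.box.iou(truth.box) >= 0.5
    assert total >= 5
    assert hits / total >= 0.9


def test_background_detector_through_pipeline(clean_handles):
    """The baseline detector plugs into the preprocessing front end; a
    near-static (pain) subject is absorbed into its own background model
    and yields fewer usable frames than a moving one — the documented
    limitation of background differencing."""
    from painpipe.pipeline import PipelineConfig, prepare_frames

    cfg = PipelineConfig(out_size=(32, 32), detector_kind="background", grayst_enabled=False)
    embeddings, counts = prepare_frames(clean_handles, cfg)
    assert counts["sampled"] == counts["detected"] + counts["dropped_no_detection"]
    by_label = {"pain": 0, "no_pain": 0}
    for e in embeddings:
        by_label[e.label] += 1
    assert by_label["no_pain"] > by_label["pain"]


def test_oracle_detector_replays_ground_truth(clean_handles):
    oracle = OracleDetector(clean_handles)
    video = clean_handles[0]
    frames = sample_frames(video)
    for f in frames:
        d = detect_subject(f, oracle)
        expected = video.boxes[f.source_frame_index]
        if expected is None:
            assert not d.found
        else:
            assert (d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max) == tuple(expected)
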