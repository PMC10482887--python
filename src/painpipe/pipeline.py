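"""Two-stage pipeline: train on everything, keep what the model trusts.

Stage 1 trains a classifier ("Model 1") on every preprocessed frame of
the training subjects. Its per-frame confidences then curate the
training set: for each training subject and each class, the N frames
scored most confidently in the video's known label form the Top-N set,
discarding occluded, blurred or otherwise uninformative frames. Stage 2
retrains the same head ("Model 2") on only those frames. Selection is
computed per cross-validation fold from training subjects only, so
held-out subjects never influence either model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import detect as _detect
from . import grayst as _grayst
from . import modeling as _modeling
from . import video_io as _video_io
from .modeling import CLASSES, Embedding, GnbModel

DEFAULT_TOP_N = 20
#: naive-Bayes posteriors are notoriously overconfident and poorly
#: calibrated: probability differences below this resolution carry no
#: evidence about frame quality. Confidences are quantized to this
#: resolution before ranking, so selection behaves as "high-confidence
#: band, earliest frames first" rather than ordering frames by
#: numerical artifacts of the independence approximation; ties fall
#: back to the declared order (earlier timestamp, then lower video id)
CONFIDENCE_RESOLUTION = 0.05


class LeakageError(ValueError):
    """Train/validation/test subject sets overlap."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself."""

    sample_interval_s: float = 1.0
    max_duration_s: float = 120.0
    detector_kind: str = "oracle"  # oracle | background | external
    detector_threshold: int = _detect.DEFAULT_DIFF_THRESHOLD
    pad_frac: float = _detect.DEFAULT_PAD_FRAC
    out_size: tuple[int, int] = (64, 64)
    grayst_enabled: bool = True
    grayst_stride: int = 1
    backend_kind: str = "pixel_stats"
    backend_grid: int = 8
    backend_histogram_bins: int = 0
    selection_n: int = DEFAULT_TOP_N
    var_smoothing: float = _modeling.DEFAULT_VAR_SMOOTHING


@dataclass
class ScoredFrame:
    """A preprocessed frame with Model-1 confidence in its video's label."""

    subject_id: str
    video_id: str
    label: str  # the video's known label
    sample_index: int
    timestamp_s: float
    probs: np.ndarray
    confidence: float
    embedding: np.ndarray


@dataclass
class TopFrameSet:
    """Per (subject, class) ordered high-confidence frame lists."""

    selection_size: int
    cells: dict[tuple[str, str], list[ScoredFrame]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def all_frames(self) -> list[ScoredFrame]:
        return [f for cell in self.cells.values() for f in cell]


@dataclass
class PipelineRun:
    """Artifacts and bookkeeping of one two-stage run on one fold."""

    config: PipelineConfig
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subjects: frozenset[str]
    model1: GnbModel
    model2: GnbModel
    top_frames: TopFrameSet
    frame_counts: dict[str, int]
    training_hashes: dict[str, str]
    training_refs: dict[str, list[tuple[str, str, int]]]
    test_frame_probs: dict[str, list[tuple[int, np.ndarray]]]  # model -> [(sample_index, probs)]
    test_frame_meta: list[tuple[str, str, str, int]]  # (subject, video, label, sample_index)


def preprocess_video(
    handle: _video_io.VideoHandle,
    config: PipelineConfig,
    detector=None,
) -> tuple[list, dict[str, int]]:
    """Sample, detect, crop and (optionally) GrayST-stack one video.

    Returns the image sequence flowing to the embedder plus per-reason
    drop counts (frame-count conservation: sampled = used + dropped;
    with stacking, "used" frames collapse into windows).
    """
    frames = _video_io.sample_frames(
        handle, config.sample_interval_s, config.max_duration_s
    )
    counts = {"sampled": len(frames), "dropped_no_detection": 0}
    if detector is None:
        detector = make_detector([handle], config)
    kept = []
    for frame in frames:
        det = _detect.detect_subject(frame, detector)
        if not det.found:
            counts["dropped_no_detection"] += 1
            continue
        kept.append(
            _detect.crop_and_resize(frame, det.box, config.pad_frac, config.out_size)
        )
    counts["detected"] = len(kept)
    if config.grayst_enabled:
        # a stack must cover three *consecutive* seconds: windows never
        # bridge a gap left by a dropped (undetected/absent) frame
        images = []
        for run in _consecutive_runs(kept):
            images.extend(_grayst.stack_grayst(run, stride=config.grayst_stride))
    else:
        images = kept
    counts["embedded"] = len(images)
    return images, counts


def _consecutive_runs(frames: list) -> list[list]:
    runs: list[list] = []
    for frame in frames:
        if runs and frame.sample_index == runs[-1][-1].sample_index + 1:
            runs[-1].append(frame)
        else:
            runs.append([frame])
    return runs


def make_detector(handles, config: PipelineConfig, frames=None):
    if config.detector_kind == "oracle":
        return _detect.OracleDetector(handles)
    if config.detector_kind == "background":
        if frames is None:
            raise ValueError("background detector needs the video's sampled frames")
        return _detect.baseline_background_detector(frames, config.detector_threshold)
    raise ValueError(f"unknown detector kind {config.detector_kind!r}")


def prepare_frames(
    handles: list[_video_io.VideoHandle],
    config: PipelineConfig,
    backend: _modeling.EmbedderBackend | None = None,
) -> tuple[list[Embedding], dict[str, int]]:
    """Run the full preprocessing + embedding front end over all videos.

    The embedder is deterministic and untrained, so embeddings can be
    computed once and re-split across cross-validation folds without
    leakage.
    """
    if backend is None:
        backend = _modeling.make_backend(
            config.backend_kind,
            grid=config.backend_grid,
            histogram_bins=config.backend_histogram_bins,
        )
    oracle = (
        _detect.OracleDetector(handles) if config.detector_kind == "oracle" else None
    )
    embeddings: list[Embedding] = []
    totals = {"sampled": 0, "dropped_no_detection": 0, "detected": 0, "embedded": 0}
    for handle in handles:
        if oracle is not None:
            detector = oracle
        else:
            frames = _video_io.sample_frames(
                handle, config.sample_interval_s, config.max_duration_s
            )
            detector = make_detector([handle], config, frames=frames)
        images, counts = preprocess_video(handle, config, detector=detector)
        for k, v in counts.items():
            totals[k] += v
        embeddings.extend(_modeling.embed(images, backend))
    return embeddings, totals


def _fit(embeddings: list[Embedding], config: PipelineConfig) -> GnbModel:
    X = np.stack([e.vector for e in embeddings])
    y = [e.label for e in embeddings]
    return _modeling.gnb_fit(X, y, classes=CLASSES, var_smoothing=config.var_smoothing)


def train_model1(embeddings: list[Embedding], config: PipelineConfig) -> GnbModel:
    """Fit the first-pass classifier on all training-subject frames."""
    if not embeddings:
        raise _modeling.FitError("empty training set")
    return _fit(embeddings, config)


def score_frames(model: GnbModel, embeddings: list[Embedding]) -> list[ScoredFrame]:
    """Confidence of each frame in its video's known label."""
    X = np.stack([e.vector for e in embeddings])
    probs = _modeling.gnb_predict_proba(model, X)
    scored = []
    for e, p in zip(embeddings, probs):
        scored.append(
            ScoredFrame(
                subject_id=e.subject_id,
                video_id=e.video_id,
                label=e.label,
                sample_index=e.sample_index,
                timestamp_s=e.timestamp_s,
                probs=p,
                confidence=_modeling.confidence_of(p, e.label, model.classes),
                embedding=e.vector,
            )
        )
    return scored


def select_top_frames(
    scored: list[ScoredFrame], n: int = DEFAULT_TOP_N, classes: tuple[str, ...] = CLASSES
) -> TopFrameSet:
    """Keep, per subject and class, the min(n, available) most confident
    frames of that subject's video of that class.

    Ranking is by confidence in the video's known label, descending,
    after quantization to ``CONFIDENCE_RESOLUTION``; ties break toward
    the earlier timestamp, then the lower video id (a deterministic
    total order). The quantization matters: a well-separated Gaussian
    head drives most typical frames' confidences within float noise of
    1, and ranking on sub-resolution differences would order frames by
    artifacts of the independence approximation instead of by evidence.
    """
    if n < 1:
        raise ValueError("selection size must be >= 1")
    q = CONFIDENCE_RESOLUTION
    top = TopFrameSet(selection_size=n)
    subjects = sorted({s.subject_id for s in scored})
    for subject in subjects:
        for label in classes:
            cell = [s for s in scored if s.subject_id == subject and s.label == label]
            if not cell:
                top.warnings.append(f"subject {subject} has no {label} frames")
                top.cells[(subject, label)] = []
                continue
            cell.sort(key=lambda s: (-round(s.confidence / q) * q, s.timestamp_s, s.video_id))
            top.cells[(subject, label)] = cell[:n]
    return top


def train_model2(top: TopFrameSet, config: PipelineConfig) -> GnbModel:
    """Refit the head on only the selected high-confidence frames."""
    frames = top.all_frames()
    if not frames:
        raise _modeling.FitError("empty Top-N selection")
    X = np.stack([f.embedding for f in frames])
    y = [f.label for f in frames]
    return _modeling.gnb_fit(X, y, classes=CLASSES, var_smoothing=config.var_smoothing)


def _training_hash(X: np.ndarray, refs: list[tuple[str, str, int]]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(repr(sorted(refs)).encode())
    return h.hexdigest()


def run_two_stage(
    embeddings: list[Embedding],
    train_subjects: set[str],
    val_subjects: set[str],
    test_subjects: set[str],
    config: PipelineConfig,
) -> PipelineRun:
    """Train Model 1, select Top-N, train Model 2, score the held-out
    subject's frames with both models.

    Validation subjects take no part in fitting (the Gaussian head has
    no checkpoint to tune); they are held aside purely to mirror the
    train/validate/test protocol and are never scored here.
    """
    sets = [set(train_subjects), set(val_subjects), set(test_subjects)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise LeakageError(f"subject overlap between splits: {sets[i] & sets[j]}")

    train_emb = [e for e in embeddings if e.subject_id in train_subjects]
    test_emb = [e for e in embeddings if e.subject_id in test_subjects]
    if not train_emb:
        raise _modeling.FitError("no training-subject frames")

    model1 = train_model1(train_emb, config)
    scored = score_frames(model1, train_emb)
    top = select_top_frames(scored, n=config.selection_n)
    model2 = train_model2(top, config)

    refs1 = [(e.subject_id, e.video_id, e.sample_index) for e in train_emb]
    top_frames = top.all_frames()
    refs2 = [(f.subject_id, f.video_id, f.sample_index) for f in top_frames]
    X1 = np.stack([e.vector for e in train_emb])
    X2 = np.stack([f.embedding for f in top_frames])

    test_probs: dict[str, list[tuple[int, np.ndarray]]] = {"model1": [], "model2": []}
    meta = []
    if test_emb:
        Xt = np.stack([e.vector for e in test_emb])
        p1 = _modeling.gnb_predict_proba(model1, Xt)
        p2 = _modeling.gnb_predict_proba(model2, Xt)
        for e, a, b in zip(test_emb, p1, p2):
            meta.append((e.subject_id, e.video_id, e.label, e.sample_index))
            test_probs["model1"].append((e.sample_index, a))
            test_probs["model2"].append((e.sample_index, b))

    return PipelineRun(
        config=config,
        train_subjects=frozenset(train_subjects),
        val_subjects=frozenset(val_subjects),
        test_subjects=frozenset(test_subjects),
        model1=model1,
        model2=model2,
        top_frames=top,
        frame_counts={
            "train_frames": len(train_emb),
            "top_frames": len(top_frames),
            "test_frames": len(test_emb),
        },
        training_hashes={
            "model1": _training_hash(X1, refs1),
            "model2": _training_hash(X2, refs2),
        },
        training_refs={"model1": refs1, "model2": refs2},
        test_frame_probs=test_probs,
        test_frame_meta=meta,
    )


def with_grayst(config: PipelineConfig, enabled: bool) -> PipelineConfig:
    return replace(config, grayst_enabled=enabled)
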