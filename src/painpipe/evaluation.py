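"""Leave-one-subject-out evaluation, frame-to-video aggregation, metrics.

LOSO cross-validation holds out every data point of one subject per
fold, preventing the classifier from exploiting individual identity;
with 24 subjects and a 4-subject validation draw this is the 19/4/1
train/validate/test protocol. Video-level prediction uses average
pooling: the per-class means of a video's frame probabilities, argmax
for the label, with an exact tie resolved conservatively to "no_pain".
Metrics pool held-out predictions across folds (per-fold metrics over
two videos would be degenerate) and are recomputable from the reported
confusion counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .modeling import CLASSES, Embedding
from .pipeline import PipelineConfig, PipelineRun, run_two_stage


class AggregationError(ValueError):
    """A video has zero scored frames (all dropped upstream)."""


class FoldConfigurationError(ValueError):
    """Too few subjects for the requested split sizes."""


@dataclass(frozen=True)
class FoldSplit:
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subjects: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.train_subjects & self.val_subjects
            or self.train_subjects & self.test_subjects
            or self.val_subjects & self.test_subjects
        ):
            raise ValueError("fold subject sets must be pairwise disjoint")
        if len(self.test_subjects) != 1:
            raise ValueError("LOSO fold must hold out exactly one test subject")


def make_loso_folds(
    subjects: list[str], n_val: int = 4, seed: int = 0
) -> list[FoldSplit]:
    """One fold per subject as test; ``n_val`` validation subjects drawn
    without replacement from the remainder using ``seed``."""
    subjects = sorted(set(subjects))
    if len(subjects) <= n_val + 1:
        raise FoldConfigurationError(
            f"need more than {n_val + 1} subjects for n_val={n_val}, got {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    folds = []
    for test in subjects:
        rest = [s for s in subjects if s != test]
        val = set(rng.choice(rest, size=n_val, replace=False))
        train = frozenset(s for s in rest if s not in val)
        folds.append(
            FoldSplit(
                train_subjects=train,
                val_subjects=frozenset(val),
                test_subjects=frozenset({test}),
            )
        )
    return folds


def aggregate_video(
    frame_probs: np.ndarray, classes: tuple[str, ...] = CLASSES, video_id: str = "?"
) -> tuple[np.ndarray, str]:
    """Average pooling over a video's frame probabilities.

    Returns (per-class mean scores, predicted label); an exact tie goes
    to "no_pain" — never flag pain with no evidence margin.
    """
    frame_probs = np.atleast_2d(np.asarray(frame_probs, dtype=np.float64))
    if frame_probs.size == 0:
        raise AggregationError(f"video {video_id}: no scored frames to aggregate")
    means = frame_probs.mean(axis=0)
    pain_idx = classes.index("pain")
    no_pain_idx = classes.index("no_pain")
    if means[pain_idx] > means[no_pain_idx]:
        return means, "pain"
    return means, "no_pain"


def compute_metrics(
    y_true: list[str], y_pred: list[str], positive_class: str = "pain"
) -> dict:
    """Accuracy / precision / recall / F1 with explicit confusion counts.

    An empty denominator (no predicted or no true positives) yields 0.0
    with a warning rather than NaN.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive_class and p == positive_class)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive_class and p == positive_class)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive_class and p != positive_class)
    tn = len(y_true) - tp - fp - fn
    n = len(y_true)

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: empty denominator, reporting 0.0", stacklevel=2)
            return 0.0
        return num / den

    accuracy = _safe(tp + tn, n, "accuracy")
    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "F1")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "n": n,
    }


@dataclass
class EvalReport:
    """Pooled held-out predictions and metrics for one model variant."""

    frame_true: list[str] = field(default_factory=list)
    frame_pred: list[str] = field(default_factory=list)
    video_rows: list[dict] = field(default_factory=list)  # subject, video, true, pred, scores

    def metrics(self) -> dict:
        return {
            "frame": compute_metrics(self.frame_true, self.frame_pred),
            "video": compute_metrics(
                [r["true"] for r in self.video_rows],
                [r["predicted"] for r in self.video_rows],
            ),
        }


def _collect_fold(run: PipelineRun, model_key: str, report: EvalReport) -> None:
    by_video: dict[str, list[np.ndarray]] = {}
    video_info: dict[str, tuple[str, str]] = {}
    for (subject, video, label, _idx), (_i, probs) in zip(
        run.test_frame_meta, run.test_frame_probs[model_key]
    ):
        by_video.setdefault(video, []).append(probs)
        video_info[video] = (subject, label)
        report.frame_true.append(label)
        report.frame_pred.append(CLASSES[int(np.argmax(probs))])
    for video, probs_list in by_video.items():
        subject, label = video_info[video]
        means, pred = aggregate_video(np.stack(probs_list), video_id=video)
        report.video_rows.append(
            {
                "subject": subject,
                "video": video,
                "true": label,
                "predicted": pred,
                "score_no_pain": float(means[CLASSES.index("no_pain")]),
                "score_pain": float(means[CLASSES.index("pain")]),
            }
        )


def cross_validate_embeddings(
    embeddings: list[Embedding],
    config: PipelineConfig,
    n_val: int = 4,
    seed: int = 0,
) -> dict:
    """LOSO over precomputed embeddings: run the two-stage pipeline per
    fold and pool held-out predictions across folds.

    Returns ``{"model1": EvalReport, "model2": EvalReport, "runs": [...]}``.
    """
    subjects = sorted({e.subject_id for e in embeddings})
    folds = make_loso_folds(subjects, n_val=n_val, seed=seed)
    reports = {"model1": EvalReport(), "model2": EvalReport()}
    runs = []
    for fold in folds:
        run = run_two_stage(
            embeddings,
            set(fold.train_subjects),
            set(fold.val_subjects),
            set(fold.test_subjects),
            config,
        )
        runs.append(run)
        for key in ("model1", "model2"):
            _collect_fold(run, key, reports[key])
    return {"model1": reports["model1"], "model2": reports["model2"], "runs": runs}


def cross_validate(
    handles,
    config: PipelineConfig,
    n_val: int = 4,
    seed: int = 0,
    grayst_modes: tuple[bool, ...] | None = None,
) -> dict:
    """Full evaluation grid: (Model 1, Model 2) x (GrayST on/off).

    ``grayst_modes`` defaults to the single mode in ``config``; pass
    ``(False, True)`` for the ablation grid. Returns nested metrics
    dictionaries keyed ``grayst_on`` / ``grayst_off``.
    """
    from .pipeline import prepare_frames, with_grayst

    if grayst_modes is None:
        grayst_modes = (config.grayst_enabled,)
    out: dict = {"modes": {}}
    for enabled in grayst_modes:
        cfg = with_grayst(config, enabled)
        embeddings, counts = prepare_frames(handles, cfg)
        result = cross_validate_embeddings(embeddings, cfg, n_val=n_val, seed=seed)
        key = "grayst_on" if enabled else "grayst_off"
        out["modes"][key] = {
            "frame_counts": counts,
            "model1": result["model1"].metrics(),
            "model2": result["model2"].metrics(),
            "reports": {"model1": result["model1"], "model2": result["model2"]},
            "runs": result["runs"],
        }
    return out
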