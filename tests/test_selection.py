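"""Two-stage orchestration: training, ranking, Top-N selection, leakage."""

import numpy as np
import pytest

from painpipe import (
    gnb_predict,
    run_two_stage,
    score_frames,
    select_top_frames,
    train_model1,
    train_model2,
)
from painpipe.modeling import Embedding, FitError
from painpipe.pipeline import (
    CONFIDENCE_RESOLUTION,
    LeakageError,
    PipelineConfig,
    ScoredFrame,
)


def gaussian_embeddings(rng, n_per_class, d=6, sep=3.0, subject="s000"):
    out = []
    for label, mu in (("no_pain", 0.0), ("pain", sep)):
        for i in range(n_per_class):
            out.append(
                Embedding(
                    vector=rng.normal(mu, 1.0, size=d),
                    subject_id=subject,
                    video_id=f"{subject}_{label}",
                    sample_index=i,
                    timestamp_s=float(i),
                    label=label,
                )
            )
    return out


def scored(subject, label, conf, ts, video=None):
    return ScoredFrame(
        subject_id=subject,
        video_id=video or f"{subject}_{label}",
        label=label,
        sample_index=int(ts),
        timestamp_s=ts,
        probs=np.array([1 - conf, conf]) if label == "pain" else np.array([conf, 1 - conf]),
        confidence=conf,
        embedding=np.zeros(2),
    )


class TestTrainModels:
    def test_separable_training_accuracy(self):
        emb = gaussian_embeddings(np.random.default_rng(0), 50)
        model = train_model1(emb, PipelineConfig())
        X = np.stack([e.vector for e in emb])
        y = [e.label for e in emb]
        acc = np.mean([p == t for p, t in zip(gnb_predict(model, X), y)])
        assert acc > 0.9

    def test_shuffled_labels_sit_at_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            emb = gaussian_embeddings(rng, 100, sep=3.0)
            labels = [e.label for e in emb]
            rng.shuffle(labels)
            for e, l in zip(emb, labels):
                e.label = l
            model = train_model1(emb, PipelineConfig())
            X = np.stack([e.vector for e in emb])
            accs.append(np.mean([p == t for p, t in zip(gnb_predict(model, X), labels)]))
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_uniform_duplication_leaves_parameters_unchanged(self):
        emb = gaussian_embeddings(np.random.default_rng(1), 20)
        a = train_model1(emb, PipelineConfig())
        b = train_model1(emb + emb, PipelineConfig())
        assert np.allclose(a.means, b.means)
        assert np.allclose(a.variances, b.variances)
        assert np.allclose(a.log_priors, b.log_priors)

    def test_single_class_rejected(self):
        emb = [e for e in gaussian_embeddings(np.random.default_rng(2), 5) if e.label == "pain"]
        with pytest.raises(FitError):
            train_model1(emb, PipelineConfig())


class TestSelectTopFrames:
    def test_keeps_min_of_n_and_available(self):
        frames = [scored("s000", "pain", 0.9 - 0.01 * i, float(i)) for i in range(5)]
        frames += [scored("s000", "no_pain", 0.8, float(i)) for i in range(30)]
        top = select_top_frames(frames, n=20)
        assert len(top.cells[("s000", "pain")]) == 5
        assert len(top.cells[("s000", "no_pain")]) == 20

    def test_quantized_confidences_non_increasing(self):
        rng = np.random.default_rng(3)
        frames = [scored("s000", "pain", rng.uniform(), float(i)) for i in range(50)]
        top = select_top_frames(frames, n=10)
        q = CONFIDENCE_RESOLUTION
        confs = [round(f.confidence / q) * q for f in top.cells[("s000", "pain")]]
        assert all(b <= a for a, b in zip(confs, confs[1:]))

    def test_tie_breaks_match_stable_sort_oracle(self):
        # several frames share one confidence at the cut: earlier timestamps win
        frames = [scored("s000", "pain", 0.99, float(t)) for t in (7, 3, 9, 1, 5)]
        frames += [scored("s000", "pain", 0.40, float(t)) for t in (0, 2)]
        top = select_top_frames(frames, n=3)
        kept = [f.timestamp_s for f in top.cells[("s000", "pain")]]
        oracle = sorted(
            [f for f in frames],
            key=lambda f: (-round(f.confidence / CONFIDENCE_RESOLUTION), f.timestamp_s, f.video_id),
        )[:3]
        assert kept == [f.timestamp_s for f in oracle] == [1.0, 3.0, 5.0]

    def test_selection_never_skips_higher_band(self):
        rng = np.random.default_rng(4)
        frames = [scored("s000", "no_pain", rng.uniform(), float(i)) for i in range(40)]
        top = select_top_frames(frames, n=15)
        q = CONFIDENCE_RESOLUTION
        kept = {f.timestamp_s for f in top.cells[("s000", "no_pain")]}
        worst_kept = min(round(f.confidence / q) for f in top.cells[("s000", "no_pain")])
        for f in frames:
            if f.timestamp_s not in kept:
                assert round(f.confidence / q) <= worst_kept

    def test_missing_class_records_warning(self):
        frames = [scored("s000", "pain", 0.9, 0.0)]
        top = select_top_frames(frames, n=5)
        assert top.cells[("s000", "no_pain")] == []
        assert any("no_pain" in w for w in top.warnings)


@pytest.fixture(scope="module")
def embeddings():
    rng = np.random.default_rng(5)
    out = []
    for i in range(4):
        out.extend(gaussian_embeddings(rng, 30, subject=f"s{i:03d}"))
    return out


class TestRunTwoStage:
    def test_overlap_rejected(self, embeddings):
        with pytest.raises(LeakageError):
            run_two_stage(embeddings, {"s000", "s001"}, {"s001"}, {"s002"}, PipelineConfig())

    def test_no_test_subject_in_training_refs(self, embeddings):
        run = run_two_stage(embeddings, {"s000", "s001", "s002"}, set(), {"s003"}, PipelineConfig())
        for refs in run.training_refs.values():
            assert all(r[0] != "s003" for r in refs)

    def test_reproducible_hashes(self, embeddings):
        cfg = PipelineConfig()
        a = run_two_stage(embeddings, {"s000", "s001", "s002"}, set(), {"s003"}, cfg)
        b = run_two_stage(embeddings, {"s000", "s001", "s002"}, set(), {"s003"}, cfg)
        assert a.training_hashes == b.training_hashes

    def test_select_all_reproduces_model1(self, embeddings):
        cfg = PipelineConfig(selection_n=10**6)
        run = run_two_stage(embeddings, {"s000", "s001", "s002"}, set(), {"s003"}, cfg)
        assert np.allclose(run.model1.means, run.model2.means)
        assert np.allclose(run.model1.variances, run.model2.variances)
        assert np.allclose(run.model1.log_priors, run.model2.log_priors)

    def test_frame_counts_conserved(self, embeddings):
        run = run_two_stage(embeddings, {"s000", "s001"}, {"s002"}, {"s003"}, PipelineConfig())
        assert run.frame_counts["train_frames"] == 2 * 2 * 30
        assert run.frame_counts["test_frames"] == 2 * 30
        assert run.frame_counts["top_frames"] == 2 * 2 * 20


def test_scored_confidence_is_label_probability():
    emb = gaussian_embeddings(np.random.default_rng(6), 25)
    model = train_model1(emb, PipelineConfig())
    for s in score_frames(model, emb):
        idx = model.classes.index(s.label)
        assert s.confidence == pytest.approx(s.probs[idx])
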