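"""Embedding backends and the Gaussian naive Bayes head."""

import numpy as np
import pytest

from painpipe import (
    CLASSES,
    GnbModel,
    PixelStatsEmbedder,
    confidence_of,
    gnb_fit,
    gnb_predict,
    gnb_predict_proba,
    make_backend,
)
from painpipe.modeling import CapabilityError, FitError


class TestPixelStatsEmbedder:
    def test_dim_contract(self):
        assert PixelStatsEmbedder(grid=8).dim == 3 * 64 + 64
        assert PixelStatsEmbedder(grid=4, histogram_bins=16).dim == 48 + 16 + 48
        e = PixelStatsEmbedder(grid=5, histogram_bins=8)
        img = np.random.default_rng(0).integers(0, 255, (33, 47, 3), dtype=np.uint8)
        assert e.embed_image(img).shape == (e.dim,)

    def test_deterministic(self):
        img = np.random.default_rng(1).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        e = PixelStatsEmbedder()
        assert np.array_equal(e.embed_image(img), e.embed_image(img))

    def test_single_pixel_sensitivity(self):
        img = np.full((16, 16, 3), 100, dtype=np.uint8)
        other = img.copy()
        other[3, 3, 1] = 250
        e = PixelStatsEmbedder(grid=8)
        assert not np.array_equal(e.embed_image(img), e.embed_image(other))

    def test_registry(self):
        assert isinstance(make_backend("pixel_stats", grid=4), PixelStatsEmbedder)
        with pytest.raises(CapabilityError):
            make_backend("external:vit")


class TestGnbFit:
    def test_hand_computed_moments(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = ["no_pain", "no_pain", "pain", "pain"]
        m = gnb_fit(X, y)
        assert m.means[:, 0] == pytest.approx([0.5, 2.5])
        assert m.variances[:, 0] == pytest.approx([0.25, 0.25], abs=1e-6)

    def test_priors_from_counts(self):
        X = np.zeros((4, 2))
        m = gnb_fit(X + np.random.default_rng(0).normal(size=(4, 2)),
                    ["no_pain"] * 3 + ["pain"])
        assert np.exp(m.log_priors) == pytest.approx([0.75, 0.25])

    def test_missing_class_rejected(self):
        with pytest.raises(FitError, match="pain"):
            gnb_fit(np.zeros((3, 2)), ["no_pain"] * 3)

    def test_constant_class_gets_smoothing_floor(self):
        X = np.array([[1.0], [1.0], [5.0], [9.0]])
        m = gnb_fit(X, ["no_pain", "no_pain", "pain", "pain"])
        assert m.variances[0, 0] == pytest.approx(m.var_smoothing_eps)
        probs = gnb_predict_proba(m, np.array([[1.0]]))
        assert np.all(np.isfinite(probs))


class TestGnbPredict:
    @pytest.fixture()
    def model(self):
        return gnb_fit(
            np.array([[0.0], [1.0], [2.0], [3.0]]),
            ["no_pain", "no_pain", "pain", "pain"],
        )

    def test_midpoint_symmetry(self, model):
        assert gnb_predict_proba(model, np.array([[1.5]]))[0] == pytest.approx([0.5, 0.5])

    def test_deep_inside_class(self, model):
        assert gnb_predict_proba(model, np.array([[0.5]]))[0, 0] > 0.99

    def test_prior_only_limit(self):
        m = GnbModel(
            classes=CLASSES,
            log_priors=np.log([0.75, 0.25]),
            means=np.zeros((2, 3)),
            variances=np.ones((2, 3)),
            var_smoothing_eps=1e-9,
        )
        probs = gnb_predict_proba(m, np.zeros((1, 3)))
        assert probs[0] == pytest.approx([0.75, 0.25])

    def test_dimension_mismatch(self, model):
        with pytest.raises(ValueError):
            gnb_predict_proba(model, np.zeros((1, 4)))

    def test_rows_sum_to_one(self, model):
        X = np.random.default_rng(2).normal(0, 3, size=(50, 1))
        probs = gnb_predict_proba(model, X)
        assert probs.sum(axis=1) == pytest.approx(np.ones(50), abs=1e-9)


class TestGnbProperties:
    def test_agrees_with_sklearn(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        y = np.array(["no_pain", "pain"] * 30)
        X[y == "pain"] += 0.8
        mine = gnb_fit(X, y)
        ref = GaussianNB(var_smoothing=1e-9).fit(X, y)
        Xt = rng.normal(size=(20, 5))
        assert gnb_predict_proba(mine, Xt) == pytest.approx(
            ref.predict_proba(Xt), abs=1e-8
        )

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = ["no_pain"] * 25 + ["pain"] * 15
        swapped = ["pain" if v == "no_pain" else "no_pain" for v in y]
        Xt = rng.normal(size=(10, 3))
        p = gnb_predict_proba(gnb_fit(X, y), Xt)
        q = gnb_predict_proba(gnb_fit(X, swapped), Xt)
        assert p == pytest.approx(q[:, ::-1], abs=1e-12)

    def test_feature_scaling_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        y = ["no_pain"] * 20 + ["pain"] * 20
        Xt = rng.normal(size=(10, 4))
        p = gnb_predict_proba(gnb_fit(X, y), Xt)
        q = gnb_predict_proba(gnb_fit(X * 37.5, y), Xt * 37.5)
        assert p == pytest.approx(q, abs=1e-9)

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(6)
        n = 10_000
        mu = {"no_pain": -1.0, "pain": 2.0}
        X = np.concatenate([rng.normal(mu["no_pain"], 1.5, size=(n, 1)),
                            rng.normal(mu["pain"], 0.7, size=(n, 1))])
        y = ["no_pain"] * n + ["pain"] * n
        m = gnb_fit(X, y)
        for i, (label, sd) in enumerate([("no_pain", 1.5), ("pain", 0.7)]):
            se = sd / np.sqrt(n)
            assert abs(m.means[i, 0] - mu[label]) < 3 * se


def test_confidence_of_reads_target_probability():
    assert confidence_of(np.array([0.9, 0.1]), "pain") == pytest.approx(0.1)
    assert confidence_of(np.array([0.9, 0.1]), "no_pain") == pytest.approx(0.9)
    assert confidence_of(np.array([0.5, 0.5]), "pain") == 0.5
    with pytest.raises(KeyError):
        confidence_of(np.array([0.5, 0.5]), "sleepy")
    with pytest.raises(ValueError):
        confidence_of(np.array([0.9, 0.9]), "pain")


def test_model_json_round_trip(tmp_path):
    m = gnb_fit(np.random.default_rng(7).normal(size=(20, 6)),
                ["no_pain", "pain"] * 10)
    path = tmp_path / "model.json"
    m.to_json(path)
    back = GnbModel.from_json(path)
    Xt = np.random.default_rng(8).normal(size=(5, 6))
    assert gnb_predict(back, Xt) == gnb_predict(m, Xt)
    assert gnb_predict_proba(back, Xt) == pytest.approx(gnb_predict_proba(m, Xt))
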