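"""Image embeddings and the Gaussian naive Bayes classification head.

Embedding backends are pluggable behind :class:`EmbedderBackend`; the
default :class:`PixelStatsEmbedder` is a deterministic, training-free
backend (per-channel downsampled intensity grid, optionally augmented
with per-channel histograms) that keeps the whole pipeline runnable on
a laptop. Pretrained encoders (e.g. a 512-d contrastive vision-language
model or a deep-CNN penultimate layer) plug in through the same
protocol and the backend registry.

The classification head is a from-scratch Gaussian naive Bayes: per
class, a log prior plus an axis-aligned Gaussian per feature with
population variances and a variance-smoothing floor. All densities are
computed in log space with log-sum-exp normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from PIL import Image
from scipy.special import logsumexp

CLASSES = ("no_pain", "pain")
DEFAULT_VAR_SMOOTHING = 1e-9


class CapabilityError(RuntimeError):
    """A requested backend is unavailable in this installation."""


class FitError(ValueError):
    """Invalid training set (e.g. a class with zero samples)."""


@dataclass
class Embedding:
    vector: np.ndarray
    subject_id: str
    video_id: str
    sample_index: int
    timestamp_s: float
    label: str


@runtime_checkable
class EmbedderBackend(Protocol):
    @property
    def dim(self) -> int: ...

    def embed_image(self, image: np.ndarray) -> np.ndarray: ...


class PixelStatsEmbedder:
    """Deterministic pixel-statistics embedding.

    The image is bilinearly downsampled to a ``grid x grid`` raster per
    channel and flattened to [0, 1]; a ``grid x grid`` raster of the
    per-pixel cross-channel range (channel dispersion — for a GrayST
    stack this is exactly the apparent-motion energy, for an RGB frame
    the color saturation) is appended, and with ``histogram_bins > 0``
    per-channel normalized intensity histograms as well. No training,
    no randomness: the same image always maps to the same vector, and
    a one-pixel change perturbs the vector.
    """

    def __init__(
        self, grid: int = 8, histogram_bins: int = 0, channel_range_grid: bool = True
    ) -> None:
        if grid < 1:
            raise ValueError("grid must be >= 1")
        self.grid = int(grid)
        self.histogram_bins = int(histogram_bins)
        self.channel_range_grid = bool(channel_range_grid)

    @property
    def dim(self) -> int:
        return (
            3 * self.grid * self.grid
            + (self.grid * self.grid if self.channel_range_grid else 0)
            + 3 * self.histogram_bins
        )

    def embed_image(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.uint8)
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ValueError(f"expected H x W x 3 image, got {image.shape}")
        small = np.asarray(
            Image.fromarray(image).resize((self.grid, self.grid), Image.BILINEAR),
            dtype=np.float64,
        )
        parts = [small.reshape(-1) / 255.0]
        if self.channel_range_grid:
            rng_img = image.max(axis=-1) - image.min(axis=-1)
            rng_small = np.asarray(
                Image.fromarray(rng_img).resize((self.grid, self.grid), Image.BILINEAR),
                dtype=np.float64,
            )
            parts.append(rng_small.reshape(-1) / 255.0)
        if self.histogram_bins:
            for c in range(3):
                hist, _ = np.histogram(
                    image[..., c], bins=self.histogram_bins, range=(0, 256)
                )
                parts.append(hist / hist.sum())
        return np.concatenate(parts)


_BACKEND_REGISTRY: dict[str, Callable[..., EmbedderBackend]] = {
    "pixel_stats": PixelStatsEmbedder,
}


def register_backend(name: str, factory: Callable[..., EmbedderBackend]) -> None:
    """Register an external embedder factory under ``external:<name>``."""
    _BACKEND_REGISTRY[f"external:{name}"] = factory


def make_backend(kind: str, **kwargs) -> EmbedderBackend:
    if kind not in _BACKEND_REGISTRY:
        raise CapabilityError(
            f"embedder backend {kind!r} is not available; "
            f"registered: {sorted(_BACKEND_REGISTRY)}"
        )
    return _BACKEND_REGISTRY[kind](**kwargs)


def embed(images: Iterable, backend: EmbedderBackend) -> list[Embedding]:
    """Embed FrameRecords or GrayStImages; one vector per image."""
    out = []
    for im in images:
        vec = np.asarray(backend.embed_image(im.image), dtype=np.float64)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite embedding for {im.video_id}[{im.sample_index}]")
        out.append(
            Embedding(
                vector=vec,
                subject_id=im.subject_id,
                video_id=im.video_id,
                sample_index=im.sample_index,
                timestamp_s=float(im.timestamp_s),
                label=im.label,
            )
        )
    return out


@dataclass
class GnbModel:
    """Fitted Gaussian naive Bayes parameters."""

    classes: tuple[str, ...]
    log_priors: np.ndarray  # (C,)
    means: np.ndarray  # (C, d)
    variances: np.ndarray  # (C, d), post-smoothing
    var_smoothing_eps: float

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown class {label!r}; classes are {self.classes}") from None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "classes": list(self.classes),
                "log_priors": self.log_priors.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "var_smoothing_eps": self.var_smoothing_eps,
            }
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "GnbModel":
        if isinstance(doc, Path) or (isinstance(doc, str) and not doc.lstrip().startswith("{")):
            doc = Path(doc).read_text()
        d = json.loads(doc)
        return cls(
            classes=tuple(d["classes"]),
            log_priors=np.asarray(d["log_priors"], dtype=np.float64),
            means=np.asarray(d["means"], dtype=np.float64),
            variances=np.asarray(d["variances"], dtype=np.float64),
            var_smoothing_eps=float(d["var_smoothing_eps"]),
        )


def gnb_fit(
    X: np.ndarray,
    y: Sequence[str],
    classes: tuple[str, ...] = CLASSES,
    var_smoothing: float = DEFAULT_VAR_SMOOTHING,
) -> GnbModel:
    """Fit per-class sample means and population variances.

    The smoothing floor added to every variance is
    ``var_smoothing * max_j Var(X_j)`` (overall per-feature variance),
    keeping densities finite when a feature is constant within a class.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_features)")
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c, n in counts.items():
        if n == 0:
            raise FitError(f"class {c!r} has no training samples")
    eps = var_smoothing * max(float(X.var(axis=0).max()), 1e-12)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    variances = np.stack([X[y == c].var(axis=0) for c in classes]) + eps
    priors = np.array([counts[c] / len(y) for c in classes])
    return GnbModel(
        classes=tuple(classes),
        log_priors=np.log(priors),
        means=means,
        variances=variances,
        var_smoothing_eps=eps,
    )


def gnb_log_joint(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """(n, C) array of log prior + summed log Gaussian densities."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension {model.dim}")
    # (n, C, d) broadcast of per-feature log N(x; mu, var)
    diff = X[:, None, :] - model.means[None, :, :]
    log_pdf = -0.5 * (
        np.log(2.0 * np.pi * model.variances)[None, :, :]
        + diff**2 / model.variances[None, :, :]
    )
    return model.log_priors[None, :] + log_pdf.sum(axis=2)


def gnb_predict_proba(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """Posterior class probabilities, rows summing to 1."""
    log_joint = gnb_log_joint(model, X)
    return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))


def gnb_predict(model: GnbModel, X: np.ndarray) -> list[str]:
    probs = gnb_predict_proba(model, X)
    return [model.classes[i] for i in probs.argmax(axis=1)]


def confidence_of(probs: np.ndarray, target_class: str, classes: tuple[str, ...] = CLASSES) -> float:
    """Confidence in ``target_class`` = that class's posterior probability."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1 or len(probs) != len(classes):
        raise ValueError("probs must be a per-class probability vector")
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError(f"probabilities sum to {probs.sum():.6f}, not 1")
    if target_class not in classes:
        raise KeyError(f"unknown class {target_class!r}")
    return float(probs[classes.index(target_class)])
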