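"""Gradient saliency attribution.

The saliency of an input element is the absolute partial derivative of the
model output — the pre-softmax logit of the target class for classification
(softmax saturation would null the gradients), or the scalar prediction for
regression — with respect to that element of the network input.  Per-sample
absolute gradients are accumulated (an L1 norm per wavelength across samples
and, for cubes, pixels) and normalized to sum to 1, giving a per-wavelength
contribution profile.  For cubes, summing over the band axis instead gives a
per-pixel spatial map.

Regression has no notion of "correctly classified", so samples are selected
by prediction error rate |measured - predicted| / measured; samples at or
below a threshold (5% or 10%) count as correctly predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import TrainedModel

__all__ = [
    "SaliencyProfile",
    "PixelSaliencyMap",
    "ErrorRateRule",
    "UntrainedModelError",
    "input_gradient",
    "select_correct_classified",
    "select_correct_regression",
    "wavelength_contributions",
    "pixel_saliency",
    "band_overlap",
]


class UntrainedModelError(RuntimeError):
    """Saliency requires a fitted :class:`TrainedModel`."""


@dataclass
class SaliencyProfile:
    """Nonnegative per-wavelength contributions summing to 1."""

    wavelengths: np.ndarray
    contributions: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.contributions = np.asarray(self.contributions, dtype=float)
        if self.wavelengths.shape != self.contributions.shape:
            raise ValueError("wavelengths and contributions must have equal length")
        if np.any(self.contributions < 0):
            raise ValueError("contributions must be nonnegative")
        if abs(self.contributions.sum() - 1.0) > 1e-9:
            raise ValueError("contributions must sum to 1")

    def mass_in(self, low: float, high: float) -> float:
        """Fraction of contribution mass with low <= wavelength <= high."""
        sel = (self.wavelengths >= low) & (self.wavelengths <= high)
        return float(self.contributions[sel].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.wavelengths, "contribution": self.contributions})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PixelSaliencyMap:
    """Per-pixel contribution grid for one cube sample."""

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("pixel saliency map must be 2-D")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("pixel saliency must be finite and nonnegative")


@dataclass
class ErrorRateRule:
    """Prediction-error-rate threshold defining 'correctly predicted'."""

    error_rate_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate_threshold < 1.0:
            raise ValueError("error rate threshold must be in (0, 1)")


def input_gradient(model: TrainedModel, samples: np.ndarray, targets: np.ndarray | None = None) -> np.ndarray:
    """Absolute gradient of the model output w.r.t. the (standardized)
    network input, one gradient tensor per sample.

    For classification, ``targets`` are the true class labels and the
    gradient is taken on the corresponding pre-softmax logits; for
    regression the scalar output's gradient is returned and ``targets`` is
    ignored.  The model runs in eval mode, so per-sample gradients are
    independent of the batch composition.
    """
    if not isinstance(model, TrainedModel):
        raise UntrainedModelError("saliency requires a TrainedModel (call train() first)")
    x = model._standardized(samples)
    out = model.net.forward(x, train=False)
    if model.task == "classification":
        if targets is None:
            raise ValueError("classification saliency needs target labels")
        targets = np.asarray(targets, dtype=int)
        dout = np.zeros_like(out)
        dout[np.arange(out.shape[0]), targets] = 1.0
    else:
        dout = np.ones_like(out)
    dx = model.net.backward(dout, need_input_grad=True)
    return np.abs(dx[:, 0])  # drop the channel axis


def select_correct_classified(model: TrainedModel, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Indices of samples whose argmax prediction matches the true label."""
    pred = model.predict(X)
    sel = np.flatnonzero(pred == np.asarray(labels))
    if sel.size == 0:
        warnings.warn("no correctly classified samples; downstream profiles will be empty")
    return sel


def select_correct_regression(
    model: TrainedModel, X: np.ndarray, measured: np.ndarray, rule: ErrorRateRule
) -> np.ndarray:
    """Indices with |measured - predicted| / measured <= threshold.

    Samples with a zero measured value have an undefined error rate and are
    excluded with a warning.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = model.predict(X)
    nonzero = measured != 0
    if not nonzero.all():
        warnings.warn(f"excluding {int((~nonzero).sum())} samples with measured value 0")
    rate = np.full(measured.shape, np.inf)
    rate[nonzero] = np.abs(measured[nonzero] - predicted[nonzero]) / np.abs(measured[nonzero])
    return np.flatnonzero(rate <= rule.error_rate_threshold)


def wavelength_contributions(gradients: np.ndarray, wavelengths: np.ndarray) -> SaliencyProfile:
    """L1 accumulation of absolute gradients into a per-wavelength profile.

    ``gradients`` is (n_samples, n_bands) for spectra or
    (n_samples, rows, cols, n_bands) for cubes (spatial axes are summed
    out); the result is normalized to sum to 1.
    """
    g = np.abs(np.asarray(gradients, dtype=float))
    if g.ndim < 2:
        raise ValueError("expected a batch of gradients (n_samples first)")
    if g.shape[0] == 0:
        raise ValueError("empty sample selection; no gradients to accumulate")
    contrib = g.sum(axis=tuple(range(g.ndim - 1)))
    total = contrib.sum()
    if total == 0:
        # a uniformly zero gradient field carries no information; keep the
        # sum-to-1 invariant with a flat profile
        contrib = np.full_like(contrib, 1.0 / contrib.size)
    else:
        contrib = contrib / total
    return SaliencyProfile(np.asarray(wavelengths, dtype=float), contrib)


def pixel_saliency(model3d: TrainedModel, sample: np.ndarray, sample_id: str = "") -> PixelSaliencyMap:
    """Absolute gradient summed over the band axis, per pixel, for one cube."""
    if model3d.config.input_kind != "cube":
        raise ValueError("pixel saliency needs a 3D (cube) model")
    sample = np.asarray(sample)
    if model3d.task == "classification":
        target = model3d.predict(sample[None])[:1]
        grad = input_gradient(model3d, sample[None], target)
    else:
        grad = input_gradient(model3d, sample[None])
    return PixelSaliencyMap(grad[0].sum(axis=-1), sample_id=sample_id)


def save_pixel_map_png(pixel_map: PixelSaliencyMap, path: str | Path, cmap: str = "viridis") -> None:
    """Render a pixel saliency map as a PNG with a low-to-high color bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    image = ax.imshow(pixel_map.values, cmap=cmap)
    fig.colorbar(image, ax=ax, label="pixel contribution")
    if pixel_map.sample_id:
        ax.set_title(pixel_map.sample_id)
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def band_overlap(
    profile: SaliencyProfile,
    low: float,
    high: float,
    top_fraction: float = 0.10,
    mode: str = "overlap",
) -> float:
    """Agreement between the top-``top_fraction`` saliency bands and the
    wavelength window [low, high].

    ``mode="overlap"`` (default) is the overlap coefficient: the fraction of
    the top bands that fall inside the window.  ``mode="jaccard"`` is the
    strict Jaccard index of the two band sets (note it is bounded above by
    the size ratio of the smaller to the larger set).
    """
    n_top = max(1, int(round(top_fraction * profile.wavelengths.size)))
    top_idx = np.argsort(-profile.contributions, kind="stable")[:n_top]
    top = np.zeros(profile.wavelengths.size, dtype=bool)
    top[top_idx] = True
    region = (profile.wavelengths >= low) & (profile.wavelengths <= high)
    inter = int((top & region).sum())
    if mode == "overlap":
        return inter / n_top
    if mode == "jaccard":
        union = int((top | region).sum())
        return inter / union if union else 0.0
    raise ValueError(f"unknown mode {mode!r}")
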