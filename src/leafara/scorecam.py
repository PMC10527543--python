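"""Score-CAM: gradient-free class-activation maps for the leaf classifier.

Each channel of a chosen convolutional layer is upsampled to input size,
min-max normalized, and used to mask the input; the increase of the target
class score of the masked input over an all-zeros baseline becomes the
channel's weight.  The heatmap is the ReLU of the softmax-weighted sum of
the activation maps, min-max normalized to [0, 1].  The whole procedure
needs only forward passes, so it works on any trained model without
gradient access.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import matplotlib
from skimage.transform import resize as _sk_resize

__all__ = ["ScoreCamMap", "score_cam", "overlay"]


@dataclass
class ScoreCamMap:
    """Saliency result for one image, layer, and target class."""

    heatmap: np.ndarray  # H x W in [0, 1]
    target_class: int
    layer: str
    baseline_score: float
    weights: np.ndarray  # per-channel, softmax-normalized


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi - lo <= 0:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def score_cam(
    model,
    image: np.ndarray,
    target_class: int,
    layer: str = "encoder",
    batch_size: int = 16,
    normalize_weights: bool = True,
) -> ScoreCamMap:
    """Compute a Score-CAM heatmap for ``image`` (shape (3, H, W), model-ready).

    ``model`` must expose ``encoder_activations(x)`` returning (1, C, h, w)
    feature maps and ``predict_proba(x)``.  Deterministic for a fixed model;
    all-zero activations yield an all-zero map with a warning.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("image must have shape (3, H, W)")
    H, W = x.shape[1:]
    acts = model.encoder_activations(x[None])[0]  # (C, h, w)
    C = acts.shape[0]
    up = np.stack(
        [_sk_resize(acts[c], (H, W), order=1, preserve_range=True) for c in range(C)]
    )
    norm = np.stack([_minmax(up[c]) for c in range(C)])
    if not norm.any():
        warnings.warn("all activation maps are zero; returning an all-zero heatmap")
        return ScoreCamMap(np.zeros((H, W)), target_class, layer, 0.0, np.zeros(C))

    baseline = float(model.predict_proba(np.zeros_like(x)[None])[0, target_class])
    scores = np.empty(C)
    masked = norm[:, None] * x[None]  # (C, 3, H, W)
    for i in range(0, C, batch_size):
        probs = model.predict_proba(masked[i : i + batch_size].astype(np.float32))
        scores[i : i + batch_size] = probs[:, target_class]
    raw = scores - baseline
    if normalize_weights:
        z = raw - raw.max()
        weights = np.exp(z) / np.exp(z).sum()
    else:
        weights = raw
    heat = np.maximum((weights[:, None, None] * norm).sum(axis=0), 0.0)
    return ScoreCamMap(_minmax(heat), target_class, layer, baseline, weights)


def overlay(image: np.ndarray, heatmap: np.ndarray, colormap: str = "jet",
            alpha: float = 0.6) -> np.ndarray:
    """Alpha-blend a heatmap onto an RGB image (uint8 H x W x 3).

    Blending weight is ``alpha * heat`` per pixel, so zero-heat pixels show
    the untouched image.
    """
    img = np.asarray(image)
    if img.shape[:2] != heatmap.shape:
        raise ValueError(f"image {img.shape[:2]} and heatmap {heatmap.shape} sizes differ")
    cmap = matplotlib.colormaps[colormap]
    colored = (cmap(heatmap)[..., :3] * 255).astype(float)
    a = (alpha * heatmap)[..., None]
    out = (1.0 - a) * img.astype(float) + a * colored
    return np.clip(out, 0, 255).astype(np.uint8)
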