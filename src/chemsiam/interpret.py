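"""Interpretability: Grad-CAM, GLCM saliency, and 2-D embedding projection.

The model is a metric learner, not a classifier, so Grad-CAM needs a
scalar objective: we use the negative squared distance between the
sample's embedding and a reference embedding (typically the anchor's).
High-attention regions are therefore the image regions pulling the
sample *toward* the reference. The heatmap is the channel-weighted,
ReLU-rectified activation of the last conv block, upsampled to the
input resolution and min–max normalized to [0, 1]. Saliency over the
texture branch is the absolute gradient of the same objective w.r.t.
the 64 GLCM entries, likewise normalized.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import zoom
from sklearn.decomposition import PCA

from .nn.network import SiameseNet
from .samples import MultimodalSample

__all__ = [
    "normalize_heatmap",
    "gradcam",
    "glcm_saliency",
    "project_embeddings",
]


def normalize_heatmap(values: np.ndarray) -> np.ndarray:
    """Min–max normalize to [0, 1]; an all-zero map is returned as-is
    (with a warning), and a constant positive map maps to all-ones.
    Idempotent."""
    v = np.asarray(values, dtype=np.float64)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        if vmax == 0.0:
            warnings.warn(
                "heatmap is identically zero (no gradient signal)", stacklevel=2
            )
            return np.zeros_like(v)
        return np.ones_like(v)
    return (v - vmin) / (vmax - vmin)


def _objective_backward(
    net: SiameseNet, sample: MultimodalSample, reference: np.ndarray
) -> np.ndarray:
    """Backprop the scalar −‖embed(sample) − reference‖²; returns d/d(GLCM)."""
    reference = np.asarray(reference, dtype=np.float64)
    emb = net.forward(sample.mep[None], sample.glcm[None])
    if reference.shape != (emb.shape[1],):
        raise ValueError(
            f"reference embedding must have shape ({emb.shape[1]},), "
            f"got {reference.shape}"
        )
    d_emb = -2.0 * (emb - reference[None, :])
    return net.backward(d_emb)


def gradcam(
    net: SiameseNet, sample: MultimodalSample, reference: np.ndarray
) -> np.ndarray:
    """Grad-CAM heatmap over the MEP image w.r.t. a reference embedding.

    Returns an ``input_size`` × ``input_size`` map in [0, 1] (max 1 for
    any non-degenerate input); all-zero when gradients vanish entirely.
    """
    _objective_backward(net, sample, reference)
    act = net.conv_act_[0]  # (C, h, w), last conv block post-ReLU
    grad = net.conv_grad_[0]
    alpha = grad.mean(axis=(1, 2))  # global-average-pooled gradients
    cam = np.maximum(np.tensordot(alpha, act, axes=1), 0.0)
    s = net.config.input_size
    cam = zoom(cam, (s / cam.shape[0], s / cam.shape[1]), order=1)
    return normalize_heatmap(np.maximum(cam, 0.0))


def glcm_saliency(
    net: SiameseNet, sample: MultimodalSample, reference: np.ndarray
) -> np.ndarray:
    """Normalized |∂ objective / ∂ GLCM entry| over the 64 texture inputs."""
    d_glcm = _objective_backward(net, sample, reference)
    return normalize_heatmap(np.abs(d_glcm[0]))


def project_embeddings(
    embeddings: dict[str, np.ndarray], method: str = "pca", seed: int = 0
) -> pd.DataFrame:
    """Project embeddings to 2-D for plotting; one (x, y) row per id.

    The default linear (principal-axis) projection is deterministic up
    to sign, which is fixed by orienting each axis so its largest-
    magnitude coordinate is positive.
    """
    if len(embeddings) < 3:
        raise ValueError("need at least 3 embeddings to project")
    if method != "pca":
        raise ValueError(f"unknown projection method {method!r}")
    ids = list(embeddings)
    mat = np.stack([np.asarray(embeddings[i], dtype=np.float64) for i in ids])
    coords = PCA(n_components=2, random_state=seed).fit_transform(mat)
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(coords, index=ids, columns=["x", "y"])
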