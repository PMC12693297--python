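"""The two-branch multimodal embedding network.

Architecture (weights shared across all triplet members, as "Siamese"
implies):

* **visual branch** — a small CNN over the MEP surface image: stacked
  conv→ReLU→2×2-max-pool blocks followed by global average pooling,
  yielding a spatial-visual feature vector;
* **texture branch** — a multilayer perceptron over the 64-d flattened
  GLCM of the RDG diagram, yielding a texture feature vector;
* **fusion** — the two vectors are concatenated and projected through
  dense layers into the shared embedding space where triplet loss and
  inverse-distance similarity operate.

Forward and backward passes are explicit, so interpretability hooks
(Grad-CAM needs the last conv block's activations and their gradient;
saliency needs the gradient at the GLCM input) fall out of one backward
call without any framework machinery.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .layers import Conv2D, Dense, GlobalAvgPool, MaxPool2, ReLU

__all__ = ["ModelConfig", "SiameseNet"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the two-branch network.

    Defaults are the smallest standard stack that trains a library of
    tens of compounds in seconds-to-minutes on one CPU: three conv blocks
    (32/64/128 filters, 3×3 kernels), an MLP 64→64→32, and a projector
    concat(160)→128→``embedding_dim``. Images are bilinearly resized to
    ``input_size``² and scaled to [0, 1] before entering the CNN.
    ``normalize_embeddings`` defaults off: unnormalized embeddings let
    pairwise distances exceed 1, matching reported inverse-distance
    similarities well below 0.5.
    """

    embedding_dim: int = 128
    conv_channels: tuple[int, ...] = (32, 64, 128)
    kernel_size: int = 3
    glcm_dim: int = 64
    mlp_hidden: tuple[int, ...] = (64, 32)
    proj_hidden: tuple[int, ...] = (128,)
    margin: float = 1.0
    input_size: int = 64
    normalize_embeddings: bool = False
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (
            self.embedding_dim,
            *self.conv_channels,
            self.glcm_dim,
            *self.mlp_hidden,
            *self.proj_hidden,
            self.input_size,
        )
        if any(s <= 0 for s in sizes):
            raise ValueError("all layer sizes must be positive")
        if self.margin <= 0:
            raise ValueError(f"margin must be > 0, got {self.margin}")
        stride = 2 ** len(self.conv_channels)
        if self.input_size % stride:
            raise ValueError(
                f"input_size must be divisible by {stride} "
                f"(one 2x pool per conv block)"
            )


class SiameseNet:
    """Explicit-backprop implementation of the multimodal embedder."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size

        self.cnn_layers: list = []
        cin = 3
        for cout in config.conv_channels:
            self.cnn_layers += [Conv2D(cin, cout, k, rng), ReLU(), MaxPool2()]
            cin = cout
        self.cnn_layers.append(GlobalAvgPool())
        # index of the last conv block's ReLU: Grad-CAM's target layer
        self._cam_idx = 3 * len(config.conv_channels) - 2

        self.mlp_layers: list = []
        fin = config.glcm_dim
        for fout in config.mlp_hidden:
            self.mlp_layers += [Dense(fin, fout, rng), ReLU()]
            fin = fout

        self.proj_layers: list = []
        fin = config.conv_channels[-1] + config.mlp_hidden[-1]
        for fout in config.proj_hidden:
            self.proj_layers += [Dense(fin, fout, rng), ReLU()]
            fin = fout
        # near-zero final projection: initial embeddings cluster at the
        # origin, so training starts at loss ~= margin with every triplet
        # active and the embedding geometry is shaped by the loss, not by
        # the random initialization.
        self.proj_layers.append(
            Dense(fin, config.embedding_dim, rng, init_scale=0.05)
        )

        self._all_layers = self.cnn_layers + self.mlp_layers + self.proj_layers
        # Interpretability captures, filled by backward():
        self.conv_act_: np.ndarray | None = None
        self.conv_grad_: np.ndarray | None = None

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._all_layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._all_layers for g in layer.grads]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.params):
            raise ValueError("state does not match this architecture")
        for p, s in zip(self.params, state):
            p[...] = s

    # -- branches -----------------------------------------------------------
    def cnn_branch(self, mep: np.ndarray) -> np.ndarray:
        """Visual features (n, conv_channels[-1]) from images (n, 3, s, s)."""
        s = self.config.input_size
        mep = np.asarray(mep, dtype=np.float64)
        if mep.ndim != 4 or mep.shape[1] != 3 or mep.shape[2:] != (s, s):
            raise ValueError(
                f"expected MEP batch of shape (n, 3, {s}, {s}), got {mep.shape}"
            )
        out = mep
        for i, layer in enumerate(self.cnn_layers):
            out = layer.forward(out)
            if i == self._cam_idx:
                self.conv_act_ = out
        return out

    def mlp_branch(self, glcm: np.ndarray) -> np.ndarray:
        """Texture features (n, mlp_hidden[-1]) from GLCM vectors (n, 64)."""
        glcm = np.asarray(glcm, dtype=np.float64)
        if glcm.ndim != 2 or glcm.shape[1] != self.config.glcm_dim:
            raise ValueError(
                f"expected GLCM batch of shape (n, {self.config.glcm_dim}), "
                f"got {glcm.shape}"
            )
        out = glcm
        for layer in self.mlp_layers:
            out = layer.forward(out)
        return out

    def fuse_project(self, visual: np.ndarray, texture: np.ndarray) -> np.ndarray:
        """Concatenate branch features and project into the shared space."""
        out = np.concatenate([visual, texture], axis=1)
        self._split = visual.shape[1]
        for layer in self.proj_layers:
            out = layer.forward(out)
        if self.config.normalize_embeddings:
            norm = np.sqrt(np.sum(out**2, axis=1, keepdims=True)) + 1e-12
            self._prenorm, self._norm = out, norm
            out = out / norm
        return out

    def forward(self, mep: np.ndarray, glcm: np.ndarray) -> np.ndarray:
        """Full forward pass: (images, GLCM vectors) -> embeddings (n, L)."""
        if mep.shape[0] != glcm.shape[0]:
            raise ValueError("MEP and GLCM batches must have equal length")
        return self.fuse_project(self.cnn_branch(mep), self.mlp_branch(glcm))

    # -- backward -----------------------------------------------------------
    def backward(self, d_emb: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. the embeddings.

        Fills every layer's parameter gradients, records the last conv
        block's activation gradient in ``conv_grad_`` (for Grad-CAM), and
        returns the gradient w.r.t. the GLCM input (for saliency).
        """
        g = np.asarray(d_emb, dtype=np.float64)
        if self.config.normalize_embeddings:
            y = self._prenorm / self._norm
            g = (g - y * np.sum(y * g, axis=1, keepdims=True)) / self._norm
        for layer in reversed(self.proj_layers):
            g = layer.backward(g)
        g_vis, g_tex = g[:, : self._split], g[:, self._split :]
        for i in range(len(self.cnn_layers) - 1, -1, -1):
            g_vis = self.cnn_layers[i].backward(g_vis)
            if i - 1 == self._cam_idx:
                self.conv_grad_ = g_vis
        for layer in reversed(self.mlp_layers):
            g_tex = layer.backward(g_tex)
        return g_tex

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str) -> None:
        """Save weights and config to a single ``.npz`` archive."""
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez_compressed(
            path, __config__=json.dumps(asdict(self.config)), **arrays
        )

    @classmethod
    def load(cls, path: str) -> "SiameseNet":
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            for key in ("conv_channels", "mlp_hidden", "proj_hidden"):
                cfg_dict[key] = tuple(cfg_dict[key])
            net = cls(ModelConfig(**cfg_dict))
            net.set_state([data[f"p{i}"] for i in range(len(net.params))])
        return net
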