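"""Scikit-learn-style estimator wrapping the multimodal triplet embedder.

``TripletEmbedder`` follows the sklearn contract (``get_params`` /
``set_params``, ``fit``, ``transform``, trailing-underscore fitted
attributes) so it composes with pipelines and model selection; the
training loop, network, and loss live in :mod:`chemsiam.train` and
:mod:`chemsiam.nn`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .nn.losses import inverse_distance_matrix
from .nn.network import ModelConfig, SiameseNet
from .samples import MultimodalSample
from .train import TrainConfig, train
from .triplets import Triplet

__all__ = ["TripletEmbedder"]


class TripletEmbedder(TransformerMixin, BaseEstimator):
    """Multimodal Siamese embedder trained with triplet loss.

    Each sample couples a molecular electrostatic potential image
    (CNN branch) with the 64-d GLCM texture vector of its reduced-density
    -gradient diagram (MLP branch); the fused embedding is trained so
    that Tanimoto-mined positives sit closer to their anchor than
    negatives by at least ``margin``. Similarity between two compounds is
    the inverse embedding distance 1 / (1 + d).

    Parameters mirror :class:`~chemsiam.nn.network.ModelConfig` and
    :class:`~chemsiam.train.TrainConfig`; see those classes for details.

    Attributes
    ----------
    net_ : SiameseNet
        The trained network (best-validation-epoch weights).
    history_ : TrainHistory
        Per-epoch train/validation losses, stop and best epochs.

    Examples
    --------
    >>> emb = TripletEmbedder(max_epochs=5, seed=0)      # doctest: +SKIP
    >>> emb.fit(samples, triplets=mined)                 # doctest: +SKIP
    >>> sim = emb.similarity(samples)                    # doctest: +SKIP
    """

    def __init__(
        self,
        embedding_dim: int = 128,
        conv_channels: tuple[int, ...] = (32, 64, 128),
        kernel_size: int = 3,
        mlp_hidden: tuple[int, ...] = (64, 32),
        proj_hidden: tuple[int, ...] = (128,),
        margin: float = 1.0,
        input_size: int = 64,
        normalize_embeddings: bool = False,
        lr: float = 1e-3,
        max_epochs: int = 20,
        patience: int = 5,
        val_fraction: float = 0.2,
        batch_size: int = 32,
        min_delta: float = 1e-4,
        seed: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.mlp_hidden = mlp_hidden
        self.proj_hidden = proj_hidden
        self.margin = margin
        self.input_size = input_size
        self.normalize_embeddings = normalize_embeddings
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.batch_size = batch_size
        self.min_delta = min_delta
        self.seed = seed

    # -- config assembly ----------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            embedding_dim=self.embedding_dim,
            conv_channels=tuple(self.conv_channels),
            kernel_size=self.kernel_size,
            mlp_hidden=tuple(self.mlp_hidden),
            proj_hidden=tuple(self.proj_hidden),
            margin=self.margin,
            input_size=self.input_size,
            normalize_embeddings=self.normalize_embeddings,
            lr=self.lr,
            seed=self.seed,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            batch_size=self.batch_size,
            min_delta=self.min_delta,
            seed=self.seed,
        )

    @staticmethod
    def _as_dict(
        X: dict[str, MultimodalSample] | list[MultimodalSample],
    ) -> dict[str, MultimodalSample]:
        if isinstance(X, dict):
            return X
        return {s.id: s for s in X}

    # -- sklearn surface ----------------------------------------------------
    def fit(self, X, y=None, triplets: list[Triplet] | None = None):
        """Fit on multimodal samples and mined triplets.

        Parameters
        ----------
        X : dict of id -> MultimodalSample, or list of MultimodalSample
        triplets : list of Triplet
            Statically mined (anchor, positive, negative) id triples.
        """
        if triplets is None:
            raise ValueError("fit requires mined triplets (triplets=...)")
        samples = self._as_dict(X)
        net = SiameseNet(self._model_config())
        self.net_, self.history_ = train(net, samples, triplets, self._train_config())
        return self

    def transform(self, X) -> np.ndarray:
        """Embed samples; rows follow the input order."""
        self._check_fitted()
        samples = list(self._as_dict(X).values())
        mep = np.stack([s.mep for s in samples])
        glcm = np.stack([s.glcm for s in samples])
        return self.net_.forward(mep, glcm)

    # -- domain conveniences ------------------------------------------------
    def embed_dict(self, X) -> dict[str, np.ndarray]:
        samples = self._as_dict(X)
        emb = self.transform(samples)
        return {s: emb[i] for i, s in enumerate(samples)}

    def similarity(self, X) -> pd.DataFrame:
        """Inverse-distance similarity matrix over the given samples."""
        return inverse_distance_matrix(self.embed_dict(X))

    def save(self, path: str) -> None:
        self._check_fitted()
        self.net_.save(path)

    @classmethod
    def from_checkpoint(cls, path: str) -> "TripletEmbedder":
        """Rebuild a fitted embedder from a saved network archive."""
        net = SiameseNet.load(path)
        cfg = net.config
        est = cls(
            embedding_dim=cfg.embedding_dim,
            conv_channels=cfg.conv_channels,
            kernel_size=cfg.kernel_size,
            mlp_hidden=cfg.mlp_hidden,
            proj_hidden=cfg.proj_hidden,
            margin=cfg.margin,
            input_size=cfg.input_size,
            normalize_embeddings=cfg.normalize_embeddings,
            lr=cfg.lr,
            seed=cfg.seed,
        )
        est.net_ = net
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise NotFittedError(
                "This TripletEmbedder is not fitted yet; call fit() or "
                "from_checkpoint() first."
            )
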