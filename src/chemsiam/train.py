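"""Triplet training loop with validation split and early stopping.

Training minimizes the mean triplet loss over mini-batches of mined
triplets. A fraction of the triplets is held out for validation; when
the validation loss stops improving for ``patience`` consecutive epochs
(plateau rule, minimum improvement ``min_delta``) training stops, and
the weights from the best validation epoch are restored. The default
20-epoch cap reflects the horizon at which libraries of this size
converge.

Because each compound's two modalities are fixed, a batch forwards each
*unique* compound once and the triplet-loss gradient is accumulated per
compound before one backward pass — triplet supervision at per-sample
cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn.losses import triplet_loss_batch
from .nn.network import SiameseNet
from .nn.optim import Adam
from .samples import MultimodalSample
from .triplets import Triplet

__all__ = ["TrainConfig", "TrainHistory", "split_triplets", "early_stop", "train"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 20
    patience: int = 5
    val_fraction: float = 0.2
    batch_size: int = 32
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if not (1 <= self.patience <= self.max_epochs):
            raise ValueError("require 1 <= patience <= max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses plus where training stopped and which epoch won.

    Epoch indices are 1-based; ``best_epoch`` is the epoch whose weights
    the trained model carries.
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


def split_triplets(
    triplets: list[Triplet], val_fraction: float, seed: int
) -> tuple[list[Triplet], list[Triplet]]:
    """Disjoint, exhaustive train/validation partition of the triplet list.

    Deterministic under a fixed seed; both parts are guaranteed
    non-empty.
    """
    if not (0.0 < val_fraction < 1.0):
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    n = len(triplets)
    if n < 2:
        raise ValueError("need at least 2 triplets to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = min(max(1, int(round(n * val_fraction))), n - 1)
    val_idx = set(order[:n_val].tolist())
    train = [t for i, t in enumerate(triplets) if i not in val_idx]
    val = [t for i, t in enumerate(triplets) if i in val_idx]
    return train, val


def early_stop(val_losses: list[float], patience: int, min_delta: float = 1e-4) -> bool:
    """True iff no new best validation loss in the last ``patience`` epochs.

    A new best must improve on the previous best by more than
    ``min_delta``; a plateau therefore counts toward stopping.
    """
    if not val_losses:
        raise ValueError("need at least one recorded validation loss")
    best_epoch = 0
    best = val_losses[0]
    for i, v in enumerate(val_losses[1:], start=1):
        if v < best - min_delta:
            best, best_epoch = v, i
    return (len(val_losses) - 1 - best_epoch) >= patience


def _index_triplets(
    triplets: list[Triplet], id_to_idx: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    try:
        ia = np.array([id_to_idx[t.anchor] for t in triplets])
        ip = np.array([id_to_idx[t.positive] for t in triplets])
        ineg = np.array([id_to_idx[t.negative] for t in triplets])
    except KeyError as exc:
        missing = exc.args[0]
        bad = next(t for t in triplets if missing in t)
        raise KeyError(f"triplet {tuple(bad)} references unknown sample {missing!r}")
    return ia, ip, ineg


def _eval_loss(
    net: SiameseNet,
    mep: np.ndarray,
    glcm: np.ndarray,
    idx: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> float:
    emb = net.forward(mep, glcm)
    return triplet_loss_batch(emb, *idx, margin=net.config.margin)


def train(
    net: SiameseNet,
    samples: dict[str, MultimodalSample],
    triplets: list[Triplet],
    cfg: TrainConfig | None = None,
) -> tuple[SiameseNet, TrainHistory]:
    """Train the network on mined triplets; returns it with best-epoch weights.

    Fully deterministic for a fixed seed, config, and data: the split,
    the per-epoch shuffles, and the (numpy) arithmetic are all seeded.
    """
    cfg = cfg or TrainConfig()
    train_set, val_set = split_triplets(triplets, cfg.val_fraction, cfg.seed)

    ids = sorted({i for t in triplets for i in t})
    id_to_idx = {s: k for k, s in enumerate(ids)}
    for s in ids:
        if s not in samples:
            bad = next(t for t in triplets if s in t)
            raise KeyError(f"triplet {tuple(bad)} references unknown sample {s!r}")
    mep = np.stack([samples[s].mep for s in ids])
    glcm = np.stack([samples[s].glcm for s in ids])

    val_idx = _index_triplets(val_set, id_to_idx)
    opt = Adam(net.params, net.grads, lr=net.config.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    hist = TrainHistory()
    best_val = np.inf
    best_state = net.get_state()
    margin = net.config.margin

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            # forward only the compounds this batch touches
            bids = sorted({i for t in batch for i in t})
            sub = {s: k for k, s in enumerate(bids)}
            rows = np.array([id_to_idx[s] for s in bids])
            ia, ip, ineg = _index_triplets(batch, sub)
            emb = net.forward(mep[rows], glcm[rows])
            loss, d_emb = triplet_loss_batch(
                emb, ia, ip, ineg, margin=margin, with_grad=True
            )
            opt.zero_grad()
            net.backward(d_emb)
            opt.step()
            epoch_loss += loss * len(batch)
            seen += len(batch)
        hist.train_loss.append(epoch_loss / max(seen, 1))
        val_loss = _eval_loss(net, mep, glcm, val_idx)
        hist.val_loss.append(val_loss)
        logger.info(
            "epoch %d: train %.4f val %.4f", epoch, hist.train_loss[-1], val_loss
        )
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_state = net.get_state()
            hist.best_epoch = epoch
        hist.stopped_epoch = epoch
        if early_stop(hist.val_loss, cfg.patience, cfg.min_delta):
            logger.info("early stop at epoch %d", epoch)
            break
    if hist.best_epoch == 0:
        hist.best_epoch = 1
    net.set_state(best_state)
    return net, hist
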