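"""Manifest and matrix I/O plus plotting (heatmaps, loss curves, overlays)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.ndimage import zoom

from .fingerprints import Compound
from .train import TrainHistory

__all__ = [
    "read_manifest",
    "write_manifest",
    "save_matrix_csv",
    "load_matrix_csv",
    "plot_heatmap",
    "plot_comparison",
    "plot_loss_curves",
    "history_to_csv",
    "render_overlay",
]

MANIFEST_COLUMNS = ["id", "smiles", "mep_path", "rdg_path"]


def read_manifest(path: str | Path) -> list[Compound]:
    """Read a compound manifest CSV (``id,smiles,mep_path,rdg_path``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate compound ids in manifest: {dupes}")
    out = []
    for _, row in df.iterrows():
        out.append(
            Compound(
                id=row["id"],
                smiles=row["smiles"],
                mep_path=row.get("mep_path"),
                rdg_path=row.get("rdg_path"),
            )
        )
    return out


def write_manifest(compounds: list[Compound], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": c.id,
                "smiles": c.smiles,
                "mep_path": c.mep_path,
                "rdg_path": c.rdg_path,
            }
            for c in compounds
        ]
    ).to_csv(path, index=False)


def save_matrix_csv(matrix: pd.DataFrame, path: str | Path, decimals: int | None = None) -> None:
    """Write a labelled square matrix as CSV; text output uses 3 decimals
    by convention, full precision when ``decimals`` is None."""
    if decimals is not None:
        matrix = matrix.round(decimals)
    matrix.to_csv(path, index_label="id")


def load_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_comparison(
    tanimoto: pd.DataFrame, invdist: pd.DataFrame, path: str | Path
) -> None:
    """Side-by-side structural (Tanimoto) vs model (d⁻¹) similarity heatmaps."""
    invdist = invdist.loc[tanimoto.index, tanimoto.columns]  # matching id order
    fig, axes = plt.subplots(1, 2, figsize=(12, 5))
    for ax, mat, title in (
        (axes[0], tanimoto, "Tanimoto (Morgan 2048, r=2)"),
        (axes[1], invdist, "Model similarity d$^{-1}$"),
    ):
        im = ax.imshow(mat.values, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_loss_curves(history: TrainHistory, path: str | Path) -> None:
    epochs = np.arange(1, len(history.train_loss) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(epochs, history.train_loss, label="train")
    ax.plot(epochs, history.val_loss, label="validation")
    ax.axvline(history.best_epoch, ls="--", c="gray", label="best epoch")
    ax.set_xlabel("epoch")
    ax.set_ylabel("triplet loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def history_to_csv(history: TrainHistory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "epoch": np.arange(1, len(history.train_loss) + 1),
            "train_loss": history.train_loss,
            "val_loss": history.val_loss,
        }
    ).to_csv(path, index=False)


def render_overlay(
    image: np.ndarray,
    heatmap: np.ndarray,
    path: str | Path,
    alpha: float = 0.45,
    cmap: str = "jet",
) -> np.ndarray:
    """Alpha-blend a [0, 1] attention map over an RGB image and save a PNG.

    The attention colorscale is independent of the image's own colors
    (red = strong contribution, blue = weak). Returns the blended uint8
    array with the same H×W as the input image.
    """
    img = np.asarray(image, dtype=np.float64) / 255.0
    h, w = img.shape[:2]
    hm = np.asarray(heatmap, dtype=np.float64)
    if hm.shape != (h, w):
        hm = zoom(hm, (h / hm.shape[0], w / hm.shape[1]), order=1)
        hm = np.clip(hm, 0.0, 1.0)
    colors = matplotlib.colormaps[cmap](hm)[..., :3]
    blended = (1 - alpha) * img + alpha * colors
    out = (np.clip(blended, 0, 1) * 255).round().astype(np.uint8)
    from PIL import Image as PILImage

    PILImage.fromarray(out).save(path)
    return out
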