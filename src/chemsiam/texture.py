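"""Gray-level co-occurrence (GLCM) texture features from RDG diagrams.

A reduced-density-gradient (RDG) diagram is a scatter-style plot whose
spike pattern encodes a molecule's non-covalent interaction profile. The
texture branch of the model summarizes such a diagram as an 8-level
gray-level co-occurrence matrix: the image is converted to luminance,
quantized into 8 equal-width bins over [0, 255], and co-occurring level
pairs are counted at a set of pixel displacements. The normalized 8×8
matrix, flattened row-major to a 64-vector, is the input of the
perceptron branch.

The co-occurrence counting itself is authored here (vectorized numpy)
because the contract — arbitrary (dy, dx) integer offsets accumulated
into one matrix, optional symmetric counting, normalization after
accumulation, optional background masking — is the exact quantity the
downstream model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "QuantizedGrid",
    "GLCMMatrix",
    "DEFAULT_OFFSETS",
    "load_image",
    "quantize",
    "glcm",
    "glcm_feature",
    "GLCMExtractor",
]

#: Distance-1 displacements in the four principal directions (dy, dx):
#: right, down, down-right, down-left. Accumulating all four makes the
#: descriptor robust to in-plane rotation of the diagram.
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class QuantizedGrid:
    """Integer level indices in [0, levels) with the source image's shape."""

    levels: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("quantized grid must be a non-empty 2-D array")
        if px.min() < 0 or px.max() >= self.levels:
            raise ValueError("pixel levels out of range [0, levels)")
        object.__setattr__(self, "pixels", px.astype(np.int64))


@dataclass(frozen=True)
class GLCMMatrix:
    """Co-occurrence counts (or probabilities) over quantized gray levels."""

    values: np.ndarray
    normalized: bool
    offsets: tuple[tuple[int, int], ...]

    @property
    def levels(self) -> int:
        return int(self.values.shape[0])


def load_image(path: str) -> np.ndarray:
    """Read a raster file as an H×W×3 uint8 array.

    Grayscale and palette images are promoted to three identical (or
    expanded) channels; an alpha channel is dropped.
    """
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except FileNotFoundError:
        raise FileNotFoundError(f"image file not found: {path}") from None
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr


def quantize(image: np.ndarray, levels: int = 8) -> QuantizedGrid:
    """Quantize an RGB (or already-gray) image into equal-width luminance bins.

    Luminance is the standard Rec. 601 weighting 0.299 R + 0.587 G +
    0.114 B, rounded to the nearest integer, then binned linearly into
    ``levels`` equal-width bins over [0, 255].
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(image)
    if arr.ndim == 3:
        lum = np.rint(arr[..., :3].astype(np.float64) @ _LUMA)
    elif arr.ndim == 2:
        lum = arr.astype(np.float64)
    else:
        raise ValueError(f"expected 2-D or 3-D image array, got ndim={arr.ndim}")
    lum = np.clip(lum, 0, 255)
    pixels = np.minimum((lum * levels / 256.0).astype(np.int64), levels - 1)
    return QuantizedGrid(levels=levels, pixels=pixels)


def glcm(
    q: QuantizedGrid,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    normalize: bool = True,
    mask_background: bool = False,
) -> GLCMMatrix:
    """Gray-level co-occurrence matrix of a quantized image.

    For each displacement (dy, dx), every pixel pair (p, p shifted by the
    displacement) contributes one count to cell (level(p), level(shifted));
    counts are accumulated over all offsets. With ``symmetric`` each pair
    is also counted in the transposed cell. With ``normalize`` the counts
    are divided by their total so the matrix sums to one.

    ``mask_background`` drops pairs where *both* pixels fall in the top
    luminance bin — useful for plots dominated by a white page background.
    """
    px = q.pixels
    h, w = px.shape
    levels = q.levels
    counts = np.zeros((levels, levels), dtype=np.float64)
    for dy, dx in offsets:
        if (dy, dx) == (0, 0):
            raise ValueError("offset (0, 0) is not a valid displacement")
        if abs(dy) >= h or abs(dx) >= w:
            raise ValueError(
                f"offset {(dy, dx)} exceeds image extent {(h, w)}"
            )
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        a = px[ys, xs]
        b = px[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)]
        if mask_background:
            keep = ~((a == levels - 1) & (b == levels - 1))
            a, b = a[keep], b[keep]
        pair_counts = np.bincount(
            (a.ravel() * levels + b.ravel()), minlength=levels * levels
        ).reshape(levels, levels)
        counts += pair_counts
        if symmetric:
            counts += pair_counts.T
    if normalize:
        total = counts.sum()
        if total == 0:
            raise ValueError("GLCM has zero total count; nothing to normalize")
        counts = counts / total
    return GLCMMatrix(values=counts, normalized=normalize, offsets=tuple(offsets))


def glcm_feature(g: GLCMMatrix) -> np.ndarray:
    """Flatten a normalized GLCM row-major into a feature vector.

    The default 8-level matrix yields the 64-vector consumed by the
    perceptron branch. Requires a normalized matrix so the vector is a
    probability distribution (sums to 1).
    """
    if not g.normalized:
        raise ValueError("glcm_feature requires a normalized GLCM (normalize=True)")
    return g.values.reshape(-1).copy()


class GLCMExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping RDG diagram images to GLCM texture vectors.

    Parameters
    ----------
    levels : int, default=8
        Number of gray levels; the output dimension is ``levels ** 2``.
    offsets : tuple of (dy, dx), default=DEFAULT_OFFSETS
        Pixel displacements accumulated into one matrix.
    symmetric : bool, default=True
        Count each pair in both orders.
    mask_background : bool, default=False
        Exclude pairs lying entirely in the top luminance bin.

    Examples
    --------
    >>> X = GLCMExtractor().fit_transform(["a.png", "b.png"])  # doctest: +SKIP
    >>> X.shape  # doctest: +SKIP
    (2, 64)
    """

    def __init__(
        self,
        levels: int = 8,
        offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
        symmetric: bool = True,
        mask_background: bool = False,
    ):
        self.levels = levels
        self.offsets = offsets
        self.symmetric = symmetric
        self.mask_background = mask_background

    def fit(self, X=None, y=None):
        # Stateless; nothing to estimate.
        self.n_features_out_ = self.levels**2
        return self

    def transform(self, X) -> np.ndarray:
        """Transform images (file paths or arrays) into texture vectors."""
        rows = []
        for item in X:
            img = load_image(item) if isinstance(item, (str, bytes)) else item
            g = glcm(
                quantize(img, self.levels),
                offsets=self.offsets,
                symmetric=self.symmetric,
                normalize=True,
                mask_background=self.mask_background,
            )
            rows.append(glcm_feature(g))
        return np.stack(rows) if rows else np.empty((0, self.levels**2))
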