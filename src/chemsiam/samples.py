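"""Multimodal sample preparation: one (MEP image, GLCM vector) pair per compound."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .fingerprints import Compound
from .texture import GLCMExtractor, load_image

__all__ = ["MultimodalSample", "preprocess_mep", "build_samples"]


@dataclass(frozen=True)
class MultimodalSample:
    """Preprocessed network input for one compound.

    ``mep`` is a (3, s, s) float array in [0, 1] (channels-first);
    ``glcm`` is the 64-d normalized texture vector of the RDG diagram.
    """

    id: str
    mep: np.ndarray
    glcm: np.ndarray


def preprocess_mep(image: np.ndarray, input_size: int) -> np.ndarray:
    """Resize an H×W×3 uint8 image bilinearly and scale to [0, 1], CHW."""
    im = Image.fromarray(np.asarray(image, dtype=np.uint8))
    im = im.resize((input_size, input_size), Image.BILINEAR)
    arr = np.asarray(im, dtype=np.float64) / 255.0
    return arr.transpose(2, 0, 1)


def build_samples(
    compounds: list[Compound],
    input_size: int = 64,
    extractor: GLCMExtractor | None = None,
) -> dict[str, MultimodalSample]:
    """Load and preprocess both modalities for every compound.

    Raises an error naming the compound if either image path is missing
    or unreadable.
    """
    extractor = extractor or GLCMExtractor()
    extractor.fit()
    out: dict[str, MultimodalSample] = {}
    for c in compounds:
        if not c.mep_path or not c.rdg_path:
            raise ValueError(f"compound {c.id!r} lacks an image path")
        try:
            mep = preprocess_mep(load_image(c.mep_path), input_size)
            glcm_vec = extractor.transform([c.rdg_path])[0]
        except (OSError, ValueError) as exc:
            raise type(exc)(f"compound {c.id!r}: {exc}") from exc
        out[c.id] = MultimodalSample(id=c.id, mep=mep, glcm=glcm_vec)
    return out
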