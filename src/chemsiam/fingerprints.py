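"""Morgan fingerprints and Tanimoto similarity.

Structural similarity between two molecules is scored with the Tanimoto
coefficient over binary circular (Morgan) fingerprints,

    S_T(A, B) = |A ∩ B| / |A ∪ B|,

where A and B are the sets of on-bits of 2048-bit, radius-2 Morgan
fingerprints computed from SMILES. These scores drive triplet mining for
the metric-learning model and serve as the structural baseline that the
learned inverse-distance similarity is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Compound",
    "Fingerprint",
    "SmilesParseError",
    "parse_smiles",
    "morgan_fingerprint",
    "tanimoto",
    "similarity_matrix",
]

# RDKit logs every rejected SMILES to stderr; we raise instead.
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Compound:
    """One library entry: identifier, structure, and its two rendered views.

    ``mep_path`` points to the molecular electrostatic potential (MEP)
    surface raster; ``rdg_path`` to the reduced-density-gradient (RDG)
    scatter diagram. Both are optional until the image pipeline is used.
    """

    id: str
    smiles: str
    mep_path: str | None = None
    rdg_path: str | None = None


@dataclass(frozen=True)
class Fingerprint:
    """A binary Morgan fingerprint: ``bits`` is a 0/1 uint8 vector."""

    bits: np.ndarray
    radius: int = 2

    @property
    def nbits(self) -> int:
        return int(self.bits.shape[0])

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        object.__setattr__(self, "bits", bits)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into a canonical RDKit molecule.

    Raises
    ------
    SmilesParseError
        If the string is empty or not valid SMILES; the message names the
        offending string.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(
    mol: Chem.Mol | str,
    radius: int = 2,
    nbits: int = 2048,
    chirality: bool = False,
) -> Fingerprint:
    """Compute a binary Morgan (circular) fingerprint.

    Parameters
    ----------
    mol
        An RDKit molecule or a SMILES string (parsed and canonicalized
        first, so SMILES dialect differences do not alter the result).
    radius
        Circular environment radius; 2 is the conventional ECFP4-like
        choice.
    nbits
        Folded length of the bit vector (default 2048).
    chirality
        Include chirality flags in the atom invariants (default off).
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    if nbits <= 0:
        raise ValueError(f"nbits must be > 0, got {nbits}")
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits, includeChirality=chirality
    )
    bv = gen.GetFingerprint(mol)
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(bv.GetOnBits())] = 1
    return Fingerprint(bits=bits, radius=radius)


def _as_bits(fp: Fingerprint | np.ndarray) -> np.ndarray:
    if isinstance(fp, Fingerprint):
        return fp.bits
    arr = np.asarray(fp)
    if arr.ndim != 1:
        raise ValueError("fingerprint must be a 1-D bit vector")
    return arr.astype(bool).astype(np.uint8)


def tanimoto(a: Fingerprint | np.ndarray, b: Fingerprint | np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two binary fingerprints.

    Two all-zero fingerprints give 0/0; by convention this returns 0.0
    (no shared substructure evidence) with a warning.
    """
    ba, bb = _as_bits(a), _as_bits(b)
    if ba.shape[0] != bb.shape[0]:
        raise ValueError(
            f"fingerprint length mismatch: {ba.shape[0]} vs {bb.shape[0]}"
        )
    inter = int(np.count_nonzero(ba & bb))
    union = int(np.count_nonzero(ba | bb))
    if union == 0:
        warnings.warn(
            "tanimoto of two empty fingerprints is undefined (0/0); returning 0.0",
            stacklevel=2,
        )
        return 0.0
    return inter / union


def similarity_matrix(
    compounds: list[Compound],
    radius: int = 2,
    nbits: int = 2048,
    chirality: bool = False,
) -> pd.DataFrame:
    """Pairwise Tanimoto matrix for a compound library.

    Returns a symmetric DataFrame with unit diagonal, indexed by compound
    id in input order. Any invalid SMILES raises an error naming the
    offending compound.
    """
    if len(compounds) < 2:
        raise ValueError("need at least 2 compounds for a similarity matrix")
    ids = [c.id for c in compounds]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids in manifest: {dupes}")
    fps = []
    for c in compounds:
        try:
            fps.append(morgan_fingerprint(c.smiles, radius, nbits, chirality))
        except SmilesParseError as exc:
            raise SmilesParseError(f"compound {c.id!r}: {exc}") from exc
    bits = np.stack([f.bits for f in fps]).astype(np.int64)
    inter = bits @ bits.T
    pop = bits.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(values, np.where(pop > 0, 1.0, 0.0))
    return pd.DataFrame(values, index=ids, columns=ids)
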