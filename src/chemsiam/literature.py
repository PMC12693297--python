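"""Standard structures of literature drugs used in the worked example.

These are the canonical published structures of four well-characterized
molecules spanning the two target systems the method has been applied
to: tacrine (THA) and donepezil (DNP), acetylcholinesterase inhibitors;
Δ9-tetrahydrocannabinol (THC), the cannabinoid used in heterodimer
design; and ponatinib, a BCR-ABL tyrosine-kinase inhibitor. THA–THC is
the classic illustration of the structural-similarity blind spot: their
Morgan/Tanimoto similarity is only 0.056 even though electrostatic and
non-covalent-interaction profiles relate them.
"""

from __future__ import annotations

from .fingerprints import Compound

__all__ = ["REFERENCE_SMILES", "reference_compounds"]

REFERENCE_SMILES: dict[str, str] = {
    # tacrine: 9-amino-1,2,3,4-tetrahydroacridine
    "THA": "Nc1c2c(nc3ccccc13)CCCC2",
    # Δ9-tetrahydrocannabinol
    "THC": "CCCCCc1cc2c(c(O)c1)C1C=C(C)CCC1C(C)(C)O2",
    # donepezil
    "DNP": "COc1cc2c(cc1OC)C(=O)C(CC1CCN(Cc3ccccc3)CC1)C2",
    # ponatinib
    "pona": "Cc1ccc(C(=O)Nc2ccc(CN3CCN(C)CC3)c(C(F)(F)F)c2)cc1C#Cc1cnc2cccnn12",
}


def reference_compounds() -> list[Compound]:
    """The bundled literature drugs as manifest-style compounds (no images)."""
    return [Compound(id=k, smiles=v) for k, v in REFERENCE_SMILES.items()]
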