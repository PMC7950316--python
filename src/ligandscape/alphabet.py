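"""The canonical 20-residue amino-acid alphabet used throughout.

Residues are kept in alphabetical one-letter order; every count matrix,
PSSM and positional profile indexes its residue axis in this order.
"""

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES = len(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_peptides(peptides) -> np.ndarray:
    """Encode equal-length peptides as an (n, L) integer matrix.

    Raises ValueError on residues outside the canonical alphabet or on
    mixed lengths.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides given")
    length = len(peptides[0])
    out = np.empty((len(peptides), length), dtype=np.int64)
    for i, pep in enumerate(peptides):
        if len(pep) != length:
            raise ValueError(
                f"mixed peptide lengths: expected {length}, got {len(pep)} "
                f"for {pep!r}"
            )
        try:
            out[i] = [AA_INDEX[aa] for aa in pep]
        except KeyError as exc:
            raise ValueError(f"invalid residue {exc.args[0]!r} in {pep!r}") from None
    return out


def decode_peptides(codes: np.ndarray) -> list:
    """Inverse of :func:`encode_peptides`."""
    return ["".join(AMINO_ACIDS[c] for c in row) for row in np.asarray(codes)]
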