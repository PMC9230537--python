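"""Amino-acid alphabet and background frequencies shared across the package.

The 20-letter canonical alphabet uses the ordering conventional for profile
HMM software (alphabetical one-letter codes).  Background frequencies follow
the Robinson & Robinson composition estimated from a large protein database,
which is the de-facto standard null model for profile-HMM log-odds scoring.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino acids in the column order used by all emission matrices.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residues that may appear in translations but are treated as unknown.
NON_CANONICAL: frozenset[str] = frozenset("BJOUXZ*")

# Robinson-Robinson amino-acid frequencies (renormalised to sum to one).
_RR = {
    "A": 0.0780, "C": 0.0152, "D": 0.0535, "E": 0.0668, "F": 0.0397,
    "G": 0.0831, "H": 0.0219, "I": 0.0577, "K": 0.0595, "L": 0.0911,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0403, "R": 0.0512,
    "S": 0.0709, "T": 0.0549, "V": 0.0641, "W": 0.0132, "Y": 0.0322,
}

BACKGROUND: np.ndarray = np.array([_RR[aa] for aa in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()
BACKGROUND.setflags(write=False)


def is_canonical(sequence: str) -> bool:
    """True iff every residue is one of the 20 canonical amino acids."""
    return bool(sequence) and all(c in AA_INDEX for c in sequence)


def encode(sequence: str) -> np.ndarray:
    """Encode a protein sequence as an integer vector over the alphabet.

    Raises ``ValueError`` on non-canonical residues.
    """
    try:
        return np.fromiter(
            (AA_INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence)
        )
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(
            f"non-canonical residue {exc.args[0]!r} in sequence"
        ) from None
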