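"""Amino-acid substitution scoring.

Pairwise homology calls use the BLOSUM60 matrix with an end-gap-free
(semi-global) Needleman-Wunsch objective.  The matrix is the canonical NCBI
BLOSUM60 shipped with biotite; the ambiguity residue X is rescored to 0
against everything so that unknown residues neither reward nor penalise an
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Canonical NCBI residue order for the 20 standard amino acids.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
#: Internal alphabet: the 20 standard residues plus X (anything else maps to X).
AA_ALPHABET = AA_ORDER + "X"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_INDEX = AA_INDEX["X"]


@lru_cache(maxsize=None)
def load_substitution_matrix(name: str = "BLOSUM60") -> np.ndarray:
    """Return a 21x21 integer score matrix over :data:`AA_ALPHABET`.

    Scores for the 20 standard residues come from the named NCBI matrix;
    the X row/column is 0 everywhere.
    """
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix

    alph = ProteinSequence.alphabet
    source = SubstitutionMatrix(alph, alph, name)
    mat = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = source.get_score(a, b)
    if not np.array_equal(mat, mat.T):
        raise ValueError(f"substitution matrix {name!r} is not symmetric")
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    gap_open is the cost of the first residue of a gap run and gap_extend the
    cost of each further residue, so a run of length k costs
    ``gap_open + (k - 1) * gap_extend``.  With ``end_gaps_free`` terminal gap
    runs in either sequence cost nothing (semi-global alignment).
    """

    matrix_name: str = "BLOSUM60"
    gap_open: int = -11
    gap_extend: int = -1
    end_gaps_free: bool = True

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    @property
    def matrix(self) -> np.ndarray:
        return load_substitution_matrix(self.matrix_name)


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into :data:`AA_ALPHABET`.

    Non-standard symbols (B, Z, U, *, ...) map to X.
    """
    if not seq:
        raise ValueError("empty protein sequence")
    return np.array([AA_INDEX.get(c, X_INDEX) for c in seq.upper()], dtype=np.int64)
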