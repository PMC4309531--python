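"""Pairwise protein homology by end-gap-free global alignment.

Two proteins are called homologous when their BLOSUM60 end-gap-free alignment
shows more than ``min_similarity_percent`` similar residues and their lengths
differ by less than ``max_length_diff_fraction`` of the longer one.
Similarity counts aligned residue pairs with a positive substitution score,
relative to the longer protein's length: a short protein cannot inflate its
similarity by matching a cherry-picked fragment of a longer one, and the
length gate bounds the deflation this can cause for genuine but truncated
homologs at a factor of two.  Identity counts exact matches over the aligned
span (terminal overhangs excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dp import DIAG, HORIZ, VERT, semiglobal_align
from .scoring import ScoringScheme, encode_protein


@dataclass(frozen=True)
class HomologyParams:
    """Thresholds of the homology predicate.

    The default 40% similarity cut-off defines protein families; the relaxed
    35% mode is used when extending the analysis to more distant genomes.
    """

    min_similarity_percent: float = 40.0
    max_length_diff_fraction: float = 0.5

    def __post_init__(self):
        if not (0 < self.min_similarity_percent <= 100):
            raise ValueError("min_similarity_percent must be in (0, 100]")
        if not (0 < self.max_length_diff_fraction < 1):
            raise ValueError("max_length_diff_fraction must be in (0, 1)")

    def relaxed(self, min_similarity_percent: float = 35.0) -> "HomologyParams":
        return HomologyParams(min_similarity_percent, self.max_length_diff_fraction)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_percent: float
    similarity_percent: float
    aligned_columns: int


def align_end_gap_free(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal end-gap-free (semi-global) alignment of two proteins."""
    scheme = scheme or ScoringScheme()
    ca = encode_protein(a)
    cb = encode_protein(b)
    mat = scheme.matrix
    S = mat[ca][:, cb]
    free = scheme.end_gaps_free
    score, moves, lead, tail = semiglobal_align(
        S, scheme.gap_open, scheme.gap_extend, free_rows=free, free_cols=free
    )

    rows_a = []
    rows_b = []
    i = j = 0
    identical = 0
    positives = 0
    for k, mv in enumerate(moves):
        if mv == DIAG:
            rows_a.append(a[i])
            rows_b.append(b[j])
            if lead <= k < tail:
                if ca[i] == cb[j] and a[i].upper() != "X":
                    identical += 1
                if mat[ca[i], cb[j]] > 0:
                    positives += 1
            i += 1
            j += 1
        elif mv == VERT:
            rows_a.append(a[i])
            rows_b.append("-")
            i += 1
        else:
            rows_a.append("-")
            rows_b.append(b[j])
            j += 1
    aligned_columns = tail - lead
    identity = 100.0 * identical / aligned_columns if aligned_columns else 0.0
    similarity = 100.0 * positives / max(len(a), len(b))
    return AlignmentResult(
        aligned_a="".join(rows_a),
        aligned_b="".join(rows_b),
        score=score,
        identity_percent=identity,
        similarity_percent=similarity,
        aligned_columns=aligned_columns,
    )


def similarity_metrics(result: AlignmentResult) -> tuple[float, float]:
    """(identity%, similarity%) of an alignment result."""
    return result.identity_percent, result.similarity_percent


def length_compatible(len_a: int, len_b: int, params: HomologyParams) -> bool:
    """Length gate: lengths must differ by < max_length_diff_fraction."""
    return abs(len_a - len_b) / max(len_a, len_b) < params.max_length_diff_fraction


def is_homolog_seq(
    a: str,
    b: str,
    params: HomologyParams | None = None,
    scheme: ScoringScheme | None = None,
) -> bool:
    """Homology predicate on raw sequences (symmetric)."""
    params = params or HomologyParams()
    if not length_compatible(len(a), len(b), params):
        return False
    result = align_end_gap_free(a, b, scheme)
    return result.similarity_percent > params.min_similarity_percent


def is_homolog(a, b, params: HomologyParams | None = None, scheme: ScoringScheme | None = None) -> bool:
    """Homology predicate on ProteinRecords (or anything with .aa_sequence)."""
    return is_homolog_seq(a.aa_sequence, b.aa_sequence, params, scheme)
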