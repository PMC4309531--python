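"""Progressive multiple alignment of protein families.

The guide tree is a UPGMA clustering of pairwise end-gap-free similarities;
merges extend the same semi-global DP to profile-to-profile alignment, where
a cell score is the average substitution score over all residue pairs drawn
from the two columns (gaps contributing nothing).  An external aligner can be
substituted as long as it returns the same row-per-member contract.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage

from ._dp import DIAG, HORIZ, VERT, semiglobal_align
from .genome_io import ProteinRecord
from .pairwise import align_end_gap_free
from .scoring import ScoringScheme, encode_protein


@dataclass
class FamilyAlignment:
    family_id: str
    rows: dict[str, str]  # protein/taxon id -> gapped sequence

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"family {self.family_id}: unequal row lengths {lengths}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def relabel(self, mapping: dict[str, str]) -> "FamilyAlignment":
        return FamilyAlignment(self.family_id, {mapping[k]: v for k, v in self.rows.items()})

    def column(self, c: int) -> list[str]:
        return [r[c] for r in self.rows.values()]


def _profile_freq(rows: list[str], n_symbols: int = 21) -> np.ndarray:
    """Per-column residue frequencies (normalised by row count; gaps -> 0)."""
    ncol = len(rows[0])
    freq = np.zeros((ncol, n_symbols))
    for row in rows:
        codes = encode_protein(row.replace("-", "X"))  # placeholder; gaps masked below
        for c, ch in enumerate(row):
            if ch != "-":
                freq[c, codes[c]] += 1.0
    return freq / len(rows)


def _merge(rows_a: dict[str, str], rows_b: dict[str, str], scheme: ScoringScheme) -> dict[str, str]:
    fa = _profile_freq(list(rows_a.values()))
    fb = _profile_freq(list(rows_b.values()))
    mat = scheme.matrix.astype(float)
    S = fa @ mat @ fb.T
    _, moves, _, _ = semiglobal_align(S, scheme.gap_open, scheme.gap_extend, True, True)
    out: dict[str, str] = {k: [] for k in itertools.chain(rows_a, rows_b)}
    i = j = 0
    for mv in moves:
        if mv == DIAG:
            for k, r in rows_a.items():
                out[k].append(r[i])
            for k, r in rows_b.items():
                out[k].append(r[j])
            i += 1
            j += 1
        elif mv == VERT:
            for k, r in rows_a.items():
                out[k].append(r[i])
            for k in rows_b:
                out[k].append("-")
            i += 1
        else:
            for k in rows_a:
                out[k].append("-")
            for k, r in rows_b.items():
                out[k].append(r[j])
            j += 1
    return {k: "".join(v) for k, v in out.items()}


def align_family(
    members: list[ProteinRecord],
    scheme: ScoringScheme | None = None,
    family_id: str = "",
) -> FamilyAlignment:
    """Progressive MSA of family members (UPGMA guide tree over pairwise
    end-gap-free similarity)."""
    scheme = scheme or ScoringScheme()
    if not members:
        raise ValueError("empty family")
    if len(members) == 1:
        return FamilyAlignment(family_id, {members[0].protein_id: members[0].aa_sequence})
    n = len(members)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align_end_gap_free(members[i].aa_sequence, members[j].aa_sequence, scheme)
            dist[i, j] = dist[j, i] = 100.0 - res.similarity_percent
    condensed = dist[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method="average")
    clusters: dict[int, dict[str, str]] = {
        i: {m.protein_id: m.aa_sequence} for i, m in enumerate(members)
    }
    for step, (a, b, _, _) in enumerate(Z):
        merged = _merge(clusters.pop(int(a)), clusters.pop(int(b)), scheme)
        clusters[n + step] = merged
    (rows,) = clusters.values()
    return FamilyAlignment(family_id, rows)
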