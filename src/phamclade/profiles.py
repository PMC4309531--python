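"""Position-specific family profiles and remote-homolog screening.

A profile stores per-column log-odds scores (half-bit units, like the
substitution matrices) built from weighted counts plus substitution-matrix
pseudocounts.  Significance comes from an extreme-value (Gumbel) fit to the
scores of shuffled decoy proteins, so a hit's e-value is
``db_size * P_null(score >= s)``.  Genomes are retained by the screen when at
least ``min_hits`` distinct family profiles find a significant match —
profile searches pick up homologs well below the pairwise 40% similarity
gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from ._dp import semiglobal_score
from .genome_io import GenomeRecord, ProteinRecord, extract_proteome
from .msa import FamilyAlignment
from .scoring import AA_ORDER, ScoringScheme, encode_protein

#: Robinson & Robinson amino-acid background frequencies (normalised).
_BG = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019, "Q": 0.043,
    "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051, "L": 0.090, "K": 0.057,
    "M": 0.022, "F": 0.039, "P": 0.052, "S": 0.071, "T": 0.058, "W": 0.013,
    "Y": 0.032, "V": 0.064,
}
BACKGROUND = np.array([_BG[a] for a in AA_ORDER])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


@dataclass
class FamilyProfile:
    family_id: str
    log_odds: np.ndarray  # (length, 21), X column = 0
    background: np.ndarray
    calibration: tuple[float, float] | None = None  # Gumbel (location, scale)
    gap_open: float = -11.0
    gap_extend: float = -1.0

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def score_sequence(self, aa_sequence: str) -> float:
        """Overhang-free (local-style) score: unmatched ends of either the
        profile or the target cost nothing, so a remote homolog scores on the
        conserved stretch it still shares with the family rather than paying
        for every diverged column."""
        codes = encode_protein(aa_sequence)
        S = self.log_odds[:, codes]
        return semiglobal_score(S, self.gap_open, self.gap_extend, free_rows=True, free_cols=True)

    def e_value(self, score: float, db_size: int) -> float:
        if self.calibration is None:
            raise ValueError(f"profile {self.family_id} is not calibrated")
        loc, scale = self.calibration
        return db_size * float(gumbel_r.sf(score, loc=loc, scale=scale))


def _position_based_weights(rows: list[str]) -> np.ndarray:
    """Henikoff position-based sequence weights, normalised to sum 1."""
    n = len(rows)
    w = np.zeros(n)
    for c in range(len(rows[0])):
        col = [r[c] for r in rows]
        residues = [x for x in col if x != "-"]
        if not residues:
            continue
        counts: dict[str, int] = {}
        for x in residues:
            counts[x] = counts.get(x, 0) + 1
        r = len(counts)
        for i, x in enumerate(col):
            if x != "-":
                w[i] += 1.0 / (r * counts[x])
    if w.sum() == 0:
        w[:] = 1.0
    return w / w.sum()


def build_profile(
    msa: FamilyAlignment,
    scheme: ScoringScheme | None = None,
    pseudocount_mass: float = 5.0,
    n_decoys: int = 200,
    seed: int = 0,
) -> FamilyProfile:
    """Build and calibrate a log-odds profile from a family alignment.

    Columns that are entirely gaps are dropped with a warning.  Calibration
    scores ``n_decoys`` shuffled member sequences and fits a Gumbel
    location/scale to them.
    """
    scheme = scheme or ScoringScheme()
    rows = list(msa.rows.values())
    weights = _position_based_weights(rows)
    mat = scheme.matrix[:20, :20].astype(float)
    # matrix-conditional substitution probabilities q(a|b) ∝ bg(a) 2^(s(a,b)/2)
    cond = BACKGROUND[:, None] * np.power(2.0, mat / 2.0)
    cond = cond / cond.sum(axis=0, keepdims=True)

    aa_index = {a: i for i, a in enumerate(AA_ORDER)}
    n_eff = len(rows)
    columns = []
    for c in range(msa.n_columns):
        counts = np.zeros(20)
        for w, row in zip(weights, rows):
            ch = row[c]
            if ch in aa_index:
                counts[aa_index[ch]] += w
        if counts.sum() == 0:
            warnings.warn(f"family {msa.family_id}: all-gap column {c} dropped", stacklevel=2)
            continue
        f = counts / counts.sum()
        g = cond @ f
        f_adj = (n_eff * f + pseudocount_mass * g) / (n_eff + pseudocount_mass)
        columns.append(f_adj)
    if not columns:
        raise ValueError(f"family {msa.family_id}: no informative columns")
    freqs = np.array(columns)
    log_odds = np.zeros((len(columns), 21))
    log_odds[:, :20] = 2.0 * np.log2(freqs / BACKGROUND[None, :])

    profile = FamilyProfile(
        family_id=msa.family_id,
        log_odds=log_odds,
        background=BACKGROUND.copy(),
        gap_open=float(scheme.gap_open),
        gap_extend=float(scheme.gap_extend),
    )
    rng = np.random.default_rng(seed)
    ungapped = [r.replace("-", "") for r in rows]
    scores = np.empty(n_decoys)
    for d in range(n_decoys):
        src = list(ungapped[int(rng.integers(len(ungapped)))])
        rng.shuffle(src)
        scores[d] = profile.score_sequence("".join(src))
    loc, scale = gumbel_r.fit(scores)
    profile.calibration = (float(loc), float(scale))
    return profile


def search_proteome(
    profile: FamilyProfile,
    proteome: list[ProteinRecord],
    db_size: int | None = None,
) -> list[tuple[str, float, float]]:
    """Score every protein against a calibrated profile.

    Returns (protein_id, score, e_value) sorted by ascending e-value.
    """
    db_size = db_size if db_size is not None else len(proteome)
    hits = [
        (p.protein_id, (s := profile.score_sequence(p.aa_sequence)), profile.e_value(s, db_size))
        for p in proteome
    ]
    hits.sort(key=lambda h: (h[2], -h[1], h[0]))
    return hits


@dataclass
class ScreenResult:
    genome_id: str
    n_families_hit: int
    retained: bool
    proteome_size: int = 0

    @property
    def proteome_fraction(self) -> float:
        return 100.0 * self.n_families_hit / self.proteome_size if self.proteome_size else 0.0


def screen_genomes(
    profiles: list[FamilyProfile],
    genomes,
    min_hits: int = 20,
    e_threshold: float = 0.001,
) -> list[ScreenResult]:
    """Count, per genome, how many family profiles find at least one
    significant match; genomes with >= min_hits such families are retained.

    ``genomes`` may be GenomeRecords or (genome_id, proteome) pairs; the
    search-space size for e-values is the total number of proteins scanned in
    this screen.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    items = []
    for g in genomes:
        if isinstance(g, GenomeRecord):
            items.append((g.genome_id, extract_proteome(g)))
        else:
            items.append(tuple(g))
    db_size = sum(len(prot) for _, prot in items)
    results = []
    for genome_id, proteome in items:
        n_hit = 0
        for profile in profiles:
            for p in proteome:
                s = profile.score_sequence(p.aa_sequence)
                if profile.e_value(s, db_size) < e_threshold:
                    n_hit += 1
                    break
        results.append(
            ScreenResult(
                genome_id=genome_id,
                n_families_hit=n_hit,
                retained=n_hit >= min_hits,
                proteome_size=len(proteome),
            )
        )
    return results
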