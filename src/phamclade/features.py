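"""Per-genome and per-clade descriptive statistics, codon-usage comparison
against a host, and coverage-based genome-termini detection.

``PUBLISHED_GENOME_TABLE`` carries the published characteristics (length,
predicted ORFs, GC%, tRNA count, accession) of the eleven PAK_P1-like and
KPP10-like phage genomes, used for clade-aggregate computations without any
download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, reverse_complement

logger = logging.getLogger(__name__)

#: Published per-genome characteristics of the two clades.
#: columns: clade, name, length (bp), predicted ORFs, GC%, functional tRNAs,
#: pseudo tRNAs, accession
PUBLISHED_GENOME_TABLE = pd.DataFrame(
    [
        ("PAK_P1-like", "PAK_P1", 93398, 181, 49.50, 13, 0, "KC862297"),
        ("PAK_P1-like", "PAK_P2", 92495, 176, 49.30, 11, 0, "KC862298"),
        ("PAK_P1-like", "PAK_P4", 93147, 174, 49.30, 13, 1, "KC862300"),
        ("PAK_P1-like", "JG004", 93017, 161, 49.30, 12, 0, "NC_019450.1"),
        ("PAK_P1-like", "C2-10_Ab1", 92777, 158, 49.28, 12, 0, "NC_019918.1"),
        ("PAK_P1-like", "PaP1", 91715, 157, 49.40, 13, 0, "NC_019913.1"),
        ("KPP10-like", "KPP10", 88322, 146, 54.80, 3, 0, "NC_015272.1"),
        ("KPP10-like", "PAK_P3", 88097, 165, 54.80, 3, 0, "KC862299"),
        ("KPP10-like", "PAK_P5", 88789, 164, 54.70, 3, 0, "KC862301"),
        ("KPP10-like", "CHA_P1", 88255, 166, 54.60, 3, 0, "KC862295"),
        ("KPP10-like", "LSL4", 87739, 165, 54.80, 3, 0, "not-deposited"),
    ],
    columns=["clade", "name", "length", "n_orfs", "gc_percent", "n_trna", "n_trna_pseudo", "accession"],
)


@dataclass
class GenomeStats:
    genome_id: str
    length: int
    gc_percent: float
    n_cds: int
    n_trna: int
    n_trna_pseudo: int


def gc_content(sequence: str) -> float:
    """GC% over unambiguous bases only."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    return 100.0 * gc / (gc + at) if gc + at else 0.0


def genome_stats(genome: GenomeRecord) -> GenomeStats:
    n_trna, n_pseudo = genome.trna_counts()
    return GenomeStats(
        genome_id=genome.genome_id,
        length=len(genome),
        gc_percent=gc_content(genome.sequence),
        n_cds=len(genome.cds_features()),
        n_trna=n_trna,
        n_trna_pseudo=n_pseudo,
    )


@dataclass
class CladeSummary:
    clade: str
    n: int
    mean_length_bp: float
    sd_length_bp: float | None
    mean_gc_percent: float
    sd_gc_percent: float | None

    @property
    def mean_length_kb(self) -> float:
        return self.mean_length_bp / 1000.0


def clade_summary(
    stats: list[GenomeStats] | pd.DataFrame, clades: dict[str, str] | None = None
) -> list[CladeSummary]:
    """Per-clade mean and sample (n-1) standard deviation of genome length
    and GC content."""
    if isinstance(stats, pd.DataFrame):
        df = stats.rename(columns={"name": "genome_id"})
        if clades is None:
            clades = dict(zip(df["genome_id"], df["clade"]))
    else:
        df = pd.DataFrame(
            [{"genome_id": s.genome_id, "length": s.length, "gc_percent": s.gc_percent} for s in stats]
        )
    if clades is None:
        raise ValueError("clade assignment required")
    df = df[df["genome_id"].isin(clades)]
    out = []
    for clade in sorted(set(clades.values())):
        sub = df[df["genome_id"].map(clades) == clade]
        n = len(sub)
        out.append(
            CladeSummary(
                clade=clade,
                n=n,
                mean_length_bp=float(sub["length"].mean()),
                sd_length_bp=float(sub["length"].std(ddof=1)) if n >= 2 else None,
                mean_gc_percent=float(sub["gc_percent"].mean()),
                sd_gc_percent=float(sub["gc_percent"].std(ddof=1)) if n >= 2 else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# codon usage

_WOBBLE = {  # anticodon wobble base (pos 34) -> codon third bases it decodes
    "G": "CT",
    "T": "AG",
    "C": "G",
    "A": "T",
    "I": "ACT",
}


def anticodon_decodes(anticodon: str) -> set[str]:
    """Codons decodable by a tRNA anticodon under standard wobble pairing."""
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3:
        raise ValueError(f"bad anticodon {anticodon!r}")
    stem = reverse_complement(anticodon[1:])  # codon positions 1-2
    return {stem + third for third in _WOBBLE.get(anticodon[0], "")}


def _codon_frequencies(cds_list: list[str]) -> dict[str, float]:
    from .genome_io import _TABLE

    counts: dict[str, int] = {}
    total = 0
    for nt in cds_list:
        if len(nt) % 3:
            raise ValueError("CDS length not divisible by 3")
        for i in range(0, len(nt), 3):
            codon = nt[i : i + 3].upper()
            if codon in _TABLE.forward_table:  # 61 sense codons
                counts[codon] = counts.get(codon, 0) + 1
                total += 1
    if total == 0:
        raise ValueError("no sense codons")
    return {c: 1000.0 * n / total for c, n in counts.items()}


def codon_usage_ratio(
    phage_cds: list[str],
    host_cds: list[str],
    trna_anticodons: list[str] | None = None,
    host_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-1000-codon frequencies for phage and host, their ratio, and which
    codons a phage tRNA decodes.

    Codons absent from the host are floored at ``host_floor`` per-1000 and
    flagged unstable.
    """
    from .genome_io import _TABLE

    if not host_cds:
        raise ValueError("empty host CDS set")
    phage = _codon_frequencies(phage_cds)
    host = _codon_frequencies(host_cds)
    decoded: set[str] = set()
    for anticodon in trna_anticodons or []:
        decoded |= anticodon_decodes(anticodon)
    rows = []
    for codon in sorted(_TABLE.forward_table):
        pf = phage.get(codon, 0.0)
        hf = host.get(codon, 0.0)
        unstable = hf < host_floor
        rows.append(
            {
                "codon": codon,
                "amino_acid": _TABLE.forward_table[codon],
                "phage_per_1000": pf,
                "host_per_1000": hf,
                "ratio": pf / max(hf, host_floor),
                "unstable": unstable,
                "trna_decoded": codon in decoded,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# termini by coverage


def detect_termini(
    depth: np.ndarray | list[int],
    fold_threshold: float = 2.0,
    window: int = 100,
) -> list[tuple[int, int]]:
    """Candidate terminal regions: maximal runs whose windowed mean depth is
    at least ``fold_threshold`` times the genome median depth.

    Region boundaries are reported at half-window resolution.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0 or depth.max() == 0:
        logger.warning("all-zero coverage track: no termini detectable")
        return []
    median = np.median(depth)
    if median == 0:
        median = depth[depth > 0].mean()
    kernel = np.ones(window) / window
    pad = window // 2
    smooth = np.convolve(np.pad(depth, pad, mode="edge"), kernel, mode="same")[pad:-pad]
    above = smooth >= fold_threshold * median
    regions = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            regions.append((start, i))
            start = None
    if start is not None:
        regions.append((start, len(above)))
    return regions
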