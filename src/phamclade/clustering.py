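"""Transitive protein-family clustering and clade-level homology statistics.

All proteomes are pooled, every protein pair passing the length gate is
aligned, and edges are drawn where the homology predicate holds.  Families
are the connected components of that graph (a protein belongs to a family if
it is homologous to any protein already in it); core families have at least
one member in every genome of the roster.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import ProteinRecord, reverse_complement
from .pairwise import HomologyParams, align_end_gap_free, length_compatible
from .scoring import ScoringScheme

logger = logging.getLogger(__name__)


@dataclass
class HomologyGraph:
    proteins: dict[str, ProteinRecord]
    genome_order: list[str]
    edges: dict[tuple[str, str], tuple[float, float, float]]  # (sim, ident, score)

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {pid: set() for pid in self.proteins}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_a": a, "protein_b": b, "score": s, "identity": i, "similarity": m, "homolog": True}
            for (a, b), (m, i, s) in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score", "identity", "similarity", "homolog"])


@dataclass
class ProteinFamily:
    family_id: str
    members: list[str]
    genomes: list[str]
    copy_counts: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FamilySet:
    families: list[ProteinFamily]
    genome_roster: list[str]
    protein_to_family: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.protein_to_family:
            self.protein_to_family = {
                pid: fam.family_id for fam in self.families for pid in fam.members
            }

    def __len__(self) -> int:
        return len(self.families)

    def family(self, family_id: str) -> ProteinFamily:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": fam.family_id,
                "n_members": fam.size,
                "genomes": ",".join(fam.genomes),
                "core": set(fam.genomes) == set(self.genome_roster),
                "loci": ",".join(fam.members),
            }
            for fam in self.families
        ]
        return pd.DataFrame(rows, columns=["family_id", "n_members", "genomes", "core", "loci"])


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_homology_graph(
    proteomes: list[list[ProteinRecord]],
    params: HomologyParams | None = None,
    scheme: ScoringScheme | None = None,
    include_within_genome: bool = True,
    kmer_prefilter: bool = False,
    prefilter_k: int = 5,
) -> HomologyGraph:
    """Evaluate all protein pairs and keep edges where the homology call holds.

    The optional shared-k-mer prefilter skips the full alignment for pairs
    without any common 5-mer.  It is off by default (exact mode): distant but
    genuine homologs near the similarity threshold frequently share no exact
    5-mer, and transitive families must not lose those edges.  Enable it only
    as a speed knob on large, closely related sets.
    """
    params = params or HomologyParams()
    scheme = scheme or ScoringScheme()
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    pool: list[ProteinRecord] = [p for prot in proteomes for p in prot]
    proteins = {p.protein_id: p for p in pool}
    if len(proteins) != len(pool):
        raise ValueError("duplicate protein ids across proteomes")
    genome_order = []
    for prot in proteomes:
        for p in prot:
            if p.genome_id not in genome_order:
                genome_order.append(p.genome_id)
    kmers = {p.protein_id: _kmer_set(p.aa_sequence, prefilter_k) for p in pool} if kmer_prefilter else None
    edges = {}
    for a, b in itertools.combinations(pool, 2):
        if not include_within_genome and a.genome_id == b.genome_id:
            continue
        if not length_compatible(a.length, b.length, params):
            continue
        if kmers is not None and kmers[a.protein_id].isdisjoint(kmers[b.protein_id]):
            continue
        res = align_end_gap_free(a.aa_sequence, b.aa_sequence, scheme)
        if res.similarity_percent > params.min_similarity_percent:
            key = tuple(sorted((a.protein_id, b.protein_id)))
            edges[key] = (res.similarity_percent, res.identity_percent, res.score)
    return HomologyGraph(proteins=proteins, genome_order=genome_order, edges=edges)


def cluster_families(graph: HomologyGraph) -> FamilySet:
    """Families = connected components of the homology graph.

    Family ids are deterministic: components are ordered by their smallest
    member, where proteins sort by (genome input order, genome coordinate).
    """
    parent = {pid: pid for pid in graph.proteins}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    genome_rank = {g: i for i, g in enumerate(graph.genome_order)}

    def sort_key(pid):
        p = graph.proteins[pid]
        return (genome_rank[p.genome_id], p.genome_coords[0], pid)

    components: dict[str, list[str]] = {}
    for pid in graph.proteins:
        components.setdefault(find(pid), []).append(pid)
    ordered = sorted(
        (sorted(members, key=sort_key) for members in components.values()),
        key=lambda mem: sort_key(mem[0]),
    )
    families = []
    for i, members in enumerate(ordered, start=1):
        counts: dict[str, int] = {}
        for pid in members:
            g = graph.proteins[pid].genome_id
            counts[g] = counts.get(g, 0) + 1
        families.append(
            ProteinFamily(
                family_id=f"fam_{i:04d}",
                members=members,
                genomes=sorted(counts, key=genome_rank.get),
                copy_counts=counts,
            )
        )
    return FamilySet(families=families, genome_roster=list(graph.genome_order))


def core_families(fams: FamilySet) -> list[str]:
    """Families with at least one member in every genome of the roster."""
    if not fams.genome_roster:
        raise ValueError("empty genome roster")
    full = set(fams.genome_roster)
    return [fam.family_id for fam in fams.families if set(fam.genomes) == full]


@dataclass
class CladeHomologyMatrix:
    values: pd.DataFrame  # percent of row genome's proteins with >=1 homolog in column genome
    clades: dict[str, str]
    within_means: dict[str, float | None]
    between_mean: float | None


def clade_homology_matrix(
    graph: HomologyGraph, clades: dict[str, str]
) -> CladeHomologyMatrix:
    """Ordered-pair shared-protein percentages and their clade-level means.

    ``values.loc[A, B]`` is the percent of A's proteins with at least one
    homolog in B (diagonal fixed at 100 by convention).
    """
    genomes = [g for g in graph.genome_order if g in clades]
    missing = [g for g in graph.genome_order if g not in clades]
    if missing:
        raise ValueError(f"genomes without clade assignment: {missing}")
    by_genome: dict[str, list[str]] = {g: [] for g in genomes}
    for p in graph.proteins.values():
        by_genome[p.genome_id].append(p.protein_id)
    adj = graph.neighbors()
    values = pd.DataFrame(100.0, index=genomes, columns=genomes)
    for a in genomes:
        for b in genomes:
            if a == b:
                continue
            hit = sum(
                1
                for pid in by_genome[a]
                if any(graph.proteins[q].genome_id == b for q in adj[pid])
            )
            values.loc[a, b] = 100.0 * hit / len(by_genome[a]) if by_genome[a] else 0.0
    within: dict[str, float | None] = {}
    for clade in sorted(set(clades.values())):
        members = [g for g in genomes if clades[g] == clade]
        pairs = [(a, b) for a in members for b in members if a != b]
        within[clade] = float(np.mean([values.loc[a, b] for a, b in pairs])) if pairs else None
    cross = [
        (a, b) for a in genomes for b in genomes if a != b and clades[a] != clades[b]
    ]
    between = float(np.mean([values.loc[a, b] for a, b in cross])) if cross else None
    return CladeHomologyMatrix(values=values, clades=dict(clades), within_means=within, between_mean=between)


def select_marker_families(
    core: list[str], external_hits: dict[str, float], e_threshold: float = 0.001
) -> list[str]:
    """Core families with no significant match in an external exclusion search.

    ``external_hits`` maps family_id to the best external e-value; families
    absent from the report are treated as having no hit.
    """
    markers = []
    for fid in core:
        if fid not in external_hits:
            logger.info("family %s absent from external hit report; treated as no hit", fid)
            markers.append(fid)
        elif external_hits[fid] > e_threshold:
            markers.append(fid)
    return markers


# ---------------------------------------------------------------------------
# degenerate primers

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_SETS = {code: s for s, code in IUPAC_CODES.items()}


@dataclass(frozen=True)
class PrimerConfig:
    min_len: int = 20
    max_len: int = 25
    max_degeneracy: int = 8
    amplicon_min: int = 100
    amplicon_max: int = 1500
    max_candidates: int = 20


@dataclass
class PrimerCandidate:
    family_id: str
    forward: str
    reverse: str
    degeneracy: int
    amplicon_range: tuple[int, int]


def _window_primer(columns: list[frozenset], max_degeneracy: int) -> tuple[str, int] | None:
    deg = 1
    out = []
    for col in columns:
        deg *= len(col)
        if deg > max_degeneracy:
            return None
        out.append(IUPAC_CODES[col])
    return "".join(out), deg


def propose_degenerate_primers(
    family_nt_alignment: dict[str, str] | list[str],
    family_id: str = "",
    config: PrimerConfig | None = None,
) -> list[PrimerCandidate]:
    """Scan a codon-aware nucleotide MSA for degenerate primer pairs.

    Conserved windows (per-position IUPAC degeneracy product within bounds,
    no gaps) yield forward/reverse primers; pairs are emitted when the
    amplicon length falls within the configured range, best (least
    degenerate) first.
    """
    config = config or PrimerConfig()
    rows = list(family_nt_alignment.values()) if isinstance(family_nt_alignment, dict) else list(family_nt_alignment)
    if len(rows) < 2:
        raise ValueError("need at least two aligned sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    ncol = len(rows[0])
    columns = []
    for c in range(ncol):
        bases = frozenset(r[c].upper() for r in rows)
        columns.append(bases if bases <= frozenset("ACGT") else None)  # gap/ambiguity disqualifies

    windows = []  # (start, length, iupac, degeneracy)
    for length in range(config.min_len, config.max_len + 1):
        for start in range(0, ncol - length + 1):
            cols = columns[start : start + length]
            if any(c is None for c in cols):
                continue
            made = _window_primer(cols, config.max_degeneracy)
            if made:
                windows.append((start, length, made[0], made[1]))

    candidates = []
    for fs, fl, fwd, fdeg in windows:
        for rs, rl, rev, rdeg in windows:
            amplicon = (rs + rl) - fs
            if rs <= fs + fl:
                continue
            if not (config.amplicon_min <= amplicon <= config.amplicon_max):
                continue
            rev_rc = "".join(IUPAC_CODES[frozenset(reverse_complement("".join(sorted(IUPAC_SETS[c]))))] for c in reversed(rev))
            candidates.append(
                PrimerCandidate(
                    family_id=family_id,
                    forward=fwd,
                    reverse=rev_rc,
                    degeneracy=fdeg * rdeg,
                    amplicon_range=(amplicon, amplicon),
                )
            )
    if not candidates:
        logger.info("family %s: no primer window satisfied the degeneracy/amplicon bounds", family_id)
    candidates.sort(key=lambda c: (c.degeneracy, c.amplicon_range[0], c.forward))
    return candidates[: config.max_candidates]
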