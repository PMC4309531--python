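"""Concatenated-core phylogeny: shared single-copy selection, trimming,
Poisson-corrected distances, neighbor-joining, bootstrap and midpoint rooting.

The internal tree engine is distance-based (NJ on Poisson-corrected
p-distances); a maximum-likelihood engine can be plugged in behind the same
tree contract.  Bootstrap supports are percentages of column-resampling
replicates containing each internal bipartition of the full-data tree.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .clustering import FamilySet
from .msa import FamilyAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class ConcatenatedAlignment:
    taxa: list[str]
    blocks: list[tuple[str, tuple[int, int]]]  # (family_id, column span)
    matrix: dict[str, str]  # taxon -> gapped row

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.matrix.values())))

    def resample_columns(self, rng: np.random.Generator) -> "ConcatenatedAlignment":
        n = self.n_columns
        idx = rng.integers(0, n, size=n)
        matrix = {t: "".join(row[i] for i in idx) for t, row in self.matrix.items()}
        return ConcatenatedAlignment(self.taxa, [("resampled", (0, n))], matrix)


@dataclass
class PhyloTree:
    """Tree with branch lengths and (optionally) bootstrap supports.

    Wraps a scikit-bio TreeNode; supports are attached per internal
    bipartition (canonical frozenset of the smaller/lexicographic side).
    """

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree)

    def to_newick(self, with_supports: bool = True) -> str:
        tree = self.tree.copy()
        if with_supports and self.supports:
            all_taxa = frozenset(t.name for t in tree.tips())
            for node in tree.non_tips(include_self=False):
                bip = _canonical({t.name for t in node.tips()}, all_taxa)
                if bip in self.supports:
                    node.name = str(int(round(self.supports[bip])))
        buf = io.StringIO()
        tree.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = TreeNode.read(io.StringIO(text), format="newick")
        supports = {}
        all_taxa = frozenset(t.name for t in tree.tips())
        for node in tree.non_tips(include_self=False):
            if node.name is not None:
                try:
                    value = float(node.name)
                except ValueError:
                    continue
                supports[_canonical({t.name for t in node.tips()}, all_taxa)] = value
        return cls(tree=tree, supports=supports)


def _canonical(side: set[str], all_taxa: frozenset) -> frozenset:
    other = all_taxa - side
    a, b = frozenset(side), frozenset(other)
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return a if sorted(a) < sorted(b) else b


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions induced by internal edges."""
    all_taxa = frozenset(t.name for t in tree.tips())
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(all_taxa) - 1:
            bips.add(_canonical(side, all_taxa))
    return bips


def select_shared_single_copy(fams: FamilySet) -> list[str]:
    """Families with exactly one member in every genome of the roster."""
    roster = set(fams.genome_roster)
    selected = []
    for fam in fams.families:
        if set(fam.genomes) != roster:
            continue
        if all(c == 1 for c in fam.copy_counts.values()):
            selected.append(fam.family_id)
        else:
            logger.info(
                "family %s is universal but duplicated (%s); rejected as a "
                "phylogenetic marker", fam.family_id, fam.copy_counts,
            )
    if not selected:
        logger.warning("no universal single-copy family found")
    return selected


def trim_columns(
    msa: FamilyAlignment, gap_cutoff: float = 0.2, entropy_cutoff: float = 0.5
) -> FamilyAlignment:
    """Drop uninformative columns: gap fraction above ``gap_cutoff`` or
    smoothed column entropy (window 3, normalised to [0, 1]) above
    ``entropy_cutoff``."""
    rows = list(msa.rows.values())
    if len(rows) < 3:
        raise ValueError(f"family {msa.family_id}: need >=3 rows to trim")
    ncol = msa.n_columns
    gap_frac = np.empty(ncol)
    entropy = np.empty(ncol)
    n = len(rows)
    for c in range(ncol):
        col = [r[c] for r in rows]
        gaps = col.count("-")
        gap_frac[c] = gaps / n
        residues = [x for x in col if x != "-"]
        if not residues:
            entropy[c] = 1.0
            continue
        _, counts = np.unique(residues, return_counts=True)
        f = counts / counts.sum()
        entropy[c] = float(-(f * np.log(f)).sum() / np.log(20))
    kernel = np.ones(3) / 3.0
    smoothed = np.convolve(np.pad(entropy, 1, mode="edge"), kernel, mode="valid")
    keep = (gap_frac <= gap_cutoff) & (smoothed <= entropy_cutoff)
    if not keep.any():
        raise ValueError(f"family {msa.family_id}: trimming would remove every column")
    idx = np.flatnonzero(keep)
    return FamilyAlignment(
        msa.family_id, {k: "".join(row[i] for i in idx) for k, row in msa.rows.items()}
    )


def poisson_distance(row_a: str, row_b: str, max_p: float = 0.95) -> float:
    """Poisson-corrected p-distance -ln(1 - p) over shared non-gap columns."""
    shared = mismatch = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            shared += 1
            if x != y:
                mismatch += 1
    if shared == 0:
        p = max_p
    else:
        p = min(mismatch / shared, max_p)
    return float(-np.log(1.0 - p))


def concatenate_and_distance(
    alignments: list[FamilyAlignment],
) -> tuple[ConcatenatedAlignment, pd.DataFrame]:
    """Concatenate family alignments (rows keyed by taxon) and compute the
    pairwise Poisson-corrected distance matrix."""
    if not alignments:
        raise ValueError("no alignments given")
    taxa = sorted(alignments[0].rows)
    for aln in alignments[1:]:
        if sorted(aln.rows) != taxa:
            diff = set(aln.rows) ^ set(taxa)
            raise ValueError(f"taxon sets differ (symmetric difference: {sorted(diff)})")
    blocks = []
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for aln in alignments:
        span = (offset, offset + aln.n_columns)
        blocks.append((aln.family_id, span))
        offset = span[1]
        for t in taxa:
            parts[t].append(aln.rows[t])
    matrix = {t: "".join(p) for t, p in parts.items()}
    concat = ConcatenatedAlignment(taxa=taxa, blocks=blocks, matrix=matrix)
    return concat, alignment_distances(concat)


def alignment_distances(concat: ConcatenatedAlignment) -> pd.DataFrame:
    taxa = concat.taxa
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            v = poisson_distance(concat.matrix[a], concat.matrix[b])
            d.loc[a, b] = d.loc[b, a] = v
    return d


def nj_tree(d: pd.DataFrame) -> PhyloTree:
    """Neighbor-joining tree; negative branch lengths are clamped to zero."""
    if d.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d.values, d.values.T):
        raise ValueError("distance matrix is not symmetric")
    dm = DistanceMatrix(d.values, ids=list(d.index))
    tree = nj(dm, neg_as_zero=True)
    return PhyloTree(tree=tree)


def bootstrap_support(
    concat: ConcatenatedAlignment,
    cfg: BootstrapConfig | None = None,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap; supports (%) are attached to the
    full-data tree's internal bipartitions."""
    cfg = cfg or BootstrapConfig()
    if tree is None:
        tree = nj_tree(alignment_distances(concat))
    target = tree.bipartitions()
    counts = {bip: 0 for bip in target}
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.replicates):
        rep = concat.resample_columns(rng)
        rep_tree = nj_tree(alignment_distances(rep))
        found = rep_tree.bipartitions()
        for bip in target:
            if bip in found:
                counts[bip] += 1
    supports = {bip: 100.0 * c / cfg.replicates for bip, c in counts.items()}
    return PhyloTree(tree=tree.tree, supports=supports)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest tip-to-tip path (idempotent)."""
    lengths = [n.length or 0.0 for n in tree.tree.traverse() if not n.is_root()]
    if sum(lengths) == 0:
        logger.warning("zero-length tree: midpoint root is arbitrary")
        return PhyloTree(tree=tree.tree.copy(), supports=dict(tree.supports))
    rooted = tree.tree.root_at_midpoint()
    return PhyloTree(tree=rooted, supports=dict(tree.supports))
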