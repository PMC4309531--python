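"""Clade-structured synthetic phage genome sets with complete planted truth.

The generator emulates the study design the pipeline targets: two clades of
related genomes (6 + 5 by default) sharing a core of protein families, plus
clade-specific families and per-genome orphans; genomes assembled at
clade-specific GC targets with tRNA annotations, intergenic spacers carrying
repeated 41-nt promoter-like elements (sigma70 boxes embedded), and per-base
coverage tracks with a high-coverage terminus.  Every planted fact is
recorded in a SimulationTruth object so each pipeline stage can be tested
against known ground truth.

Proteins evolve down a two-level star-within-clades genealogy: a root
ancestor per core family, clade ancestors at half the between-clade
divergence each, and genome copies at the within-clade divergence.
Substitutions replace a residue by a draw from the substitution-matrix-
conditional distribution, so conservative exchanges dominate, as in real
divergence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .genome_io import Feature, GenomeRecord, write_annotation_table, write_fasta, write_genbank
from .profiles import BACKGROUND
from .scoring import AA_ORDER, ScoringScheme

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codon_table():
    if not _CODONS_BY_AA:
        from .genome_io import _TABLE

        for codon, aa in _TABLE.forward_table.items():
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
        for aa in _CODONS_BY_AA:
            _CODONS_BY_AA[aa].sort()
    return _CODONS_BY_AA


@dataclass(frozen=True)
class RepeatSpec:
    element_length: int = 41
    copies_per_genome: tuple[tuple[int, ...], ...] = ((5, 6, 5, 6, 5, 5), (2, 2, 2, 2, 2))
    mutation_prob: float = 0.012
    minus35_offset: int = 4
    spacer: int = 17
    protect_boxes: bool = True


@dataclass(frozen=True)
class CoverageSpec:
    base_depth: int = 50
    terminus_fold: float = 3.0
    terminus_width: int = 500


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_clades: int = 2
    genomes_per_clade: tuple[int, ...] = (6, 5)
    n_core_families: int = 26
    n_clade_specific: tuple[int, ...] = (45, 45)
    n_orphans: int = 10
    mean_protein_length: int = 150
    protein_length_spread: int = 40
    within_clade_divergence: float = 0.05
    between_clade_divergence: float = 0.85
    # site-rate heterogeneity: conserved motif blocks (near-zero rate) in an
    # otherwise fast-evolving protein; this is what makes profile searches
    # find homologs the pairwise 40%-similarity gate misses
    n_conserved_blocks: int = 2
    conserved_block_len: int = 12
    fast_rate_shape: float = 4.0
    gc_targets: tuple[float, ...] = (49.3, 54.8)
    trna_counts: tuple[int, ...] = (12, 3)
    repeat_spec: RepeatSpec = field(default_factory=RepeatSpec)
    coverage_spec: CoverageSpec = field(default_factory=CoverageSpec)

    def __post_init__(self):
        if not (0 <= self.within_clade_divergence < 1 and 0 <= self.between_clade_divergence < 1):
            raise ValueError("divergences must lie in [0, 1)")
        if self.within_clade_divergence >= self.between_clade_divergence:
            raise ValueError("within-clade divergence must be below between-clade divergence")
        if len(self.genomes_per_clade) != self.n_clades:
            raise ValueError("genomes_per_clade length must equal n_clades")


@dataclass
class SimulationTruth:
    clades: dict[str, str]
    family_of: dict[str, str]  # protein_id -> planted family label
    universal_single_copy: list[str]
    repeat_instances: list[tuple[str, int, int, str]]  # genome, start, end, strand
    repeat_conserved_count: dict[str, int]  # clade -> strictly conserved positions
    termini: dict[str, tuple[int, int]]
    spacers: dict[str, list[tuple[int, int]]]
    coverage: dict[str, list[int]]
    remote_pairs: list[tuple[str, str]] = field(default_factory=list)
    ancestors: dict[str, str] = field(default_factory=dict)
    site_rates: dict[str, list[float]] = field(default_factory=dict)

    def planted_family_count(self) -> int:
        return len(set(self.family_of.values()))


# ---------------------------------------------------------------------------
# protein evolution

_TRNA_PRODUCTS = [
    "tRNA-Asn", "tRNA-Tyr", "tRNA-Gln", "tRNA-Leu", "tRNA-Arg", "tRNA-Ser",
    "tRNA-Gly", "tRNA-Pro", "tRNA-Thr", "tRNA-Met", "tRNA-Ile", "tRNA-Asp",
    "tRNA-Glu", "tRNA-Phe",
]


def _conditional_matrix(scheme: ScoringScheme | None = None) -> np.ndarray:
    """P(replacement b | ancestor a) for b != a, from the score matrix.

    The tempered exponent (s/4 rather than the matrix's native half-bits)
    keeps single substitutions biased towards conservative exchanges while
    letting repeated substitution converge towards the background — without
    it, deeply diverged sequences never drop below ~45% similarity.
    """
    scheme = scheme or ScoringScheme()
    mat = scheme.matrix[:20, :20].astype(float)
    cond = BACKGROUND[None, :] * np.power(2.0, mat / 4.0)
    np.fill_diagonal(cond, 0.0)
    return cond / cond.sum(axis=1, keepdims=True)


_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}


def random_protein(length: int, rng: np.random.Generator) -> str:
    body = rng.choice(list(AA_ORDER), size=length - 1, p=BACKGROUND)
    return "M" + "".join(body)


def evolve_protein(
    ancestor: str,
    divergence: float,
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
    rates: np.ndarray | None = None,
) -> str:
    """Substitute each site independently with probability ``divergence``.

    With ``rates`` (per-site rate multipliers, mean ~1, shared by all members
    of a family) the per-site probability becomes ``1 - (1-divergence)**r``:
    slow sites stay conserved across deep divergence, the heterogeneity that
    makes profile searches more sensitive than pairwise comparison.
    """
    if not (0 <= divergence < 1):
        raise ValueError("divergence must lie in [0, 1)")
    if divergence == 0:
        return ancestor
    if rates is None:
        p = np.full(len(ancestor), divergence)
    else:
        if len(rates) != len(ancestor):
            raise ValueError("rates length must match the ancestor")
        p = 1.0 - np.power(1.0 - divergence, np.asarray(rates))
    cond = _conditional_matrix(scheme)
    out = list(ancestor)
    hit = rng.random(len(ancestor)) < p
    for i in np.flatnonzero(hit):
        a = _AA_IDX.get(out[i])
        if a is None:
            continue
        out[i] = AA_ORDER[rng.choice(20, p=cond[a])]
    return "".join(out)


# ---------------------------------------------------------------------------
# codon bias tuned to a GC target

_GC_COUNT = {b: (1 if b in "GC" else 0) for b in "ACGT"}


def _codon_gc(codon: str) -> int:
    return sum(_GC_COUNT[b] for b in codon)


def _expected_gc(
    theta: float,
    residue_counts: dict[str, int],
    fixed_gc: float = 0.0,
    fixed_bases: float = 0.0,
) -> float:
    """Expected GC fraction of coding sequence under exponential codon tilt.

    ``fixed_gc``/``fixed_bases`` account for sequence outside the tilt's
    control (the TAA stop codons appended to every gene)."""
    table = _codon_table()
    gc = fixed_gc
    bases = fixed_bases
    for aa, n in residue_counts.items():
        codons = table[aa]
        w = np.array([np.exp(theta * _codon_gc(c)) for c in codons])
        w /= w.sum()
        gc += n * float(sum(wi * _codon_gc(c) for wi, c in zip(w, codons)))
        bases += 3 * n
    return gc / bases


def solve_codon_tilt(
    residue_counts: dict[str, int],
    gc_target_percent: float,
    fixed_gc: float = 0.0,
    fixed_bases: float = 0.0,
) -> float:
    """Tilt parameter making expected coding GC hit the target."""
    target = gc_target_percent / 100.0

    def f(theta):
        return _expected_gc(theta, residue_counts, fixed_gc, fixed_bases) - target

    lo, hi = -8.0, 8.0
    if f(lo) * f(hi) > 0:
        raise ValueError(f"GC target {gc_target_percent}% infeasible for this codon table")
    return float(brentq(f, lo, hi, xtol=1e-10))


def reverse_translate(protein: str, theta: float, rng: np.random.Generator) -> str:
    table = _codon_table()
    parts = []
    for aa in protein:
        codons = table[aa]
        w = np.array([np.exp(theta * _codon_gc(c)) for c in codons])
        w /= w.sum()
        parts.append(codons[int(rng.choice(len(codons), p=w))])
    parts.append("TAA")
    return "".join(parts)


def _random_nt(length: int, gc_percent: float, rng: np.random.Generator) -> str:
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    return "".join(rng.choice(list("ACGT"), size=length, p=[a, g, g, a]))


# ---------------------------------------------------------------------------
# genome assembly

from .repeats import MINUS10, MINUS35  # noqa: E402


def _make_repeat_master(spec: RepeatSpec, gc: float, rng: np.random.Generator) -> str:
    flank_left = _random_nt(spec.minus35_offset, gc, rng)
    spacer = _random_nt(spec.spacer, gc, rng)
    used = spec.minus35_offset + 6 + spec.spacer + 6
    flank_right = _random_nt(spec.element_length - used, gc, rng)
    return flank_left + MINUS35 + spacer + MINUS10 + flank_right


def _mutate_element(master: str, spec: RepeatSpec, rng: np.random.Generator) -> str:
    protected = set()
    if spec.protect_boxes:
        protected |= set(range(spec.minus35_offset, spec.minus35_offset + 6))
        start10 = spec.minus35_offset + 6 + spec.spacer
        protected |= set(range(start10, start10 + 6))
    out = list(master)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < spec.mutation_prob:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def simulate_genome_set(cfg: SimulationConfig) -> tuple[list[GenomeRecord], SimulationTruth]:
    """Generate the full clade-structured genome set plus planted truth."""
    rng = np.random.default_rng(cfg.seed)
    clade_names = [chr(ord("A") + i) for i in range(cfg.n_clades)]

    # --- family plan -------------------------------------------------------
    def _length() -> int:
        return int(
            rng.integers(
                cfg.mean_protein_length - cfg.protein_length_spread,
                cfg.mean_protein_length + cfg.protein_length_spread + 1,
            )
        )

    def _rates(length: int) -> np.ndarray:
        shape = cfg.fast_rate_shape
        r = rng.gamma(shape, 1.0 / shape, length) / 0.85
        span = cfg.conserved_block_len
        if cfg.n_conserved_blocks and span < length:
            for s in rng.choice(length - span, size=cfg.n_conserved_blocks, replace=False):
                r[s : s + span] = 0.02
        return r

    ancestors: dict[str, str] = {}
    rates: dict[str, np.ndarray] = {}
    core_ids = [f"core_{i:02d}" for i in range(1, cfg.n_core_families + 1)]
    for fid in core_ids:
        ancestors[fid] = random_protein(_length(), rng)
        rates[fid] = _rates(len(ancestors[fid]))
    clade_specific: dict[str, list[str]] = {}
    for ci, clade in enumerate(clade_names):
        ids = [f"cs_{clade}_{i:02d}" for i in range(1, cfg.n_clade_specific[ci] + 1)]
        clade_specific[clade] = ids
        for fid in ids:
            ancestors[fid] = random_protein(_length(), rng)
            rates[fid] = _rates(len(ancestors[fid]))

    # clade-level ancestors of the core families
    clade_core_anc: dict[tuple[str, str], str] = {}
    for fid in core_ids:
        for clade in clade_names:
            clade_core_anc[(clade, fid)] = evolve_protein(
                ancestors[fid], cfg.between_clade_divergence / 2.0, rng,
                rates=rates[fid],
            )

    # strand per shared family (fixed across genomes)
    strand_of = {
        fid: ("+" if rng.random() < 0.8 else "-")
        for fid in core_ids + [f for ids in clade_specific.values() for f in ids]
    }

    # global gene order: core and clade-specific slots interleaved, the first
    # slot always the anchor core family (the "large terminase" stand-in)
    slot_pool = core_ids[1:] + [f for ids in clade_specific.values() for f in ids]
    order = list(rng.permutation(slot_pool))
    slots = [core_ids[0]] + order

    # --- evolve proteomes --------------------------------------------------
    genome_ids = []
    clades: dict[str, str] = {}
    proteins: dict[str, dict[str, str]] = {}  # genome -> {family label -> aa}
    for ci, clade in enumerate(clade_names):
        for gi in range(cfg.genomes_per_clade[ci]):
            gid = f"phi{clade}{gi + 1:02d}"
            genome_ids.append(gid)
            clades[gid] = clade
            prot = {}
            for fid in core_ids:
                prot[fid] = evolve_protein(
                    clade_core_anc[(clade, fid)], cfg.within_clade_divergence, rng,
                    rates=rates[fid],
                )
            for fid in clade_specific[clade]:
                prot[fid] = evolve_protein(
                    ancestors[fid], cfg.within_clade_divergence, rng, rates=rates[fid]
                )
            for oi in range(1, cfg.n_orphans + 1):
                fid = f"orphan_{gid}_{oi:02d}"
                prot[fid] = random_protein(_length(), rng)
                strand_of[fid] = "+" if rng.random() < 0.8 else "-"
            proteins[gid] = prot

    # --- codon tilt per clade ----------------------------------------------
    thetas = {}
    for ci, clade in enumerate(clade_names):
        counts: dict[str, int] = {}
        n_genes = 0
        for gid in genome_ids:
            if clades[gid] != clade:
                continue
            for aa_seq in proteins[gid].values():
                n_genes += 1
                for aa in aa_seq:
                    counts[aa] = counts.get(aa, 0) + 1
        thetas[clade] = solve_codon_tilt(
            counts, cfg.gc_targets[ci], fixed_gc=0.0, fixed_bases=3.0 * n_genes
        )

    # --- repeat masters per clade ------------------------------------------
    masters = {
        clade: _make_repeat_master(cfg.repeat_spec, cfg.gc_targets[ci], rng)
        for ci, clade in enumerate(clade_names)
    }

    # --- assemble genomes ---------------------------------------------------
    genomes = []
    truth = SimulationTruth(
        clades=clades,
        family_of={},
        universal_single_copy=list(core_ids),
        repeat_instances=[],
        repeat_conserved_count={},
        termini={},
        spacers={},
        coverage={},
        ancestors=dict(ancestors),
        site_rates={fid: [float(x) for x in r] for fid, r in rates.items()},
    )
    clade_instances: dict[str, list[str]] = {c: [] for c in clade_names}
    for ci, clade in enumerate(clade_names):
        gc = cfg.gc_targets[ci]
        members = [g for g in genome_ids if clades[g] == clade]
        for gi, gid in enumerate(members):
            copies = cfg.repeat_spec.copies_per_genome[ci][gi]
            prot = proteins[gid]
            gene_slots = [fid for fid in slots if fid in prot]
            orphan_ids = sorted(f for f in prot if f.startswith("orphan_"))
            for fid in orphan_ids:
                pos = int(rng.integers(1, len(gene_slots) + 1))
                gene_slots.insert(pos, fid)
            # which inter-gene spacers carry a repeat element
            n_gaps = len(gene_slots) - 1
            repeat_gaps = set(
                int(x) for x in rng.choice(n_gaps, size=copies, replace=False)
            )
            parts: list[str] = []
            feats: list[Feature] = []
            spacer_spans: list[tuple[int, int]] = []
            pos = 0

            def _add_spacer(length: int, with_repeat: bool = False):
                nonlocal pos
                if with_repeat:
                    pre = _random_nt(30, gc, rng)
                    element = _mutate_element(masters[clade], cfg.repeat_spec, rng)
                    post = _random_nt(max(10, length - 30 - len(element)), gc, rng)
                    seq = pre + element + post
                    truth.repeat_instances.append(
                        (gid, pos + 30, pos + 30 + len(element), "+")
                    )
                    clade_instances[clade].append(element)
                else:
                    seq = _random_nt(length, gc, rng)
                spacer_spans.append((pos, pos + len(seq)))
                parts.append(seq)
                pos += len(seq)

            _add_spacer(60)
            # tRNA block sits upstream of the anchor (terminase) ORF
            for t in range(cfg.trna_counts[ci]):
                trna_seq = _random_nt(76, gc, rng)
                feats.append(
                    Feature("tRNA", pos, pos + 76, "+", f"{gid}_t{t + 1:02d}",
                            product=_TRNA_PRODUCTS[t])
                )
                parts.append(trna_seq)
                pos += 76
            _add_spacer(40)
            for slot_idx, fid in enumerate(gene_slots):
                locus = f"gp{slot_idx + 1:03d}"
                aa = prot[fid]
                nt = reverse_translate(aa, thetas[clade], rng)
                strand = strand_of[fid]
                if strand == "-":
                    from .genome_io import reverse_complement

                    nt = reverse_complement(nt)
                product = "large terminase subunit" if fid == core_ids[0] else "hypothetical protein"
                feats.append(Feature("CDS", pos, pos + len(nt), strand, locus, product=product))
                truth.family_of[f"{gid}:{locus}"] = fid
                parts.append(nt)
                pos += len(nt)
                if slot_idx < len(gene_slots) - 1:
                    gap = int(rng.integers(20, 81))
                    _add_spacer(gap, with_repeat=slot_idx in repeat_gaps)
            _add_spacer(60)
            sequence = "".join(parts)
            genome = GenomeRecord(
                genome_id=gid,
                display_name=f"synthetic phage {gid} (clade {clade})",
                sequence=sequence,
                topology="circular-permuted",
                features=feats,
                source="synthetic",
            )
            genomes.append(genome)
            truth.spacers[gid] = spacer_spans
            # coverage with a high-depth terminus at the genome start
            cov = rng.poisson(cfg.coverage_spec.base_depth, len(sequence)).astype(float)
            width = cfg.coverage_spec.terminus_width
            cov[:width] *= cfg.coverage_spec.terminus_fold
            truth.coverage[gid] = [int(x) for x in cov]
            truth.termini[gid] = (0, width)

    for clade, elements in clade_instances.items():
        if not elements:
            truth.repeat_conserved_count[clade] = 0
            continue
        length = len(elements[0])
        truth.repeat_conserved_count[clade] = sum(
            1 for i in range(length) if len({e[i] for e in elements}) == 1
        )
    return genomes, truth


def simulate_outgroup_genome(
    cfg: SimulationConfig,
    truth: SimulationTruth,
    n_shared_families: int = 25,
    divergence: float = 0.99,
    seed: int = 999,
    genome_id: str = "phiOut01",
) -> tuple[GenomeRecord, list[str]]:
    """A distant relative sharing remote homologs of planted core/clade
    families at sub-threshold pairwise similarity, for profile-screen tests."""
    rng = np.random.default_rng(seed)
    shared = truth.universal_single_copy[:n_shared_families]
    if len(shared) < n_shared_families:
        extra = sorted(f for f in truth.ancestors if f.startswith("cs_"))
        shared = shared + extra[: n_shared_families - len(shared)]
    prot: dict[str, str] = {}
    for fid in shared:
        fam_rates = truth.site_rates.get(fid)
        prot[fid] = evolve_protein(
            truth.ancestors[fid], divergence, rng,
            rates=np.asarray(fam_rates) if fam_rates is not None else None,
        )
    for oi in range(1, cfg.n_orphans + 1):
        prot[f"orphan_{genome_id}_{oi:02d}"] = random_protein(cfg.mean_protein_length, rng)
    counts: dict[str, int] = {}
    for aa_seq in prot.values():
        for aa in aa_seq:
            counts[aa] = counts.get(aa, 0) + 1
    theta = solve_codon_tilt(
        counts, cfg.gc_targets[0], fixed_gc=0.0, fixed_bases=3.0 * len(prot)
    )
    parts = []
    feats = []
    pos = 0
    remote_pairs = []
    for idx, fid in enumerate(sorted(prot), start=1):
        spacer = _random_nt(40, cfg.gc_targets[0], rng)
        parts.append(spacer)
        pos += 40
        nt = reverse_translate(prot[fid], theta, rng)
        locus = f"gp{idx:03d}"
        feats.append(Feature("CDS", pos, pos + len(nt), "+", locus, product="hypothetical protein"))
        if not fid.startswith("orphan_"):
            remote_pairs.append((f"{genome_id}:{locus}", fid))
        parts.append(nt)
        pos += len(nt)
    genome = GenomeRecord(
        genome_id=genome_id,
        display_name=f"synthetic outgroup {genome_id}",
        sequence="".join(parts) + _random_nt(40, cfg.gc_targets[0], rng),
        features=feats,
        source="synthetic",
    )
    truth.remote_pairs.extend(remote_pairs)
    return genome, [fid for fid in shared]


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(genomes: list[GenomeRecord], truth: SimulationTruth, directory) -> list[Path]:
    """Write GenBank, FASTA, annotation tables, coverage TSV and truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for g in genomes:
        gb = directory / f"{g.genome_id}.gbk"
        write_genbank(g, gb)
        fa = directory / f"{g.genome_id}.fasta"
        write_fasta([g], fa)
        tsv = directory / f"{g.genome_id}.features.tsv"
        write_annotation_table(g, tsv)
        written += [gb, fa, tsv]
        if g.genome_id in truth.coverage:
            cov = directory / f"{g.genome_id}.coverage.tsv"
            with open(cov, "w") as fh:
                fh.write("position\tdepth\n")
                for i, d in enumerate(truth.coverage[g.genome_id]):
                    fh.write(f"{i}\t{d}\n")
            written.append(cov)
    tpath = directory / "truth.json"
    payload = asdict(truth)
    payload.pop("coverage")
    with open(tpath, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    written.append(tpath)
    return written
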