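"""Pipeline orchestration: run all stages on a genome set and write reports.

Stage order: input -> pairwise homology -> families -> profiles -> phylogeny
-> per-genome stats -> repeats.  The all-vs-all alignment is done once at the
relaxed (35%) threshold; the strict (40%) family graph is derived from it by
filtering, so the two thresholds are a parameter switch rather than separate
passes.  Also hosts genus-level classification of a query genome against a
reference set (shared-protein fraction with the standard homology predicate,
standing in for gene-content taxonomy tools).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .clustering import (
    FamilySet,
    HomologyGraph,
    IUPAC_SETS,
    PrimerCandidate,
    build_homology_graph,
    clade_homology_matrix,
    cluster_families,
    core_families,
)
from .features import clade_summary, genome_stats
from .genome_io import GenomeRecord, extract_proteome, read_genome_record, reverse_complement
from .msa import FamilyAlignment, align_family
from .pairwise import HomologyParams, is_homolog
from .phylogeny import (
    BootstrapConfig,
    PhyloTree,
    bootstrap_support,
    concatenate_and_distance,
    midpoint_root,
    nj_tree,
    select_shared_single_copy,
    trim_columns,
)
from .profiles import FamilyProfile, build_profile, screen_genomes
from .repeats import consensus_profile, find_intergenic_repeats, merge_repeats_across_genomes, scan_sigma70
from .scoring import ScoringScheme

logger = logging.getLogger(__name__)

ALL_STAGES = ("stats", "families", "profiles", "tree", "repeats")


@dataclass
class PipelineConfig:
    genome_paths: list[str] = field(default_factory=list)
    clades: dict[str, str] = field(default_factory=dict)
    output_dir: str = "phamclade_out"
    seed: int = 1
    min_similarity: float = 40.0
    relaxed_similarity: float = 35.0
    max_length_diff: float = 0.5
    gap_open: int = -11
    gap_extend: int = -1
    min_hits: int = 20
    e_threshold: float = 0.001
    bootstrap_replicates: int = 100
    repeat_min_len: int = 40
    repeat_min_copies: int = 2
    repeat_min_identity: float = 0.8
    genus_threshold: float = 40.0
    stages: tuple[str, ...] = ALL_STAGES

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(gap_open=self.gap_open, gap_extend=self.gap_extend)

    @property
    def params(self) -> HomologyParams:
        return HomologyParams(self.min_similarity, self.max_length_diff)

    @property
    def relaxed_params(self) -> HomologyParams:
        return HomologyParams(self.relaxed_similarity, self.max_length_diff)


def filter_graph(graph: HomologyGraph, min_similarity: float) -> HomologyGraph:
    """Restrict a homology graph to edges above a higher similarity cutoff."""
    edges = {k: v for k, v in graph.edges.items() if v[0] > min_similarity}
    return HomologyGraph(proteins=graph.proteins, genome_order=graph.genome_order, edges=edges)


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    graph: HomologyGraph | None = None
    relaxed_graph: HomologyGraph | None = None
    families: FamilySet | None = None
    relaxed_families: FamilySet | None = None
    core: list[str] = field(default_factory=list)
    family_alignments: dict[str, FamilyAlignment] = field(default_factory=dict)
    profiles: dict[str, FamilyProfile] = field(default_factory=dict)
    tree: PhyloTree | None = None
    repeat_clusters: list = field(default_factory=list)
    reports: dict[str, str] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig, genomes: list[GenomeRecord] | None = None) -> PipelineResult:
    """Execute the configured stages and write versioned reports.

    ``genomes`` may be supplied directly (e.g. from the simulator); otherwise
    they are read from ``cfg.genome_paths``.  Stage failures raise with the
    stage name; reports written so far are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d params=%s", cfg.seed, cfg.params)
    if genomes is None:
        genomes = [read_genome_record(p) for p in cfg.genome_paths]
    if len(genomes) < 2:
        raise ValueError("pipeline needs at least two genomes")
    result = PipelineResult(genomes=genomes)
    proteomes = {g.genome_id: extract_proteome(g) for g in genomes}
    clades = cfg.clades or {g.genome_id: "all" for g in genomes}

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("stats"):
            stats = [genome_stats(g) for g in genomes]
            path = out / "genome_stats.tsv"
            with open(path, "w") as fh:
                fh.write("genome_id\tlength\tgc_percent\tn_cds\tn_trna\tn_trna_pseudo\tclade\n")
                for s in stats:
                    fh.write(
                        f"{s.genome_id}\t{s.length}\t{s.gc_percent:.2f}\t{s.n_cds}"
                        f"\t{s.n_trna}\t{s.n_trna_pseudo}\t{clades.get(s.genome_id, '')}\n"
                    )
            result.reports["stats"] = str(path)
            summaries = clade_summary(stats, clades)
            path = out / "clade_summary.tsv"
            with open(path, "w") as fh:
                fh.write("clade\tn\tmean_length_kb\tsd_length_bp\tmean_gc\tsd_gc\n")
                for cs in summaries:
                    sd_l = f"{cs.sd_length_bp:.0f}" if cs.sd_length_bp is not None else "NA"
                    sd_g = f"{cs.sd_gc_percent:.2f}" if cs.sd_gc_percent is not None else "NA"
                    fh.write(f"{cs.clade}\t{cs.n}\t{cs.mean_length_kb:.1f}\t{sd_l}\t{cs.mean_gc_percent:.1f}\t{sd_g}\n")
            result.reports["clade_summary"] = str(path)
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

    try:
        if _stage("families") or _stage("profiles") or _stage("tree"):
            relaxed = build_homology_graph(
                list(proteomes.values()), cfg.relaxed_params, cfg.scheme
            )
            result.relaxed_graph = relaxed
            result.graph = filter_graph(relaxed, cfg.min_similarity)
            result.families = cluster_families(result.graph)
            result.relaxed_families = cluster_families(relaxed)
            result.core = core_families(result.families)
            fam_path = out / "families.tsv"
            result.families.to_frame().to_csv(fam_path, sep="\t", index=False)
            result.reports["families"] = str(fam_path)
            core_path = out / "core_families.txt"
            core_path.write_text("\n".join(result.core) + "\n")
            result.reports["core"] = str(core_path)
            if len(set(clades.values())) >= 1:
                matrix = clade_homology_matrix(result.graph, clades)
                mat_path = out / "clade_homology.tsv"
                matrix.values.to_csv(mat_path, sep="\t")
                result.reports["clade_homology"] = str(mat_path)
                summary_path = out / "clade_homology_summary.json"
                summary_path.write_text(
                    json.dumps(
                        {"within": matrix.within_means, "between": matrix.between_mean},
                        indent=1,
                    )
                )
                result.reports["clade_homology_summary"] = str(summary_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'families' failed: {exc}") from exc

    try:
        if _stage("profiles"):
            pool = {p.protein_id: p for ps in proteomes.values() for p in ps}
            for fam in result.families.families:
                if fam.size < 2:
                    continue
                members = [pool[pid] for pid in fam.members]
                msa = align_family(members, cfg.scheme, family_id=fam.family_id)
                result.family_alignments[fam.family_id] = msa
                result.profiles[fam.family_id] = build_profile(
                    msa, cfg.scheme, seed=cfg.seed
                )
            logger.info("built %d family profiles", len(result.profiles))
    except Exception as exc:
        raise RuntimeError(f"stage 'profiles' failed: {exc}") from exc

    try:
        if _stage("tree"):
            single_copy = select_shared_single_copy(result.relaxed_families)
            pool = {p.protein_id: p for ps in proteomes.values() for p in ps}
            blocks = []
            for fid in single_copy:
                fam = result.relaxed_families.family(fid)
                members = [pool[pid] for pid in fam.members]
                msa = align_family(members, cfg.scheme, family_id=fid)
                by_genome = {pool[pid].genome_id: pid for pid in fam.members}
                msa = msa.relabel({pid: g for g, pid in by_genome.items()})
                try:
                    msa = trim_columns(msa)
                except ValueError:
                    logger.warning("family %s fully trimmed; kept untrimmed", fid)
                blocks.append(msa)
            if blocks:
                concat, dist = concatenate_and_distance(blocks)
                dist.to_csv(out / "distances.tsv", sep="\t")
                tree = nj_tree(dist)
                tree = bootstrap_support(
                    concat, BootstrapConfig(cfg.bootstrap_replicates, cfg.seed), tree
                )
                tree = midpoint_root(tree)
                result.tree = tree
                tree_path = out / "tree.nwk"
                tree_path.write_text(tree.to_newick() + "\n")
                result.reports["tree"] = str(tree_path)
            else:
                logger.warning("no universal single-copy family; tree stage skipped")
    except Exception as exc:
        raise RuntimeError(f"stage 'tree' failed: {exc}") from exc

    try:
        if _stage("repeats"):
            per_genome = [
                find_intergenic_repeats(
                    g,
                    min_len=cfg.repeat_min_len,
                    min_copies=cfg.repeat_min_copies,
                    min_identity=cfg.repeat_min_identity,
                )
                for g in genomes
            ]
            merged = merge_repeats_across_genomes(per_genome, cfg.repeat_min_identity)
            result.repeat_clusters = merged
            rep_path = out / "repeats.tsv"
            with open(rep_path, "w") as fh:
                fh.write("cluster_id\tgenome_id\tstart\tend\tstrand\tsequence\n")
                for cluster in merged:
                    for gid, s, e, strand, seq in cluster.instances:
                        fh.write(f"{cluster.cluster_id}\t{gid}\t{s}\t{e}\t{strand}\t{seq}\n")
            result.reports["repeats"] = str(rep_path)
            sig_path = out / "sigma70.tsv"
            with open(sig_path, "w") as fh:
                fh.write("cluster_id\tgenome_id\tinstance_start\thit_offset\tstrand\tminus35\tspacer\tminus10\tmm35\tmm10\n")
                for cluster in merged:
                    for gid, s, e, strand, seq in cluster.instances:
                        for hit in scan_sigma70(seq, genome_id=gid):
                            fh.write(
                                f"{cluster.cluster_id}\t{gid}\t{s}\t{hit.start}\t{hit.strand}"
                                f"\t{hit.minus35}\t{hit.spacer_length}\t{hit.minus10}"
                                f"\t{hit.mismatches[0]}\t{hit.mismatches[1]}\n"
                            )
            result.reports["sigma70"] = str(sig_path)
            cons_path = out / "repeat_consensus.tsv"
            with open(cons_path, "w") as fh:
                fh.write("cluster_id\tn_instances\tconsensus\tstrictly_conserved\n")
                for cluster in merged:
                    if cluster.n_instances < 2:
                        continue
                    try:
                        prof = consensus_profile(cluster)
                    except ValueError as exc:
                        logger.warning("cluster %s: %s", cluster.cluster_id, exc)
                        continue
                    fh.write(
                        f"{cluster.cluster_id}\t{cluster.n_instances}"
                        f"\t{prof.consensus}\t{prof.strictly_conserved_count}\n"
                    )
            result.reports["repeat_consensus"] = str(cons_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'repeats' failed: {exc}") from exc

    logger.info("pipeline finished; reports: %s", sorted(result.reports))
    return result


# ---------------------------------------------------------------------------
# classification of a new genome


@dataclass
class ClassificationResult:
    query_id: str
    shared_fractions: dict[str, float]  # reference genome -> % of query proteins with a homolog
    best_reference: str
    best_genus: str
    genus_call: str  # assigned | novel-subfamily-candidate | unrelated
    primer_amplification: dict[str, bool] = field(default_factory=dict)


def _iupac_regex(primer: str) -> str:
    return "".join(
        f"[{''.join(sorted(IUPAC_SETS[c]))}]" if c in IUPAC_SETS else re.escape(c)
        for c in primer
    )


def primer_pair_amplifies(
    sequence: str,
    primers: PrimerCandidate,
    max_product: int = 5000,
) -> bool:
    """In-silico PCR: exact degenerate matching of both primers on opposite
    strands with a plausible product size."""
    fwd = re.compile(_iupac_regex(primers.forward))
    rev = re.compile(_iupac_regex(reverse_complement(primers.reverse)))
    for strand_seq in (sequence, reverse_complement(sequence)):
        for m in fwd.finditer(strand_seq):
            stop = min(len(strand_seq), m.start() + max_product)
            m2 = rev.search(strand_seq, m.end(), stop)
            if m2:
                return True
    return False


def classify_genome(
    query: GenomeRecord,
    reference_genomes: list[GenomeRecord],
    reference_clades: dict[str, str],
    primers: list[PrimerCandidate] | None = None,
    profiles: list[FamilyProfile] | None = None,
    params: HomologyParams | None = None,
    scheme: ScoringScheme | None = None,
    genus_threshold: float = 40.0,
    subfamily_threshold: float = 20.0,
    min_profile_hits: int = 20,
) -> ClassificationResult:
    """Place a query genome against reference clades by shared-protein
    fraction (genus rule: >= 40% shared proteins), falling back to the
    profile screen for subfamily-level relationships."""
    params = params or HomologyParams()
    scheme = scheme or ScoringScheme()
    query_prot = extract_proteome(query)
    if not query_prot:
        raise ValueError(f"{query.genome_id}: empty proteome")
    fractions = {}
    for ref in reference_genomes:
        ref_prot = extract_proteome(ref)
        n_hit = sum(
            1 for q in query_prot if any(is_homolog(q, r, params, scheme) for r in ref_prot)
        )
        fractions[ref.genome_id] = 100.0 * n_hit / len(query_prot)
    best_ref = max(fractions, key=lambda g: (fractions[g], g))
    best = fractions[best_ref]
    if best >= genus_threshold:
        call = "assigned"
    elif best >= subfamily_threshold:
        # subfamily-level kinship; the more sensitive profile screen can veto
        call = "novel-subfamily-candidate"
        if profiles:
            screen = screen_genomes(profiles, [query], min_hits=min_profile_hits)
            if not screen[0].retained:
                call = "unrelated"
    else:
        call = "unrelated"
    amp = {}
    for p in primers or []:
        amp[f"{p.family_id}:{p.forward[:8]}"] = primer_pair_amplifies(query.sequence, p)
    return ClassificationResult(
        query_id=query.genome_id,
        shared_fractions=fractions,
        best_reference=best_ref,
        best_genus=reference_clades.get(best_ref, ""),
        genus_call=call,
        primer_amplification=amp,
    )
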