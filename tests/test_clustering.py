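import random

import networkx as nx
import pytest

from phamclade.clustering import (
    HomologyGraph,
    PrimerConfig,
    build_homology_graph,
    clade_homology_matrix,
    cluster_families,
    core_families,
    propose_degenerate_primers,
    select_marker_families,
)
from phamclade.genome_io import ProteinRecord


def _protein(pid, genome, seq="MKVLLRWAGHKKL", start=0):
    return ProteinRecord(f"{genome}:{pid}", genome, seq, (start, start + 3 * len(seq), "+"))


def _graph_from_edges(n, edges, genomes=None):
    proteins = {}
    order = []
    for i in range(n):
        genome = genomes[i] if genomes else f"g{i % 3}"
        p = _protein(f"p{i}", genome, start=i * 100)
        proteins[p.protein_id] = p
        if genome not in order:
            order.append(genome)
    ids = sorted(proteins)
    edge_map = {
        tuple(sorted((ids[a], ids[b]))): (50.0, 40.0, 100.0) for a, b in edges
    }
    return HomologyGraph(proteins=proteins, genome_order=order, edges=edge_map), ids


class TestTransitiveClustering:
    def test_transitivity_chains_families(self):
        graph, ids = _graph_from_edges(4, [(0, 1), (1, 2)])
        fams = cluster_families(graph)
        parts = sorted(sorted(f.members) for f in fams.families)
        assert parts == [sorted([ids[0], ids[1], ids[2]]), [ids[3]]]

    def test_no_edges_gives_singletons(self):
        graph, _ = _graph_from_edges(5, [])
        assert len(cluster_families(graph)) == 5

    def test_matches_networkx_components_on_random_graphs(self):
        rng = random.Random(99)
        for _ in range(50):
            n = rng.randint(2, 50)
            edges = {
                (a, b)
                for a, b in (
                    sorted(rng.sample(range(n), 2)) for _ in range(rng.randint(0, 2 * n))
                )
            }
            graph, ids = _graph_from_edges(n, edges)
            ours = {frozenset(f.members) for f in cluster_families(graph).families}
            G = nx.Graph()
            G.add_nodes_from(ids)
            G.add_edges_from((ids[a], ids[b]) for a, b in edges)
            theirs = {frozenset(c) for c in nx.connected_components(G)}
            assert ours == theirs

    def test_partition_conserves_protein_count(self, small_analysis):
        fams = small_analysis["families"]
        total = sum(f.size for f in fams.families)
        assert total == len(small_analysis["graph"].proteins)
        assert set(fams.protein_to_family) == set(small_analysis["graph"].proteins)

    def test_genome_order_permutation_preserves_partition(self, small_analysis):
        proteomes = small_analysis["proteomes"]
        fwd = build_homology_graph(proteomes)
        rev = build_homology_graph(proteomes[::-1])
        parts_fwd = {frozenset(f.members) for f in cluster_families(fwd).families}
        parts_rev = {frozenset(f.members) for f in cluster_families(rev).families}
        assert parts_fwd == parts_rev

    def test_recovers_planted_families_exactly(self, small_analysis):
        from sklearn.metrics import adjusted_rand_score

        truth = small_analysis["truth"]
        fams = small_analysis["families"]
        pids = sorted(fams.protein_to_family)
        ari = adjusted_rand_score(
            [truth.family_of[p] for p in pids], [fams.protein_to_family[p] for p in pids]
        )
        assert ari == 1.0


class TestCoreFamilies:
    def test_family_in_all_genomes_is_core(self):
        graph, ids = _graph_from_edges(3, [(0, 1), (1, 2)], genomes=["g0", "g1", "g2"])
        fams = cluster_families(graph)
        assert core_families(fams) == [fams.families[0].family_id]

    def test_family_missing_one_genome_excluded(self):
        graph, _ = _graph_from_edges(4, [(0, 1)], genomes=["g0", "g1", "g2", "g2"])
        fams = cluster_families(graph)
        core = core_families(fams)
        assert core == []

    def test_planted_core_count(self, small_analysis):
        truth = small_analysis["truth"]
        core = core_families(small_analysis["families"])
        assert len(core) == len(truth.universal_single_copy)

    def test_core_bounded_by_smallest_proteome(self, small_analysis):
        core = core_families(small_analysis["families"])
        smallest = min(len(p) for p in small_analysis["proteomes"])
        assert len(core) <= smallest


class TestCladeMatrix:
    def test_identical_proteomes_within_mean_100(self):
        p1 = [_protein(f"p{i}", "g0", start=i * 100) for i in range(3)]
        p2 = [
            ProteinRecord(f"g1:p{i}", "g1", p.aa_sequence, p.genome_coords)
            for i, p in enumerate(p1)
        ]
        graph = build_homology_graph([p1, p2])
        mat = clade_homology_matrix(graph, {"g0": "c", "g1": "c"})
        assert mat.within_means["c"] == 100.0
        assert mat.between_mean is None

    def test_disjoint_proteomes_between_mean_0(self):
        p1 = [_protein("a", "g0", "MKVLLRWAGHKKL" * 3)]
        p2 = [_protein("b", "g1", "WWHHPPGGCCDDE" * 3)]
        graph = build_homology_graph([p1, p2])
        mat = clade_homology_matrix(graph, {"g0": "x", "g1": "y"})
        assert mat.between_mean == 0.0
        assert mat.values.loc["g0", "g0"] == 100.0

    def test_unassigned_genome_rejected(self, small_analysis):
        with pytest.raises(ValueError, match="without clade"):
            clade_homology_matrix(small_analysis["graph"], {"phiA01": "A"})

    def test_planted_clade_contrast(self, small_analysis):
        truth = small_analysis["truth"]
        mat = clade_homology_matrix(small_analysis["graph"], dict(truth.clades))
        cfg_core, cfg_cs, cfg_orph = 8, 6, 2
        proteome = cfg_core + cfg_cs + cfg_orph
        expected_within = 100.0 * (cfg_core + cfg_cs) / proteome
        expected_between = 100.0 * cfg_core / proteome
        for clade, mean in mat.within_means.items():
            assert mean == pytest.approx(expected_within, abs=5)
        assert mat.between_mean == pytest.approx(expected_between, abs=5)


class TestMarkersAndPrimers:
    def test_marker_selection_by_evalue(self):
        core = ["f1", "f2", "f3"]
        hits = {"f1": 1e-10, "f2": 0.5}
        assert select_marker_families(core, hits) == ["f2", "f3"]

    def test_perfectly_conserved_alignment_gives_degeneracy_1(self):
        seq = "ATGGCGCATCAGCGTCTTAGCAACTGGCTGGCGCATCAGCGTCTTAGCAACTGGCTTGGCATCAGCGTCTTAGCAACTGGCTTATGGCGCATCAGCGTCTTAGCAACTGGCTGGCGCATCAGCGTCTTAGC"
        primers = propose_degenerate_primers([seq, seq, seq], "fam")
        assert primers and primers[0].degeneracy == 1
        assert primers[0].forward in seq

    def test_two_base_column_emits_iupac_code(self):
        rng = random.Random(1)
        base = "".join(rng.choice("ACGT") for _ in range(120))
        other = base[:25] + ("T" if base[25] != "T" else "C") + base[26:]
        # the varying column is {base[25], T} -> one of the two-base codes
        cfg = PrimerConfig(min_len=20, max_len=20, max_degeneracy=2,
                           amplicon_min=60, amplicon_max=120, max_candidates=100_000)
        primers = propose_degenerate_primers([base, other], "fam", cfg)
        from phamclade.clustering import IUPAC_CODES
        code = IUPAC_CODES[frozenset({base[25], other[25]})]
        covering = [p for p in primers if code in p.forward]
        assert covering and all(p.degeneracy == 2 for p in covering)

    def test_candidates_match_exhaustive_window_scan(self):
        rng = random.Random(5)
        rows = ["".join(rng.choice("ACGT") for _ in range(200)) for _ in range(2)]
        rows[1] = rows[0][:50] + rows[1][50:150] + rows[0][150:]
        cfg = PrimerConfig(min_len=20, max_len=20, max_degeneracy=4, amplicon_min=80, amplicon_max=250, max_candidates=10_000)
        got = propose_degenerate_primers(rows, "fam", cfg)
        # independent exhaustive scan
        cols = [set(r[c] for r in rows) for c in range(200)]
        windows = []
        for start in range(181):
            deg = 1
            for c in range(start, start + 20):
                deg *= len(cols[c])
            if deg <= 4:
                windows.append((start, deg))
        expected_pairs = sum(
            1
            for fs, fd in windows
            for rs, rd in windows
            if rs > fs + 20 and 80 <= rs + 20 - fs <= 250
        )
        assert len(got) == expected_pairs
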