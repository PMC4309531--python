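"""Shared fixtures: a small synthetic two-clade set for module tests and the
full default set (seed 1) for end-to-end checks.  Both are generated in
memory; nothing is downloaded or read from disk."""

import pytest

from phamclade.clustering import build_homology_graph, cluster_families
from phamclade.genome_io import extract_proteome
from phamclade.pairwise import HomologyParams
from phamclade.pipeline import filter_graph
from phamclade.simulate import RepeatSpec, SimulationConfig, simulate_genome_set


SMALL_CONFIG = SimulationConfig(
    seed=7,
    genomes_per_clade=(3, 2),
    n_core_families=8,
    n_clade_specific=(6, 6),
    n_orphans=2,
    mean_protein_length=120,
    protein_length_spread=20,
    trna_counts=(4, 3),
    repeat_spec=RepeatSpec(copies_per_genome=((3, 3, 4), (2, 2))),
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_genome_set(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    genomes, truth = small_sim
    proteomes = [extract_proteome(g) for g in genomes]
    relaxed = build_homology_graph(proteomes, HomologyParams(35.0))
    strict = filter_graph(relaxed, 40.0)
    return {
        "genomes": genomes,
        "truth": truth,
        "proteomes": proteomes,
        "relaxed_graph": relaxed,
        "graph": strict,
        "families": cluster_families(strict),
        "relaxed_families": cluster_families(relaxed),
    }


@pytest.fixture(scope="session")
def default_sim():
    return simulate_genome_set(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    genomes, truth = default_sim
    proteomes = [extract_proteome(g) for g in genomes]
    relaxed = build_homology_graph(proteomes, HomologyParams(35.0))
    strict = filter_graph(relaxed, 40.0)
    return {
        "genomes": genomes,
        "truth": truth,
        "proteomes": proteomes,
        "relaxed_graph": relaxed,
        "graph": strict,
        "families": cluster_families(strict),
        "relaxed_families": cluster_families(relaxed),
    }
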