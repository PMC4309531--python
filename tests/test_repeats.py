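import random

import pytest

from phamclade.genome_io import Feature, GenomeRecord, reverse_complement
from phamclade.repeats import (
    MINUS10,
    MINUS35,
    consensus_profile,
    find_intergenic_repeats,
    merge_repeats_across_genomes,
    RepeatCluster,
    scan_sigma70,
)

ELEMENT = "GACT" + MINUS35 + "ACGTACGTACGTACGTA" + MINUS10 + "CCGGTTAA"  # 41 nt
assert len(ELEMENT) == 41


def _genome_with_elements(elements, genome_id="toy", spacer_len=120, seed=0):
    """Genes of 300 bp separated by spacers; each spacer may hold an element."""
    rng = random.Random(seed)
    parts = []
    feats = []
    pos = 0
    for i, elem in enumerate(elements + [None]):
        gene = "".join(rng.choice("ACGT") for _ in range(300))
        feats.append(Feature("CDS", pos, pos + 300, "+", f"gp{i:02d}"))
        parts.append(gene)
        pos += 300
        if elem is not None:
            pre = "".join(rng.choice("ACGT") for _ in range(40))
            post = "".join(rng.choice("ACGT") for _ in range(spacer_len - 40 - len(elem)))
            parts.append(pre + elem + post)
            pos += spacer_len
        elif i < len(elements):
            filler = "".join(rng.choice("ACGT") for _ in range(60))
            parts.append(filler)
            pos += 60
    return GenomeRecord(genome_id, genome_id, "".join(parts), features=feats)


class TestRepeatDiscovery:
    def test_three_exact_copies_form_one_cluster(self):
        g = _genome_with_elements([ELEMENT, ELEMENT, ELEMENT])
        clusters = find_intergenic_repeats(g)
        assert len(clusters) == 1
        assert clusters[0].n_instances == 3

    def test_no_repeated_kmers_gives_empty(self):
        g = _genome_with_elements([None], seed=3)
        assert find_intergenic_repeats(g) == []

    def test_instance_sequences_match_genome_slices(self):
        g = _genome_with_elements([ELEMENT, ELEMENT, ELEMENT])
        for cluster in find_intergenic_repeats(g):
            for gid, s, e, strand, seq in cluster.instances:
                sl = g.sequence[s:e]
                assert seq == (sl if strand == "+" else reverse_complement(sl))

    def test_reverse_orientation_instance_recovered(self):
        g = _genome_with_elements([ELEMENT, reverse_complement(ELEMENT), ELEMENT])
        clusters = find_intergenic_repeats(g)
        assert len(clusters) == 1
        assert clusters[0].n_instances == 3
        strands = {inst[3] for inst in clusters[0].instances}
        assert strands == {"+", "-"}

    def test_mutated_copies_cluster_at_80_percent(self):
        rng = random.Random(1)
        def mutate(s, n):
            s = list(s)
            for i in rng.sample(range(len(s)), n):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            return "".join(s)
        near = [ELEMENT, mutate(ELEMENT, 3), mutate(ELEMENT, 3)]
        g = _genome_with_elements(near)
        clusters = find_intergenic_repeats(g, min_identity=0.8)
        assert len(clusters) == 1 and clusters[0].n_instances == 3

    def test_repeats_found_only_in_intergenic_by_default(self):
        # plant the element inside a CDS: with default settings it is unseen
        rng = random.Random(9)
        gene = ELEMENT + "".join(rng.choice("ACGT") for _ in range(100)) + ELEMENT
        g = GenomeRecord("g", "g", gene + "A" * 30, features=[Feature("CDS", 0, len(gene), "+", "gp1")])
        assert find_intergenic_repeats(g) == []
        assert find_intergenic_repeats(g, whole_genome=True)


class TestCrossGenomeMerge:
    def test_identical_element_merges_with_provenance(self):
        g1 = _genome_with_elements([ELEMENT, ELEMENT], "g1", seed=1)
        g2 = _genome_with_elements([ELEMENT, ELEMENT], "g2", seed=2)
        merged = merge_repeats_across_genomes(
            [find_intergenic_repeats(g1), find_intergenic_repeats(g2)]
        )
        assert len(merged) == 1
        assert {i[0] for i in merged[0].instances} == {"g1", "g2"}

    def test_unrelated_elements_stay_separate(self):
        other = "TTTT" + MINUS35 + "GGGGGGGGGGGGGGGGG" + MINUS10 + "AAAACCCC"
        g1 = _genome_with_elements([ELEMENT, ELEMENT], "g1", seed=1)
        g2 = _genome_with_elements([other, other], "g2", seed=2)
        merged = merge_repeats_across_genomes(
            [find_intergenic_repeats(g1), find_intergenic_repeats(g2)]
        )
        assert len(merged) == 2


class TestConsensus:
    def test_identical_instances_fully_conserved(self):
        cluster = RepeatCluster(
            "c", [("g", 0, 41, "+", ELEMENT)] * 3, element_length=41
        )
        prof = consensus_profile(cluster)
        assert prof.strictly_conserved_count == 41
        assert prof.consensus == ELEMENT

    def test_single_difference_drops_one_position(self):
        variant = "A" + ELEMENT[1:] if ELEMENT[0] != "A" else "C" + ELEMENT[1:]
        cluster = RepeatCluster(
            "c", [("g", 0, 41, "+", ELEMENT), ("g", 100, 141, "+", variant)], 41
        )
        prof = consensus_profile(cluster)
        assert prof.strictly_conserved_count == 40
        assert prof.consensus[0].islower()

    def test_counts_conserve_instance_number(self):
        cluster = RepeatCluster(
            "c", [("g", 0, 41, "+", ELEMENT)] * 4, element_length=41
        )
        prof = consensus_profile(cluster)
        for pos in range(prof.length):
            assert sum(prof.counts[b][pos] for b in "ACGT") == 4

    def test_irreconcilable_lengths_rejected(self):
        cluster = RepeatCluster(
            "c",
            [("g", 0, 41, "+", ELEMENT), ("g", 100, 150, "+", ELEMENT + "AAAAAAAAA")],
            41,
        )
        with pytest.raises(ValueError, match="irreconcilable"):
            consensus_profile(cluster)


class TestSigma70:
    def test_canonical_promoter_found(self):
        seq = "G" * 20 + MINUS35 + "N" * 0 + "A" * 17 + MINUS10 + "G" * 20
        hits = scan_sigma70(seq)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        h = fwd[0]
        assert (h.start, h.spacer_length, h.mismatches) == (20, 17, (0, 0))

    def test_tag_aat_variant_counts_one_mismatch(self):
        seq = "G" * 10 + MINUS35 + "A" * 17 + "TAGAAT" + "G" * 10
        hits = [h for h in scan_sigma70(seq) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].mismatches == (0, 1)
        assert hits[0].minus10 == "TAGAAT"

    def test_planted_element_contains_exactly_one_hit(self):
        assert len(scan_sigma70(ELEMENT)) == 1

    def test_spacer_out_of_range_not_reported(self):
        seq = "G" * 10 + MINUS35 + "A" * 25 + MINUS10 + "G" * 10
        assert scan_sigma70(seq, spacer_range=(15, 19)) == []

    def test_agrees_with_naive_full_scan(self):
        rng = random.Random(12)
        seq = "".join(rng.choice("ACGT") for _ in range(10_000))
        got = {(h.start, h.strand, h.spacer_length) for h in scan_sigma70(seq)}

        def naive(s):
            found = set()
            for strand in "+-":
                t = s if strand == "+" else reverse_complement(s)
                for i in range(len(t)):
                    for spacer in range(15, 20):
                        j = i + 6 + spacer
                        if j + 6 > len(t):
                            continue
                        mm35 = sum(a != b for a, b in zip(t[i : i + 6], MINUS35))
                        mm10 = sum(a != b for a, b in zip(t[j : j + 6], MINUS10))
                        if mm35 <= 1 and mm10 <= 1:
                            span = 12 + spacer
                            start = i if strand == "+" else len(t) - (i + span)
                            found.add((start, strand, spacer))
            return found

        assert got == naive(seq)


class TestPlantedTruthRecovery:
    def test_all_planted_instances_recovered(self, small_sim):
        genomes, truth = small_sim
        per_genome = [find_intergenic_repeats(g) for g in genomes]
        merged = merge_repeats_across_genomes(per_genome)
        recovered = {
            (gid, s, e) for c in merged for gid, s, e, _, _ in c.instances
        }
        planted = [(g, s, e) for g, s, e, _ in truth.repeat_instances]
        n_found = sum(
            1
            for g, s, e in planted
            if any(gg == g and abs(ss - s) <= 2 and abs(ee - e) <= 2 for gg, ss, ee in recovered)
        )
        assert n_found >= 0.8 * len(planted)
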