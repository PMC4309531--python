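import io

import numpy as np
import pandas as pd
import pytest

from phamclade.msa import FamilyAlignment
from phamclade.phylogeny import (
    BootstrapConfig,
    PhyloTree,
    alignment_distances,
    bootstrap_support,
    concatenate_and_distance,
    midpoint_root,
    nj_tree,
    poisson_distance,
    select_shared_single_copy,
    tree_bipartitions,
    trim_columns,
)


def _additive_distances(tree_dists: dict[tuple[str, str], float], taxa):
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for (a, b), v in tree_dists.items():
        d.loc[a, b] = d.loc[b, a] = v
    return d


class TestSelection:
    def test_single_copy_universal_selected(self, small_analysis):
        truth = small_analysis["truth"]
        selected = select_shared_single_copy(small_analysis["relaxed_families"])
        fams = small_analysis["relaxed_families"]
        for fid in selected:
            fam = fams.family(fid)
            assert set(fam.genomes) == set(fams.genome_roster)
            assert all(c == 1 for c in fam.copy_counts.values())
        # every planted universal family is single copy in every genome, but
        # the relaxed 35% threshold may merge a few with orphans; the
        # selected set must be a subset of the planted universal families
        planted_members = {
            frozenset(p for p, f in truth.family_of.items() if f == fid)
            for fid in truth.universal_single_copy
        }
        selected_members = {frozenset(fams.family(fid).members) for fid in selected}
        assert selected_members <= planted_members
        assert len(selected) >= 1

    def test_duplicated_family_rejected(self, small_analysis):
        fams = small_analysis["relaxed_families"]
        duplicated = [
            f.family_id
            for f in fams.families
            if set(f.genomes) == set(fams.genome_roster)
            and any(c > 1 for c in f.copy_counts.values())
        ]
        selected = set(select_shared_single_copy(fams))
        assert not (selected & set(duplicated))


class TestTrimming:
    def test_conserved_gapfree_alignment_unchanged(self):
        msa = FamilyAlignment("f", {"a": "MKVRW", "b": "MKVRW", "c": "MKVRW"})
        assert trim_columns(msa).rows == msa.rows

    def test_gappy_column_removed(self):
        msa = FamilyAlignment(
            "f",
            {"a": "MKVRWMKVRW-MKVRW", "b": "MKVRWMKVRW-MKVRW", "c": "MKVRWMKVRWKMKVRW", "d": "MKVRWMKVRWKMKVRW"},
        )
        trimmed = trim_columns(msa, gap_cutoff=0.2)
        assert trimmed.n_columns == 15
        assert all("-" not in r for r in trimmed.rows.values())

    def test_would_empty_alignment_raises(self):
        msa = FamilyAlignment("noisy", {"a": "-K", "b": "M-", "c": "-M"})
        with pytest.raises(ValueError, match="noisy"):
            trim_columns(msa, gap_cutoff=0.1)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        msa = FamilyAlignment("f", {"a": "MKVRW" * 10, "b": "MKVRW" * 10, "c": "MKVRW" * 10})
        concat, d = concatenate_and_distance([msa])
        assert (d.values == 0).all()

    def test_poisson_correction_closed_form(self):
        rng = np.random.default_rng(0)
        row_a = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWY"), 1000))
        row_b = list(row_a)
        flip = rng.choice(1000, size=100, replace=False)
        for i in flip:
            row_b[i] = "V"  # guaranteed mismatch: V absent from row_a's alphabet
        d = poisson_distance(row_a, "".join(row_b))
        assert d == pytest.approx(-np.log(0.9))

    def test_blocks_tile_concatenation(self):
        a = FamilyAlignment("f1", {"x": "M" * 100, "y": "M" * 100, "z": "M" * 100})
        b = FamilyAlignment("f2", {"x": "K" * 50, "y": "K" * 50, "z": "K" * 50})
        concat, _ = concatenate_and_distance([a, b])
        assert concat.n_columns == 150
        assert concat.blocks == [("f1", (0, 100)), ("f2", (100, 150))]

    def test_taxon_mismatch_raises(self):
        a = FamilyAlignment("f1", {"x": "M", "y": "M"})
        b = FamilyAlignment("f2", {"x": "K", "z": "K"})
        with pytest.raises(ValueError, match="symmetric difference"):
            concatenate_and_distance([a, b])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = _additive_distances({("a", "b"): 3.0, ("a", "c"): 5.0, ("b", "c"): 6.0}, list("abc"))
        tree = nj_tree(d)
        tip = {t.name: t.length for t in tree.tree.tips()}
        assert tip["a"] == pytest.approx(1.0)
        assert tip["b"] == pytest.approx(2.0)
        assert tip["c"] == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "split,branches",
        [
            (frozenset({"a", "b"}), dict(a=1.0, b=2.0, c=1.5, d=2.5, internal=3.0)),
            (frozenset({"a", "c"}), dict(a=0.5, c=0.5, b=4.0, d=1.0, internal=2.0)),
        ],
    )
    def test_four_taxon_additive_matrix_recovered_exactly(self, split, branches):
        taxa = list("abcd")
        other = frozenset(set(taxa) - split)
        dists = {}
        for i, x in enumerate(taxa):
            for y in taxa[i + 1 :]:
                v = branches[x] + branches[y]
                if not ({x, y} <= split or {x, y} <= other):
                    v += branches["internal"]
                dists[(x, y)] = v
        tree = nj_tree(_additive_distances(dists, taxa))
        assert split in tree.bipartitions() or other in tree.bipartitions()
        tips = {t.name: t.length for t in tree.tree.tips()}
        for t in taxa:
            assert tips[t] == pytest.approx(branches[t])

    def test_five_taxon_caterpillar_recovered(self):
        # caterpillar ((a,b),c),d),e with all branches 1: path lengths known
        paths = {
            ("a", "b"): 2, ("a", "c"): 3, ("a", "d"): 4, ("a", "e"): 5,
            ("b", "c"): 3, ("b", "d"): 4, ("b", "e"): 5,
            ("c", "d"): 3, ("c", "e"): 4, ("d", "e"): 3,
        }
        tree = nj_tree(_additive_distances({k: float(v) for k, v in paths.items()}, list("abcde")))
        bips = tree.bipartitions()
        assert frozenset({"a", "b"}) in bips
        assert frozenset({"d", "e"}) in bips or frozenset({"a", "b", "c"}) in bips

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(d)


class TestBootstrapAndRooting:
    @pytest.fixture(scope="class")
    def separated_alignment(self):
        rng = np.random.default_rng(4)
        base1 = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 300))
        base2 = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), 300))
        def mutate(s, n):
            s = list(s)
            for i in rng.choice(len(s), size=n, replace=False):
                s[i] = "W"
            return "".join(s)
        rows = {f"x{i}": mutate(base1, 10) for i in range(3)}
        rows |= {f"y{i}": mutate(base2, 10) for i in range(3)}
        return FamilyAlignment("sep", rows)

    def test_clean_split_gets_full_support(self, separated_alignment):
        concat, d = concatenate_and_distance([separated_alignment])
        tree = bootstrap_support(concat, BootstrapConfig(50, seed=3))
        split = frozenset({"x0", "x1", "x2"})
        assert tree.supports[split] == 100.0

    def test_same_seed_same_supports(self, separated_alignment):
        concat, _ = concatenate_and_distance([separated_alignment])
        t1 = bootstrap_support(concat, BootstrapConfig(25, seed=9))
        t2 = bootstrap_support(concat, BootstrapConfig(25, seed=9))
        assert t1.supports == t2.supports

    def test_midpoint_root_halves_longest_path(self):
        d = _additive_distances(
            {("a", "b"): 10.0, ("a", "c"): 7.0, ("b", "c"): 9.0}, list("abc")
        )
        rooted = midpoint_root(nj_tree(d))
        depths = {t.name: t.distance(rooted.tree) for t in rooted.tree.tips()}
        assert max(depths.values()) == pytest.approx(5.0)

    def test_midpoint_rooting_idempotent(self):
        d = _additive_distances(
            {("a", "b"): 2.0, ("a", "c"): 4.0, ("b", "c"): 4.0}, list("abc")
        )
        once = midpoint_root(nj_tree(d))
        twice = midpoint_root(once)
        assert {t.name: round(t.distance(once.tree), 9) for t in once.tree.tips()} == {
            t.name: round(t.distance(twice.tree), 9) for t in twice.tree.tips()
        }

    def test_newick_roundtrip_preserves_everything(self, separated_alignment):
        concat, d = concatenate_and_distance([separated_alignment])
        tree = midpoint_root(bootstrap_support(concat, BootstrapConfig(20, seed=1)))
        text = tree.to_newick()
        back = PhyloTree.from_newick(text)
        assert back.bipartitions() == tree.bipartitions()
        orig = {t.name: round(t.length or 0, 6) for t in tree.tree.tips()}
        new = {t.name: round(t.length or 0, 6) for t in back.tree.tips()}
        assert orig == new
        for bip, sup in tree.supports.items():
            if bip in back.supports:
                assert back.supports[bip] == pytest.approx(sup, abs=0.5)
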