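"""Distances, neighbor joining (exact on additive inputs), bootstrap, and
the monophyly/duplication queries with brute-force oracles."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from p5crkit.msa_filter import MultipleAlignment
from p5crkit.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_supports,
    distance_matrix,
    find_duplications,
    is_monophyletic,
    leaf_labels,
    nj_tree,
    read_newick,
    write_newick,
)


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(list("ab"), ["MKVA", "MKVA"])
        assert distance_matrix(aln).d[0, 1] == 0.0

    def test_p_distance_counts_mismatches(self):
        aln = MultipleAlignment(list("ab"), ["MKVA", "MKVW"])
        assert distance_matrix(aln, "p").d[0, 1] == 0.25

    def test_poisson_closed_form(self):
        aln = MultipleAlignment(list("ab"), ["MKVA", "MKVW"])
        assert distance_matrix(aln, "poisson").d[0, 1] == pytest.approx(
            -math.log(0.75)
        )

    def test_gap_only_overlap_is_an_error_naming_the_pair(self):
        aln = MultipleAlignment(list("ab"), ["MK--", "--VA"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix(aln)

    def test_pairwise_deletion(self):
        aln = MultipleAlignment(list("ab"), ["MK-A", "MKV-"])
        assert distance_matrix(aln).d[0, 1] == 0.0  # only 2 comparable cols


def _tree_path_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(
            taxa[labels[i]], taxa[labels[j]]
        )
    return labels, d


def _random_tree(n_leaves, rng):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_leaves)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        taxon_namespace=taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(0.2 + rng.random())
    tree.is_rooted = False
    return tree


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # Hand-built tree: ((a:1,b:2):1,(c:3,d:1)) with internal edge 1.
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels, d))
        assert bipartitions(tree) == {frozenset({"c", "d"})} or \
            bipartitions(tree) == {frozenset({"a", "b"})}
        # Additivity: path lengths reproduce the input distances exactly.
        got_labels, got = _tree_path_distances(tree)
        order = [got_labels.index(l) for l in labels]
        assert np.allclose(got[np.ix_(order, order)], d)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 0.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_ultrametric_matches_single_linkage_topology(self):
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        tree = nj_tree(DistanceMatrix(list("abcd"), d))
        assert frozenset({"a", "b"}) in bipartitions(tree) or \
            frozenset({"c", "d"}) in bipartitions(tree)

    @pytest.mark.parametrize("n_leaves", [5, 6, 8])
    def test_random_additive_trees_recovered_exactly(self, n_leaves):
        import random

        rng = random.Random(n_leaves * 7)
        for _ in range(3):
            true_tree = _random_tree(n_leaves, rng)
            labels, d = _tree_path_distances(true_tree)
            est = nj_tree(DistanceMatrix(labels, d))
            assert bipartitions(est) == bipartitions(true_tree)
            est_labels, est_d = _tree_path_distances(est)
            order = [est_labels.index(l) for l in labels]
            assert np.allclose(est_d[np.ix_(order, order)], d, atol=1e-9)


class TestBootstrap:
    def _clean_split_alignment(self):
        # Ten duplicated columns supporting the a,b | c,d split.
        return MultipleAlignment(
            list("abcd"),
            ["A" * 10, "A" * 10, "W" * 10, "W" * 10],
        )

    def test_clean_split_has_full_support(self):
        tree, supports = bootstrap_supports(
            self._clean_split_alignment(), n_reps=30, seed=1
        )
        assert supports[frozenset({"c", "d"})] == 1.0

    def test_supports_within_unit_interval(self, small_family):
        aln = small_family.alignment()
        _, supports = bootstrap_supports(aln, n_reps=20, seed=2)
        assert all(0.0 <= s <= 1.0 for s in supports.values())

    def test_seed_reproducibility(self, small_family):
        aln = small_family.alignment()
        _, s1 = bootstrap_supports(aln, n_reps=15, seed=9)
        _, s2 = bootstrap_supports(aln, n_reps=15, seed=9)
        assert s1 == s2


class TestMonophyly:
    def test_cherry_is_monophyletic(self):
        tree = read_newick("((a,b),(c,d));")
        assert is_monophyletic(tree, {"a", "b"})

    def test_split_pair_is_not(self):
        tree = read_newick("((a,b),(c,d));")
        assert not is_monophyletic(tree, {"a", "c"})

    def test_unknown_label_is_an_error(self):
        tree = read_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="zzz"):
            is_monophyletic(tree, {"zzz"})

    def test_rerooting_invariance(self):
        tree1 = read_newick("((a,b),((c,d),e));")
        tree2 = read_newick("(c,(d,(e,(a,b))));")
        for taxa in ({"a", "b"}, {"c", "d"}, {"c", "d", "e"}, {"a", "c"}):
            assert is_monophyletic(tree1, taxa) == is_monophyletic(tree2, taxa)

    def test_agrees_with_bipartition_enumeration(self):
        import random

        rng = random.Random(42)
        for rep in range(5):
            tree = _random_tree(8, rng)
            leaves = sorted(leaf_labels(tree))
            all_bps = bipartitions(tree, informative_only=False)
            full = frozenset(leaves)
            ref = min(leaves)
            for _ in range(20):
                taxa = frozenset(rng.sample(leaves, rng.randint(1, 7)))
                side = frozenset(full - taxa) if ref in taxa else taxa
                expected = (
                    len(taxa) in (1, len(leaves))
                    or side in all_bps
                )
                assert is_monophyletic(tree, set(taxa)) == expected


class TestDuplications:
    def test_soybean_style_cherry(self):
        tree = read_newick("((gmax1,gmax2),rice);")
        species = {"gmax1": "Glycine max", "gmax2": "Glycine max",
                   "rice": "Oryza sativa"}
        assert find_duplications(tree, species) == [
            ("Glycine max", ("gmax1", "gmax2"))
        ]

    def test_all_distinct_species_no_duplications(self):
        tree = read_newick("((a,b),(c,d));")
        species = {l: l.upper() for l in "abcd"}
        assert find_duplications(tree, species) == []

    def test_nested_clades_reported_once_maximal(self):
        tree = read_newick("(((x1,x2),x3),y);")
        species = {"x1": "X", "x2": "X", "x3": "X", "y": "Y"}
        dups = find_duplications(tree, species)
        assert dups == [("X", ("x1", "x2", "x3"))]

    def test_unmapped_leaf_is_an_error(self):
        tree = read_newick("((a,b),c);")
        with pytest.raises(ValueError, match="'c'"):
            find_duplications(tree, {"a": "A", "b": "B"})

    def test_matches_bruteforce_over_all_clades(self):
        import random

        rng = random.Random(7)
        tree = _random_tree(8, rng)
        leaves = sorted(leaf_labels(tree))
        species = {l: rng.choice(["S1", "S2", "S3"]) for l in leaves}
        got = find_duplications(tree, species)
        # Brute force: every internal node's leaf set, keep uniform-species
        # clades of size >= 2 not contained in a larger reported one.
        clades = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            ls = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            sp = {species[l] for l in ls}
            if len(ls) >= 2 and len(sp) == 1:
                clades.append((sp.pop(), ls))
        maximal = [
            c for c in clades
            if not any(set(c[1]) < set(o[1]) for o in clades)
        ]
        assert got == sorted(set(maximal))

    def test_family_simulator_duplication_is_found(self):
        from p5crkit.synthetic_data import FamilyConfig, simulate_family

        fam = simulate_family(
            FamilyConfig(n_taxa=8, duplication_species="Glycine max", seed=3)
        )
        dups = find_duplications(fam.tree, fam.species_of)
        assert ("Glycine max" in {d[0] for d in dups})


class TestNewickIO:
    def test_round_trip(self):
        text = "((a:1.0,b:2.0):0.5,(c:3.0,d:1.0):0.5);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert leaf_labels(again) == {"a", "b", "c", "d"}
        assert bipartitions(again) == bipartitions(tree)
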