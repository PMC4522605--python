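"""Shared helpers for tree-based oracle tests."""

import itertools

import dendropy
import numpy as np

from p5crkit.phylo import bipartitions


def random_tree(n_leaves, rng):
    """Random birth-death topology with random branch lengths."""
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


def random_tree_with_distances(n_leaves, rng):
    """(labels, additive distance matrix, true bipartitions) of a random
    tree."""
    tree = random_tree(n_leaves, rng)
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(
            taxa[labels[i]], taxa[labels[j]]
        )
    return labels, d, bipartitions(tree)
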