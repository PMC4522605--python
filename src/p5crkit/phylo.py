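"""Distance-based tree building and the evolutionary queries used on the
P5CR family: monophyly of named groups and lineage-specific duplications.

Neighbor joining here is a desk-scale stand-in for maximum-likelihood
inference: it is exact on additive distances, dependency-free and fast,
and the downstream queries (monophyly, duplications) only need a sensible
topology. Externally built trees can be imported as Newick and run through
the same queries.

Trees are :class:`dendropy.Tree` objects throughout; NJ output is rooted at
a trifurcation, i.e. canonically unrooted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .msa_filter import GAP_CHARS, MultipleAlignment

POISSON_CAP = 10.0


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def distance_matrix(aln: MultipleAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion.

    ``model='p'`` is the mismatch fraction over both-non-gap columns;
    ``'poisson'`` is -ln(1-p), capped at 10 as p approaches 1.
    A pair with zero comparable columns is an error naming the pair.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model: {model!r}")
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(aln.rows[i], aln.rows[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {aln.ids[i]!r} and "
                    f"{aln.ids[j]!r}"
                )
            p = mismatch / comparable
            if model == "p":
                dist = p
            else:
                dist = -math.log1p(-p) if p < 1.0 - math.exp(-POISSON_CAP) \
                    else POISSON_CAP
                dist = min(dist, POISSON_CAP)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.ids), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Deterministic: ties in Q are broken by the lowest index pair. Negative
    branch lengths are clamped to zero. For n=3 the closed-form star
    resolution is returned. The result is rooted at a trifurcation.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # Grow the matrix with the new node's row.
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new_idx, k] = d[k, new_idx] = max(dk, 0.0)
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    root = dendropy.Node()
    nodes[i].edge.length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].edge.length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].edge.length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    for node in (nodes[i], nodes[j], nodes[k]):
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def read_newick(text_or_path: str, from_path: bool = False) -> dendropy.Tree:
    src = {"path": text_or_path} if from_path else {"data": text_or_path}
    return dendropy.Tree.get(schema="newick", **src)


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree, informative_only: bool = True
                 ) -> set[frozenset[str]]:
    """Leaf-set bipartitions of the tree's internal edges, each canonicalised
    to the side NOT containing the alphabetically first leaf label."""
    all_leaves = leaf_labels(tree)
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if informative_only and node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = frozenset(all_leaves - below) if ref in below else below
        if informative_only and not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        out.add(side)
    return out


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """True iff some edge splits the leaves exactly into ``taxa`` vs the
    rest (unrooted semantics). Singletons are trivially monophyletic."""
    all_leaves = leaf_labels(tree)
    unknown = set(taxa) - all_leaves
    if unknown:
        raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
    if not taxa:
        raise ValueError("taxa set must be non-empty")
    taxa = frozenset(taxa)
    if len(taxa) in (1, len(all_leaves)):
        return True
    complement = frozenset(all_leaves - taxa)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if below == taxa or below == complement:
            return True
    return False


def find_duplications(tree: dendropy.Tree, species_of: dict[str, str]
                      ) -> list[tuple[str, tuple[str, ...]]]:
    """Maximal clades of >=2 leaves that all share one species: candidate
    lineage-specific duplications. Returns (species, leaf ids) pairs."""
    missing = leaf_labels(tree) - set(species_of)
    if missing:
        raise ValueError(f"unmapped leaf label(s): {sorted(missing)}")

    out: list[tuple[str, tuple[str, ...]]] = []

    def uniform_species(node) -> str | None:
        species = {species_of[l.taxon.label] for l in node.leaf_iter()}
        return species.pop() if len(species) == 1 else None

    def walk(node, parent_uniform: bool) -> None:
        if node.is_leaf():
            return
        sp = uniform_species(node)
        if sp is not None and not parent_uniform:
            leaves = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            if len(leaves) >= 2:
                out.append((sp, leaves))
        for child in node.child_nodes():
            walk(child, parent_uniform or sp is not None)

    walk(tree.seed_node, False)
    return sorted(out)


def bootstrap_supports(
    aln: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "p",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap supports for the NJ tree of ``aln``.

    Resamples alignment columns with replacement (seeded), rebuilds the NJ
    tree for each replicate, and scores each internal edge of the base tree
    by the fraction of replicates containing its bipartition. Supports are
    attached to the base tree's internal nodes as ``node.label`` and also
    returned as a bipartition -> support map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = nj_tree(distance_matrix(aln, model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(base)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, aln.width, size=aln.width)
        rows = ["".join(row[c] for c in cols) for row in aln.rows]
        rep = MultipleAlignment(list(aln.ids), rows)
        rep_bps = bipartitions(nj_tree(distance_matrix(rep, model)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: c / n_reps for bp, c in counts.items()}
    all_leaves = leaf_labels(base)
    ref = min(all_leaves)
    for node in base.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = frozenset(all_leaves - below) if ref in below else below
        if side in supports:
            node.label = f"{supports[side]:.3f}"
    return base, supports
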