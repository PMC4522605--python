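"""Substitution-matrix access shared by alignment, clustering and column statistics.

Matrices come from Biopython's bundled collection. One family-wide convention
is applied on load: the ambiguity residue ``X`` scores 0 against everything,
so unknown residues neither reward nor penalise a column or an alignment.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue classes used for "similar character" judgements (conservation,
#: determinant-window comparison). Small/aliphatic, aromatic, hydroxyl,
#: acidic, amide, basic; Cys, Gly and Pro stand alone.
SIMILARITY_GROUPS: tuple[str, ...] = (
    "AVLIM",
    "FWY",
    "ST",
    "DE",
    "NQ",
    "KRH",
    "C",
    "G",
    "P",
)

_GROUP_OF: dict[str, str] = {
    res: group for group in SIMILARITY_GROUPS for res in group
}


def same_class(a: str, b: str) -> bool:
    """True if residues are identical or share a similarity group."""
    if a == b:
        return True
    ga, gb = _GROUP_OF.get(a), _GROUP_OF.get(b)
    return ga is not None and ga == gb


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix by name, with X re-scored to 0.

    Raises
    ------
    ValueError
        If the name is not in Biopython's matrix collection.
    """
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix: {name!r}") from exc
    mat = mat.copy()
    if "X" in mat.alphabet:
        i = mat.alphabet.index("X")
        mat[i, :] = 0.0
        mat[:, i] = 0.0
    return mat


@lru_cache(maxsize=None)
def matrix_range(name: str = "BLOSUM62") -> tuple[float, float]:
    """(s_min, s_max) over the 20 standard residues: the minimum entry and the
    maximum diagonal entry. For BLOSUM62 this is (-4, 11)."""
    mat = load_matrix(name)
    idx = [mat.alphabet.index(a) for a in AMINO_ACIDS if a in mat.alphabet]
    core = np.array(mat)[np.ix_(idx, idx)]
    return float(core.min()), float(np.diag(core).max())


def pair_score(a: str, b: str, name: str = "BLOSUM62") -> float:
    mat = load_matrix(name)
    return float(mat[a, b])
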