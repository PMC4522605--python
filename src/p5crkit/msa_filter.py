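"""Per-column alignment statistics and the informative-site filter.

A column is kept when its gap fraction is <= 0.5 AND its homogeneity is
>= 0.1 (strict exclusion of ``>0.5`` and ``<0.1``; boundary values stay).

Homogeneity is the min-max-normalised mean pairwise substitution score of
the column's non-gap residues:

    h = (s_mean - s_min) / (s_max - s_min)

with s_max the maximum diagonal entry and s_min the minimum entry of the
scoring matrix over the 20 standard residues (BLOSUM62 default: 11, -4).
Columns with a single non-gap residue score 1.0. The formula is recorded in
exported metadata so results are self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._scoring import load_matrix, matrix_range

GAP_CHARS = frozenset("-.")

HOMOGENEITY_FORMULA = (
    "min-max normalised mean pairwise substitution score; "
    "h=(s_mean-s_min)/(s_max-s_min)"
)


@dataclass
class MultipleAlignment:
    """Aligned rows (equal length, '-' or '.' gaps) with unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> str:
        """1-based column accessor."""
        if not 1 <= col <= self.width:
            raise IndexError(f"column {col} outside 1..{self.width}")
        return "".join(row[col - 1] for row in self.rows)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")


@dataclass(frozen=True)
class ColumnStats:
    index: int  # 1-based
    gap_fraction: float
    homogeneity: float | None  # None for all-gap columns
    kept: bool


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion thresholds: drop columns with gap fraction > ``gap_max``
    or homogeneity < ``hom_min``."""

    gap_max: float = 0.5
    hom_min: float = 0.1
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_max <= 1.0 and 0.0 <= self.hom_min <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


def column_gap_fraction(aln: MultipleAlignment, col: int) -> float:
    """Exact gaps/rows for a 1-based column."""
    column = aln.column(col)
    return sum(1 for c in column if c in GAP_CHARS) / aln.n_rows


def column_homogeneity(aln: MultipleAlignment, col: int,
                       matrix: str = "BLOSUM62") -> float:
    """Min-max-normalised mean pairwise substitution score of a column."""
    column = aln.column(col)
    residues = [c for c in column if c not in GAP_CHARS]
    if not residues:
        raise ValueError(f"column {col} is all gaps; homogeneity undefined")
    if len(residues) == 1:
        return 1.0
    mat = load_matrix(matrix)
    s_min, s_max = matrix_range(matrix)
    scores = [float(mat[a, b]) for a, b in combinations(residues, 2)]
    s_mean = sum(scores) / len(scores)
    return (s_mean - s_min) / (s_max - s_min)


def column_stats(aln: MultipleAlignment,
                 cfg: FilterConfig = FilterConfig()) -> list[ColumnStats]:
    """Gap fraction, homogeneity and keep/drop flag for every column."""
    out = []
    for col in range(1, aln.width + 1):
        gf = column_gap_fraction(aln, col)
        hom = None if gf == 1.0 else column_homogeneity(aln, col, cfg.matrix)
        kept = gf <= cfg.gap_max and hom is not None and hom >= cfg.hom_min
        out.append(ColumnStats(col, gf, hom, kept))
    return out


def stats_table(aln: MultipleAlignment,
                cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Per-column stats as a DataFrame (for TSV export); carries the
    homogeneity formula and matrix in ``df.attrs``."""
    stats = column_stats(aln, cfg)
    df = pd.DataFrame(
        {
            "index": [s.index for s in stats],
            "gap_fraction": [s.gap_fraction for s in stats],
            "homogeneity": [s.homogeneity for s in stats],
            "kept": [s.kept for s in stats],
        }
    )
    df.attrs["homogeneity_formula"] = HOMOGENEITY_FORMULA
    df.attrs["matrix"] = cfg.matrix
    return df


def filter_columns(
    aln: MultipleAlignment, cfg: FilterConfig = FilterConfig()
) -> tuple[MultipleAlignment | None, list[int]]:
    """Keep exactly the columns passing both thresholds.

    Returns the filtered alignment (None, with a warning, if no column
    survives) and the kept 1-based column indices in ascending order.
    """
    kept = [s.index for s in column_stats(aln, cfg) if s.kept]
    if not kept:
        warnings.warn("no columns survive the filter; empty alignment")
        return None, []
    rows = ["".join(row[i - 1] for i in kept) for row in aln.rows]
    return MultipleAlignment(list(aln.ids), rows), kept
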