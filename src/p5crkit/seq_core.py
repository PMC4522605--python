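"""Protein sequence I/O, pairwise global alignment and greedy clustering.

The clustering mirrors the conventions used to reduce redundancy in large
P5CR sequence sets: two sequences are linked when both are covered over at
least a minimum fraction of their length by the alignment and the alignment
score per aligned column exceeds a density threshold (defaults 0.95 and
1.5); linked components are merged by single linkage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner

from ._scoring import load_matrix

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_SPECIES_RE = re.compile(r"\[([^\[\]]+)\]\s*$")


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with an optional species tag."""

    id: str
    residues: str
    description: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"{self.id}: residues must be non-empty")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"{self.id}: illegal residue character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """An ordered collection of records with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows plus summary statistics of a global alignment."""

    rows: tuple[str, str]
    score: float
    identity_pct: float
    coverage_a: float
    coverage_b: float

    def __post_init__(self) -> None:
        if len(self.rows[0]) != len(self.rows[1]):
            raise ValueError("alignment rows must have equal length")


@dataclass(frozen=True)
class ClusterSet:
    """A partition of record ids produced by single-linkage clustering."""

    clusters: tuple[tuple[str, ...], ...]
    coverage_min: float
    density_min: float


def parse_species(description: str) -> str:
    """Extract ``Genus species`` from a trailing bracketed suffix, if any."""
    m = _SPECIES_RE.search(description)
    return m.group(1).strip() if m else ""


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Species tags are parsed from a trailing ``[Genus species]`` suffix in the
    description. Errors: empty file, duplicate ids, illegal residue
    characters (reported with 1-based position).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id: {entry.id!r}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                residues=str(entry.seq).upper(),
                description=entry.description,
                species=parse_species(entry.description),
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, wrapping residues at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in seqs:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(matrix)
    # Biopython convention: a gap of length L scores open + (L-1)*extend.
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _coverage(row_self: str, row_other: str) -> float:
    """Fraction of this sequence falling inside the aligned span (the region
    between the first and last column where both rows hold residues)."""
    both = [i for i, (x, y) in enumerate(zip(row_self, row_other))
            if x != "-" and y != "-"]
    n_res = sum(1 for c in row_self if c != "-")
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    inside = sum(1 for c in row_self[lo : hi + 1] if c != "-")
    return inside / n_res


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gaps.

    Returns the optimal score and a deterministic traceback (the first
    optimal alignment in Biopython's enumeration order).
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ident = _identity_pct(row_a, row_b)
    return PairwiseAlignment(
        rows=(row_a, row_b),
        score=float(aln.score),
        identity_pct=ident,
        coverage_a=_coverage(row_a, row_b),
        coverage_b=_coverage(row_b, row_a),
    )


def _identity_pct(row_a: str, row_b: str) -> float:
    both = [(x, y) for x, y in zip(row_a, row_b) if x != "-" and y != "-"]
    if not both:
        raise ValueError("alignment has no column where both rows hold residues")
    ident = sum(1 for x, y in both if x == y)
    return 100.0 * ident / len(both)


def percent_identity(aln: PairwiseAlignment, denominator: str = "aligned") -> float:
    """Percent identity of a pairwise alignment.

    ``denominator='aligned'`` (default) divides by the number of columns
    where both rows hold residues; ``'shorter'`` divides by the length of
    the shorter ungapped sequence.
    """
    row_a, row_b = aln.rows
    if denominator == "aligned":
        return _identity_pct(row_a, row_b)
    if denominator == "shorter":
        ident = sum(
            1 for x, y in zip(row_a, row_b) if x != "-" and y != "-" and x == y
        )
        shorter = min(
            sum(1 for c in row_a if c != "-"), sum(1 for c in row_b if c != "-")
        )
        return 100.0 * ident / shorter
    raise ValueError(f"unknown identity denominator: {denominator!r}")


def cluster_sequences(
    seqs: SequenceSet,
    coverage_min: float = 0.95,
    density_min: float = 1.5,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> ClusterSet:
    """Single-linkage clustering over the pairwise link predicate.

    Records a, b are linked iff both coverages are >= ``coverage_min`` and
    the alignment score divided by the alignment length (columns) is >=
    ``density_min``. Deterministic in input order.
    """
    if len(seqs) == 0:
        raise ValueError("cannot cluster an empty sequence set")
    ids = seqs.ids
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    recs = list(seqs)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            aln = global_align(recs[i], recs[j], matrix, gap_open, gap_extend)
            n_cols = len(aln.rows[0])
            if (
                aln.coverage_a >= coverage_min
                and aln.coverage_b >= coverage_min
                and aln.score / n_cols >= density_min
            ):
                ra, rb = find(recs[i].id), find(recs[j].id)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for rid in ids:
        groups.setdefault(find(rid), []).append(rid)
    # Deterministic: clusters ordered by first member's input position.
    order = {rid: k for k, rid in enumerate(ids)}
    clusters = sorted(groups.values(), key=lambda g: min(order[r] for r in g))
    return ClusterSet(
        clusters=tuple(tuple(g) for g in clusters),
        coverage_min=coverage_min,
        density_min=density_min,
    )
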