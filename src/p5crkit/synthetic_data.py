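"""Synthetic inputs with known ground truth for every pipeline stage.

Generators are pure functions of their config (seed included): P5CR-like
families evolved along a random tree with planted oligomer determinants,
alignments with exactly specified per-column gap fractions and homogeneity
bands, toy two-chain assemblies with planted bridge/stacking geometry and
hinge rotations, and SEC elution volumes drawn from a known calibration
line.

Substitutions are uniform over the 19 alternative residues (no indels), so
leaf coordinates coincide with scaffold coordinates; the divergence knob is
the expected per-site substitution count from root to leaf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from ._scoring import AMINO_ACIDS
from .msa_filter import MultipleAlignment
from .reference import synthetic_reference
from .sec_calibration import ColumnGeometry, Standard
from .seq_core import ProteinRecord, SequenceSet
from .structure3d import Atom, Residue, StructureModel

#: Decamer-type determinant replacement material (rice 202-214) and the
#: printed bacterial dimer exemplar windows.
DECAMER_DD = "ADGGVAAGLPRDL"
DIMER_DD_WINDOWS = ("QNAAIRQGFDMAE", "QEAAEQLGLTKET")

#: Salt-bridge residues planted for decamer-type leaves and their
#: replacements in dimer-type leaves (position -> residue, rice numbering).
DECAMER_BRIDGES = {236: "H", 241: "K", 242: "D"}
DIMER_BRIDGES = {236: "Q", 241: "E", 242: "A"}

DD_SPAN = (202, 214)


@dataclass(frozen=True)
class FamilyConfig:
    """Study conditions for the family simulator.

    ``rate`` is the expected per-site substitution count from the root to a
    leaf (the tree is scaled to unit root-to-leaf depth); motif columns
    mutate at ``rate * motif_rate_multiplier``.
    """

    n_taxa: int = 12
    scaffold: ProteinRecord | None = None  # default: synthetic rice reference
    rate: float = 0.08
    motif_rate_multiplier: float = 0.1
    fraction_dimer_type: float = 0.5
    duplication_species: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.rate < 0 or not 0.0 <= self.motif_rate_multiplier <= 1.0:
            raise ValueError("rates must be >= 0, multiplier in [0, 1]")
        if not 0.0 <= self.fraction_dimer_type <= 1.0:
            raise ValueError("fraction_dimer_type must lie in [0, 1]")


@dataclass
class FamilyResult:
    sequences: SequenceSet
    tree: dendropy.Tree
    labels: dict[str, str]       # leaf id -> "decamer" | "dimer"
    species_of: dict[str, str]   # leaf id -> species tag
    scaffold: ProteinRecord

    def alignment(self) -> MultipleAlignment:
        """The (gap-free) alignment implied by indel-free evolution."""
        return MultipleAlignment(
            [r.id for r in self.sequences], [r.residues for r in self.sequences]
        )


def _motif_columns(scaffold_length: int) -> set[int]:
    """0-based columns under conserved windows of the rice frame: the
    fingerprint motifs, the determinant region, the bridge residues and the
    family signature window."""
    from .fingerprint import builtin_motifs
    from .reference import _PLANTED

    cols: set[int] = set()
    for lo, hi in (
        [m.ref_span for m in builtin_motifs()] + list(_PLANTED)
    ):
        cols.update(range(lo - 1, min(hi, scaffold_length)))
    for pos in (236, 241, 242, 251):
        if pos <= scaffold_length:
            cols.add(pos - 1)
    return cols


def _random_ultrametric_tree(labels: list[str], rng: np.random.Generator
                             ) -> dendropy.Tree:
    """Random coalescent-style bifurcating tree, scaled to unit depth."""
    taxa = dendropy.TaxonNamespace(labels)
    lineages = [(dendropy.Node(taxon=taxa.get_taxon(l)), 0.0) for l in labels]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (ni, hi), (nj, hj) = lineages[i], lineages[j]
        parent = dendropy.Node()
        ni.edge.length = t - hi
        nj.edge.length = t - hj
        parent.add_child(ni)
        parent.add_child(nj)
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, t))
    root, depth = lineages[0]
    for node in root.preorder_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    return tree


def _mutate(residues: str, p_background: float, p_motif: float,
            motif_cols: set[int], rng: np.random.Generator) -> str:
    out = list(residues)
    u = rng.random(len(out))
    for i, orig in enumerate(out):
        p = p_motif if i in motif_cols else p_background
        if u[i] < p:
            choices = [a for a in AMINO_ACIDS if a != orig]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_family(cfg: FamilyConfig) -> FamilyResult:
    """Evolve a P5CR-like family on a random tree with planted oligomer
    determinants.

    After evolution, every leaf's determinant region is overwritten by its
    planted label: decamer-type leaves get the decamer consensus window and
    the canonical salt-bridge residues, dimer-type leaves get one of the
    printed bacterial dimer windows with the bridge network ablated.
    """
    rng = np.random.default_rng(cfg.seed)
    scaffold = cfg.scaffold or synthetic_reference()
    if len(scaffold) < DD_SPAN[1]:
        raise ValueError("scaffold shorter than the last determinant span")
    labels = [f"t{i + 1}" for i in range(cfg.n_taxa)]
    tree = _random_ultrametric_tree(labels, rng)
    motif_cols = _motif_columns(len(scaffold))

    seqs: dict[str, str] = {}

    def evolve(node, seq: str) -> None:
        for child in node.child_nodes():
            blen = child.edge.length or 0.0
            child_seq = _mutate(
                seq,
                cfg.rate * blen,
                cfg.rate * cfg.motif_rate_multiplier * blen,
                motif_cols,
                rng,
            )
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                evolve(child, child_seq)

    evolve(tree.seed_node, scaffold.residues)

    n_dimer = round(cfg.fraction_dimer_type * cfg.n_taxa)
    dimer_ids = set(rng.permutation(labels)[:n_dimer])
    truth: dict[str, str] = {}
    records: list[ProteinRecord] = []
    species_of: dict[str, str] = {
        label: f"Species {i + 1}" for i, label in enumerate(labels)
    }
    if cfg.duplication_species is not None:
        for node in tree.seed_node.preorder_iter():
            children = node.child_nodes()
            if len(children) == 2 and all(c.is_leaf() for c in children):
                for c in children:
                    species_of[c.taxon.label] = cfg.duplication_species
                break

    lo, hi = DD_SPAN
    for k, label in enumerate(labels):
        seq = list(seqs[label])
        if label in dimer_ids:
            truth[label] = "dimer"
            window = DIMER_DD_WINDOWS[k % len(DIMER_DD_WINDOWS)]
            bridges = DIMER_BRIDGES
        else:
            truth[label] = "decamer"
            window = DECAMER_DD
            bridges = DECAMER_BRIDGES
        seq[lo - 1 : hi] = list(window)
        for pos, res in bridges.items():
            seq[pos - 1] = res
        records.append(
            ProteinRecord(
                id=label,
                residues="".join(seq),
                description=f"{label} simulated P5CR [{species_of[label]}]",
                species=species_of[label],
            )
        )
    return FamilyResult(
        sequences=SequenceSet(records),
        tree=tree,
        labels=truth,
        species_of=species_of,
        scaffold=scaffold,
    )


def _sample_column(n_residues: int, band: tuple[float, float],
                   matrix: str, rng: np.random.Generator,
                   max_attempts: int = 5000) -> list[str]:
    """Rejection-sample residues whose column homogeneity lies in ``band``."""
    aa = list(AMINO_ACIDS)
    lo, hi = band
    for attempt in range(max_attempts):
        mode = rng.integers(3)
        if mode == 0:
            col = [aa[rng.integers(20)]] * n_residues
        elif mode == 1:
            a, b = rng.choice(20, size=2, replace=False)
            k = int(rng.integers(1, n_residues)) if n_residues > 1 else 1
            col = [aa[a]] * k + [aa[b]] * (n_residues - k)
        else:
            col = [aa[rng.integers(20)] for _ in range(n_residues)]
        h = _homogeneity_of(col, matrix)
        if lo <= h <= hi:
            return col
    raise ValueError(
        f"could not realise homogeneity band {band} with {n_residues} "
        f"residues in {max_attempts} attempts"
    )


def _homogeneity_of(residues: list[str], matrix: str) -> float:
    """Column homogeneity of a bare residue list (same formula as
    :func:`p5crkit.msa_filter.column_homogeneity`)."""
    from itertools import combinations

    from ._scoring import load_matrix, matrix_range

    if len(residues) < 2:
        return 1.0
    mat = load_matrix(matrix)
    s_min, s_max = matrix_range(matrix)
    scores = [float(mat[a, b]) for a, b in combinations(residues, 2)]
    return (sum(scores) / len(scores) - s_min) / (s_max - s_min)


def make_alignment_with_stats(
    column_specs: list[tuple[float, tuple[float, float]]],
    n_rows: int,
    seed: int = 0,
    matrix: str = "BLOSUM62",
) -> MultipleAlignment:
    """Build an alignment whose columns have exactly the requested gap
    fractions and homogeneities within the requested bands.

    Each spec is ``(gap_fraction, (h_lo, h_hi))``; the gap count must be an
    integer for ``n_rows``. Infeasible bands raise after bounded attempts.
    """
    rng = np.random.default_rng(seed)
    columns: list[list[str]] = []
    for gap_fraction, band in column_specs:
        n_gaps = gap_fraction * n_rows
        if abs(n_gaps - round(n_gaps)) > 1e-9:
            raise ValueError(
                f"gap fraction {gap_fraction} not integral for {n_rows} rows"
            )
        n_gaps = int(round(n_gaps))
        n_res = n_rows - n_gaps
        col = ["-"] * n_rows
        if n_res:
            residues = _sample_column(n_res, band, matrix, rng)
            slots = rng.permutation(n_rows)[:n_res]
            for slot, res in zip(sorted(slots), residues):
                col[slot] = res
        columns.append(col)
    ids = [f"r{i + 1}" for i in range(n_rows)]
    rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
    return MultipleAlignment(ids, rows)


@dataclass(frozen=True)
class ToyStructureConfig:
    """Layout of the toy two-chain assembly.

    Two parallel poly-alanine C-alpha helices (1.5 A rise, 100 deg turn)
    separated along x; optional Arg/Asp pseudo-side-chain groups planted at
    an exact minimum N-O distance; optional second-chain hinge rotation of
    the first half of the helix about a y-axis through the hinge residue.
    """

    helix_length: int = 12
    separation: float = 10.0
    bridge_distance: float | None = 2.8
    stack_distance: float | None = None
    hinge_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")


def _helix_ca(n: int, radius: float = 2.3, rise: float = 1.5,
              turn_deg: float = 100.0) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(turn_deg) * i
    return np.column_stack(
        (radius * np.cos(theta), radius * np.sin(theta), rise * i)
    )


def hinge_displacement(points: np.ndarray, angle_deg: float,
                       axis_point: np.ndarray) -> float:
    """Analytic mean displacement of ``points`` rotated by ``angle_deg``
    about the y-axis through ``axis_point``: 2 sin(theta/2) * mean distance
    from the axis."""
    rel = points - axis_point
    rho = np.sqrt(rel[:, 0] ** 2 + rel[:, 2] ** 2)  # distance from y-axis
    return float(2.0 * math.sin(math.radians(angle_deg) / 2.0) * rho.mean())


def build_toy_assembly(cfg: ToyStructureConfig) -> StructureModel:
    """Build the toy two-chain assembly described by ``cfg``."""
    if cfg.separation < 5.0:
        warnings.warn("chains closer than 5 A; expect heavy overlap")
    n = cfg.helix_length
    ca_a = _helix_ca(n)
    ca_b = ca_a.copy()
    hinge_res = n // 2 + 1  # first residue of the fixed (aligned) half
    if cfg.hinge_angle_deg:
        axis_point = ca_b[hinge_res - 1]
        theta = math.radians(cfg.hinge_angle_deg)
        rot = np.array(
            [
                [math.cos(theta), 0.0, math.sin(theta)],
                [0.0, 1.0, 0.0],
                [-math.sin(theta), 0.0, math.cos(theta)],
            ]
        )
        moving = ca_b[: hinge_res - 1] - axis_point
        ca_b[: hinge_res - 1] = moving @ rot.T + axis_point
    ca_b = ca_b + np.array([cfg.separation, 0.0, 0.0])

    serial = [0]

    def make_residue(chain: str, seq: int, name: str,
                     atom_specs: list[tuple[str, np.ndarray]]) -> Residue:
        atoms = []
        for atom_name, xyz in atom_specs:
            serial[0] += 1
            atoms.append(
                Atom(
                    serial=serial[0],
                    name=atom_name,
                    element=_element_of(atom_name),
                    res_name=name,
                    res_seq=seq,
                    icode="",
                    chain_id=chain,
                    xyz=tuple(float(v) for v in xyz),
                )
            )
        return Residue(name=name, seq=seq, icode="", chain_id=chain,
                       atoms=tuple(atoms))

    chain_a = [
        make_residue("A", i + 1, "ALA", [("CA", ca_a[i])]) for i in range(n)
    ]
    chain_b = [
        make_residue("B", i + 1, "ALA", [("CA", ca_b[i])]) for i in range(n)
    ]

    mid_z = 1.5 * (n - 1) / 2.0
    if cfg.bridge_distance is not None:
        cz = np.array([cfg.separation / 2.0 - 2.0, 6.0, mid_z])
        nh1 = cz + np.array([1.2, 0.0, 0.0])
        arg = make_residue(
            "A", n + 1, "ARG",
            [
                ("CZ", cz),
                ("NH1", nh1),
                ("NH2", cz + np.array([-0.6, 1.0, 0.0])),
                ("NE", cz + np.array([-0.6, -1.0, 0.0])),
            ],
        )
        od1 = nh1 + np.array([cfg.bridge_distance, 0.0, 0.0])
        asp = make_residue(
            "B", n + 1, "ASP",
            [("OD1", od1), ("OD2", od1 + np.array([0.8, 1.0, 0.0]))],
        )
        chain_a.append(arg)
        chain_b.append(asp)
    if cfg.stack_distance is not None:
        cz_a = np.array([cfg.separation / 2.0 - 2.0, -6.0, mid_z])
        quad_a = [
            ("CZ", cz_a),
            ("NH1", cz_a + np.array([1.2, 0.0, 0.0])),
            ("NH2", cz_a + np.array([-0.6, 1.0, 0.0])),
            ("NE", cz_a + np.array([-0.6, -1.0, 0.0])),
        ]
        offset = np.array([0.0, 0.0, cfg.stack_distance])
        quad_b = [(nm, xyz + offset) for nm, xyz in quad_a]
        chain_a.append(make_residue("A", n + 2, "ARG", quad_a))
        chain_b.append(make_residue("B", n + 2, "ARG", quad_b))
    return StructureModel(chains={"A": chain_a, "B": chain_b})


def _element_of(atom_name: str) -> str:
    return atom_name[0]


@dataclass(frozen=True)
class SecSimConfig:
    """Known calibration line plus standards/unknowns to elute through it.

    Defaults mirror the family's SEC setup: a preparative column (void 45
    mL, bed 120 mL), the four standards at 25/67/275/669 kDa, and one
    decamer-type unknown whose subunit mass is the printed 28,624 Da.
    """

    slope: float = -0.4
    intercept: float = 2.5
    geometry: ColumnGeometry = field(
        default_factory=lambda: ColumnGeometry(Vo=45.0, Vt=120.0)
    )
    standards_mw: tuple[float, ...] = (25_000.0, 67_000.0, 275_000.0, 669_000.0)
    unknowns: tuple[tuple[str, float, int], ...] = (
        ("AtP5CR-like", 28_624.0, 10),
    )  # (name, subunit mass Da, true subunit count)
    sigma: float = 0.5  # Gaussian noise on Ve, mL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class SecUnknown:
    name: str
    Ve: float
    subunit_mw: float


@dataclass
class SecSimResult:
    standards: list[Standard]
    unknowns: list[SecUnknown]
    truth: dict[str, tuple[float, int]]  # name -> (true mass Da, true count)


def simulate_sec(cfg: SecSimConfig) -> SecSimResult:
    """Generate elution volumes from the true calibration line plus noise."""
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry

    def elute(mw: float) -> float:
        k_true = cfg.slope * math.log10(mw) + cfg.intercept
        ve_true = geom.Vo + (geom.Vt - geom.Vo) * k_true
        for _ in range(100):
            ve = ve_true + (rng.normal(0.0, cfg.sigma) if cfg.sigma else 0.0)
            if geom.Vo < ve < geom.Vt:
                return ve
        raise ValueError(
            f"elution volume for mw={mw} repeatedly outside the column; "
            "check the calibration line"
        )

    standards = [
        Standard(name=f"std{i + 1}", mw=mw, Ve=elute(mw))
        for i, mw in enumerate(cfg.standards_mw)
    ]
    unknowns = []
    truth = {}
    for name, subunit, n_true in cfg.unknowns:
        true_mw = subunit * n_true
        unknowns.append(SecUnknown(name=name, Ve=elute(true_mw),
                                   subunit_mw=subunit))
        truth[name] = (true_mw, n_true)
    return SecSimResult(standards=standards, unknowns=unknowns, truth=truth)
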