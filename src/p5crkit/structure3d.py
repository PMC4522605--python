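"""Structural measurements: superposition/RMSD, solvent-accessible and
buried surface area, interface salt bridges and arginine stacking, hinge
domain motion, and inter-region distances.

The PDB reader is a minimal fixed-column parser with a pinned policy:
first MODEL only, hydrogens excluded, waters excluded, and for alternate
locations the highest-occupancy conformer kept (ties go to altloc 'A').

Surface areas use the Shrake-Rupley method with a deterministic
golden-spiral point set (960 points, probe 1.4 A) and heavy-atom radii
C 1.70 / N 1.55 / O 1.52 / S 1.80 A (default 1.70 A for anything else).
Buried area across an interface is ASA(A) + ASA(B) - ASA(A u B), summed
over both groups; divide by two for a one-sided value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: Default rice-frame domain boundaries: dinucleotide-binding N domain and
#: C-terminal dimerisation domain.
N_DOMAIN_SPAN = (1, 175)
C_DOMAIN_SPAN = (176, 284)

BASIC_SIDECHAIN_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
GUANIDINIUM_ATOMS = ("CZ", "NH1", "NH2", "NE")


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    icode: str
    chain_id: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_RADIUS)


@dataclass(frozen=True)
class Residue:
    name: str
    seq: int
    icode: str
    chain_id: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Atoms grouped chain -> residue, in file order."""

    chains: dict[str, list[Residue]]
    model_number: int = 1

    def residues(self, chain_ids: set[str] | None = None):
        for cid, residues in self.chains.items():
            if chain_ids is None or cid in chain_ids:
                yield from residues

    def atoms(self, chain_ids: set[str] | None = None) -> list[Atom]:
        return [a for r in self.residues(chain_ids) for a in r.atoms]

    def chain(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]


def _infer_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else ""


def read_pdb(path: str | Path, keep_hydrogens: bool = False,
             keep_waters: bool = False, model: int = 1) -> StructureModel:
    """Parse a PDB-format text file into a :class:`StructureModel`.

    ATOM and HETATM records only; the requested MODEL (first by default);
    per residue+atom name the highest-occupancy altloc is kept, ties going
    to 'A'. Malformed coordinate fields raise with the line number.
    """
    raw: list[Atom] = []
    current_model = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                fields = line.split()
                current_model = int(fields[1]) if len(fields) > 1 else 1
                continue
            if rec == "ENDMDL":
                current_model = None
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if current_model is not None and current_model != model:
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed coordinate field at line {lineno}"
                ) from exc
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError(
                    f"{path}: non-finite coordinate at line {lineno}"
                )
            try:
                occupancy = float(line[54:60])
            except ValueError:
                occupancy = 1.0
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            name = line[12:16].strip()
            if not element:
                element = _infer_element(name)
            raw.append(
                Atom(
                    serial=int(line[6:11]),
                    name=name,
                    element=element,
                    res_name=line[17:20].strip(),
                    res_seq=int(line[22:26]),
                    icode=line[26].strip(),
                    chain_id=line[21].strip() or "A",
                    xyz=(x, y, z),
                    occupancy=occupancy,
                    altloc=line[16].strip(),
                )
            )
    if not raw:
        raise ValueError(f"{path}: no atoms")

    chains: dict[str, dict[tuple, dict[str, Atom]]] = {}
    res_meta: dict[tuple, tuple[str, int, str, str]] = {}
    for atom in raw:
        if not keep_hydrogens and atom.element in ("H", "D"):
            continue
        if not keep_waters and atom.res_name in WATER_NAMES:
            continue
        rkey = (atom.chain_id, atom.res_seq, atom.icode, atom.res_name)
        res_meta.setdefault(rkey, (atom.res_name, atom.res_seq, atom.icode,
                                   atom.chain_id))
        per_res = chains.setdefault(atom.chain_id, {}).setdefault(rkey, {})
        existing = per_res.get(atom.name)
        if existing is None:
            per_res[atom.name] = atom
        else:
            # Altloc policy: highest occupancy wins; exact tie -> 'A'.
            if atom.occupancy > existing.occupancy or (
                atom.occupancy == existing.occupancy and atom.altloc == "A"
            ):
                per_res[atom.name] = atom

    model_chains: dict[str, list[Residue]] = {}
    for cid, residues in chains.items():
        model_chains[cid] = [
            Residue(
                name=res_meta[rkey][0],
                seq=res_meta[rkey][1],
                icode=res_meta[rkey][2],
                chain_id=cid,
                atoms=tuple(per_res.values()),
            )
            for rkey, per_res in residues.items()
        ]
    return StructureModel(chains=model_chains, model_number=model)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal fixed-column PDB file."""
    with open(path, "w") as fh:
        serial = 0
        for res in model.residues():
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.xyz
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} "
                    f"{res.chain_id:1s}{res.seq:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}  0.00"
                    f"          {atom.element:>2s}\n"
                )
        fh.write("END\n")


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray
                     ) -> SuperpositionResult:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns a proper rotation (reflection corrected), the translation, and
    the RMSD measured by actually applying the transform. Degenerate
    (collinear or coincident) point sets raise.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("coordinate sets must have matching shapes")
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape[0] < 3:
        raise ValueError("need at least 3 paired 3-D points")
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    mv, fx = moving - cm, fixed - cf
    sv = np.linalg.svd(mv.T @ fx, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1e-30):
        raise ValueError("degenerate (collinear) coordinate set")
    rot, _ = Rotation.align_vectors(fx, mv)
    rmat = rot.as_matrix()
    translation = cf - rmat @ cm
    transformed = moving @ rmat.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - fixed) ** 2, axis=1))))
    return SuperpositionResult(rotation=rmat, translation=translation,
                               rmsd=rmsd, n_atoms=moving.shape[0])


def pair_chains_by_residue(
    model_a: StructureModel,
    chain_a: str,
    model_b: StructureModel | None = None,
    chain_b: str | None = None,
    atom_name: str = "CA",
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """Coordinates of the named atom for residues common to two chains.

    Pairing is by residue number + insertion code, ordered by residue
    number; at least 3 common residues are required.
    """
    model_b = model_b if model_b is not None else model_a
    chain_b = chain_b if chain_b is not None else chain_a

    def atom_map(model: StructureModel, cid: str) -> dict[tuple[int, str], Atom]:
        out = {}
        for res in model.chain(cid):
            atom = res.atom(atom_name)
            if atom is not None:
                out[(res.seq, res.icode)] = atom
        return out

    map_a = atom_map(model_a, chain_a)
    map_b = atom_map(model_b, chain_b)
    common = sorted(set(map_a) & set(map_b))
    if len(common) < 3:
        raise ValueError(
            f"chains share only {len(common)} residues with atom {atom_name!r}"
        )
    ca = np.array([map_a[k].xyz for k in common])
    cb = np.array([map_b[k].xyz for k in common])
    return ca, cb, common


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass(frozen=True)
class SasaResult:
    total: float
    per_residue: dict[tuple[str, int, str], float]
    per_atom: dict[int, float]


def sasa(model: StructureModel, subset: set[str] | None = None,
         probe: float = 1.4, points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    ``subset`` selects the chains treated as the molecule (all others are
    ignored entirely). Deterministic golden-spiral point set.
    """
    atoms = model.atoms(subset)
    if not atoms:
        raise ValueError("no atoms selected for surface computation")
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([a.radius + probe for a in atoms])
    sphere = golden_spiral_points(points)
    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom: dict[int, float] = {}
    per_residue: dict[tuple[str, int, str], float] = {}
    atom_res = [
        (res.chain_id, res.seq, res.icode)
        for res in model.residues(subset)
        for _ in res.atoms
    ]
    for i, atom in enumerate(atoms):
        ri = radii[i]
        neighbor_idx = [
            j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i
        ]
        test = coords[i] + ri * sphere
        if neighbor_idx:
            ncoords = coords[neighbor_idx]
            nradii = radii[neighbor_idx]
            d2 = ((test[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nradii**2)[None, :]).any(axis=1)
            accessible_frac = 1.0 - buried.mean()
        else:
            accessible_frac = 1.0
        area = 4.0 * math.pi * ri * ri * accessible_frac
        per_atom[i] = area
        key = atom_res[i]
        per_residue[key] = per_residue.get(key, 0.0) + area
    return SasaResult(
        total=float(sum(per_atom.values())),
        per_residue=per_residue,
        per_atom=per_atom,
    )


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: tuple[str, int, str, str]   # (chain, seq, icode, resname)
    acidic_residue: tuple[str, int, str, str]
    distance: float  # minimum N-O distance, A


@dataclass(frozen=True)
class InterfaceReport:
    bsa_total: float
    bsa_per_group: dict[str, float]
    fraction_of_surface: dict[str, float]
    contact_residues: dict[str, tuple[tuple[str, int, str], ...]]
    salt_bridges: tuple[SaltBridge, ...]
    stacking_pairs: tuple[tuple[tuple[str, int, str, str],
                                tuple[str, int, str, str], float], ...]


def detect_salt_bridges(model: StructureModel, group_a: set[str],
                        group_b: set[str], cutoff: float = 4.0
                        ) -> list[SaltBridge]:
    """Inter-group salt bridges: basic side-chain N (Arg/Lys/His) within
    ``cutoff`` A of an acidic side-chain O (Asp/Glu). One bridge per residue
    pair, at the minimum distance."""

    def collect(chain_ids, table):
        out = []
        for res in model.residues(chain_ids):
            names = table.get(res.name)
            if not names:
                continue
            for nm in names:
                atom = res.atom(nm)
                if atom is not None:
                    out.append((res, atom))
        return out

    bridges: dict[tuple, SaltBridge] = {}
    for basics, acidics in (
        (collect(group_a, BASIC_SIDECHAIN_N), collect(group_b, ACIDIC_SIDECHAIN_O)),
        (collect(group_b, BASIC_SIDECHAIN_N), collect(group_a, ACIDIC_SIDECHAIN_O)),
    ):
        for bres, batom in basics:
            for ares, aatom in acidics:
                dist = math.dist(batom.xyz, aatom.xyz)
                if dist > cutoff:
                    continue
                key = (bres.key, ares.key)
                if key not in bridges or dist < bridges[key].distance:
                    bridges[key] = SaltBridge(
                        basic_residue=(*bres.key, bres.name),
                        acidic_residue=(*ares.key, ares.name),
                        distance=dist,
                    )
    return sorted(bridges.values(), key=lambda b: b.distance)


def detect_arg_stacking(model: StructureModel, group_a: set[str],
                        group_b: set[str], centroid_cutoff: float = 6.0
                        ) -> list[tuple[tuple[str, int, str, str],
                                        tuple[str, int, str, str], float]]:
    """Arg-Arg pairs across the interface whose guanidinium centroids
    (mean of CZ, NH1, NH2, NE) lie within ``centroid_cutoff`` A."""

    def centroids(chain_ids):
        out = []
        for res in model.residues(chain_ids):
            if res.name != "ARG":
                continue
            atoms = [res.atom(nm) for nm in GUANIDINIUM_ATOMS]
            if any(a is None for a in atoms):
                warnings.warn(
                    f"ARG {res.chain_id}{res.seq}: incomplete guanidinium; "
                    "skipped"
                )
                continue
            out.append((res, np.mean([a.xyz for a in atoms], axis=0)))
        return out

    pairs = []
    for res_a, ca in centroids(group_a):
        for res_b, cb in centroids(group_b):
            dist = float(np.linalg.norm(ca - cb))
            if dist <= centroid_cutoff:
                pairs.append(
                    ((*res_a.key, res_a.name), (*res_b.key, res_b.name), dist)
                )
    return sorted(pairs, key=lambda p: p[2])


def buried_interface_area(model: StructureModel, group_a: set[str],
                          group_b: set[str], probe: float = 1.4,
                          points: int = 960,
                          contact_threshold: float = 0.1) -> InterfaceReport:
    """Buried surface area and interface contacts between two chain groups.

    bsa_total = ASA(A alone) + ASA(B alone) - ASA(A u B), i.e. summed over
    both groups. Per-group burial and its fraction of the isolated group
    surface are reported, along with residues losing more than
    ``contact_threshold`` A^2, salt bridges and Arg-Arg stacking pairs.
    """
    if group_a & group_b:
        raise ValueError("chain groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("both chain groups must be non-empty")
    sasa_a = sasa(model, group_a, probe, points)
    sasa_b = sasa(model, group_b, probe, points)
    sasa_ab = sasa(model, group_a | group_b, probe, points)
    bsa_total = sasa_a.total + sasa_b.total - sasa_ab.total

    per_group: dict[str, float] = {}
    fraction: dict[str, float] = {}
    contacts: dict[str, tuple] = {}
    for name, alone in (("A", sasa_a), ("B", sasa_b)):
        in_complex = {
            key: sasa_ab.per_residue.get(key, 0.0) for key in alone.per_residue
        }
        buried = sum(alone.per_residue[k] - in_complex[k]
                     for k in alone.per_residue)
        per_group[name] = buried
        fraction[name] = buried / alone.total if alone.total else 0.0
        contacts[name] = tuple(
            k
            for k in alone.per_residue
            if alone.per_residue[k] - in_complex[k] > contact_threshold
        )
    return InterfaceReport(
        bsa_total=bsa_total,
        bsa_per_group=per_group,
        fraction_of_surface=fraction,
        contact_residues=contacts,
        salt_bridges=tuple(detect_salt_bridges(model, group_a, group_b)),
        stacking_pairs=tuple(detect_arg_stacking(model, group_a, group_b)),
    )


@dataclass(frozen=True)
class DomainMotionResult:
    rmsd_all: float
    mean_displacement: float
    max_displacement: float
    n_align: int
    n_measure: int


def domain_motion(model: StructureModel, chain_a: str, chain_b: str,
                  align_span: tuple[int, int] = C_DOMAIN_SPAN,
                  measure_span: tuple[int, int] = N_DOMAIN_SPAN,
                  atom_name: str = "CA") -> DomainMotionResult:
    """Hinge-motion measurement between two copies of a protomer.

    Chain B is superposed onto chain A using only the ``align_span``
    residues (rice-frame C-terminal domain by default); the whole-chain
    RMSD and the displacement statistics over ``measure_span`` (N-terminal
    domain by default) are then reported under that transform.
    """
    ca, cb, common = pair_chains_by_residue(model, chain_a, model, chain_b,
                                            atom_name)
    lo, hi = align_span
    align_idx = [i for i, (seq, _) in enumerate(common) if lo <= seq <= hi]
    mlo, mhi = measure_span
    measure_idx = [i for i, (seq, _) in enumerate(common) if mlo <= seq <= mhi]
    if len(align_idx) < 3:
        raise ValueError("fewer than 3 alignment atoms in align_span")
    if not measure_idx:
        raise ValueError("no atoms in measure_span")
    sup = kabsch_superpose(cb[align_idx], ca[align_idx])
    cb_t = sup.apply(cb)
    diffs = np.linalg.norm(cb_t - ca, axis=1)
    return DomainMotionResult(
        rmsd_all=float(np.sqrt(np.mean(diffs**2))),
        mean_displacement=float(diffs[measure_idx].mean()),
        max_displacement=float(diffs[measure_idx].max()),
        n_align=len(align_idx),
        n_measure=len(measure_idx),
    )


def inter_region_distance(model: StructureModel,
                          region_a: set[tuple[str, int]],
                          region_b: set[tuple[str, int]],
                          mode: str = "centroid") -> float:
    """Distance between two residue sets: C-alpha centroid distance
    (``mode='centroid'``) or minimum heavy-atom distance (``'min'``)."""
    if not region_a or not region_b:
        raise ValueError("regions must be non-empty")

    def gather(region, ca_only):
        coords = []
        for res in model.residues():
            if (res.chain_id, res.seq) not in region:
                continue
            for atom in res.atoms:
                if ca_only and atom.name != "CA":
                    continue
                coords.append(atom.xyz)
        if not coords:
            raise ValueError("region selects no atoms")
        return np.asarray(coords)

    if mode == "centroid":
        ca = gather(region_a, True).mean(axis=0)
        cb = gather(region_b, True).mean(axis=0)
        return float(np.linalg.norm(ca - cb))
    if mode == "min":
        a = gather(region_a, False)
        b = gather(region_b, False)
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min()))
    raise ValueError(f"unknown mode: {mode!r}")
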