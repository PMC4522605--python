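"""PDB parsing, superposition, surface area, interface detection and hinge
motion, with analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from p5crkit.structure3d import (
    Atom,
    Residue,
    StructureModel,
    buried_interface_area,
    detect_arg_stacking,
    detect_salt_bridges,
    domain_motion,
    golden_spiral_points,
    inter_region_distance,
    kabsch_superpose,
    pair_chains_by_residue,
    read_pdb,
    sasa,
    write_pdb,
)
from p5crkit.synthetic_data import ToyStructureConfig, build_toy_assembly

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C
END
"""

MULTIMODEL_PDB = """\
MODEL         1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL         2
ATOM      1  CA  ALA A   1       5.000   5.000   5.000  1.00  0.00           C
ENDMDL
END
"""


def _single_atom_model(xyz=(0.0, 0.0, 0.0), element="C"):
    atom = Atom(1, "CA", element, "ALA", 1, "", "A", xyz)
    return StructureModel(
        chains={"A": [Residue("ALA", 1, "", "A", (atom,))]}
    )


class TestReadPdb:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_pdb(path)
        atoms = model.atoms()
        assert len(atoms) == 2
        assert atoms[0].xyz == (1.0, 2.0, 3.0)
        assert atoms[1].res_name == "GLY"

    def test_altloc_tie_keeps_a(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_pdb(path)
        atoms = model.atoms()
        assert len(atoms) == 1
        assert atoms[0].altloc == "A" and atoms[0].xyz == (0.0, 0.0, 0.0)

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "nmr.pdb"
        path.write_text(MULTIMODEL_PDB)
        model = read_pdb(path)
        assert model.atoms()[0].xyz == (0.0, 0.0, 0.0)

    def test_malformed_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(MINIMAL_PDB.replace("   4.000", "  4.x000", 1))
        with pytest.raises(ValueError, match="line 2"):
            read_pdb(path)

    def test_no_atoms_is_an_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER  NOTHING\nEND\n")
        with pytest.raises(ValueError, match="no atoms"):
            read_pdb(path)

    def test_agrees_with_gemmi_on_roundtrip(self, tmp_path, toy_assembly):
        gemmi = pytest.importorskip("gemmi")
        path = tmp_path / "toy.pdb"
        write_pdb(toy_assembly, path)
        ours = read_pdb(path)
        theirs = gemmi.read_structure(str(path))
        g_atoms = [
            (a.name, round(a.pos.x, 3), round(a.pos.y, 3), round(a.pos.z, 3))
            for chain in theirs[0] for res in chain for a in res
        ]
        o_atoms = [
            (a.name, round(a.xyz[0], 3), round(a.xyz[1], 3),
             round(a.xyz[2], 3))
            for a in ours.atoms()
        ]
        assert sorted(g_atoms) == sorted(o_atoms)


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_recovers_planted_rotation(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.rotation, rot, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_apply_and_measure_reproduces_rmsd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 3))
        b = a + 0.3 * rng.normal(size=(20, 3))
        res = kabsch_superpose(a, b)
        raw = np.sqrt(np.mean(np.sum((res.apply(a) - b) ** 2, axis=1)))
        assert res.rmsd == pytest.approx(raw, abs=1e-9)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(12, 3))
        b = a + 0.2 * rng.normal(size=(12, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd
        )

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line * 2.0)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestChainPairing:
    def test_identical_chains_fully_paired(self, toy_assembly):
        ca, cb, common = pair_chains_by_residue(toy_assembly, "A",
                                                toy_assembly, "B")
        assert len(common) == 12  # helix residues; side-chain stubs differ
        assert np.allclose(cb - ca, cb[0] - ca[0])

    def test_deletion_pairs_intersection(self, toy_assembly):
        pruned = StructureModel(
            chains={
                "A": toy_assembly.chains["A"],
                "B": [r for r in toy_assembly.chains["B"] if r.seq not in (3, 5)],
            }
        )
        _, _, common = pair_chains_by_residue(pruned, "A", pruned, "B")
        assert [seq for seq, _ in common] == [
            s for s in range(1, 13) if s not in (3, 5)
        ]

    def test_order_independent_of_input_order(self, toy_assembly):
        shuffled = StructureModel(
            chains={
                "A": list(reversed(toy_assembly.chains["A"])),
                "B": toy_assembly.chains["B"],
            }
        )
        _, _, c1 = pair_chains_by_residue(toy_assembly, "A", toy_assembly, "B")
        _, _, c2 = pair_chains_by_residue(shuffled, "A", shuffled, "B")
        assert c1 == c2


class TestSasa:
    def test_single_carbon_analytic_sphere(self):
        total = sasa(_single_atom_model()).total
        assert total == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_far_apart_atoms_are_additive(self):
        a1 = Atom(1, "CA", "C", "ALA", 1, "", "A", (0.0, 0.0, 0.0))
        a2 = Atom(2, "CA", "C", "ALA", 2, "", "A", (50.0, 0.0, 0.0))
        model = StructureModel(chains={"A": [
            Residue("ALA", 1, "", "A", (a1,)),
            Residue("ALA", 2, "", "A", (a2,)),
        ]})
        assert sasa(model).total == pytest.approx(
            2 * 4 * math.pi * 3.1**2, rel=1e-9
        )

    def test_two_overlapping_spheres_match_closed_form(self):
        # Equal spheres radius R at distance d: each loses a cap of height
        # h = R - d/2; exposed area = 2 * (4 pi R^2 - 2 pi R h).
        d = 3.0
        R = 1.7 + 1.4
        a1 = Atom(1, "CA", "C", "ALA", 1, "", "A", (0.0, 0.0, 0.0))
        a2 = Atom(2, "CA", "C", "ALA", 2, "", "A", (d, 0.0, 0.0))
        model = StructureModel(chains={"A": [
            Residue("ALA", 1, "", "A", (a1,)),
            Residue("ALA", 2, "", "A", (a2,)),
        ]})
        expected = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * (R - d / 2))
        assert sasa(model).total == pytest.approx(expected, rel=0.02)

    def test_rotation_translation_invariance(self, toy_assembly):
        base = sasa(toy_assembly).total
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved_chains = {}
        for cid, residues in toy_assembly.chains.items():
            moved = []
            for res in residues:
                atoms = tuple(
                    Atom(a.serial, a.name, a.element, a.res_name, a.res_seq,
                         a.icode, a.chain_id,
                         tuple(rot @ np.array(a.xyz) + np.array([7, -3, 11])))
                    for a in res.atoms
                )
                moved.append(Residue(res.name, res.seq, res.icode,
                                     res.chain_id, atoms))
            moved_chains[cid] = moved
        rotated = sasa(StructureModel(chains=moved_chains)).total
        assert rotated == pytest.approx(base, rel=0.005)

    def test_golden_spiral_points_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-2


class TestInterface:
    def test_separated_groups_bury_nothing(self):
        cfg = ToyStructureConfig(separation=80.0, bridge_distance=None)
        model = build_toy_assembly(cfg)
        rep = buried_interface_area(model, {"A"}, {"B"})
        assert rep.bsa_total == pytest.approx(0.0, abs=1e-6)

    def test_buried_area_converges_with_point_density(self):
        cfg = ToyStructureConfig(separation=7.0, bridge_distance=None)
        model = build_toy_assembly(cfg)
        coarse = buried_interface_area(model, {"A"}, {"B"}, points=960)
        fine = buried_interface_area(model, {"A"}, {"B"}, points=4000)
        assert coarse.bsa_total > 0
        assert coarse.bsa_total == pytest.approx(fine.bsa_total, rel=0.05)

    def test_disjoint_groups_required(self, toy_assembly):
        with pytest.raises(ValueError):
            buried_interface_area(toy_assembly, {"A"}, {"A"})

    def test_fractions_and_per_group_consistent(self, toy_assembly):
        rep = buried_interface_area(toy_assembly, {"A"}, {"B"})
        assert rep.bsa_total == pytest.approx(
            rep.bsa_per_group["A"] + rep.bsa_per_group["B"], rel=1e-6
        )
        assert 0 <= rep.fraction_of_surface["A"] <= 1


class TestSaltBridges:
    def test_planted_bridge_found_at_exact_distance(self, toy_assembly):
        bridges = detect_salt_bridges(toy_assembly, {"A"}, {"B"})
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(2.8)
        assert bridges[0].basic_residue[3] == "ARG"
        assert bridges[0].acidic_residue[3] == "ASP"

    def test_beyond_cutoff_is_empty(self):
        model = build_toy_assembly(ToyStructureConfig(bridge_distance=4.5))
        assert detect_salt_bridges(model, {"A"}, {"B"}) == []

    def test_matches_bruteforce_on_random_placements(self, rng):
        basics, acidics = [], []
        for i in range(12):
            xyz = tuple(rng.uniform(-8, 8, size=3))
            basics.append(Residue("LYS", i + 1, "", "A",
                                  (Atom(i, "NZ", "N", "LYS", i + 1, "", "A",
                                        xyz),)))
        for i in range(12):
            xyz = tuple(rng.uniform(-8, 8, size=3))
            acidics.append(Residue("GLU", i + 1, "", "B",
                                   (Atom(100 + i, "OE1", "O", "GLU", i + 1,
                                         "", "B", xyz),)))
        model = StructureModel(chains={"A": basics, "B": acidics})
        got = {
            (b.basic_residue[1], b.acidic_residue[1]): b.distance
            for b in detect_salt_bridges(model, {"A"}, {"B"})
        }
        expected = {}
        for rb in basics:
            for ra in acidics:
                dist = math.dist(rb.atoms[0].xyz, ra.atoms[0].xyz)
                if dist <= 4.0:
                    expected[(rb.seq, ra.seq)] = dist
        assert got == pytest.approx(expected)


class TestArgStacking:
    def test_planted_pair_within_cutoff(self):
        model = build_toy_assembly(
            ToyStructureConfig(bridge_distance=None, stack_distance=4.0)
        )
        pairs = detect_arg_stacking(model, {"A"}, {"B"})
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(4.0)

    def test_distant_pair_not_reported(self):
        model = build_toy_assembly(
            ToyStructureConfig(bridge_distance=None, stack_distance=8.0)
        )
        assert detect_arg_stacking(model, {"A"}, {"B"}) == []

    def test_incomplete_guanidinium_skipped_with_warning(self, toy_assembly):
        broken = StructureModel(chains={
            "A": [Residue("ARG", 1, "", "A",
                          (Atom(1, "CZ", "C", "ARG", 1, "", "A", (0, 0, 0)),))],
            "B": toy_assembly.chains["B"],
        })
        with pytest.warns(UserWarning, match="guanidinium"):
            assert detect_arg_stacking(broken, {"A"}, {"B"}) == []


class TestDomainMotion:
    def test_identical_chains_report_zero(self):
        model = build_toy_assembly(
            ToyStructureConfig(hinge_angle_deg=0.0, bridge_distance=None)
        )
        res = domain_motion(model, "A", "B", align_span=(7, 12),
                            measure_span=(1, 6))
        assert res.rmsd_all == pytest.approx(0.0, abs=1e-9)
        assert res.mean_displacement == pytest.approx(0.0, abs=1e-9)

    def test_hinge_rotation_matches_analytic_displacement(self):
        from p5crkit.synthetic_data import _helix_ca, hinge_displacement

        angle = 10.0
        model = build_toy_assembly(
            ToyStructureConfig(hinge_angle_deg=angle, bridge_distance=None)
        )
        res = domain_motion(model, "A", "B", align_span=(7, 12),
                            measure_span=(1, 6))
        ca = _helix_ca(12)
        expected = hinge_displacement(ca[:6], angle, ca[6])
        assert res.mean_displacement == pytest.approx(expected, rel=0.05)

    def test_missing_align_span_rejected(self, toy_assembly):
        with pytest.raises(ValueError):
            domain_motion(toy_assembly, "A", "B", align_span=(500, 600),
                          measure_span=(1, 6))


class TestInterRegionDistance:
    def test_coincident_regions(self, toy_assembly):
        region = {("A", 1), ("A", 2)}
        assert inter_region_distance(toy_assembly, region, region) == 0.0

    def test_three_four_five(self):
        a1 = Atom(1, "CA", "C", "ALA", 1, "", "A", (0.0, 0.0, 0.0))
        a2 = Atom(2, "CA", "C", "ALA", 2, "", "A", (3.0, 4.0, 0.0))
        model = StructureModel(chains={"A": [
            Residue("ALA", 1, "", "A", (a1,)),
            Residue("ALA", 2, "", "A", (a2,)),
        ]})
        assert inter_region_distance(model, {("A", 1)}, {("A", 2)}) == 5.0

    def test_centroid_matches_bruteforce(self, toy_assembly, rng):
        seqs = list(range(1, 13))
        ra = {("A", int(s)) for s in rng.choice(seqs, 4, replace=False)}
        rb = {("B", int(s)) for s in rng.choice(seqs, 5, replace=False)}
        got = inter_region_distance(toy_assembly, ra, rb)
        def centroid(region):
            pts = [
                np.array(res.atom("CA").xyz)
                for res in toy_assembly.residues()
                if (res.chain_id, res.seq) in region and res.atom("CA")
            ]
            return np.mean(pts, axis=0)
        assert got == pytest.approx(
            float(np.linalg.norm(centroid(ra) - centroid(rb)))
        )

    def test_empty_region_rejected(self, toy_assembly):
        with pytest.raises(ValueError):
            inter_region_distance(toy_assembly, set(), {("A", 1)})
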