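"""Contact detection: geometry criteria, oracles, invariances."""

import math

import numpy as np
import pytest

from bindscape import interactions as ia
from bindscape.fixtures import ComplexPlantSpec, ContactPlant, synth_complex, write_pdb

_SER = [0]


def atom(name, element, x, y, z, res_name="ALA", res_seq=1, chain="A", b=20.0, occ=1.0):
    _SER[0] += 1
    return ia.Atom(
        serial=_SER[0], name=name, element=element, res_name=res_name, res_seq=res_seq,
        icode="", chain=chain, x=float(x), y=float(y), z=float(z), b_factor=b, occupancy=occ,
    )


def complex_of(protein, ligand):
    return ia.ComplexStructure(
        protein_atoms=protein, ligand_atoms=ligand, ligand_selector=("LIG", "L", 900)
    )


def lig_atom(name, element, x, y, z):
    return atom(name, element, x, y, z, res_name="LIG", res_seq=900, chain="L")


class TestLoadComplex:
    def test_round_trips_coordinates_exactly(self, tmp_path):
        # coordinates representable at PDB precision (3 decimals)
        protein = [atom("CA", "C", 1.5, 2.25, -3.125)]
        ligand = [lig_atom("C1", "C", 4.0, 2.25, -3.125)]
        cx = complex_of(protein, ligand)
        path = tmp_path / "five.pdb"
        write_pdb(cx, path)
        back = ia.load_complex(path, ("LIG", None, None))
        assert [(a.x, a.y, a.z) for a in back.ligand_atoms] == [(4.0, 2.25, -3.125)]
        assert [(a.x, a.y, a.z) for a in back.protein_atoms] == [(1.5, 2.25, -3.125)]

    def test_selector_mismatch_lists_candidates(self, tmp_path, narrated_complex):
        _spec, _cx, pdb_text = narrated_complex
        path = tmp_path / "c.pdb"
        path.write_text(pdb_text)
        with pytest.raises(ValueError, match="candidates"):
            ia.load_complex(path, ("XYZ", None, None))

    def test_water_selector_rejected(self, tmp_path, narrated_complex):
        _spec, _cx, pdb_text = narrated_complex
        path = tmp_path / "c.pdb"
        path.write_text(pdb_text)
        with pytest.raises(ValueError, match="water"):
            ia.load_complex(path, ("HOH", None, None))

    def test_water_bridge_partner_only_with_opt_in(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A  10      -8.000   0.000   0.000  1.00 10.00           C\n"
            "TER\n"
            "HETATM    2  O   HOH A 200       0.000   0.000   0.000  1.00 20.00           O\n"
            "HETATM    3  N1  LIG L 900       3.000   0.000   0.000  1.00 20.00           N\n"
            "HETATM    4  H1  LIG L 900       2.100   0.170   0.000  1.00 20.00           H\n"
            "END\n"
        )
        path = tmp_path / "w.pdb"
        path.write_text(pdb)
        default = ia.load_complex(path, ("LIG", None, None))
        assert ia.detect_hbonds(default) == []
        retained = ia.load_complex(path, ("LIG", None, None), keep_waters=True)
        bridges = ia.detect_hbonds(retained)
        assert [r.residue for r in bridges] == [("HOH", 200, "A")]

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A  10       0.000   0.000   0.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A  10       5.000   0.000   0.000  0.60 12.00           C\n"
            "TER\n"
            "HETATM    3  C1  LIG L 900       9.000   0.000   0.000  1.00 20.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(pdb)
        cx = ia.load_complex(path, ("LIG", None, None))
        assert len(cx.protein_atoms) == 1
        assert cx.protein_atoms[0].x == pytest.approx(5.0)  # occupancy 0.60 wins


class TestHBonds:
    def planted(self, d, theta):
        cx, _ = synth_complex(ComplexPlantSpec(plants=[ContactPlant("hbond", d, theta)]))
        return ia.detect_hbonds(cx)

    def test_near_linear_bond_is_strong(self):
        recs = self.planted(3.14, 165.0)
        assert [r.strength_class for r in recs] == ["strong"]
        assert recs[0].distance == pytest.approx(3.14, abs=1e-9)
        assert recs[0].angle == pytest.approx(165.0, abs=1e-6)

    def test_long_nonlinear_bond_is_weak_only(self):
        recs = self.planted(3.81, 102.05)
        assert [r.strength_class for r in recs] == ["weak"]

    def test_beyond_cutoff_not_detected(self):
        assert self.planted(6.0, 165.0) == []

    @pytest.mark.parametrize(
        "d,theta,expected",
        [
            (3.6 - 1e-3, 165.0, "strong"),
            (3.6 + 1e-3, 165.0, "weak"),
            (4.1 - 1e-3, 165.0, "weak"),
            (4.1 + 1e-3, 165.0, None),
            (3.0, 120.0 + 1e-3, "strong"),
            (3.0, 120.0 - 1e-3, "weak"),
            (3.0, 90.0 - 1e-3, None),
        ],
    )
    def test_envelope_boundaries(self, d, theta, expected):
        recs = self.planted(d, theta)
        if expected is None:
            assert recs == []
        else:
            assert [r.strength_class for r in recs] == [expected]

    def test_no_hydrogens_without_inference_raises(self):
        protein = [atom("O", "O", 0, 0, 0), atom("C", "C", -1.0, -0.7, 0)]
        ligand = [lig_atom("N1", "N", 3.0, 0, 0), lig_atom("C1", "C", 4.4, 0, 0)]
        cx = complex_of(protein, ligand)
        with pytest.raises(ValueError, match="infer"):
            ia.detect_hbonds(cx, infer_missing_h=False)
        # surrogate angle path: antecedent C1-N1...O is linear here
        recs = ia.detect_hbonds(cx, infer_missing_h=True)
        assert len(recs) == 1 and recs[0].angle == pytest.approx(180.0)

    def test_records_sorted_by_distance(self, narrated_complex):
        _spec, cx, _ = narrated_complex
        recs = ia.detect_hbonds(cx)
        assert [r.distance for r in recs] == sorted(r.distance for r in recs)


class TestHalogenBonds:
    def planted(self, d, theta):
        cx, _ = synth_complex(ComplexPlantSpec(plants=[ContactPlant("halogen_bond", d, theta)]))
        return ia.detect_halogen_bonds(cx)

    def test_near_linear_sigma_hole_detected(self):
        recs = self.planted(3.0, 172.68)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.0, abs=1e-9)
        assert recs[0].angle == pytest.approx(172.68, abs=1e-6)

    def test_perpendicular_geometry_rejected(self):
        assert self.planted(3.0, 90.0) == []

    @pytest.mark.parametrize("d,theta,hit", [(3.8 - 1e-3, 170, True), (3.8 + 1e-3, 170, False),
                                             (3.0, 140 + 1e-3, True), (3.0, 140 - 1e-3, False)])
    def test_cutoff_boundaries(self, d, theta, hit):
        assert bool(self.planted(d, theta)) is hit

    def test_fluorine_only_ligand_gives_empty_list(self):
        protein = [atom("O", "O", 0, 0, 0)]
        ligand = [lig_atom("F1", "F", 3.0, 0, 0), lig_atom("C1", "C", 4.4, 0, 0)]
        assert ia.detect_halogen_bonds(complex_of(protein, ligand)) == []


class TestHydrophobic:
    def test_planted_contact_detected(self):
        cx, _ = synth_complex(ComplexPlantSpec(plants=[ContactPlant("hydrophobic", 3.9)]))
        recs = ia.detect_hydrophobic(cx)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.9, abs=1e-9)
        assert recs[0].residue[0] == "LEU"

    def test_beyond_cutoff_rejected(self):
        cx, _ = synth_complex(ComplexPlantSpec(plants=[ContactPlant("hydrophobic", 4.5)]))
        assert ia.detect_hydrophobic(cx) == []

    def test_polarized_carbon_excluded(self):
        # protein carbon covalently bonded to O is not apolar
        protein = [atom("C", "C", 0, 0, 0), atom("O", "O", 1.23, 0, 0)]
        ligand = [lig_atom("C1", "C", -3.5, 0, 0)]
        assert ia.detect_hydrophobic(complex_of(protein, ligand)) == []

    def test_aggregated_to_min_distance_per_residue(self):
        protein = [atom("CD1", "C", 0, 0, 0, res_name="LEU"),
                   atom("CD2", "C", 0, 1.8, 0, res_name="LEU")]
        ligand = [lig_atom("C1", "C", 3.5, 0, 0)]
        recs = ia.detect_hydrophobic(complex_of(protein, ligand))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.5)


class TestBruteForceOracle:
    """The kd-tree search must agree with an all-pairs double loop."""

    def _random_complex(self, rng, n_protein=1200, n_ligand=40):
        elements = ["C", "N", "O"]
        protein = [
            atom(f"X{i}", elements[rng.integers(3)], *rng.uniform(-25, 25, 3),
                 res_name="GLY", res_seq=int(i // 5) + 1)
            for i in range(n_protein)
        ]
        ligand = [
            lig_atom(f"L{i}", elements[rng.integers(3)], *rng.uniform(-6, 6, 3))
            for i in range(n_ligand)
        ]
        return complex_of(protein, ligand)

    def test_hydrophobic_matches_all_pairs_loop(self):
        rng = np.random.default_rng(42)
        cx = self._random_complex(rng)
        got = {(r.ligand_atom.serial, r.residue, round(r.distance, 9))
               for r in ia.detect_hydrophobic(cx, d_max=4.0)}
        lig_c = ia._apolar_carbons(cx.ligand_atoms)
        prot_c = ia._apolar_carbons(cx.protein_atoms)
        best = {}
        for la in lig_c:
            for pa in prot_c:
                d = math.dist((la.x, la.y, la.z), (pa.x, pa.y, pa.z))
                if d <= 4.0:
                    key = (la.serial, (pa.res_name, pa.res_seq, pa.chain))
                    best[key] = min(best.get(key, math.inf), d)
        expected = {(s, res, round(d, 9)) for (s, res), d in best.items()}
        assert got == expected

    def test_halogen_acceptor_pairs_match_loop(self):
        rng = np.random.default_rng(7)
        protein = [atom(f"O{i}", "O", *rng.uniform(-15, 15, 3), res_seq=i + 1)
                   for i in range(300)]
        ligand = []
        for i in range(10):
            center = rng.uniform(-12, 12, 3)
            ligand.append(lig_atom(f"BR{i}", "BR", *center))
            ligand.append(lig_atom(f"C{i}", "C", *(center + np.array([1.9, 0, 0]))))
        cx = complex_of(protein, ligand)
        got = {(r.ligand_atom.serial, r.partner_atom.serial) for r in
               ia.detect_halogen_bonds(cx)}
        expected = set()
        for x in cx.ligand_atoms:
            if x.element != "BR":
                continue
            c = next(a for a in cx.ligand_atoms if a.serial == x.serial + 1)
            for acc in cx.protein_atoms:
                d = math.dist((x.x, x.y, x.z), (acc.x, acc.y, acc.z))
                if d <= 3.8 and d > 0:
                    v1 = np.array([c.x - x.x, c.y - x.y, c.z - x.z])
                    v2 = np.array([acc.x - x.x, acc.y - x.y, acc.z - x.z])
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= 140:
                        expected.add((x.serial, acc.serial))
        assert got == expected


def _rigid_transform(cx, rng):
    theta = rng.uniform(0, 2 * math.pi, 3)
    Rx = np.array([[1, 0, 0], [0, math.cos(theta[0]), -math.sin(theta[0])],
                   [0, math.sin(theta[0]), math.cos(theta[0])]])
    Rz = np.array([[math.cos(theta[2]), -math.sin(theta[2]), 0],
                   [math.sin(theta[2]), math.cos(theta[2]), 0], [0, 0, 1]])
    R = Rz @ Rx
    t = rng.uniform(-50, 50, 3)

    def move(a):
        p = R @ np.array([a.x, a.y, a.z]) + t
        return a._replace(x=p[0], y=p[1], z=p[2])

    return ia.ComplexStructure(
        protein_atoms=[move(a) for a in cx.protein_atoms],
        ligand_atoms=[move(a) for a in cx.ligand_atoms],
        ligand_selector=cx.ligand_selector,
    )


class TestRigidMotionInvariance:
    def test_detection_invariant_under_rotation_translation(self, narrated_complex):
        _spec, cx, _ = narrated_complex
        rng = np.random.default_rng(3)
        moved = _rigid_transform(cx, rng)
        orig = ia.detect_all_contacts(cx)
        after = ia.detect_all_contacts(moved)
        assert len(orig) == len(after)
        for a, b in zip(orig, after):
            assert a.kind == b.kind and a.residue == b.residue
            assert a.distance == pytest.approx(b.distance, abs=1e-6)
            if a.angle is not None:
                assert a.angle == pytest.approx(b.angle, abs=1e-6)


class TestMeasureGeometry:
    def test_unit_separation(self):
        cx = complex_of([atom("CA", "C", 0, 0, 0)], [lig_atom("C1", "C", 1, 0, 0)])
        d, ang = ia.measure_geometry(cx, ("A", 1, "CA"), ("L", 900, "C1"))
        assert d == pytest.approx(1.0)
        assert ang is None

    def test_collinear_triple_is_180(self):
        cx = complex_of(
            [atom("CA", "C", 0, 0, 0), atom("CB", "C", 2, 0, 0)],
            [lig_atom("C1", "C", 1, 0, 0)],
        )
        _d, ang = ia.measure_geometry(cx, ("A", 1, "CA"), ("L", 900, "C1"), ("A", 1, "CB"))
        assert ang == pytest.approx(180.0)

    def test_planted_halogen_geometry_recovered(self, narrated_complex):
        _spec, cx, _ = narrated_complex
        br = next(a for a in cx.ligand_atoms if a.element == "BR")
        carbon = next(a for a in cx.ligand_atoms if a.element == "C")
        acceptor = next(a for a in cx.protein_atoms
                        if a.name == "O" and a.res_name == "VAL")
        d, _ = ia.measure_geometry(cx, br, acceptor)
        _, ang = ia.measure_geometry(cx, carbon, br, acceptor)
        assert d == pytest.approx(3.0, abs=1e-6)
        assert ang == pytest.approx(172.68, abs=1e-4)

    def test_missing_atom_names_reference(self):
        cx = complex_of([atom("CA", "C", 0, 0, 0)], [lig_atom("C1", "C", 1, 0, 0)])
        with pytest.raises(KeyError, match="ZZ"):
            ia.measure_geometry(cx, ("A", 1, "ZZ"), ("L", 900, "C1"))


class TestContactsToFingerprint:
    def _contact(self, res, d=3.0, lig_name="C1"):
        la = lig_atom(lig_name, "C", 0, 0, 0)
        pa = atom("CB", "C", d, 0, 0, res_name=res[:3].upper(), res_seq=int(res[3:]))
        return ia.ContactRecord(
            kind="hydrophobic", ligand_atom=la, partner_atom=pa,
            residue=(res[:3].upper(), int(res[3:]), "A"), distance=d, angle=None,
            strength_class="strong",
        )

    def test_residue_counts(self):
        contacts = [self._contact("VAL66"), self._contact("VAL66"), self._contact("ILE174")]
        fp = ia.contacts_to_fingerprint(contacts, "residue", "count")
        assert fp.entries == {"VAL66": 2.0, "ILE174": 1.0}

    def test_empty_contacts_empty_fingerprint(self):
        assert ia.contacts_to_fingerprint([], "residue", "count").entries == {}

    def test_distance_weight_sums_reciprocals(self):
        contacts = [self._contact("VAL66", d=2.0), self._contact("VAL66", d=2.0)]
        fp = ia.contacts_to_fingerprint(contacts, "residue", "distance_weight")
        assert fp.entries == {"VAL66": pytest.approx(1.0)}

    def test_ligand_atom_perspective(self):
        contacts = [self._contact("VAL66", lig_name="C7"), self._contact("ILE174", lig_name="C7")]
        fp = ia.contacts_to_fingerprint(contacts, "ligand_atom", "count")
        assert fp.entries == {"C7": 2.0}
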