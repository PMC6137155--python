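"""Contact detection: planted geometry, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stdgem.contacts import (
    Contact, ContactCutoffs, ContactKind, catalogue, detect_cation_pi,
    detect_contacts, detect_hbonds, detect_hydrophobic,
    per_proton_contact_counts,
)
from stdgem.structures import Atom, ComplexStructure, LigandTopology
from oracles import oracle_cation_pi, oracle_hbonds, oracle_hydrophobic


def A(name, element, resname, resnum, xyz, ligand=False, chain=None):
    return Atom(name, element, resname, resnum,
                chain or ("L" if ligand else "A"), ligand, np.array(xyz, float))


def hbond_pair(d_NO=2.9, angle_deg=165.0):
    """Ligand N-H donor pointing at a backbone carbonyl O acceptor."""
    n = np.zeros(3)
    h = np.array([1.01, 0.0, 0.0])
    # place O so that the N-H...A angle at H equals angle_deg
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve for the O position at distance d_NO from N along the H-ray
    lo, hi = 0.0, 10.0
    for _ in range(60):
        mid = (lo + hi) / 2
        o = h + mid * direction
        if np.linalg.norm(o - n) < d_NO:
            lo = mid
        else:
            hi = mid
    o = h + lo * direction
    return ComplexStructure([
        A("N1", "N", "LIG", 1, n, ligand=True),
        A("HN1", "H", "LIG", 1, h, ligand=True),
        A("O", "O", "GLY", 12, o),
        A("CA", "C", "GLY", 12, o + [0.0, 2.4, 0.0]),
    ])


class TestHbonds:
    def test_constructed_donor_acceptor_found(self):
        found = detect_hbonds(hbond_pair(2.9, 165.0))
        assert len(found) == 1
        c = found[0]
        assert c.kind is ContactKind.HBOND
        assert c.protein_residue == "Gly12"
        assert c.ligand_atom == "N1"
        assert c.distance_A == pytest.approx(2.9, abs=1e-6)
        assert c.angle_deg == pytest.approx(165.0, abs=0.5)

    def test_beyond_distance_cutoff_rejected(self):
        assert detect_hbonds(hbond_pair(4.2, 165.0)) == []

    def test_poor_angle_rejected(self):
        assert detect_hbonds(hbond_pair(2.9, 90.0)) == []

    def test_donor_without_hydrogens_downgrades_to_distance(self, caplog):
        complex = hbond_pair(2.9, 165.0)
        stripped = ComplexStructure(
            [a for a in complex.atoms if a.element != "H"]
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="stdgem.contacts"):
            found = detect_hbonds(stripped)
        assert len(found) == 1
        assert found[0].angle_deg is None
        assert any("downgraded" in r.message for r in caplog.records)


class TestHydrophobic:
    def test_methyl_pair_within_cutoff(self):
        complex = ComplexStructure([
            A("C1", "C", "LIG", 1, [0, 0, 0], ligand=True),
            A("CD1", "C", "ILE", 7, [4.0, 0, 0]),
        ])
        found = detect_hydrophobic(complex)
        assert [(c.protein_residue, c.ligand_atom) for c in found] == [("Ile7", "C1")]

    def test_polar_carbon_excluded(self):
        """A carbonyl carbon (bonded to O) makes no hydrophobic contact."""
        complex = ComplexStructure([
            A("C1", "C", "LIG", 1, [0, 0, 0], ligand=True),
            A("C", "C", "GLY", 7, [4.0, 0, 0]),
            A("O", "O", "GLY", 7, [4.0, 1.23, 0]),
        ])
        assert detect_hydrophobic(complex) == []

    def test_deduplicated_to_minimal_distance_per_pair(self):
        complex = ComplexStructure([
            A("C1", "C", "LIG", 1, [0, 0, 0], ligand=True),
            A("CD1", "C", "LEU", 7, [4.0, 0, 0]),
            A("CD2", "C", "LEU", 7, [0, 3.8, 0]),
        ])
        found = detect_hydrophobic(complex)
        assert len(found) == 1
        assert found[0].distance_A == pytest.approx(3.8)


def benzene_with_cation(dist, angle_deg):
    """Benzene ring plus a Lys NZ at the given centroid distance/angle."""
    atoms = []
    for i in range(6):
        th = np.radians(60 * i)
        atoms.append(A(f"C{i+1}", "C", "LIG", 1,
                       [1.39 * np.cos(th), 1.39 * np.sin(th), 0], ligand=True))
    t = np.radians(angle_deg)
    pos = dist * np.array([np.sin(t), 0.0, np.cos(t)])
    atoms.append(A("NZ", "N", "LYS", 55, pos))
    topo = LigandTopology(bonds=[], ring_systems=[frozenset(
        f"C{i}" for i in range(1, 7))])
    return ComplexStructure(atoms), topo


class TestCationPi:
    def test_on_axis_cation_found(self):
        complex, topo = benzene_with_cation(4.0, 0.0)
        found = detect_cation_pi(complex, topo)
        assert len(found) == 1
        assert found[0].protein_residue == "Lys55"
        assert found[0].distance_A == pytest.approx(4.0)
        assert set(found[0].ligand_atoms) == {f"C{i}" for i in range(1, 7)}

    def test_beyond_distance_rejected(self):
        complex, topo = benzene_with_cation(7.5, 0.0)
        assert detect_cation_pi(complex, topo) == []

    def test_in_plane_cation_rejected(self):
        complex, topo = benzene_with_cation(4.0, 90.0)
        assert detect_cation_pi(complex, topo) == []

    def test_undersized_ring_rejected(self):
        complex, _ = benzene_with_cation(4.0, 0.0)
        topo = LigandTopology(bonds=[], ring_systems=[frozenset({"C1", "C2"})])
        with pytest.raises(ValueError, match="ring"):
            detect_cation_pi(complex, topo)


class TestOracleEquivalence:
    """Detector output equals exhaustive all-pairs oracles on small toys."""

    def as_pairs(self, contacts):
        return {(c.protein_residue, c.ligand_atom) for c in contacts}

    def test_planted_pocket_matches_oracles(self, toy_complex):
        complex, topo, truth = toy_complex
        assert self.as_pairs(detect_hbonds(complex)) == oracle_hbonds(complex.atoms)
        assert self.as_pairs(detect_hydrophobic(complex)) == oracle_hydrophobic(
            complex.atoms)
        cp = detect_cation_pi(complex, topo)
        assert {(c.protein_residue, c.ligand_atoms) for c in cp} == \
            oracle_cation_pi(complex.atoms, topo.ring_systems)

    def test_planted_contacts_all_recovered(self, toy_complex):
        complex, topo, truth = toy_complex
        found = detect_contacts(complex, topo)
        found_pairs = {(c.kind.value, c.protein_residue) for c in found}
        for kind, residue, _ in truth.contacts:
            assert (kind, residue) in found_pairs

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_small_systems_match_oracles(self, seed):
        """<=50-atom random scatters of mixed atom types."""
        rng = np.random.default_rng(seed)
        atoms = []
        for i in range(12):
            atoms.append(A(f"C{i+1}", "C", "LIG", 1,
                           rng.uniform(-4, 4, 3), ligand=True))
        residues = [("LEU", "CD1", "C"), ("SER", "OG", "O"),
                    ("ASN", "OD1", "O"), ("LYS", "NZ", "N"),
                    ("GLY", "O", "O"), ("ILE", "CG2", "C")]
        for j in range(30):
            resname, name, el = residues[j % len(residues)]
            atoms.append(A(name, el, resname, 10 + j, rng.uniform(-8, 8, 3)))
        complex = ComplexStructure(atoms)
        assert self.as_pairs(detect_hbonds(complex)) == oracle_hbonds(complex.atoms)
        assert self.as_pairs(detect_hydrophobic(complex)) == \
            oracle_hydrophobic(complex.atoms)


class TestInvariances:
    def test_rigid_motion_leaves_contacts_unchanged(self, toy_complex):
        complex, topo, _ = toy_complex
        reference = sorted(
            (c.kind.value, c.protein_residue, c.ligand_atom,
             round(c.distance_A, 9))
            for c in detect_contacts(complex, topo)
        )
        rng = np.random.default_rng(11)
        for _ in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-30, 30, 3)
            moved = complex.transformed(R, t)
            got = sorted(
                (c.kind.value, c.protein_residue, c.ligand_atom,
                 round(c.distance_A, 9))
                for c in detect_contacts(moved, topo)
            )
            assert got == reference

    def test_counts_monotone_in_cutoffs(self, toy_complex):
        complex, topo, _ = toy_complex
        loose = ContactCutoffs()
        tight = ContactCutoffs(
            hbond_distance_A=3.0, hbond_angle_deg=150.0,
            hydrophobic_distance_A=4.0, cation_pi_distance_A=4.0,
            cation_pi_angle_deg=30.0,
        )
        assert len(detect_contacts(complex, topo, tight)) <= \
            len(detect_contacts(complex, topo, loose))


class TestPerProtonProjection:
    def test_direct_bond_projection(self):
        topo = LigandTopology(bonds=[("C7", "H7")])
        contact = Contact(ContactKind.HBOND, "Asn25", "C7", 3.0)
        assert per_proton_contact_counts([contact], topo) == {"H7": 1}

    def test_no_contacts_gives_zeros(self):
        topo = LigandTopology(bonds=[("C1", "H1"), ("C2", "H2")])
        assert per_proton_contact_counts([], topo) == {"H1": 0, "H2": 0}

    def test_one_bond_neighbourhood(self, toy_complex):
        """A ring contact projects onto protons of adjacent ring atoms."""
        complex, topo, _ = toy_complex
        contact = Contact(ContactKind.HYDROPHOBIC, "Ile132", "C4", 4.0)
        counts = per_proton_contact_counts([contact], topo, complex)
        assert counts["H4"] == 1          # on the contacted atom
        assert counts["H3"] == 1          # one bond away
        assert counts["H5"] == 1
        assert counts["H6"] == 0          # two bonds away

    def test_orphan_proton_named_in_error(self):
        topo = LigandTopology(bonds=[("C1", "H1")])
        with pytest.raises(KeyError, match="H9"):
            per_proton_contact_counts([], topo, protons=["H1", "H9"])

    def test_projection_covers_all_planted_contacts(self, toy_complex):
        complex, topo, truth = toy_complex
        found = detect_contacts(complex, topo)
        counts = per_proton_contact_counts(found, topo, complex)
        assert sum(counts.values()) >= len(truth.contacts)


class TestCatalogue:
    def test_residue_rows_sorted_by_number(self):
        contacts = [
            Contact(ContactKind.CATION_PI, "Arg97", "ring(C1)", 4.0),
            Contact(ContactKind.HBOND, "Asn25", "O1", 2.9),
        ]
        table = catalogue(contacts)
        assert list(table["protein_residue"]) == ["Asn25", "Arg97"]
        assert list(table["count"]) == [1, 1]

    def test_duplicates_aggregate(self):
        contacts = [
            Contact(ContactKind.HBOND, "Asn25", "O1", 2.9),
            Contact(ContactKind.HBOND, "Asn25", "N2", 3.1),
        ]
        table = catalogue(contacts)
        assert len(table) == 1
        assert table["count"].iloc[0] == 2

    def test_empty_set_gives_empty_report(self):
        assert catalogue([]).empty
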