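"""Protein-ligand interaction fingerprints.

Detects and catalogues the three contact types used to rationalise
ligand-observed NMR epitopes against docked poses: hydrogen bonds,
hydrophobic (apolar carbon-carbon) contacts, and cation-pi interactions
between Arg/Lys cationic groups and ligand aromatic rings.  Contact
counts can be projected onto ligand protons through a one-bond
neighbourhood so they are directly comparable with per-proton STD
intensities.

Geometric cutoffs follow common structural-biology practice and are all
exposed through :class:`ContactCutoffs`.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from stdgem.structures import Atom, ComplexStructure, LigandTopology

__all__ = [
    "Contact", "ContactKind", "ContactSet", "ContactCutoffs",
    "detect_hbonds", "detect_hydrophobic", "detect_cation_pi",
    "detect_contacts", "per_proton_contact_counts", "catalogue",
    "catalogue_to_frame",
]

logger = logging.getLogger(__name__)

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Side-chain hydrogen-bond donor / acceptor heavy atoms per residue.
# The backbone amide N donates (except Pro) and the carbonyl O accepts
# for every residue type.
SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "ASN": {"ND2"},
    "GLN": {"NE2"}, "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
    "TRP": {"NE1"}, "HIS": {"ND1", "NE2"},
}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

# Cationic side-chain groups for cation-pi detection.
CATION_ATOMS = {"ARG": {"NE", "CZ", "NH1", "NH2"}, "LYS": {"NZ"}}


class ContactKind(enum.Enum):
    HBOND = "HBOND"
    HYDROPHOBIC = "HYDROPHOBIC"
    CATION_PI = "CATION_PI"


@dataclass(frozen=True)
class Contact:
    """One typed protein-ligand contact.

    ``ligand_atom`` is a single display name; ``ligand_atoms`` lists every
    ligand heavy atom the contact touches (the whole ring for a cation-pi
    contact) and is what per-proton projection uses.
    """

    kind: ContactKind
    protein_residue: str
    ligand_atom: str
    distance_A: float
    angle_deg: float | None = None
    ligand_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.distance_A > 0:
            raise ValueError(f"contact distance must be > 0, got {self.distance_A}")
        if not self.ligand_atoms:
            object.__setattr__(self, "ligand_atoms", (self.ligand_atom,))


ContactSet = list


@dataclass(frozen=True)
class ContactCutoffs:
    """Geometric criteria for the three detectors (Angstrom / degrees)."""

    hbond_distance_A: float = 3.5
    hbond_angle_deg: float = 120.0
    hydrophobic_distance_A: float = 4.5
    cation_pi_distance_A: float = 6.0
    cation_pi_angle_deg: float = 45.0


def _angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    u = a - vertex
    v = c - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_acceptor_sets(
    complex: ComplexStructure,
) -> tuple[list[int], list[int], list[int], list[int], dict[int, list[int]]]:
    """Indices of donors/acceptors on each side plus attached hydrogens.

    Standard amino acids use the residue templates; ligand atoms and any
    non-standard protein residue fall back to the element rule (N/O with
    an attached hydrogen donates, every N/O accepts).  In a partition
    modelled without any hydrogens, every N/O is kept as a potential
    donor — the caller then applies the distance-only downgrade.
    """
    atoms = complex.atoms
    h_map = complex.attached_hydrogens(atoms)
    lig_has_h = any(a.element == "H" for a in atoms if a.is_ligand)
    prot_has_h = any(a.element == "H" for a in atoms if not a.is_ligand)

    prot_donors, prot_acceptors, lig_donors, lig_acceptors = [], [], [], []
    for i, a in enumerate(atoms):
        if a.element == "H":
            continue
        if a.is_ligand:
            if a.element in ("N", "O"):
                lig_acceptors.append(i)
                if h_map.get(i) or not lig_has_h:
                    lig_donors.append(i)
            continue
        if a.residue_name in STANDARD_AA:
            if a.atom_name == "N" and a.residue_name != "PRO":
                prot_donors.append(i)
            if a.atom_name in SIDECHAIN_DONORS.get(a.residue_name, ()):
                prot_donors.append(i)
            if a.atom_name in ("O", "OXT"):
                prot_acceptors.append(i)
            if a.atom_name in SIDECHAIN_ACCEPTORS.get(a.residue_name, ()):
                prot_acceptors.append(i)
        elif a.element in ("N", "O"):
            prot_acceptors.append(i)
            if h_map.get(i) or not prot_has_h:
                prot_donors.append(i)
    return prot_donors, prot_acceptors, lig_donors, lig_acceptors, h_map


def detect_hbonds(
    complex: ComplexStructure,
    cutoffs: ContactCutoffs = ContactCutoffs(),
) -> ContactSet:
    """Hydrogen bonds between protein and ligand.

    A donor-acceptor pair qualifies when the heavy-atom D...A distance is
    within the cutoff and, where the donor carries explicit hydrogens, the
    best D-H...A angle (measured at H) meets the angle cutoff.  A donor
    without hydrogens is downgraded to the distance-only criterion with a
    logged notice.  Both protein->ligand and ligand->protein directions
    are scanned; a protein-atom / ligand-atom pair is reported once.
    """
    complex.require_partitions()
    atoms = complex.atoms
    pd_idx, pa_idx, ld_idx, la_idx, h_map = _donor_acceptor_sets(complex)

    found: dict[tuple[int, str], Contact] = {}
    downgraded = False

    def scan(donors: Sequence[int], acceptors: Sequence[int], donor_is_protein: bool):
        nonlocal downgraded
        for d in donors:
            hs = h_map.get(d, [])
            for a in acceptors:
                dist = float(np.linalg.norm(atoms[d].xyz - atoms[a].xyz))
                if dist > cutoffs.hbond_distance_A or dist < 1e-6:
                    continue
                angle: float | None = None
                if hs:
                    angle = max(
                        _angle_deg(atoms[d].xyz, atoms[h].xyz, atoms[a].xyz)
                        for h in hs
                    )
                    if angle < cutoffs.hbond_angle_deg:
                        continue
                else:
                    downgraded = True
                prot_atom = atoms[d] if donor_is_protein else atoms[a]
                lig_atom = atoms[a] if donor_is_protein else atoms[d]
                key = (id(prot_atom), lig_atom.atom_name)
                if key not in found:
                    found[key] = Contact(
                        kind=ContactKind.HBOND,
                        protein_residue=prot_atom.residue_tag,
                        ligand_atom=lig_atom.atom_name,
                        distance_A=dist,
                        angle_deg=angle,
                    )

    scan(pd_idx, la_idx, donor_is_protein=True)
    scan(ld_idx, pa_idx, donor_is_protein=False)
    if downgraded:
        logger.warning(
            "hydrogen-bond detection downgraded to heavy-atom distance for "
            "donors without explicit hydrogens"
        )
    return list(found.values())


def _apolar_carbons(complex: ComplexStructure) -> set[int]:
    """Indices of carbons not covalently bonded to N or O."""
    atoms = complex.atoms
    polar_neighbour: set[int] = set()
    for i, j in complex.bonded_pairs():
        if atoms[i].element == "C" and atoms[j].element in ("N", "O"):
            polar_neighbour.add(i)
        if atoms[j].element == "C" and atoms[i].element in ("N", "O"):
            polar_neighbour.add(j)
    return {
        i for i, a in enumerate(atoms)
        if a.element == "C" and i not in polar_neighbour
    }


def detect_hydrophobic(
    complex: ComplexStructure,
    cutoffs: ContactCutoffs = ContactCutoffs(),
) -> ContactSet:
    """Apolar carbon-carbon contacts within the distance cutoff.

    Apolar means a carbon with no bonded N/O (bonds inferred from
    geometry).  Multiple atom pairs between one residue and one ligand
    atom collapse to a single contact at the minimal distance.
    """
    complex.require_partitions()
    atoms = complex.atoms
    apolar = _apolar_carbons(complex)
    prot = [i for i in apolar if not atoms[i].is_ligand]
    lig = [i for i in apolar if atoms[i].is_ligand]

    best: dict[tuple[str, str], Contact] = {}
    for i in prot:
        for j in lig:
            dist = float(np.linalg.norm(atoms[i].xyz - atoms[j].xyz))
            if dist > cutoffs.hydrophobic_distance_A:
                continue
            key = (atoms[i].residue_tag, atoms[j].atom_name)
            if key not in best or dist < best[key].distance_A:
                best[key] = Contact(
                    kind=ContactKind.HYDROPHOBIC,
                    protein_residue=atoms[i].residue_tag,
                    ligand_atom=atoms[j].atom_name,
                    distance_A=dist,
                )
    return list(best.values())


def _ring_geometry(
    complex: ComplexStructure, ring: frozenset[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a declared aromatic ring."""
    if len(ring) < 3:
        raise ValueError(
            f"aromatic ring needs >= 3 declared atoms, got {sorted(ring)}"
        )
    coords = np.array(
        [a.xyz for a in complex.ligand_atoms() if a.atom_name in ring]
    ).reshape(-1, 3)
    if len(coords) < 3:
        raise ValueError(
            f"ring atoms {sorted(ring)} not all present in the ligand "
            f"(found {len(coords)})"
        )
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def detect_cation_pi(
    complex: ComplexStructure,
    topology: LigandTopology,
    cutoffs: ContactCutoffs = ContactCutoffs(),
) -> ContactSet:
    """Cation-pi contacts between Arg/Lys cations and ligand rings.

    The cationic centre is the centroid of the Arg guanidinium atoms or
    the Lys NZ.  A contact requires the cation within the distance cutoff
    of the ring centroid and within the angular cone about the ring
    normal (the angle between the normal and the centroid->cation vector).
    """
    complex.require_partitions()
    # cation centres grouped by residue
    groups: dict[tuple[str, int, str], list[np.ndarray]] = {}
    tags: dict[tuple[str, int, str], str] = {}
    for a in complex.protein_atoms():
        names = CATION_ATOMS.get(a.residue_name)
        if names and a.atom_name in names:
            key = (a.chain_id, a.residue_number, a.residue_name)
            groups.setdefault(key, []).append(a.xyz)
            tags[key] = a.residue_tag

    contacts = []
    for ring in topology.ring_systems:
        centroid, normal = _ring_geometry(complex, ring)
        ring_atoms = tuple(sorted(ring))
        for key, coords in groups.items():
            cation = np.mean(coords, axis=0)
            vec = cation - centroid
            dist = float(np.linalg.norm(vec))
            if dist > cutoffs.cation_pi_distance_A or dist < 1e-6:
                continue
            cosang = abs(float(np.dot(vec / dist, normal)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            if angle > cutoffs.cation_pi_angle_deg:
                continue
            contacts.append(
                Contact(
                    kind=ContactKind.CATION_PI,
                    protein_residue=tags[key],
                    ligand_atom="ring(" + "-".join(ring_atoms) + ")",
                    distance_A=dist,
                    angle_deg=angle,
                    ligand_atoms=ring_atoms,
                )
            )
    return contacts


def detect_contacts(
    complex: ComplexStructure,
    topology: LigandTopology | None = None,
    cutoffs: ContactCutoffs = ContactCutoffs(),
) -> ContactSet:
    """All three contact types; cation-pi only when a topology is given."""
    contacts = detect_hbonds(complex, cutoffs) + detect_hydrophobic(complex, cutoffs)
    if topology is not None and topology.ring_systems:
        contacts += detect_cation_pi(complex, topology, cutoffs)
    return contacts


def per_proton_contact_counts(
    contacts: ContactSet,
    topology: LigandTopology,
    complex: ComplexStructure | None = None,
    protons: Iterable[str] | None = None,
) -> dict[str, int]:
    """Project contacts onto ligand protons over a one-bond neighbourhood.

    A proton's count is the number of contacts touching its bonded heavy
    atom or any heavy atom one covalent bond away (heavy-atom bonds are
    inferred geometrically from ``complex`` when provided; without
    coordinates only the directly bonded atom counts).  A requested proton
    absent from the topology raises ``KeyError`` naming the orphans.
    """
    labels = list(protons) if protons is not None else topology.proton_labels
    known = set(topology.proton_labels)
    orphans = [l for l in labels if l not in known]
    if orphans:
        raise KeyError(f"protons with no topology entry: {orphans}")

    neighbours: dict[str, set[str]] = {}
    if complex is not None:
        heavies = [a for a in complex.ligand_atoms() if a.element != "H"]
        for i, j in complex.bonded_pairs(heavies):
            neighbours.setdefault(heavies[i].atom_name, set()).add(heavies[j].atom_name)
            neighbours.setdefault(heavies[j].atom_name, set()).add(heavies[i].atom_name)

    counts: dict[str, int] = {}
    for label in labels:
        heavy = topology.heavy_for(label)
        shell = {heavy} | neighbours.get(heavy, set())
        counts[label] = sum(
            1 for c in contacts if shell.intersection(c.ligand_atoms)
        )
    return counts


_RESNUM_RE = re.compile(r"(\d+)$")


def catalogue(contacts: ContactSet) -> pd.DataFrame:
    """Residue-level contact summary, sorted by residue number.

    One row per (residue, contact kind) with its count, residues named in
    the conventional style (``Arg97``).
    """
    rows: dict[tuple[str, str], int] = {}
    for c in contacts:
        key = (c.protein_residue, c.kind.value)
        rows[key] = rows.get(key, 0) + 1
    if not rows:
        return pd.DataFrame(columns=["protein_residue", "kind", "count"])

    def resnum(tag: str) -> int:
        m = _RESNUM_RE.search(tag)
        return int(m.group(1)) if m else 0

    records = [
        {"protein_residue": res, "kind": kind, "count": n}
        for (res, kind), n in rows.items()
    ]
    records.sort(key=lambda r: (resnum(r["protein_residue"]),
                                r["protein_residue"], r["kind"]))
    return pd.DataFrame(records)


# Backwards-friendly alias used by the CLI export path.
catalogue_to_frame = catalogue
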