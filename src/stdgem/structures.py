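"""Coordinate containers and PDB / topology I/O.

A :class:`ComplexStructure` is a flat list of atoms with a ligand/protein
partition, read from or written to PDB format via gemmi.  A
:class:`LigandTopology` maps ligand proton labels to their bonded heavy
atoms and declares aromatic ring systems; it is the plumbing that lets
per-proton NMR quantities be compared with per-atom contact counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = ["Atom", "ComplexStructure", "LigandTopology"]

# Single-bond covalent radii (Angstrom), used for geometric bond inference.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20,
}
_BOND_TOLERANCE = 1.25  # bonded if d <= tol * (r_i + r_j)


@dataclass
class Atom:
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_ligand: bool
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(
                f"atom {self.atom_name!r}: coordinates must be a finite "
                f"3-vector, got {self.xyz!r}"
            )
        self.element = self.element.upper()

    @property
    def residue_tag(self) -> str:
        """Residue label in the conventional style, e.g. ``Arg97``."""
        return f"{self.residue_name.capitalize()}{self.residue_number}"


class ComplexStructure:
    """Atoms of one protein-ligand complex (coordinates in Angstrom)."""

    def __init__(self, atoms: Iterable[Atom]):
        self.atoms: list[Atom] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def ligand_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_ligand]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_ligand]

    def require_partitions(self) -> None:
        if not self.ligand_atoms() or not self.protein_atoms():
            raise ValueError(
                "contact detection needs both a ligand and a protein "
                f"partition (got {len(self.ligand_atoms())} ligand / "
                f"{len(self.protein_atoms())} protein atoms)"
            )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Copy with ``x -> R x + t`` applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = []
        for a in self.atoms:
            out.append(
                Atom(a.atom_name, a.element, a.residue_name, a.residue_number,
                     a.chain_id, a.is_ligand, R @ a.xyz + t)
            )
        return ComplexStructure(out)

    # -- bond inference -----------------------------------------------------

    def bonded_pairs(self, atoms: Sequence[Atom] | None = None) -> list[tuple[int, int]]:
        """Geometrically inferred covalent bonds among ``atoms`` (indices)."""
        atoms = self.atoms if atoms is None else list(atoms)
        xyz = np.array([a.xyz for a in atoms]).reshape(-1, 3)
        radii = np.array(
            [_COVALENT_RADII.get(a.element, 0.77) for a in atoms]
        )
        pairs = []
        for i in range(len(atoms)):
            d = np.linalg.norm(xyz[i + 1:] - xyz[i], axis=1)
            limit = _BOND_TOLERANCE * (radii[i] + radii[i + 1:])
            for off in np.nonzero(d <= limit)[0]:
                pairs.append((i, int(i + 1 + off)))
        return pairs

    def attached_hydrogens(self, atoms: Sequence[Atom]) -> dict[int, list[int]]:
        """Map heavy-atom index -> indices of covalently attached H."""
        atoms = list(atoms)
        out: dict[int, list[int]] = {}
        for i, j in self.bonded_pairs(atoms):
            ei, ej = atoms[i].element, atoms[j].element
            if ei == "H" and ej != "H":
                out.setdefault(j, []).append(i)
            elif ej == "H" and ei != "H":
                out.setdefault(i, []).append(j)
        return out

    # -- PDB I/O ------------------------------------------------------------

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        ligand_resname: str | None = None,
        model_index: int = 0,
    ) -> "ComplexStructure":
        """Read one model of a PDB file.

        The ligand partition is the set of HETATM records (waters excluded),
        or the residues matching ``ligand_resname`` when given.
        """
        st = gemmi.read_pdb(str(path))
        if not len(st):
            raise ValueError(f"{path}: no models")
        model = st[model_index]
        atoms = []
        for chain in model:
            for res in chain:
                if res.name == "HOH":
                    continue
                if ligand_resname is not None:
                    is_lig = res.name == ligand_resname
                else:
                    is_lig = res.het_flag == "H"
                for at in res:
                    atoms.append(
                        Atom(
                            atom_name=at.name,
                            element=at.element.name,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain_id=chain.name,
                            is_ligand=is_lig,
                            xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        )
                    )
        return cls(atoms)

    def to_pdb(self, path: str | Path) -> None:
        st = gemmi.Structure()
        st.name = "stdgem"
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        for a in self.atoms:
            if a.chain_id not in chains:
                chains[a.chain_id] = gemmi.Chain(a.chain_id)
            chain = chains[a.chain_id]
            if (len(chain) == 0
                    or chain[-1].seqid.num != a.residue_number
                    or chain[-1].name != a.residue_name):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.is_ligand else "A"
                chain.add_residue(res)
            res = chain[-1]
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.xyz)
            res.add_atom(at)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


@dataclass
class LigandTopology:
    """Proton-to-heavy-atom bonds and aromatic ring systems of a ligand.

    ``bonds`` maps each proton label to exactly one bonded heavy atom;
    ``ring_systems`` lists sets of heavy-atom names forming aromatic rings
    (used for cation-pi detection and for projecting ring-level contacts
    onto ring protons).
    """

    bonds: list[tuple[str, str]] = field(default_factory=list)  # (heavy, proton)
    ring_systems: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        protons = [p for _, p in self.bonds]
        if len(set(protons)) != len(protons):
            dupes = sorted({p for p in protons if protons.count(p) > 1})
            raise ValueError(
                f"protons mapped to more than one heavy atom: {dupes}"
            )
        self.ring_systems = [frozenset(r) for r in self.ring_systems]

    def heavy_for(self, proton_label: str) -> str:
        for heavy, proton in self.bonds:
            if proton == proton_label:
                return heavy
        raise KeyError(proton_label)

    @property
    def proton_labels(self) -> list[str]:
        return [p for _, p in self.bonds]

    # -- I/O: bonds as CSV, rings as JSON ------------------------------------

    def write(self, bonds_csv: str | Path, rings_json: str | Path | None = None) -> None:
        pd.DataFrame(self.bonds, columns=["heavy_atom", "proton_label"]).to_csv(
            bonds_csv, index=False
        )
        if rings_json is not None:
            Path(rings_json).write_text(
                json.dumps([sorted(r) for r in self.ring_systems], indent=2)
            )

    @classmethod
    def read(
        cls, bonds_csv: str | Path, rings_json: str | Path | None = None
    ) -> "LigandTopology":
        df = pd.read_csv(bonds_csv, comment="#")
        for col in ("heavy_atom", "proton_label"):
            if col not in df.columns:
                raise ValueError(f"{bonds_csv}: missing column {col!r}")
        bonds = [(str(h), str(p)) for h, p in zip(df["heavy_atom"], df["proton_label"])]
        rings: list[frozenset[str]] = []
        if rings_json is not None and Path(rings_json).exists():
            rings = [frozenset(r) for r in json.loads(Path(rings_json).read_text())]
        return cls(bonds=bonds, ring_systems=rings)
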