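"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain loops, direct geometry,
exhaustive enumeration — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.spatial.transform import Rotation

# --- absolute-STD binning: piecewise ranges on the one-decimal value -----


def bin_oracle(value_pct: float) -> str:
    if value_pct > 1.0:
        return ">1"
    if value_pct < 0.2:
        return "<0.2"
    r = math.floor(value_pct * 10 + 0.5) / 10
    if 0.9 <= r <= 1.0:
        return "1.0-0.9"
    if 0.7 <= r <= 0.8:
        return "0.8-0.7"
    if 0.5 <= r <= 0.6:
        return "0.6-0.5"
    return "0.4-0.2"


# --- superposition: dense quaternion grid with local refinement ----------


def grid_rmsd(A: np.ndarray, B: np.ndarray, rng: np.random.Generator) -> float:
    """Minimum RMSD over a dense sampled grid of rotations."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def evaluate(rots: Rotation) -> np.ndarray:
        moved = np.einsum("nij,kj->nki", rots.as_matrix(), Bc)
        return np.sqrt(((Ac[None] - moved) ** 2).sum(axis=(1, 2)) / len(A))

    rots = Rotation.random(8000, rng=rng)
    r = evaluate(rots)
    i = int(np.argmin(r))
    best_r, best_rot = float(r[i]), rots[i]
    for scale in (0.3, 0.1, 0.03, 0.01):
        pert = Rotation.from_rotvec(rng.normal(0, scale, size=(1500, 3))) * best_rot
        r = evaluate(pert)
        i = int(np.argmin(r))
        if r[i] < best_r:
            best_r, best_rot = float(r[i]), pert[i]
    return best_r


# --- k-medoids: exhaustive enumeration over all medoid sets --------------


def exhaustive_kmedoids_cost(M: np.ndarray, k: int) -> float:
    n = len(M)
    return min(
        sum(M[i, min(medoids, key=lambda m: M[i, m])] for i in range(n))
        for medoids in itertools.combinations(range(n), min(k, n))
    )


# --- contact detection: all-pairs loops with their own typing tables -----

_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}

_AA = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"}
_SC_DONOR = {"SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "ASN": ["ND2"],
             "GLN": ["NE2"], "LYS": ["NZ"], "ARG": ["NE", "NH1", "NH2"],
             "TRP": ["NE1"], "HIS": ["ND1", "NE2"]}
_SC_ACCEPTOR = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
                "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
                "HIS": ["ND1", "NE2"]}


def _bonded(a, b) -> bool:
    ra = _RADII.get(a.element, 0.77)
    rb = _RADII.get(b.element, 0.77)
    return float(np.linalg.norm(a.xyz - b.xyz)) <= 1.25 * (ra + rb)


def _hydrogens_of(atoms, heavy):
    return [h for h in atoms
            if h.element == "H" and h.is_ligand == heavy.is_ligand
            and _bonded(heavy, h)]


def _is_donor(atoms, a) -> bool:
    if a.element not in ("N", "O"):
        return False
    if not a.is_ligand and a.residue_name in _AA:
        if a.atom_name == "N" and a.residue_name != "PRO":
            return True
        return a.atom_name in _SC_DONOR.get(a.residue_name, [])
    return bool(_hydrogens_of(atoms, a))


def _is_acceptor(a) -> bool:
    if a.element not in ("N", "O"):
        return False
    if not a.is_ligand and a.residue_name in _AA:
        if a.atom_name in ("O", "OXT"):
            return True
        return a.atom_name in _SC_ACCEPTOR.get(a.residue_name, [])
    return True


def oracle_hbonds(atoms, d_max=3.5, ang_min=120.0) -> set:
    """Set of (protein_residue_tag, ligand_atom) hydrogen-bond pairs."""
    heavies = [a for a in atoms if a.element != "H"]
    out = set()
    for d, acc in itertools.permutations(heavies, 2):
        if d.is_ligand == acc.is_ligand:
            continue
        if not (_is_donor(atoms, d) and _is_acceptor(acc)):
            continue
        dist = float(np.linalg.norm(d.xyz - acc.xyz))
        if dist > d_max or dist < 1e-6:
            continue
        hs = _hydrogens_of(atoms, d)
        if hs:
            ok = False
            for h in hs:
                u = d.xyz - h.xyz
                v = acc.xyz - h.xyz
                ang = math.degrees(math.acos(
                    np.clip(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v),
                            -1, 1)))
                if ang >= ang_min:
                    ok = True
            if not ok:
                continue
        prot, lig = (d, acc) if not d.is_ligand else (acc, d)
        out.add((prot.residue_tag, lig.atom_name))
    return out


def oracle_hydrophobic(atoms, d_max=4.5) -> set:
    """Set of (protein_residue_tag, ligand_atom) apolar C-C pairs."""
    def apolar(c):
        return c.element == "C" and not any(
            o.element in ("N", "O") and _bonded(c, o) for o in atoms if o is not c
        )

    out = set()
    for p in atoms:
        if p.is_ligand or not apolar(p):
            continue
        for l in atoms:
            if not l.is_ligand or not apolar(l):
                continue
            if float(np.linalg.norm(p.xyz - l.xyz)) <= d_max:
                out.add((p.residue_tag, l.atom_name))
    return out


def oracle_cation_pi(atoms, rings, d_max=6.0, ang_max=45.0) -> set:
    """Set of (protein_residue_tag, ring_atoms_tuple) cation-pi pairs.

    The ring normal comes from a cross product of ring-edge vectors — a
    different construction from the SVD plane fit it checks.
    """
    cation_names = {"ARG": {"NE", "CZ", "NH1", "NH2"}, "LYS": {"NZ"}}
    groups = {}
    for a in atoms:
        if a.is_ligand:
            continue
        names = cation_names.get(a.residue_name)
        if names and a.atom_name in names:
            groups.setdefault((a.chain_id, a.residue_number, a.residue_tag),
                              []).append(a.xyz)
    out = set()
    for ring in rings:
        coords = [a.xyz for a in atoms if a.is_ligand and a.atom_name in ring]
        centroid = np.mean(coords, axis=0)
        normal = np.cross(coords[1] - coords[0], coords[2] - coords[0])
        normal = normal / np.linalg.norm(normal)
        for (chain, num, tag), pts in groups.items():
            cat = np.mean(pts, axis=0)
            vec = cat - centroid
            dist = float(np.linalg.norm(vec))
            if dist > d_max or dist < 1e-6:
                continue
            ang = math.degrees(math.acos(
                np.clip(abs(np.dot(vec / dist, normal)), 0, 1)))
            if ang <= ang_max:
                out.add((tag, tuple(sorted(ring))))
    return out
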