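"""Synthetic inputs with planted ground truth.

Generates everything the analysis consumes — toy protein-ligand
complexes with planted hydrogen-bond / hydrophobic / cation-pi geometry,
peak tables produced by a distance-dependent saturation-transfer model,
multi-compound panels containing a known non-binder, and two-state
conformer ensembles — while recording the planted truth separately so
recovery can be scored.  The analysis stages never read the truth.

The experimental conditions emulated are those of a ligand-observed STD
screen run at large ligand excess: defaults of 400 uM ligand against
0.4 uM protein (a 1000:1 ratio, which suppresses rebinding perturbations
of the epitope map) and a 2.94 s saturation train.

The saturation-transfer model makes the qualitative physics quantitative:
the fractional STD effect of a proton is

    f = S * (1 - exp(-t_sat / T)) * sum_over_protein_atoms (r0 / r)^m

with a build-up time constant ``T``, transfer exponent ``m`` (default 6,
an inverse-sixth-power dipolar kernel) and scale ``r0``.  Noise is
multiplicative log-normal so integrals stay positive.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from stdgem.quantify import PeakRecord, write_peak_table
from stdgem.structures import Atom, ComplexStructure, LigandTopology
from stdgem.conformers import ConformerEnsemble

__all__ = [
    "GenerationConfig", "PlantedTruth", "PanelCompound", "Panel",
    "make_complex", "simulate_std", "make_panel", "make_two_state_ensemble",
    "write_panel",
]


@dataclass(frozen=True)
class GenerationConfig:
    """Study conditions for the synthetic generator.

    ``ligand_excess`` must equal ``ligand_conc_uM / protein_conc_uM``;
    the defaults encode the 1000:1 excess (400 uM / 0.4 uM) and the
    2.94 s optimised saturation train of the emulated experiment.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal noise on the fractional STD effect.
    """

    seed: int = 0
    n_compounds: int = 13
    n_protons_per_compound: int = 10
    ligand_excess: float = 1000.0
    ligand_conc_uM: float = 400.0
    protein_conc_uM: float = 0.4
    saturation_time_s: float = 2.94
    noise_cv: float = 0.05
    transfer_exponent: float = 6.0
    transfer_scale_A: float = 4.0
    saturation_efficiency: float = 0.002
    buildup_T_s: float = 1.5

    def __post_init__(self) -> None:
        positive = {
            "ligand_excess": self.ligand_excess,
            "ligand_conc_uM": self.ligand_conc_uM,
            "protein_conc_uM": self.protein_conc_uM,
            "saturation_time_s": self.saturation_time_s,
            "transfer_exponent": self.transfer_exponent,
            "transfer_scale_A": self.transfer_scale_A,
            "saturation_efficiency": self.saturation_efficiency,
            "buildup_T_s": self.buildup_T_s,
            "n_compounds": self.n_compounds,
            "n_protons_per_compound": self.n_protons_per_compound,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv!r}")
        ratio = self.ligand_conc_uM / self.protein_conc_uM
        if abs(ratio - self.ligand_excess) > 1e-9 * max(ratio, self.ligand_excess):
            raise ValueError(
                f"ligand_excess ({self.ligand_excess}) inconsistent with "
                f"concentrations ({self.ligand_conc_uM}/{self.protein_conc_uM}"
                f" = {ratio})"
            )


@dataclass
class PlantedTruth:
    """Ground truth recorded at generation time, never read by analysis."""

    proton_min_distance_A: dict[str, float] = field(default_factory=dict)
    contacts: list[tuple[str, str, str]] = field(default_factory=list)
    binder: bool = True
    state_labels: list[str] | None = None
    ref_coords: dict[str, np.ndarray] | None = None
    rank_permutation: list[int] | None = None

    def to_json_dict(self) -> dict:
        return {
            "proton_min_distance_A": self.proton_min_distance_A,
            "contacts": [list(c) for c in self.contacts],
            "binder": self.binder,
            "state_labels": self.state_labels,
            "rank_permutation": self.rank_permutation,
        }


def _record_min_distances(
    complex: ComplexStructure, topology: LigandTopology
) -> dict[str, float]:
    prot = np.array(
        [a.xyz for a in complex.protein_atoms() if a.element != "H"]
    ).reshape(-1, 3)
    out = {}
    lig = {a.atom_name: a.xyz for a in complex.ligand_atoms()}
    for _, proton in topology.bonds:
        out[proton] = float(np.min(np.linalg.norm(prot - lig[proton], axis=1)))
    return out


# ---------------------------------------------------------------------------
# Toy pocket complex with planted contact geometry


def make_complex(
    config: GenerationConfig,
    seed: int | None = None,
    planted: Sequence[str] = ("HBOND", "HYDROPHOBIC", "CATION_PI"),
    n_filler_residues: int = 10,
    include_ligand: bool = True,
    max_retries: int = 200,
) -> tuple[ComplexStructure, LigandTopology, PlantedTruth]:
    """Toy pocket around a phenol-like ligand with planted contacts.

    The ligand is a benzene ring with five aromatic protons and a
    hydroxyl.  Requested contact kinds are planted with geometry well
    inside the default cutoffs: an Asn carboxamide oxygen accepting the
    hydroxyl (H-bond), an Ile side-chain carbon near an aromatic carbon
    (hydrophobic), and an Arg guanidinium stacked on the ring axis
    (cation-pi).  Filler glycine pseudo-residues complete a 20-80 atom
    pocket shell; placements that would clash are retried and eventually
    rejected with an error.
    """
    if not include_ligand:
        raise ValueError("a complex requires a ligand (zero-ligand request)")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    atoms: list[Atom] = []

    def lig(name, element, xyz):
        atoms.append(Atom(name, element, "LIG", 1, "L", True, np.asarray(xyz, float)))

    # benzene ring, C1 substituted by a hydroxyl
    for i in range(6):
        th = math.radians(60.0 * i)
        lig(f"C{i+1}", "C", [1.39 * math.cos(th), 1.39 * math.sin(th), 0.0])
        if i > 0:
            lig(f"H{i+1}", "H", [2.47 * math.cos(th), 2.47 * math.sin(th), 0.0])
    lig("O1", "O", [2.75, 0.0, 0.0])
    lig("HO1", "H", [3.72, 0.0, 0.0])

    topology = LigandTopology(
        bonds=[(f"C{i}", f"H{i}") for i in range(2, 7)] + [("O1", "HO1")],
        ring_systems=[frozenset(f"C{i}" for i in range(1, 7))],
    )

    truth = PlantedTruth()

    def prot(name, element, resname, resnum, xyz):
        atoms.append(
            Atom(name, element, resname, resnum, "A", False, np.asarray(xyz, float))
        )

    if "HBOND" in planted:
        # Asn OD1 accepting the ligand hydroxyl: O1...OD1 = 2.9 A, linear
        prot("OD1", "O", "ASN", 25, [5.65, 0.0, 0.0])
        prot("CG", "C", "ASN", 25, [6.40, 0.95, 0.0])
        prot("ND2", "N", "ASN", 25, [7.55, 0.70, 0.0])
        truth.contacts.append(("HBOND", "Asn25", "O1"))
    if "HYDROPHOBIC" in planted:
        # Ile CD1 4.0 A from ring carbon C4
        prot("CD1", "C", "ILE", 132, [-5.39, 0.0, 0.0])
        prot("CG1", "C", "ILE", 132, [-6.90, 0.0, 0.0])
        truth.contacts.append(("HYDROPHOBIC", "Ile132", "C4"))
    if "CATION_PI" in planted:
        # Arg guanidinium centroid 4.2 A above the ring centroid, on axis
        prot("CZ", "C", "ARG", 97, [0.0, 0.0, 4.2])
        for k, name in enumerate(("NE", "NH1", "NH2")):
            th = math.radians(120.0 * k + 30.0)
            prot(name, "N", "ARG", 97,
                 [1.33 * math.cos(th), 1.33 * math.sin(th), 4.2])
        truth.contacts.append(("CATION_PI", "Arg97", "ring"))

    # filler shell of glycine pseudo-residues at 8-14 A from the origin
    local = np.array(
        [[0.0, 0.0, 0.0], [1.46, 0.0, 0.0], [-0.53, 1.43, 0.0], [-0.60, 2.40, 0.9]]
    )  # CA, N, C, O local geometry (approximate)
    names = ["CA", "N", "C", "O"]
    elements = ["C", "N", "C", "O"]
    resnum = 200
    for _ in range(n_filler_residues):
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise RuntimeError(
                    "could not place a filler residue without clashes "
                    f"after {max_retries} retries"
                )
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            centre = direction * rng.uniform(8.0, 14.0)
            R = Rotation.random(rng=rng).as_matrix()
            coords = centre + local @ R.T
            existing = np.array([a.xyz for a in atoms])
            dmin = np.min(
                np.linalg.norm(existing[:, None, :] - coords[None, :, :], axis=2)
            )
            if dmin >= 2.4:
                break
        for nm, el, xyz in zip(names, elements, coords):
            prot(nm, el, "GLY", resnum, xyz)
        resnum += 1

    complex = ComplexStructure(atoms)
    n_prot_heavy = sum(
        1 for a in complex.protein_atoms() if a.element != "H"
    )
    if not 20 <= n_prot_heavy <= 80:
        raise ValueError(
            f"pocket size {n_prot_heavy} heavy atoms outside the 20-80 "
            "target; adjust n_filler_residues"
        )
    truth.proton_min_distance_A = _record_min_distances(complex, topology)
    return complex, topology, truth


# ---------------------------------------------------------------------------
# Saturation-transfer simulation


def simulate_std(
    complex: ComplexStructure,
    topology: LigandTopology,
    config: GenerationConfig,
    compound_id: str = "cpd01",
    rng: np.random.Generator | None = None,
    null_transfer: bool = False,
) -> list[PeakRecord]:
    """Peak table from the distance-dependent saturation-transfer model.

    Each proton's fractional STD effect is the saturation build-up factor
    times the sum of ``(r0/r)^m`` over protein heavy atoms, clipped to
    [0, 0.99], then multiplied by log-normal noise of CV ``noise_cv``.
    ``Isat = I0 * (1 - f)`` with ``I0`` drawn positive.  With
    ``null_transfer`` the transfer is zeroed before noise — the
    non-binder condition, where on- and off-resonance integrals match.
    """
    if not topology.bonds:
        raise ValueError("topology declares no protons")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    prot = np.array(
        [a.xyz for a in complex.protein_atoms() if a.element != "H"]
    ).reshape(-1, 3)
    lig = {a.atom_name: a.xyz for a in complex.ligand_atoms()}

    buildup = 1.0 - math.exp(-config.saturation_time_s / config.buildup_T_s)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))

    records = []
    for i, (heavy, proton) in enumerate(topology.bonds):
        if proton not in lig:
            raise KeyError(f"proton atom {proton!r} missing from the complex")
        r = np.linalg.norm(prot - lig[proton], axis=1)
        f = (
            config.saturation_efficiency
            * buildup
            * float(np.sum((config.transfer_scale_A / r) ** config.transfer_exponent))
        )
        f = min(max(f, 0.0), 0.99)
        if null_transfer:
            f = 0.0
        if config.noise_cv > 0:
            f = min(f * rng.lognormal(-0.5 * sigma ** 2, sigma), 0.99)
        I0 = float(rng.uniform(80.0, 120.0))
        records.append(
            PeakRecord(
                compound_id=compound_id,
                proton_label=proton,
                shift_ppm=round(7.8 - 0.15 * i, 3),
                I0=I0,
                Isat=I0 * (1.0 - f),
                saturation_time_s=config.saturation_time_s,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Multi-compound panel with one planted non-binder


@dataclass
class PanelCompound:
    compound_id: str
    records: list[PeakRecord]
    poses: dict[str, ComplexStructure]
    topology: LigandTopology
    truth: PlantedTruth


@dataclass
class Panel:
    compounds: list[PanelCompound]
    consistent_state: str = "closed"

    def __iter__(self):
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)


#: Ladder-pose geometry: chain spacing, slab box and exclusion (Angstrom)
_CHAIN_STEP = 1.5
_SLAB_TOP_Y = -3.0
_SLAB_DEPTH = 3.8
_SLAB_HALF_Z = 2.0
_SLAB_MIN_SEP = 1.5
_HEIGHT_SPAN = 2.2


def _ladder_pose(
    heights: np.ndarray,
    rng: np.random.Generator,
    displace_ligand: bool = False,
    max_retries: int = 400,
) -> tuple[ComplexStructure, LigandTopology]:
    """Chain ligand lying over a slab of apolar side-chain carbons.

    Chain carbon ``j`` sits at height ``heights[j]`` above the slab top,
    so its distance to the protein — and with it both the simulated STD
    of its proton and its hydrophobic contact count — grades with the
    height profile.  ``displace_ligand`` moves the ligand 25 A away: the
    external-surface, no-contact pose of a non-binder.
    """
    n_protons = len(heights)
    atoms: list[Atom] = []
    shift = np.array([0.0, 25.0, 0.0]) if displace_ligand else np.zeros(3)
    for j in range(n_protons):
        c = np.array([_CHAIN_STEP * j, float(heights[j]), 0.0])
        atoms.append(Atom(f"C{j+1}", "C", "LIG", 1, "L", True, c + shift))
        atoms.append(Atom(f"H{j+1}", "H", "LIG", 1, "L", True,
                          c + shift + np.array([0.0, 0.0, 1.09])))

    topology = LigandTopology(
        bonds=[(f"C{j+1}", f"H{j+1}") for j in range(n_protons)]
    )

    # random slab of single-atom LEU CD1 pseudo-residues below the chain
    n_slab = 4 * n_protons
    x_lo, x_hi = -1.5, _CHAIN_STEP * n_protons + 0.5
    placed: list[np.ndarray] = []
    for _ in range(n_slab):
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise RuntimeError(
                    "could not place a slab atom without clashes"
                )
            pos = np.array([
                rng.uniform(x_lo, x_hi),
                rng.uniform(_SLAB_TOP_Y - _SLAB_DEPTH, _SLAB_TOP_Y),
                rng.uniform(-_SLAB_HALF_Z, _SLAB_HALF_Z),
            ])
            if placed and np.min(
                np.linalg.norm(np.array(placed) - pos, axis=1)
            ) < _SLAB_MIN_SEP:
                continue
            placed.append(pos)
            break
    for i, pos in enumerate(placed):
        atoms.append(Atom("CD1", "C", "LEU", 10 + i, "A", False, pos))

    return ComplexStructure(atoms), topology


def _epitope_heights(n: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth per-proton height profile: one chain end buried, one exposed.

    A monotone ramp (random direction) with small jitter keeps
    neighbouring protons at similar depths, as in a real pose where one
    ligand end inserts into the pocket.
    """
    base = np.linspace(0.0, _HEIGHT_SPAN, n)
    if rng.random() < 0.5:
        base = base[::-1]
    return np.clip(base + rng.uniform(-0.1, 0.1, size=n), 0.0, None)


def make_panel(
    config: GenerationConfig,
    states: Sequence[str] = ("closed", "open"),
    consistent_state: str = "closed",
) -> Panel:
    """Multi-compound panel with one planted non-binder (the last).

    Every binder gets one pose per requested state: the consistent state's
    pose is the geometry the STD table was simulated from, while the other
    states' poses shuffle the per-proton burial depths — in-silico
    contacts that do not match the NMR epitope.  The non-binder has zero
    transfer before noise and an external-surface pose in every state.
    """
    if config.n_compounds < 2:
        raise ValueError("a panel needs at least 2 compounds (one non-binder)")
    if consistent_state not in states:
        raise ValueError(f"consistent_state {consistent_state!r} not in {states}")
    rng = np.random.default_rng(config.seed)
    n = config.n_protons_per_compound

    compounds = []
    for c in range(config.n_compounds):
        compound_id = f"cpd{c+1:02d}"
        is_binder = c < config.n_compounds - 1
        heights = _epitope_heights(n, rng)
        poses = {}
        for s in states:
            h = heights if s == consistent_state else rng.permutation(heights)
            pose, topology = _ladder_pose(
                h, rng, displace_ligand=not is_binder,
            )
            poses[s] = pose
        records = simulate_std(
            poses[consistent_state], topology, config,
            compound_id=compound_id, rng=rng,
            null_transfer=not is_binder,
        )
        truth = PlantedTruth(
            proton_min_distance_A=_record_min_distances(
                poses[consistent_state], topology
            ),
            binder=is_binder,
            rank_permutation=[int(x) for x in np.argsort(np.argsort(heights))],
        )
        compounds.append(
            PanelCompound(compound_id, records, poses, topology, truth)
        )
    return Panel(compounds=compounds, consistent_state=consistent_state)


def write_panel(panel: Panel, out_dir: str | Path) -> None:
    """Write a panel in the CSV/PDB dialects the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_records = [r for c in panel for r in c.records]
    write_peak_table(all_records, out / "peaks.csv")
    (out / "panel.json").write_text(json.dumps({
        "compound_ids": [c.compound_id for c in panel],
        "states": sorted(panel.compounds[0].poses),
        "consistent_state": panel.consistent_state,
    }, indent=2))
    for c in panel:
        cdir = out / c.compound_id
        cdir.mkdir(exist_ok=True)
        for state, pose in c.poses.items():
            pose.to_pdb(cdir / f"pose_{state}.pdb")
        c.topology.write(cdir / "topology.csv", cdir / "rings.json")
        (cdir / "truth.json").write_text(
            json.dumps(c.truth.to_json_dict(), indent=2)
        )


# ---------------------------------------------------------------------------
# Two-state conformer ensembles


def make_two_state_ensemble(
    config: GenerationConfig,
    n_frames: int = 40,
    n_atoms: int = 30,
    separation_A: float = 5.0,
    noise_sigma_A: float = 0.2,
    n_states: int = 2,
) -> tuple[ConformerEnsemble, PlantedTruth]:
    """Frames scattered around two reference conformations.

    The references are built so their superposed RMSD equals
    ``separation_A``; frames alternate between the states, add isotropic
    Gaussian noise of ``noise_sigma_A``, and receive a random rigid
    motion so that superposition is non-trivial.  A separation-to-noise
    ratio below 3 triggers a warning because label recovery is then not
    guaranteed.  ``n_states=1`` collapses the request to a single-state
    ensemble (pure noise around one reference).
    """
    from stdgem.conformers import superpose  # local to avoid cycle at import

    if n_states not in (1, 2):
        raise ValueError(f"n_states must be 1 or 2, got {n_states}")
    if n_states == 2 and noise_sigma_A > 0 and separation_A / noise_sigma_A < 3:
        warnings.warn(
            f"separation/noise ratio {separation_A / noise_sigma_A:.2f} < 3: "
            "cluster recovery of the planted states is not guaranteed",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    ref_open = rng.normal(0.0, 4.0, size=(n_atoms, 3))
    direction = rng.normal(size=(n_atoms, 3))
    s = 1.0
    for _ in range(8):
        _, _, r = superpose(ref_open, ref_open + s * direction)
        if r <= 0:
            break
        s *= separation_A / r
    ref_closed = ref_open + s * direction

    refs = {"OPEN": ref_open, "CLOSED": ref_closed}
    if n_states == 1:
        labels = ["OPEN"] * n_frames
    else:
        labels = ["OPEN" if i % 2 == 0 else "CLOSED" for i in range(n_frames)]
    frames = []
    for lab in labels:
        coords = refs[lab] + rng.normal(0.0, noise_sigma_A, size=(n_atoms, 3))
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-10.0, 10.0, size=3)
        frames.append(coords @ R.T + t)
    ensemble = ConformerEnsemble(frames=np.array(frames))
    truth = PlantedTruth(
        binder=True,
        state_labels=labels,
        ref_coords={k: v.copy() for k, v in refs.items()},
    )
    return ensemble, truth
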