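"""End-to-end orchestration: simulate -> quantify -> contacts -> cluster -> concord.

Each stage reads its inputs from and writes its outputs to the run
directory, records its status in a machine-readable manifest
(``manifest.json``) together with the fully resolved configuration, the
seed, and the package version.  Because stages communicate only through
files, a partial run can be resumed stage by stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

import pandas as pd

import stdgem
from stdgem.concordance import (
    PoseLocation, classify_agreement, classify_pose_location, panel_summary,
    proton_concordance, select_state,
)
from stdgem.conformers import ConformerEnsemble, cluster_frames, rmsd_matrix
from stdgem.contacts import (
    ContactCutoffs, catalogue, detect_contacts, per_proton_contact_counts,
)
from stdgem.quantify import (
    bin_counts_to_csv, count_by_bin, profile_from_json, profile_to_json,
    profiles_to_frame, quantify_peaks, read_peak_table,
    DEFAULT_NOISE_FLOOR_PCT,
)
from stdgem.structures import ComplexStructure, LigandTopology
from stdgem.synthetic import (
    GenerationConfig, make_panel, make_two_state_ensemble, write_panel,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "quantify", "contacts", "cluster", "concord"]


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run.

    Values merge, in increasing precedence: built-in defaults, a YAML
    config file, command-line flags.  The resolved config is serialised
    into the run manifest for provenance.
    """

    out_dir: str = "stdgem_run"
    seed: int = 0
    n_compounds: int = 13
    n_protons: int = 10
    noise_cv: float = 0.05
    noise_floor_pct: float = DEFAULT_NOISE_FLOOR_PCT
    saturation_time_s: float = 2.94
    ligand_conc_uM: float = 400.0
    protein_conc_uM: float = 0.4
    transfer_exponent: float = 6.0
    transfer_scale_A: float = 4.0
    hbond_distance_A: float = 3.5
    hbond_angle_deg: float = 120.0
    hydrophobic_distance_A: float = 4.5
    cation_pi_distance_A: float = 6.0
    cation_pi_angle_deg: float = 45.0
    burial_radius_A: float = 8.0
    burial_threshold: float = 0.15
    k_clusters: int = 10
    n_frames: int = 40
    state_separation_A: float = 5.0
    frame_noise_A: float = 0.2

    @classmethod
    def from_sources(cls, config_file: str | Path | None = None,
                     **overrides: Any) -> "RunConfig":
        import yaml

        values: dict[str, Any] = {}
        if config_file is not None:
            loaded = yaml.safe_load(Path(config_file).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{config_file}: expected a YAML mapping")
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = sorted(set(loaded) - known)
            if unknown:
                raise ValueError(f"{config_file}: unknown keys {unknown}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def generation_config(self) -> GenerationConfig:
        return GenerationConfig(
            seed=self.seed,
            n_compounds=self.n_compounds,
            n_protons_per_compound=self.n_protons,
            ligand_conc_uM=self.ligand_conc_uM,
            protein_conc_uM=self.protein_conc_uM,
            ligand_excess=self.ligand_conc_uM / self.protein_conc_uM,
            saturation_time_s=self.saturation_time_s,
            noise_cv=self.noise_cv,
            transfer_exponent=self.transfer_exponent,
            transfer_scale_A=self.transfer_scale_A,
        )

    def cutoffs(self) -> ContactCutoffs:
        return ContactCutoffs(
            hbond_distance_A=self.hbond_distance_A,
            hbond_angle_deg=self.hbond_angle_deg,
            hydrophobic_distance_A=self.hydrophobic_distance_A,
            cation_pi_distance_A=self.cation_pi_distance_A,
            cation_pi_angle_deg=self.cation_pi_angle_deg,
        )

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed after its inputs were validated."""


def _write_manifest(out: Path, config: RunConfig, stages: dict[str, str]) -> None:
    manifest = {
        "package": "stdgem",
        "version": stdgem.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.as_dict(),
        "stages": [{"name": s, "status": stages.get(s, "pending")}
                   for s in STAGES],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _panel_meta(out: Path) -> dict:
    return json.loads((out / "panel" / "panel.json").read_text())


def _stage_simulate(config: RunConfig, out: Path) -> None:
    gen = config.generation_config()
    panel = make_panel(gen)
    write_panel(panel, out / "panel")
    ensemble, _ = make_two_state_ensemble(
        gen, n_frames=config.n_frames,
        separation_A=config.state_separation_A,
        noise_sigma_A=config.frame_noise_A,
    )
    ensemble.to_pdb(out / "panel" / "ensemble.pdb")


def _stage_quantify(config: RunConfig, out: Path) -> None:
    records = read_peak_table(out / "panel" / "peaks.csv")
    by_compound: dict[str, list] = {}
    for r in records:
        by_compound.setdefault(r.compound_id, []).append(r)
    profiles = {
        cid: quantify_peaks(recs, noise_floor_pct=config.noise_floor_pct)
        for cid, recs in sorted(by_compound.items())
    }
    profiles_to_frame(profiles.values()).to_csv(out / "profiles.csv", index=False)
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for cid, prof in profiles.items():
        profile_to_json(prof, prof_dir / f"{cid}.json")
    bin_counts_to_csv(count_by_bin(profiles.values()), out / "bin_summary.csv")


def _stage_contacts(config: RunConfig, out: Path) -> None:
    meta = _panel_meta(out)
    cutoffs = config.cutoffs()
    contact_dir = out / "contacts"
    contact_dir.mkdir(exist_ok=True)
    locations: dict[str, str] = {}
    for cid in meta["compound_ids"]:
        cdir = out / "panel" / cid
        topology = LigandTopology.read(cdir / "topology.csv", cdir / "rings.json")
        for state in meta["states"]:
            pose = ComplexStructure.from_pdb(cdir / f"pose_{state}.pdb")
            contacts = detect_contacts(pose, topology, cutoffs)
            catalogue(contacts).to_csv(
                contact_dir / f"{cid}_{state}_catalogue.csv", index=False)
            counts = per_proton_contact_counts(contacts, topology, pose)
            pd.Series(counts, name="contact_count").rename_axis(
                "proton_label"
            ).to_csv(contact_dir / f"{cid}_{state}_counts.csv")
            if state == meta["consistent_state"]:
                locations[cid] = classify_pose_location(
                    pose, radius_A=config.burial_radius_A,
                    burial_threshold=config.burial_threshold,
                ).value
    (contact_dir / "pose_locations.json").write_text(
        json.dumps(locations, indent=2))


def _stage_cluster(config: RunConfig, out: Path) -> None:
    ensemble = ConformerEnsemble.from_pdb(out / "panel" / "ensemble.pdb")
    M = rmsd_matrix(ensemble)
    result = cluster_frames(M, k=config.k_clusters, seed=config.seed)
    cdir = out / "clusters"
    cdir.mkdir(exist_ok=True)
    result.to_frame(ensemble.frame_ids).to_csv(
        cdir / "cluster_report.csv", index=False)
    ensemble.to_pdb(cdir / "representatives.pdb", result.medoid_indices)


def _stage_concord(config: RunConfig, out: Path) -> None:
    meta = _panel_meta(out)
    consistent = meta["consistent_state"]
    locations = json.loads(
        (out / "contacts" / "pose_locations.json").read_text())
    ncdir = out / "concordance"
    ncdir.mkdir(exist_ok=True)
    rhos_per_state: dict[str, list] = {}
    reports = []
    for state in meta["states"]:
        for cid in meta["compound_ids"]:
            profile = profile_from_json(out / "profiles" / f"{cid}.json")
            table = pd.read_csv(out / "contacts" / f"{cid}_{state}_counts.csv")
            counts = dict(zip(table["proton_label"].astype(str),
                              table["contact_count"].astype(int)))
            report = proton_concordance(profile, counts)
            if state == consistent:
                report.classification_agreement = classify_agreement(
                    profile.binder, PoseLocation(locations[cid]))
                report.to_json(ncdir / f"{cid}.json")
                reports.append(report)
            if profile.binder:
                rhos_per_state.setdefault(state, []).append(report.spearman_rho)
    panel_summary(reports).to_csv(ncdir / "panel_summary.csv", index=False)
    winner, means, margin = select_state(rhos_per_state)
    (ncdir / "state_selection.json").write_text(json.dumps({
        "selected_state": winner,
        "mean_rho_per_state": means,
        "margin": margin,
    }, indent=2))


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], None]] = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "contacts": _stage_contacts,
    "cluster": _stage_cluster,
    "concord": _stage_concord,
}


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Run every stage on a synthetic panel; returns the run directory.

    With ``resume`` stages already marked completed in an existing
    manifest are skipped, so an interrupted run continues where it
    stopped.  Outputs per stage::

        panel/                  peak tables, poses, topologies (simulate)
        profiles.csv, profiles/ per-proton STD + per-compound JSON (quantify)
        bin_summary.csv         interacting-proton counts per range
        contacts/               contact catalogues + per-proton counts
        clusters/               RMSD cluster report + representatives
        concordance/            per-compound reports + state selection
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        stages = {s["name"]: s["status"] for s in previous.get("stages", [])
                  if s["status"] == "completed"}
    _write_manifest(out, config, stages)

    for name in STAGES:
        if stages.get(name) == "completed":
            logger.info("stage %s: already completed, skipped", name)
            continue
        logger.info("stage %s", name)
        try:
            _STAGE_FUNCS[name](config, out)
        except (FileNotFoundError, ValueError, KeyError):
            raise
        except Exception as exc:  # runtime failure inside a stage
            raise StageError(f"stage {name} failed: {exc}") from exc
        stages[name] = "completed"
        _write_manifest(out, config, stages)

    logger.info("run complete: %s", out)
    return out
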