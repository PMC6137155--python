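"""Concordance between NMR epitopes and in-silico contact maps.

For each compound the absolute STD percentage of every proton is compared
with the number of protein contacts its neighbourhood makes in a docked
pose; the agreement is summarised by a Spearman rank correlation (the two
quantities live on incommensurate scales, so only their orderings are
compared).  Panel-level summaries feed a protein-state selection: the
conformational state whose poses best reproduce the measured epitopes.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stdgem.quantify import STDProfile
from stdgem.structures import ComplexStructure

__all__ = [
    "PoseLocation", "Agreement", "ConcordanceReport",
    "proton_concordance", "classify_agreement", "classify_pose_location",
    "select_state",
]


class PoseLocation(enum.Enum):
    POCKET_INTERIOR = "POCKET_INTERIOR"
    EXTERNAL_SURFACE = "EXTERNAL_SURFACE"


class Agreement(enum.Enum):
    AGREE_BINDER = "AGREE_BINDER"
    AGREE_NONBINDER = "AGREE_NONBINDER"
    DISAGREE = "DISAGREE"


@dataclass
class ConcordanceReport:
    """Per-compound comparison of STD intensities with contact counts."""

    compound_id: str
    n_protons: int
    spearman_rho: float | None
    table: pd.DataFrame  # proton_label, absolute_std_pct, contact_count
    missing_from_counts: list[str] = field(default_factory=list)
    missing_from_profile: list[str] = field(default_factory=list)
    degenerate: bool = False  # rho undefined because a variable is constant
    classification_agreement: Agreement | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "compound_id": self.compound_id,
            "n_protons": self.n_protons,
            "spearman_rho": self.spearman_rho,
            "degenerate": self.degenerate,
            "missing_from_counts": self.missing_from_counts,
            "missing_from_profile": self.missing_from_profile,
            "classification_agreement": (
                self.classification_agreement.value
                if self.classification_agreement else None
            ),
            "per_proton": self.table.to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def proton_concordance(
    profile: STDProfile, counts: Mapping[str, int]
) -> ConcordanceReport:
    """Spearman rank correlation of absolute STD % vs contact counts.

    Only protons present on both sides enter the correlation (average
    ranks for ties); protons missing from either side are listed, never
    imputed.  Fewer than three shared protons, or a constant variable,
    leaves rho undefined while the per-proton table is still reported.
    """
    std_map = profile.absolute_map()
    shared = [p for p in std_map if p in counts]
    table = pd.DataFrame(
        {
            "proton_label": shared,
            "absolute_std_pct": [std_map[p] for p in shared],
            "contact_count": [int(counts[p]) for p in shared],
        }
    )
    report = ConcordanceReport(
        compound_id=profile.compound_id,
        n_protons=len(shared),
        spearman_rho=None,
        table=table,
        missing_from_counts=sorted(p for p in std_map if p not in counts),
        missing_from_profile=sorted(p for p in counts if p not in std_map),
    )
    if len(shared) < 3:
        return report
    x = table["absolute_std_pct"].to_numpy()
    y = table["contact_count"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        report.degenerate = True
        return report
    rho = stats.spearmanr(x, y).statistic
    report.spearman_rho = float(rho)
    return report


def classify_pose_location(
    complex: ComplexStructure,
    radius_A: float = 8.0,
    burial_threshold: float = 0.15,
) -> PoseLocation:
    """Interior vs external pose call by ligand-centroid burial.

    The burial fraction is the share of protein atoms lying within
    ``radius_A`` of the ligand centroid; a pose is interior when that
    fraction exceeds ``burial_threshold``.
    """
    complex.require_partitions()
    centroid = np.mean([a.xyz for a in complex.ligand_atoms()], axis=0)
    prot = np.array([a.xyz for a in complex.protein_atoms()])
    frac = float(np.mean(np.linalg.norm(prot - centroid, axis=1) <= radius_A))
    return (
        PoseLocation.POCKET_INTERIOR
        if frac > burial_threshold
        else PoseLocation.EXTERNAL_SURFACE
    )


def classify_agreement(binder: bool, pose_location: PoseLocation) -> Agreement:
    """Cross-tabulate the NMR binder call with the pose location."""
    interior = pose_location is PoseLocation.POCKET_INTERIOR
    if binder and interior:
        return Agreement.AGREE_BINDER
    if not binder and not interior:
        return Agreement.AGREE_NONBINDER
    return Agreement.DISAGREE


def select_state(
    panel: Mapping[str, Iterable[float | None]],
) -> tuple[str, dict[str, float], float]:
    """Pick the protein state whose poses best match the STD epitopes.

    ``panel`` maps a state id to the per-compound Spearman rho values of
    that state's poses (undefined rhos may be passed as None and are
    ignored).  Returns the state with the highest mean rho, the mean rho
    of every state, and the winning margin.  Exact ties break to the
    lexicographically first state id with a warning.
    """
    means: dict[str, float] = {}
    for state, rhos in panel.items():
        vals = [r for r in rhos if r is not None and np.isfinite(r)]
        if vals:
            means[state] = float(np.mean(vals))
    if not means:
        raise ValueError("no defined Spearman rho for any state")

    best_mean = max(means.values())
    tied = sorted(s for s, m in means.items() if m == best_mean)
    if len(tied) > 1:
        warnings.warn(
            f"states {tied} tie at mean rho {best_mean:.4f}; "
            f"choosing {tied[0]!r} by id order",
            stacklevel=2,
        )
    winner = tied[0]
    others = [m for s, m in means.items() if s != winner]
    margin = best_mean - max(others) if others else 0.0
    return winner, means, margin


def panel_summary(
    reports: Sequence[ConcordanceReport],
) -> pd.DataFrame:
    """Panel-level table: one row per compound with rho and agreement."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in reports],
            "n_protons": [r.n_protons for r in reports],
            "spearman_rho": [r.spearman_rho for r in reports],
            "agreement": [
                r.classification_agreement.value
                if r.classification_agreement else ""
                for r in reports
            ],
        }
    )
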