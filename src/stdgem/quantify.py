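"""Quantification of saturation-transfer difference (STD) NMR effects.

Turns raw on/off-resonance peak integrals into per-proton absolute and
relative STD percentages, assigns group-epitope colour classes, bins
absolute intensities into the standard reporting ranges, and makes a
binder / non-binder call per compound.

The fractional STD effect of one proton is ``(I0 - Isat) / I0`` where
``I0`` is the peak integral in the off-resonance (reference) spectrum and
``Isat`` the integral in the on-resonance spectrum.  Absolute STD % is 100x
that fraction; relative STD % normalises a compound's absolute values so
the most intense signal is exactly 100%.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PeakRecord", "ProtonSTD", "STDProfile", "EpitopeClass", "AbsBin",
    "fractional_std", "quantify_peaks", "relative_std", "classify_epitope",
    "bin_absolute", "detect_binding", "count_by_bin",
    "read_peak_table", "write_peak_table",
    "profiles_to_frame", "profile_to_json", "bin_counts_to_csv",
    "DEFAULT_NOISE_FLOOR_PCT",
]

#: Default detection limit for absolute STD, in percent.  Protons at or
#: below this are treated as noise; a compound is a binder only if at least
#: one proton exceeds it.
DEFAULT_NOISE_FLOOR_PCT = 0.05

PEAK_TABLE_COLUMNS = [
    "compound_id", "proton_label", "shift_ppm", "I0", "Isat",
    "saturation_time_s",
]


class EpitopeClass(enum.Enum):
    """Colour-coded relative-STD classes of a group epitope map.

    ``MAX`` marks the most intense signal (black dot, 100% relative STD);
    ``DARK_RED`` is relative STD over 80%, ``ORANGE`` over 40%, ``LIME``
    under 40%.  ``BELOW_FLOOR`` marks protons whose absolute STD does not
    exceed the noise floor.
    """

    MAX = "MAX"
    DARK_RED = "DARK_RED"
    ORANGE = "ORANGE"
    LIME = "LIME"
    BELOW_FLOOR = "BELOW_FLOOR"


class AbsBin(enum.Enum):
    """Absolute-STD reporting ranges (percent, one-decimal convention)."""

    GT_1 = ">1"
    R10_09 = "1.0-0.9"
    R08_07 = "0.8-0.7"
    R06_05 = "0.6-0.5"
    R04_02 = "0.4-0.2"
    LT_02 = "<0.2"


@dataclass(frozen=True)
class PeakRecord:
    """One integrated resonance of one compound-protein STD experiment.

    Parameters
    ----------
    compound_id
        Identifier of the compound the proton belongs to.
    proton_label
        Resonance label, e.g. ``"H6"`` or ``"2''"``; unique per compound.
    shift_ppm
        Chemical shift of the resonance in ppm.
    I0, Isat
        Peak integrals in the off-resonance (reference) and on-resonance
        spectra, arbitrary but common units.  ``I0`` must be positive.
    saturation_time_s
        Length of the selective saturation train in seconds.
    """

    compound_id: str
    proton_label: str
    shift_ppm: float
    I0: float
    Isat: float
    saturation_time_s: float

    def __post_init__(self) -> None:
        if not self.I0 > 0:
            raise ValueError(
                f"I0 must be positive, got {self.I0!r} for proton "
                f"{self.proton_label!r} of {self.compound_id!r}"
            )
        if not self.saturation_time_s > 0:
            raise ValueError(
                f"saturation_time_s must be positive, got "
                f"{self.saturation_time_s!r}"
            )


@dataclass
class ProtonSTD:
    """Quantified STD effect of one proton."""

    proton_label: str
    shift_ppm: float
    fractional_std: float
    absolute_std_pct: float
    relative_std_pct: float | None = None
    epitope_class: EpitopeClass | None = None
    abs_bin: AbsBin | None = None
    artefact: bool = False


@dataclass
class STDProfile:
    """Per-proton STD quantification for one compound.

    ``binder`` is True when at least one proton's absolute STD exceeds the
    noise floor.  Relative percentages and epitope classes are populated
    only for binders; for a non-binder they are left unset, mirroring the
    "no signal shown" reporting convention.
    """

    compound_id: str
    protons: list[ProtonSTD] = field(default_factory=list)
    binder: bool = False
    noise_floor_pct: float = DEFAULT_NOISE_FLOOR_PCT

    def __iter__(self):
        return iter(self.protons)

    def __len__(self) -> int:
        return len(self.protons)

    def proton(self, label: str) -> ProtonSTD:
        for p in self.protons:
            if p.proton_label == label:
                return p
        raise KeyError(label)

    def absolute_map(self) -> dict[str, float]:
        return {p.proton_label: p.absolute_std_pct for p in self.protons}


def fractional_std(I0: float, Isat: float) -> float:
    """Fractional STD effect ``(I0 - Isat) / I0`` of one resonance.

    Raises ``ValueError`` for non-positive ``I0``.  ``Isat > I0`` gives a
    negative fraction, which is returned unchanged with a warning — such
    values indicate phasing or subtraction artefacts and must stay visible
    rather than being clipped to zero.
    """
    if not I0 > 0:
        raise ValueError(f"I0 must be positive, got {I0!r}")
    f = (I0 - Isat) / I0
    if f < 0:
        warnings.warn(
            f"Isat ({Isat}) exceeds I0 ({I0}): negative STD effect kept "
            "and flagged as artefact",
            stacklevel=2,
        )
    return f


def relative_std(profile: STDProfile) -> STDProfile:
    """Fill in relative STD percentages by normalising to the maximum.

    The proton with the largest absolute STD is assigned exactly 100; all
    others get ``100 * absolute / max``.  If no proton has positive
    absolute STD the compound shows no signal and relative values are left
    unset (the profile is returned unchanged).
    """
    if not profile.protons:
        return profile
    best = max(profile.protons, key=lambda p: p.absolute_std_pct)
    if best.absolute_std_pct <= 0:
        return profile
    for p in profile.protons:
        if p is best:
            p.relative_std_pct = 100.0
        else:
            # ratio first: guarantees the result never exceeds 100 by an ulp
            p.relative_std_pct = 100.0 * (
                p.absolute_std_pct / best.absolute_std_pct
            )
    return profile


def classify_epitope(relative_std_pct: float, is_max: bool) -> EpitopeClass:
    """Colour class for one proton's relative STD percentage.

    The most intense signal is ``MAX`` regardless of value; otherwise
    strictly over 80 is ``DARK_RED``, strictly over 40 is ``ORANGE``, the
    rest ``LIME`` (so exactly 80 -> ORANGE and exactly 40 -> LIME).
    """
    if is_max:
        return EpitopeClass.MAX
    if not 0.0 <= relative_std_pct <= 100.0:
        raise ValueError(
            f"relative STD % out of [0, 100]: {relative_std_pct!r}"
        )
    if relative_std_pct > 80.0:
        return EpitopeClass.DARK_RED
    if relative_std_pct > 40.0:
        return EpitopeClass.ORANGE
    return EpitopeClass.LIME


def _round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (0.85 -> 0.9), platform-stable."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def bin_absolute(absolute_std_pct: float) -> AbsBin:
    """Assign an absolute STD % to its one-decimal reporting range.

    The two open-ended ranges compare the raw value (strictly above 1
    percent, strictly below 0.2 percent); the interior ranges (1.0-0.9,
    0.8-0.7, 0.6-0.5, 0.4-0.2) leave gaps in their printed bounds, closed
    by rounding the value to one decimal (half away from zero) before
    assignment.  Negative artefact values land in ``LT_02``.
    """
    if not math.isfinite(absolute_std_pct):
        raise ValueError(f"absolute STD % must be finite, got {absolute_std_pct!r}")
    if absolute_std_pct > 1.0:
        return AbsBin.GT_1
    if absolute_std_pct < 0.2:
        return AbsBin.LT_02
    r = _round_half_away(absolute_std_pct, 1)
    if r >= 0.9:
        return AbsBin.R10_09
    if r >= 0.7:
        return AbsBin.R08_07
    if r >= 0.5:
        return AbsBin.R06_05
    return AbsBin.R04_02


def detect_binding(profile: STDProfile, noise_floor_pct: float | None = None) -> bool:
    """Binder call: at least one proton strictly above the noise floor."""
    floor = profile.noise_floor_pct if noise_floor_pct is None else noise_floor_pct
    if floor < 0:
        raise ValueError(f"noise floor must be >= 0, got {floor!r}")
    return any(p.absolute_std_pct > floor for p in profile.protons)


def quantify_peaks(
    records: Iterable[PeakRecord],
    noise_floor_pct: float = DEFAULT_NOISE_FLOOR_PCT,
) -> STDProfile:
    """Full quantification of one compound's peak table.

    Computes fractional and absolute STD per proton, makes the binder
    call, and — for binders — relative percentages, epitope colour classes
    and absolute-range bins.  Protons of a binder that do not exceed the
    noise floor are classed ``BELOW_FLOOR``; a non-binder's protons get no
    class or relative value at all.
    """
    records = list(records)
    if not records:
        raise ValueError("empty peak table")
    compound_ids = {r.compound_id for r in records}
    if len(compound_ids) != 1:
        raise ValueError(
            f"peak table mixes compounds: {sorted(compound_ids)}"
        )
    labels = [r.proton_label for r in records]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate proton labels: {dupes}")

    profile = STDProfile(
        compound_id=records[0].compound_id,
        noise_floor_pct=noise_floor_pct,
    )
    for r in records:
        f = fractional_std(r.I0, r.Isat)
        profile.protons.append(
            ProtonSTD(
                proton_label=r.proton_label,
                shift_ppm=r.shift_ppm,
                fractional_std=f,
                absolute_std_pct=100.0 * f,
                abs_bin=bin_absolute(100.0 * f),
                artefact=f < 0,
            )
        )
    profile.binder = detect_binding(profile)
    if profile.binder:
        relative_std(profile)
        best = max(profile.protons, key=lambda p: p.absolute_std_pct)
        for p in profile.protons:
            if p.absolute_std_pct <= noise_floor_pct:
                p.epitope_class = EpitopeClass.BELOW_FLOOR
            else:
                p.epitope_class = classify_epitope(
                    p.relative_std_pct, is_max=p is best
                )
    return profile


def count_by_bin(profiles: Iterable[STDProfile]) -> pd.DataFrame:
    """Per-compound counts of interacting protons in each absolute range.

    Only protons strictly above each profile's noise floor are counted, so
    a row sum equals the number of interacting protons of that compound
    and a non-binder contributes an all-zero row.
    """
    profiles = list(profiles)
    cols = [b.value for b in AbsBin]
    if not profiles:
        return pd.DataFrame(columns=cols, dtype=int)
    rows = {}
    for prof in profiles:
        counts = dict.fromkeys(cols, 0)
        for p in prof.protons:
            if p.absolute_std_pct > prof.noise_floor_pct:
                counts[p.abs_bin.value] += 1
        rows[prof.compound_id] = counts
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = "compound_id"
    return out.astype(int)


# ---------------------------------------------------------------------------
# External interfaces: peak-table CSV, profile CSV/JSON, bin-count CSV


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a peak-table CSV (header required, '#' comment lines allowed)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                PeakRecord(
                    compound_id=str(row["compound_id"]),
                    proton_label=str(row["proton_label"]),
                    shift_ppm=float(row["shift_ppm"]),
                    I0=float(row["I0"]),
                    Isat=float(row["Isat"]),
                    saturation_time_s=float(row["saturation_time_s"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad record at data row {i}: {exc}") from exc
    return records


def write_peak_table(records: Sequence[PeakRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "proton_label": r.proton_label,
                "shift_ppm": r.shift_ppm,
                "I0": r.I0,
                "Isat": r.Isat,
                "saturation_time_s": r.saturation_time_s,
            }
            for r in records
        ],
        columns=PEAK_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False)


def profiles_to_frame(profiles: Iterable[STDProfile]) -> pd.DataFrame:
    """One row per proton across profiles, suitable for CSV export."""
    rows = []
    for prof in profiles:
        for p in prof.protons:
            rows.append(
                {
                    "compound_id": prof.compound_id,
                    "proton_label": p.proton_label,
                    "shift_ppm": p.shift_ppm,
                    "fractional_std": p.fractional_std,
                    "absolute_std_pct": p.absolute_std_pct,
                    "relative_std_pct": p.relative_std_pct,
                    "epitope_class": p.epitope_class.value if p.epitope_class else "",
                    "abs_bin": p.abs_bin.value if p.abs_bin else "",
                    "artefact": p.artefact,
                    "binder": prof.binder,
                }
            )
    return pd.DataFrame(rows)


def profile_to_json(profile: STDProfile, path: str | Path | None = None) -> str:
    """Serialise one compound's profile as a JSON document."""
    doc = {
        "compound_id": profile.compound_id,
        "binder": profile.binder,
        "noise_floor_pct": profile.noise_floor_pct,
        "protons": [
            {
                "proton_label": p.proton_label,
                "shift_ppm": p.shift_ppm,
                "fractional_std": p.fractional_std,
                "absolute_std_pct": p.absolute_std_pct,
                "relative_std_pct": p.relative_std_pct,
                "epitope_class": p.epitope_class.value if p.epitope_class else None,
                "abs_bin": p.abs_bin.value if p.abs_bin else None,
                "artefact": p.artefact,
            }
            for p in profile.protons
        ],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def profile_from_json(path: str | Path) -> STDProfile:
    doc = json.loads(Path(path).read_text())
    prof = STDProfile(
        compound_id=doc["compound_id"],
        binder=doc["binder"],
        noise_floor_pct=doc["noise_floor_pct"],
    )
    for p in doc["protons"]:
        prof.protons.append(
            ProtonSTD(
                proton_label=p["proton_label"],
                shift_ppm=p["shift_ppm"],
                fractional_std=p["fractional_std"],
                absolute_std_pct=p["absolute_std_pct"],
                relative_std_pct=p["relative_std_pct"],
                epitope_class=(
                    EpitopeClass(p["epitope_class"]) if p["epitope_class"] else None
                ),
                abs_bin=AbsBin(p["abs_bin"]) if p["abs_bin"] else None,
                artefact=p["artefact"],
            )
        )
    return prof


def bin_counts_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)
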