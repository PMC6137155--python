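"""Superposition, RMSD matrices, k-medoids clustering and state labels.

The clustering workflow mirrors the standard treatment of an MD
trajectory: every pair of frames is superposed independently by the
optimal least-squares rigid transform (Kabsch), the resulting RMSD matrix
is clustered with PAM-style k-medoids so that cluster representatives are
actual frames, and individual structures are labelled "open" or "closed"
by their superposed RMSD to two reference conformations.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ConformerEnsemble", "ClusterResult", "StateLabel",
    "superpose", "rmsd_matrix", "cluster_frames", "assign_state",
]


class StateLabel(enum.Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"
    UNASSIGNED = "UNASSIGNED"


@dataclass
class ConformerEnsemble:
    """Ordered frames with a shared atom ordering (coordinates in A)."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if not self.frame_ids:
            self.frame_ids = [f"frame{i:04d}" for i in range(len(self.frames))]
        if len(self.frame_ids) != len(self.frames):
            raise ValueError("frame_ids length does not match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_pdb(cls, path: str | Path) -> "ConformerEnsemble":
        """Read a multi-model PDB (MODEL/ENDMDL) as an ensemble."""
        st = gemmi.read_pdb(str(path))
        frames, ids = [], []
        for model in st:
            coords = [
                [at.pos.x, at.pos.y, at.pos.z]
                for chain in model for res in chain for at in res
            ]
            frames.append(coords)
            ids.append(f"model{model.num}")
        if not frames:
            raise ValueError(f"{path}: no models found")
        counts = {len(f) for f in frames}
        if len(counts) != 1:
            raise ValueError(f"{path}: models differ in atom count: {sorted(counts)}")
        return cls(frames=np.array(frames, dtype=float), frame_ids=ids)

    def to_pdb(self, path: str | Path, frame_indices: Sequence[int] | None = None) -> None:
        """Write frames as a multi-model PDB of pseudo-atoms."""
        idx = range(len(self)) if frame_indices is None else frame_indices
        lines = []
        for mi, fi in enumerate(idx, start=1):
            lines.append(f"MODEL     {mi:4d}")
            for ai, (x, y, z) in enumerate(self.frames[fi], start=1):
                lines.append(
                    f"ATOM  {ai:5d}  CA  GLY A{ai:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            lines.append("ENDMDL")
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ClusterResult:
    """k-medoids partition of an ensemble."""

    labels: np.ndarray            # frame index -> cluster index
    medoid_indices: list[int]     # one frame index per cluster
    representatives: list[str]    # frame_ids of the medoids
    within_cluster_cost: float    # sum of frame-to-medoid RMSDs (A)

    def to_frame(self, frame_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_id": list(frame_ids),
                "cluster": self.labels,
                "representative_flag": [
                    i in self.medoid_indices for i in range(len(self.labels))
                ],
            }
        )


def superpose(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``B`` onto ``A`` (Kabsch).

    Returns ``(R, t, rmsd)`` where the proper rotation ``R`` (det = +1)
    and translation ``t`` minimise the RMSD between ``A`` and
    ``B @ R.T + t``.

    Requires matching atom counts (>= 3) and non-degenerate geometry:
    collinear point sets leave the rotation about the axis undetermined
    and are rejected.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError(f"atom-count mismatch: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError(f"need (n >= 3, 3) coordinate arrays, got {A.shape}")

    ca, cb = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - ca, B - cb
    for name, X in (("A", Ac), ("B", Bc)):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise ValueError(
                f"degenerate geometry in {name}: points are collinear "
                "(rotation about the axis is undetermined)"
            )

    H = Bc.T @ Ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = Ac - Bc @ R.T
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def rmsd_matrix(ensemble: ConformerEnsemble) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs.

    Each pair is fitted independently, so the result is not guaranteed to
    satisfy the triangle inequality; violations are reported as warnings
    only.
    """
    n = len(ensemble)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(ensemble.frames[i], ensemble.frames[j])
            M[i, j] = M[j, i] = r
    # triangle-inequality audit (vectorised over the third index)
    viol = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(M[i, j] > M[i] + M[j] + 1e-9):
                viol += 1
    if viol:
        warnings.warn(
            f"RMSD matrix violates the triangle inequality for {viol} pairs "
            "(expected: independently superposed RMSD is not a metric)",
            stacklevel=2,
        )
    return M


def _assign(M: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = M[:, medoids]                 # (n, k)
    nearest = np.argmin(sub, axis=1)    # ties -> lowest medoid position
    cost = float(sub[np.arange(len(M)), nearest].sum())
    return nearest, cost


def _swap_to_convergence(
    M: np.ndarray, medoids: list[int]
) -> tuple[list[int], float]:
    """Best-improvement SWAP passes until no single swap lowers the cost."""
    n = len(M)
    medoids = sorted(medoids)
    _, cost = _assign(M, medoids)
    while True:
        best = (cost, None, None)
        for mi in range(len(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                _, c = _assign(M, trial)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is None:
            return medoids, cost
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
        cost = best[0]


def cluster_frames(
    matrix: np.ndarray, k: int, seed: int | None = None, n_restarts: int = 10
) -> ClusterResult:
    """PAM-style k-medoids on a precomputed RMSD matrix.

    A greedy BUILD initialisation plus ``n_restarts`` seeded random
    initialisations are each refined with best-improvement SWAP passes;
    the lowest-cost solution wins.  The result is deterministic given
    ``seed`` (ties break to the lowest frame index).  ``k`` larger than
    the number of frames is reduced with a warning.
    """
    M = np.asarray(matrix, float)
    n = len(M)
    if M.shape != (n, n):
        raise ValueError(f"matrix must be square, got {M.shape}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        warnings.warn(f"k={k} exceeds n_frames={n}; using k={n}", stacklevel=2)
        k = n

    # BUILD: greedily add the medoid that lowers total cost the most
    medoids: list[int] = []
    for _ in range(k):
        best_c, best_m = np.inf, -1
        for m in range(n):
            if m in medoids:
                continue
            _, c = _assign(M, sorted(medoids + [m]))
            if c < best_c - 1e-12:
                best_c, best_m = c, m
        medoids.append(best_m)

    best_medoids, best_cost = _swap_to_convergence(M, medoids)

    rng = np.random.default_rng(0 if seed is None else seed)
    for _ in range(n_restarts):
        init = list(rng.choice(n, size=k, replace=False))
        meds, cost = _swap_to_convergence(M, init)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and meds < best_medoids
        ):
            best_medoids, best_cost = meds, cost

    labels, cost = _assign(M, best_medoids)
    frame_ids = [f"frame{i:04d}" for i in range(n)]
    return ClusterResult(
        labels=labels,
        medoid_indices=best_medoids,
        representatives=[frame_ids[m] for m in best_medoids],
        within_cluster_cost=cost,
    )


def assign_state(
    structure: np.ndarray,
    open_ref: np.ndarray,
    closed_ref: np.ndarray,
    tie_tolerance_A: float = 1e-6,
) -> tuple[StateLabel, float]:
    """Label a structure by its nearer reference conformation.

    Returns the state of the reference with the smaller superposed RMSD
    and the margin ``|rmsd_open - rmsd_closed|``; a margin within the tie
    tolerance yields ``UNASSIGNED``.
    """
    _, _, r_open = superpose(open_ref, structure)
    _, _, r_closed = superpose(closed_ref, structure)
    margin = abs(r_open - r_closed)
    if margin <= tie_tolerance_A:
        return StateLabel.UNASSIGNED, margin
    return (StateLabel.OPEN if r_open < r_closed else StateLabel.CLOSED), margin
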