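"""Pairwise-RMSD trajectory clustering (GROMOS neighbor-counting method)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observables import AnchorError, kabsch
from .structure_io import StructureModel, Trajectory, select

__all__ = ["RMSDMatrix", "Clustering", "rmsd_matrix", "gromos_cluster",
           "best_cluster_frame", "MAX_FRAMES"]

MAX_FRAMES = 20_000  # dense-matrix cap; stride longer trajectories


@dataclass
class RMSDMatrix:
    values: np.ndarray          # symmetric (n, n), nm
    selection: object = None

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if np.any(v < 0):
            raise ValueError("RMSD values must be nonnegative")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RMSD matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    clusters: list[tuple[int, list[int]]]   # (center index, member indices)
    cutoff: float

    def __post_init__(self):
        members = [i for _, ms in self.clusters for i in ms]
        if len(members) != len(set(members)):
            raise ValueError("clusters overlap")

    @property
    def n_frames(self) -> int:
        return sum(len(ms) for _, ms in self.clusters)

    def labels(self) -> np.ndarray:
        lab = np.full(self.n_frames, -1, dtype=int)
        for ci, (_, ms) in enumerate(self.clusters):
            for i in ms:
                lab[i] = ci
        return lab

    def to_dict(self) -> dict:
        return {"cutoff_nm": self.cutoff,
                "clusters": [{"center": c, "size": len(ms), "members": ms}
                             for c, ms in self.clusters]}


def rmsd_matrix(traj: Trajectory, selection=None,
                superpose: bool = True, stride: int = 1) -> RMSDMatrix:
    """All-pairs RMSD of a selection over trajectory frames, nm."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        idx = np.arange(traj.topology.n_atoms)
    else:
        sel = select(traj.topology, selection) if isinstance(selection, str) else selection
        idx = np.asarray(sel.indices)
        if len(idx) == 0:
            raise AnchorError("empty selection for RMSD matrix")
    frames = [np.asarray(f)[idx] for f in traj.frames[::stride]]
    n = len(frames)
    if n > MAX_FRAMES:
        raise ValueError(f"{n} frames exceeds dense-matrix cap {MAX_FRAMES}; "
                         "increase stride")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = frames[i], frames[j]
            if superpose:
                R, t = kabsch(a, b)
                a = a @ R.T + t
            M[i, j] = M[j, i] = np.sqrt(((a - b) ** 2).sum(axis=1).mean()) / 10.0
    return RMSDMatrix(M, selection)


def gromos_cluster(matrix: RMSDMatrix, cutoff: float = 0.45) -> Clustering:
    """Greedy neighbor-counting partition.

    Repeatedly the frame with the most neighbors within ``cutoff`` becomes a
    cluster center and is removed together with its neighbors. Ties go to
    the lowest frame index; clusters are ordered by decreasing size, ties by
    lower center index, so the result is deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.n
    within = matrix.values <= cutoff
    remaining = np.ones(n, dtype=bool)
    clusters: list[tuple[int, list[int]]] = []
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))   # argmax takes the lowest index on ties
        members = np.where(within[center] & remaining)[0]
        clusters.append((center, members.tolist()))
        remaining[members] = False
    clusters.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    return Clustering(clusters, cutoff)


def best_cluster_frame(clustering: Clustering, traj: Trajectory) -> StructureModel:
    """Structure of the center frame of the largest cluster."""
    if not clustering.clusters:
        raise ValueError("empty clustering")
    center, _ = clustering.clusters[0]
    return traj.frame_model(center)
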