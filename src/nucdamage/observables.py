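"""Per-frame geometric observables and their trajectory series.

Distances are reported in nm, dihedrals in degrees, times in ps. Internal
coordinates are Angstrom (see structure_io); the 0.1 conversion happens at
the reporting boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .damage import DamageSite
from .structure_io import AtomSet, StructureModel, Trajectory, select

__all__ = [
    "ObservableSeries", "HBondCriteria", "AnchorError",
    "dihedral_deg", "kabsch",
    "gap_distance", "local_twist", "gyre_gaping", "pair_distance",
    "rmsd_to_reference",
    "gap_distance_series", "local_twist_series", "gyre_gaping_series",
    "pair_distance_series", "hbond_series", "rmsd_series",
    "series_stats", "correlate",
]

A_PER_NM = 10.0


class AnchorError(KeyError):
    """An observable's anchor atom could not be resolved."""


@dataclass
class ObservableSeries:
    name: str
    values: np.ndarray
    units: str
    times: np.ndarray | None = None
    anchors: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.times is None:
            self.times = np.arange(len(self.values), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")

    def __len__(self):
        return len(self.values)


@dataclass
class HBondCriteria:
    max_DA_distance: float = 3.5   # Angstrom, donor-acceptor heavy atoms
    max_H_angle_dev: float = 30.0  # degrees (applied only with hydrogens)
    heavy_only: bool = True

    def __post_init__(self):
        if self.max_DA_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_H_angle_dev <= 90:
            raise ValueError("angle deviation must be in (0, 90]")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def dihedral_deg(a, b, c, d) -> float:
    """Signed dihedral angle of the ordered quadruple, degrees in (-180, 180]."""
    a, b, c, d = (np.asarray(x, float) for x in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))


def kabsch(mobile: np.ndarray, target: np.ndarray,
           weights: np.ndarray | None = None):
    """Least-squares superposition: returns (rotation, translation) mapping
    ``mobile`` onto ``target`` (proper rotation via SVD)."""
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    pc = (w[:, None] * P).sum(axis=0)
    qc = (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * (P - pc)).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _atom_coord(topology: StructureModel, frame: np.ndarray | None,
                chain: str, resid: int, name: str) -> np.ndarray:
    try:
        i = topology.atom_index(chain, resid, name)
    except KeyError:
        raise AnchorError(f"missing anchor atom {chain}:{resid}:{name}") from None
    if frame is None:
        return topology.coords()[i]
    return np.asarray(frame, float)[i]


# ---------------------------------------------------------------------------
# per-frame observables
# ---------------------------------------------------------------------------

def gap_distance(topology: StructureModel, frame: np.ndarray | None,
                 ssb: DamageSite) -> float:
    """SSB gap distance: C3'(5' terminus) to C3'(3' terminus), nm."""
    c5, r5, _ = ssb.ends["five"]
    c3, r3, _ = ssb.ends["three"]
    p5 = _atom_coord(topology, frame, c5, r5, "C3'")
    p3 = _atom_coord(topology, frame, c3, r3, "C3'")
    return float(np.linalg.norm(p5 - p3)) / A_PER_NM


def local_twist(topology: StructureModel, frame: np.ndarray | None,
                ssb: DamageSite, convention: str = "unsigned") -> float:
    """Local twist dihedral over the C3' atoms of the two base pairs flanking
    the unpaired nucleotide, mapped to [0, 180] degrees.

    Ordering (fixed by calibration against relaxed B-DNA at 10.4 bp/turn):
    cut-strand 5'-flank, its partner, the 3'-flank's partner, 3'-flank.
    """
    if not ssb.phi_anchors:
        raise AnchorError("damage site carries no phi anchors")
    pts = [_atom_coord(topology, frame, c, r, "C3'") for c, r in ssb.phi_anchors]
    phi = dihedral_deg(*pts)
    if convention == "signed":
        return phi
    return abs(phi)


def pick_gyre_partner(topology: StructureModel, frame: np.ndarray | None,
                      site: DamageSite | tuple[str, int], shlmap,
                      shl_window: float = 1.0) -> tuple[str, int]:
    """Choose the adjacent-gyre nucleotide whose P is closest to the site P."""
    if isinstance(site, DamageSite):
        if site.unpaired is None:
            raise AnchorError("ssb site has no unpaired nucleotide recorded")
        key = site.unpaired
    else:
        key = tuple(site)
    my_gyre = shlmap.gyre_of.get(key)
    if my_gyre is None:
        raise AnchorError(f"{key} not in SHL map")
    p0 = _atom_coord(topology, frame, key[0], key[1], "P")
    best, best_d = None, np.inf
    for other, gyre in shlmap.gyre_of.items():
        if gyre == my_gyre:
            continue
        try:
            q = _atom_coord(topology, frame, other[0], other[1], "P")
        except AnchorError:
            continue
        d = np.linalg.norm(q - p0)
        if d < best_d:
            best, best_d = other, d
    if best is None:
        raise AnchorError("no adjacent winding found (dyad site?)")
    return best


def gyre_gaping(topology: StructureModel, frame: np.ndarray | None,
                site: DamageSite | tuple[str, int], shlmap,
                partner: tuple[str, int] | None = None) -> float:
    """Gaping distance dw: P of the site nucleotide to the P of its
    adjacent-winding partner, nm. The partner is normally chosen once on
    frame 0 (pass it back in) so dw is a paired time series."""
    if isinstance(site, DamageSite):
        key = site.unpaired
        if key is None:
            raise AnchorError("ssb site has no unpaired nucleotide recorded")
    else:
        key = tuple(site)
    if partner is None:
        partner = pick_gyre_partner(topology, frame, site, shlmap)
    p = _atom_coord(topology, frame, key[0], key[1], "P")
    q = _atom_coord(topology, frame, partner[0], partner[1], "P")
    return float(np.linalg.norm(p - q)) / A_PER_NM


def _resolve_selection(topology: StructureModel, sel) -> AtomSet:
    if isinstance(sel, AtomSet):
        return sel
    if isinstance(sel, str):
        return select(topology, sel)
    raise TypeError(f"cannot interpret selection {sel!r}")


_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
           "S": 32.06, "ZN": 65.38}


def pair_distance(topology: StructureModel, frame: np.ndarray | None,
                  a, b, mode: str = "com") -> float:
    """Distance between two selections, nm. ``mode='min'``: minimum
    heavy-atom distance; ``mode='com'``: mass-weighted centroid distance."""
    sa = _resolve_selection(topology, a)
    sb = _resolve_selection(topology, b)
    if len(sa) == 0 or len(sb) == 0:
        raise AnchorError("empty selection in pair_distance")
    ca = sa.coords(frame)
    cb = sb.coords(frame)
    if mode == "min":
        heavy_a = [i for i, at in enumerate(sa.atoms) if at.element.upper() != "H"]
        heavy_b = [i for i, at in enumerate(sb.atoms) if at.element.upper() != "H"]
        if not heavy_a or not heavy_b:
            raise AnchorError("no heavy atoms in selection")
        diff = ca[heavy_a][:, None, :] - cb[heavy_b][None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2)).min()
    elif mode == "com":
        wa = np.array([_MASSES.get(at.element.upper(), 12.0) for at in sa.atoms])
        wb = np.array([_MASSES.get(at.element.upper(), 12.0) for at in sb.atoms])
        d = np.linalg.norm((wa[:, None] * ca).sum(0) / wa.sum()
                           - (wb[:, None] * cb).sum(0) / wb.sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(d) / A_PER_NM


def rmsd_to_reference(topology: StructureModel, frame: np.ndarray | None,
                      reference: StructureModel | np.ndarray,
                      selection=None, ref_selection=None,
                      superpose: bool = True) -> float:
    """RMSD of a selection against a reference structure, nm.

    With ``superpose`` the optimal rigid superposition is applied first.
    The selection must map 1:1 between frame and reference (same atom count,
    taken in model order)."""
    if selection is None:
        mob = topology.coords() if frame is None else np.asarray(frame, float)
    else:
        mob = _resolve_selection(topology, selection).coords(frame)
    if isinstance(reference, StructureModel):
        rsel = ref_selection if ref_selection is not None else selection
        if rsel is None:
            ref = reference.coords()
        else:
            ref = _resolve_selection(reference, rsel).coords(None)
    else:
        ref = np.asarray(reference, float)
    if mob.shape != ref.shape:
        raise AnchorError(f"selection maps {mob.shape[0]} atoms onto "
                          f"{ref.shape[0]} reference atoms")
    if superpose:
        R, t = kabsch(mob, ref)
        mob = mob @ R.T + t
    return float(np.sqrt(((mob - ref) ** 2).sum(axis=1).mean())) / A_PER_NM


# ---------------------------------------------------------------------------
# trajectory series
# ---------------------------------------------------------------------------

def gap_distance_series(traj: Trajectory, ssb: DamageSite) -> ObservableSeries:
    vals = [gap_distance(traj.topology, f, ssb) for f in traj.frames]
    return ObservableSeries("dg", vals, "nm", traj.times,
                            anchors=[ssb.ends["five"], ssb.ends["three"]])


def local_twist_series(traj: Trajectory, ssb: DamageSite) -> ObservableSeries:
    vals = [local_twist(traj.topology, f, ssb) for f in traj.frames]
    return ObservableSeries("phi", vals, "degrees", traj.times,
                            anchors=list(ssb.phi_anchors or []))


def gyre_gaping_series(traj: Trajectory, site, shlmap,
                       refresh_partner: bool = False) -> ObservableSeries:
    partner = pick_gyre_partner(traj.topology, traj.frames[0], site, shlmap)
    vals = []
    for f in traj.frames:
        p = None if refresh_partner else partner
        vals.append(gyre_gaping(traj.topology, f, site, shlmap, partner=p))
    return ObservableSeries("dw", vals, "nm", traj.times, anchors=[partner])


def pair_distance_series(traj: Trajectory, a, b, mode: str = "com",
                         name: str = "pair_distance") -> ObservableSeries:
    sa = _resolve_selection(traj.topology, a)
    sb = _resolve_selection(traj.topology, b)
    vals = [pair_distance(traj.topology, f, sa, sb, mode=mode)
            for f in traj.frames]
    return ObservableSeries(name, vals, "nm", traj.times)


def hbond_series(traj: Trajectory, donor_sel, acceptor_sel,
                 criteria: HBondCriteria | None = None):
    """Distance + presence series for a single donor/acceptor heavy-atom pair.

    Returns (present: bool array, distances: ObservableSeries in nm)."""
    criteria = criteria or HBondCriteria()
    sd = _resolve_selection(traj.topology, donor_sel)
    sa = _resolve_selection(traj.topology, acceptor_sel)
    if len(sd) != 1 or len(sa) != 1:
        raise AnchorError("hbond_series needs single-atom selections")
    i, j = sd.indices[0], sa.indices[0]
    d = np.array([np.linalg.norm(f[i] - f[j]) for f in traj.frames])
    present = d <= criteria.max_DA_distance
    series = ObservableSeries("hbond_distance", d / A_PER_NM, "nm", traj.times,
                              anchors=[sd.atoms[0].name, sa.atoms[0].name])
    return present, series


def rmsd_series(traj: Trajectory, reference: StructureModel, selection=None,
                superpose: bool = True) -> ObservableSeries:
    vals = [rmsd_to_reference(traj.topology, f, reference, selection,
                              superpose=superpose) for f in traj.frames]
    return ObservableSeries("rmsd", vals, "nm", traj.times)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def series_stats(series: ObservableSeries, window: int = 10, bins: int = 50,
                 range_: tuple[float, float] | None = None) -> dict:
    """Normalized histogram (mass sums to 1) plus summary statistics."""
    v = np.asarray(series.values, float)
    if v.size == 0:
        raise ValueError("empty series")
    counts, edges = np.histogram(v, bins=bins, range=range_)
    mass = counts / counts.sum()
    window = max(1, min(int(window), v.size))
    kernel = np.ones(window) / window
    running = np.convolve(v, kernel, mode="valid")
    return {
        "histogram": {"mass": mass, "edges": edges},
        "mean": float(v.mean()),
        "min": float(v.min()),
        "max": float(v.max()),
        "std": float(v.std()),
        "running_average": running,
        "n": int(v.size),
    }


def correlate(x: ObservableSeries, y: ObservableSeries) -> dict:
    """Least-squares line and Pearson r between two equal-length series."""
    xv = np.asarray(x.values, float)
    yv = np.asarray(y.values, float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(xv) == 0:
        raise ZeroDivisionError("zero variance in x: slope undefined")
    res = _scipy_stats.linregress(xv, yv)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r": float(res.rvalue), "stderr": float(res.stderr),
            "intercept_stderr": float(res.intercept_stderr)}
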