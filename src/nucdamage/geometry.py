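"""Superhelical coordinate system of a nucleosome model.

Maps every nucleotide to a superhelical location (SHL, in double-helix turns
from the dyad), labels the two gyres, finds the inward-facing minor-groove
contact points, and classifies damage-site accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .damage import antiparallel_pairs
from .structure_io import Residue, StructureModel

__all__ = ["SHLMap", "AccessibilityCall", "GeometryError",
           "fit_superhelix", "shl_map", "contact_points",
           "classify_accessibility", "DEFAULT_TAIL_RANGES"]

# Canonical histone N-terminal tail ranges (author numbering), overridable.
DEFAULT_TAIL_RANGES = {
    "H3": [(1, 44)],
    "H4": [(1, 24)],
    "H2A": [(1, 16), (118, 130)],
    "H2B": [(1, 30)],
}


class GeometryError(ValueError):
    pass


@dataclass
class SHLMap:
    axis: np.ndarray                      # unit superhelical axis
    center: np.ndarray                    # Angstrom
    dyad: tuple[str, int]
    shl_of: dict[tuple[str, int], float]
    gyre_of: dict[tuple[str, int], str]   # 'upper' | 'lower'
    contact_points: list[float] = field(default_factory=list)
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    bp_per_turn: float = 10.4

    def partner_of(self, key: tuple[str, int]) -> tuple[str, int] | None:
        for a, b in self.pairs:
            if a == key:
                return b
            if b == key:
                return a
        return None

    def to_records(self) -> list[dict]:
        return [{"chain": c, "resid": r, "shl": self.shl_of[(c, r)],
                 "gyre": self.gyre_of[(c, r)]}
                for (c, r) in sorted(self.shl_of)]


@dataclass
class AccessibilityCall:
    site: tuple[str, int]
    klass: str                 # easy | medium | hard
    tail_proximal: bool
    tail_id: str | None = None
    theta_deg: float | None = None

    def __post_init__(self):
        if self.klass not in {"easy", "medium", "hard"}:
            raise ValueError(f"bad accessibility class {self.klass!r}")


# ---------------------------------------------------------------------------

def fit_superhelix(model: StructureModel, dna_chains: Sequence[str],
                   min_phosphates: int = 100):
    """Best-fit superhelical axis and center from DNA phosphate positions.

    The axis is the normal of the least-squares plane through the P atoms;
    the center is their centroid. The sign is chosen so the DNA winds
    left-handed about +axis.
    """
    pts = []
    order = []
    for cid in dna_chains:
        ch = model.chain(cid)
        for res in ch.residues:
            p = res.atom("P")
            if p is not None:
                pts.append(p.coord)
                order.append(cid)
    if len(pts) < min_phosphates:
        raise GeometryError(f"only {len(pts)} phosphates found "
                            f"(need >= {min_phosphates})")
    P = np.asarray(pts, float)
    center = P.mean(axis=0)
    _, _, Vt = np.linalg.svd(P - center, full_matrices=False)
    axis = Vt[2]  # smallest singular direction = plane normal
    axis = axis / np.linalg.norm(axis)
    # the plane normal is biased when the wrap is a non-integer number of
    # turns; refine with a cylinder fit (constant radial distance)
    axis, center = _refine_cylinder_axis(P, axis, center)

    # handedness: along the first strand 5'->3', a left-handed wrap has
    # azimuthal advance and axial advance of opposite sign
    first = dna_chains[0]
    strand = P[[i for i, c in enumerate(order) if c == first]]
    if len(strand) >= 3:
        rel = strand - center
        z = rel @ axis
        xy = rel - np.outer(z, axis)
        hand = 0.0
        for i in range(len(strand) - 1):
            dphi = np.cross(xy[i], xy[i + 1]) @ axis
            dz = z[i + 1] - z[i]
            hand += dphi * dz
        if hand > 0:
            axis = -axis
    return axis, center


def _refine_cylinder_axis(P: np.ndarray, axis0: np.ndarray,
                          center0: np.ndarray):
    """Least-squares cylinder axis: minimize the variance of radial
    distances of the points about the axis line."""
    from scipy.optimize import least_squares

    u0 = _perp(axis0, 0)
    v0 = _perp(axis0, 1)

    def unpack(p):
        a, b, cx, cy = p
        axis = axis0 + a * u0 + b * v0
        axis = axis / np.linalg.norm(axis)
        center = center0 + cx * u0 + cy * v0
        return axis, center

    def resid(p):
        axis, center = unpack(p)
        rel = P - center
        radial = rel - np.outer(rel @ axis, axis)
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    sol = least_squares(resid, np.zeros(4), method="lm", max_nfev=200)
    axis, center = unpack(sol.x)
    if axis @ axis0 < 0:
        axis = -axis
    return axis, center


def shl_map(model: StructureModel, dna_chains: Sequence[str],
            bp_per_turn: float = 10.4,
            pairing: Sequence[tuple[int, int]] | None = None,
            flip_sign: bool = False,
            min_phosphates: int = 100) -> SHLMap:
    """Per-nucleotide SHL coordinates, dyad and gyre labels.

    SHL(bp) = (signed base-pair offset from the dyad) / bp_per_turn, positive
    on the 3' side of the first chain (sign flippable). The dyad is the
    midpoint base pair of the wrapped path. Gyre labels split at the dyad and
    are named by axial position: 'upper' has the larger axis projection.
    """
    axis, center = fit_superhelix(model, dna_chains, min_phosphates=min_phosphates)
    pairs = antiparallel_pairs(model, dna_chains, pairing=pairing)
    n = len(pairs)
    if n == 0:
        raise GeometryError("no base pairs")
    mid = (n - 1) / 2.0
    sign = -1.0 if flip_sign else 1.0
    shl_of: dict[tuple[str, int], float] = {}
    gyre_of: dict[tuple[str, int], str] = {}
    proj_half = {"neg": [], "pos": []}
    for k, (ri, rj) in enumerate(pairs):
        shl = sign * (k - mid) / bp_per_turn
        for r in (ri, rj):
            shl_of[r.key] = shl
        c = _bp_center(ri, rj)
        if shl < -0.5:
            proj_half["neg"].append((c - center) @ axis)
        elif shl > 0.5:
            proj_half["pos"].append((c - center) @ axis)
    neg_z = np.mean(proj_half["neg"]) if proj_half["neg"] else 0.0
    pos_z = np.mean(proj_half["pos"]) if proj_half["pos"] else 0.0
    neg_label = "upper" if neg_z >= pos_z else "lower"
    pos_label = "lower" if neg_label == "upper" else "upper"
    for key, shl in shl_of.items():
        gyre_of[key] = neg_label if shl < 0 else pos_label
    dyad_pair = pairs[int(round(mid))]
    smap = SHLMap(axis=axis, center=center, dyad=dyad_pair[0].key,
                  shl_of=shl_of, gyre_of=gyre_of,
                  pairs=[(a.key, b.key) for a, b in pairs],
                  bp_per_turn=bp_per_turn)
    return smap


def _bp_center(ri: Residue, rj: Residue) -> np.ndarray:
    pts = []
    for r in (ri, rj):
        a = r.atom("C1'") or r.atom("CEN") or r.atom("C3'")
        if a is not None:
            pts.append(a.coord)
    if not pts:
        pts = [a.coord for a in ri.atoms + rj.atoms]
    return np.mean(pts, axis=0)


def _backbone_mid(ri: Residue, rj: Residue) -> np.ndarray | None:
    pts = []
    for r in (ri, rj):
        a = r.atom("P") or r.atom("C3'")
        if a is None:
            return None
        pts.append(a.coord)
    return np.mean(pts, axis=0)


def contact_points(shlmap: SHLMap, model: StructureModel,
                   smooth_window: int = 3, min_separation_bp: int = 6,
                   threshold: float = 0.0,
                   min_wrap_radius: float = 12.0) -> list[float]:
    """SHL values of inward-facing minor-groove contact points.

    For each base pair the minor-groove direction (base-pair center toward
    the backbone midpoint, projected off the superhelical axis) is compared
    with the inward radial direction; local maxima of the inwardness along
    the path are the contacts. Straight (unwrapped) DNA yields none.
    """
    axis, center = shlmap.axis, shlmap.center
    pairs = []
    for a, b in shlmap.pairs:
        try:  # residues deleted after mapping (e.g. an SSB) are skipped
            pairs.append((model.residue(*a), model.residue(*b)))
        except KeyError:
            continue
    shls, centers, bmids = [], [], []
    for ri, rj in pairs:
        bmid = _backbone_mid(ri, rj)
        if bmid is None:
            continue
        shls.append(shlmap.shl_of[ri.key])
        centers.append(_bp_center(ri, rj))
        bmids.append(bmid)
    if len(centers) < 3:
        return []
    centers = np.asarray(centers)
    bmids = np.asarray(bmids)
    # local duplex-axis points: bp centers smoothed over one helical period
    # (kills the cross-section wobble, leaves the superhelical path)
    period = max(3, int(round(shlmap.bp_per_turn)) | 1)
    axis_pts = _moving_average(centers, period)
    rel = axis_pts - center
    radial = rel - np.outer(rel @ axis, axis)
    nr = np.linalg.norm(radial, axis=1)
    # straight (unwrapped) DNA: the duplex-axis path hugs the fitted axis
    if np.mean(nr) < min_wrap_radius:
        return []
    groove = bmids - axis_pts
    groove = groove - np.outer(groove @ axis, axis)
    ng = np.linalg.norm(groove, axis=1)
    ok = (nr > 1e-9) & (ng > 1e-9)
    inward = np.where(ok, -(groove * radial).sum(axis=1) / (ng * nr + 1e-30), -1.0)
    shls = list(np.asarray(shls))
    inward = list(inward)
    x = np.asarray(inward, float)
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        x = np.convolve(x, k, mode="same")
    order = np.argsort(np.abs(x))[::-1]
    chosen: list[int] = []
    for i in order:
        if x[i] <= threshold:
            continue
        if 0 < i < len(x) - 1 and not (x[i] >= x[i - 1] and x[i] >= x[i + 1]):
            continue
        if any(abs(i - j) < min_separation_bp for j in chosen):
            continue
        chosen.append(int(i))
    out = sorted(shls[i] for i in chosen)
    shlmap.contact_points = out
    return out


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with edge truncation."""
    n = len(x)
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean(axis=0)
    return out


def _perp(axis: np.ndarray, which: int) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    if which == 0:
        return u
    v = np.cross(axis, u)
    return v / np.linalg.norm(v)


def classify_accessibility(model: StructureModel, site: tuple[str, int],
                           shlmap: SHLMap,
                           tail_ranges: dict | None = None,
                           tail_cutoff: float = 5.0,
                           easy_max_deg: float = 60.0,
                           hard_min_deg: float = 120.0) -> AccessibilityCall:
    """Classify a nucleotide's solvent accessibility from its base orientation.

    theta is the angle between the base's radial vector (base centroid minus
    the local helical-axis point) and the outward radial direction:
    theta < easy_max -> easy, > hard_min -> hard, else medium. Tail proximity
    is any histone-tail heavy atom within ``tail_cutoff`` Angstrom.
    """
    site = tuple(site)
    res = model.residue(*site)
    if res.kind != "nucleotide":
        raise ValueError(f"{site}: not a nucleotide")
    if site not in shlmap.shl_of:
        raise ValueError(f"{site} not in SHL map")
    partner_key = shlmap.partner_of(site)
    partner = model.residue(*partner_key) if partner_key else res
    local_axis_pt = _bp_center(res, partner)
    from ._chem import base_atoms
    batoms = base_atoms(res)
    if not batoms:
        raise ValueError(f"{site}: no base atoms")
    centroid = np.mean([a.coord for a in batoms], axis=0)
    rel = local_axis_pt - shlmap.center
    outward = rel - (rel @ shlmap.axis) * shlmap.axis
    outward = outward / np.linalg.norm(outward)
    v = centroid - local_axis_pt
    v = v - (v @ shlmap.axis) * shlmap.axis
    nv = np.linalg.norm(v)
    theta = 90.0 if nv < 1e-9 else float(np.degrees(np.arccos(
        np.clip((v / nv) @ outward, -1, 1))))
    if theta < easy_max_deg:
        klass = "easy"
    elif theta > hard_min_deg:
        klass = "hard"
    else:
        klass = "medium"

    tail_proximal, tail_id = _tail_proximity(model, res, tail_ranges, tail_cutoff)
    return AccessibilityCall(site=site, klass=klass, tail_proximal=tail_proximal,
                             tail_id=tail_id, theta_deg=theta)


# histone identification by canonical chain naming or residue count
_HISTONE_HINTS = {"A": "H3", "B": "H4", "C": "H2A", "D": "H2B",
                  "E": "H3", "F": "H4", "G": "H2A", "H": "H2B"}


def _tail_proximity(model, res, tail_ranges, cutoff):
    tail_ranges = tail_ranges or DEFAULT_TAIL_RANGES
    site_xyz = np.array([a.coord for a in res.atoms
                         if a.element.upper() != "H"])
    best = (False, None)
    for ch in model.chains:
        if not any(r.kind == "amino-acid" for r in ch.residues):
            continue
        histone = _HISTONE_HINTS.get(ch.chain_id.upper())
        ranges = tail_ranges.get(histone) if histone else None
        if ranges is None:
            # unknown chain: treat leading 25 residues as a tail surrogate
            resids = [r.resid for r in ch.residues]
            ranges = [(min(resids), min(resids) + 24)] if resids else []
        for lo, hi in ranges:
            for r in ch.residues:
                if not (lo <= r.resid <= hi):
                    continue
                for a in r.atoms:
                    if a.element.upper() == "H":
                        continue
                    d = np.min(np.linalg.norm(site_xyz - a.coord, axis=1))
                    if d <= cutoff:
                        return True, histone or ch.chain_id
    return best
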