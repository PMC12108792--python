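"""Synthetic structures and trajectories with known ground truth.

Builds idealized B-DNA duplexes, wraps them on a left-handed nucleosomal
superhelix, and generates seeded conformational ensembles in which target
observables (gap distance, local twist, gyre gaping, probe distances) follow
prescribed per-frame schedules exactly before noise is added. This replaces
an MD engine for testing: every injected signal is logged so analysis code
can be validated by parameter recovery.

Geometry notes
--------------
The duplex is coarse but self-consistent: every nucleotide carries the full
backbone path P-O5'-C5'-C4'-C3'-O3', the sugar C1', and a full idealized
heavy-atom base plus a CEN centroid pseudo-atom, all placed on exact
cylindrical helical coordinates. The paired-strand backbone phase offset
(default 100 deg) is calibrated so the local-twist dihedral of relaxed
B-DNA at 10.4 bp/turn falls in the 60-70 degree band.

Superhelix defaults (radius 41.8 A, pitch 25.9 A) follow canonical
nucleosome crystallography; they are implementation defaults, not fitted
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _chem, observables
from .damage import DamageSite
from .structure_io import Atom, Chain, Residue, StructureModel, Trajectory

__all__ = ["HelixParams", "SuperhelixParams", "DeformationSignal", "ProbeSpec",
           "build_bdna", "wrap_superhelix", "make_trajectory",
           "place_probe_residues", "CompositionError"]


class CompositionError(ValueError):
    """Two deformation signals claim the same atoms."""


@dataclass
class HelixParams:
    rise: float = 3.4                 # Angstrom / bp
    bp_per_turn: float = 10.4
    strand_phase_deg: float = 100.0   # paired-strand backbone phase offset
    backbone_radius: float = 9.4      # P radius, Angstrom
    c1_radius: float = 5.9

    def __post_init__(self):
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < self.twist_deg < 60:
            raise ValueError("twist per bp must be in (0, 60) degrees")

    @property
    def twist_deg(self) -> float:
        return 360.0 / self.bp_per_turn


@dataclass
class SuperhelixParams:
    radius: float = 41.8      # Angstrom
    pitch: float = 25.9       # Angstrom / superhelical turn
    handedness: str = "left"
    total_bp: int = 145

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.handedness != "left":
            raise ValueError("nucleosome mimic is left-handed only")


@dataclass
class DeformationSignal:
    """A per-frame schedule for one observable.

    target: 'dg' | 'phi' | 'dw' | 'probe_distance'. Schedules are in the
    observable's units (nm, or degrees for phi); noise_sigma likewise.
    """
    target: str
    schedule: np.ndarray
    noise_sigma: float = 0.0
    site: DamageSite | None = None
    anchors: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.target not in {"dg", "phi", "dw", "probe_distance"}:
            raise ValueError(f"unknown signal target {self.target!r}")
        self.schedule = np.asarray(self.schedule, dtype=float)


@dataclass
class ProbeSpec:
    """A placeable pseudo amino-acid probe (e.g. a Leu151 analogue)."""
    label: str                        # e.g. 'LEU151'
    anchor: tuple[str, int, str]      # chain, resid, atom name
    distance: float                   # nm, initial placement
    chain_id: str = "P"
    direction: np.ndarray | None = None


# relative atom placements: name -> (radius, phase offset rad, z offset A)
_BACKBONE_LAYOUT = {
    "P":   (9.4, -0.30, -1.8),
    "O5'": (9.2, -0.20, -1.2),
    "C5'": (9.0, -0.12, -0.8),
    "C4'": (8.9, -0.04, -0.2),
    "C3'": (8.9,  0.08,  0.6),
    "O3'": (9.2,  0.18,  1.3),
    "C1'": (5.9,  0.10,  0.0),
}


def build_bdna(sequence: str, params: HelixParams | None = None,
               chain_ids: tuple[str, str] = ("I", "J"),
               phase0_deg: float = 0.0) -> StructureModel:
    """Build an idealized straight B-DNA duplex along +z.

    ``sequence`` is the first strand 5'->3'; the second strand is its
    reverse complement with antiparallel index pairing (residue i of chain I
    pairs residue n+1-i of chain J). Geometry follows rise/twist exactly.
    """
    params = params or HelixParams()
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTU")
    if bad or len(sequence) < 2:
        raise ValueError(f"invalid sequence {sequence!r}")
    n = len(sequence)
    twist = np.radians(params.twist_deg)
    delta = np.radians(params.strand_phase_deg)
    phase0 = np.radians(phase0_deg)
    scale_bb = params.backbone_radius / 9.4
    scale_c1 = params.c1_radius / 5.9

    def atom_pos(strand: int, k: int, radius, dphase, dz) -> np.ndarray:
        th = phase0 + k * twist
        if strand == 0:
            ph, z = th + dphase, k * params.rise + dz
        else:
            ph, z = th + delta - dphase, k * params.rise - dz
        return np.array([radius * np.cos(ph), radius * np.sin(ph), z])

    strands: list[list[Residue]] = [[], []]
    for k in range(n):
        base_i = sequence[k]
        base_j = _chem.COMPLEMENT[base_i]
        positions = {}
        for s, base in ((0, base_i), (1, base_j)):
            atoms = []
            for name, (r0, dp, dz) in _BACKBONE_LAYOUT.items():
                r = r0 * (scale_c1 if name == "C1'" else scale_bb)
                atoms.append(Atom(name, "", atom_pos(s, k, r, dp, dz)))
            positions[s] = atoms
        # bases along the C1'-C1' chord, idealized templates
        c1 = {s: next(a for a in positions[s] if a.name == "C1'") for s in (0, 1)}
        for s, base in ((0, base_i), (1, base_j)):
            u = c1[1 - s].coord - c1[s].coord
            u = u / np.linalg.norm(u)
            p = np.cross(u, np.array([0.0, 0.0, 1.0]))
            p = p / np.linalg.norm(p)
            for name, pos in _chem.place_base_template(base, c1[s].coord, u, p):
                positions[s].append(Atom(name, "", pos))
            resname = _chem.RESNAME_OF_BASE[base]
            resid = k + 1 if s == 0 else n - k
            strands[s].append(Residue(resname, resid, chain_ids[s],
                                      positions[s]))
    # chain J written in its own 5'->3' order (resid 1..n)
    strands[1].sort(key=lambda r: r.resid)
    model = StructureModel([Chain(chain_ids[0], strands[0]),
                            Chain(chain_ids[1], strands[1])],
                           title=f"ideal B-DNA {n} bp")
    # drop 5'-terminal phosphate groups (no upstream linkage)
    for ch in model.chains:
        first = ch.residues[0]
        first.atoms = [a for a in first.atoms if a.name not in {"P", "O5'"}]
    model.validate()
    return model


def wrap_superhelix(duplex: StructureModel,
                    params: SuperhelixParams | None = None,
                    align: str = "axis-z") -> StructureModel:
    """Map a straight duplex onto a left-handed superhelical path.

    Local cross-sections are transported rigidly along the path; the duplex
    is pre-rotated about its own axis so the dyad minor groove faces outward
    (which puts the inward-facing minor grooves at half-integral SHLs).
    ``align='axis-z'`` leaves the superhelical axis on +z; ``align='duplex'``
    rigidly re-places the result so the dyad base pair keeps its original
    position (the radius->infinity limit then reproduces the input).
    """
    params = params or SuperhelixParams()
    if params.radius < 15.0:
        raise ValueError(f"superhelix radius {params.radius} A would "
                         "self-intersect the duplex")
    out = duplex.copy()
    coords = out.coords()
    z = coords[:, 2]
    z_mid = 0.5 * (z.min() + z.max())

    # pre-rotate about z so the central-bp minor groove points along +x
    alpha = _central_groove_angle(out)
    ca, sa = np.cos(-alpha), np.sin(-alpha)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    coords = coords @ rot.T

    R = params.radius
    c = params.pitch / (2 * np.pi)
    L = np.hypot(R, c)

    s = coords[:, 2] - z_mid
    t = s / L
    x, y = coords[:, 0], coords[:, 1]
    cos_t, sin_t = np.cos(t), np.sin(t)
    center = np.stack([R * cos_t, -R * sin_t, c * t], axis=1)
    u = np.stack([cos_t, -sin_t, np.zeros_like(t)], axis=1)        # outward
    tang = np.stack([-R * sin_t, -R * cos_t, np.full_like(t, c)], axis=1) / L
    w = np.cross(tang, u)
    new = center + x[:, None] * u + y[:, None] * w

    if align == "duplex":
        u0 = np.array([1.0, 0.0, 0.0])
        t0 = np.array([0.0, -R, c]) / L
        w0 = np.cross(t0, u0)
        M = np.outer([1, 0, 0], u0) + np.outer([0, 1, 0], w0) + np.outer([0, 0, 1], t0)
        new = (new - np.array([R, 0.0, 0.0])) @ M.T
        new = (new @ rot) + np.array([0.0, 0.0, z_mid])
    elif align != "axis-z":
        raise ValueError(f"unknown align mode {align!r}")
    out.set_coords(new)
    out.title = (duplex.title + " wrapped").strip()
    return out


def _central_groove_angle(duplex: StructureModel) -> float:
    """Azimuth of the minor-groove direction at the central base pair."""
    ci, cj = duplex.chains[0], duplex.chains[1]
    n = len(ci.residues)
    k = n // 2
    ri = ci.residues[k]
    rj = cj.residues[n - 1 - k]   # antiparallel partner
    bp_center = 0.5 * (ri.atom("C1'").coord + rj.atom("C1'").coord)
    bmid = 0.5 * (ri.atom("C3'").coord + rj.atom("C3'").coord)
    g = bmid - bp_center
    return float(np.arctan2(g[1], g[0]))


def place_probe_residues(model: StructureModel, probes: Sequence[ProbeSpec]
                         ) -> StructureModel:
    """Add single-atom pseudo amino-acid probes at prescribed distances
    from their anchor atoms."""
    out = model.copy()
    all_xyz = out.coords()
    centroid = all_xyz.mean(axis=0)
    for spec in probes:
        if spec.distance < 0:
            raise ValueError(f"probe {spec.label}: negative distance")
        ch_id = spec.chain_id
        anchor = out.residue(spec.anchor[0], spec.anchor[1]).atom(spec.anchor[2])
        if anchor is None:
            raise KeyError(f"probe anchor atom {spec.anchor} not found")
        if spec.direction is not None:
            d = np.asarray(spec.direction, float)
        else:
            d = anchor.coord - centroid
        nd = np.linalg.norm(d)
        d = d / nd if nd > 1e-9 else np.array([1.0, 0.0, 0.0])
        pos = anchor.coord + spec.distance * observables.A_PER_NM * d
        resname = spec.label[:3].upper()
        try:
            resid = int(spec.label[3:])
        except ValueError:
            resid = 1
        chain = next((c for c in out.chains if c.chain_id == ch_id), None)
        if chain is None:
            chain = Chain(ch_id, [])
            out.chains.append(chain)
        chain.residues.append(Residue(resname, resid, ch_id,
                                      [Atom("CA", "C", pos)]))
    out.invalidate()
    out.validate()
    return out


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _signal_atom_indices(model: StructureModel, sig: DeformationSignal) -> set[int]:
    """Flat indices of atoms a signal's operator will move."""
    def residue_indices(chain, resid):
        res = model.residue(chain, resid)
        return {model.atom_index(chain, resid, a.name) for a in res.atoms}

    if sig.target in {"dg", "phi"}:
        c, r, _ = sig.site.ends["five"]
        return residue_indices(c, r)
    if sig.target == "dw":
        c, r = sig.site.unpaired
        return residue_indices(c, r)
    if sig.target == "probe_distance":
        c, r = sig.anchors["probe"]
        return residue_indices(c, r)
    raise ValueError(sig.target)


_ORDER = {"phi": 0, "dg": 1, "dw": 2, "probe_distance": 3}


def make_trajectory(model: StructureModel, signals: Sequence[DeformationSignal],
                    n_frames: int | None = None, dt_ps: float = 10.0,
                    seed: int = 0, shlmap=None,
                    global_noise_sigma: float = 0.0,
                    ar1_corr: float = 0.0,
                    ) -> tuple[Trajectory, pd.DataFrame]:
    """Generate a seeded trajectory in which each signal's observable hits
    its schedule exactly, then add Gaussian noise.

    Per-signal noise is Gaussian in observable space (sigma in the signal's
    units), clipped at 3 sigma and applied through the same deformation
    operator, so analysis code recovers every schedule within 3 sigma by
    construction. ``global_noise_sigma`` (nm) adds i.i.d. per-atom jitter,
    with optional AR(1) frame correlation ``ar1_corr`` in [0, 1).

    Returns the trajectory and a tidy ground-truth log with the pre-noise
    achieved value of every signal at every frame.
    """
    signals = list(signals)
    if n_frames is None:
        if signals:
            n_frames = len(signals[0].schedule)
        else:
            raise ValueError("n_frames required when no signals given")
    for sig in signals:
        if len(sig.schedule) != n_frames:
            raise ValueError(f"signal {sig.target}: schedule length "
                             f"{len(sig.schedule)} != n_frames {n_frames}")

    # composition check: only phi+dg on the same site may share atoms
    claimed: dict[int, DeformationSignal] = {}
    for sig in signals:
        for i in _signal_atom_indices(model, sig):
            other = claimed.get(i)
            if other is not None:
                pair = {other.target, sig.target}
                same_site = other.site is sig.site
                if not (pair == {"phi", "dg"} and same_site):
                    raise CompositionError(
                        f"signals {other.target!r} and {sig.target!r} both "
                        f"move atom index {i}")
            claimed[i] = sig

    signals.sort(key=lambda s: _ORDER[s.target])
    phi_sites = {id(s.site) for s in signals if s.target == "phi"}
    for s in signals:
        if s.target == "dg" and id(s.site) in phi_sites:
            s.anchors["share_phi"] = True
    rng = np.random.default_rng(seed)
    sig_rngs = [np.random.default_rng(s.seed) if s.seed is not None
                else np.random.default_rng(rng.integers(2 ** 63))
                for s in signals]

    # pre-resolve anchors
    plans = [_plan_signal(model, s, shlmap) for s in signals]

    base = model.coords()
    n_atoms = base.shape[0]
    frames: list[np.ndarray] = []
    truth_rows: list[dict] = []
    ar_state = np.zeros((n_atoms, 3))
    for f in range(n_frames):
        coords = base.copy()
        for sig, plan in zip(signals, plans):
            achieved = plan["apply"](coords, float(sig.schedule[f]))
            truth_rows.append({"frame": f, "time_ps": f * dt_ps,
                               "target": sig.target,
                               "scheduled": float(sig.schedule[f]),
                               "achieved": achieved,
                               "units": "degrees" if sig.target == "phi" else "nm"})
        for sig, plan, srng in zip(signals, plans, sig_rngs):
            if sig.noise_sigma <= 0:
                continue
            # observable-space noise, clipped at 3 sigma: the documented
            # parameter-recovery bound (max error < 3 sigma) is structural,
            # not probabilistic
            bound = (3.0 - 1e-6) * sig.noise_sigma
            eps = float(np.clip(srng.normal(0.0, sig.noise_sigma),
                                -bound, bound))
            if sig.target == "phi":
                plan["jitter_rotation"](coords, eps)
            else:
                plan["apply"](coords, float(sig.schedule[f]) + eps)
        if global_noise_sigma > 0:
            white = rng.normal(0.0, global_noise_sigma * observables.A_PER_NM,
                               size=(n_atoms, 3))
            if ar1_corr > 0:
                ar_state = (ar1_corr * ar_state
                            + np.sqrt(1 - ar1_corr ** 2) * white)
                coords += ar_state
            else:
                coords += white
        frames.append(coords)
    traj = Trajectory(model.copy(), frames,
                      np.arange(n_frames, dtype=float) * dt_ps)
    return traj, pd.DataFrame(truth_rows)


def _plan_signal(model: StructureModel, sig: DeformationSignal, shlmap):
    """Compile a signal into an apply(coords, target) -> achieved closure."""
    A = observables.A_PER_NM
    moved = np.array(sorted(_signal_atom_indices(model, sig)), dtype=int)

    if sig.target == "dg":
        site = sig.site
        a_i = site.three_c3_index(model)
        d_i = site.five_c3_index(model)
        # when a phi signal shares this site, slide along the partner-pair
        # axis instead of the gap vector: that path leaves the dihedral
        # azimuth (and hence phi) unchanged
        has_phi_partner = bool(sig.anchors.get("share_phi")) and bool(site.phi_anchors)
        if has_phi_partner:
            b_i = model.atom_index(site.phi_anchors[1][0],
                                   site.phi_anchors[1][1], "C3'")
            c_i = model.atom_index(site.phi_anchors[2][0],
                                   site.phi_anchors[2][1], "C3'")

        def apply(coords, target_nm):
            target = target_nm * A
            a, d = coords[a_i], coords[d_i]
            if has_phi_partner:
                axis = coords[c_i] - coords[b_i]
            else:
                axis = d - a
            u = axis / np.linalg.norm(axis)
            k = (d - a) @ u
            disc = k * k - ((d - a) @ (d - a) - target * target)
            if disc < 0:
                raise ValueError(f"dg target {target_nm} nm unreachable "
                                 "along slide axis")
            roots = np.array([-k + np.sqrt(disc), -k - np.sqrt(disc)])
            t = roots[np.argmin(np.abs(roots))]
            coords[moved] += t * u
            return float(np.linalg.norm(coords[d_i] - coords[a_i])) / A

        return {"apply": apply, "moved": moved}

    if sig.target == "phi":
        site = sig.site
        idx = site.phi_indices(model)
        a_i, b_i, c_i, d_i = idx

        def rotate(coords, angle_deg):
            axis = coords[c_i] - coords[b_i]
            origin = coords[b_i].copy()
            from .damage import _rodrigues
            Rm = _rodrigues(axis, np.radians(angle_deg))
            coords[moved] = origin + (coords[moved] - origin) @ Rm.T

        def current(coords):
            return observables.dihedral_deg(coords[a_i], coords[b_i],
                                            coords[c_i], coords[d_i])

        def apply(coords, target_deg):
            phi0 = current(coords)
            want = np.sign(phi0 or 1.0) * target_deg
            rotate(coords, want - phi0)
            if abs(abs(current(coords)) - target_deg) > 1e-6:
                rotate(coords, -2 * (want - phi0))
            return abs(current(coords))

        return {"apply": apply, "moved": moved, "jitter_rotation": rotate}

    if sig.target == "dw":
        site = sig.site
        if shlmap is None:
            raise ValueError("dw signal requires an SHL map")
        key = site.unpaired if isinstance(site, DamageSite) else tuple(site)
        partner = sig.anchors.get("partner")
        if partner is None:
            partner = observables.pick_gyre_partner(model, None, site, shlmap)
        p_i = model.atom_index(key[0], key[1], "P")
        q_i = model.atom_index(partner[0], partner[1], "P")
        axis = np.asarray(shlmap.axis, float)

        def apply(coords, target_nm):
            target = target_nm * A
            p, q = coords[p_i], coords[q_i]
            u = axis
            k = (p - q) @ u
            disc = k * k - ((p - q) @ (p - q) - target * target)
            if disc < 0:
                raise ValueError(f"dw target {target_nm} nm unreachable "
                                 "along the superhelical axis")
            roots = np.array([-k + np.sqrt(disc), -k - np.sqrt(disc)])
            t = roots[np.argmin(np.abs(roots))]
            coords[moved] += t * u
            return float(np.linalg.norm(coords[p_i] - coords[q_i])) / A

        return {"apply": apply, "moved": moved}

    if sig.target == "probe_distance":
        pc, pr = sig.anchors["probe"]
        ac, ar, aname = sig.anchors["anchor"]
        probe_i = model.atom_index(pc, pr, "CA")
        anchor_i = model.atom_index(ac, ar, aname)
        d0 = model.coords()[probe_i] - model.coords()[anchor_i]
        nd0 = np.linalg.norm(d0)
        direction = d0 / nd0 if nd0 > 1e-9 else np.array([1.0, 0.0, 0.0])

        def apply(coords, target_nm):
            target = target_nm * A
            pos = coords[anchor_i] + target * direction
            coords[moved] += pos - coords[probe_i]
            return float(np.linalg.norm(coords[probe_i] - coords[anchor_i])) / A

        return {"apply": apply, "moved": moved}

    raise ValueError(sig.target)
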