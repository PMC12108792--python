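"""Protein-DNA interface descriptors: numerical SASA, buried interface area,
and hydrogen-bond / salt-bridge / hydrophobic contact counts with optional
single-residue (damage-site) splits.

SASA is a Shrake-Rupley-style sphere sampling on a deterministic Fibonacci
lattice. Contact cutoffs are community defaults (donor-acceptor 3.5 A,
salt bridge 4.0 A, carbon-carbon 4.5 A) and are configurable; solvation
free energies are never computed here — the report keeps an optional field
for externally imported values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _chem
from .structure_io import AtomSet, StructureModel, select

__all__ = ["InterfaceReport", "sasa", "interface_area", "count_contacts",
           "interface_report", "RadiusError"]


class RadiusError(KeyError):
    pass


@dataclass
class InterfaceReport:
    partner_a: str
    partner_b: str
    interface_area: float
    hbonds_total: int
    hbonds_site: int
    salt_bridges_total: int
    salt_bridges_site: int
    hydrophobic_total: int
    hydrophobic_site: int
    per_contact: list = field(default_factory=list)
    delta_gs: float | None = None   # imported externally, never computed

    def __post_init__(self):
        if self.interface_area < 0:
            raise ValueError("interface area must be nonnegative")
        for total, site in ((self.hbonds_total, self.hbonds_site),
                            (self.salt_bridges_total, self.salt_bridges_site),
                            (self.hydrophobic_total, self.hydrophobic_site)):
            if site > total:
                raise ValueError("site-restricted count exceeds total")

    def to_dict(self) -> dict:
        return {
            "partner_a": self.partner_a, "partner_b": self.partner_b,
            "interface_area_A2": self.interface_area,
            "hbonds": [self.hbonds_total, self.hbonds_site],
            "salt_bridges": [self.salt_bridges_total, self.salt_bridges_site],
            "hydrophobic": [self.hydrophobic_total, self.hydrophobic_site],
            "delta_gs_kcal_mol": self.delta_gs,
            "contacts": self.per_contact,
        }


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _resolve(model: StructureModel, sel) -> AtomSet:
    if isinstance(sel, AtomSet):
        return sel
    if sel is None:
        return select(model)
    return select(model, sel)


def _radii(atomset: AtomSet) -> np.ndarray:
    out = np.empty(len(atomset))
    for i, a in enumerate(atomset.atoms):
        try:
            out[i] = _chem.vdw_radius(a.element)
        except KeyError:
            raise RadiusError(f"no radius for atom {a.name!r} "
                              f"(element {a.element!r})") from None
    return out


def sasa(model: StructureModel, selection=None, probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> tuple[np.ndarray, float]:
    """Per-atom and total solvent-accessible surface area, A^2.

    Deterministic for a fixed point count (Fibonacci sphere sampling)."""
    atoms = _resolve(model, selection)
    if len(atoms) == 0:
        return np.zeros(0), 0.0
    xyz = atoms.coords()
    radii = _radii(atoms) + probe_radius
    sphere = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(xyz)
    areas = np.zeros(len(atoms))
    max_r = radii.max()
    for i in range(len(atoms)):
        pts = xyz[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            diff = pts[:, None, :] - xyz[nb][None, :, :]
            d2 = (diff ** 2).sum(axis=2)
            r2 = (radii[nb] ** 2)[None, :]
            eps = 1e-6 * r2
            inside = d2 < r2 - eps
            # points exactly on a neighbor's surface (coincident atoms):
            # the lower-index atom owns the shared boundary
            on_surface = (np.abs(d2 - r2) <= eps) & (nb < i)[None, :]
            buried = (inside | on_surface).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4 * np.pi * radii[i] ** 2 * frac
    return areas, float(areas.sum())


def interface_area(model: StructureModel, part_a, part_b,
                   probe_radius: float = 1.4,
                   n_sphere_points: int = 960) -> float:
    """Buried interface area: (SASA(a) + SASA(b) - SASA(a+b)) / 2, A^2."""
    sa = _resolve(model, part_a)
    sb = _resolve(model, part_b)
    if set(sa.indices) & set(sb.indices):
        raise ValueError("interface partners overlap")
    sub_a = _submodel(model, sa)
    sub_b = _submodel(model, sb)
    sub_ab = _submodel(model, sa, sb)
    _, area_a = sasa(sub_a, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    _, area_b = sasa(sub_b, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    _, area_ab = sasa(sub_ab, probe_radius=probe_radius, n_sphere_points=n_sphere_points)
    return max(0.0, (area_a + area_b - area_ab) / 2.0)


def _submodel(model: StructureModel, *atomsets: AtomSet) -> StructureModel:
    """A throwaway model containing only the given atoms (for SASA)."""
    from .structure_io import Atom, Chain, Residue
    out = StructureModel()
    cur_res_key = None
    cur_res = None
    cur_chain = None
    for aset in atomsets:
        for res, atom in aset.members:
            key = (res.chain_id, res.resid, res.icode)
            if key != cur_res_key:
                if cur_chain is None or cur_chain.chain_id != res.chain_id:
                    cur_chain = Chain(res.chain_id)
                    out.chains.append(cur_chain)
                cur_res = Residue(res.resname, res.resid, res.chain_id, icode=res.icode)
                cur_chain.residues.append(cur_res)
                cur_res_key = key
            cur_res.atoms.append(Atom(atom.name, atom.element, atom.coord.copy()))
    return out


def count_contacts(model: StructureModel, part_a, part_b, kind: str,
                   site_filter: tuple[str, int] | None = None,
                   hbond_cutoff: float = 3.5, salt_cutoff: float = 4.0,
                   hydrophobic_cutoff: float = 4.5) -> tuple[int, int, list]:
    """Count interface contacts of one kind between two selections.

    hbond: donor/acceptor heavy-atom pairs within the cutoff (typing from
    bundled tables, either direction across the interface);
    salt_bridge: charged-group N/O pairs (Arg/Lys/His vs Asp/Glu/phosphate);
    hydrophobic: apolar residue pairs with any C-C under the cutoff, counted
    per residue pair. Returns (total, site_restricted, contact records).
    """
    sa = _resolve(model, part_a)
    sb = _resolve(model, part_b)
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError("empty selection")
    res_a = sa.residues
    res_b = sb.residues
    contacts = []
    if kind == "hbond":
        contacts = (_typed_pairs(res_a, res_b, _chem.donor_atoms,
                                 _chem.acceptor_atoms, hbond_cutoff)
                    + _typed_pairs(res_a, res_b, _chem.acceptor_atoms,
                                   _chem.donor_atoms, hbond_cutoff))
        # a donor-acceptor pair counted from both directions collapses to one
        seen = set()
        uniq = []
        for c in contacts:
            key = frozenset([(c["res_a"], c["atom_a"]), (c["res_b"], c["atom_b"])])
            if key not in seen:
                seen.add(key)
                uniq.append(c)
        contacts = uniq
    elif kind == "salt_bridge":
        contacts = (_typed_pairs(res_a, res_b, _chem.cation_atoms,
                                 _chem.anion_atoms, salt_cutoff)
                    + _typed_pairs(res_a, res_b, _chem.anion_atoms,
                                   _chem.cation_atoms, salt_cutoff))
    elif kind == "hydrophobic":
        for ra in res_a:
            ca = _chem.apolar_carbons(ra)
            if not ca:
                continue
            xa = np.array([a.coord for a in ca])
            for rb in res_b:
                cb = _chem.apolar_carbons(rb)
                if not cb:
                    continue
                xb = np.array([a.coord for a in cb])
                d = np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(2))
                if d.min() <= hydrophobic_cutoff:
                    contacts.append({"res_a": (ra.chain_id, ra.resid),
                                     "res_b": (rb.chain_id, rb.resid),
                                     "atom_a": "", "atom_b": "",
                                     "distance": float(d.min())})
    else:
        raise ValueError(f"unknown contact kind {kind!r}")
    total = len(contacts)
    if site_filter is None:
        site = 0
    else:
        sf = tuple(site_filter)
        site = sum(1 for c in contacts if c["res_a"] == sf or c["res_b"] == sf)
    return total, site, contacts


def _typed_pairs(res_a, res_b, type_fn_a, type_fn_b, cutoff):
    atoms_a = [(r, a) for r in res_a for a in type_fn_a(r)]
    atoms_b = [(r, a) for r in res_b for a in type_fn_b(r)]
    out = []
    if not atoms_a or not atoms_b:
        return out
    xb = np.array([a.coord for _, a in atoms_b])
    for ra, aa in atoms_a:
        d = np.linalg.norm(xb - aa.coord, axis=1)
        for j in np.where(d <= cutoff)[0]:
            rb, ab = atoms_b[j]
            out.append({"res_a": (ra.chain_id, ra.resid),
                        "res_b": (rb.chain_id, rb.resid),
                        "atom_a": aa.name, "atom_b": ab.name,
                        "distance": float(d[j])})
    return out


def interface_report(model: StructureModel, part_a, part_b,
                     site: tuple[str, int] | None = None,
                     label_a: str = "a", label_b: str = "b",
                     **kwargs) -> InterfaceReport:
    """Full interface descriptor set for one structure."""
    area = interface_area(model, part_a, part_b,
                          probe_radius=kwargs.get("probe_radius", 1.4),
                          n_sphere_points=kwargs.get("n_sphere_points", 960))
    hb_t, hb_s, hb = count_contacts(model, part_a, part_b, "hbond", site)
    sb_t, sb_s, _ = count_contacts(model, part_a, part_b, "salt_bridge", site)
    hp_t, hp_s, _ = count_contacts(model, part_a, part_b, "hydrophobic", site)
    return InterfaceReport(
        partner_a=label_a, partner_b=label_b, interface_area=area,
        hbonds_total=hb_t, hbonds_site=hb_s,
        salt_bridges_total=sb_t, salt_bridges_site=sb_s,
        hydrophobic_total=hp_t, hydrophobic_site=hp_s,
        per_contact=hb)
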