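"""DNA damage constructs: base substitution, extrahelical flipping, and
single-strand breaks with defined termini.

All builders are purely geometric: only the documented atoms change, nothing
is energy-minimized, and hydrogens are never synthesized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _chem
from .structure_io import (Atom, Residue, StructureModel, normalize_atom_name)

__all__ = ["DamageSite", "DamageError", "swap_base", "flip_base", "make_ssb",
           "set_flank_motif", "antiparallel_pairs"]


class DamageError(ValueError):
    pass


@dataclass
class DamageSite:
    """A located lesion and the atom anchors observables need.

    For an SSB, ``ends`` holds the 5' and 3' terminus records
    ``(chain, resid, cap)`` flanking the removed nucleotide, ``unpaired``
    the opposite-strand residue left without a partner, and ``phi_anchors``
    the ordered (chain, resid) quadruple whose C3' atoms define the local
    twist dihedral.
    """

    kind: str                       # uracil-swap | flipped-base | ssb
    anchor: tuple[str, int]
    shl: float | None = None
    ends: dict | None = None
    unpaired: tuple[str, int] | None = None
    rotation_deg: float | None = None
    phi_anchors: list[tuple[str, int]] | None = None

    def __post_init__(self):
        if self.kind not in {"uracil-swap", "flipped-base", "ssb"}:
            raise ValueError(f"unknown damage kind {self.kind!r}")
        if self.kind == "ssb":
            if not self.ends:
                raise ValueError("ssb site requires ends")
            c5, r5, _ = self.ends["five"]
            c3, r3, _ = self.ends["three"]
            if c5 != c3 or abs(r5 - r3) != 2:
                raise ValueError("ssb ends must flank a removed nucleotide "
                                 "(resid gap of exactly 1)")

    # -- anchor atom handles ------------------------------------------------
    def three_c3_index(self, model: StructureModel) -> int:
        c, r, _ = self.ends["three"]
        return model.atom_index(c, r, "C3'")

    def five_c3_index(self, model: StructureModel) -> int:
        c, r, _ = self.ends["five"]
        return model.atom_index(c, r, "C3'")

    def unpaired_p_index(self, model: StructureModel) -> int:
        c, r = self.unpaired
        return model.atom_index(c, r, "P")

    def phi_indices(self, model: StructureModel) -> list[int]:
        if not self.phi_anchors:
            raise DamageError("site has no phi anchors")
        return [model.atom_index(c, r, "C3'") for c, r in self.phi_anchors]

    # -- (de)serialization --------------------------------------------------
    def to_json(self, path=None) -> str:
        d = asdict(self)
        s = json.dumps(d, indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "DamageSite":
        if hasattr(source, "read"):
            d = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        d["anchor"] = tuple(d["anchor"])
        if d.get("unpaired"):
            d["unpaired"] = tuple(d["unpaired"])
        if d.get("ends"):
            d["ends"] = {k: tuple(v) for k, v in d["ends"].items()}
        if d.get("phi_anchors"):
            d["phi_anchors"] = [tuple(x) for x in d["phi_anchors"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def antiparallel_pairs(model: StructureModel, dna_chains: Sequence[str],
                       pairing: Sequence[tuple[int, int]] | None = None,
                       ) -> list[tuple[Residue, Residue]]:
    """Base pairs of two DNA chains by antiparallel index pairing.

    Residue i of the first chain pairs with residue n-1-i of the second.
    An explicit ``pairing`` table of (resid_i, resid_j) overrides this for
    chains of unequal length.
    """
    ci, cj = (model.chain(c) for c in dna_chains)
    ri = [r for r in ci.residues if r.kind == "nucleotide"]
    rj = [r for r in cj.residues if r.kind == "nucleotide"]
    if pairing is not None:
        bi = {r.resid: r for r in ri}
        bj = {r.resid: r for r in rj}
        return [(bi[a], bj[b]) for a, b in pairing]
    if len(ri) != len(rj):
        raise DamageError(
            f"chains {dna_chains[0]}/{dna_chains[1]} have unequal lengths "
            f"({len(ri)} vs {len(rj)}) and no pairing table was given")
    return list(zip(ri, rj[::-1]))


def _frame_from_residue(res: Residue):
    """Glycosidic frame (c1 position, e1, e2) of an existing nucleotide."""
    c1 = res.atom("C1'")
    if c1 is None:
        raise DamageError(f"{res.chain_id}:{res.resid}: missing C1'")
    glyc = res.atom("N1") or res.atom("N9")
    base = _chem.base_atoms(res)
    if glyc is None:
        if not base:
            raise DamageError(f"{res.chain_id}:{res.resid}: no base atoms to orient on")
        cen = np.mean([a.coord for a in base], axis=0)
        e1 = cen - c1.coord
    else:
        e1 = glyc.coord - c1.coord
    e1 = e1 / np.linalg.norm(e1)
    origin = c1.coord + _chem.GLYCOSIDIC_BOND * e1
    orient = res.atom("C2") if glyc is None or glyc.name == "N1" else res.atom("C8")
    if orient is None:
        orient = res.atom("C2") or res.atom("C8")
    if orient is not None:
        v = orient.coord - origin
    else:
        cen = np.mean([a.coord for a in base], axis=0) if base else origin + np.array([0, 1.0, 0])
        v = cen - origin
    e2 = v - (v @ e1) * e1
    n = np.linalg.norm(e2)
    if n < 1e-6:
        # degenerate orientation: any perpendicular will do
        e2 = np.cross(e1, [0.0, 0.0, 1.0])
        if np.linalg.norm(e2) < 1e-6:
            e2 = np.cross(e1, [0.0, 1.0, 0.0])
        n = np.linalg.norm(e2)
    return c1.coord, e1, e2 / n


def _strand_neighbors(model: StructureModel, res: Residue):
    chain = model.chain(res.chain_id)
    idx = chain.residues.index(res)
    prev = chain.residues[idx - 1] if idx > 0 else None
    nxt = chain.residues[idx + 1] if idx < len(chain.residues) - 1 else None
    return prev, nxt


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def swap_base(model: StructureModel, site: tuple[str, int], new_base: str,
              clash_tol: float = 0.5) -> tuple[StructureModel, DamageSite]:
    """Replace the base of a nucleotide with an idealized ``new_base``.

    Backbone and sugar atoms are untouched; the new base is placed on the
    existing glycosidic frame. T->U removes exactly the C7 methyl.
    """
    new_base = new_base.upper()
    if new_base not in _chem.BASE_TEMPLATES:
        raise DamageError(f"unknown base {new_base!r}")
    out = model.copy()
    res = out.residue(*site)
    if res.kind != "nucleotide":
        raise DamageError(f"{site}: not a nucleotide")
    c1, e1, e2 = _frame_from_residue(res)
    placed = _chem.place_base_template(new_base, c1, e1, e2)
    keep = [a for a in res.atoms
            if a.name in _chem.BACKBONE_SUGAR_NAMES or a.name.startswith("H")]
    new_atoms = [Atom(nm, "", pos) for nm, pos in placed]
    # clash check against own backbone
    if keep:
        bb = np.array([a.coord for a in keep])
        for a in new_atoms:
            d = np.min(np.linalg.norm(bb - a.coord, axis=1))
            if d < clash_tol:
                warnings.warn(f"swap_base {site}: atom {a.name} within "
                              f"{d:.2f} A of backbone", stacklevel=2)
                break
    res.atoms = keep + new_atoms
    res.resname = _chem.RESNAME_OF_BASE[new_base]
    out.invalidate()
    return out, DamageSite(kind="uracil-swap", anchor=tuple(site))


def flip_base(model: StructureModel, site: tuple[str, int],
              angle_deg: float = 180.0) -> tuple[StructureModel, DamageSite]:
    """Rotate a nucleoside into extrahelical position about the axis through
    the flanking phosphate P atoms. Backbone phosphates stay fixed."""
    out = model.copy()
    res = out.residue(*site)
    if res.kind != "nucleotide":
        raise DamageError(f"{site}: not a nucleotide")
    _, nxt = _strand_neighbors(out, res)
    p_self = res.atom("P")
    p_next = nxt.atom("P") if nxt is not None else None
    if p_self is None or p_next is None:
        raise DamageError(f"{site}: terminal nucleotide, flanking phosphates missing")
    axis_origin = p_self.coord.copy()
    axis = p_next.coord - p_self.coord
    axis = axis / np.linalg.norm(axis)
    rot = _rodrigues(axis, np.radians(angle_deg))
    frozen = {"P", "OP1", "OP2", "O1P", "O2P"}
    for a in res.atoms:
        if a.name in frozen:
            continue
        a.coord = axis_origin + rot @ (a.coord - axis_origin)
    out.invalidate()
    return out, DamageSite(kind="flipped-base", anchor=tuple(site),
                           rotation_deg=float(angle_deg))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.asarray(axis, float)
    k = k / np.linalg.norm(k)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_ssb(model: StructureModel, site: tuple[str, int],
             five_cap: str = "drp", three_cap: str = "OH",
             dna_chains: Sequence[str] | None = None,
             ) -> tuple[StructureModel, DamageSite]:
    """Delete one whole nucleotide and fix the hanging termini.

    The 3' neighbour keeps (or gains) its O3' as a 3'-OH terminus; the 5'
    neighbour carries the chosen cap: ``'phosphate'`` keeps its own 5'-P,
    ``'drp'`` additionally grafts an abasic deoxyribose-phosphate (atoms of
    the excised sugar, renamed with an R suffix). The opposite-strand
    partner is flagged unpaired. No other atom moves.
    """
    five_cap = five_cap.lower()
    if five_cap not in {"drp", "phosphate", "oh"}:
        raise DamageError(f"unknown 5' cap {five_cap!r}")
    if three_cap.upper() not in {"OH", "PHOSPHATE"}:
        raise DamageError(f"unknown 3' cap {three_cap!r}")
    out = model.copy()
    res = out.residue(*site)
    if res.kind != "nucleotide":
        raise DamageError(f"{site}: not a nucleotide")
    prev, nxt = _strand_neighbors(out, res)
    if prev is None or nxt is None:
        raise DamageError(f"{site}: cannot break at a chain terminus")
    for nb, nm in ((prev, "C3'"), (nxt, "C3'")):
        if nb.atom(nm) is None:
            raise DamageError(f"{nb.chain_id}:{nb.resid}: missing backbone atom {nm}")

    # unpaired partner on the opposite strand (antiparallel index pairing)
    unpaired = None
    partner_of: dict[tuple[str, int], tuple[str, int]] = {}
    if dna_chains is None:
        dna_chains = _guess_dna_chains(out, site[0])
    if dna_chains is not None:
        try:
            pairs = antiparallel_pairs(out, dna_chains)
            for ri, rj in pairs:
                partner_of[ri.key] = rj.key
                partner_of[rj.key] = ri.key
            unpaired = partner_of.get(res.key)
        except DamageError:
            pass

    if five_cap == "drp":
        # graft the excised deoxyribose-phosphate onto the 5' neighbour
        rename = {"P": "PR", "O5'": "O5R", "C5'": "C5R", "C4'": "C4R",
                  "O4'": "O4R", "C3'": "C3R", "C2'": "C2R", "C1'": "C1R"}
        for a in res.atoms:
            if a.name in rename:
                nxt.atoms.append(Atom(rename[a.name], a.element, a.coord.copy()))

    chain = out.chain(res.chain_id)
    chain.residues.remove(res)
    out.invalidate()

    ends = {"five": (nxt.chain_id, nxt.resid, "dRP" if five_cap == "drp" else five_cap),
            "three": (prev.chain_id, prev.resid, three_cap.upper())}
    phi = None
    if partner_of:
        pp = partner_of.get(prev.key)
        pn = partner_of.get(nxt.key)
        if pp and pn:
            phi = [prev.key, pp, pn, nxt.key]
    return out, DamageSite(kind="ssb", anchor=tuple(site), ends=ends,
                           unpaired=unpaired, phi_anchors=phi)


def _guess_dna_chains(model: StructureModel, anchor_chain: str):
    nuc_chains = [ch.chain_id for ch in model.chains
                  if any(r.kind == "nucleotide" for r in ch.residues)]
    if len(nuc_chains) == 2 and anchor_chain in nuc_chains:
        if nuc_chains[0] != anchor_chain:
            nuc_chains.reverse()
        return nuc_chains
    return None


def set_flank_motif(model: StructureModel, ssb_site: DamageSite,
                    motif: str = "G*G", opposite: str = "CTC",
                    dna_chains: Sequence[str] | None = None) -> StructureModel:
    """Force the SSB flanking sequence to the default 5'-G*G-3' / 3'-CTC-5'
    motif, applying base swaps only where needed (idempotent)."""
    if len(motif) != 3 or motif[1] != "*" or len(opposite) != 3:
        raise DamageError("motif must be like 'G*G' with a 3-letter opposite")
    if ssb_site.kind != "ssb":
        raise DamageError("flank motif applies to ssb sites only")
    c3, r3, _ = ssb_site.ends["three"]   # 5'-side flank (upstream of gap)
    c5, r5, _ = ssb_site.ends["five"]    # 3'-side flank (downstream)
    out = model
    targets = [((c3, r3), motif[0]), ((c5, r5), motif[2])]
    # opposite triplet given 3'->5', aligned with the cut strand read 5'->3';
    # flank partners were recorded at construction time (phi_anchors)
    if ssb_site.phi_anchors:
        opp_keys = [ssb_site.phi_anchors[1], ssb_site.unpaired,
                    ssb_site.phi_anchors[2]]
        for key, want in zip(opp_keys, opposite):
            if key is not None:
                targets.append((tuple(key), want))
    for key, want in targets:
        res = out.residue(*key)
        cur = _chem.BASE_OF_RESNAME.get(res.resname.upper())
        if cur != want:
            out, _ = swap_base(out, key, want)
    return out
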