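"""Molecular coordinate I/O and atom selection.

Reads and writes the PDB dialect used throughout the package (fixed-column
ATOM/HETATM/MODEL/TER records) into a small hierarchical model, and provides
the selection primitive every analysis module builds on.

Conventions
-----------
* Internal length unit is Angstrom.
* Atom-name primes are accepted as ``'``, ``′`` or ``*`` and
  canonicalized to the ASCII apostrophe (``C3'``).
* Residue numbering is author numbering; nothing is renumbered on read.
* Alternate locations resolve to the highest occupancy, ties to the first
  encountered.
* Atom serials above 99999 wrap modulo 100000 on write (GROMACS-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "Trajectory",
    "AtomSet",
    "FormatError",
    "TopologyError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "normalize_atom_name",
]

# Residues dropped on read when ignore_solvent is set.
SOLVENT_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP", "NA", "CL", "K", "MG", "NA+", "CL-"}

NUCLEOTIDE_RESNAMES = {
    "DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U",
    "ADE", "THY", "GUA", "CYT", "URA", "DRP",
}

AMINO_ACID_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "MSE",
}


class FormatError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class TopologyError(ValueError):
    """Raised when frame/topology atom counts disagree."""


class SelectionError(ValueError):
    """Raised for malformed selection expressions."""


def normalize_atom_name(name: str) -> str:
    """Canonicalize prime marks in atom names (C3* / C3′ -> C3')."""
    return name.strip().replace("′", "'").replace("*", "'").upper()


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    serial: int = 0

    def __post_init__(self):
        self.name = normalize_atom_name(self.name)
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not self.element:
            self.element = _guess_element(self.name)


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            # two-letter elements occurring in biomolecular PDB files
            if name[:2].upper() in {"FE", "ZN", "MG", "MN", "NA", "CL", "BR"}:
                return name[:2].capitalize()
            return ch.upper()
    return "X"


@dataclass
class Residue:
    resname: str
    resid: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def kind(self) -> str:
        if self.resname.upper() in NUCLEOTIDE_RESNAMES:
            return "nucleotide"
        if self.resname.upper() in AMINO_ACID_RESNAMES:
            return "amino-acid"
        return "other"

    def atom(self, name: str) -> Atom | None:
        name = normalize_atom_name(name)
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.resid)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


class StructureModel:
    """Ordered chains of ordered residues of ordered atoms."""

    def __init__(self, chains: Sequence[Chain] | None = None, title: str = ""):
        self.chains: list[Chain] = list(chains) if chains else []
        self.title = title
        self._index: dict[tuple[str, int, str], Residue] | None = None
        self._atom_index: dict[tuple[str, int, str], int] | None = None

    # -- iteration ---------------------------------------------------------
    def iter_residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.iter_residues():
            for a in res.atoms:
                yield res, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array in model order."""
        return np.array([a.coord for _, a in self.iter_atoms()], dtype=float).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError(f"expected {(self.n_atoms, 3)}, got {coords.shape}")
        for (res, a), xyz in zip(self.iter_atoms(), coords):
            a.coord = np.array(xyz, dtype=float)

    # -- lookup ------------------------------------------------------------
    def _build_index(self) -> None:
        self._index = {}
        self._atom_index = {}
        i = 0
        for res in self.iter_residues():
            self._index[(res.chain_id, res.resid, res.icode)] = res
            for a in res.atoms:
                self._atom_index[(res.chain_id, res.resid, a.name)] = i
                i += 1

    def invalidate(self) -> None:
        """Drop cached indices after a topology edit."""
        self._index = None
        self._atom_index = None

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r}")

    def residue(self, chain_id: str, resid: int, icode: str = "") -> Residue:
        if self._index is None:
            self._build_index()
        try:
            return self._index[(chain_id, resid, icode)]
        except KeyError:
            raise KeyError(f"no residue {chain_id}:{resid}{icode}") from None

    def atom_index(self, chain_id: str, resid: int, name: str) -> int:
        """Flat index of an atom in model order; raises KeyError if absent."""
        if self._atom_index is None:
            self._build_index()
        key = (chain_id, resid, normalize_atom_name(name))
        try:
            return self._atom_index[key]
        except KeyError:
            raise KeyError(f"no atom {chain_id}:{resid}:{name}") from None

    def validate(self) -> None:
        seen = set()
        for res in self.iter_residues():
            k = (res.chain_id, res.resid, res.icode)
            if k in seen:
                raise ValueError(f"duplicate residue {k}")
            seen.add(k)
            if not res.atoms:
                raise ValueError(f"residue {k} has no atoms")

    def copy(self) -> "StructureModel":
        chains = [
            Chain(ch.chain_id, [
                Residue(r.resname, r.resid, r.chain_id,
                        [Atom(a.name, a.element, a.coord.copy(), a.serial) for a in r.atoms],
                        r.icode)
                for r in ch.residues
            ])
            for ch in self.chains
        ]
        return StructureModel(chains, self.title)


@dataclass
class Trajectory:
    """Frames of coordinates sharing one topology."""

    topology: StructureModel
    frames: list[np.ndarray]
    times: np.ndarray | None = None

    def __post_init__(self):
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise TopologyError(f"frame {i}: expected {(n, 3)} coords, got {f.shape}")
            self.frames[i] = f
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise TopologyError("times length != frame count")
            if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_model(self, i: int) -> StructureModel:
        m = self.topology.copy()
        m.set_coords(self.frames[i])
        return m


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_record(line: str) -> dict:
    try:
        return {
            "serial": int(line[6:11].strip() or 0),
            "name": line[12:16],
            "altloc": line[16],
            "resname": line[17:20].strip() or line[17:21].strip(),
            "chain": line[21],
            "resid": int(line[22:26]),
            "icode": line[26].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "occ": float(line[54:60]) if line[54:60].strip() else 1.0,
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM record: {line.rstrip()!r}") from exc


def _records_to_model(records: Iterable[dict], title: str, ignore_solvent: bool) -> StructureModel:
    model = StructureModel(title=title)
    altloc_seen: dict[tuple, float] = {}
    cur_chain: Chain | None = None
    cur_res: Residue | None = None
    for rec in records:
        if ignore_solvent and rec["resname"].upper() in SOLVENT_RESNAMES:
            continue
        atom_key = (rec["chain"], rec["resid"], rec["icode"], normalize_atom_name(rec["name"]))
        if rec["altloc"] not in (" ", ""):
            best = altloc_seen.get(atom_key)
            if best is not None:
                if rec["occ"] > best:
                    # replace previously kept altloc in place
                    res = cur_res
                    if res is not None:
                        for a in res.atoms:
                            if a.name == normalize_atom_name(rec["name"]):
                                a.coord = np.array([rec["x"], rec["y"], rec["z"]])
                                a.serial = rec["serial"]
                        altloc_seen[atom_key] = rec["occ"]
                continue
            altloc_seen[atom_key] = rec["occ"]
        if cur_chain is None or cur_chain.chain_id != rec["chain"]:
            cur_chain = Chain(rec["chain"])
            model.chains.append(cur_chain)
            cur_res = None
        if (cur_res is None or cur_res.resid != rec["resid"]
                or cur_res.icode != rec["icode"] or cur_res.resname != rec["resname"]):
            cur_res = Residue(rec["resname"], rec["resid"], rec["chain"], icode=rec["icode"])
            cur_chain.residues.append(cur_res)
        cur_res.atoms.append(Atom(rec["name"], rec["element"],
                                  np.array([rec["x"], rec["y"], rec["z"]]), rec["serial"]))
    return model


def read_structure(path: str | Path, dialect: str = "pdb",
                   ignore_solvent: bool = True) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file into a :class:`StructureModel`.

    Only the first MODEL of a multi-model file is read; use
    :func:`read_trajectory` for ensembles.
    """
    if dialect != "pdb":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    title = ""
    records = []
    with open(path) as fh:
        for line in fh:
            tag = line[:6]
            if tag.startswith("TITLE"):
                title += line[10:].strip() + " "
            elif tag in ("ATOM  ", "HETATM"):
                records.append(_parse_atom_record(line))
            elif tag.startswith("ENDMDL"):
                break
    if not records:
        raise FormatError(f"{path}: no ATOM/HETATM records parsed")
    model = _records_to_model(records, title.strip(), ignore_solvent)
    return model


def _format_atom_name(name: str) -> str:
    # PDB convention: names of <4 chars start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(serial: int, a: Atom, res: Residue) -> str:
    s = serial % 100000  # hybrid wrap above 99999
    return (f"ATOM  {s:5d} {_format_atom_name(a.name)} {res.resname:>3.3s} "
            f"{res.chain_id}{res.resid % 10000:4d}{res.icode or ' '}   "
            f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n")


def _write_model_records(fh, model: StructureModel, serial_start: int = 1) -> int:
    serial = serial_start
    for ch in model.chains:
        for res in ch.residues:
            for a in res.atoms:
                fh.write(_atom_line(serial, a, res))
                serial += 1
        fh.write("TER\n")
    return serial


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as standard PDB (3-decimal coordinates, TER per chain)."""
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    with open(path, "w") as fh:
        if model.title:
            fh.write(f"TITLE     {model.title}\n")
        _write_model_records(fh, model)
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB with per-frame time remarks."""
    path = Path(path)
    top = traj.topology.copy()
    with open(path, "w") as fh:
        if top.title:
            fh.write(f"TITLE     {top.title}\n")
        for i, (frame, t) in enumerate(zip(traj.frames, traj.times), start=1):
            fh.write(f"MODEL     {i:4d}\n")
            fh.write(f"REMARK   6 TIME_PS {t:.4f}\n")
            top.set_coords(frame)
            _write_model_records(fh, top)
            fh.write("ENDMDL\n")
        fh.write("END\n")


FrameIterator = Iterable[tuple[np.ndarray, float | None]]


def read_trajectory(topology: StructureModel, path: str | Path | None = None,
                    format: str = "multi-model-pdb",
                    adapter: FrameIterator | Callable[[], FrameIterator] | None = None,
                    ) -> Trajectory:
    """Read a conformational ensemble sharing ``topology``.

    ``format='multi-model-pdb'`` parses MODEL blocks from ``path``;
    ``format='adapter'`` consumes any iterable yielding ``(coords, time)``
    pairs (the hook used for binary formats such as XTC/DCD, which the core
    never parses itself).
    """
    n = topology.n_atoms
    frames: list[np.ndarray] = []
    times: list[float] = []
    if format == "adapter":
        if adapter is None:
            raise ValueError("format='adapter' requires an adapter")
        it = adapter() if callable(adapter) else adapter
        for i, (coords, t) in enumerate(it):
            coords = np.asarray(coords, dtype=float)
            if coords.shape != (n, 3):
                raise TopologyError(f"frame {i}: atom count mismatch "
                                    f"({coords.shape[0]} vs topology {n})")
            frames.append(coords)
            times.append(float(t) if t is not None else float(i))
    elif format == "multi-model-pdb":
        if path is None:
            raise ValueError("path required for multi-model-pdb")
        cur: list[list[float]] = []
        cur_time: float | None = None
        seen_model = False
        with open(path) as fh:
            for line in fh:
                tag = line[:6]
                if tag.startswith("MODEL"):
                    seen_model = True
                    cur = []
                    cur_time = None
                elif tag in ("ATOM  ", "HETATM"):
                    rec = _parse_atom_record(line)
                    if rec["resname"].upper() in SOLVENT_RESNAMES:
                        continue
                    cur.append([rec["x"], rec["y"], rec["z"]])
                elif line.startswith("REMARK   6 TIME_PS"):
                    cur_time = float(line.split()[-1])
                elif tag.startswith("ENDMDL"):
                    _append_frame(frames, times, cur, cur_time, n)
                    cur = []
        if not seen_model and cur:
            # plain single-structure file: one frame
            _append_frame(frames, times, cur, cur_time, n)
        elif seen_model and cur:
            _append_frame(frames, times, cur, cur_time, n)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    if not frames:
        raise FormatError(f"{path}: no frames read")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        t = np.arange(len(frames), dtype=float)
    return Trajectory(topology, frames, t)


def _append_frame(frames, times, cur, cur_time, n):
    if not cur:
        return
    coords = np.asarray(cur, dtype=float)
    if coords.shape != (n, 3):
        raise TopologyError(f"frame {len(frames)}: atom count mismatch "
                            f"({coords.shape[0]} vs topology {n})")
    frames.append(coords)
    times.append(cur_time if cur_time is not None else float(len(frames) - 1))


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class AtomSet:
    """Ordered atom references into a model (model order preserved)."""

    model: StructureModel
    indices: np.ndarray                  # flat atom indices
    members: list[tuple[Residue, Atom]]  # parallel to indices

    def __len__(self) -> int:
        return len(self.members)

    def coords(self, frame: np.ndarray | None = None) -> np.ndarray:
        if frame is None:
            return np.array([a.coord for _, a in self.members]).reshape(-1, 3)
        frame = np.asarray(frame, dtype=float)
        return frame[self.indices]

    @property
    def atoms(self) -> list[Atom]:
        return [a for _, a in self.members]

    @property
    def residues(self) -> list[Residue]:
        seen, out = set(), []
        for r, _ in self.members:
            if id(r) not in seen:
                seen.add(id(r))
                out.append(r)
        return out


_FIELDS = {"chain": "chain", "chainid": "chain", "resid": "resid",
           "resname": "resname", "name": "name"}


def _parse_values(field: str, raw: str) -> set:
    vals = set()
    for tok in raw.split(","):
        tok = tok.strip()
        if not tok:
            continue
        if field == "resid":
            if "-" in tok[1:] or ":" in tok:
                sep = ":" if ":" in tok else "-"
                lo, hi = tok.split(sep, 1)
                vals.update(range(int(lo), int(hi) + 1))
            else:
                vals.add(int(tok))
        elif field == "name":
            vals.add(normalize_atom_name(tok))
        else:
            vals.add(tok.upper())
    return vals


def _parse_query(query: str) -> dict[str, set]:
    clauses: dict[str, set] = {}
    for part in query.split(" and "):
        part = part.strip()
        if not part:
            continue
        toks = part.replace("=", " ").split(None, 1)
        if len(toks) != 2 or toks[0].lower() not in _FIELDS:
            raise SelectionError(f"malformed selection clause {part!r}")
        field = _FIELDS[toks[0].lower()]
        vals = _parse_values(field, toks[1])
        if field in clauses:
            clauses[field] &= vals
        else:
            clauses[field] = vals
    return clauses


def select(model: StructureModel, query: str | None = None, *,
           chain: str | Sequence[str] | None = None,
           resid: int | Sequence[int] | None = None,
           resname: str | Sequence[str] | None = None,
           name: str | Sequence[str] | None = None,
           kind: str | None = None) -> AtomSet:
    """Select atoms matching all given clauses, in model order.

    Accepts either a query string (``"chain I and resid 34 and name C3'"``)
    or keyword clauses. Empty result is allowed.
    """
    clauses: dict[str, set] = _parse_query(query) if query else {}

    def as_set(v, field):
        if v is None:
            return None
        if isinstance(v, (str, int)):
            v = [v]
        return _parse_values(field, ",".join(str(x) for x in v))

    for field, v in (("chain", chain), ("resid", resid),
                     ("resname", resname), ("name", name)):
        s = as_set(v, field)
        if s is not None:
            clauses[field] = clauses.get(field, s) & s if field in clauses else s

    indices, members = [], []
    i = 0
    for res in model.iter_residues():
        res_ok = (("chain" not in clauses or res.chain_id.upper() in clauses["chain"])
                  and ("resid" not in clauses or res.resid in clauses["resid"])
                  and ("resname" not in clauses or res.resname.upper() in clauses["resname"])
                  and (kind is None or res.kind == kind))
        for a in res.atoms:
            if res_ok and ("name" not in clauses or a.name in clauses["name"]):
                indices.append(i)
                members.append((res, a))
            i += 1
    return AtomSet(model, np.asarray(indices, dtype=int), members)
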