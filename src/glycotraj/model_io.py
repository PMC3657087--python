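"""Structure/trajectory I/O, the topology data model, and atom selections.

Internal units are fixed throughout the package: lengths in nm, times in ps,
masses in amu, energies in kJ/mol, charges in units of the elementary charge.
PDB files (which are in Angstrom) are converted at the boundary.

Three text formats are understood:

* PDB (``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``CONECT``), read and written.
* A plain frames format: a header line ``natoms time_step`` followed, per
  frame, by one ``x y z`` line per atom (nm).
* A parameter sidecar: a whitespace table with one row per
  ``(resname, atomname)`` giving mass, charge and Lennard-Jones C6/C12 —
  the PDB format has no fields for these.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Topology",
    "Frame",
    "FrameStream",
    "Selection",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_frames",
    "read_parameter_sidecar",
    "read_energy_series",
    "select",
    "minimum_image",
]

ANGSTROM_PER_NM = 10.0

#: Default atomic masses (amu) by element symbol.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "MG": 24.305, "CL": 35.45, "K": 39.098,
    "CA": 40.078, "FE": 55.845, "ZN": 65.38, "SE": 78.971,
}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

BACKBONE_NAMES = {"N", "CA", "C", "O"}

# Side-chain bond templates for standard amino acids (heavy atoms and the
# polar hydrogens GROMOS-style topologies keep explicit).  Backbone bonds
# (N-H, N-CA, CA-C, C-O, CA-CB, inter-residue C-N) are added generically.
_SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2"), ("NE", "HE"),
            ("NH1", "HH11"), ("NH1", "HH12"), ("NH2", "HH21"), ("NH2", "HH22")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2"),
            ("ND2", "HD21"), ("ND2", "HD22")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG"), ("SG", "HG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2"),
            ("NE2", "HE21"), ("NE2", "HE22")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
            ("NE2", "CD2"), ("CD2", "CG"), ("ND1", "HD1"), ("NE2", "HE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ"),
            ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG"), ("OG", "HG")],
    "THR": [("CB", "OG1"), ("CB", "CG2"), ("OG1", "HG1")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2"), ("NE1", "HE1")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH"),
            ("OH", "HH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}


class PDBParseError(ValueError):
    """Raised for malformed PDB records, with the offending line number."""


class SelectionError(ValueError):
    """Raised for selection expressions that do not parse."""


@dataclass
class AtomRecord:
    """One atom of the topology.

    Charges and Lennard-Jones C6/C12 (kJ mol^-1 nm^6 / nm^12) default to zero
    and are normally supplied via the parameter sidecar.
    """

    name: str
    element: str
    mass: float
    charge: float = 0.0
    lj_c6: float = 0.0
    lj_c12: float = 0.0
    is_united_carbon: bool = False
    serial: int | None = None
    occupancy: float = 1.0
    bfactor: float = 0.0


@dataclass(frozen=True)
class Residue:
    resname: str
    resid: int
    chain: str
    start: int  # first atom index
    stop: int   # one past last atom index

    @property
    def atom_indices(self) -> range:
        return range(self.start, self.stop)


class Topology:
    """Static atom/residue/bond description of the system."""

    def __init__(self, atoms: Sequence[AtomRecord], residues: Sequence[Residue],
                 bonds: Iterable[tuple[int, int]] = ()):
        self.atoms: list[AtomRecord] = list(atoms)
        self.residues: list[Residue] = list(residues)
        self.bonds: list[tuple[int, int]] = []
        self._adj: dict[int, set[int]] = {i: set() for i in range(len(self.atoms))}
        for a, b in bonds:
            self.add_bond(a, b)
        # per-atom residue arrays for fast selection
        n = len(self.atoms)
        self.atom_resname = np.empty(n, dtype=object)
        self.atom_resid = np.zeros(n, dtype=int)
        self.atom_chain = np.empty(n, dtype=object)
        for res in self.residues:
            self.atom_resname[res.start:res.stop] = res.resname
            self.atom_resid[res.start:res.stop] = res.resid
            self.atom_chain[res.start:res.stop] = res.chain
        self._validate()

    def _validate(self) -> None:
        covered = np.zeros(self.n_atoms, dtype=int)
        for res in self.residues:
            covered[res.start:res.stop] += 1
        if self.n_atoms and not np.all(covered == 1):
            bad = int(np.flatnonzero(covered != 1)[0])
            raise ValueError(f"atom {bad} belongs to {covered[bad]} residues (must be exactly 1)")
        for rec in self.atoms:
            if not rec.mass > 0:
                raise ValueError(f"atom {rec.name}: mass must be > 0, got {rec.mass}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def add_bond(self, a: int, b: int) -> None:
        if not (0 <= a < len(self.atoms) and 0 <= b < len(self.atoms)):
            raise ValueError(f"bond ({a}, {b}) references atom outside [0, {len(self.atoms)})")
        if a == b:
            raise ValueError(f"self-bond on atom {a}")
        pair = (min(a, b), max(a, b))
        if pair[1] not in self._adj[pair[0]]:
            self.bonds.append(pair)
            self._adj[pair[0]].add(pair[1])
            self._adj[pair[1]].add(pair[0])

    def bonded_neighbors(self, i: int) -> list[int]:
        return sorted(self._adj[i])

    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms], dtype=object)

    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms], dtype=object)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def residue_of(self, atom_index: int) -> Residue:
        for res in self.residues:
            if res.start <= atom_index < res.stop:
                return res
        raise IndexError(atom_index)


@dataclass
class Frame:
    """One trajectory frame: coordinates in nm, time in ps, optional box."""

    coordinates: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got {self.coordinates.shape}")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)


class FrameStream:
    """Re-iterable ordered sequence of frames.

    Wraps a factory returning a fresh frame iterator so multi-pass analyses
    (e.g. RMSF after a mean-structure pass) can re-read the stream.
    """

    def __init__(self, factory: Callable[[], Iterator[Frame]],
                 n_frames: int | None = None):
        self._factory = factory
        self._n_frames = n_frames

    def __iter__(self) -> Iterator[Frame]:
        return self._factory()

    def __len__(self) -> int:
        if self._n_frames is None:
            self._n_frames = sum(1 for _ in self)
        return self._n_frames

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "FrameStream":
        frames = list(frames)
        return cls(lambda: iter(frames), n_frames=len(frames))

    @classmethod
    def from_array(cls, coords: np.ndarray, times: np.ndarray | None = None,
                   box: np.ndarray | None = None) -> "FrameStream":
        coords = np.asarray(coords, dtype=float)
        if times is None:
            times = np.arange(len(coords), dtype=float)

        def gen():
            for i in range(len(coords)):
                yield Frame(coords[i], time=float(times[i]), box=box)

        return cls(gen, n_frames=len(coords))

    def coordinates(self) -> np.ndarray:
        """Materialize all frames as one (n_frames, n_atoms, 3) array."""
        return np.array([f.coordinates for f in self])


@dataclass
class Selection:
    """A resolved atom selection: the expression plus sorted unique indices."""

    expression: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=int))

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB reading/writing


def _guess_element(name: str, resname: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if two in ELEMENT_MASSES and two not in ("CA",):  # CA is calcium only outside residues
        if resname not in AMINO_ACIDS or two not in ("CA", "CD", "CE", "CG", "CZ"):
            if two in ("NA", "MG", "CL", "FE", "ZN", "SE") and len(stripped) <= 2:
                return two
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    occ_s = line[54:60].strip()
    bf_s = line[60:66].strip()
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    occupancy = float(occ_s) if occ_s else 1.0
    bfactor = float(bf_s) if bf_s else 0.0
    if not elem:
        elem = _guess_element(name, resname)
    return serial, name, resname, chain, resid, (x, y, z), occupancy, bfactor, elem


def _template_bonds(topology: Topology) -> list[tuple[int, int]]:
    """Bonds for standard amino-acid residues from the built-in template."""
    bonds: list[tuple[int, int]] = []
    prev_c: int | None = None
    prev_res: Residue | None = None
    for res in topology.residues:
        if res.resname not in AMINO_ACIDS:
            prev_c = None
            prev_res = None
            continue
        name_to_idx = {topology.atoms[i].name: i for i in res.atom_indices}
        generic = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
                   ("N", "H"), ("C", "OXT")]
        for a, b in generic + _SIDECHAIN_BONDS.get(res.resname, []):
            if a in name_to_idx and b in name_to_idx:
                bonds.append((name_to_idx[a], name_to_idx[b]))
        if prev_c is not None and "N" in name_to_idx and prev_res is not None \
                and res.resid == prev_res.resid + 1 and res.chain == prev_res.chain:
            bonds.append((prev_c, name_to_idx["N"]))
        prev_c = name_to_idx.get("C")
        prev_res = res
    return bonds


def _read_pdb_models(path) -> tuple[Topology, list[Frame], dict[int, int]]:
    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    coords: list[list[float]] = []
    model_coords: list[np.ndarray] = []
    conect_pairs: list[tuple[int, int]] = []
    serial_to_index: dict[int, int] = {}
    cur_res_key = None
    in_first_model = True
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                serial, name, resname, chain, resid, xyz, occ, bf, elem = \
                    _parse_atom_line(line, lineno)
                if in_first_model:
                    if serial in serial_to_index:
                        raise PDBParseError(f"line {lineno}: duplicate atom serial {serial}")
                    serial_to_index[serial] = len(atoms)
                    mass = ELEMENT_MASSES.get(elem, 12.011)
                    atoms.append(AtomRecord(name=name, element=elem, mass=mass,
                                            serial=serial, occupancy=occ, bfactor=bf))
                    key = (resname, resid, chain)
                    if key != cur_res_key:
                        if residues:
                            pass
                        residues.append(Residue(resname, resid, chain,
                                                start=len(atoms) - 1, stop=len(atoms)))
                        cur_res_key = key
                    else:
                        last = residues[-1]
                        residues[-1] = Residue(last.resname, last.resid, last.chain,
                                               last.start, len(atoms))
                coords.append([c / ANGSTROM_PER_NM for c in xyz])
            elif rec == "ENDMDL":
                model_coords.append(np.array(coords))
                coords = []
                in_first_model = False
            elif rec == "CONECT":
                fields = line.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: malformed CONECT record") from exc
                for other in serials[1:]:
                    conect_pairs.append((serials[0], other))
            elif rec.startswith("CRYST1"):
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])]) / ANGSTROM_PER_NM
                except ValueError:
                    pass
    if coords:
        model_coords.append(np.array(coords))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")

    bonds: list[tuple[int, int]] = []
    if conect_pairs:
        for sa, sb in conect_pairs:
            if sa in serial_to_index and sb in serial_to_index:
                bonds.append((serial_to_index[sa], serial_to_index[sb]))
    topology = Topology(atoms, residues, bonds)
    if not conect_pairs:
        for a, b in _template_bonds(topology):
            topology.add_bond(a, b)
    frames = [Frame(c, time=float(i), box=box) for i, c in enumerate(model_coords)]
    for i, f in enumerate(frames):
        if f.coordinates.shape[0] != topology.n_atoms:
            raise PDBParseError(
                f"model {i + 1}: {f.coordinates.shape[0]} atoms, expected {topology.n_atoms}")
    return topology, frames, serial_to_index


def read_pdb(path) -> tuple[Topology, Frame]:
    """Read a PDB file; returns the topology and the first model's frame.

    Coordinates are converted from Angstrom to nm.  Bonds come from CONECT
    records when present, else from the amino-acid template table.
    """
    topology, frames, _ = _read_pdb_models(path)
    return topology, frames[0]


def write_pdb(path, topology: Topology, frames: Frame | Sequence[Frame]) -> None:
    """Write one or more frames as a (multi-model) PDB with CONECT records."""
    if isinstance(frames, Frame):
        frames = [frames]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(frames, start=1):
            if frame.coordinates.shape[0] != topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            serial = 0
            for res in topology.residues:
                hetatm = res.resname not in AMINO_ACIDS
                for i in res.atom_indices:
                    a = topology.atoms[i]
                    serial = i + 1
                    x, y, z = frame.coordinates[i] * ANGSTROM_PER_NM
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    fh.write(
                        f"{'HETATM' if hetatm else 'ATOM  '}{serial:5d} {name:<4s}"
                        f" {res.resname:<3s} {res.chain:1s}{res.resid:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
                        f"          {a.element:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        for a, b in sorted(topology.bonds):
            fh.write(f"CONECT{a + 1:5d}{b + 1:5d}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory streaming


def _iter_frames_text(path, topology: Topology) -> Iterator[Frame]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: expected header 'natoms time_step'")
        natoms, dt = int(header[0]), float(header[1])
        if natoms != topology.n_atoms:
            raise ValueError(
                f"{path}: frame atom count {natoms} != topology {topology.n_atoms}")
        iframe = 0
        while True:
            rows = []
            for _ in range(natoms):
                line = fh.readline()
                if not line:
                    if rows:
                        raise ValueError(
                            f"{path}: truncated final frame {iframe + 1} "
                            f"({len(rows)}/{natoms} atoms)")
                    return
                rows.append([float(v) for v in line.split()[:3]])
            yield Frame(np.array(rows), time=iframe * dt)
            iframe += 1


def _iter_frames_pdb(path, topology: Topology, dt: float) -> Iterator[Frame]:
    # stream MODEL blocks without loading the whole file
    coords: list[list[float]] = []
    iframe = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                _, _, _, _, _, xyz, _, _, _ = _parse_atom_line(line, lineno)
                coords.append([c / ANGSTROM_PER_NM for c in xyz])
            elif rec == "ENDMDL":
                if len(coords) != topology.n_atoms:
                    raise ValueError(
                        f"frame {iframe + 1}: {len(coords)} atoms, "
                        f"expected {topology.n_atoms}")
                yield Frame(np.array(coords), time=iframe * dt)
                coords = []
                iframe += 1
    if coords:
        if len(coords) != topology.n_atoms:
            raise ValueError(
                f"frame {iframe + 1}: {len(coords)} atoms (truncated?), "
                f"expected {topology.n_atoms}")
        yield Frame(np.array(coords), time=iframe * dt)
        iframe += 1
    if iframe == 0:
        raise ValueError(f"{path}: no frames found")


def read_trajectory(path, topology: Topology, dt: float = 0.5) -> FrameStream:
    """Open a trajectory (multi-model PDB or plain frames text) lazily.

    ``dt`` (ps) spaces frame times for PDB input, which carries no time stamps.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty trajectory file")
    if first[:6] in ("MODEL ", "ATOM  ", "HETATM") or first.startswith(
            ("REMARK", "CRYST1", "TITLE", "HEADER")):
        return FrameStream(lambda: _iter_frames_pdb(path, topology, dt))
    return FrameStream(lambda: _iter_frames_text(path, topology))


def write_frames(path, stream: FrameStream | Sequence[Frame], dt: float | None = None) -> None:
    """Write frames in the plain text format (header 'natoms time_step')."""
    frames = list(stream)
    if not frames:
        raise ValueError("no frames to write")
    if dt is None:
        dt = frames[1].time - frames[0].time if len(frames) > 1 else 0.5
    n = frames[0].coordinates.shape[0]
    with open(path, "w") as fh:
        fh.write(f"{n} {dt:g}\n")
        for f in frames:
            np.savetxt(fh, f.coordinates, fmt="%.9g")


def read_parameter_sidecar(path, topology: Topology) -> Topology:
    """Apply a whitespace parameter table to the topology, in place.

    Columns: resname atomname mass charge c6 c12 [united]; ``#`` comments.
    A trailing ``U`` flag marks a united (implicit-hydrogen) carbon.
    """
    table: dict[tuple[str, str], tuple[float, float, float, float, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path} line {lineno}: expected "
                                 "'resname atomname mass charge c6 c12 [U]'")
            united = len(fields) > 6 and fields[6].upper() == "U"
            table[(fields[0], fields[1])] = (
                float(fields[2]), float(fields[3]), float(fields[4]),
                float(fields[5]), united)
    for res in topology.residues:
        for i in res.atom_indices:
            a = topology.atoms[i]
            key = (res.resname, a.name)
            if key in table:
                a.mass, a.charge, a.lj_c6, a.lj_c12, a.is_united_carbon = table[key]
    return topology


def write_parameter_sidecar(path, topology: Topology) -> None:
    """Write the topology's masses/charges/LJ/united flags as a sidecar table."""
    with open(path, "w") as fh:
        fh.write("# resname atomname mass charge c6 c12 [U]\n")
        seen = set()
        for res in topology.residues:
            for i in res.atom_indices:
                a = topology.atoms[i]
                key = (res.resname, a.name)
                if key in seen:
                    continue
                seen.add(key)
                flag = " U" if a.is_united_carbon else ""
                fh.write(f"{res.resname} {a.name} {a.mass:.6g} {a.charge:.6g} "
                         f"{a.lj_c6:.6g} {a.lj_c12:.6g}{flag}\n")


def read_energy_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time ps, energy kJ/mol) text series."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, energy)")
    return data[:, 0], data[:, 1]


# ---------------------------------------------------------------------------
# Selections

_KEYWORDS = {"resname", "resid", "name", "element", "index",
             "backbone", "protein", "all", "and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(expression):
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expression) and not expression[j].isspace() \
                and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _SelParser:
    """Recursive-descent parser: or < and < not < primary."""

    def __init__(self, tokens: list[tuple[str, int]], topology: Topology,
                 expression: str):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.expression = expression

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def error(self, msg: str):
        where = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expression)
        raise SelectionError(f"{msg} at position {where} in {self.expression!r}")

    def parse(self) -> np.ndarray:
        mask = self.expr_or()
        if self.pos != len(self.tokens):
            self.error(f"unexpected token {self.peek()!r}")
        return mask

    def expr_or(self) -> np.ndarray:
        mask = self.expr_and()
        while self.peek() == "or":
            self.pos += 1
            mask = mask | self.expr_and()
        return mask

    def expr_and(self) -> np.ndarray:
        mask = self.expr_not()
        while self.peek() == "and":
            self.pos += 1
            mask = mask & self.expr_not()
        return mask

    def expr_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.pos += 1
            return ~self.expr_not()
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while (tok := self.peek()) is not None and tok not in _KEYWORDS:
            vals.append(tok)
            self.pos += 1
        if not vals:
            self.error("expected one or more values")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.peek()
        n = self.top.n_atoms
        if tok is None:
            self.error("unexpected end of expression")
        if tok == "(":
            self.pos += 1
            mask = self.expr_or()
            if self.peek() != ")":
                self.error("expected ')'")
            self.pos += 1
            return mask
        if tok == "all":
            self.pos += 1
            return np.ones(n, dtype=bool)
        if tok == "protein":
            self.pos += 1
            return np.isin(self.top.atom_resname, list(AMINO_ACIDS))
        if tok == "backbone":
            self.pos += 1
            names = self.top.names()
            return (np.isin(self.top.atom_resname, list(AMINO_ACIDS))
                    & np.isin(names, list(BACKBONE_NAMES)))
        if tok == "resname":
            self.pos += 1
            return np.isin(self.top.atom_resname, self._values())
        if tok == "name":
            self.pos += 1
            return np.isin(self.top.names(), self._values())
        if tok == "element":
            self.pos += 1
            vals = [v.upper() for v in self._values()]
            return np.isin(self.top.elements(), vals)
        if tok in ("resid", "index"):
            self.pos += 1
            vals = self._values()
            chosen = np.zeros(n, dtype=bool)
            target = self.top.atom_resid if tok == "resid" else np.arange(n)
            for v in vals:
                try:
                    if ":" in v:
                        lo, hi = v.split(":")
                        chosen |= (target >= int(lo)) & (target <= int(hi))
                    else:
                        chosen |= target == int(v)
                except ValueError:
                    self.error(f"bad {tok} value {v!r}")
            return chosen
        self.error(f"unknown token {tok!r}")


def select(expression: str, topology: Topology) -> Selection:
    """Resolve a selection expression to sorted, unique atom indices.

    Grammar: ``resname``/``resid``/``name``/``element``/``index`` primaries
    (each taking one or more values; ``resid``/``index`` accept ``lo:hi``
    ranges), the keywords ``backbone``, ``protein``, ``all``, and the
    operators ``and``, ``or``, ``not`` with parentheses.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, topology, expression).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(expression=expression, indices=indices)


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors (rectangular box)."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)
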