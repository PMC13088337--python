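"""Molecular structures, trajectories, bonds, selections, and basic geometry.

The containers here are deliberately small: an ordered list of atoms with
Cartesian coordinates in Å, named cofactor groups (HEME / FMN / FES), an
inferred covalent-bond topology, and a trajectory that shares one topology
across frames.  PDB input follows the fixed-column v3.3 dialect with
MODEL/ENDMDL delimiting frames; a minimal multi-frame XYZ reader covers
plain coordinate dumps.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import covalent_radius

__all__ = [
    "Atom",
    "Structure",
    "BondTopology",
    "Trajectory",
    "HBond",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "infer_covalent_bonds",
    "select",
    "min_distance",
    "detect_hbonds",
    "angle_deg",
]

# HETATM residue names auto-registered as cofactor groups
_COFACTOR_RESNAMES = {
    "HEM": "HEME",
    "HEC": "HEME",
    "FMN": "FMN",
    "FES": "FES",
    "SF4": "FES",
    "FS4": "FES",
}


@dataclass(frozen=True)
class Atom:
    """One atom: identity, residue context, and position in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element.strip():
            raise ValueError(f"atom {self.serial}: element must be non-empty")


@dataclass
class Structure:
    """Ordered atom list plus named cofactor groups (atom-index sets)."""

    atoms: list[Atom]
    cofactor_groups: dict[str, set[int]] = field(default_factory=dict)
    title: str = ""

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a Structure requires at least one atom")
        n = len(self.atoms)
        for gname, idx in self.cofactor_groups.items():
            bad = [i for i in idx if not (0 <= i < n)]
            if bad:
                raise ValueError(f"cofactor group {gname}: invalid atom indices {bad}")
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.residue_id, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom identity {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def heavy_atom_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"]


@dataclass
class BondTopology:
    """Symmetric set of covalent bonds as unordered atom-index pairs."""

    bonds: set[frozenset]
    source: str = "inferred"

    def __post_init__(self):
        for b in self.bonds:
            if len(b) != 2:
                raise ValueError(f"self-bond or malformed bond: {set(b)}")

    def bonded(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self.bonds

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for b in self.bonds:
            if i in b:
                out.update(b - {i})
        return out


@dataclass
class Trajectory:
    """Multi-frame coordinates over a fixed topology."""

    topology: Structure
    frames: list[np.ndarray]
    frame_times: list[float] | None = None

    def __post_init__(self):
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {k}: expected {n} atoms, got shape {f.shape}"
                )
            self.frames[k] = f
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != len(self.frames):
                raise ValueError("frame_times length must match frame count")
            if np.any(np.diff(t) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class HBond:
    """A detected hydrogen bond: heavy donor, hydrogen, heavy acceptor."""

    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor–acceptor, Å
    angle: float  # D–H–A, degrees


class PDBParseError(ValueError):
    pass


class SelectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PDB / XYZ I/O
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int) -> Atom | None:
    """Parse one ATOM/HETATM record; return None for skipped altlocs."""
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-column field ({exc})") from None
    if icode not in (" ", ""):
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported"
        )
    if altloc not in (" ", "A"):
        return None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the atom-name convention: first alphabetic character,
        # honouring two-letter elements left-justified in column 13
        stripped = name
        if stripped[:2].upper() in ("FE", "ZN", "MG", "CL", "NA"):
            element = stripped[:2].capitalize()
        else:
            m = re.search(r"[A-Za-z]", stripped)
            if not m:
                raise PDBParseError(f"line {lineno}: cannot infer element from {name!r}")
            element = m.group(0).upper()
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_id=resid,
        chain=chain,
        position=np.array([x, y, z]),
        is_hetero=line.startswith("HETATM"),
    )


def read_structure(text: str) -> Structure:
    """Read a Structure from fixed-column PDB text (first model only).

    HETATM residues named HEM/HEC, FMN, and FES/SF4 are auto-registered as
    the cofactor groups HEME, FMN, and FES.
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    atoms: list[Atom] = []
    title = ""
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "TITLE":
            title = (title + " " + line[10:].strip()).strip()
        elif rec in ("ATOM", "HETATM"):
            atom = _parse_pdb_atom_line(line, lineno)
            if atom is not None:
                atoms.append(atom)
        elif rec == "ENDMDL":
            break
    if not atoms:
        raise PDBParseError("no ATOM or HETATM records found")
    groups: dict[str, set[int]] = {}
    for i, a in enumerate(atoms):
        gname = _COFACTOR_RESNAMES.get(a.residue_name.upper())
        if gname is not None:
            groups.setdefault(gname, set()).add(i)
    return Structure(atoms=atoms, cofactor_groups=groups, title=title)


def write_structure(structure: Structure) -> str:
    """Serialize to fixed-column PDB text (coordinates to 3 decimals)."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    lines.extend(_atom_lines(structure, structure.coords))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _atom_lines(structure: Structure, coords: np.ndarray) -> list[str]:
    out = []
    for a, xyz in zip(structure.atoms, coords):
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        out.append(
            f"{rec}{a.serial:>5d} {name}{' '}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_id:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element.upper():>2s}"
        )
    return out


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB text."""
    lines = []
    for k, frame in enumerate(traj.frames, start=1):
        lines.append(f"MODEL     {k:>4d}")
        lines.extend(_atom_lines(traj.topology, frame))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _looks_like_xyz(text: str) -> bool:
    first = text.lstrip().splitlines()[0].strip()
    return first.isdigit()


def _read_xyz_frames(text: str, n_expected: int) -> list[np.ndarray]:
    lines = text.splitlines()
    frames = []
    i = 0
    frame_idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_idx += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise PDBParseError(
                f"frame {frame_idx}: expected atom count line, got {lines[i]!r}"
            ) from None
        if n != n_expected:
            raise PDBParseError(
                f"frame {frame_idx}: atom count {n} does not match topology "
                f"({n_expected})"
            )
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise PDBParseError(f"frame {frame_idx}: truncated coordinate block")
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise PDBParseError(
                    f"frame {frame_idx}: malformed XYZ line {ln!r}"
                )
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        i += 2 + n
    return frames


def read_trajectory(text: str, topology: Structure) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ trajectory.

    Format is auto-detected from content; every frame must carry the same
    atom count as ``topology``.
    """
    if not text.strip():
        raise PDBParseError("empty trajectory input")
    n = topology.n_atoms
    if _looks_like_xyz(text):
        frames = _read_xyz_frames(text, n)
    else:
        frames = []
        current: list[np.ndarray] | None = None
        frame_idx = 0
        saw_model = False
        for lineno, line in enumerate(text.splitlines(), start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                frame_idx += 1
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    frame_idx += 1
                    current = []
                atom = _parse_pdb_atom_line(line, lineno)
                if atom is not None:
                    current.append(atom.position)
            elif rec == "ENDMDL":
                if current is None:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                if len(current) != n:
                    raise PDBParseError(
                        f"frame {frame_idx}: has {len(current)} atoms, "
                        f"topology has {n}"
                    )
                frames.append(np.array(current))
                current = None
        if current is not None:
            if len(current) != n:
                raise PDBParseError(
                    f"frame {frame_idx}: has {len(current)} atoms, topology has {n}"
                )
            frames.append(np.array(current))
        if not frames:
            raise PDBParseError("no coordinate frames found")
        del saw_model
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def infer_covalent_bonds(structure: Structure, tolerance: float = 0.4) -> BondTopology:
    """Infer covalent bonds from interatomic distances and covalent radii.

    Pair (i, j) is bonded iff |r_i - r_j| <= radius(i) + radius(j) + tolerance.
    Hydrogen atoms are restricted to at most one heavy-atom bond (nearest
    wins); H–H pairs are never bonded.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    coords = structure.coords
    elements = [a.element.upper() for a in structure.atoms]
    radii = np.array([covalent_radius(e) for e in elements])
    n = structure.n_atoms
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + tolerance
    bonded = (d <= cut) & ~np.eye(n, dtype=bool)

    bonds: set[frozenset] = set()
    is_h = np.array([e == "H" for e in elements])
    for i in range(n):
        if is_h[i]:
            continue
        for j in range(i + 1, n):
            if is_h[j]:
                continue
            if bonded[i, j]:
                bonds.add(frozenset((i, j)))
    # hydrogens: nearest bonded heavy atom only
    for i in np.nonzero(is_h)[0]:
        heavy = [j for j in range(n) if not is_h[j] and bonded[i, j]]
        if heavy:
            nearest = min(heavy, key=lambda j: d[i, j])
            bonds.add(frozenset((int(i), int(nearest))))
    return BondTopology(bonds=bonds, source="inferred")


# ---------------------------------------------------------------------------
# Selection grammar
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[\w\-']+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            raise SelectionError(
                f"selection syntax error at position {pos}: "
                f"{expression[pos:pos + 10]!r}"
            )
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    """Recursive-descent parser for the small selection grammar:

    expr := term ('or' term)* ; term := factor ('and' factor)* ;
    factor := 'not' factor | '(' expr ')' | primary ;
    primary := chain ID | resid A[-B] | resname N | name N | group G
    """

    def __init__(self, tokens, structure: Structure):
        self.tokens = tokens
        self.i = 0
        self.s = structure
        self.all = set(range(structure.n_atoms))

    def _peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self):
        if self.i >= len(self.tokens):
            raise SelectionError("unexpected end of selection expression")
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> set[int]:
        result = self.expr()
        if self.i != len(self.tokens):
            tok, pos = self.tokens[self.i]
            raise SelectionError(f"unexpected token {tok!r} at position {pos}")
        return result

    def expr(self) -> set[int]:
        out = self.term()
        while self._peek() == "or":
            self._next()
            out = out | self.term()
        return out

    def term(self) -> set[int]:
        out = self.factor()
        while self._peek() == "and":
            self._next()
            out = out & self.factor()
        return out

    def factor(self) -> set[int]:
        tok = self._peek()
        if tok == "not":
            self._next()
            return self.all - self.factor()
        if tok == "(":
            self._next()
            out = self.expr()
            close, pos = self._next()
            if close != ")":
                raise SelectionError(f"expected ')' at position {pos}")
            return out
        return self.primary()

    def primary(self) -> set[int]:
        key, pos = self._next()
        if key == "chain":
            val, _ = self._next()
            return {i for i, a in enumerate(self.s.atoms) if a.chain == val}
        if key == "resid":
            val, vpos = self._next()
            m = re.fullmatch(r"(\d+)(?:-(\d+))?", val)
            if m is None:
                raise SelectionError(f"bad resid range {val!r} at position {vpos}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return {
                i for i, a in enumerate(self.s.atoms) if lo <= a.residue_id <= hi
            }
        if key == "resname":
            val, _ = self._next()
            return {
                i for i, a in enumerate(self.s.atoms)
                if a.residue_name.upper() == val.upper()
            }
        if key == "name":
            val, _ = self._next()
            return {
                i for i, a in enumerate(self.s.atoms)
                if a.name.upper() == val.upper()
            }
        if key == "group":
            val, _ = self._next()
            return set(self.s.cofactor_groups.get(val.upper(), set()))
        raise SelectionError(f"unknown selection keyword {key!r} at position {pos}")


def select(structure: Structure, expression: str) -> set[int]:
    """Evaluate a selection expression; returns a (possibly empty) index set."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    return _SelParser(tokens, structure).parse()


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _coords_of(structure_or_frame, structure: Structure | None = None) -> np.ndarray:
    if isinstance(structure_or_frame, Structure):
        return structure_or_frame.coords
    return np.asarray(structure_or_frame, dtype=float)


def min_distance(
    structure_or_frame,
    setA: Iterable[int],
    setB: Iterable[int],
    mode: str = "min",
    structure: Structure | None = None,
) -> float:
    """Distance between two atom sets under a chosen convention, Å.

    Modes: ``min`` (minimum pairwise), ``cog`` (center of geometry),
    ``fe-fe`` (iron atom pair: each set restricted to Fe atoms and the
    minimizing Fe–Fe pair used; the field convention for d[FeS–Heme]).
    The ``fe-fe`` mode requires a Structure (either as the first argument or
    via ``structure=`` alongside a raw frame).
    """
    A = sorted(set(setA))
    B = sorted(set(setB))
    if not A or not B:
        raise ValueError("both atom sets must be non-empty")
    if set(A) & set(B):
        raise ValueError("atom sets must be disjoint")
    coords = _coords_of(structure_or_frame)
    if mode == "fe-fe":
        struct = structure_or_frame if isinstance(structure_or_frame, Structure) else structure
        if struct is None:
            raise ValueError("fe-fe mode needs the Structure for element lookup")
        A = [i for i in A if struct.atoms[i].element.upper() == "FE"]
        B = [i for i in B if struct.atoms[i].element.upper() == "FE"]
        if not A or not B:
            raise ValueError("fe-fe mode: no iron atoms in one of the sets")
        mode = "min"
    if mode == "min":
        d = np.linalg.norm(coords[A][:, None, :] - coords[B][None, :, :], axis=-1)
        return float(d.min())
    if mode == "cog":
        return float(np.linalg.norm(coords[A].mean(axis=0) - coords[B].mean(axis=0)))
    raise ValueError(f"unknown distance mode {mode!r}")


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a–vertex–b in degrees, in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(b, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("coincident atoms: angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(math.degrees(math.acos(c)))


def detect_hbonds(
    structure: Structure,
    bonds: BondTopology,
    coords: np.ndarray | None = None,
    donor_acceptor_max: float = 3.5,
    dha_angle_min: float = 135.0,
) -> list[HBond]:
    """Geometric hydrogen-bond detection on a single frame.

    Donors are N/O heavy atoms with a covalently bonded hydrogen; acceptors
    are N/O atoms.  Criterion: d(D, A) <= donor_acceptor_max and
    angle(D, H, A) >= dha_angle_min.
    """
    if coords is None:
        coords = structure.coords
    coords = np.asarray(coords, float)
    out: list[HBond] = []
    polar = {
        i for i, a in enumerate(structure.atoms) if a.element.upper() in ("N", "O")
    }
    hydrogens = {
        i for i, a in enumerate(structure.atoms) if a.element.upper() == "H"
    }
    for h in sorted(hydrogens):
        donors = [d for d in bonds.neighbors(h) if d in polar]
        if not donors:
            continue
        donor = donors[0]
        for acc in sorted(polar - {donor}):
            dda = float(np.linalg.norm(coords[donor] - coords[acc]))
            if dda > donor_acceptor_max:
                continue
            ang = angle_deg(coords[donor], coords[h], coords[acc])
            if ang >= dha_angle_min:
                out.append(HBond(donor, h, acc, dda, ang))
    return out
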