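"""Core data model and structure/trajectory I/O.

All coordinates are stored in nanometres internally, times in picoseconds,
regardless of the on-disk format (PDB files are in angstroms and converted on
read/write).  Atom indexing is 0-based in memory and 1-based in serialized
PDB/GRO records.  Boxes are rectangular; triclinic cells are not supported.

File parsing and writing are delegated to MDAnalysis; this module only adapts
between its angstrom-based model and the nm-based containers used here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._errors import (
    FormatError,
    SelectionError,
    TopologyMismatchError,
    UnsupportedFormatError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
]

_NM_PER_ANGSTROM = 0.1


@dataclass(frozen=True)
class Atom:
    """A single atom: metadata plus a position in nm."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.index}: element must be non-empty")
        object.__setattr__(self, "position", pos)


class Structure:
    """An ordered set of atoms with optional rectangular box (lengths in nm).

    Internally column-oriented (numpy arrays) for speed; :meth:`atom` and
    :attr:`atoms` provide the record view.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_indices: Sequence[int],
        chain_ids: Sequence[str],
        positions: np.ndarray,
        box: Sequence[float] | None = None,
    ) -> None:
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        for arr, label in (
            (self.names, "names"),
            (self.elements, "elements"),
            (self.residue_names, "residue_names"),
            (self.residue_indices, "residue_indices"),
            (self.chain_ids, "chain_ids"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label}: expected {n} entries, got {len(arr)}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if any(not e for e in self.elements):
            raise ValueError("every atom needs a non-empty element symbol")
        if box is not None:
            box = tuple(float(b) for b in box)
            if len(box) != 3 or any(b <= 0 for b in box):
                raise ValueError("box must be three positive lengths (nm)")
        self.box: tuple[float, float, float] | None = box

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Iterable[Atom], box=None) -> "Structure":
        atoms = list(atoms)
        return cls(
            names=[a.name for a in atoms],
            elements=[a.element for a in atoms],
            residue_names=[a.residue_name for a in atoms],
            residue_indices=[a.residue_index for a in atoms],
            chain_ids=[a.chain_id for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=float),
            box=box,
        )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def atom(self, i: int) -> Atom:
        return Atom(
            index=i,
            name=self.names[i],
            element=self.elements[i],
            residue_name=self.residue_names[i],
            residue_index=int(self.residue_indices[i]),
            chain_id=self.chain_ids[i],
            position=self.positions[i].copy(),
        )

    @property
    def atoms(self) -> list[Atom]:
        return [self.atom(i) for i in range(self.n_atoms)]

    # -- geometry helpers ----------------------------------------------------

    def with_positions(self, positions: np.ndarray, box=None) -> "Structure":
        """A copy sharing all metadata but carrying new coordinates."""
        return Structure(
            self.names,
            self.elements,
            self.residue_names,
            self.residue_indices,
            self.chain_ids,
            np.asarray(positions, dtype=float),
            box=self.box if box is None else box,
        )

    def with_box(self, box) -> "Structure":
        return self.with_positions(self.positions.copy(), box=box)

    def translated(self, shift) -> "Structure":
        return self.with_positions(self.positions + np.asarray(shift, dtype=float))

    def rotated(self, matrix: np.ndarray, about=(0.0, 0.0, 0.0)) -> "Structure":
        about = np.asarray(about, dtype=float)
        pos = (self.positions - about) @ np.asarray(matrix, dtype=float).T + about
        return self.with_positions(pos)

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            self.names[idx],
            self.elements[idx],
            self.residue_names[idx],
            self.residue_indices[idx],
            self.chain_ids[idx],
            self.positions[idx],
            box=self.box,
        )

    @staticmethod
    def concatenate(parts: Sequence["Structure"], box=None) -> "Structure":
        return Structure(
            np.concatenate([p.names for p in parts]),
            np.concatenate([p.elements for p in parts]),
            np.concatenate([p.residue_names for p in parts]),
            np.concatenate([p.residue_indices for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
            np.vstack([p.positions for p in parts]),
            box=box,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Structure {self.n_atoms} atoms, box={self.box}>"


class Trajectory:
    """Ordered frames (times in ps, coordinates in nm) over a fixed topology."""

    def __init__(
        self,
        topology: Structure,
        times: Sequence[float],
        coordinates: np.ndarray,
        boxes: Sequence | None = None,
    ) -> None:
        self.topology = topology
        self.times = np.asarray(times, dtype=float)
        self.coordinates = np.asarray(coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != topology.n_atoms:
            raise TopologyMismatchError(
                f"frames carry {self.coordinates.shape[1]} atoms but the "
                f"topology has {topology.n_atoms}"
            )
        if len(self.times) != self.coordinates.shape[0]:
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.boxes = list(boxes) if boxes is not None else [topology.box] * len(self.times)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_positions(self.coordinates[i], box=self.boxes[i])

    def __iter__(self) -> Iterator[Structure]:
        return (self.frame(i) for i in range(self.n_frames))


@dataclass(frozen=True)
class Selection:
    """A named, sorted set of atom indices into a Structure."""

    label: str
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def union(self, other: "Selection") -> "Selection":
        return Selection(
            f"({self.label}) or ({other.label})",
            np.union1d(self.indices, other.indices),
        )

    def intersects(self, other: "Selection") -> bool:
        return len(np.intersect1d(self.indices, other.indices)) > 0


# ---------------------------------------------------------------------------
# selection mini-grammar
# ---------------------------------------------------------------------------

_KEYWORDS = {"chain", "resname", "name", "element", "resid"}
_OPERATORS = {"and", "or", "not"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    """Recursive-descent parser for the selection grammar.

    expr    := or_expr
    or_expr := and_expr ("or" and_expr)*
    and_expr:= unary ("and" unary)*
    unary   := "not" unary | "(" expr ")" | keyword value+
    """

    def __init__(self, expression: str, structure: Structure) -> None:
        self.expression = expression
        self.structure = structure
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expression))

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _fail(self, message: str, at: int):
        raise SelectionError(
            f"selection syntax error at position {at} in {self.expression!r}: {message}"
        )

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self._fail("empty expression", 0)
        mask = self._or_expr()
        tok, at = self._peek()
        if tok is not None:
            self._fail(f"unexpected token {tok!r}", at)
        return mask

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while self._peek()[0] == "or":
            self._next()
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while self._peek()[0] == "and":
            self._next()
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        tok, at = self._peek()
        if tok is None:
            self._fail("unexpected end of expression", at)
        if tok == "not":
            self._next()
            return ~self._unary()
        if tok == "(":
            self._next()
            mask = self._or_expr()
            tok, at = self._next()
            if tok != ")":
                self._fail("expected ')'", at)
            return mask
        if tok in _KEYWORDS:
            return self._term()
        self._fail(f"expected a keyword ({', '.join(sorted(_KEYWORDS))}), 'not' or '('", at)

    def _term(self) -> np.ndarray:
        keyword, at = self._next()
        values = []
        while True:
            tok, vat = self._peek()
            if tok is None or tok in _KEYWORDS or tok in _OPERATORS or tok in "()":
                break
            values.append(self._next()[0])
        if not values:
            self._fail(f"keyword {keyword!r} needs at least one value", at)
        s = self.structure
        if keyword == "resid":
            try:
                wanted = {int(v) for v in values}
            except ValueError:
                self._fail("resid values must be integers", at)
            return np.array([int(r) in wanted for r in s.residue_indices])
        column = {
            "chain": s.chain_ids,
            "resname": s.residue_names,
            "name": s.names,
            "element": s.elements,
        }[keyword]
        wanted = set(values)
        return np.array([v in wanted for v in column])


def select(structure: Structure, expression: str) -> Selection:
    """Resolve a selection expression against a structure.

    The grammar supports the keywords ``chain``, ``resname``, ``name``,
    ``element`` and ``resid`` (each followed by one or more values, combined
    as alternatives) joined with ``and``/``or``/``not`` and parentheses,
    e.g. ``"name O2 and resname DT"``.  An expression matching nothing yields
    an empty selection without error.
    """
    mask = _Parser(expression, structure).parse()
    return Selection(expression, np.nonzero(mask)[0])


# ---------------------------------------------------------------------------
# file I/O (via MDAnalysis)
# ---------------------------------------------------------------------------

_STRUCT_EXT = {".pdb": "pdb", ".gro": "gro"}
_TRAJ_EXT = {".xtc": "xtc", ".dcd": "dcd", ".pdb": "multi-pdb"}


def _element_from_name(name: str) -> str:
    """Fall back element guess from an atom name (first alphabetic char)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _resolve_format(path: Path, fmt: str, table: dict, kind: str) -> str:
    if fmt != "auto":
        return fmt
    ext = path.suffix.lower()
    if ext not in table:
        raise UnsupportedFormatError(
            f"cannot infer {kind} format from extension {ext!r} of {path}; "
            f"pass format explicitly ({', '.join(sorted(set(table.values())))})"
        )
    return table[ext]


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or GRO file into a Structure (coordinates converted to nm)."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _resolve_format(path, format, _STRUCT_EXT, "structure")
    if fmt not in ("pdb", "gro"):
        raise UnsupportedFormatError(f"unsupported structure format {fmt!r}")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt.upper())
        ag = u.atoms
        names = [a.name for a in ag]
        resnames = [a.resname for a in ag]
        resids = [int(a.resid) for a in ag]
        try:
            chains = [str(a.chainID) for a in ag]
        except (AttributeError, mda.exceptions.NoDataError):
            chains = [""] * len(names)
        try:
            elements = [str(e) for e in ag.elements]
        except (AttributeError, mda.exceptions.NoDataError):
            elements = [_element_from_name(n) for n in names]
        elements = [
            e if e else _element_from_name(n) for e, n in zip(elements, names)
        ]
        positions = ag.positions * _NM_PER_ANGSTROM
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = tuple(float(x) * _NM_PER_ANGSTROM for x in u.dimensions[:3])
    except (UnsupportedFormatError, FormatError):
        raise
    except Exception as exc:
        raise FormatError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc
    if all(c == "" for c in chains):
        chains = _synthesize_chains(resids)
    return Structure(names, elements, resnames, resids, chains, positions, box=box)


def _synthesize_chains(resids) -> list[str]:
    """Chain ids for formats without a chain field (GRO): a new chain starts
    wherever the residue number fails to increase."""
    import string

    chains = []
    chain_no = 0
    prev = None
    for r in resids:
        if prev is not None and r < prev:
            chain_no += 1
        prev = r
        q, k = divmod(chain_no, len(string.ascii_uppercase))
        chains.append(string.ascii_uppercase[k] * (q + 1))
    return chains


def _as_mda_universe(structure: Structure):
    """Build an in-memory MDAnalysis Universe mirroring a Structure (angstrom)."""
    import MDAnalysis as mda

    n = structure.n_atoms
    # consecutive (chain, resid) runs define residues
    res_keys = list(zip(structure.chain_ids, structure.residue_indices))
    resindex = np.zeros(n, dtype=int)
    boundaries = [0]
    for i in range(1, n):
        if res_keys[i] != res_keys[i - 1]:
            boundaries.append(i)
        resindex[i] = len(boundaries) - 1
    n_res = len(boundaries)
    res_chains = [structure.chain_ids[b] for b in boundaries]
    seg_ids = sorted(set(res_chains))
    seg_lookup = {c: k for k, c in enumerate(seg_ids)}
    segindex = np.array([seg_lookup[c] for c in res_chains], dtype=int)

    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=n_res,
        n_segments=len(seg_ids),
        atom_resindex=resindex,
        residue_segindex=segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(structure.names))
    u.add_TopologyAttr("elements", list(structure.elements))
    u.add_TopologyAttr("resnames", [structure.residue_names[b] for b in boundaries])
    u.add_TopologyAttr("resids", [int(structure.residue_indices[b]) for b in boundaries])
    u.add_TopologyAttr("chainIDs", [c if c else "X" for c in structure.chain_ids])
    u.add_TopologyAttr("segids", [c if c else "X" for c in seg_ids])
    u.atoms.positions = structure.positions / _NM_PER_ANGSTROM
    if structure.box is not None:
        u.dimensions = [b / _NM_PER_ANGSTROM for b in structure.box] + [90.0, 90.0, 90.0]
    return u


def write_structure(structure: Structure, path, format: str = "auto") -> None:
    """Write a Structure as PDB or GRO (1-based serials, occupancy 1.00/B 0.00)."""
    path = Path(path)
    fmt = _resolve_format(path, format, _STRUCT_EXT, "structure")
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    if fmt == "pdb" and structure.n_atoms > 99999:
        raise FormatError(
            f"{structure.n_atoms} atoms exceed the strict PDB serial limit "
            "(99999); write GRO instead"
        )
    import warnings

    u = _as_mda_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "pdb":
            from MDAnalysis.coordinates.PDB import PDBWriter

            with PDBWriter(str(path)) as w:
                w.write(u.atoms)
        else:
            from MDAnalysis.coordinates.GRO import GROWriter

            with GROWriter(str(path), n_atoms=structure.n_atoms) as w:
                w.write(u.atoms)


def read_trajectory(
    path, topology: Structure, format: str = "auto", dt: float = 1.0
) -> Trajectory:
    """Read an XTC/DCD/multi-model-PDB trajectory against a known topology.

    Times are taken from the file where the format records them; otherwise
    they are synthesized as ``frame_index * dt`` (ps).
    """
    path = Path(path)
    fmt = _resolve_format(path, format, _TRAJ_EXT, "trajectory")
    readers = {}
    from MDAnalysis.coordinates.XTC import XTCReader
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.PDB import PDBReader

    readers = {"xtc": XTCReader, "dcd": DCDReader, "multi-pdb": PDBReader, "pdb": PDBReader}
    if fmt not in readers:
        raise UnsupportedFormatError(f"unsupported trajectory format {fmt!r}")
    times_from_file = fmt in ("xtc", "dcd")
    coords, times, boxes = [], [], []
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = readers[fmt](str(path))
            for k, ts in enumerate(reader):
                if ts.n_atoms != topology.n_atoms:
                    raise TopologyMismatchError(
                        f"frame {k} of {path} has {ts.n_atoms} atoms but the "
                        f"topology has {topology.n_atoms}"
                    )
                coords.append(ts.positions.copy() * _NM_PER_ANGSTROM)
                times.append(float(ts.time) if times_from_file else k * dt)
                if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                    boxes.append(tuple(float(x) * _NM_PER_ANGSTROM for x in ts.dimensions[:3]))
                else:
                    boxes.append(topology.box)
            reader.close()
    except (TopologyMismatchError, UnsupportedFormatError):
        raise
    except Exception as exc:
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return Trajectory(topology, times, np.array(coords), boxes=boxes)


def write_trajectory(trajectory: Trajectory, path, format: str = "auto") -> None:
    """Write a Trajectory as XTC or multi-model PDB."""
    path = Path(path)
    fmt = _resolve_format(path, format, _TRAJ_EXT, "trajectory")
    import warnings

    u = _as_mda_universe(trajectory.topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "xtc":
            from MDAnalysis.coordinates.XTC import XTCWriter

            with XTCWriter(str(path), n_atoms=trajectory.topology.n_atoms) as w:
                for i in range(trajectory.n_frames):
                    u.atoms.positions = trajectory.coordinates[i] / _NM_PER_ANGSTROM
                    u.trajectory.ts.time = trajectory.times[i]
                    u.trajectory.ts.frame = i
                    box = trajectory.boxes[i]
                    if box is not None:
                        u.dimensions = [b / _NM_PER_ANGSTROM for b in box] + [90.0, 90.0, 90.0]
                    w.write(u.atoms)
        elif fmt in ("multi-pdb", "pdb"):
            from MDAnalysis.coordinates.PDB import PDBWriter

            with PDBWriter(str(path), multiframe=True) as w:
                for i in range(trajectory.n_frames):
                    u.atoms.positions = trajectory.coordinates[i] / _NM_PER_ANGSTROM
                    u.trajectory.ts.frame = i
                    w.write(u.atoms)
        else:
            raise UnsupportedFormatError(f"unsupported trajectory format {fmt!r}")
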