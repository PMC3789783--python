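"""Structure/trajectory I/O and atom selection.

Structures are plain-text PDB files; a multi-model PDB is the native
trajectory format (one MODEL per frame).  Coordinates are stored in a
single ``F x A x 3`` float array in Angstrom, frame times in ns.

Parsing and writing are delegated to :mod:`biotite.structure.io.pdb`;
this module owns the topology model, altloc policy and the selection
grammar used everywhere else in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "AtomRecord",
    "Topology",
    "Trajectory",
    "FormatError",
    "ConsistencyError",
    "SelectionError",
    "DEFAULT_WATER_NAMES",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
]

#: Residue names treated as water unless overridden.
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL", "SPC"})

BACKBONE_NAMES = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """File is not a usable PDB (no atoms, malformed records...)."""


class ConsistencyError(ValueError):
    """Frames disagree with the topology (atom count/order mismatch)."""


class SelectionError(ValueError):
    """Invalid selection expression or empty required selection."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology, PDB conventions throughout."""

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain: str
    element: str

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Topology:
    """Ordered atom table plus the derived residue table.

    ``water_residue_names`` identifies solvent; everything else is treated
    as solute.  Residue identity is (chain, residue_seq) with 1-based
    author numbering taken verbatim from the file.
    """

    atoms: list[AtomRecord]
    water_residue_names: frozenset[str] = DEFAULT_WATER_NAMES

    # derived, filled in __post_init__
    residues: list[tuple[str, int, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ConsistencyError("duplicate atom serials in topology")
        seen: dict[tuple[str, int], str] = {}
        order: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain, a.residue_seq)
            if key not in seen:
                seen[key] = a.residue_name
                order.append((a.chain, a.residue_seq, a.residue_name))
            elif seen[key] != a.residue_name:
                raise ConsistencyError(
                    f"residue {key} has conflicting names "
                    f"{seen[key]!r} and {a.residue_name!r}"
                )
        self.residues = order

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_indices_of_residue(self, residue_seq: int, chain: str | None = None) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_seq == residue_seq and (chain is None or a.chain == chain)
        ]

    def is_water(self, atom: AtomRecord) -> bool:
        return atom.residue_name in self.water_residue_names


@dataclass
class Trajectory:
    """Topology + F x A x 3 coordinate frames (Angstrom) + times (ns)."""

    topology: Topology
    coordinates: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ConsistencyError("coordinates must be F x A x 3")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ConsistencyError(
                f"coordinate atom count {self.coordinates.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.coordinates.shape[0] < 1:
            raise ConsistencyError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ConsistencyError("non-finite coordinates")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coordinates.shape[0],):
            raise ConsistencyError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ConsistencyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


_ELEMENT_FALLBACK = re.compile(r"[A-Z]")


def _element_from_name(name: str) -> str:
    """PDB-convention element guess for files lacking the element column."""
    stripped = name.strip()
    if stripped[:1].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    if stripped[:1] == "H":
        return "H"
    m = _ELEMENT_FALLBACK.match(stripped)
    return m.group(0) if m else "X"


def _atoms_from_array(arr: struc.AtomArray) -> list[AtomRecord]:
    atom_ids = (
        arr.atom_id
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    records = []
    for i in range(arr.array_length()):
        elem = str(arr.element[i]).strip().capitalize().upper() if arr.element[i] else ""
        if not elem or elem == "X":
            elem = _element_from_name(str(arr.atom_name[i]))
        elif len(elem) == 2:
            elem = elem[0] + elem[1].lower()
        records.append(
            AtomRecord(
                serial=int(atom_ids[i]),
                name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                residue_seq=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]) or "A",
                element=elem,
            )
        )
    return records


def _read_pdb_models(path: str | Path, model: int | None = None) -> struc.AtomArrayStack:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=model, altloc="all", extra_fields=["atom_id"])
        if model is not None:
            stack = struc.stack([stack])
    except IOError:
        raise
    except Exception as exc:  # biotite raises various InvalidFileError subclasses
        raise FormatError(f"{path}: not a parseable PDB file ({exc})") from exc
    if stack.array_length() == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    # keep only blank/'A' alternate locations
    if "altloc_id" in stack.get_annotation_categories():
        keep = np.isin(stack.altloc_id, (" ", "", ".", "A"))
        stack = stack[..., keep]
    if stack.array_length() == 0:
        raise FormatError(f"{path}: all atoms carried non-primary altloc ids")
    return stack


def read_structure(
    path: str | Path, water_names: Iterable[str] | None = None
) -> tuple[Topology, np.ndarray]:
    """Read a PDB file; return the topology and the first model's coordinates.

    Alternate locations other than blank/'A' are dropped; HETATM records
    (ligands, waters) are retained.
    """
    stack = _read_pdb_models(path, model=1)
    first = stack[0]
    water = frozenset(water_names) if water_names is not None else DEFAULT_WATER_NAMES
    topo = Topology(_atoms_from_array(first), water_residue_names=water)
    return topo, np.array(first.coord, dtype=float)


def read_trajectory(
    topology: Topology,
    path: str | Path,
    dt_ns: float = 1.0,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory over an existing topology.

    Each model must contain the topology's atoms in the same order.  Frame
    times default to ``dt_ns * model_index`` (PDB carries no time field).
    """
    # cheap pre-scan: unequal per-model atom counts are a consistency
    # problem with a clear message, not a generic parse failure
    counts: list[int] = []
    current = 0
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
            elif rec == "ENDMDL":
                counts.append(current)
    if not saw_model:
        counts = [current]
    if len(set(counts)) > 1:
        raise ConsistencyError(f"models have unequal atom counts: {sorted(set(counts))}")
    stack = _read_pdb_models(path)
    if stack.array_length() != topology.n_atoms:
        raise ConsistencyError(
            f"model atom count {stack.array_length()} != topology {topology.n_atoms}"
        )
    names = [a.name for a in topology.atoms]
    if list(stack.atom_name) != names:
        raise ConsistencyError("model atom order does not match topology")
    n_frames = stack.stack_depth()
    if times is None:
        times = np.arange(n_frames) * dt_ns
    return Trajectory(topology, np.array(stack.coord, dtype=float), np.asarray(times, float))


def _stack_from_trajectory(traj: Trajectory) -> struc.AtomArrayStack:
    topo = traj.topology
    stack = struc.AtomArrayStack(traj.n_frames, topo.n_atoms)
    stack.set_annotation("chain_id", np.array([a.chain for a in topo.atoms], dtype="U4"))
    stack.set_annotation("res_id", np.array([a.residue_seq for a in topo.atoms]))
    stack.set_annotation("ins_code", np.array([""] * topo.n_atoms, dtype="U1"))
    stack.set_annotation("res_name", np.array([a.residue_name for a in topo.atoms], dtype="U5"))
    stack.set_annotation("atom_name", np.array([a.name for a in topo.atoms], dtype="U6"))
    stack.set_annotation("element", np.array([a.element.upper() for a in topo.atoms], dtype="U2"))
    stack.set_annotation(
        "hetero",
        np.array([a.residue_name in topo.water_residue_names for a in topo.atoms]),
    )
    stack.coord = np.asarray(traj.coordinates, dtype=np.float32)
    return stack


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB, one MODEL per frame.

    Round-trips with :func:`read_trajectory` to PDB field precision
    (0.001 A).  Output is deterministic for identical input.
    """
    pdb = PDBFile()
    pdb.set_structure(_stack_from_trajectory(traj))
    pdb.write(str(path))


def write_structure(topology: Topology, coordinates: np.ndarray, path: str | Path) -> None:
    """Write a single-model PDB."""
    traj = Trajectory(topology, np.asarray(coordinates, float)[None, :, :], np.zeros(1))
    pdb = PDBFile()
    stack = _stack_from_trajectory(traj)
    pdb.set_structure(stack[0])
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# selection grammar
#
#   expr     := or_expr
#   or_expr  := and_expr ('or' and_expr)*
#   and_expr := atom ('and' atom)*
#   atom     := '(' expr ')' | 'not' atom | term
#   term     := 'resid' RANGE+ | 'name' WORD+ | 'resname' WORD+
#             | 'chain' WORD+ | 'backbone' | 'heavy' | 'water' | 'all'
#   RANGE    := INT | INT '-' INT | INT 'to' INT
# ---------------------------------------------------------------------------

_KEYWORDS = {"resid", "name", "resname", "chain", "backbone", "heavy", "water",
             "all", "and", "or", "not", "(", ")", "to"}


def _tokenize(spec: str) -> list[str]:
    out = []
    for raw in spec.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.topo = topology

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.atom()
        while self.peek() == "and":
            self.take()
            mask = mask & self.atom()
        return mask

    def atom(self) -> np.ndarray:
        tok = self.peek()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "not":
            self.take()
            return ~self.atom()
        return self.term()

    # -- terms ----------------------------------------------------------
    def _values(self) -> list[str]:
        vals = []
        while (tok := self.peek()) is not None and tok not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword requires at least one value")
        return vals

    def term(self) -> np.ndarray:
        atoms = self.topo.atoms
        tok = self.take()
        if tok == "resid":
            selected = set()
            for v in self._resid_values():
                selected.update(v)
            return np.array([a.residue_seq in selected for a in atoms])
        if tok == "name":
            names = set(self._values())
            return np.array([a.name in names for a in atoms])
        if tok == "resname":
            names = set(self._values())
            return np.array([a.residue_name in names for a in atoms])
        if tok == "chain":
            chains = set(self._values())
            return np.array([a.chain in chains for a in atoms])
        if tok == "backbone":
            return np.array([a.name in BACKBONE_NAMES for a in atoms])
        if tok == "heavy":
            return np.array([a.is_heavy for a in atoms])
        if tok == "water":
            return np.array([self.topo.is_water(a) for a in atoms])
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        raise SelectionError(f"unknown token {tok!r} in selection")

    def _resid_values(self) -> list[range]:
        ranges: list[range] = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS:
                break
            tok = self.take()
            m = re.fullmatch(r"(-?\d+)-(-?\d+)", tok)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
            else:
                try:
                    lo = int(tok)
                except ValueError:
                    raise SelectionError(f"bad residue id {tok!r}") from None
                if self.peek() == "to":
                    self.take()
                    try:
                        hi = int(self.take())
                    except ValueError:
                        raise SelectionError("bad residue range") from None
                else:
                    hi = lo
            if hi < lo:
                raise SelectionError(f"empty residue range {lo}-{hi}")
            ranges.append(range(lo, hi + 1))
        if not ranges:
            raise SelectionError("'resid' requires at least one id or range")
        return ranges


def selection_mask(topology: Topology, spec: str) -> np.ndarray:
    """Boolean mask over topology atoms for a selection expression."""
    if not spec or not spec.strip():
        raise SelectionError("empty selection expression")
    return _Parser(_tokenize(spec), topology).parse()


def select_atoms(topology: Topology, spec: str) -> np.ndarray:
    """Evaluate a selection expression; return strictly increasing atom indices.

    Grammar: ``resid`` ranges, ``name``/``resname``/``chain`` sets, keywords
    ``backbone`` (N, CA, C, O), ``heavy``, ``water``, ``all``; combined with
    ``and`` / ``or`` / ``not`` and parentheses.  An empty result is valid.
    """
    return np.flatnonzero(selection_mask(topology, spec))
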