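"""Coordinate I/O, atom selection, and superposition.

This module is the geometric substrate for the rest of the package. It reads
and writes PDB-format coordinate files (single- and multi-model, delegating the
record parsing to :mod:`gemmi`), a minimal plain-text trajectory dialect with
explicit time stamps, provides a small boolean selection grammar, and
least-squares (Kabsch) superposition of paired coordinate sets.

Units are angstroms for coordinates and nanoseconds for times throughout; no
unit autodetection is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ConsistencyError,
    DimensionError,
    FormatError,
    NotFoundError,
    SelectionError,
)

ION_ELEMENTS = {"K", "NA", "MG", "CA"}


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus a position in angstroms."""

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise DimensionError(
                f"atom {self.name} position must be a finite 3-vector, got {pos!r}"
            )
        object.__setattr__(self, "position", pos)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Structure:
    """A single conformation: an ordered collection of atoms."""

    atoms: list[Atom]
    model_id: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise DimensionError("a Structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions, angstroms."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise DimensionError(
                f"expected coordinates of shape {(len(self.atoms), 3)}, got {coords.shape}"
            )
        atoms = [
            Atom(a.serial, a.name, a.residue_name, a.residue_number, a.chain_id,
                 a.element, c)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, model_id=self.model_id)

    def subset(self, indices: Sequence[int] | "AtomIndexSet") -> "Structure":
        idx = indices.indices if isinstance(indices, AtomIndexSet) else list(indices)
        return Structure([self.atoms[i] for i in idx], model_id=self.model_id)


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in angstroms; ``times`` is
    strictly increasing, in nanoseconds.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ConsistencyError(
                f"frames shape {self.frames.shape} does not match topology with "
                f"{len(self.topology)} atoms"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise ConsistencyError("one time stamp per frame required")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
            raise ConsistencyError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_structure(cls, structure: Structure, time: float = 0.0) -> "Trajectory":
        """Wrap a single conformation as a one-frame trajectory."""
        return cls(structure, structure.coords[None, :, :], np.array([time]))


@dataclass(frozen=True)
class AtomIndexSet:
    """Duplicate-free indices into a structure's atom order, with provenance."""

    indices: tuple[int, ...]
    selector: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise SelectionError(f"duplicate indices in selection {self.selector!r}")

    def __len__(self) -> int:
        return len(self.indices)

    def sole(self) -> int:
        """Return the only index; raise if the selection is not a single atom."""
        if len(self.indices) != 1:
            raise SelectionError(
                f"selection {self.selector!r} matched {len(self.indices)} atoms, "
                "expected exactly 1"
            )
        return self.indices[0]


# ---------------------------------------------------------------------------
# PDB reading / writing


def _validate_pdb_text(path: Path) -> None:
    # gemmi silently zeroes unparsable coordinate fields, so coordinate columns
    # are checked here to honour the fail-loudly contract.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise FormatError(
                            f"{path}: unparsable coordinate field {fieldtxt!r} "
                            f"on line {lineno}"
                        ) from None


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for atoms in by_name.values():
        if len(atoms) == 1:
            chosen.append(atoms[0])
        else:
            chosen.append(
                min(atoms, key=lambda a: (-a.occ, a.altloc != "A", a.altloc))
            )
    chosen.sort(key=lambda a: a.serial)
    return chosen


def _model_to_structure(model: gemmi.Model, model_id: int) -> Structure:
    # gemmi may merge split residue blocks on read; a stable sort by serial
    # restores the file's atom order afterwards
    atoms = []
    for chain in model:
        for residue in chain:
            for atom in _resolve_altlocs(residue):
                atoms.append(
                    Atom(
                        serial=atom.serial,
                        name=atom.name,
                        residue_name=residue.name.strip(),
                        residue_number=residue.seqid.num,
                        chain_id=chain.name or "A",
                        element=atom.element.name.upper(),
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
    if not atoms:
        raise FormatError(f"model {model_id} contains no atoms")
    atoms.sort(key=lambda a: a.serial)
    return Structure(atoms, model_id=model_id)


def read_structure(path: str | Path, model: int | None = None) -> Structure:
    """Read one model from a PDB file.

    HETATM ion records (K, NA, MG, CA, ...) are retained as ordinary atoms.
    ``model`` selects a MODEL number; default is the first model present.
    """
    path = Path(path)
    if not path.exists():
        raise NotFoundError(f"no such file: {path}")
    _validate_pdb_text(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models found")
    if model is None:
        return _model_to_structure(st[0], st[0].num)
    for m in st:
        if m.num == model:
            return _model_to_structure(m, m.num)
    raise NotFoundError(
        f"{path}: model {model} not found (available: {[m.num for m in st]})"
    )


def write_structure(path: str | Path, structures: Structure | Iterable[Structure]) -> None:
    """Write one or more models to a PDB file (one MODEL per structure)."""
    if isinstance(structures, Structure):
        structures = [structures]
    st = gemmi.Structure()
    st.name = "introntoggle"
    for i, s in enumerate(structures, start=1):
        model = gemmi.Model(i)
        for a in s.atoms:
            chain_name = a.chain_id
            chain = None
            for ch in model:
                if ch.name == chain_name:
                    chain = ch
                    break
            if chain is None:
                model.add_chain(gemmi.Chain(chain_name))
                chain = model[len(model) - 1]
            res = None
            if len(chain) > 0:
                last = chain[len(chain) - 1]
                if last.seqid.num == a.residue_number and last.name == a.residue_name:
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                elt = a.element.upper()
                res.het_flag = "H" if elt in ION_ELEMENTS and a.residue_name in ION_ELEMENTS else "A"
                chain.add_residue(res)
                res = chain[len(chain) - 1]
            ga = gemmi.Atom()
            ga.name = a.name
            ga.serial = a.serial
            ga.element = gemmi.Element(a.element.capitalize())
            ga.pos = gemmi.Position(*a.position)
            ga.occ = 1.0
            res.add_atom(ga)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Plain frame format: "t=<ns>" header line then n_atoms lines "name x y z".


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory in the plain frame dialect (full float precision)."""
    with open(path, "w") as fh:
        for t, frame in zip(traj.times, traj.frames):
            fh.write(f"t={float(t)!r}\n")
            for atom, pos in zip(traj.topology.atoms, frame):
                fh.write(f"{atom.name} {float(pos[0])!r} {float(pos[1])!r} "
                         f"{float(pos[2])!r}\n")


def _read_plain_frames(path: Path, n_atoms: int) -> tuple[np.ndarray, list[float | None]]:
    frames: list[np.ndarray] = []
    times: list[float | None] = []
    current: list[list[float]] | None = None

    def flush() -> None:
        if current is None:
            return
        if len(current) != n_atoms:
            raise ConsistencyError(
                f"{path}: frame {len(frames)} has {len(current)} atoms, "
                f"topology has {n_atoms}"
            )
        frames.append(np.array(current, dtype=float))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("t="):
                flush()
                current = []
                try:
                    times.append(float(line[2:]))
                except ValueError:
                    raise FormatError(
                        f"{path}: bad time header on line {lineno}: {line!r}"
                    ) from None
                continue
            if current is None:
                raise FormatError(f"{path}: coordinates before first 't=' header "
                                  f"(line {lineno})")
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}: expected 'name x y z' on line {lineno}")
            try:
                current.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise FormatError(
                    f"{path}: unparsable coordinate on line {lineno}"
                ) from None
    flush()
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return np.stack(frames), times


def read_trajectory(path: str | Path, topology: Structure, dt: float = 1.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB or the plain frame format.

    ``dt`` (ns) supplies times for formats without time stamps (multi-model
    PDB), as frame_index * dt.
    """
    path = Path(path)
    if not path.exists():
        raise NotFoundError(f"no such file: {path}")
    with open(path) as fh:
        head = fh.read(4096)
    first = next((ln for ln in head.splitlines() if ln.strip()), "")
    if first.strip().startswith("t="):
        frames, times = _read_plain_frames(path, len(topology))
        tarr = np.array([times[i] if times[i] is not None else i * dt
                         for i in range(len(frames))], dtype=float)
        return Trajectory(topology, frames, tarr)
    # multi-model PDB
    _validate_pdb_text(path)
    st = gemmi.read_pdb(str(path))
    frames = []
    for i, m in enumerate(st):
        s = _model_to_structure(m, m.num)
        if len(s) != len(topology):
            raise ConsistencyError(
                f"{path}: frame {i} has {len(s)} atoms, topology has {len(topology)}"
            )
        frames.append(s.coords)
    return Trajectory(topology, np.stack(frames),
                      np.arange(len(frames), dtype=float) * dt)


# ---------------------------------------------------------------------------
# Selection grammar
#
#   expr     := or_expr
#   or_expr  := and_expr ('or' and_expr)*
#   and_expr := unary ('and' unary)*
#   unary    := 'not' unary | '(' expr ')' | primary
#   primary  := 'all' | 'heavy' | 'ion'
#             | ('resnum'|'resname'|'name'|'element'|'chain') value[,value...]
#
# resnum values may be ranges like 285-290.


def _tokenize(selector: str) -> list[str]:
    out: list[str] = []
    for raw in selector.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    def __init__(self, tokens: list[str], structure: Structure, selector: str):
        self.tokens = tokens
        self.pos = 0
        self.structure = structure
        self.selector = selector

    def fail(self, msg: str) -> "SelectionError":
        return SelectionError(f"selector {self.selector!r}: {msg}")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise self.fail("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_expr()
            if self.take() != ")":
                raise self.fail("missing closing parenthesis")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        atoms = self.structure.atoms
        tok = self.take()
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        if tok == "heavy":
            return np.array([not a.is_hydrogen for a in atoms])
        if tok == "ion":
            return np.array([a.element.upper() in ION_ELEMENTS for a in atoms])
        if tok in ("resnum", "resname", "name", "element", "chain", "serial"):
            values = self.take().split(",")
            if tok in ("resnum", "serial"):
                numbers: set[int] = set()
                for v in values:
                    if "-" in v[1:]:  # allow leading minus just in case
                        lo_s, hi_s = v.rsplit("-", 1)
                        try:
                            lo, hi = int(lo_s), int(hi_s)
                        except ValueError:
                            raise self.fail(f"bad range {v!r}") from None
                        numbers.update(range(lo, hi + 1))
                    else:
                        try:
                            numbers.add(int(v))
                        except ValueError:
                            raise self.fail(f"bad integer {v!r}") from None
                if tok == "resnum":
                    return np.array([a.residue_number in numbers for a in atoms])
                return np.array([a.serial in numbers for a in atoms])
            wanted = {v.upper() for v in values}
            if tok == "resname":
                return np.array([a.residue_name.upper() in wanted for a in atoms])
            if tok == "name":
                return np.array([a.name.upper() in wanted for a in atoms])
            if tok == "element":
                return np.array([a.element.upper() in wanted for a in atoms])
            return np.array([a.chain_id.upper() in wanted for a in atoms])
        raise self.fail(f"unknown keyword {tok!r}")


def select_atoms(structure: Structure, selector: str) -> AtomIndexSet:
    """Evaluate a selection expression; deterministic, order-preserving.

    An empty result is allowed (it is a valid selection).
    """
    tokens = _tokenize(selector)
    if not tokens:
        raise SelectionError("empty selector")
    mask = _SelParser(tokens, structure, selector).parse()
    return AtomIndexSet(tuple(int(i) for i in np.nonzero(mask)[0]), selector)


# ---------------------------------------------------------------------------
# Superposition


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference``; the
    rotation is proper (det = +1). ``weights`` are optional per-atom weights
    (e.g. masses); the returned rmsd is then weight-averaged.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DimensionError(
            f"point sets must share shape (n, 3); got {mobile.shape} vs "
            f"{reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DimensionError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise DimensionError("one weight per atom required")
    wsum = w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_c = (w[:, None] * reference).sum(axis=0) / wsum
    a = reference - ref_c
    b = mobile - mob_c
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rot, _ = Rotation.align_vectors(a, b, weights=w)
    for warning in caught:
        if "unique" in str(warning.message).lower() or "rank" in str(warning.message).lower():
            warnings.warn(
                "degenerate (rank-deficient) point configuration; superposition "
                "is a best-effort transform",
                stacklevel=2,
            )
    r = rot.as_matrix()
    t = ref_c - r @ mob_c
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt((w * ((moved - reference) ** 2).sum(axis=1)).sum() / wsum))
    return r, t, rmsd


def rmsd_after_superposition(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Convenience: the rmsd component of :func:`superpose`."""
    return superpose(mobile, reference, weights)[2]
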