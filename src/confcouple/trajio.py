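"""Structure, trajectory, alignment and table I/O.

Conventions used by every downstream module:

* Coordinates are in Ångström everywhere in memory; readers convert
  (XTC stores nm, converted on read).
* Author (file) residue numbering is preserved verbatim and never
  renumbered; insertion codes are carried as a separate text field.
* Hydrogens are read and kept, flagged via ``Atom.is_heavy``;
  selections decide whether to keep them.
* For altloc groups the highest-occupancy conformer is kept; ties go
  to altloc ``'A'`` (then lexicographically first).

The plain-text trajectory dialect ("frames-text") makes the whole
package testable without binary-format dependencies::

    <n_atoms>
    x y z        (n_atoms lines, frame 1)
    x y z        (n_atoms lines, frame 2)
    ...

Coordinates are written with 17 significant digits so a write/read
round trip is bitwise exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "StructureModel",
    "Trajectory",
    "AtomSelection",
    "Msa",
    "SelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "read_msa",
    "write_msa",
    "read_table",
]

_HYDROGEN_ELEMENTS = {"H", "D", "T"}


@dataclass(frozen=True)
class Atom:
    """One atom row of the topology table (author numbering preserved)."""

    atom_index: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    is_heavy: bool
    insertion_code: str = ""

    @property
    def residue_key(self) -> str:
        """Internal residue key: author number plus insertion code."""
        return f"{self.residue_number}{self.insertion_code}"


class StructureModel:
    """Flat atom table plus coordinates for one model of a structure."""

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        for i, a in enumerate(atoms):
            if a.atom_index != i:
                raise ValueError("atom_index must be contiguous from 0")
            if a.is_heavy != (a.element.upper() not in _HYDROGEN_ELEMENTS):
                raise ValueError(f"is_heavy inconsistent with element for atom {i}")
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        self.coords = coords
        self._index = {
            (a.chain_id, a.residue_key, a.atom_name): a.atom_index for a in self.atoms
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, chain_id: str, residue_number, atom_name: str) -> int:
        """Look up an atom by chain, author residue number and name."""
        key = (chain_id, str(residue_number), atom_name)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} of residue {residue_number} chain {chain_id} "
                "not found in topology"
            ) from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"<StructureModel n_atoms={self.n_atoms}>"


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology (Å)."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float = 1.0  # ps, informational

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class AtomSelection:
    """Ordered set of 0-based atom indices into a topology."""

    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        idx = tuple(int(i) for i in self.indices)
        if len(idx) == 0:
            raise ValueError(f"empty selection ({self.label!r})")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selection indices must be strictly increasing")
        if idx[0] < 0:
            raise ValueError("negative atom index in selection")
        object.__setattr__(self, "indices", idx)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Msa:
    """A multiple sequence alignment as (id, gapped sequence) records."""

    records: list[tuple[str, str]]
    n_columns: int

    def __post_init__(self):
        if not self.records:
            raise ValueError("empty alignment")
        for rid, seq in self.records:
            if len(seq) != self.n_columns:
                raise ValueError(
                    f"ragged alignment: {rid!r} has length {len(seq)}, "
                    f"expected {self.n_columns}"
                )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def sequence(self, seq_id: str) -> str:
        for rid, seq in self.records:
            if rid == seq_id:
                return seq
        raise KeyError(f"sequence {seq_id!r} not in alignment")


# ---------------------------------------------------------------------------
# PDB structures (gemmi-backed)
# ---------------------------------------------------------------------------


def _pick_altloc(group: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by altloc letter ('A' first)
    return sorted(group, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(path, model_index: int = 0) -> StructureModel:
    """Read one model of a PDB file into a :class:`StructureModel`.

    Atoms come back in file order with author residue numbering.  For
    alternate locations the highest-occupancy conformer is kept (ties
    to ``'A'``).  Hydrogens are retained, flagged via ``is_heavy``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    model = st[model_index]
    atoms: list[Atom] = []
    rows: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            groups: dict[str, list[gemmi.Atom]] = {}
            order: list[str] = []
            for at in residue:
                if at.name not in groups:
                    groups[at.name] = []
                    order.append(at.name)
                groups[at.name].append(at)
            for name in order:
                at = _pick_altloc(groups[name])
                element = at.element.name.upper()
                atoms.append(
                    Atom(
                        atom_index=len(atoms),
                        atom_name=name,
                        element=element,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                        is_heavy=element not in _HYDROGEN_ELEMENTS,
                        insertion_code=(residue.seqid.icode or "").strip(),
                    )
                )
                rows.append(np.array([at.pos.x, at.pos.y, at.pos.z]))
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records readable in {path}")
    return StructureModel(atoms, np.vstack(rows))


def _to_gemmi(model: StructureModel, coords: np.ndarray | None = None) -> gemmi.Model:
    coords = model.coords if coords is None else coords
    gm = gemmi.Model(1)
    chain = None
    residue = None
    res_id = None
    for a, xyz in zip(model.atoms, coords):
        if chain is None or chain.name != a.chain_id:
            chain = gemmi.Chain(a.chain_id)
            gm.add_chain(chain)
            chain = gm[-1]
            res_id = None
        rid = (a.residue_number, a.insertion_code, a.residue_name)
        if rid != res_id:
            residue = gemmi.Residue()
            residue.name = a.residue_name
            residue.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            residue.het_flag = "A"
            chain.add_residue(residue)
            residue = chain[-1]
            res_id = rid
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*xyz)
        at.occ = 1.0
        residue.add_atom(at)
    return gm


def write_structure(model: StructureModel, path) -> None:
    """Write a :class:`StructureModel` as a single-model PDB file."""
    st = gemmi.Structure()
    st.add_model(_to_gemmi(model))
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_FRAMES_TEXT_FMT = "%.17g"


def _read_frames_text(path: Path, n_atoms_expected: int) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 1:
            raise ValueError(f"{path}: frames-text header must be a single integer")
        n_atoms = int(header[0])
        if n_atoms != n_atoms_expected:
            raise ValueError(
                f"{path}: atom count {n_atoms} does not match topology "
                f"({n_atoms_expected})"
            )
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    if values.size == 0:
        raise ValueError(f"{path}: no frames")
    if values.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, got {values.shape[1]}")
    if values.shape[0] % n_atoms != 0:
        raise ValueError(
            f"{path}: truncated frame ({values.shape[0]} coordinate lines is "
            f"not a multiple of {n_atoms} atoms)"
        )
    return values.reshape(-1, n_atoms, 3)


def _read_multi_model_pdb(path: Path, n_atoms_expected: int) -> np.ndarray:
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    frames = []
    for model in st:
        xyz = [
            [at.pos.x, at.pos.y, at.pos.z]
            for chain in model
            for residue in chain
            for at in residue
        ]
        if len(xyz) != n_atoms_expected:
            raise ValueError(
                f"{path}: model has {len(xyz)} atoms, topology has "
                f"{n_atoms_expected}"
            )
        frames.append(xyz)
    if not frames:
        raise ValueError(f"{path}: no models")
    return np.asarray(frames, dtype=float)


def _read_mda(path: Path, fmt: str, n_atoms_expected: int) -> np.ndarray:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            f"reading {fmt} trajectories requires MDAnalysis "
            "(install the 'mdformats' extra)"
        ) from exc
    u = mda.Universe.empty(n_atoms_expected, trajectory=True)
    try:
        u.load_new(str(path), format=fmt.upper())
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: cannot read as {fmt}: {exc}") from exc
    # MDAnalysis reports positions in Å regardless of on-disk units
    return np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)


def nm_to_angstrom(coords_nm: np.ndarray) -> np.ndarray:
    """Exact nm → Å conversion used by the nm-based format adapters."""
    return np.asarray(coords_nm, dtype=float) * 10.0


def read_trajectory(
    topology: StructureModel,
    path,
    format: str = "frames-text",
    frame_interval: float = 1.0,
) -> Trajectory:
    """Read a coordinate trajectory over ``topology``.

    Supported formats: ``frames-text`` (package dialect, Å),
    ``multi-model-pdb`` (Å), ``dcd`` (Å) and ``xtc`` (nm on disk,
    converted to Å) via the MDAnalysis adapter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "frames-text":
        frames = _read_frames_text(path, topology.n_atoms)
    elif format == "multi-model-pdb":
        frames = _read_multi_model_pdb(path, topology.n_atoms)
    elif format in ("dcd", "xtc"):
        frames = _read_mda(path, format, topology.n_atoms)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(topology, frames, frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path, format: str = "frames-text") -> None:
    path = Path(path)
    if format == "frames-text":
        with open(path, "w") as fh:
            fh.write(f"{traj.n_atoms}\n")
            np.savetxt(fh, traj.frames.reshape(-1, 3), fmt=_FRAMES_TEXT_FMT)
    elif format == "multi-model-pdb":
        st = gemmi.Structure()
        for i in range(traj.n_frames):
            gm = _to_gemmi(traj.topology, traj.frames[i])
            gm.num = i + 1
            st.add_model(gm)
        st.setup_entities()
        st.write_pdb(str(path))
    elif format in ("dcd", "xtc"):
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                f"writing {format} requires MDAnalysis (the 'mdformats' extra)"
            ) from exc
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for frame in traj.frames:
                u.atoms.positions = frame
                w.write(u.atoms)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Atom selection mini-grammar
# ---------------------------------------------------------------------------


class SelectionError(ValueError):
    """Raised for selection syntax errors or empty results."""


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    """Recursive-descent parser for the documented selection grammar.

    expr   := term ('or' term)*
    term   := factor ('and' factor)*
    factor := '(' expr ')' | 'not' factor | keyword
    keyword:= 'name' W | 'resname' W | 'resnum' a[-b] | 'chain' C
              | 'heavy' | 'hydrogen' | 'all'
    """

    def __init__(self, spec: str, topology: StructureModel):
        self.tokens = _TOKEN_RE.findall(spec)
        self.pos = 0
        self.top = topology

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        result = self.expr()
        if self._peek() is not None:
            raise SelectionError(f"trailing tokens at {self._peek()!r}")
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
        tok = self._next()
        if tok == "(":
            out = self.expr()
            if self._next() != ")":
                raise SelectionError("missing closing parenthesis")
            return out
        if tok == "not":
            return set(range(self.top.n_atoms)) - self.factor()
        if tok == "all":
            return set(range(self.top.n_atoms))
        if tok == "heavy":
            return {a.atom_index for a in self.top.atoms if a.is_heavy}
        if tok == "hydrogen":
            return {a.atom_index for a in self.top.atoms if not a.is_heavy}
        if tok == "name":
            w = self._next()
            return {a.atom_index for a in self.top.atoms if a.atom_name == w}
        if tok == "resname":
            w = self._next()
            return {a.atom_index for a in self.top.atoms if a.residue_name == w}
        if tok == "chain":
            w = self._next()
            return {a.atom_index for a in self.top.atoms if a.chain_id == w}
        if tok == "resnum":
            w = self._next()
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", w)
            if m is None:
                raise SelectionError(f"bad resnum range {w!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return {
                a.atom_index
                for a in self.top.atoms
                if lo <= a.residue_number <= hi
            }
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(topology: StructureModel, spec: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    The grammar supports ``name``, ``resname``, ``resnum a[-b]``,
    ``chain``, ``heavy``, ``hydrogen``, ``all``, combined with
    ``and``/``or``/``not`` and parentheses.  Results are deterministic
    and sorted ascending; an empty result is an error.
    """
    matched = _SelParser(spec, topology).parse()
    if not matched:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return AtomSelection(tuple(sorted(matched)), label=spec)


# ---------------------------------------------------------------------------
# Alignments and tables
# ---------------------------------------------------------------------------


def read_msa(path, format: str = "fasta") -> Msa:
    """Read a FASTA or Clustal multiple alignment (case-normalized to upper)."""
    from Bio import AlignIO

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in aln]
    if not records:
        raise ValueError(f"{path}: empty alignment")
    return Msa(records, aln.get_alignment_length())


def write_msa(msa: Msa, path, format: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio import AlignIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in msa.records]
    )
    AlignIO.write(aln, str(path), format)


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a delimited assay table (CSV/TSV with a header row)."""
    return pd.read_csv(path, sep=None, engine="python", **kwargs)
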