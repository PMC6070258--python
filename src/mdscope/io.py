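"""Structure/trajectory containers, PDB parsing and DCD/XTC round-tripping.

Coordinates are stored in Angstrom everywhere; time is carried in picoseconds
and converted to nanoseconds only at reporting boundaries.  Residue numbers are
author numbering taken verbatim from the PDB file — selections accept an offset
for inputs expressed in a different numbering scheme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np


class ParseError(ValueError):
    """A structure or trajectory file could not be interpreted."""


class SelectionError(ValueError):
    """An atom-selection expression matched nothing or is malformed."""


_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA2", "MN", "SE"}


def _element_from_name(name: str) -> str:
    """Best-effort element guess from an atom name (PDB without element column)."""
    stripped = re.sub(r"[^A-Za-z]", "", name)
    if not stripped:
        return "X"
    # Protein atom names starting with C/N/O/S/H/P are single-letter elements
    # ("CA" is an alpha carbon, not calcium, in ATOM records).
    return stripped[0].upper()


@dataclass
class Structure:
    """A set of atoms with author numbering, coordinates (A) and optional B-factors (A^2)."""

    atom_serial: np.ndarray
    atom_name: np.ndarray
    residue_name: np.ndarray
    residue_id: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    bfactor: np.ndarray | None = None
    element: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.bfactor is not None:
            self.bfactor = np.asarray(self.bfactor, dtype=np.float64)
            if (self.bfactor < 0).any():
                raise ValueError("B-factors must be >= 0")
        if self.element is None:
            self.element = np.array(
                [_element_from_name(n) for n in self.atom_name], dtype="U2"
            )
        for name in ("atom_serial", "residue_id"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("atom_name", "residue_name", "chain_id"):
            setattr(self, name, np.asarray(getattr(self, name)))

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=np.float64))

    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain, resid) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for ch, rid in zip(self.chain_id, self.residue_id):
            seen.setdefault((str(ch), int(rid)), None)
        return list(seen)


@dataclass
class Trajectory:
    """frames x atoms x 3 coordinates (A) at fixed frame spacing dt_ps."""

    coords: np.ndarray
    dt_ps: float
    atoms: Structure

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] == 0:
            raise ValueError("a trajectory must contain at least one frame")
        if self.coords.shape[1] != self.atoms.n_atoms:
            raise ValueError(
                f"trajectory has {self.coords.shape[1]} atoms per frame but the "
                f"atom table has {self.atoms.n_atoms}"
            )
        if not self.dt_ps > 0:
            raise ValueError("dt_ps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ps / 1000.0

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(coords=coords, dt_ps=self.dt_ps, atoms=self.atoms)


@dataclass
class AtomSelection:
    """Ordered, unique indices into an atom table."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("selection indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        return {
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "resname": line[17:20].strip(),
            "chain": line[21].strip() or "A",
            "resid": int(line[22:26]),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "bfactor": float(line[60:66]) if line[60:66].strip() else 0.0,
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc


def _records_to_structure(records: list[dict]) -> Structure:
    element = np.array(
        [r["element"] or _element_from_name(r["name"]) for r in records], dtype="U2"
    )
    return Structure(
        atom_serial=np.array([r["serial"] for r in records]),
        atom_name=np.array([r["name"] for r in records]),
        residue_name=np.array([r["resname"] for r in records]),
        residue_id=np.array([r["resid"] for r in records]),
        chain_id=np.array([r["chain"] for r in records]),
        coords=np.array([[r["x"], r["y"], r["z"]] for r in records]),
        bfactor=np.array([r["bfactor"] for r in records]),
        element=element,
    )


def read_ensemble(path: str | Path) -> list[Structure]:
    """Read a PDB file, one Structure per MODEL (a single list entry if no MODEL cards)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    models: list[list[dict]] = []
    current: list[dict] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
        elif rec.startswith("ENDMDL"):
            if current:
                models.append(current)
            current = []
    if current:
        models.append(current)
    if not models:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return [_records_to_structure(m) for m in models]


def read_structure(path: str | Path, model: int = 0) -> Structure:
    """Read one model of a PDB file (default: the first)."""
    models = read_ensemble(path)
    if model >= len(models):
        raise ParseError(f"{path}: requested model {model} but file has {len(models)}")
    return models[model]


def chain_gaps(structure: Structure) -> list[tuple[str, int, int]]:
    """Residue-numbering gaps: (chain, last resid before gap, first resid after)."""
    gaps = []
    keys = structure.residue_keys()
    for (ch_a, ra), (ch_b, rb) in zip(keys, keys[1:]):
        if ch_a == ch_b and rb > ra + 1:
            gaps.append((ch_a, ra, rb))
    return gaps


_PDB_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{resname:>4s} {chain:1s}{resid:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{bfac:6.2f}          {elem:>2s}\n"
)


def _format_atom_name(name: str) -> str:
    # Single-letter-element names are right-padded starting at column 14.
    return f" {name:<3s}" if len(name) < 4 else name


def write_structure(structure: Structure, path: str | Path) -> None:
    path = Path(path)
    bfac = structure.bfactor
    with path.open("w") as fh:
        for i in range(structure.n_atoms):
            fh.write(
                _PDB_ATOM_FMT.format(
                    serial=int(structure.atom_serial[i]) % 100000,
                    name=_format_atom_name(str(structure.atom_name[i])),
                    resname=str(structure.residue_name[i]),
                    chain=str(structure.chain_id[i])[:1] or "A",
                    resid=int(structure.residue_id[i]) % 10000,
                    x=structure.coords[i, 0],
                    y=structure.coords[i, 1],
                    z=structure.coords[i, 2],
                    occ=1.0,
                    bfac=float(bfac[i]) if bfac is not None else 0.0,
                    elem=str(structure.element[i]),
                )
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectories (DCD / XTC via MDAnalysis)
# ---------------------------------------------------------------------------

def _open_reader(path: Path):
    import MDAnalysis as mda

    ext = path.suffix.lower()
    if ext == ".dcd":
        return mda.coordinates.DCD.DCDReader(str(path))
    if ext == ".xtc":
        return mda.coordinates.XTC.XTCReader(str(path))
    raise ParseError(f"{path}: unknown trajectory extension {ext!r} (expected .dcd or .xtc)")


def read_trajectory(
    path: str | Path, topology: Structure, dt_ps: float | None = None
) -> Trajectory:
    """Read a DCD or XTC trajectory; coordinates are returned in Angstrom."""
    path = Path(path)
    reader = _open_reader(path)
    try:
        if reader.n_atoms != topology.n_atoms:
            raise ParseError(
                f"{path}: trajectory has {reader.n_atoms} atoms but the topology "
                f"has {topology.n_atoms}"
            )
        frames = [ts.positions.astype(np.float64).copy() for ts in reader]
        if not frames:
            raise ParseError(f"{path}: trajectory contains no frames")
        if dt_ps is None:
            dt_ps = float(getattr(reader.ts, "dt", 1.0)) or 1.0
    finally:
        reader.close()
    return Trajectory(coords=np.stack(frames), dt_ps=dt_ps, atoms=topology)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a DCD or XTC file (MDAnalysis handles the A <-> nm convention for XTC)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    if path.suffix.lower() not in (".dcd", ".xtc"):
        raise ParseError(f"{path}: unknown trajectory extension (expected .dcd or .xtc)")
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.load_new(
        traj.coords.astype(np.float32), format=MemoryReader, dt=traj.dt_ps, order="fac"
    )
    with mda.Writer(str(path), n_atoms=traj.n_atoms, dt=traj.dt_ps) as writer:
        for _ in u.trajectory:
            writer.write(u.atoms)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _parse_resid_tokens(tokens: list[str]) -> list[tuple[int, int]]:
    ranges = []
    for tok in tokens:
        m = re.fullmatch(r"(-?\d+)-(-?\d+)", tok)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
        elif re.fullmatch(r"-?\d+", tok):
            lo = hi = int(tok)
        else:
            raise SelectionError(f"bad resid token {tok!r}")
        if hi < lo:
            raise SelectionError(f"inverted resid range {tok!r}")
        ranges.append((lo, hi))
    return ranges


def select_atoms(
    structure: Structure, expression: str, resid_offset: int = 0
) -> AtomSelection:
    """Resolve a selection expression against a structure.

    Grammar: clauses joined by ``and``; each clause one of
    ``name <N>...``, ``heavy``, ``all``, ``resid <a>-<b> ...``, ``chain <C>...``.
    ``resid`` numbers are interpreted in the caller's numbering scheme;
    ``resid_offset`` is added to the structure's author numbering before matching.
    """
    mask = np.ones(structure.n_atoms, dtype=bool)
    clauses = re.split(r"\s+and\s+", expression.strip())
    if not expression.strip():
        raise SelectionError("empty selection expression")
    for clause in clauses:
        tokens = clause.split()
        kw = tokens[0].lower()
        if kw == "all":
            continue
        if kw == "heavy":
            mask &= structure.element != "H"
        elif kw == "name":
            if len(tokens) < 2:
                raise SelectionError("'name' clause needs at least one atom name")
            mask &= np.isin(structure.atom_name, tokens[1:])
        elif kw == "chain":
            if len(tokens) < 2:
                raise SelectionError("'chain' clause needs at least one chain id")
            mask &= np.isin(structure.chain_id, tokens[1:])
        elif kw == "resid":
            if len(tokens) < 2:
                raise SelectionError("'resid' clause needs at least one id or range")
            effective = structure.residue_id + resid_offset
            sub = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in _parse_resid_tokens(tokens[1:]):
                sub |= (effective >= lo) & (effective <= hi)
            mask &= sub
        else:
            raise SelectionError(f"unknown selection keyword {kw!r} in {clause!r}")
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(f"selection {expression!r} matched no atoms")
    return AtomSelection(indices=indices, label=expression)
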