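"""File formats touched by the pipeline.

- PDB v3.3 fixed-column dialect (ATOM/HETATM/CRYST1/CONECT/TER/END) with
  hybrid-36 atom serials so structures beyond 99,999 atoms round-trip.
- Plain whitespace/comma tables with a header row for stress–strain series.
- A minimal text trajectory format, one frame per block:
  ``id type x y z [vx vy vz [fx fy fz]]``.

Coordinates are Å throughout; no unit conversion happens at I/O boundaries.
"""

from __future__ import annotations

import io
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .cell_geometry import TriclinicCell
from .elements import UnknownElementError, element_from_atom_name, mass_of, normalize_symbol
from .structure import AtomRecord, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "StressStrainSeries",
    "read_series",
    "write_series",
    "read_frames",
    "write_frames",
    "Frame",
]


class PDBParseError(ValueError):
    """Malformed fixed-width PDB record; message carries the line number."""


# ---------------------------------------------------------------------------
# hybrid-36 serials (width 5): 1..99999 decimal, then A0000.. upper-case
# base-36, then a0000.. lower-case base-36.

_U0 = 10 * 36**4 - 100000          # offset for the upper-case range
_L0 = 10 * 36**4 - 100000 - 26 * 36**4  # offset for the lower-case range
_UPPER_MAX = 100000 + 26 * 36**4


def encode_serial(value: int) -> str:
    if value < 1:
        raise ValueError("serial must be >= 1")
    if value < 100000:
        return f"{value:5d}"
    if value < _UPPER_MAX:
        digits = np.base_repr(value + _U0, 36)
        return digits.rjust(5, "0")
    v = value + _L0
    if v >= 36**5:
        raise ValueError(f"serial {value} exceeds hybrid-36 range")
    return np.base_repr(v, 36).lower().rjust(5, "0")


def decode_serial(text: str) -> int:
    s = text.strip()
    if not s:
        raise ValueError("empty serial field")
    if s[0] in string.ascii_uppercase:
        return int(s, 36) - _U0
    if s[0] in string.ascii_lowercase:
        return int(s, 36) - _L0
    return int(s)


# ---------------------------------------------------------------------------
# PDB reading


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    try:
        return float(line[lo:hi])
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {line[lo:hi]!r}"
        ) from None


def read_pdb(path: str | Path, keep_hydrogens: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    CRYST1 populates the cell; CONECT records populate bonds. Atom serials
    (hybrid-36 tolerated) are preserved as read. With ``keep_hydrogens``
    false, H atoms are dropped and bonds reindexed.
    """
    atoms: list[AtomRecord] = []
    cell: TriclinicCell | None = None
    conect_pairs: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec == "CRYST1":
                try:
                    cell = TriclinicCell(
                        float(raw[6:15]), float(raw[15:24]), float(raw[24:33]),
                        float(raw[33:40]), float(raw[40:47]), float(raw[47:54]),
                    )
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: bad CRYST1 record ({exc})") from None
            elif rec in ("ATOM  ", "HETATM"):
                line = raw.rstrip("\n").ljust(80)
                try:
                    serial = decode_serial(line[6:11])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed serial field {line[6:11]!r}"
                    ) from None
                name = line[12:16]
                elem_field = line[76:78].strip()
                if elem_field:
                    try:
                        element = normalize_symbol(elem_field)
                        mass_of(element)
                    except UnknownElementError:
                        raise PDBParseError(
                            f"line {lineno}: unknown element {elem_field!r} "
                            f"for atom {name.strip()!r} serial {serial}"
                        ) from None
                else:
                    try:
                        element = element_from_atom_name(name)
                    except UnknownElementError:
                        raise PDBParseError(
                            f"line {lineno}: cannot infer element for atom "
                            f"{name.strip()!r} serial {serial}"
                        ) from None
                pos = [
                    _parse_float(line, 30, 38, "x coordinate", lineno),
                    _parse_float(line, 38, 46, "y coordinate", lineno),
                    _parse_float(line, 46, 54, "z coordinate", lineno),
                ]
                occ_f, beta_f = line[54:60].strip(), line[60:66].strip()
                try:
                    resseq = int(line[22:26]) if line[22:26].strip() else 1
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed residue number {line[22:26]!r}"
                    ) from None
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name.strip(),
                        element=element,
                        residue_name=line[17:21].strip() or "UNK",
                        residue_seq=resseq,
                        chain_id=line[21].strip() or "A",
                        position=np.array(pos),
                        occupancy=float(occ_f) if occ_f else 1.0,
                        beta=float(beta_f) if beta_f else 0.0,
                    )
                )
            elif rec == "CONECT":
                fields = [raw[6:11], raw[11:16], raw[16:21], raw[21:26], raw[26:31]]
                try:
                    serials = [decode_serial(f) for f in fields if f.strip()]
                except ValueError:
                    raise PDBParseError(f"line {lineno}: malformed CONECT record") from None
                for other in serials[1:]:
                    pair = (min(serials[0], other), max(serials[0], other))
                    if pair[0] != pair[1]:
                        conect_pairs.add(pair)
    serial_to_index: dict[int, int] = {}
    for i, a in enumerate(atoms):
        serial_to_index.setdefault(a.serial, i)
    bonds = [
        (serial_to_index[i], serial_to_index[j])
        for i, j in sorted(conect_pairs)
        if i in serial_to_index and j in serial_to_index
    ]
    st = Structure.from_atoms(atoms, bonds=np.array(bonds) if bonds else None, cell=cell)
    if not keep_hydrogens:
        st = st.select(st.elements != "H")
    return st


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(structure: Structure, path: str | Path, *, renumber: bool = True) -> None:
    """Write a structure as fixed-column PDB v3.3.

    Serials above 99,999 are encoded in hybrid-36. By default atoms are
    renumbered 1..n on output (stable and collision-free); pass
    ``renumber=False`` to keep stored serials.
    """
    lines: list[str] = []
    if structure.cell is not None:
        c = structure.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1           1"
        )
    serials = (
        np.arange(1, len(structure) + 1)
        if renumber
        else np.asarray(structure.serials)
    )
    for i in range(len(structure)):
        name = str(structure.names[i])
        element = str(structure.elements[i])
        if len(structure.chain_ids[i]) > 1:
            raise ValueError(f"chain id {structure.chain_ids[i]!r} longer than 1 char")
        if len(name) < 4 and len(element) == 1:
            name_field = f" {name:<3s}"
        else:
            name_field = f"{name:<4s}"
        x, y, z = structure.positions[i]
        lines.append(
            f"ATOM  {encode_serial(int(serials[i]))} {name_field[:4]}"
            f" {str(structure.residue_names[i]):<4.4s}"
            f"{str(structure.chain_ids[i]) or 'A'}{int(structure.residue_seqs[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{structure.occupancies[i]:6.2f}"
            f"{structure.betas[i]:6.2f}          {element.upper():>2.2s}"
        )
    # CONECT from the bond list (periodic shifts are not expressible in PDB;
    # the bond itself is still recorded)
    neigh: dict[int, list[int]] = {}
    for i, j in structure.bonds:
        neigh.setdefault(int(i), []).append(int(j))
        neigh.setdefault(int(j), []).append(int(i))
    for i in sorted(neigh):
        partners = sorted(neigh[i])
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            lines.append(
                "CONECT"
                + encode_serial(int(serials[i]))
                + "".join(encode_serial(int(serials[j])) for j in chunk)
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# stress–strain series


@dataclass
class StressStrainSeries:
    """Ordered (strain, stress) pairs; strain dimensionless, stress GPa."""

    strain: np.ndarray
    stress: np.ndarray
    label: str = ""
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float).ravel()
        self.stress = np.asarray(self.stress, dtype=float).ravel()
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress lengths differ")
        if np.any(np.diff(self.strain) < 0):
            order = np.argsort(self.strain, kind="stable")
            self.strain = self.strain[order]
            self.stress = self.stress[order]

    def __len__(self) -> int:
        return len(self.strain)


def read_series(
    path: str | Path | TextIO, x_column: str = "strain", y_column: str = "stress"
) -> StressStrainSeries:
    """Read a header-bearing whitespace or comma table into a series.

    Rows with NaN in either column are dropped with a warning; rows are
    sorted by the x column.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    for col in (x_column, y_column):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not found; available columns: {list(df.columns)}"
            )
    sub = df[[x_column, y_column]].apply(pd.to_numeric, errors="coerce")
    n_bad = int(sub.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("read_series: dropping %d row(s) with non-numeric values", n_bad)
        sub = sub.dropna()
    sub = sub.sort_values(x_column, kind="stable")
    label = getattr(path, "name", str(path))
    return StressStrainSeries(sub[x_column].to_numpy(), sub[y_column].to_numpy(), label=label)


def write_series(series: StressStrainSeries, path: str | Path,
                 x_column: str = "strain", y_column: str = "stress") -> None:
    pd.DataFrame({x_column: series.strain, y_column: series.stress}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# minimal trajectory frames


@dataclass
class Frame:
    """One trajectory frame: positions (Å), optional velocities (Å/fs) and
    forces (kcal/mol/Å), box lengths (Å), and an optional configurational
    virial tensor (kcal/mol) carried in the frame header."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    forces: np.ndarray | None = None
    box: np.ndarray | None = None
    virial: np.ndarray | None = None
    types: np.ndarray | None = None


def write_frames(frames: Sequence[Frame], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            n = len(fr.positions)
            fh.write(f"FRAME {n}\n")
            if fr.box is not None:
                fh.write("BOX " + " ".join(f"{v:.10g}" for v in np.ravel(fr.box)) + "\n")
            if fr.virial is not None:
                fh.write(
                    "VIRIAL " + " ".join(f"{v:.17g}" for v in np.ravel(fr.virial)) + "\n"
                )
            for i in range(n):
                cols = [str(i + 1)]
                cols.append(str(int(fr.types[i])) if fr.types is not None else "1")
                cols += [f"{v:.10g}" for v in fr.positions[i]]
                if fr.velocities is not None:
                    cols += [f"{v:.17g}" for v in fr.velocities[i]]
                if fr.forces is not None:
                    cols += [f"{v:.17g}" for v in fr.forces[i]]
                fh.write(" ".join(cols) + "\n")


def read_frames(path: str | Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        line = fh.readline()
        while line:
            if not line.startswith("FRAME"):
                line = fh.readline()
                continue
            n = int(line.split()[1])
            box = virial = None
            pos = fh.tell()
            line = fh.readline()
            while line.startswith(("BOX", "VIRIAL")):
                vals = np.array([float(v) for v in line.split()[1:]])
                if line.startswith("BOX"):
                    box = vals
                else:
                    virial = vals.reshape(3, 3)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            rows = [fh.readline().split() for _ in range(n)]
            data = np.array(rows, dtype=float)
            types = data[:, 1].astype(int)
            positions = data[:, 2:5]
            vel = data[:, 5:8] if data.shape[1] >= 8 else None
            frc = data[:, 8:11] if data.shape[1] >= 11 else None
            frames.append(
                Frame(positions=positions, velocities=vel, forces=frc,
                      box=box, virial=virial, types=types)
            )
            line = fh.readline()
    return frames
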