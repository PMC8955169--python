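"""Atom-array container shared by every pipeline stage.

``Structure`` stores per-atom fields as parallel numpy arrays (positions,
elements, names, ...) plus a bond list with optional periodic image shifts
and an optional triclinic cell. ``AtomRecord`` is a lightweight per-atom
view for element-wise access.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Sequence

import numpy as np

from .elements import mass_of

if TYPE_CHECKING:  # pragma: no cover
    from .cell_geometry import TriclinicCell


@dataclass
class AtomRecord:
    """One atom: identity, position (Å), mass (amu) and optional charge (e)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    beta: float = 0.0
    charge: float | None = None

    @property
    def mass(self) -> float:
        return mass_of(self.element)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if self.serial <= 0:
            raise ValueError("atom serial must be positive")
        if len(self.chain_id) > 1:
            raise ValueError(f"chain id {self.chain_id!r} longer than 1 character")
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: non-positive mass")


class Structure:
    """Ordered collection of atoms with bonds and an optional periodic cell.

    Bonds are stored as an (m, 2) integer index array; ``bond_shifts`` is the
    matching (m, 3) array of integer lattice translations applied to the
    second atom of each pair to realize the bond at minimum image. A shift of
    (0, 0, 0) marks a non-periodic bond.
    """

    def __init__(
        self,
        positions: np.ndarray,
        elements: Sequence[str],
        *,
        names: Sequence[str] | None = None,
        residue_names: Sequence[str] | None = None,
        residue_seqs: Sequence[int] | None = None,
        chain_ids: Sequence[str] | None = None,
        serials: Sequence[int] | None = None,
        occupancies: np.ndarray | None = None,
        betas: np.ndarray | None = None,
        charges: np.ndarray | None = None,
        bonds: np.ndarray | None = None,
        bond_shifts: np.ndarray | None = None,
        cell: "TriclinicCell | None" = None,
    ) -> None:
        self.positions = np.array(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom positions")
        self.elements = np.array([e for e in elements], dtype=object)
        if len(self.elements) != n:
            raise ValueError("elements length mismatch")
        self.names = np.array(list(names) if names is not None else self.elements, dtype=object)
        self.residue_names = np.array(
            list(residue_names) if residue_names is not None else ["UNK"] * n, dtype=object
        )
        self.residue_seqs = np.array(
            list(residue_seqs) if residue_seqs is not None else [1] * n, dtype=int
        )
        self.chain_ids = np.array(
            list(chain_ids) if chain_ids is not None else ["A"] * n, dtype=object
        )
        self.serials = np.array(
            list(serials) if serials is not None else range(1, n + 1), dtype=int
        )
        self.occupancies = (
            np.array(occupancies, dtype=float) if occupancies is not None else np.ones(n)
        )
        self.betas = np.array(betas, dtype=float) if betas is not None else np.zeros(n)
        self.charges = np.array(charges, dtype=float) if charges is not None else None
        self.cell = cell
        self.set_bonds(bonds, bond_shifts)
        # per-atom masses derived once from elements
        self.masses = np.array([mass_of(e) for e in self.elements], dtype=float)

    # -- bonds ---------------------------------------------------------

    def set_bonds(self, bonds: np.ndarray | None, shifts: np.ndarray | None = None) -> None:
        n = len(self.positions)
        if bonds is None:
            self.bonds = np.empty((0, 2), dtype=int)
            self.bond_shifts = np.empty((0, 3), dtype=int)
            return
        b = np.array(bonds, dtype=int).reshape(-1, 2)
        if b.size and (b.min() < 0 or b.max() >= n):
            raise ValueError("bond index out of range")
        if np.any(b[:, 0] == b[:, 1]):
            raise ValueError("self-bond in bond list")
        s = (
            np.array(shifts, dtype=int).reshape(-1, 3)
            if shifts is not None
            else np.zeros((len(b), 3), dtype=int)
        )
        if len(s) != len(b):
            raise ValueError("bond_shifts length mismatch")
        # canonical orientation: i < j, shift applies to j
        flip = b[:, 0] > b[:, 1]
        b[flip] = b[flip][:, ::-1]
        s[flip] = -s[flip]
        self.bonds = b
        self.bond_shifts = s

    # -- pythonic access ----------------------------------------------

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serials[i]),
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_name=str(self.residue_names[i]),
            residue_seq=int(self.residue_seqs[i]),
            chain_id=str(self.chain_ids[i]),
            position=self.positions[i].copy(),
            occupancy=float(self.occupancies[i]),
            beta=float(self.betas[i]),
            charge=None if self.charges is None else float(self.charges[i]),
        )

    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield self.atom(i)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def element_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.elements:
            out[e] = out.get(e, 0) + 1
        return out

    def copy(self) -> "Structure":
        return Structure(
            self.positions.copy(),
            list(self.elements),
            names=list(self.names),
            residue_names=list(self.residue_names),
            residue_seqs=list(self.residue_seqs),
            chain_ids=list(self.chain_ids),
            serials=list(self.serials),
            occupancies=self.occupancies.copy(),
            betas=self.betas.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            bonds=self.bonds.copy(),
            bond_shifts=self.bond_shifts.copy(),
            cell=self.cell,
        )

    def select(self, mask: np.ndarray, *, renumber: bool = False) -> "Structure":
        """Sub-structure of atoms where ``mask`` is true; bonds reindexed,
        bonds touching removed atoms dropped."""
        mask = np.asarray(mask, dtype=bool)
        idx_map = -np.ones(len(self), dtype=int)
        idx_map[mask] = np.arange(int(mask.sum()))
        keep_b = mask[self.bonds[:, 0]] & mask[self.bonds[:, 1]] if len(self.bonds) else np.empty(0, bool)
        new_bonds = idx_map[self.bonds[keep_b]] if len(self.bonds) else None
        new_shifts = self.bond_shifts[keep_b] if len(self.bonds) else None
        serials = np.arange(1, int(mask.sum()) + 1) if renumber else self.serials[mask]
        return Structure(
            self.positions[mask],
            list(self.elements[mask]),
            names=list(self.names[mask]),
            residue_names=list(self.residue_names[mask]),
            residue_seqs=list(self.residue_seqs[mask]),
            chain_ids=list(self.chain_ids[mask]),
            serials=list(serials),
            occupancies=self.occupancies[mask],
            betas=self.betas[mask],
            charges=None if self.charges is None else self.charges[mask],
            bonds=new_bonds,
            bond_shifts=new_shifts,
            cell=self.cell,
        )

    @classmethod
    def from_atoms(
        cls,
        atoms: Sequence[AtomRecord],
        *,
        bonds: np.ndarray | None = None,
        bond_shifts: np.ndarray | None = None,
        cell: "TriclinicCell | None" = None,
    ) -> "Structure":
        return cls(
            np.array([a.position for a in atoms], dtype=float).reshape(-1, 3),
            [a.element for a in atoms],
            names=[a.name for a in atoms],
            residue_names=[a.residue_name for a in atoms],
            residue_seqs=[a.residue_seq for a in atoms],
            chain_ids=[a.chain_id for a in atoms],
            serials=[a.serial for a in atoms],
            occupancies=np.array([a.occupancy for a in atoms]),
            betas=np.array([a.beta for a in atoms]),
            charges=(
                np.array([a.charge if a.charge is not None else 0.0 for a in atoms])
                if any(a.charge is not None for a in atoms)
                else None
            ),
            bonds=bonds,
            bond_shifts=bond_shifts,
            cell=cell,
        )


def concatenate(parts: Sequence[Structure], cell: "TriclinicCell | None" = None) -> Structure:
    """Concatenate structures; bonds reindexed, serials renumbered from 1."""
    offs = np.cumsum([0] + [len(p) for p in parts[:-1]])
    bonds = (
        np.vstack([p.bonds + o for p, o in zip(parts, offs) if len(p.bonds)])
        if any(len(p.bonds) for p in parts)
        else None
    )
    shifts = (
        np.vstack([p.bond_shifts for p in parts if len(p.bonds)])
        if any(len(p.bonds) for p in parts)
        else None
    )
    n_tot = sum(len(p) for p in parts)
    charges = (
        np.concatenate([
            p.charges if p.charges is not None else np.zeros(len(p)) for p in parts
        ])
        if any(p.charges is not None for p in parts)
        else None
    )
    return Structure(
        np.vstack([p.positions for p in parts]),
        [e for p in parts for e in p.elements],
        names=[x for p in parts for x in p.names],
        residue_names=[x for p in parts for x in p.residue_names],
        residue_seqs=[x for p in parts for x in p.residue_seqs],
        chain_ids=[x for p in parts for x in p.chain_ids],
        serials=list(range(1, n_tot + 1)),
        occupancies=np.concatenate([p.occupancies for p in parts]),
        betas=np.concatenate([p.betas for p in parts]),
        charges=charges,
        bonds=bonds,
        bond_shifts=shifts,
        cell=cell if cell is not None else parts[0].cell,
    )
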