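"""Triclinic cell algebra: fractional transforms, periodic wrapping,
minimum-image distances, and super-cell replication.

Convention: the cell matrix ``H`` is lower-triangular with the **a** vector
along x and **b** in the xy-plane (the standard crystallographic
convention, shared by common visualization tools). Columns of ``H`` are the
lattice vectors, so cartesian = H · fractional. Fractional coordinates are
wrapped into the half-open interval [0, 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure import Structure, concatenate


@dataclass(frozen=True)
class TriclinicCell:
    """Lattice parameters (lengths Å, angles degrees) of a triclinic cell."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must be in (0, 180) degrees")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError("degenerate cell (non-positive volume)")

    @property
    def matrix(self) -> np.ndarray:
        """3×3 lower-triangular matrix whose columns are the lattice vectors."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cx = self.c * np.cos(be)
        cy = self.c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz_sq = self.c**2 - cx**2 - cy**2
        if cz_sq <= 0:
            raise ValueError("inconsistent cell angles (imaginary c_z)")
        return np.array(
            [
                [self.a, self.b * np.cos(ga), cx],
                [0.0, self.b * np.sin(ga), cy],
                [0.0, 0.0, np.sqrt(cz_sq)],
            ]
        )

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def volume(self) -> float:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos(al), np.cos(be), np.cos(ga)
        return float(
            self.a * self.b * self.c
            * np.sqrt(max(1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg, 0.0))
        )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def is_orthorhombic(self) -> bool:
        return all(abs(x - 90.0) < 1e-9 for x in (self.alpha, self.beta, self.gamma))

    @classmethod
    def from_matrix(cls, H: np.ndarray) -> "TriclinicCell":
        H = np.asarray(H, dtype=float)
        av, bv, cv = H[:, 0], H[:, 1], H[:, 2]
        a, b, c = (np.linalg.norm(v) for v in (av, bv, cv))
        alpha = np.degrees(np.arccos(np.clip(bv @ cv / (b * c), -1, 1)))
        beta = np.degrees(np.arccos(np.clip(av @ cv / (a * c), -1, 1)))
        gamma = np.degrees(np.arccos(np.clip(av @ bv / (a * b), -1, 1)))
        return cls(float(a), float(b), float(c), float(alpha), float(beta), float(gamma))

    @classmethod
    def cubic(cls, edge: float) -> "TriclinicCell":
        return cls(edge, edge, edge)

    @classmethod
    def orthorhombic(cls, lx: float, ly: float, lz: float) -> "TriclinicCell":
        return cls(lx, ly, lz)


def to_fractional(cell: TriclinicCell, positions: np.ndarray) -> np.ndarray:
    """Cartesian Å → fractional coordinates (vectorized over leading axes)."""
    return np.asarray(positions, dtype=float) @ cell.inverse.T


def to_cartesian(cell: TriclinicCell, fractional: np.ndarray) -> np.ndarray:
    return np.asarray(fractional, dtype=float) @ cell.matrix.T


def wrap(structure: Structure, mode: str = "atom") -> Structure:
    """Wrap a structure into its unit cell.

    mode="atom": every atom is translated so its fractional coordinates lie
    in [0, 1). mode="molecule": each bonded connected component is rigidly
    translated by one lattice vector so its geometric center lies in [0, 1);
    internal geometry is untouched.
    """
    if structure.cell is None:
        raise ValueError("wrap requires a structure with a cell")
    cell = structure.cell
    out = structure.copy()
    if mode == "atom":
        frac = to_fractional(cell, out.positions)
        out.positions = to_cartesian(cell, frac - np.floor(frac))
    elif mode == "molecule":
        from .topology import molecules  # deferred: topology depends on this module

        frac = to_fractional(cell, out.positions)
        for comp in molecules(structure):
            idx = np.fromiter(comp, dtype=int)
            center = frac[idx].mean(axis=0)
            out.positions[idx] = to_cartesian(cell, frac[idx] - np.floor(center))
    else:
        raise ValueError(f"unknown wrap mode {mode!r}")
    return out


_NEIGHBOR_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def min_image_vector(cell: TriclinicCell, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Shortest displacement q→p over the 27 neighbor images (vectorized)."""
    d = np.atleast_2d(np.asarray(p, float) - np.asarray(q, float))
    frac = to_fractional(cell, d)
    frac -= np.round(frac)
    base = to_cartesian(cell, frac)
    # round() is exact for orthorhombic cells; skewed cells need the 27-image check
    cand = base[:, None, :] + (_NEIGHBOR_SHIFTS @ cell.matrix.T)[None, :, :]
    best = np.argmin(np.einsum("ijk,ijk->ij", cand, cand), axis=1)
    out = cand[np.arange(len(cand)), best]
    return out[0] if np.ndim(p) == 1 and np.ndim(q) == 1 else out


def min_image_distance(cell: TriclinicCell, p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    v = min_image_vector(cell, p, q)
    return float(np.linalg.norm(v)) if v.ndim == 1 else np.linalg.norm(v, axis=-1)


def replicate(structure: Structure, nx: int, ny: int, nz: int) -> Structure:
    """Tile a periodic structure into an (nx, ny, nz) super-cell.

    Bonds are replicated within each image; periodic bonds are re-targeted to
    the neighboring image, and only bonds that leave the super-cell remain
    periodic (with the reduced image shift).
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("replication counts must be >= 1")
    if structure.cell is None:
        raise ValueError("replicate requires a structure with a cell")
    cell = structure.cell
    H = cell.matrix
    n = len(structure)
    reps = [(ix, iy, iz) for ix in range(nx) for iy in range(ny) for iz in range(nz)]
    image_index = {r: k for k, r in enumerate(reps)}
    parts = []
    for r in reps:
        img = structure.copy()
        img.positions = img.positions + H @ np.array(r, dtype=float)
        img.set_bonds(None)
        parts.append(img)
    counts = np.array([nx, ny, nz])
    new_bonds, new_shifts = [], []
    for (i, j), s in zip(structure.bonds, structure.bond_shifts):
        for r in reps:
            k_src = image_index[r]
            target = np.array(r) + s
            reduced, new_s = np.divmod(target, counts)[1], np.floor_divide(target, counts)
            k_dst = image_index[tuple(reduced)]
            new_bonds.append((k_src * n + i, k_dst * n + j))
            new_shifts.append(new_s)
    new_cell = TriclinicCell.from_matrix(H * np.array([nx, ny, nz])[None, :])
    out = concatenate(parts, cell=new_cell)
    if new_bonds:
        out.set_bonds(np.array(new_bonds), np.array(new_shifts))
    return out
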