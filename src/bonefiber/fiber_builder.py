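"""From a periodic fibril crystal to a fiber model with explicit
intra- and extra-fibrillar volumes.

The fibril unit cell is periodic in all three directions, so collagen
molecules are covalently bonded across the lateral (x, y) boundaries and no
room exists for an extra-fibrillar matrix. ``extract_nanofiber`` makes every
molecule whole by lattice translations in x and y only, yielding a bundle
that is periodic along the fiber axis (z) alone. ``build_fiber`` replicates
that nanofiber laterally on the crystal lattice vectors and embeds it in an
enlarged orthorhombic simulation box; the intra-fibrillar volume (IFV) is an
axis-aligned box around the collagen bundle, and the extra-fibrillar volume
(EFV) is the remainder of the simulation box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .cell_geometry import TriclinicCell, to_cartesian, to_fractional
from .structure import Structure, concatenate
from .topology import classify_periodic_bonds, crossing_counts, molecules


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned parallelepiped region, corners in Å."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    label: str = "SIMBOX"

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if not np.all(up > lo):
            raise ValueError(f"{self.label}: upper corner must exceed lower componentwise")

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        return np.all((p >= lo) & (p <= up), axis=1)

    def contains_box(self, other: "RegionBox") -> bool:
        return bool(
            np.all(np.asarray(other.lower) >= np.asarray(self.lower))
            and np.all(np.asarray(other.upper) <= np.asarray(self.upper))
        )


@dataclass
class FiberModel:
    """A laterally replicated nanofiber inside an orthorhombic simulation box."""

    structure: Structure
    ifv: RegionBox
    simbox: RegionBox
    provenance: dict[str, Any] = field(default_factory=dict)
    _molecule_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.simbox.contains_box(self.ifv):
            raise ValueError("IFV must lie inside the simulation box")
        if self.efv_volume <= 0:
            raise ValueError("EFV volume must be positive")

    @property
    def efv_volume(self) -> float:
        return self.simbox.volume - self.ifv.volume

    @property
    def molecule_ids(self) -> np.ndarray:
        """Per-atom molecule index (connected components of the bond graph)."""
        if self._molecule_ids is None:
            ids = np.empty(len(self.structure), dtype=int)
            for m, comp in enumerate(molecules(self.structure)):
                ids[comp] = m
            self._molecule_ids = ids
        return self._molecule_ids


class IrreducibleMoleculeError(ValueError):
    """A molecule winds around a lateral boundary and cannot be made whole."""


def extract_nanofiber(fibril: Structure) -> Structure:
    """Make every molecule x/y-contiguous by whole-lattice translations.

    Atoms are translated by integer combinations of the a and b lattice
    vectors only; bonds across the axial (z) boundary keep their periodic
    image shifts, so the result is periodic along z alone. Atom count, bond
    count, and all bond lengths are preserved exactly.
    """
    if fibril.cell is None:
        raise ValueError("extract_nanofiber requires a structure with a cell")
    if len(fibril.bonds) == 0:
        raise ValueError("extract_nanofiber requires bonds (infer or read them first)")
    cls = classify_periodic_bonds(fibril)
    n = len(fibril)
    adj: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n)]
    for c in cls:
        i, j = c.bond
        s = np.array(c.image_shift, dtype=int)
        adj[i].append((j, s))       # shift applied to j when walking i -> j
        adj[j].append((i, -s))
    t = np.zeros((n, 3), dtype=int)
    seen = np.zeros(n, dtype=bool)
    for comp_id, comp in enumerate(molecules(fibril)):
        seed = int(comp[0])
        seen[seed] = True
        stack = [seed]
        while stack:
            i = stack.pop()
            for j, s in adj[i]:
                cand = t[i] + s
                if not seen[j]:
                    t[j] = cand
                    seen[j] = True
                    stack.append(j)
                elif np.any(cand[:2] != t[j][:2]):
                    raise IrreducibleMoleculeError(
                        f"molecule {comp_id} (atoms {comp[0]}..{comp[-1]}) winds "
                        "around a lateral boundary and cannot be made x/y-contiguous"
                    )
    t_xy = t.copy()
    t_xy[:, 2] = 0
    out = fibril.copy()
    out.positions = fibril.positions + t_xy.astype(float) @ fibril.cell.matrix.T
    # residual shifts: s' = s - (t_j - t_i), zero in x and y by construction
    i_idx, j_idx = fibril.bonds[:, 0], fibril.bonds[:, 1]
    shifts = np.array([c.image_shift for c in cls], dtype=int)
    residual = shifts - (t_xy[j_idx] - t_xy[i_idx])
    assert np.all(residual[:, :2] == 0)
    out.set_bonds(fibril.bonds.copy(), residual)
    return out


def build_fiber(
    nanofiber: Structure,
    nx: int,
    ny: int,
    margins: tuple[float, float, float] = (14.0, 14.0, 0.5),
    *,
    ifv_percentile: float = 1.0,
    ifv_corners: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None,
) -> FiberModel:
    """Replicate a nanofiber laterally and embed it in a larger box.

    ``nx`` × ``ny`` copies are placed on the original a/b lattice vectors so
    the quasi-hexagonal packing of the crystal is preserved. The simulation
    box is the bounding box of the copies expanded by ``margins`` in x and y;
    its z length is the axial period of the cell, preserving z-periodicity.
    The IFV defaults to the percentile bounding box of the collagen atoms
    (``ifv_percentile``..100−``ifv_percentile``) and can be overridden with
    literal corners.
    """
    if nanofiber.cell is None:
        raise ValueError("build_fiber requires a nanofiber with a cell")
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    m = np.asarray(margins, dtype=float)
    if m[0] <= 0 or m[1] <= 0:
        raise ValueError("x and y margins must be positive (no EFV otherwise)")
    H = nanofiber.cell.matrix
    parts = []
    for ix in range(nx):
        for iy in range(ny):
            img = nanofiber.copy()
            img.positions = img.positions + H @ np.array([ix, iy, 0.0])
            img.set_bonds(None)
            parts.append(img)
    fiber = concatenate(parts)
    # per-copy bonds; axial periodic shifts survive unchanged
    nb = len(nanofiber)
    bonds = np.vstack([nanofiber.bonds + k * nb for k in range(nx * ny)])
    shifts = np.vstack([nanofiber.bond_shifts] * (nx * ny))
    fiber.set_bonds(bonds, shifts)

    lz = float(H[2, 2])  # axial repeat distance of the (possibly skewed) cell
    pos = fiber.positions
    lo_xy = pos[:, :2].min(axis=0) - m[:2]
    hi_xy = pos[:, :2].max(axis=0) + m[:2]
    z0 = float(pos[:, 2].min())
    simbox = RegionBox(
        (float(lo_xy[0]), float(lo_xy[1]), z0),
        (float(hi_xy[0]), float(hi_xy[1]), z0 + lz),
        label="SIMBOX",
    )
    fiber.cell = TriclinicCell.orthorhombic(
        float(hi_xy[0] - lo_xy[0]), float(hi_xy[1] - lo_xy[1]), lz
    )
    if ifv_corners is not None:
        ifv = RegionBox(ifv_corners[0], ifv_corners[1], label="IFV")
    else:
        p = float(ifv_percentile)
        lo = np.percentile(pos, p, axis=0)
        hi = np.percentile(pos, 100.0 - p, axis=0)
        lo = np.maximum(lo, simbox.lower)
        hi = np.minimum(hi, simbox.upper)
        ifv = RegionBox(tuple(lo), tuple(hi), label="IFV")
    if not simbox.contains_box(ifv):
        raise ValueError("IFV override corners fall outside the simulation box")
    provenance = {
        "nx": nx,
        "ny": ny,
        "margins": [float(v) for v in m],
        "ifv_rule": "corners" if ifv_corners is not None else f"percentile {ifv_percentile}",
        "n_atoms": len(fiber),
        "axial_period": lz,
    }
    return FiberModel(structure=fiber, ifv=ifv, simbox=simbox, provenance=provenance)


def cross_section_count(model: FiberModel, z: float, delta: float = 2.5) -> int:
    """Distinct molecules with at least one atom in the slab z ± delta.

    The slab is periodic along the fiber axis.
    """
    lo, hi = model.simbox.lower[2], model.simbox.upper[2]
    if not lo - delta <= z <= hi + delta:
        raise ValueError(f"z = {z} outside the simulation box [{lo}, {hi}]")
    lz = hi - lo
    dz = model.structure.positions[:, 2] - z
    dz -= np.round(dz / lz) * lz
    in_slab = np.abs(dz) <= delta
    if not np.any(in_slab):
        import logging

        logging.getLogger(__name__).warning("empty cross-section slab at z = %.2f", z)
        return 0
    return len(np.unique(model.molecule_ids[in_slab]))


def gap_overlap_profile(
    model: FiberModel, n_samples: int = 200, delta: float = 2.5
) -> tuple[np.ndarray, np.ndarray]:
    """Molecule-count profile along z; gaps are its minima, overlaps its maxima."""
    zs = np.linspace(model.simbox.lower[2], model.simbox.upper[2], n_samples, endpoint=False)
    counts = np.array([cross_section_count(model, float(z), delta) for z in zs])
    return zs, counts


def locate_gap_overlap(model: FiberModel, n_samples: int = 200) -> tuple[float, float]:
    """Representative (gap_z, overlap_z) found from the count profile."""
    zs, counts = gap_overlap_profile(model, n_samples)
    return float(zs[np.argmin(counts)]), float(zs[np.argmax(counts)])
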